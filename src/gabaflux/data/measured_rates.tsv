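condition	glucose	succinate	gaba	glutamate	acetate	growth_rate
neutral-2gl	1.806954	0.086198	0.008443	1.021887	0.306986	0.221086
acidic-2gl	1.201905	0.272554	0.177000	0.611939	0.000000	0.140696
acidic-4gl	1.8382	1.785084	0.2756	0.773662	0.000000	0.188196
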