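# reaction id -> pathway label for the toy_core_gaba fixture
GLCpts	glycolysis
PGI	glycolysis
PFK	glycolysis
FBA	glycolysis
GAPD	glycolysis
PYK	glycolysis
PDH	glycolysis
G6PDH2r	pentose phosphate pathway
GND	pentose phosphate pathway
TKTTAL	pentose phosphate pathway
CS	TCA cycle
ACONT	TCA cycle
ICDHyr	TCA cycle
AKGDH	TCA cycle
SUCOAS	TCA cycle
SUCDi	TCA cycle
FUM	TCA cycle
MDH	TCA cycle
ME2	TCA cycle
PPC	TCA cycle
ICL	TCA cycle
MALS	TCA cycle
PTAr	acetate fermentation
ACKr	acetate fermentation
ACt	acetate fermentation
GLUDy	GABA shunt
GLUDC	GABA shunt
ABTA	GABA shunt
SSALy	GABA shunt
GLUt	GABA shunt
ABUTt	GABA shunt
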