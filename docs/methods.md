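# Methods

This note documents the models, estimators and numerical choices behind
gabaflux, and what the synthetic fixtures do and do not establish.

## Scope and model assumptions

The pipeline infers intracellular fluxes for a batch-grown *E. coli*
production strain under the standard constraint-based assumptions:

* **Pseudo steady state.** Intracellular metabolite pools are balanced
  (S·v = 0) over the analysis window.  This is defensible only during
  balanced exponential growth, which is why the rate estimator restricts
  itself to the log phase.
* **Condition = rate vector.** Culture conditions (pH, medium composition)
  enter the model *only* through their measured exchange rates and growth
  rate.  No pH-dependent kinetics or regulation is modelled; two conditions
  that produced identical rates would be indistinguishable.
* **Knockouts are absolute.** A deleted gene silences every reaction whose
  GPR rule evaluates false, by pinning both bounds to zero.  No residual
  activity, no regulatory rerouting.

## Rate estimation

For X(t) = X₀e^{μt} and constant specific rate q (mmol gDCW⁻¹ h⁻¹),
dC/dt = q·X gives C(t) = C₀ + (q/μ)(X(t) − X₀): molar concentration is
linear in biomass concentration.  The estimator therefore fits

* μ as the least-squares slope of ln OD600 vs time inside the selected
  window (OD→biomass conversion cancels out of this fit);
* q = μ · slope of C (mmol/l) against X (gDCW/l), per species, signed by
  the slope (consumption negative).

The q = μ·dC/dX form is exact under exponential balanced growth and was
preferred over (ΔC/Δt)/X̄ because the two agree exactly only in that
regime and the generator produces that regime; with real, noisy data the
dC/dX regression additionally pools all in-window samples into one fit,
with the per-species R² reported as a diagnostic.

**Log-phase selection** maximises the ln-OD slope over contiguous windows
of a fixed width (default 4 h, matching typical annotated log phases of
3–5 h in this kind of batch run).  Candidate windows are anchored at every
sample time plus one flush with the profile end; ties break toward the
earliest start.  An exhaustive-scan oracle in the test suite checks the
implementation on randomized piecewise-exponential curves.

**Parameters.**

| parameter | default | units | note |
|---|---|---|---|
| biomass_factor | 0.36 | gDCW l⁻¹ per OD600 | OD-to-dry-weight conversion; common *E. coli* range 0.3–0.5. The measured-rate table bypasses it entirely. |
| molar masses | glucose 180.16, succinic acid 118.09, GABA 103.12, glutamate 147.13, acetic acid 60.05 | g/mol | overridable per call |
| window width | 4.0 | h | CLI flag `--window-hours` |

## Flux fitting

Three linear programs share one abstract problem description and a
pluggable backend:

* **FBA** — optimise c·v subject to S·v = 0, lb ≤ v ≤ ub.
* **pFBA** — stage 1 fixes c·v ≥ f·Z\* (default f = 1, no relaxation);
  stage 2 minimises Σ|v| via auxiliary variables tᵢ ≥ ±vᵢ.  Balanced
  internal cycles carry zero flux at the optimum because they add |v|
  without improving the objective.
* **LAD** — minimise Σ wᵢ(dᵢ⁺ + dᵢ⁻) with vᵢ − v̂ᵢ = dᵢ⁺ − dᵢ⁻, d ≥ 0.
  Default weights are 1 for all six references (the five exchanges and
  growth); nothing in the data argued for unequal weighting, and weights
  are exposed per reference.

**Condition simulation** defaults to *LAD-then-pFBA*: fit the six measured
values by LAD, pin the fitted values as hard bounds (±1e−9), then run pFBA
on growth.  This order lets mildly inconsistent measurements be
reconciled against the stoichiometry before a flux distribution is chosen;
the alternative *hard-pFBA* (pin the raw measurements) is provided and the
two provably coincide when the measurement vector is feasible — a test
asserts exactly that on the fixture.  Growth is treated as a sixth LAD
reference rather than a hard constraint, for the same
reconcile-before-commit reason.

**Numerics.** LP feasibility tolerance 1e−9; mass-balance acceptance
max|S·v| ≤ 1e−6; reporting rounded at 1e−6.  Backends: scipy `linprog`
(HiGHS, default) and optlang/GLPK.  The test suite solves FBA, pFBA and
LAD on 100+ randomized ≤12-reaction models with both backends and requires
objective agreement to 1e−6; per-reaction fluxes are *not* compared across
backends because vertex selection under degeneracy is solver-specific.
All reported per-reaction comparisons operate on the returned vertex.

## Flux-change classification

With ε = 1e−6 (zero tolerance) and threshold θ = 0.20:
both |v| < ε → `unchanged`; off→on → `de-novo`; on→off → `abolished`;
sign flip → `inverted`; otherwise r = (|v_B| − |v_A|)/|v_A| with
r > θ → `induced`, r < −θ → `suppressed`.  The denominator is the
*before*-condition magnitude; this makes the three-way part of the scheme
slightly asymmetric near the threshold (a −20% change back-computes to
+25%), which the property tests encode precisely.  The structural classes
exist because a plain induced/suppressed/unchanged scheme cannot express a
direction flip; `collapse_to_three_groups` folds them back
(inverted/de-novo → induced, abolished → suppressed) for three-colour
pathway maps.

## The fixture network

`toy_core_gaba` is a hand-curated stoichiometric model (40 metabolites, 46
reactions, 40 genes) covering glycolysis with PTS uptake, the oxidative
and non-oxidative PPP, the full TCA cycle with glyoxylate shunt, the
acetate branch (PTAr/ACKr), the GABA shunt (GLUDy → GLUDC → ABTA → SSALy)
and a lumped biomass drain.  Design rules:

* every internal reaction is elementally balanced (checked at build time);
  the biomass drain is the single exemption;
* respiration is lumped (NADH + ½O₂ + 2ADP + 2Pi → NAD + 2ATP, i.e. P/O=2,
  and a respiration-coupled succinate dehydrogenase) and a reversible
  transhydrogenase couples the NADH/NADPH pools, so energy and redox never
  dominate the carbon constraints;
* the biomass composition (9.1 mmol C per gDCW across G6P, R5P, PEP,
  pyruvate, acetyl-CoA, OAA, glutamate and succinyl-CoA, plus 20 ATP and
  3 NADPH) was chosen so that all three measured rate vectors are jointly
  feasible on the ΔAKGDH/ΔABTA strain — the build verifies this by a
  feasibility LP per condition and refuses to build otherwise;
* the succinyl-CoA requirement keeps succinyl-CoA synthetase active in the
  knockout (as in real cells, where lysine/peptidoglycan synthesis needs
  it); with AKGDH deleted it is the *only* succinyl-CoA source, so its
  direction cannot flip between conditions on this network — direction
  inversions of the kind genome-scale models can show require alternative
  succinyl-CoA routes that this fixture deliberately omits.  Inversion
  detection is therefore exercised on synthetic flux pairs rather than on
  the fixture comparison.

GPR rules use the conventional *E. coli* loci (AKGDH: `sucA and sucB and
lpdA`; ABTA: `gabT`; GLUDC: `gadA or gadB`; …) so the strain can be built
either by gene deletion or by direct reaction knockout; a test asserts the
two routes disable identical reaction sets.

## Synthetic profiles

Profiles are closed-form (no ODE integration): OD = X₀e^{μt} and
concentrations exactly linear in biomass, so the estimator has an analytic
target and noiseless recovery is tested at 1e−6 relative error.
Measurement error is multiplicative lognormal (mean 1, CV as configured)
applied per observation — concentrations and OD are positive quantities
with roughly proportional HPLC/plate-reader error — with a seeded
generator (identical seeds ⇒ bit-identical profiles).  Default truth
values are the three measured-rate rows; default grid hourly over 0–12 h;
initial OD 0.1; initial glucose 20 g/l and succinate 2 or 4 g/l, matching
the fermentation medium, products starting at 0.

What passing tests show: the estimators and solvers are correct on data
satisfying their own assumptions, and the full pipeline closes (measured
row → profile → estimator → flux fit) to ≤1e−4 relative error.  What they
do not show: robustness to lag/stationary-phase contamination of the
window, substrate depletion within the window, sampling sparser than
~5 points per window, or model misspecification — real batch data violate
all of these to some degree.

## Degenerate and edge inputs

* LAD with an infeasible reference vector returns the L1-closest feasible
  point (on a box this is clamping); residual > 0 flags the inconsistency.
* pFBA/LAD optima may be non-unique in flux space; classifications are
  computed on the returned vertex.  Cross-backend tests pin objectives,
  not vertices.
* Empty GPR ⇒ reaction always active.  Empty constraint set ⇒ model
  unchanged.  Windows with <3 samples, non-positive OD, unknown ids and
  unmapped species raise named errors rather than propagating NaNs.

## Known limitations

* Conditions interact only through their rate vectors; pH itself is never
  modelled (no proton exchange, no pH-dependent enzyme activity).
* The fixture's lumped respiration fixes P/O = 2; absolute ATP-linked
  fluxes on the toy network are therefore illustrative, not predictive.
* No flux-variability analysis: a reaction classified `induced` on the
  returned vertex may admit alternate optima with a different class.  The
  comparator's optional degeneracy flag re-solves with the flux pinned to
  the other condition's value but is off by default.
* Genome-scale models load and solve through the same code paths, but all
  quantitative guarantees in the test suite are stated on the fixture.
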