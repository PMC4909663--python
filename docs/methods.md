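# Methods

## The mechanical model

The respiratory system is a set of parallel compartments, each with
compliance `C_i` (L/cmH₂O), an inspiratory Ohmic resistance `R_i`
(cmH₂O·s/L) and a volume share `s_i` (Σ s_i = 1). Compartment volume `V_i`
is measured above the relaxation volume at zero airway pressure, so alveolar
pressure is `Palv_i = V_i / C_i`.

**Inspiration** (volume-controlled, constant flow `V̇ = VT/Ti`) delivers
`s_i·V̇` to each compartment. Airway pressure is the share-weighted sum of
elastic recoil and resistive drop; with the default allocation
`R_i = R_rs / s_i` the resistive term seen at the airway opening equals the
series resistance `R_rs`, so the bedside formula `(Ppk − Pplat)/V̇`
recovers the generating value.

**Expiration** is passive into a circuit held at the applied PEEP `P`. A
non-flow-limited compartment empties Ohmically,
`q_i = (Palv_i − P)/R_exp,i`, an exponential with time constant
`τ_i = R_exp,i·C_i` toward the equilibrium `V_i = C_i·P`. A flow-limited
compartment expires at

    q_i = min( (Palv_i − P)/R_exp,i ,  k_i · V_i )

where `k_i` is the slope of its maximal-expiratory-flow envelope. This is
the minimal one-parameter description of wave-speed/Starling behaviour:
wherever the envelope binds, flow depends on volume alone and raising or
lowering downstream pressure changes nothing. The envelope never limits
inflow, and envelope flow vanishes at the relaxation volume (airway
closure), so flow-limited units cannot be squeezed below it.

`expiratory_resistance` (default: equal to `resistance`) exists because one
Ohmic constant cannot simultaneously represent the inspiratory resistance
measured from `Ppk − Pplat` and the effective expiratory emptying rate:
dynamic airway narrowing makes real expiratory resistance larger in
obstructed patients (the generator uses ratios around 2 for slow open
lungs), while in flow-limited regions the envelope does the limiting and the
residual Ohmic pathway is fast. For a flow-limited compartment this
parameter also fixes where the envelope stops binding: under applied PEEP
the envelope governs down to `V* = C·P/(1 − k·R_exp·C)`, so complete
absorption of a PEEP `P < auto-PEEP` requires `k·R_exp·C ≤ 1 − P/aP`. The
package's "pure flow limitation" invariants hold in that regime; with larger
`k·R_exp·C` a nominally flow-limited unit is partially re-inflated near
end-expiration, which is itself a physiologically sensible intermediate
behaviour.

### Integration

Every phase is linear (or piecewise linear with at most one regime switch
per expiration), so the state is advanced by exact exponential maps and the
switch times are computed analytically. The sampling grid (default 100 Hz)
only determines what is *recorded*; it never affects the trajectory, and the
closed-form steady state

    auto-PEEP = (VT_i / C_i) / (exp(r·Te) − 1),   r = 1/(R_exp·C)  or  k

is reproduced to machine precision. A `StepSizeError` is raised when the
sample interval exceeds the smallest time constant, since measurements made
on such a grid would be unreliable.

**Occlusions** clamp airway flow to zero; compartments then redistribute gas
through their airway resistances plus a fixed collateral pathway (default
25 cmH₂O·s/L), a linear system solved by eigendecomposition. The occluded
plateau converges to the compliance-weighted mean alveolar pressure
`P* = Σ C_i·Palv_i / Σ C_i = Σ V_i / Σ C_i` regardless of the conductances;
the collateral path only sets the equilibration speed (well within the 4-s
maneuver at defaults). Envelope limitation is ignored during occlusions: the
redistributing flows (< 0.1 L/s) stay below the envelope at the volumes
involved.

**Sensor noise** is additive Gaussian on pressure only (sd 0.2 cmH₂O,
matching the stated 1-cmH₂O accuracy of bedside pressure readings); flow
noise is off by default. Plateau pressures are means over the final 0.5 s of
an occlusion; non-convergence is flagged when the fitted end slope exceeds
both 0.05 cmH₂O/s and three times its own standard error (the second
condition stops sensor noise from masquerading as a residual slope).

### Measurement conventions

* `Ppk` is the maximum airway pressure over the inspiratory phase of the
  breath immediately preceding each end-inspiratory occlusion.
* The triplicate repeatability rule is applied to Ppk, Pplat and PEEPtot
  separately; a patient is valid only if all three pass. The 10 % is of the
  triplicate mean and the comparison is inclusive at the boundary.
* Applied PEEP is `round(0.8 × auto-PEEP)` to the nearest integer cmH₂O,
  ties rounding up — ventilators take integer settings.
* ΔPEEPtot ≤ 1 cmH₂O (including decreases) is *complete* absorption;
  `Δ < 0.5 × applied` is *high*; exactly 50 % is *low* (the "less than" is
  strict).

## Flow-limitation detection

Passive and abdominal-compression expirations are compared as flow–volume
loops on a common expired-volume grid (200 points). Compression adds a
constant `Δ` (default 10 cmH₂O) to every alveolar pressure from the moment
insufflation ends. A grid point is superimposed when
`|q_c − q_p| ≤ max(0.02 L/s, 0.05·q_p)`, and a maneuver is positive when a
*contiguous* superimposed run covers ≥ 20 % of the overlapping volume range
(scattered crossings do not superimpose visually). A patient is flow limited
only if all three maneuvers are positive. The tolerances operationalize a
criterion that is visual at the bedside; they are config-exposed and were
fixed before any cohort-level evaluation.

A derived property worth stating explicitly: in a *mixed* lung (one open,
one flow-limited compartment of comparable compliance) the total-flow loops
do **not** superimpose anywhere, even though the flow-limited branch is
envelope-bound throughout. Compression makes the open compartment expel an
extra `C_open·Δ` (≈ 0.26 L at defaults), so at matched *total* expired
volume the flow-limited compartment is at a higher volume — the whole
compressed loop sits above the passive one. Detection by superposition
therefore identifies lungs whose expired flow is envelope-governed
throughout (all compartments limited), and the generator encodes bedside
flow limitation that way. The intermediate absorber spectrum is produced by
*heterogeneity of trapped pressures among flow-limited units*: applied PEEP
re-inflates only the units whose own auto-PEEP it exceeds, so
`ΔPEEPtot ≈ Σ_i w_i · max(0, P − aP_i)`, reproducing behaviour anywhere
between the two textbook extremes.

## The synthetic cohort

Each patient is drawn from one of four mechanistic phenotypes with
probabilities 0.33 / 0.21 / 0.07 / 0.39:

| phenotype | lungs | emergent label |
|---|---|---|
| `complete` | two flow-limited compartments, auto-PEEPs within ±10 % of the target | complete |
| `high` | two flow-limited compartments, one below the predicted applied PEEP (target Δ between 22 % and 45 % of applied) | high |
| `low_fl` | 80/20 shares: a large nearly-open flow-limited region plus a small region with very high trapped pressure (target Δ 55–70 %) | low |
| `low_nonfl` | one Ohmic compartment | low |

This makes 61 % of patients flow limited and lets every label emerge from
the simulated protocol. Envelope slopes come from the closed form
`k = ln(1 + VT_i/(C_i·aP))/Te`; expiratory Ohmic resistances are set small
enough that the envelope binds where the phenotype requires it (see above).
Class-conditional covariates (age, sex, BMI, chronic/acute pulmonary
disease, smoking, PaO₂/FiO₂, position) reproduce the published per-class
marginals; respiratory rate is N(16, 3) /min for complete absorbers and
N(22, 4) for everyone else, rounded to integers. Total auto-PEEP targets are
truncated normals ≥ 5.2 cmH₂O (enrollment requires ≥ 5 measured), 8 ± 2.5
for absorbers and 5.6 ± 1 for the low classes.

What the generator does *not* emulate: spontaneous breathing or expiratory
muscle activity, airway recruitment or PEEP-dependent resistance, gas
exchange, measurement-session drift (triplicates differ only by sensor
noise, so the validation rule almost never excludes a synthetic patient),
and non-flow-limited complete absorbers (one existed in the real cohort;
in this model an open compartment always transmits applied PEEP in full, so
such a patient can only arise from measurement error). Passing tests
therefore demonstrate internal consistency of the mechanism and pipeline,
not clinical performance on real waveforms.

## Statistical pipeline

* Univariate logistic screen over the a-priori candidate list, Wald p-values
  with a likelihood-ratio fallback whenever (quasi-)separation is detected
  (empty outcome cell for a binary covariate, |coef| > 8, or SE > 10).
  Because all synthetic complete absorbers are flow limited, the flow-
  limitation covariate is quasi-separated by construction — exactly as the
  original near-separated odds ratio (18, CI 1.7–476) suggests for the real
  data.
* VIF pruning at threshold 5, recomputed after each removal, highest first,
  never removing the last covariate. Exact collinearity gives several
  infinite VIFs; ties resolve toward dropping the covariate listed later in
  the candidate ordering, which keeps respiratory rate over expiratory time
  and minute ventilation (its deterministic functions). With sampled data
  the covariate with the genuinely largest VIF goes first, whichever it is.
* The respiratory-rate threshold maximizes Youden's J over midpoints of
  consecutive observed rates, ties toward the lower threshold.
* Overoptimism correction: stratified tenfold CV, corrected AUROC from the
  pooled out-of-fold predictions (per-fold averaging selectable); the RR
  threshold is re-chosen inside each training fold by default. CI by
  stratified bootstrap over patients (2000 replicates). Calibration MAE
  compares out-of-fold predictions with a smoothed observed-frequency curve:
  lowess (it = 0, adaptive span) when predictions are continuous, exact
  grouping when the score is discrete; a 10-bin alternative is selectable.
* Diagnostic metrics use exact Clopper–Pearson intervals; a zero margin
  yields NaN rather than an error.
* Multinomial fits use the low-absorber class as reference; a singular
  Hessian under separation reports estimates without standard errors.
* No multiple-testing correction beyond the α = 0.05 screen, mirroring the
  original analysis rather than improving it.

## Problem sizes and numerical defaults

Simulations run at 100 Hz. The acceptance script uses one 200-patient cohort
for the pipeline quantities and 500 noiseless patients for detector
fidelity; the test suite checks pipeline recovery over 20 seeds at n = 200
(60 seeds for the threshold's in-band proportion, whose sampling
distribution is wide enough that 20 replicates estimate it poorly). The
closed-form auto-PEEP oracle is checked over R ∈ {5,10,20,30} cmH₂O·s/L,
C ∈ {0.03,0.05,0.1} L/cmH₂O, Te ∈ {0.75,1.5,3} s.

## Known limitations

* Passive ventilation only; nothing here generalizes to actively breathing
  patients.
* The flow-limitation envelope is linear in volume; real maximal-flow curves
  are convex, which would change loop shapes but not the superposition
  logic.
* Compression is a constant pressure step; real abdominal compression has a
  rise time and a hand-dependent magnitude, both unquantified at the
  bedside.
* Single-step PEEP titration (80 % of auto-PEEP) only; some patients absorb
  PEEP completely only at lower fractions.
* Measured resistance is inspiratory; expiratory resistance is a modelling
  device, not an output claimed to match bedside measurements.
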