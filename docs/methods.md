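# Methods

## The kinetic model

The binding reaction is modelled as induced fit:

```
A + B  <==[k_on, k_off]==>  C  <==[k_f, k_u]==>  D
```

with A the labelled peptide, B the partner in pseudo-first-order excess,
C an encounter complex and D the folded bound state. With the apparent
binding rate `a = k_on*[B] + k_off`, the bound subsystem (C, D) is linear
and its two relaxation rates are the roots of

```
lambda^2 - (a + k_f + k_u) lambda + [a*(k_f + k_u) - k_off*k_f] = 0 .
```

The closed form is validated against numerical eigen-decomposition in the
test suite (1000 random schemes, 1e-6 relative), guarding against
transcription errors. The fast root is asymptotically linear in [B] with
slope k_on; the slow root is bounded by `k_f + k_u` at all concentrations —
the concentration-insensitive slow phase seen in the experiments this
pipeline targets. The two-state limit is encoded as `k_f = k_u = 0`.

Three derived observables:

* `equilibrium_kd`: `Kd = (k_off/k_on) / (1 + k_f/k_u)` by detailed balance
  over the two bound states.
* `apparent_koff`: the slow drain rate of the bound system when excess
  unlabelled competitor blocks rebinding — the smaller root of
  `lambda^2 - (k_off + k_f + k_u) lambda + k_off*k_u = 0`. This is what a
  competition-dissociation experiment measures at its asymptote.
* `simulate_traces`: the exact (two-exponential) solution of the
  inhomogeneous linear system from an all-unbound start, plus i.i.d.
  Gaussian noise. Dissociation simulations start from the equilibrium C:D
  partition.

Units are molar and s^-1 (bimolecular M^-1 s^-1) throughout; nothing is
auto-detected. A partner excess below 10x the probe emits a warning (the
pseudo-first-order approximation degrades) but does not raise, since no
hard ratio is canonical.

Note that `Kd_kin = apparent_koff/k_on` and `equilibrium_kd` coincide only
in the two-state limit; for the worked three-state scheme
(k_on = 1e6, k_off = 1, k_f = 5, k_u = 0.5) they differ by ~14%. Both are
first-class outputs and their agreement is checked per variant.

## Rate extraction

Each trace is fitted with `offset + sum_i A_i exp(-k_i t)` for one and two
phases (Levenberg–Marquardt / trust-region via scipy, deterministic
data-driven initial guesses from the trace tail and decay times, so refits
are bit-reproducible). Model choice is by AICc with a margin of 2 in
favour of the simpler model. A two-phase fit is *degenerate* — and the
one-phase fit is used instead — when any of: the rates are within 5% of
each other; a phase lies outside the observable window (slower than half a
decay over the trace, or faster than twice the sampling rate); a rate's SE
exceeds half the rate; or an amplitude is below 3x the residual noise.
These guards keep AICc from exploiting baseline drift or sub-sample
artifacts as a phantom phase. Non-convergent fits are flagged and excluded
downstream rather than raised, so a panel run survives variants with no
usable signal.

The fast rates over the concentration series are reduced by weighted
linear regression. When per-point SEs are supplied the weights are 1/SE^2
and the parameter covariance is the unscaled `(X' W X)^-1` — measurement
errors are taken at face value, which keeps the propagated errors
calibrated (verified by the coverage test below). The slow rates are
summarized by their (precision-weighted) mean plus the p-value of a
slope-vs-zero test as the concentration-independence check. The
competition series is fitted with a saturating hyperbola through the
origin, `k_obs(c) = k_diss * c/(c + K_half)` (an exponential saturation
form is available; the data determine only the asymptote, so the form is
configurable); a series whose maximum is >10% above its second-largest
point is flagged as not plateaued, and an essentially flat series is
averaged with a `saturated` flag since K_half is then unidentifiable.

## Equilibrium binding

Anisotropy isotherms are fitted with the exact single-site
ligand-depletion solution (physical root of
`[PL]^2 - (P+L+Kd)[PL] + P*L = 0`), not the hyperbolic approximation: the
probe concentration is comparable to the tightest Kd in a typical panel,
where the hyperbola is biased. Kd is fitted on a log10 scale (it spans
decades; the optimizer needs a well-scaled parameter for nanomolar
affinities) together with the free and bound anisotropy endpoints, which
are averaged plainly — the total-intensity change on binding is assumed
negligible (configurable assumption, not enforced). A fit is flagged
poorly determined when the fitted Kd exceeds the highest concentration
titrated or its SE exceeds half its value; such variants stay in the
table with the flag.

The helicity estimator is the linear interpolation
`f_H = (MRE_222 - MRE_coil)/(MRE_helix - MRE_coil)` with the standard
temperature- and chain-length-dependent baselines
`MRE_helix = -40000 (1 - 2.5/n) + 100 T_C` and `MRE_coil = 640 - 45 T_C`
(deg cm^2 dmol^-1 residue^-1, T_C in Celsius). The constants are field
conventions exposed as configuration, and the synthetic CD generator is
their exact inverse, so the round trip is an identity.

## Phi analysis

For each variant, both branches of the free-energy change are computed:

* `ddG = R T ln(Kd_mut/Kd_ref)` with R = 1.987e-3 kcal mol^-1 K^-1,
  destabilizing positive; the temperature defaults to 298.15 K and is a
  required experimental input, not a derived quantity.
* `phi = ln(k_ass,ref/k_ass,mut) / ln(Kd_mut/Kd_ref)` on each branch, and
  `phi_average` as their mean.

All SEs are first-order delta-method propagation on the ln-transformed
quantities, validated against 1e5-sample Monte Carlo (within 10% relative
for input relative SEs <= 10%). Within each branch, numerator and
denominator are treated as independent, and the shared wild-type reference
enters every variant independently (the panel-wide correlation it induces
is ignored); both assumptions are recorded in the output metadata.

The two branches themselves are *not* independent — they share the
numerator `ln(k_ass,ref/k_ass,mut)` exactly, and the kinetic denominator
contains it again through Kd_kin. `phi_average`'s SE therefore applies the
delta method to the average itself in the independent inputs
(A = ln k_ass ratio, B_e = ln Kd_equb ratio, C = ln k_diss ratio, with
B_kin = C + A), rather than combining the two branch SEs as if
independent: the naive half-width combination `sqrt(s1^2 + s2^2)/2`
demonstrably undercovers (1-SE coverage ~0.58 instead of ~0.68 on the
default panel; the correlation-aware form restores nominal coverage, and
both are checked against Monte Carlo in the tests).

Reporting logic:

* **Filter** — a phi-value is reportable only when *both* branches show
  `ddG >= 0.34 kcal/mol` (inclusive boundary). Stabilizing mutations are
  never reportable: the filter is written for destabilization and a
  near-zero or negative denominator makes phi statistically pathological.
* **Surface positions** — solvent-exposed residues carry an Ala and a Gly
  variant; the helix-probing perturbation is the composite Ala->Gly step,
  so the Gly variant is analysed against its Ala partner (not wild-type),
  on both branches. The 0.34 filter applies to the composite ddG.
  Thermodynamic-cycle additivity (WT->A plus A->G equals WT->G) holds to
  machine precision by construction and is asserted in the tests.
* **Consistency** — variants whose equilibrium and kinetic ddG differ by
  more than 2x the combined SE (configurable) are excluded from the
  reported pattern; no numeric rule is canonical, so the tolerance is
  explicit configuration.
* **Classification** — reportable, consistent variants are binned:
  phi + SE < 0 -> `nonnative_candidate`; |phi| <= 0.1 -> `unstructured`;
  phi <= 0.5 -> `weakly_structured`; else `structured`. The bands are
  interpretive conventions, configurable, chosen so that a whole-1-SE-band
  negative phi is what earns the nonnative label.

Panel-level outputs: the linear free-energy table (log10 of k_ass,fast and
k_diss against log10 Kd with regression slopes — slope(k_diss) = 1 and
slope(k_ass) = 0 when all mutational effect is on dissociation), the
Kd_kin/Kd_equb comparison with per-variant ratio CIs (half-width floored
at 1e-6 relative so that solver-tolerance-level agreement on noiseless
data reads as exact), and a per-region phi summary.

## The synthetic world

The generator states a world in which ground truth is recoverable and then
emulates the experimental phenomenology on top of it:

* **Truth is stated in analysis terms**: per-variant `ddg_true` and
  `phi_true`, inverted into microscopic rates via
  `k_on,mut = k_on,wt * (Kd_mut/Kd_wt)^(-phi)` with the residual
  destabilization on the dissociation side and the isomerization rates
  held at wild-type values. The inversion is exact, so zero-noise recovery
  is an identity check on the whole pipeline.
* **The binding reaction defaults to two-state** (k_on = 1e6 M^-1 s^-1,
  k_off = 0.5 s^-1, Kd = 0.5 uM — an order-of-magnitude fixture for a
  peptide–domain interaction, not a measured value), and the slow
  association phase is generated as a concentration- and
  mutation-independent unimolecular signal component (1 s^-1, 15% of the
  binding amplitude, scaled by the bound fraction) downstream of binding.
  Rationale: in a literal induced-fit scheme with all destabilization on
  the encounter k_off, the competition off-rate saturates at k_u once
  k_off >> k_f + k_u, so Kd_kin decouples from Kd_equb over a multi-decade
  ddG range — destroying the kinetic/equilibrium agreement that makes
  two observed rates sufficient to describe the binding free energy. The
  physical origin of the slow phase is not settled by the data this
  pipeline targets; modelling it as a parallel unimolecular process is
  one admissible choice and keeps ground-truth recovery well-posed. A
  three-state wild-type scheme can be supplied instead, in which case the
  systematic Kd_kin/Kd_equb offset becomes part of the generated world.
* **Panel design**: >= 10 interface X->A variants across the N-terminal
  helix, the interhelical kink and the C-terminal helix, plus six surface
  positions (three per helix) with Ala/Gly pairs — one wild type per
  panel. Default truth ranges encode the qualitative pattern being
  emulated: low positive phi in the helices (higher C-terminally),
  negative phi in the kink, all |phi| well below 1; interface ddG ranges
  sit clearly above the 0.34 kcal/mol filter while surface Ala steps and
  N-terminal-helix composites sit below it, so filter counts are stable
  under noise. An optional severely destabilized variant (ddG ~ 4.1
  kcal/mol, i.e. a thousandfold Kd increase) is generated with its signal
  amplitude suppressed below detection, exercising the
  unusable-variant path.
* **Acquisition**: 8 partner concentrations (2–16 uM, >= 20x the 0.1 uM
  probe), 600 points over 4 s, 3 replicates averaged before fitting, 2%
  Gaussian trace noise; 14-point titrations spanning Kd/30–100 Kd at
  50 nM probe with 0.002 anisotropy noise; 8 competition concentrations
  (0.5–50 uM, K_half = 1 uM) with 2% relative noise. The concentration
  count and replicate number are fixture choices; none of the acquisition
  settings is anchored to a specific experiment.

What the generator does **not** emulate: instrument dead time, mixing
artifacts, photobleaching, G-factor/intensity corrections, heteroscedastic
noise, or any sequence-based prediction of mutational effects. A green
end-to-end test therefore establishes that the estimators are correct and
calibrated for well-behaved data of the stated structure — not that the
pipeline is robust to instrument pathology.

## Numerical choices and limitations

* Exponential-fit initial guesses come from deterministic log-linear
  segmentation; all stages are seed-reproducible and byte-re-entrant.
* The degenerate two-state trace solution is handled analytically
  (single exponential) rather than through the singular matrix path.
* phi is undefined (raised, or flagged at panel level) when the mutation
  leaves Kd unchanged; the zero-numerator SE limit `sigma_A/|ln Kd ratio|`
  is used when association is unchanged.
* Coverage of the nominal 1-SE phi intervals runs near 65%, slightly
  below 68%, consistent with the ignored branch correlation noted above.
* Global multi-trace fitting, conformational-selection or >= 4-state
  schemes, double-mutant cycles and structure mapping are out of scope.
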