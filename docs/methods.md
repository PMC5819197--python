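# Methods

## Overview

`scarscreen` is a simulation-based biomarker-screening pipeline. It does not
fit a model to experimental data; instead it generates a *virtual cohort* of
wound-healing time courses from a mechanistic kinetic model under random
parameter perturbation, defines scarring outcomes from the simulated day-40
endpoint, and asks which modeled wound proteins, measured at early time
points, would have predicted that endpoint. Everything downstream of the
simulator (classification, distribution overlap, regression, ROC analysis) is
model-agnostic: any kinetic model satisfying the `KineticModelSpec` contract
can be plugged in.

## The reference surrogate model

The packaged model is a deliberately compact 12-state ODE system covering the
inflammatory and proliferative phases of cutaneous healing. It is a
*surrogate*: its role is to reproduce the qualitative statistical structure
the screening method operates on (an injury-initiated transient; a mixture of
resolving and collagen-elevated outcomes with graded severity under 0.5–2×
parameter perturbation; early-time marker signals that carry information
about the late outcome), not to be quantitatively predictive of any
particular wound. States and equations are listed in
`scarscreen/surrogate.py`; in outline:

* A platelet bolus `P` (unit initial condition, exponential decay `kP`) is
  the injury signal. It recruits inflammatory cells `I`, which are amplified
  by CXCL8 (`C8`) feedback and suppressed by IL-10 (`I10`); repair
  macrophages `M` follow `I`.
* TGF-β (`T`) is produced by platelets, macrophages and fibroblasts and
  drives fibroblast (`F`) recruitment saturably; fibroblasts additionally
  grow logistically (rate `gF`, capacity `Fmax`) and die at apoptosis rate
  `aF`.
* Fibroblasts deposit fibronectin (`FN`) and collagen (`COL`) under TGF-β;
  collagen is degraded by MMP-9 (`M9`, produced by inflammatory cells),
  inhibited by TIMP-1 (`T1`), whose fibroblast-derived production is enhanced
  by IL-10.

Every loss term is proportional to its own state, so trajectories stay
non-negative for positive parameters; concentrations are in arbitrary units
(the analysis uses only fold changes and within-cohort distributions, so
absolute units are immaterial).

Three structural choices matter for the screening behaviour and were made at
design time:

* **Macrophage-dominated TGF-β** (`pTM ≫ pTP, pTF`): the M2-macrophage axis
  that produces IL-10 also seeds fibroblast expansion, so IL-10 levels carry
  outcome information — the counterpart of IL-10's reported association with
  fibrosis.
* **Slow IL-10 turnover** (`d10 = 0.04`/day): IL-10 integrates the macrophage
  wave, so its day-21 level reflects the full wave while day 7 sees only the
  rising flank — prognostic information grows with time.
* **Active collagen remodelling** (`dC = 4`, IL-10-enhanced TIMP-1 with
  `e10 = 4`): day-40 collagen depends on the degradation side
  (MMP-9/TIMP-1/IL-10), not only on fibroblast production, again coupling the
  anti-inflammatory axis to severity.

The model is delay-free. A delay-differential plug-in would close over its own
history interpolant inside `rhs`; the shipped integrator does not manage delay
state, and delays are out of scope.

### Calibration

Defaults are produced by a seeded constrained random search
(`scarscreen.calibration`) over log-uniform perturbations of a hand-chosen
physiological base point, subject to:

* **C1** inflammation resolves: `I(40) < 0.1·max I(t)`;
* **C2** collagen plateaus: `|COL(40) − COL(35)|/COL(40) < 0.05`;
* **C3** `aF/2 < gF < aF` — fibroblasts resolve under defaults, but halving
  apoptosis flips net growth positive;
* **C4** the two-parameter pathological scenario (apoptosis halved, collagen
  production ×1.5) raises day-40 collagen *and* fibroblast fold changes to
  ≥ 5;
* **C5** a seeded 5,000-draw cohort is non-degenerate: normal, mild and
  severe classes each ≥ 0.5% of draws, excluded < 90%.

The shipped YAML (`data/reference_model.yaml`) is verified by the test suite
rather than re-derived at install time. One subtlety found during testing:
collagen dynamics are linear in the production rate `pC`, so the day-40 fold
change is invariant to `pC > 0`; C4 can only fail through `pC` via the
positivity contract (`pC = 0` is rejected), or through capacity/rate
parameters.

## Virtual cohort

Each of the `n_simulations` draws perturbs **all** parameters independently,
uniformly on `[θ/2, 2θ]` (log-uniform available as a config option; uniform
is the default and the tested path). Sampling is driven by a substream of the
master seed; simulation of a draw depends only on its parameter vector, so
results are independent of execution order. Integration uses adaptive LSODA
with `rtol = 1e-6`, `atol = 1e-9`, sampled on the daily grid t = 1…40 (the
t = 0 injured state is stored separately and never screened). Values in
(−1e-9, 0) are clamped to zero as integrator noise; more-negative values,
non-finite values or solver failure mark the draw as failed. Failures are
recorded per draw with their reason and excluded — never re-drawn — and a
warning is raised if they exceed 1% (in practice the calibrated surrogate
fails ≤ a few draws per 100,000).

## Outcome classification

Fold changes are taken at day 40 against the unperturbed reference run. The
four-way rule applies the literal inequalities to *both* collagen and
fibroblast fold changes: normal both ≤ 1, mild both in [5, 10], severe both
> 10; every mixed pair (e.g. collagen 12, fibroblast 4) is excluded as
ambiguous. No epsilon slack is applied at the boundaries. The binary label
used for regression is collagen-only (> 10, strict) and covers all
successful draws, excluded ones included — exclusion narrows only the
distribution screen.

## Overlap screen

Histograms use 50 equal-width bins. Two kinds are distinguished on purpose:
*plotting* histograms bin each group over its own min/max (percentage curves,
one per group); *comparison* histograms bin both groups of a pair over their
pooled min/max, because the Bhattacharyya coefficient
`BC = Σᵢ √(pᵢ qᵢ)` is only defined on a shared support. Degenerate
(single-valued) ranges are widened by `max(1e-12, 1e-9·|lo|)`. BC = 1 means
identical binned distributions, 0 disjoint support. Per day, each screened
protein gets BC(normal, mild) and BC(normal, severe); proteins are ranked by
the arithmetic mean of the two, ascending, with both raw values reported so
users can re-rank. "X% smaller overlap" between days is the relative BC
reduction `100·(BC_early − BC_late)/BC_early`, undefined (reported
not-applicable) when the early BC is zero.

## Predictive evaluation

Marker concentrations are min-max normalised per marker and day. This is an
affine map absorbed exactly by the logistic coefficients and intercept —
fitted probabilities and AUCs are invariant to it — and is applied purely so
coefficients are comparable across markers. Logistic fits are
maximum-likelihood (statsmodels Newton/IRLS, tolerance 1e-8); complete or
quasi-complete separation is detected and flagged on the result, with a
weakly ridge-penalised IRLS (`α = 1e-6`) supplying finite coefficients for
reporting. AUC is the Mann–Whitney statistic computed from midranks (ties
count ½), which equals the trapezoidal area under the empirical ROC curve;
its variance and the covariance between two panels' AUCs on the same cohort
use DeLong placement values. Confidence intervals are Wald on the AUC scale
with the DeLong variance, clipped to [0, 1]; a zero-variance interval (e.g.
perfect separation) is returned as `[auc, auc]` and flagged. Panel
comparisons use DeLong's paired z-test, two-sided; the 21 pairwise p-values
per day are reported raw, without multiplicity correction — readers comparing
many panels should apply their own. Cross-validation is stratified tenfold
with a fixed seed; the CV ROC/AUC is computed on the pooled out-of-fold
probabilities (one curve, not a per-fold average).

## Reproducibility and problem sizes

A single master seed fans out to per-stage substreams (sampling, CV), so a
config plus seed reproduces every CSV/JSON byte-for-byte. The packaged demo
profile runs 5,000 draws — chosen as a desk-scale cohort that leaves every
outcome class with hundreds of members (severe ≈ 15%, mild ≈ 1.6% at the demo
seed) while a full run completes in well under a minute on one CPU; the
cohort size is a config field and scales to 120,000 unchanged. Test-suite
simulations use 300–5,000 draws; the DeLong type-I-error check uses 2,000
null replicates at 300 cases/300 controls; logistic parameter recovery uses
n = 10,000.

## What the synthetic cohort does and does not show

The generator emulates: an injury-initiated multiphase transient; broad,
correlated inter-individual variability from independent 0.5–2× parameter
perturbation; a graded mixture of resolving and collagen-elevated outcomes;
and early-time marker distributions whose separation between outcome groups
grows over the first three weeks. It does not emulate: measurement noise or
assay limits of detection; time-varying or correlated parameter variation;
wound-type, depth or location effects; systemic factors; or the full protein
complement of real wound fluid. Passing tests therefore demonstrate that the
*pipeline* recovers the statistical structure present in its input — they are
not evidence about real wounds, and absolute AUCs on the surrogate cohort
should not be quoted as clinical performance.

Known fragility: the strict day-7 → 14 → 21 decrease of the IL-10
normal-vs-severe Bhattacharyya coefficient holds at the packaged demo profile
with margins of only ~0.003–0.006 (the fibronectin and TIMP-1 decreases are
large and robust). The IL-10 separation signal is real but small
(standardised group difference ≈ 0.4), and at other cohort seeds the day-14
and day-21 coefficients can tie within histogram noise. The demo profile is
deterministic, so the packaged check is stable; users re-screening at other
seeds should expect the IL-10 ordering, uniquely among the three markers, to
be marginal.

## Numerical conventions

* Integrator: LSODA, `rtol 1e-6 / atol 1e-9`; tests that compare against
  closed forms or the fixed-step RK4 oracle tighten `atol` because several
  states decay to ~1e-9 by day 40, and relative comparisons are floored at
  the package's own 1e-9 output-clamp threshold.
* Histogram bins are right-open except the last (numpy convention); BC is
  clipped to [0, 1] against floating-point drift.
* Classification thresholds are compared with the exact stated inequalities;
  no tolerance is added.
* DeLong degenerate cases: identical score vectors give p = 1 (flagged);
  zero estimated variance with unequal AUCs gives an infinite z and p = 0
  (flagged).
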