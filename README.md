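# scarscreen

In-silico screening of prognostic biomarkers of pathological scarring in skin
wounds, from virtual-cohort simulations of a kinetic wound-healing model.

## The problem

Hypertrophic scars — raised, collagen-rich fibrotic scars — follow traumatic
and surgical skin injuries at high incidence, yet there are no protein
biomarkers in clinical use that predict, *early* in healing, whether a wound
will scar pathologically. Prospective human studies are difficult: samples are
scarce, and pathological outcomes only declare themselves weeks after injury.
`scarscreen` implements a computational alternative aimed at systems
biologists and wound-healing researchers: generate a large virtual cohort of
wound-healing trajectories from a mechanistic kinetic model, define scarring
outcomes from the simulated endpoint, and screen every modeled wound protein
for its ability to *predict* that endpoint from early time points.

## The method

1. **Virtual cohort.** An injury-initiated kinetic model (ODE system;
   platelets, inflammatory and repair cells, fibroblasts, cytokines
   IL-6/CXCL8/IL-10/TGF-β, MMP-9/TIMP-1, fibronectin, collagen) is simulated
   daily over 40 days. Inter-individual variability is emulated by drawing
   each parameter θ independently and uniformly from [θ/2, 2θ] around its
   default, once per virtual patient.
2. **Outcome classification.** Each simulation is scored by day-40 fold
   changes of collagen and fibroblasts relative to the default-parameter
   (normal-healing) run: *normal* (both ≤ 1), *mild* (both in [5, 10]),
   *severe* (both > 10); anything else is ambiguous and excluded from the
   distribution screen. A binary outcome (*pathological* iff collagen fold
   change > 10) labels every simulation for regression.
3. **Overlap screen.** For each protein and day, per-group concentration
   histograms (50 shared equal-width bins) are compared with the
   Bhattacharyya coefficient BC = Σᵢ √(pᵢqᵢ) ∈ [0, 1]; small overlap between
   normal and pathological groups marks a candidate biomarker (diagnostic at
   day 40, prognostic at days 7/14/21).
4. **Predictive evaluation.** Logistic regressions of the binary outcome on
   min-max-normalised marker panels (3 singles, 3 pairs, 1 triple per day)
   are summarised by ROC curves, Mann–Whitney (midrank) AUC with DeLong 95%
   confidence intervals, pairwise DeLong tests between panels, and stratified
   tenfold cross-validation with pooled out-of-fold probabilities.

The package ships a calibrated 12-state reference surrogate model; any model
can be plugged in through the `KineticModelSpec` contract (named states and
parameters, initial state, RHS function, marker-role map).

## Worked example

```python
from scarscreen import demo_config, run_pipeline

report = run_pipeline(demo_config())   # 5,000 draws, fixed seed, ~30 s

n = sum(report.class_counts.values())
print({k: f"{100*v/n:.1f}%" for k, v in sorted(report.class_counts.items())})

tab = report.overlap_table
fn = tab[(tab.protein == "FN") & (tab.pair == "normal-vs-severe")]
print(fn[["day", "bc"]].to_string(index=False))

ev21 = report.evaluations[21]
print(f"day-21 triple-panel AUC {ev21.panel('I10','T1','FN').auc:.3f}, "
      f"tenfold-CV AUC {ev21.cv.auc:.3f}")
```

prints

```
{'excluded': '38.8%', 'mild': '1.6%', 'normal': '45.0%', 'severe': '14.6%'}
 day       bc
   7 0.764389
  14 0.503918
  21 0.434147
  40 0.400068
day-21 triple-panel AUC 0.961, tenfold-CV AUC 0.960
```

Reading: under 0.5–2× parameter perturbation, 45.0% of the virtual cohort
heals normally and 14.6% scars severely (38.8% of simulations fall in the
ambiguous fold-change band and are excluded from the distribution screen).
The fibronectin concentration distributions of normal-healing versus
severe-scarring patients overlap less and less from day 7 to day 21 — an
early *prognostic* signal — and a logistic panel of the three markers
(IL-10, TIMP-1, fibronectin analogs) measured at day 21 predicts the day-40
binary outcome with in-sample AUC 0.961, essentially unchanged (0.960) under
tenfold cross-validation.

The same pipeline runs from the shell:

```bash
scarscreen run --config my_config.yaml --out results/
scarscreen simulate-cohort --n 5000 --seed 7 --out cohort/
scarscreen classify --cohort cohort/ --out labels.csv
scarscreen screen --cohort cohort/ --labels labels.csv --days 7,14,21,40 --out screen/
scarscreen evaluate --cohort cohort/ --labels labels.csv --days 14,21 --out eval/
```

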