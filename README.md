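# mpisurv

End-to-end survival training for myocardial-perfusion tomogram stacks:
a convolutional risk-score model optimized with the batch Cox partial
likelihood, the full risk-stratification evaluation protocol around it, and
a SPECT-like cardiac phantom simulator that makes the whole pipeline
verifiable against known ground truth at desk scale.

## The problem

Myocardial perfusion imaging (MPI) visualizes blood flow through the heart
muscle at rest and under stress as a stack of 2D grayscale tomographic
slices (the standard layout: 96 slices = 2 conditions × 24 short-axis +
12 horizontal-long + 12 vertical-long).  For patients with
moderate-to-severe ischemia, the clinically useful question is not "is this
scan abnormal?" but "how soon will this patient have a cardiovascular
event?" — a *time-to-event* question with censored follow-up, which binary
classifiers cannot answer.

`mpisurv` trains a network f(x) to emit a scalar log-relative-hazard under
the proportional-hazards model

    h(t | xᵢ) = h₀(t) · exp(f(xᵢ)),

by maximizing the Cox log partial likelihood per mini-batch,

    log L = Σᵢ δᵢ [ f(xᵢ) − log Σ_{j ∈ R(tᵢ)} exp(f(xⱼ)) ],

where δᵢ flags an observed event and R(tᵢ) is the within-batch risk set.
The baseline hazard h₀ cancels, censored subjects contribute through risk
sets, and the trained score orders patients by imminent risk.  Scored
cohorts are then stratified at the median (and the upper quartile) and
analyzed with Kaplan–Meier curves, log-rank tests, Harrell's C (overall and
truncated at 1000/2000/3000 days), threshold-sweep and three-segment
stratified ROC curves, and per-subgroup hazard-ratio (forest) fits.

Because real hospital cohorts are not distributable, the package includes a
phantom generator: annular "myocardium" slices with a wedge-shaped,
severity-proportional perfusion deficit (deeper under stress than rest),
and event times drawn from the same hazard model the trainer assumes — so
recovery of the injected signal is a measurable, seedable experiment.

## Worked example

Simulate a 300-subject training cohort (8-slice reduced layout, 32 px
slices, ~15% event rate), run fivefold cross-validated training of the tiny
residual encoder, score an independent 200-subject test cohort, and
evaluate:

```bash
mpisurv simulate --n 300 --seed 11 --out cohort  --profile tiny
mpisurv crossval --data cohort --seed 11 --out cv --profile tiny \
                 --epochs 10 --k-folds 5
mpisurv simulate --n 200 --seed 99 --out testset --profile tiny
mpisurv score    --data testset --checkpoint cv/checkpoint.npz \
                 --seed 11 --out scored
mpisurv evaluate --scores scored/scores.csv \
                 --survival testset/survival.csv --seed 11 --out report
```

`cv/crossval_report.json` records one validation C-index per fold and
horizon and the selected fold (here fold 3, best validation C = 0.838).
`report/metrics.json` from this exact run contains:

```
c_index              0.805
c_index_by_horizon   {1000: 0.813, 2000: 0.814, 3000: 0.809}
strata_sizes         median 100/100; three-level 100/50/50
logrank (median)     chi2 = 19.77, df = 1, p = 8.7e-06
auc                  alltime sweep 0.822; stratified 3-level 0.792
```

Reading: on unseen phantoms the trained score ranks a random comparable
patient pair correctly ~80% of the time (the generator's ground-truth
severity ceiling is ≈ 0.75–0.84 per cohort), the median split separates
survival curves decisively (log-rank p < 1e-5), and the three-segment
stratified ROC — the ROC of calling only the high, then high+intermediate,
strata positive — has AUC 0.79.  `report/` also holds per-stratum
Kaplan–Meier TSVs, ROC TSVs, and pairwise log-rank results; every run
writes a `run_record.json` with its seed, config hash and file inventory.

The same pipeline runs on real data supplied in the documented CSV/PNG (or
`.npz` container) dialects: a `subject_id,time_days,event` survival table,
a `subject_id,file,condition,axis,slice_index` manifest, and optionally a
six-covariate clinical table (age, sex, diabetes, hypertension,
hyperlipidemia, smoking) for the `clinical_only` / `combined` fusion modes.

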