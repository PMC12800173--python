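# pdmci

Data-driven diagnosis of mild cognitive impairment (MCI) in Parkinson's
disease (PD), implemented as a tested, reusable analysis pipeline.

## The problem

MCI is a transitional stage between normal cognition and dementia and, in
PD, a strong risk factor for further decline. The clinical gold standard —
the Movement Disorder Society's comprehensive ("Level II") PD-MCI criteria —
requires a ten-test neuropsychological battery (two tests per cognitive
domain: attention, executive, memory, visuospatial, language), expert
interpretation, and rigid cut-offs. This package implements that reference
procedure *and* an unsupervised, clinically gated alternative built from
routine clinical data, then quantifies whether the data-driven model is
non-inferior to the clinical criteria and whether it surfaces an "early-MCI"
subgroup the criteria miss.

Because cohort data of this kind are not publicly redistributable, the
package ships a synthetic cohort generator that emulates the statistical
structure such a study assumes (covariate-driven normative scores, three
latent cognitive classes, annual follow-up with class-specific decline) with
planted ground truth, so the entire pipeline is testable end to end.

## The models

**Normative z-scoring.** For each test, ordinary least squares on the
healthy-control reference sample gives the covariate-adjusted expectation

    Y_exp = Y + f_age·Age + f_ed·Education + f_sex·Sex,
    z = (Y_obs − Y_exp) / SD,

with SD the residual standard deviation of the control regression. Timed
scores (TMT-A, TMT B−A) are sign-flipped at the z stage so lower z always
means worse performance.

**Clinical reference test.** A test is impaired when z ≤ −1.5 (1.5 SD or
more below the adjusted normative mean, boundary inclusive); a person with
PD is PD-MCI when at least two of the ten tests are impaired, regardless of
domain.

**Data-driven model.** A 20-feature design (10 battery z-scores;
robust-scaled age at onset, disease duration, MDS-UPDRS III, Hoehn & Yahr,
RBDSQ; five 0/1 comorbidity/lifestyle flags) is clustered with k = 2 by
spectral clustering on the symmetric normalised Laplacian
(W_ij = exp(−‖x_i−x_j‖²/2σ²), L_sym = I − D^{−1/2} W D^{−1/2}), K-Means and
Gaussian mixtures. A silhouette-guided grid search is gated by external
clinical-plausibility rules (the lower-MoCA cluster must also be older, with
longer disease duration and at least as advanced Hoehn & Yahr); implausible
solutions are discarded regardless of silhouette.

**Comparison and validation.** The two diagnostic procedures are compared by
a 10,000-iteration bootstrap of the Cohen's-d difference on MoCA total,
MDS-UPDRS 1.1 and the PDQ-39 subjective-cognitive-complaint subscore
(items 30–33); a 95% percentile CI excluding zero marks a significant
difference. Crossing the two labelings yields four subgroups whose
longitudinal trajectories are validated with Cox proportional-hazards models
(events: MoCA ≤ 21 or MDS-UPDRS 1.1 ≥ 3; death right-censors; covariates:
age, education, baseline score; Schoenfeld-residual proportionality checks).

## Worked example

```python
from pdmci.pipeline import PipelineConfig, run_all

bundle = run_all(PipelineConfig(seed=1))
print(bundle["selected_algorithm"], bundle["evaluations"][bundle["selected_algorithm"]])
print(bundle["subgroup_sizes"])
print(bundle["effect_size_comparison"][
    ["feature", "d_model", "d_reference", "delta", "ci_low", "ci_high", "significant"]
].round(3))
```

prints (abridged):

```
spectral {'sensitivity': 0.696, 'precision': 0.975, 'accuracy': 0.843, 'auc': 0.91, ...}
{'NC_both': 58, 'ref_only_MCI': 17, 'model_only_MCI': 1, 'MCI_both': 39}
   feature  d_model  d_reference  delta  ci_low  ci_high  significant
moca_total    1.796        1.169  0.627   0.040    1.239         True
 updrs_1_1   -0.881       -0.734 -0.147  -0.716    0.413        False
 pdq39_scc   -1.349       -1.142 -0.207  -0.933    0.457        False
```

Reading this: the spectral model was selected (highest MCI sensitivity
against the clinical reference, AUC 0.91 breaking ties); crossing its
labels with the reference gives the four diagnostic-overlap subgroups,
including a data-driven (model-only) MCI group the clinical criteria did
not flag; and the model separates NC from MCI on global cognition (MoCA)
*more* strongly than the reference test (Δd = 0.63, CI excludes 0) while
being statistically indistinguishable on the other two external measures —
the non-inferiority pattern the pipeline is designed to detect. The same
bundle carries the Cox validation: the MoCA ≤ 21 endpoint differs across
subgroups with a global log-rank p ≈ 1e−8, driven by the baseline score
and subgroup membership.

The same analysis is available from the shell:

```sh
pdmci run-all --seed 1 --out-dir results/
pdmci simulate --seed 1 --out-dir cohort/   # tables + planted ground truth
```

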