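# Methods

This note documents the statistical procedures the package implements, the
defaults it ships, the design choices made where the design was genuinely
open, and what the synthetic cohort does and does not emulate.

## Normative scoring

Per-test normative models are ordinary least-squares regressions of the raw
score on age, years of education and sex (coded 0 = female, 1 = male),
fitted on the healthy-control reference sample with complete-case handling
per test. The z-score divides the residual by the *residual* standard
deviation of the control regression with the unbiased n − 4 denominator:
since the expectation is covariate-adjusted, the matching spread is the
residual spread, not the marginal SD. Fits require more than 4 complete
rows and a full-rank design; a constant response yields SD = 0 and is
flagged degenerate (z undefined, scoring raises).

Direction handling happens at the z stage, not by negating raw inputs: raw
tables stay faithful to the source instruments, and timed tests (TMT-A,
TMT B−A, seconds, larger = worse) have their standardised residuals negated
so that lower z uniformly means worse performance. MoCA-derived subitems
(clock drawing, naming) are treated as ordinal-valued numerics in the same
regression machinery — one framework for all ten tests.

## Reference classification

Impairment is z ≤ −1.5, boundary inclusive ("1.5 SD or more below" the
adjusted normative mean); PD-MCI is at least two impaired tests out of ten,
irrespective of domain. Domain-level impairment for *profiling* (not part
of the MCI rule) is "at least one of the domain's two tests impaired"; the
profile is none / single-domain / multi-domain with an amnestic flag when
memory is involved. This domain rule is a package choice: the two-test MCI
criterion is defined at the test level, and some domain rule is needed to
make profile summaries computable. A missing z marks the test untested,
never impaired; participants with untested items remain classifiable but
carry a completeness caveat.

## Data-driven model

The design matrix holds 20 features: the 10 battery z-scores (entered
unscaled — they are already standardised and direction-aligned), 5
robust-scaled numerics (age at onset, disease duration, MDS-UPDRS III,
Hoehn & Yahr, RBDSQ) and 5 binary flags (cardiovascular disease,
hypertension, diabetes, smoking, alcohol). Robust scaling is
(x − median)/IQR on the fitting cohort, with parameters retained. A
zero-IQR column that is genuinely constant raises; a zero-IQR column that
still varies (coarse ordinal scales such as Hoehn & Yahr, whose sample IQR
is frequently 0) falls back to the sample SD as the spread. MoCA total and
MDS-UPDRS 1.1 are deliberately excluded from the features — they serve as
external validation variables. The feature list is configuration-driven.

Spectral clustering is implemented explicitly: Gaussian (RBF) affinity on
Euclidean distance with the bandwidth as a grid hyperparameter (the
standard construction when only "Euclidean affinity" is specified), zero
diagonal, L_sym = I − D^{−1/2} W D^{−1/2}, eigenvectors of the k smallest
eigenvalues, row-normalised, partitioned by seeded k-means. Zero-degree
points raise with a suggestion to widen the bandwidth. K-Means (multi-restart
best inertia) and Gaussian mixtures (EM, full or diagonal covariance) come
from scikit-learn.

Model selection evaluates every grid point, discards degenerate
(single-cluster) solutions and solutions failing the external clinical
rules, then picks the highest silhouette per algorithm, ties broken by grid
order. The external rules identify the putative MCI cluster as the one with
the lower median MoCA and require it to be at least as old, with at least
as long disease duration and at least as advanced Hoehn & Yahr stage as the
other cluster (ties on these three pass; the MoCA rule is strict).
Default grids: k = 2 (3 and 4 can be explored; selection stays at 2),
spectral bandwidth ∈ {0.5, 1, 2, 5} × median pairwise distance, GMM
covariance ∈ {full, diag}, k-means with 10 restarts. Across algorithms the
winner is the solution with the highest MCI sensitivity against the
clinical reference, AUC breaking ties — the comparison that motivates
choosing a "most sensitive, comparably precise" model. AUC uses a soft
MCI-likeness score: the component posterior for GMM, and the signed
difference of distances to the two centroids in the assignment space
(spectral embedding or feature space) for the hard clusterings — one of
several defensible conventions for hard labels, reported alongside the
label-based metrics.

Feature importance is the mutual information between each feature and the
cluster labels, with continuous features discretised into equal-frequency
5-bin quantiles. The binned estimator is deterministic and exactly
verifiable against the Σ p log(p/p_x p_y) definition, which is why it was
preferred over nearest-neighbour MI estimators.

## Procedure comparison

Cohen's d uses the pooled-SD denominator with (n−1)-weighted variances,
oriented NC minus MCI. The bootstrap comparison resamples, in each of
10,000 iterations, the four (procedure × group) samples independently with
replacement at original sizes, computes d per procedure and stores the
difference; the 95% CI is the 2.5th/97.5th percentile, and a CI excluding
zero is significant. Degenerate resamples (zero pooled SD) are redrawn and
counted. Routed two-group testing: categorical/ordinal → Pearson chi-squared
with phi (2×2) or Cramér's V; numeric → per-group Shapiro–Wilk at α = 0.05,
then Student's pooled-variance t-test (both normal) or two-tailed
Mann–Whitney U with tie-corrected normal approximation and the standardised
point-biserial effect size r = Z/√n (the named measure carries no published
formula; this is the standard standardisation). Benjamini–Hochberg
adjustment is applied within one analysis table at a time; the family is
explicit in the API.

## Subgroups and survival

Crossing model and reference labels partitions the PD cohort into
concordant-NC, concordant-MCI and two discordant groups; groups below the
minimum size (default 5 — a published analysis dropped an n = 1 group
without stating a threshold) are flagged and excluded from downstream
statistics. Characterisation runs the routed test for every manifest
feature and retained group pair, BH-adjusted over the whole table
(pairwise, not omnibus, matching the tabular reporting convention).

Survival events are the first visit with MoCA ≤ 21 (global cognition
materially affecting daily living; the MMSE < 26 equivalent) or
MDS-UPDRS 1.1 ≥ 3 (moderate physician-rated impairment). Time is measured
from PD diagnosis (baseline disease duration plus years since baseline);
interval censoring between annual visits is ignored, as a visit-based
design implies. Participants already at the endpoint at baseline are
excluded (onset time unknowable); death before the event right-censors
(no competing-risks model — deaths are few by design); otherwise censoring
is at the last visit. Cox models use Efron tie handling (annual visits make
ties common), subgroup indicators against the concordant-NC reference, and
age, education and the baseline outcome score as covariates. The
proportional-hazards assumption is checked per covariate by correlating
scaled Schoenfeld residuals with event-time rank; a violated adjustment
covariate is dropped and the model refitted (the conventional handling when
e.g. sex violates proportionality), with the verdict still reported. Group
differences are additionally tested by the global log-rank test with
BH-adjusted pairwise post-hocs.

## Synthetic cohort

The generator emulates the statistical structure the analysis assumes, with
defaults fixed as the package's study conditions: 226 healthy controls and
115 people with PD (the eligible-population sizes of the motivating study
design), PD latent classes NC / early-MCI / MCI in proportions
0.435 / 0.226 / 0.339, male fractions 0.72 (PD) and 0.54 (HC), and up to 8
annual PD follow-up visits. Control test scores are exactly linear in age,
education and sex plus Gaussian noise, unclipped so that regression refits
recover the planted coefficients without truncation bias. PD scores add
class deficits in control-SD units, in each test's "worse" direction:
early-MCI 1.0–1.1 SD on two executive/memory tests (clinically meaningful
but mostly below the two-test criterion), MCI ≥ 1.0 SD across ≥ 4 domains
including visuospatial. Clinical measures are class-conditional; the
early-MCI class is deliberately close to MCI on age, disease duration,
Hoehn & Yahr and comorbidity prevalence — a cognitively subthreshold but
clinically burdened phenotype, which is exactly the subgroup the
data-driven model is supposed to surface. Follow-up MoCA declines with
class-specific slopes (0.25/0.55/0.90 points/year plus visit noise); the
MDS-UPDRS 1.1 endpoint time is exponential proportional-hazards with class
log-HRs 0/0.9/1.6 over a 0.06/year baseline; deaths are independent of
cognition at 0.012/year (a simplification consistent with treating death
as censoring). Generated controls emulate an already-screened reference
group (no risk flags), so the eligibility filters are near-identity on
default synthetic data; the filters are exercised with crafted tables in
the tests.

What the generator does **not** emulate: correlation between the ten tests
beyond their class-conditional means (no shared g-factor or domain-block
noise correlation), informative missingness, practice effects,
language-of-administration effects, medication or genetic effects. Passing
tests therefore demonstrate the pipeline's correctness and calibration
under its stated assumptions, not performance on real cohort data — real
batteries have correlated residuals, which raises the false-positive rate
of count-based rules relative to the independent-noise case.

## Numerical choices and problem sizes

All randomness flows through per-stage child seeds derived from one master
seed (SeedSequence spawning, seeds kept below 2^31); rerunning a
configuration is bit-identical. Tie-breaks everywhere are by deterministic
grid or row order. The Laplacian is symmetrised against round-off before
the eigensolve; eigenvalues are checked to 1e-8 against dense solvers in
tests. The test suite exercises the heavy calibration properties at sizes
chosen to characterise behaviour well while keeping the default run fast:
500 replicates × 2,000 bootstrap iterations for the null calibration of the
effect-size comparison, 200 simulated cohorts of n = 300 for the Cox
recovery study, 100 randomised grids for selection soundness, and 2,000
controls for normative-coefficient recovery.

## Known limitations

The eligibility rules assume the "absence of delirium" component of the
dementia exclusion is unrecorded (no variable), so it is not applied. The
4-level Hoehn & Yahr scale and the 0–4 MDS-UPDRS 1.1 are treated as
numerics where the design calls for scaling and as ordinal in testing; both
conventions are defensible and the config allows switching features off.
The silhouette on real-scale mixed features rewards compact clusters and
can prefer conservative splits; the external clinical gate, not the
silhouette, is what anchors the solution to the MCI phenotype.
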