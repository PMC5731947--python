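# Methods

## Scope and data model

The package analyses retrospective ovarian-cancer cohorts in which every
patient carries: age and menopausal status; the two intraoperative binary
findings ascites (A, 0/1) and tumour laterality (L, 0 unilateral / 1
bilateral); binary flags for 15 surveyed metastatic sites; and a panel of
numeric medical examination indicators (MEIs). The per-patient *site
count* (0–15) is the working measure of metastatic burden, and
*multi-organ metastasis* means strictly more than 3 positive sites.
Missing MEI values are represented explicitly and handled by complete-case
analysis within each computation; no imputation is performed.

## Co-metastasis enrichment

Each of the 105 site pairs is tested with the upper hypergeometric tail of
the observed co-positive count m, with the cohort size as the sampling
universe N and the two per-site positive counts as M and n. Two tail
conventions are exposed: the default evaluates the strictly-greater tail
P(X > m) = 1 − Σ_{k≤m} C(n,k)C(N−n,M−k)/C(N,M); `tail="geq"` gives the
conventional P(X ≥ m). Degenerate pairs with an empty marginal (M = 0 or
n = 0) return P = 1 by definition — the formula's vacuous sum would
otherwise produce a spurious zero. Probabilities come from
`scipy.stats.hypergeom` (log-space survival function) and are clamped to
[0,1]; −lg(adjusted P) is capped at 300 for display matrices.

Family-wise error over the 105 tests is controlled by Holm–Bonferroni
step-down, implemented directly (sort ascending, adj_i = max_{j≤i}
(m−j+1)p_j, capped at 1) and cross-checked in the test suite against
statsmodels. Significance is adjusted P < 0.001 (−lgP > 3); network
exports use a strict threshold, with −lgP > 10 as the default display cut.

## MEI screening

Stage 1 (*metastasis-related*): for each MEI and site, the AUC of the MEI
for site-positive vs site-negative patients via the Mann–Whitney rank
identity (ties worth one half), with the two-sided normal-approximation
p-value (continuity-corrected; an exact variant is available for small
samples). The criterion is applied to the marker's discriminating
direction — max(AUC, 1−AUC) > 0.5 with P < 0.001 — so inversely-directed
markers such as prealbumin-like indicators (lower values in sicker
patients) are retained; reported AUCs stay unoriented. Stage 2
(*MOM-related*): Spearman |ρ| > 0.1 and P < 0.001 against the site count.
Spearman is used throughout because MEI panels routinely fail the
D'Agostino–Pearson normality test; that test is provided as a diagnostic
report and gates nothing.

Correlation-intensity labels bin |ρ| as [0.1,0.3) extremely weak, [0.3,0.5)
weak, [0.5,0.7) moderate, [0.7,0.9) strong, ≥0.9 extremely strong — the
scheme under which a 0.397 single-marker correlation is "weak" and a 0.6
index correlation "moderate".

Collinearity filtering visits MOM-related candidates in descending |ρ| vs
site count (catalog order breaks ties) and retains a candidate iff its
pairwise Spearman |ρ| with every already-retained candidate is ≤ 0.3.
This is the greedy drop-the-weaker rule expressed constructively: in a
collinear chain A–B, B–C with outcome correlations A>B>C, B is displaced
by A and C survives. The elimination audit records who displaced whom.

## Neural network cascade

All MEIs entering the cascade are min–max normalized to [0,1] on the
training cohort (validation values clip); the target is the site count
divided by its theoretical maximum 15, not the observed range, so fitted
models transfer across cohorts.

Each ladder sub-model is an RBF network with 11 Gaussian hidden units and
1 or 2 inputs. The original construction used a proprietary commercial
trainer; here a standard reproducible recipe defines it: rows are split
2:1:1 (training = round(n/2); the remainder halved, extra record to
verification — reproducing 267/134/133 at n=534); centers are seeded
k-means (k=11, shrinking to floor(n_train/2) with a warning when data are
scarce); each width is 2× the distance to the nearest other center,
floored at 1e-6; the output layer (11 weights + unpenalized bias) solves a
ridge least-squares problem in augmented form (numerically stable at tiny
penalties), with the penalty chosen from the grid 1e-10…1e-1 by
verification-subset MSE. R_Tr and R_Te are Pearson correlations of
prediction vs target on the training and testing subsets; similar values
indicate the sub-model generalizes.

The ladder visits candidates in descending |ρ| vs site count. A 1-input
sub-model on the top MEI seeds the ladder; a 2-input sub-model on the top
two replaces it only if it raises the cohort-level Spearman ρ of the
(clipped) output against the site count by more than ε = 0.005, the same
acceptance rule every later step faces with (incumbent parameter, next
MEI) as inputs. Measuring acceptance on the whole cohort rather than the
internal training subset damps chance acceptance of noise MEIs by subnet
overfit. Rejected MEIs are recorded with their ρ deficit. Validation is
by 10-fold cross-validation — shuffled folds differing by at most one
record, the cascade rebuilt from scratch per fold, Spearman ρ pooled over
out-of-fold predictions — and by scoring a held-out cohort.

## The metastasis index

Ordinary least squares regresses the normalized site count on
(1, NNC output, L, A); no interactions or variable selection, per the
three-predictor design. The fit errors on rank-deficient designs, naming
the constant column. Raw index scores are min–max normalized by their
training range (clipped) for interval-based displays. The M/P curve bins
a normalized score into 10 equidistant intervals ([i/10,(i+1)/10), last
closed); M/P is the per-interval ratio of summed sites to patients, and
the slope is defined as OLS of M/P on the non-empty interval midpoints
(the abscissa convention had to be fixed; midpoints make the slope
invariant to adding empty bins). AUC confidence intervals use the
Hanley–McNeil variance. Report annotations include one-way ANOVA across
the four A×L strata under the global significance rule P < 0.001.

## Synthetic cohorts

The generator emulates the joint structure the analysis assumes:

* latent burden b = z + 0.8·A + 1.0·L + 0.5·A·L with z ~ N(0,1); ascites
  and bilaterality each Bernoulli(0.55). The effect sizes give
  bilateral-with-ascites patients ≥ 2 more expected sites than
  unilateral-without-ascites patients, the planted synergy the evaluation
  strata must recover.
* per-site flags ~ Bernoulli(expit(a_s + 1.2·b + pair terms)). The
  intercept a_s is solved by root-finding on the realized sample so each
  site's marginal incidence matches its configured base rate regardless of
  slope or coupling. Default base rates descend from large intestine
  0.596 and greater omentum 0.554 to stomach/ureter < 0.06 and sum to
  ≈3.75, so the cohort mean site count lands near 3.7–3.8.
* planted co-metastasis: designated pairs — (LI, GO) and the low-incidence
  (SPL, LIV) by default — share an extra per-patient latent component with
  coupling 1.2 added to both logits, creating co-occurrence beyond what
  the common burden induces.
* MEIs by Gaussian copula: the MEI's normal score is correlated with the
  burden's rank-based normal score at the Pearson value 2·sin(πρ/6)
  matching the target Spearman ρ, then pushed through the marginal family
  (log-normal for tumour-marker-like indicators, truncated normal for
  percentages/counts). Spearman targets are invariant to those monotone
  marginal transforms. Defaults: CA-125 analogue ρ=0.40, platelet count
  0.30, neutrophil percentage 0.22, prealbumin −0.18, plus two noise
  indicators (chloridion and thrombin-time analogues, ρ=0).

Discretizing the burden into a 0–15 count attenuates rank correlations by
roughly 15%, so a ρ=0.40 MEI shows ≈0.34 against the site count. The
weakest informative default is −0.18 rather than −0.15 for exactly this
reason: after attenuation it still clears the |ρ| > 0.1 screening
threshold with adequate power at the n=2000 used in the simulation tests
(sampling SD ≈ 0.022).

What the generator does *not* emulate: real units and reference ranges of
a full 88-item panel, between-MEI partial correlations beyond the shared
burden, informative missingness, site-specific indicator effects
(every MEI sees only the global burden), or survival outcomes. Passing
simulation tests therefore demonstrates that the pipeline recovers planted
structure of the assumed form — not that any particular clinical panel
carries such structure.

## Determinism and numerical choices

Every stochastic step (generation, splits, k-means, folds) draws from an
explicit seed; the pipeline derives stage seeds from one global seed by
fixed offsets modulo 2^31, so stages can be rerun in isolation and two
runs of one config are byte-identical. Cohort CSVs serialize floats with
shortest-round-trip precision and are parsed back with round-trip float
parsing, making load(write(c)) the identity. Degenerate inputs are
defined, not left to chance: constant targets report r = 0 with a warning,
empty M/P intervals are excluded from the slope (undefined below 2
occupied intervals), empty evaluation strata report size 0, and strata
with fewer than 3 patients report an undefined ρ.

## Problem sizes

The shipped defaults exercise the pipeline at the study scale — training
cohorts of 534 with 267-record validation sets for end-to-end runs, and
n=2000 cohorts across 20 seeds for the simulation properties — sizes at
which each full pipeline pass takes well under a second on a single CPU.

## Known limitations

* The RBF recipe is a faithful, reproducible stand-in for a proprietary
  trainer, not a bit-level reproduction; absolute ρ values on real data
  would differ in the second decimal.
* The hypergeometric universe N is fixed to the cohort size; the verbal
  definition it replaces is ambiguous, and other choices (e.g. the union
  of the two sites' positives) would change borderline pairs.
* Greedy collinearity filtering and greedy ladder acceptance are
  order-dependent by design; the documented ordering (descending |ρ|)
  makes them deterministic but not globally optimal.
* With all-noise inputs the cascade degenerates to the single seed MEI
  (with a warning) rather than refusing to fit; downstream nullity is then
  visible in the CV report, not in the model object.
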