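# ocmi

Tools for dissecting ovarian-cancer cohorts: which organs are invaded
together, which routine medical examination indicators (MEIs) track the
spread, and how to fuse those indicators into a single **ovarian cancer
metastasis index (OCMI)** that ranks patients by their number of metastatic
sites.

The package is aimed at biostatisticians and clinical-data scientists
working with retrospective gynecological-oncology cohorts: one row per
patient, binary flags for 15 intraoperatively surveyed metastatic sites
(bladder, diaphragm, greater omentum, internal genital organ, large
intestine, liver, lymph node, mesentery, paracolic sulci, peritoneum,
rectouterine fossa, small intestine, spleen, stomach, ureter), the two
intraoperative findings ascites (A) and tumour laterality (L), and an
arbitrary panel of numeric indicators such as CA-125 or blood counts.

## The analysis

**Co-metastasis testing.** For each unordered pair of sites (i, j) the
overlap m between the two patient sets is scored against the
hypergeometric null of drawing the M site-i patients at random from the N
cohort members, n of whom carry site j:

    P = 1 − Σ_{k=0}^{m} C(n,k) · C(N−n, M−k) / C(N,M)

All C(15,2) = 105 tests are adjusted by Holm–Bonferroni step-down; pairs
with adjusted P < 0.001 (−lgP > 3) are called co-metastatic, and the −lgP
matrix/edge list can be exported for heatmap or network tools.

**MEI screening.** An MEI is *metastasis-related* if it separates
site-positive from site-negative patients for at least one site
(Mann–Whitney ROC, P < 0.001), and *multi-organ-metastasis (MOM)-related*
if additionally its Spearman correlation with the per-patient site count
satisfies |ρ| > 0.1 with P < 0.001. Collinear candidates (pairwise
|ρ| > 0.3) are thinned greedily, keeping the stronger correlate of the
site count.

**Neural network cascade (NNC).** Surviving MEIs, min–max normalized to
[0,1], are folded one at a time into an integrated parameter by a ladder
of small radial-basis-function networks (1-11-1 or 2-11-1: one or two
inputs, 11 Gaussian units, one linear output). Each sub-model is trained
on a random 2:1:1 training/verification/testing split (n=534 → 267/134/133)
with k-means centers, nearest-neighbour widths, and a ridge-regularized
output layer; R_Tr/R_Te report its generalization. A ladder step is kept
only when it raises the cohort-level Spearman ρ against the site count —
uninformative MEIs are rejected.

**The index.** A multiple linear regression fuses the cascade output with
the two intraoperative findings,

    OCMI = b0 + b1·NNC + b2·L + b3·A,

targeting the site count normalized by its theoretical range [0,15].
Performance is evaluated by 10-fold cross-validation, Spearman ρ (overall
and by menopausal status), ROC for multi-organ metastasis (> 3 sites) and
any metastasis, and the M/P curve: patients binned into 10 equidistant
intervals of the normalized score, M/P = (sum of sites)/(patients) per
interval, whose slope measures how steeply the score tracks burden.

Because real cohorts of this kind cannot be redistributed, the package
ships a synthetic-cohort generator (`ocmi.synthetic`) that plants the same
statistical structure — a latent metastasis burden behind all 15 sites,
extra coupling for chosen site pairs, ascites/laterality shifts with a
synergy term, and MEIs tied to the burden through a Gaussian copula at
configurable Spearman targets — plus the ground truth needed for
parameter-recovery tests.

## Worked example

```python
from ocmi import (default_config, generate_cohort, analyze_comet, screen_meis,
                  collinearity_filter, build_cascade, cascade_predict_cohort,
                  fit_ocmi, ocmi_score)
from scipy.stats import spearmanr

config = default_config(n_patients=534, seed=7)
cohort, truth = generate_cohort(config)
counts = cohort.site_counts()
print(f"patients: {len(cohort)}, mean metastatic sites: {counts.mean():.2f}")

comet = analyze_comet(cohort)
print(f"LI incidence: {comet.incidence['LI']:.3f}; "
      f"(LI,GO) adjusted P: {comet.adjusted_p.loc['LI','GO']:.2e}")

screen = screen_meis(cohort)
retained, dropped = collinearity_filter(screen.mom_related, cohort, screen)
print(f"MOM-related MEIs: {screen.mom_related} -> retained: {retained}")

model = build_cascade(cohort, ordered_meis=retained, seed=7)
nnc = cascade_predict_cohort(model, cohort)
index = fit_ocmi(nnc, cohort.column("laterality"), cohort.column("ascites"), counts)
ocmi_raw, _ = ocmi_score(index, nnc, cohort.column("laterality"), cohort.column("ascites"))

print(f"rho CA-125: {spearmanr(cohort.mei_frame()['CA125'], counts).statistic:.3f}")
print(f"rho NNC:    {model.rho_train:.3f}")
print(f"rho OCMI:   {spearmanr(ocmi_raw, counts).statistic:.3f}")
```

Output:

```
patients: 534, mean metastatic sites: 3.81
LI incidence: 0.597; (LI,GO) adjusted P: 1.32e-18
MOM-related MEIs: ['CA125', 'PLT', 'NEUT_pct', 'PA'] -> retained: ['CA125', 'PLT', 'PA', 'NEUT_pct']
rho CA-125: 0.348
rho NNC:    0.432
rho OCMI:   0.635
```

Reading the numbers: the generated cohort averages 3.81 metastatic sites
per patient, led by the large intestine (59.7% incidence), and the planted
large-intestine/greater-omentum co-metastasis is detected at adjusted
P ≈ 10⁻¹⁸. All four informative indicator analogues pass the MOM screen
(the two noise indicators do not), and the integration chain raises the
correlation with the site count from 0.348 (best single MEI, a weak
correlation) through 0.432 (cascade) to 0.635 (index, a moderate
correlation): adding ascites and laterality contributes ranking
information no blood indicator carries.

The same flow is available from the shell:

```
ocmi simulate --n 534 --seed 7 --out cohort.csv
ocmi run --config pipeline.yaml
ocmi score --model out/model.json --cohort new_cohort.csv --out scores.tsv
```

`ocmi run` writes incidence/co-metastasis matrices, the screening report,
the serialized cascade + regression model (`model.json`), cross-validation
and evaluation reports, per-patient scores, and a manifest; identical
configs and seeds reproduce every file byte for byte.

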