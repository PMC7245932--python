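# Methods

## Measurement model and scores

The pipeline's input is a manual per-nucleus tally of transcription-site
signals of imprinted genes, counted in four representative high-power
fields per gene and sample: `n0` nuclei without signal, `n1` with one
signal, `n2` with two, `n2plus` with more than two.  Fields are **summed,
not averaged**, before scoring: the three scores are ratios of pooled
nuclei, and summing keeps integer counts and weights fields by how many
nuclei they actually contain.

With `E = n1 + n2 + n2plus` expressing nuclei and `T = n0 + E` total,

* `TE  = 100·E/T` — fraction of nuclei expressing at all,
* `BAE = 100·n2/E` — biallelic fraction among expressing nuclei,
* `MAE = 100·n2plus/E` — multiallelic fraction among expressing nuclei.

Degenerate denominators: when `E = 0` we set `BAE = MAE = 0` (and
`TE = 0` when `T = 0`).  Absence of expression cannot be evidence of
malignancy, and the TE gate classifies such samples negative regardless,
so the convention is inert downstream.

Scores are carried as floating percentages throughout; rounding to
integer percent (half away from zero) happens only in human-readable
reports.

Group summaries use medians with interquartile ranges; quartiles use
linear interpolation between order statistics (numpy's default), a
convention we fix explicitly because several exist.  Z-score matrices
used for heat-map export are standardised per cancer type with the
sample standard deviation (n−1); whether the original heat maps used
sample or population scaling is not determinable, and the choice only
rescales columns.

## Threshold calibration

A gene calls a sample through the rule

```
negative           if te < te_min          (TE gate)
positive (bae)     elif bae > bae_min
positive (mae)     elif mae > mae_min
negative           otherwise
```

Boundary conventions are the literal reading of the decision rule: the
gate fires strictly below its threshold (equality passes), positivity
requires strictly exceeding a cutoff.  The TE gate exists because at
very low total expression (a few percent) a couple of two- or three-dot
nuclei inflate BAE/MAE arithmetically without signalling malignancy.

ROC curves are built over the score's admissible cutoffs — midpoints
between consecutive distinct observed values plus ±∞ sentinels — with
the trapezoidal AUC, which on that threshold set equals the
Mann–Whitney pair-count probability with ties counted half.  The
single-measure "optimal threshold" maximises Youden's J (the criterion
pROC calls "best"); no criterion was stated for the original analysis,
and Youden is the field default.  Ties break toward higher specificity,
then the lower cutoff.

Full calibration searches the exhaustive grid of `(te_min, bae_min,
mae_min)` candidate triples (each measure's midpoint candidates plus the
disabling sentinels 0 and 100).  The per-measure Youden optima are grid
members, so the joint search starts from and can only improve on them.
The specificity floor is a hard constraint and sensitivity the
objective:

* screening mode (all cancer types pooled): specificity ≥ 80 %;
* per-cancer mode (model building): sensitivity and specificity both
  strictly > 70 %.

Ties break toward higher specificity, then the lowest TE gate, then the
lowest BAE and MAE cutoffs, making calibration deterministic.  The
search is evaluated through 2-D cumulative histograms per TE-gate
candidate, so it is O(n³) in distinct values but vectorised; study-scale
cohorts calibrate in seconds.  When the floors are unsatisfiable the
constrained-best triple (maximal min(sensitivity, specificity), then
maximal sum) is returned with `feasible=False` rather than an error, so
screening can still report how badly a gene fails.

Gene screening retains a gene when it achieves sensitivity > 80 % at the
80 % specificity floor, drops it below 60 %, and flags the band between
for review.  Screening pools every cancer type; gastric SNRPN
observations are excluded from pooled statistics via a configurable
(cancer type, gene) exclusion list, because SNRPN scores *fall* with
malignancy in gastric tissue and would contaminate the pooled estimate.

## Panel models

Each cancer type gets a model over GNAS, GRB10 and SNRPN with per-cancer
thresholds and a 2-of-3 positive vote for malignancy.  The gastric
exception — SNRPN excluded, GNAS and GRB10 both required — is expressed
as configuration (`genes`, `required_genes`) rather than code, so other
tissue-specific rules are data.  Models serialise to JSON; the file
alone is sufficient to classify new score tables.

Evaluation counts TN/FP/FN/TP against benign/malignant truth and derives
sensitivity, specificity and accuracy.  A rate whose class is empty is
reported as undefined, never as zero.  The package embeds the published
per-cancer confusion counts of the ten-cancer clinical study it is
designed after, purely as a cross-check that the evaluation arithmetic
reproduces the reported percentages after integer rounding.

## Robust rank-order test

"Robust rank-order" is implemented as the Fligner–Policello test, the
standard procedure by that name for two-sample location problems with
unequal variances; ties are half-counted in the placements.  We orient
the statistic so that U > 0 when the first sample tends larger (the
mirror image of the textbook orientation, which is clearer for the
one-tailed "greater" alternative used throughout).

p-values: the standard normal upper tail when both groups have ≥ 12
observations (configurable), otherwise the permutation distribution of
the placement sum — exhaustive enumeration when the number of label
assignments is ≤ 20 000, else Monte Carlo with an explicit, mandatory
seed.  Exact enumeration uses the mid-p convention (half weight on
assignments tying the observed statistic), so exchangeable samples give
p = 0.5 exactly, matching the asymptotic p at U = 0; Monte Carlo uses
the add-one rule (the observed assignment counts once).  A zero
studentising denominator — both groups internally constant — falls back
to the permutation path, where the placement sum is always defined.

The significance screen tests malignant > benign > normal one-tailed for
every gene × measure at α = 0.01 with no multiplicity adjustment,
matching the original analysis; Benjamini–Hochberg is available but off
by default.

## Synthetic cohorts

No per-class score distributions were published numerically (box plots
only), so the generator's class profiles are design values chosen to
reproduce the qualitative ordering normal < benign < malignant in TE,
BAE and MAE:

| class | (p0, p1, p2, p2plus) | TE | BAE | MAE |
|---|---|---|---|---|
| normal | 0.88, 0.10, 0.018, 0.002 | 12 % | 15 % | 1.7 % |
| benign | 0.75, 0.17, 0.06, 0.02 | 25 % | 24 % | 8 % |
| malignant | 0.50, 0.22, 0.18, 0.10 | 50 % | 36 % | 20 % |

Per sample × gene the probability vector is drawn from a Dirichlet with
concentration 50 around the profile (Dirichlet-multinomial rather than
plain multinomial, so cohorts show realistic between-sample
overdispersion and ROC curves are non-degenerate); nuclei per field are
Poisson(150); the four fields are multinomial draws from the sample's
vector.  IGF2 and IGF2R use deliberately weak profiles — mild loss of
imprinting in every class, a small benign→malignant shift and
concentration 10 — so that screening exercises rejection as well as
retention: across seeds they calibrate to roughly 40–60 % sensitivity at
the 80 % specificity floor, below the retention bar.  Gastric SNRPN is
modelled by swapping the benign and malignant profiles when the
inversion flag is set.

Randomness is keyed per (seed, sample, gene, field) through CRC-derived
entropy into numpy's `default_rng`, so any subset of a cohort is
byte-reproducible independently of generation order.

The default study-scale config mirrors the published model-building
evaluation set: ten cancer types totalling 204 benign and 654 malignant
samples (per-type sizes taken from the evaluation table, whose bladder
and thyroid benign counts are 3 lower than the recruitment table's — we
follow the set the models were actually evaluated on), plus a screening
sub-config with 3 normal and 5 benign controls per type and 99 malignant
samples over the ten types, five genes.  Summed, the two synthetic sets
contain 1037 samples; the original study counted 1013 *cases* because
normal screening tissue was taken adjacent to benign lesions from the
same patients.

## What the synthetic results do and do not show

The parameter-recovery experiment (simulate at study scale → calibrate
per cancer under the >70 % floors → panel vote → evaluate) recovers
near-perfect operating characteristics at the default profiles.  That
validates the machinery — the calibration search honours its
constraints, the vote and the gastric rule compose correctly, seeded
runs are reproducible — but it is not a reproduction of the clinical
performance figures: the generator's class separation is a design
choice, thresholds are evaluated on their own calibration cohort (as in
the original model-building sets), and real tissue heterogeneity,
counting error and between-hospital variation are not modelled.  The
published confusion counts are reproduced exactly, but only as
arithmetic on the printed table.

## Problem sizes and numerical choices

Tests run the full study-scale recovery (858 samples × 3 genes × 4
fields), a 2000-replicate null calibration of the rank test at groups of
25, a 120-replicate power check at groups (20, 40), 200-instance ROC
oracle sweeps and brute-force calibration comparisons on cohorts of ≤ 12
samples; the whole suite completes in well under a minute.  Floating
comparisons against oracles use 1e−12 tolerances; count arithmetic is
exact integer.  Threshold feasibility is decided on integer counts
(`tn·100 ≥ floor·n_neg`) to avoid floating-point boundary artifacts.

## Known limitations

* Calibration evaluates thresholds on the cohort that produced them;
  there is no held-out validation (the original study reported
  model-building performance the same way and deferred validation to
  later cohorts).
* The Fligner–Policello identification of "robust rank-order" is the
  standard reading but an inference; no citation pinned the test down.
* Generator profiles are qualitative stand-ins, not fitted to data.
* The classifier is binary; no graded malignancy score is produced.
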