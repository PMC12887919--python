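# Methods

## Design under analysis

The pipeline targets a dual-batch label-free quantification (LFQ)
design: a shared protein universe measured in two LC-MS/MS acquisition
batches ("group1", "group2"), each batch holding its own treatment and
control specimens (2+2 in the emulated study), with a full
treatment×control comparison cross inside each batch. Batches differ
only in acquisition date, but spectral ionization varies between runs,
so each batch is filtered independently and conclusions are restricted
to proteins observed in both (the combined group, CG).

## Identification-quality filtering

A protein survives QC when q ≤ `q_max` (default 0.05), distinct
peptides ≥ `min_peptides` (default 2) and PSMs ≥ `min_psms` (default
4). The defaults encode the conventional exclusion wording — "q
greater than 0.05", "fewer than two peptides", "three or fewer PSMs" —
as inclusive retention bounds, so the boundary cases (q = 0.05, 2
peptides, 4 PSMs) are kept. Thresholds are monotone: tightening any of
them can only shrink the survivor set, and the filter is idempotent.

## Ratios, censoring and significance

Specimen intensities are first rescaled so every specimen has the same
total abundance (the median of per-specimen totals). This is a
composition-sensitive step: it assumes most proteins are unchanged,
which holds for proteome-scale tables but fails on very small protein
panels where one strongly shifted protein moves the totals
(demonstrated in `examples/04`); on such inputs normalization should
be skipped or replaced.

The abundance ratio for one comparison is treatment over control on
the normalized protein intensity. Its log2 is clamped to ±`cap`
(default 3.32 = log2 10, i.e. raw ratios live in [0.1, 10]); clamped
values are flagged censored, mirroring the ±3.32 sentinels that LFQ
software emits for effectively infinite ratios.

The per-comparison p-value is a reconstruction, since pairwise designs
admit no specimen-level replication: a two-sided one-sample t-test of
the protein's peptide-level log2 ratios against 0, using the peptides
quantified on both sides (≥ 2 required, otherwise p is missing).
Zero-variance degenerate cases return p = 1 when all ratios sit at the
null and no p (rather than a spuriously exact 0) when they sit at a
common non-null value. Adjustment is Benjamini–Hochberg across
proteins within each comparison (configurable to Bonferroni or none).
Swapping treatment and control negates the log2 ratio and leaves p
unchanged.

CGSig selection: significant (adjusted p ≤ `alpha`, default 0.05) in
at least one comparison of *each* batch, and missing in at most
`max_missing` (default 1) of the 8 comparisons, pooled across batches.
The pooled reading of the missingness rule is a choice; per-batch
counts are derivable from the ratio table and the manifest surfaces
retained/discarded separately so either reading can be audited.

## Fold-change summary

Per CGSig protein, the mean log2 fold change averages the uncensored
significant comparisons (censored values carry direction but no usable
magnitude, so they count only toward `n_up`/`n_down`/`n_censored`).
The mean is withheld — the record is "unstable", reported as `xU/yD` —
when the uncensored significant set is empty, |mean| < `epsilon`
(default 0.3), or removing any single value flips the mean's sign.
The leave-one-out rule plus the epsilon floor makes deterministic an
otherwise editorial judgement ("close to 0 and/or one outlier could
change the sign"); epsilon is configurable and logged. Direction comes
from the mean when stable, else from the majority of significant
signs (ties → Mixed).

## Pathway over-representation

`hypergeom_upper_tail(x, K, n, N)` sums the hypergeometric pmf in log
space (log-factorial terms via `gammaln` + `logsumexp`), exact to
~1e-13 against enumeration and stable to N = 1e7. The test is
one-sided over-representation with no cross-pathway correction by
default (significance declared at raw p ≤ 0.05); ranking among
significant pathways is by entity ratio K/N descending, ties broken by
smaller p then pathway id. Note the tail probability *decreases* as N
grows with (x, K, n) fixed — a larger background makes the same
overlap rarer by chance.

The background N for the bundled reference table is not published;
`infer_background` recovers it from the printed 4-decimal (K, ratio)
pairs by interval arithmetic (half-ULP rounding bounds per pair) plus
integer least squares. All 34 bundled pairs are simultaneously
consistent with N ∈ [11015, 11023]; the package default is 11017,
which reproduces every printed ratio exactly at 4 decimals. Recomputed
p-values match the printed ones within 0.001 absolute or 10% relative
on all 34 rows; the residual third-decimal differences reflect the
original web service's query-to-entity identifier mapping (its
effective per-pathway query size differs slightly from 120), which is
not recoverable and is deliberately not absorbed.

## Morphometrics

Skull length is the Euclidean distance between the two cranial
landmarks. Crown area is computed by centering the 25 crown-outline
landmarks, projecting onto the two dominant principal axes of their
covariance (SVD), and taking the area of the planar convex hull
(Qhull). A 2-D projected hull is used because crown "area" is a
footprint in mm²; a 3-D hull would measure surface or volume instead.
Configurations whose second principal extent vanishes are rejected as
collinear. Both phenotypes are exactly invariant under rigid motions.

Welch's unequal-variance t-test with Welch–Satterthwaite (real-valued)
degrees of freedom compares group means; the one-sided alternative is
control > treatment (`a` = control), matching a design that predicts
smaller treatment phenotypes, with a two-sided option. With equal
variances and equal n the df reduces to n1+n2−2.

## Synthetic data generator

The generator emulates the study conditions, not just convenient test
input. Defaults: 2,400-protein universe; per-batch detection
probabilities 0.95/0.70 so the mapped tables are roughly 2,200 and
1,600 proteins with ~1,500 shared (cosmetic sizing, not
acceptance-bearing); 5% planted proteins with signed log2 effects
drawn from ±[1.0, 2.5]; baseline log2 intensity N(20, 2.5); 2–12
peptides per protein per batch with lognormal per-peptide offsets (sd
1.0 log2 units) and per-observation noise sd 0.4; protein intensity is
the sum of its peptide intensities, so protein ratios track the
planted effects.

Dropout is missing-not-at-random: an observation is lost with
probability `logistic(mnar_slope × (mnar_threshold − log2 A))`
(defaults slope 1, threshold 15), giving ~2–3% missing observations
and putting ~5–8% of candidate proteins past the two-missing-
comparison discard rule, similar to the emulated study's 15 of 135. A
protein whose specimens all drop out in a batch stays in that batch's
mapped table as identified-but-unquantified (0 peptides, 0 PSMs): this
keeps the batch-overlap statistics exactly binomial and lets the QC
peptide filter remove it downstream. 2% of proteins per batch are made
to fail each QC criterion. Planted proteins are drawn among proteins
detected in ≥ 1 batch so the ground-truth bookkeeping always holds.

Landmark sets place the skull points at ±L/2 on an axis and the 25
crown points on an ellipse (aspect 1.6) whose inscribed-polygon area
equals the target exactly; isotropic Gaussian noise (skull default
0.05 mm; molar a tenth of that, the molar being an order of magnitude
smaller) and a random rotation + translation are applied per specimen.

What the generator does **not** emulate: peptide-level (as opposed to
protein-level) dropout, shared peptides across proteins, batch effects
beyond detection probability, intensity-dependent variance, or
correlated biological variation between specimens. Passing recovery
tests therefore demonstrates correctness of the selection logic under
the stated model, not robustness to every pathology of real LFQ data.

## Calibration checking of discrete p-values

The hypergeometric statistic is discrete, so its raw upper-tail
p-values are super-uniform by construction: P(p ≤ α) ≤ α, with steps
as large as the largest pmf atom (~0.1–0.3 at realistic pathway and
query sizes). A Kolmogorov–Smirnov comparison of raw tails against a
continuous Uniform(0,1) therefore rejects even for a perfect
implementation. Calibration is instead checked with randomized
p-values, u = P(X > x) + U·P(X = x) with U ~ Uniform(0,1), which are
exactly uniform under the null; the raw tails are separately checked
for super-uniformity at nominal levels. Reported enrichment results
always use the plain upper tail.

## Reproducibility and problem sizes

Every generator is a pure function of its configuration including the
seed; the pipeline derives per-stage seeds from one top-level seed via
`numpy.random.SeedSequence.spawn` and echoes configuration, seeds and
stage counts into a JSON manifest. The shipped test suite runs the
synthetic recovery study at 2,000 proteins × 10 seeds, the exhaustive
hypergeometric enumeration at N ≤ 40, and the brute-force hull
comparison on 200 random 25-point sets — sizes chosen so the whole
suite completes in about a minute on one core while keeping every
statistical check at meaningful power.

## Known limitations

- The per-comparison t-test is a reconstruction; pipelines consuming
  vendor-exported per-comparison p-values can bypass it by feeding the
  deposited ratios/p-values directly into selection and summary.
- Total-intensity normalization is composition-sensitive on small
  panels (see above).
- Enrichment reproduces entity ratios exactly but published p-values
  only up to the original service's identifier mapping.
- No imputation, no protein inference from shared peptides, no
  mixed-model handling of litter or batch covariates.
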