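# Methods

## Data model

An activity panel is a herb × endpoint table of percent-of-control
values on an inverted inhibition scale: 0 = maximal inhibition of the
endpoint, 100 = no effect, values above 100 = enhancement (flagged as
"enhancer/pro-oxidant"; e.g. the enzymatic lipid-peroxidation reading of
149 for *A. dahurica*). Two normalization helpers convert into this
scale: `inhibition_to_remaining` (100 − percent-inhibition, so a reported
enhancement of −49% maps to 149) and `raw_to_percent_of_control`
(100 × treated/control, control > 0). Missing cells are read as `-`,
empty, or `NA` and always written as `-`. Every cell carries provenance:
`measured`, or `literature` with a citation tag for values substituted
from published assays of the same or similar material (cell syntax
`25[lit:hwang2002]`). The `measured_only` pipeline flag masks literature
cells to missing so the sensitivity of any result to these substitutions
can be quantified — whether such literature values were re-normalized to
the same percent-of-control convention upstream is unknowable from the
printed data, so they are stored as printed.

Characters per herb: an ordinal nature (cold, slightly_cold, neutral,
slightly_warm, warm, hot), a non-empty flavor set over {bitter, sweet,
pungent, sour, bland}, meridian tokens, and free-text action tokens.
For plotting and enrichment the nature scale is collapsed to three
levels (cold/neutral/warm), matching the blue/grey/red convention of the
original scatterplots. Free-text property strings ("Pungent, bitter,
slightly warm.") are tokenized on read; unknown flavor tokens warn but
do not abort, a missing nature token does.

## Vector-magnitude scores

For a named endpoint subset the score is the Euclidean norm of the
herb's value vector, rounded to the nearest integer with ties away from
zero. Defaults:

| score | endpoints            | space                  |
|-------|----------------------|------------------------|
| α     | LNE, LE              | lipid peroxidation     |
| β     | 5-LOX, COX-1         | eicosanoid (2D)        |
| χ     | 5-LOX, COX-1, 12-LOX | eicosanoid (3D)        |

Because the scale is inverted, a *small* norm means a *strongly
inhibiting* herb. Under the default `drop_herb` missing policy a herb
lacking any endpoint of a score gets a missing score (this reproduces
the reduced 11-herb χ analysis — four herbs lack a 12-LOX value);
`available_case` computes the norm over the endpoints present.

α definition. The narrative definition of the antioxidant space spans
three endpoints (LNE, LE, XO), but the printed magnitudes are consistent
with the two-component ‖(LNE, LE)‖ norm for 14 of the 15 herbs' columns
— only *A. dahurica*'s printed 191 equals the three-component norm
(‖(94, 149, 74)‖ = 191.1; the two-component value is 176.2). The package
defaults to (LNE, LE) and exposes the three-component variant as
`ALPHA3_SPEC`; both values are reported where they disagree.

Reproduction limits. With integer components as printed, β reproduces
all 15 printed values and χ all 11. α reproduces 11 of 15: besides
*A. dahurica*, three printed values differ by one from the norm of the
printed integers (*A. sinensis* 133 vs computed 133.6, *C. pilosula* 132
vs 132.9, *C. chinensis* 60 vs 59.5). No rounding rule reconciles all
three without breaking β (truncation would turn the printed β of 103
into 102), so these are best explained by norms computed upstream on
unrounded raw data whose printed components were rounded independently.
The tests assert exactly this pattern rather than pretending the printed
column is self-consistent.

## Clustering

k-means with squared-Euclidean cost on the (α, β) and (α, χ) planes,
k = 3 by default, no feature scaling by default (both axes live on the
same 0–200 percent-magnitude scale; z-scoring is available for
generalized use). Herbs with a missing coordinate are excluded from that
plane. Two solvers:

- **Exact** (default for n ≤ 18): depth-first enumeration of set
  partitions into at most k non-empty blocks in restricted-growth-string
  order over herbs sorted by id, with branch-and-bound pruning — adding
  point x to a block of size m and mean μ raises the objective by
  m/(m+1)·‖x−μ‖², which is non-negative, so any partial assignment whose
  cost reaches the incumbent is pruned. Ties go to the lexicographically
  smallest assignment vector (first-found under strict improvement).
  For the 15-point panel (2,375,101 3-block partitions) this runs in
  well under a second.
- **Lloyd** (any n): k-means++ seeding, 100 restarts by default from one
  master seed, assignment ties to the lowest centroid index, empty
  clusters repaired by re-seeding at the point farthest from its current
  centroid. Deterministic given the seed; input order is irrelevant
  because points are sorted by herb id first.

Clusters are canonically relabelled 1..k by ascending centroid norm, so
cluster 1 is always the most active group; equal-norm ties break on the
smallest member id.

On the real (α, β) panel both solvers find the same global optimum
(wss = 13104.4): sizes 4/3/8, with the four bitter/cold cleansing herbs
as cluster 1 and the three sweet eicosanoid-selective herbs as
cluster 2. On the reduced (α, χ) panel the solvers again agree on the
global optimum; the membership shown in the original (α, χ) scatter
differs from that optimum and is consistent with a local optimum of an
unseeded clustering run, so it is reported for comparison but never
asserted. k is fixed at 3 by design; no model selection is attempted.

## Trait association (extension)

The original character overlay is qualitative. The package quantifies it
— and labels the output as an extension: for each trait (collapsed
nature level, flavor, or highlighted action token — expel_wind,
tonify_qi, clear_heat, remove_toxicity, with a small synonym map folding
e.g. "invigorate qi" into tonify_qi) a 2 × k carrier table over clusters
is built. Tests: Fisher's exact (k = 2); for k > 2 an exact test by
complete enumeration of tables with the observed margins under
probability ordering (the Fisher–Freeman–Halton convention, verified
against an independent reference implementation) when at most 10⁶ tables
exist, else a seeded Monte-Carlo permutation of cluster labels
(10⁵ draws, add-one correction so p > 0). Degenerate margins give p = 1
with no rejection. Per trait × cluster pairs, 2 × 2 Fisher p-values with
a 0.5-continuity-corrected odds ratio are BH-adjusted as one family per
run. BH is a monotone transform capped at 1; note it is *not*
idempotent as a function of p-values (q-values of q-values grow), so
only monotonicity and q ≥ p are asserted as invariants. The qualitative
per-cluster composition report is emitted alongside, and reproduces the
original statements (cluster 1: bitter 4/4, cold 4/4; cluster 2:
sweet 3/3).

## Synthetic panels

`generate_panel` draws herbs from a Gaussian mixture in endpoint space:
round-robin cluster memberships (small panels cannot lose a cluster by
chance), independent normal noise per endpoint clipped at 0 (not
truncated-renormalized — simple, and representable enhancer values
above 100 can occur), independent per-cell missingness, and a signature
flavor per cluster carried with probability `trait_purity` (else a
uniformly drawn other signature; the herb's nature is coupled to the
realized flavor). Everything is reproducible from the spec seed. The
"paper-like" centroid preset is the real panel's fitted cluster means,
(38.0, 28.5), (133.0, 30.7), (128.9, 105.4), so synthetic tests exercise
the same geometry as the real data. Defaults: 15 herbs, 3 clusters,
spread 10 (centroid separation ≥ 7× spread — clearly separated, matching
the compact structure of the real panel), purity 1, missingness 0.

What the generator does *not* emulate: assay-level kinetics or
dose–response, correlated noise across endpoints, cluster-size
imbalance, and the mixed-provenance cells of real tables. Passing
recovery tests therefore shows the pipeline recovers planted Gaussian
structure, not that real panels are Gaussian.

Recovery behaviour (computed by the test suite, not assumed): at n = 30,
k = 3, spread 10 and purity 1, mean adjusted Rand index over 100 seeds
is ≥ 0.95 and every cluster-signature trait reaches q < 0.05 in ≥ 95% of
runs; mean ARI is non-increasing across spreads 5 → 15 → 40. Problem
sizes in the suite (50 oracle-equivalence panels at n ≤ 15; 100 recovery
seeds at n = 30; 30 seeds per spread level) were chosen as the smallest
giving stable statistics for these checks.

## Pipeline and outputs

`run_pipeline` chains read → (optional literature masking) → join →
score → cluster (both planes) → associate → report. Outputs: score,
cluster, centroid and enrichment TSVs, the overlay text report, SVG+PNG
scatterplots colored by collapsed nature with species numbered in input
order, a plotted-coordinate TSV manifest (determinism of figures is
defined on this manifest, not raster bytes), and a JSON run manifest
(config, seed, SHA-256 of inputs, package version) sufficient to
re-execute the run. Numeric outputs are byte-identical across reruns
with the same config and seed. Any stage error aborts the run and
removes partial outputs. Reports print the legend line "0 = maximal
inhibition" because the inverted scale is the least obvious convention
in this analysis.

## Known limitations

- The α column inconsistencies above make perfect reproduction of the
  printed magnitude table impossible from its own integer components.
- The exact solver is exponential in principle; the `exact_max_n = 18`
  guard keeps it in the sub-second-to-seconds range and directs larger
  panels to Lloyd.
- The enrichment tests treat herbs as independent draws; phylogenetic or
  phytochemical relatedness (e.g. the two berberine-alkaloid herbs) is
  not modelled.
- No IC50 / dose–response fitting: inputs are single-concentration
  percent values.
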