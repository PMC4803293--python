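# Methods

## The quantity at the core: the histone modification ratio

For a genomic region $R$ and a set of called peaks $P$ for one histone
mark at one developmental stage, the histone modification ratio is the
coverage fraction

$$\mathrm{HMR}(R, P) = \frac{|R \cap \bigcup P|}{|R|} \in [0, 1].$$

Peaks are sorted and merged (including abutting intervals) before the
intersection, so stacked or duplicated peak calls cannot inflate the
ratio. Each core promoter contributes two regions: the core promoter
interval itself (CP) and the transcribed region (T), defined as the span
from the promoter's TSS to the farthest transcription end site among
transcripts sharing that TSS. With three marks (H3K4me3, H3K27ac —
active; H3K27me3 — inactive) this yields six features per promoter and
stage. A study with $n_g$ promoters in a CPE group and 11 stages
produces an $n_g \times 11$-row observation matrix per group (264, 363,
275 and 154 rows at the default group sizes 24/33/25/14).

Coordinates are 0-based half-open throughout. The transcribed region is
stored as the unoriented interval $(\min(tss, tes), \max(tss, tes))$ of
length $|tes - tss|$; for minus-strand promoters the +1 base sits on the
interval boundary, a 1 bp convention choice that is irrelevant to
coverage fractions.

## CPE classification

Promoters are partitioned by the presence of the TATA box and DPE into
Inr (neither), TATA, DPE, and TATA_DPE. Motif presence is decided by
anchored IUPAC consensus matching:

| motif | consensus         | anchoring                                      |
|-------|-------------------|------------------------------------------------|
| Inr   | `TCAGTYKNNNTYNR`  | match starts at −2 (the A of TCA at +1)        |
| TATA  | `STATAWAAR`       | the upstream T (position 2) at −31 or −30      |
| DPE   | `CRWMGCGWKCGGTTS` | match window starts at any of +28..+33         |

Promoter positions have no 0 (−1 abuts +1); the conversion to string
indices happens in exactly one function. The 15-nt DPE consensus is
longer than the stated +28..+33 placement range; the default reads that
range as the set of allowed window *starts*, and a "contained"
registration (window must cover +28..+33, i.e. starts +19..+28) is
selectable. In annotation mode (a curated promoter table) only the
TATA/DPE flags partition promoters; in sequence-scan mode a promoter
with no detectable Inr is left unassigned, since the four groups are
defined among Inr-containing focused promoters. Genes whose promoters
fall into different groups are excluded entirely.

## Expression

A promoter's FPKM at a stage is the sum over transcripts sharing its
TSS (transcripts missing from a stage's table count as zero, with a
warning). Log transformation adds a group-level pseudocount $m$ before
the natural log: $\log(\mathrm{FPKM} + m)$. The default $m$ is the
group's minimum **positive** FPKM: a literal group minimum would be zero
whenever any observation is zero and would fail to prevent $\log 0$,
defeating the pseudocount's purpose. The literal rule remains available
behind a config switch. Note the transform's side effect: observations
with FPKM near zero are raised to $\approx \log m$, and all values gain
$\log(1 + m e^{-y})$; with genome-scale tables $m$ sits at the detection
limit and the shift is negligible, but in a small synthetic group
($\leq$ 363 observations) $m$ can be 0.1–0.4, which visibly shifts the
measured log FPKM of silent observations (see "Known limitations").

## Monte-Carlo cluster significance

Given the matrix rows as points in $[0,1]^d$ and $k$ cluster centers
(taken from a k-means partition by default), the observed statistic is
$W = \sum_i \min_k \lVert x_i - c_k \rVert^2$. The null replaces the
centers by $k$ points drawn uniformly per dimension inside the data's
bounding box (uniform on $[0,1]^d$ selectable), and

$$p_{\mathrm{emp}} = \frac{1 + \#\{W_{\mathrm{null}} \le W_{\mathrm{obs}}\}}{n_{\mathrm{iter}} + 1}.$$

An empirical fraction cannot resolve below $1/(n_{\mathrm{iter}}+1)$, so
a Gaussian lower-tail approximation from the null moments is reported
alongside it; only such a parametric tail can produce the extremely
small magnitudes that tight high-dimensional clusters warrant (the null
$W$ concentrates as the dimension grows, so the z-score scales roughly
with $\sqrt{d}$). The add-one empirical p-value is exactly uniform under
the null, a property the test suite checks by Kolmogorov–Smirnov over
200 replicates. The operation's default is $10^6$ draws; the pipeline
default is $10^5$ and tests use $10^3$–$10^4$, sizes chosen to keep the
suites fast while leaving the statistic's calibration unchanged.

## Regression battery

**Best-subset OLS.** All 63 subsets of the six features are fitted by
OLS (statsmodels); the best model of each size by $R^2$ is kept. The
final model is the *largest* per-size winner in which every coefficient
is individually significant (two-sided t-test, $\alpha = 0.05$), with
ties broken by adjusted $R^2$; an override hook can force a stated
subset, supporting curated exceptions where a marginally non-significant
term is retained on importance grounds. If nothing qualifies, the best
single-feature model is returned carrying a warning flag.

**Cross-validation.** 10-fold CV with a seeded uniform random partition
(no stratification); every observation is predicted exactly once
out-of-fold, and the report carries the Pearson correlation between
measured and predicted log FPKM. Out-of-fold predictions of pure noise
have a small negative correlation bias — the null band on CV r is
one-sided.

**LMG relative importance.** For a $p$-feature model, feature $k$'s LMG
value averages its $R^2$ increment over all $p!$ orders of entry;
grouping orders by the predecessor set gives the exact subset-weighted
form implemented here,
$\mathrm{LMG}_k = \sum_{S \not\ni k} \frac{|S|!\,(p-|S|-1)!}{p!}\left(R^2(S \cup k) - R^2(S)\right),$
normalized to sum 1. Each increment is non-negative, so the weights are
too. The test suite verifies the closed form against an independent
enumeration over orderings to $10^{-10}$, and against the
variance-share closed form on orthogonal designs.

**Random forest.** scikit-learn's RandomForestRegressor with mtry = 2
(`max_features`) and ntree = 500, seeded. Importance is the normalized
mean decrease in node impurity; the measured-vs-predicted correlation
uses out-of-bag predictions by default (the honest analogue of the
linear CV), with resubstitution fitted values selectable.

**Void split.** TATA-containing groups harbour promoters in the void
state: no modification anywhere, yet substantial measured RNA. A linear
model sees those observations at $x \approx 0$ and predicts
$\approx$ the intercept, so they populate a narrow predicted-log-FPKM
window regardless of their measured values. The split moves
observations whose prediction falls inside a closed window — (0.7, 1.0)
for TATA, (0, 1.0) for TATA_DPE by default — into the "n" subset,
leaving the prediction-consistent "p" subset. The prediction vector is
an argument, not recomputed, because linear CV and forest predictions
give different splits. The pipeline feeds the full six-feature model's
CV predictions to the split rather than the selected subset's: the
split is a prediction task, and the full model avoids the
omitted-variable intercept shifts that arise in seeds where selection
drops a weak term.

## The synthetic study generator

The generator emits everything the pipeline consumes — promoter FASTA
with planted motifs, promoter/transcript BED, 33 peak BED files, an
expression TSV — plus ground-truth tables. Design choices, with the
reasoning:

* **Archetypes.** Each promoter is `active` (active marks high,
  H3K27me3 low), `inactive` (H3K27me3 high, active marks low), or
  `void` (every HMR exactly 0 — the void state is the absence of
  detected modification). Default mixes: Inr 10/8/6, DPE 10/9/6, TATA
  11/7/15, TATA_DPE 4/3/7 (active/inactive/void).
* **Feature ranges.** Within an archetype every feature draws
  independently from its own uniform range (e.g. active H3K4me3_CP in
  0.45–1.0 but active H3K4me3_T in 0.1–0.6). Peak breadth differs
  between the promoter-proximal window and the gene body, so the same
  mark's CP and T ratios are correlated through the archetype but far
  from identical. These within-archetype spreads are also what makes
  the planted regression slopes identifiable: with near-degenerate
  ranges the six features collapse onto the two between-archetype
  directions and no subset selection can separate same-polarity
  features. The ranges were fixed after a design-stage power analysis.
* **Stage dynamics.** TATA-less promoters hold their state across the
  11 stages up to ±0.015 jitter (their modifications are static);
  TATA-containing non-void promoters toggle their whole state on/off
  per stage with probability 0.5, and an "off" stage has zero HMRs but
  still follows the expression model.
* **Expression.** log FPKM = planted per-group linear model on the
  *realized* HMRs + N(0, 1). The planted models are the published
  per-group equations (e.g. Inr: 2.98·K27ac_T + 1.61·K4me3_CP −
  0.80·K27me3_CP + 0.82). Void promoters in TATA-containing groups
  instead draw log FPKM uniformly on intercept ± 1 — expression
  decoupled from the (absent) chromatin features, centered on the
  intercept so that the void subpopulation does not displace the
  fitted intercept; that centering is precisely what places their
  predictions inside the void removal window. Emitted FPKM is
  $e^y$ split across 1–3 TSS-sharing transcripts by Dirichlet weights,
  with values below 0.01 reported as 0.
* **Peak realization.** A target CP ratio becomes a single peak of
  round(target × 100) bp anchored at the CP region start; the
  transcribed-region target is topped up by a far-end (TES-side) peak
  whose length accounts exactly for the CP peak's overlap with the
  transcribed region. Realized ratios are therefore exact at 1 bp
  resolution, and the truth tables store the realized values.
* **Calibration mode.** `feature_distribution="iid_uniform"` replaces
  the archetype draw with i.i.d. uniform features — a neutral, fully
  identifiable design used to calibrate the selection rule's recovery
  properties separately from the archetype geometry.
* **Determinism.** One root seed spawns named substreams (sequences,
  targets, expression, geometry); the same seed reproduces every output
  file byte for byte.

## What the generator does and does not emulate

It reproduces the study's *structure*: group sizes, stage count,
archetype patterns and their group-specific dynamics, planted linear
links between chromatin state and RNA output, motif placement at the
canonical offsets. It does not emulate read-level noise, peak-caller
artifacts, genome-scale sequence composition, nucleosome occupancy,
isoform structure inside transcribed regions, or the long-tailed
genome-wide FPKM distribution. Passing tests therefore demonstrate that
the estimators recover planted structure under the study's geometry and
noise scale — not that the biological conclusions transfer to any real
dataset.

## Numerical choices and degenerate inputs

* Interval merging treats abutting intervals as one; coverage is the
  only consumer.
* Exact-zero-length regions are rejected at construction
  (start < end is an interval invariant).
* Rank-deficient OLS designs raise an error naming the collinear
  features; constant responses make the forest refuse to fit; constant
  features yield NaN correlations (undefined, never silently 0).
* The frequency statistic uses a strict inequality (HMR > 0.5) and
  counts promoter × stage observations; a per-promoter mode (stage
  median above threshold) is available.
* k-means restarts use nested seeds (seed, seed+1, …), making the
  best-of-restarts WCSS monotone non-increasing in the restart count.
* Cluster-test chunking bounds memory at a few hundred MB regardless of
  the draw count; results are independent of chunk size.

## Known limitations

* With a small synthetic expression table the group-minimum pseudocount
  is large (0.1–0.4), which raises measured log FPKM of silent
  observations by up to log 2 and shifts fitted intercepts upward by
  ~0.05–0.15. In the file-backed round trip this moves void-state
  predictions toward the upper edge of the fixed removal window; the
  void-split guarantees are therefore stated (and tested) on the
  observation matrix the regression consumes. Real, genome-scale tables
  do not show this artifact.
* Exact support recovery by the all-significant selection rule is
  capped near 85% at $\alpha = 0.05$ with three inactive features: the
  probability that the best size-4 subset happens to have all
  coefficients significant is $\approx 1 - 0.95^3$ by the exactness of
  the t-test null. Recovery guarantees are therefore stated as support
  *inclusion* with slope accuracy, not exact equality.
* With three archetypes the between-archetype feature variation spans
  only two directions; a slope of 0.80 on a [0,1]-bounded feature at
  n = 264, sigma = 1 is then at the edge of detectability no matter how
  the ranges are drawn. The archetype defaults reach ~80% inclusion
  recovery; the iid-uniform calibration mode reaches ~96%.
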