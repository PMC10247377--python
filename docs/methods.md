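# Methods

This note documents the models, numerical choices and defaults behind each
stage of `preneo`, what the simulator does and does not emulate, and the known
limitations. Problem sizes quoted for validation studies are the ones the
test suite and `scripts/acceptance.py` actually run.

## The simulated experiment

The simulator reproduces the design of a long-term organoid evolution
experiment: clonally derived cultures grown for hundreds of days under weekly
passaging, barcoded once with heritable expressed barcodes (one unique
barcode per cell), split into replicates that evolve in parallel, and
sampled longitudinally by shallow WGS, barcode amplicon sequencing and
scRNA-seq.

### Branching process

Time advances in whole days. Each cell divides with probability

    p_div = base_growth_rate · fitness(clone) · max(0, 1 − N/K)

where `N` is the population size and `K` the carrying capacity. Fitness is
the product over the clone's distinct events of per-event coefficients
(1 + s per event) times contingency multipliers `(prerequisite, event) → m`
applied when both events are present. An optional per-day death probability
(`death_rate`, default 0) allows cultures to crash; without it extinction is
unreachable under division-plus-bottleneck dynamics.

At each division, every chromosome arm missegregates independently with
probability `missegregation_rate` (the daughter gains or loses one copy,
bounded to [0, 4]; whole-genome doubling is excluded because the modelled
cultures remain essentially diploid), and each named fragile locus suffers a
focal one-copy deletion with `focal_deletion_rate`. Events are recorded as an
append-only tuple, so a child clone's event list strictly extends its
parent's.

Every `passage_interval_days` (default 7) the population is multinomially
downsampled to `bottleneck_size` — the drift mechanism of the system. The
pre-bottleneck census is recorded; it doubles as the per-passage total cell
count consumed by the growth-curve stage.

At `barcoding_day` every cell receives a unique barcode (each cell founds a
lineage clone). The pool then expands until `split_day` — by default one
passage interval later — and is partitioned uniformly at random into
`n_replicates` independent continuations. The expansion step matters: if the
split happened at barcoding, each barcode would exist in exactly one
replicate and cross-replicate winner concordance would be undefined. Barcode
dropout (lineage-level silencing, default off) is decided per lineage per
passage and recorded in the ground truth.

All randomness flows from one seed through named substreams
(`evolution`/`swgs`/`barcode`/`scrna`, with per-replicate and per-day
children), so the same seed reproduces the entire history bit for bit while
observation draws at different days remain independent.

### Default parameters

| parameter | default | rationale |
| --- | --- | --- |
| `n_founder` | 100 cells | clonally derived culture, order of magnitude guess |
| `bottleneck_size` | 1 000 cells | organoid passage; effective size unknown in the real system |
| `carrying_capacity` | 30 000 cells | ~30× outgrowth between passages is never reached in 7 days |
| `base_growth_rate` | 0.35/day | ~8-fold weekly outgrowth, typical of organoid culture |
| `passage_interval_days` | 7 | weekly passaging |
| `missegregation_rate` | 1e-3 per arm per division | elevated chromosomal instability after the knockout; places early arm events at detectable frequency around days 100–250 and contingent late events around days 300–500, the ranges the real cultures show |
| `focal_deletion_rate` | 2.5e-4 per locus per division | fragile-site deletions appear early and often |
| `fitness_table` | 9p−, 3p−: 1.08; FHIT−, CDKN2A−: 1.02 | the two early arm losses appear first and at comparable times, so they share one coefficient |
| `contingency_table` | 18q−, 20q+: ×1.08 given 9p− or 3p− | encodes the preferred order: late events are neutral until an early loss is present |
| `barcoding_day` | 108 | within the real transduction window (days 101–115) |
| `n_replicates` | 3 | the experimental design |
| `n_days` | 400 | long enough for one full sweep plus the start of a second |

The population sizes are order-of-magnitude choices, not claims about the
real cultures (whose effective size is unstated); conclusions that depend on
absolute drift strength (e.g. the numeric value of the neutral concordance)
are statements about these defaults only.

### Observation models

*Shallow WGS*: the expected read count of a bin is proportional to the
population-weighted mean copy number ÷ 2, scaled so the genome-wide mean
equals `mean_coverage · bin_size / read_length`; counts are Poisson. The
default 0.2× emulates the real depth; validation studies that need reliable
arm calls sample at 2–5×.

*Barcode reads*: Dirichlet-multinomial around the true readable-barcode
frequencies; `overdispersion` is 1/concentration, so 0 is exactly
multinomial. Silenced lineages contribute no reads.

*scRNA-seq*: cells drawn proportional to clone sizes; gene counts are
negative binomial with mean `baseline · depth · (copy number / 2)` for genes
on altered arms (focal deletions subtract half the dosage over their
interval). Genes are laid out evenly along each arm; a few `MT-*` genes on a
dedicated contig support QC. Baselines depend only on the seed, so query and
reference samples from one experiment share them. A `low_quality_fraction`
collapses that share of cells to 3% depth to exercise QC.

The simulator does **not** emulate: GC or mappability bias, sequence-level
variation (SNVs/SVs), barcode sequencing errors or collisions, batch effects,
doublets, ambient RNA, or cell-type heterogeneity within a clone. Passing
tests therefore demonstrate correctness of the inference machinery under the
stated generative model, not robustness to those real-data artefacts.

### The scaled demo genome

`demo_genome()` has 22 autosomes at one tenth of the human lengths with
centromeres at their human relative positions, 1 Mb bins (287 bins total) and
the two fragile loci (FHIT on 3p, CDKN2A on 9p). Arm identities carry over;
everything accepts a full-size genome model via `read_genome_model` (default
bin size 50 kb).

## Copy-number stage

Normalization divides counts by optional per-bin baseline weights (e.g. a
matched wild-type sample), then by the median of the nonzero ratios;
zero-count bins are imputed to half the smallest nonzero ratio and flagged.
GC correction is deliberately omitted (simulated reads carry no GC bias);
the baseline hook is where it would enter for real data.

Segmentation is per-chromosome recursive binary splitting on the RSS
reduction statistic `n_l n_r / n · (mean_l − mean_r)²`, with ties broken at
the leftmost bin. A split is accepted when the reduction exceeds
`penalty · σ²` (default penalty 10), with σ per chromosome from
`1.4826 · MAD(first differences) / √2`; on noise-free input σ = 0 and any
positive reduction is accepted, which makes the procedure exact there — the
test suite checks equality with an exhaustive minimal-breakpoint search on
500 random noise-free profiles.

Calling: a bin is altered when its segment mean crosses ±0.15 (≈ a one-copy
change in 20% of cells on a diploid background); an arm event needs ≥ 50% of
the arm's bins altered in one direction; a focal event needs an altered
segment overlapping the named locus with the surrounding arm not called the
same way. These defaults are declared, configurable, and not claimed to match
any particular published pipeline. FGA counts altered autosomal bins; wGII
averages per-chromosome altered fractions with equal weights; sex chromosomes
are excluded from both.

## Event timing

Persistence is a strict suffix condition (present at the final day and at
every sampled day from appearance onward); a `tolerance` knob allows k
missed intermediate calls, default 0, because a 0.2× profile can drop an
event below threshold at a single time point. Appearance is reported as the
sampled day, not an interpolated midpoint. One caveat discovered during
testing: removing a *present* intermediate time point can delay the
appearance day (the suffix loses a witness), so the monotonicity property
holds only for removing absent time points — the property test asserts that
form. The FGA plateau day is the first sampled day after which an isotonic
fit rises by less than 10% of its total range; it is descriptive plumbing,
not an asserted claim about real data.

## Subclone deconvolution

The mixture algebra assumes a diploid background and one-copy events:
R = 2^(segment mean), loss f = 2(1−R), gain f = 2(R−1), clamped to [0, 1]
with an out-of-model warning beyond [−0.05, 1.05]. Overlapping events on the
same arm in different clones are outside the model by construction.
Trajectories are compared in L∞ distance (correlation is unstable near 0)
and grouped by complete linkage at threshold 0.1. Nesting uses frequency
containment within `nesting_tolerance` (default 0.1, matching shallow-depth
noise) plus first-appearance ordering; parents are assigned along a canonical
order (appearance day, then mean frequency, then name), which makes the
result acyclic by construction, and a pigeonhole check flags sibling sets
whose frequencies sum above their parent. Violations mark the result
unresolved rather than raising.

## Barcode dynamics

Loess is local-linear with tricube weights over the `ceil(span·n)` nearest
neighbours (default span 0.75, degree 1 — unstated in the original analysis,
so declared here); the local slope at each point is the derivative. The
fitness surrogate is the derivative of *log* abundance, which removes the
census scale: with abundance = frequency × census, constant frequencies give
every lineage the census growth rate. Zero abundances are floored at half a
cell before the log. Winner = final-day maximum (ties flagged, smallest
barcode id wins); dominance day = first sampled day at ≥ 0.5. Replicate
concordance uses per-barcode Spearman correlations over time, averaged over
barcodes above `min_frequency` in any replicate; colour ranks order barcodes
by maximum cross-replicate frequency (rank 1 = the "red" clone) and are
invariant to replicate order. `fit_selection` is OLS on logit frequency —
exact on noiseless logistic trajectories because the logit linearizes them —
with a t-interval from the slope standard error.

## Single-cell stage

The expression-CNA caller is intentionally a light re-implementation of the
moving-average approach (no HMM): log₂ ratio of CP10K expression to the
reference-cell mean per gene (pseudocount 1), smoothed along each chromosome
with a centred `window_genes` moving average (default 101), median-centred
per cell (this, plus CP10K, makes calls exactly invariant to per-cell depth
scaling), then re-centred on the smoothed reference cells so diploid arms sit
at 0. Arms with fewer than `window_genes / 2` measured genes are uncallable.
Calls use |arm mean| ≥ 0.1 (a 3-copy arm sits near log₂ 1.5 ≈ 0.585);
per-barcode consensus is the majority call over cells, emitted only for
barcodes with ≥ 10 cells. Specificity depends on gene density and depth: the
generative-null test uses ~200 genes per arm at high expression, comparable
in information to a few thousand informative genes in a real run.

LSI follows the projection recipe: top-variance gene vocabulary, TF-IDF
(log1p of depth-normalized TF × 10⁴, IDF = log(1 + N/(1 + df))), truncated
SVD (default 30 dims; 10 in desk-scale demos), L2 normalization; the stored
IDF and loadings project query cells without refitting, so reference cells
reproduce their own coordinates. kNN label transfer uses Euclidean distance
on the normalized coordinates with k = 25; per-sample frequencies average
per-cell neighbour-label fractions (a majority-vote variant sits behind a
flag, since either reading of "projected cell type frequencies" is
defensible). Batch correction is out of scope; pre-corrected matrices can be
supplied directly.

Differential expression is a two-sided Wilcoxon rank-sum test on
depth-normalized log counts — exact enumeration below 10 cells per group
when ties permit, tie-corrected normal approximation otherwise; constant
genes get p = 1; Bonferroni multiplies by the gene count. Gene-set enrichment
is the two-sample KS statistic between in-set and out-of-set ranks (exact
below 20 members), signed by the mean rank shift, with Benjamini–Hochberg
across sets; sets with fewer than 5 members in the ranking are skipped.
Under a null ranking the KS p-values are uniform (the calibration study
measures the fraction below 0.05 over 2000 draws).

## Validation studies (sizes as run)

* Segmentation oracle: 500 noise-free profiles, ≤ 50 bins, ≤ 2 breakpoints,
  adjacent levels ≥ 0.05 apart; boundary sets must match exhaustive search
  exactly.
* Selection recovery: one clone at 5% of 400 barcoded founders, advantage
  s ∈ {0.05, 0.1}/day, weekly bottleneck 1 000, reads at depth 10⁴ over 8
  weekly time points, 100 runs; bias < 0.02 and RMSE < 0.03 per day
  (measured ≈ 0.006).
* Winner determinism: 20 barcoded founders, one carrying s = 0.1 (initial
  frequency 0.05), split into 3 replicates at day 14, winners read from
  sampled barcode counts at day 100; the same barcode wins all three
  replicates in ≥ 90% of 100 runs. The drift-only null is *estimated by
  simulation* (100 neutral triplets), because replicates share pre-split
  drift and weak post-split drift preserves the pool ranking — both the
  exchangeable 1/B² null and the fixation-probability martingale are wrong at
  this horizon; a second, independent 100 triplets must fall inside the
  99.9% binomial interval of that estimate.
* Timing order: 50 unbarcoded cultures, 600 days, ground-truth event
  frequencies sampled weekly; an event is present at ≥ 20% population
  frequency, appearance follows the same persistence rule as the bulk
  pipeline. Per culture, median appearance of {9p−, 3p−} must precede that of
  {18q−, 20q+}; with the shipped contingency table this holds in ≥ 95% of
  cultures, with pooled medians near days 210 (early) and 330–350 (late).
* Statistical calibration: the 3-vs-3 two-sided rank-sum example has exact
  p = 2/C(6,3) = 0.1; KS null p-values are uniform at the 0.05 mark within a
  binomial interval over 2 000 draws; Bonferroni and BH are monotone and
  Bonferroni is at least as conservative.
* kNN oracle: indexed 25-NN frequencies equal a brute-force distance scan on
  a 200-cell reference exactly.
* End-to-end: the default demo configuration (300 days, 6 sWGS time points,
  5 barcode time points, 300 cells) runs all stages in a few seconds and is
  byte-identical on a reseeded rerun.

## Known limitations

* The simulator's clone-level bookkeeping caps per-arm copy number at 4 and
  omits whole-genome doubling, allele-specific states and LOH.
* The mixture algebra cannot separate two subclones altering the same arm in
  the same direction; such configurations surface as out-of-model warnings or
  unresolved trees rather than wrong answers.
* The demo experiment is not calibrated to reproduce the real system's
  headline magnitudes (e.g. a single dominant barcode at 75% within 144 days
  of barcoding requires a stronger, rarer pre-barcoding advantage than the
  default mutation-driven regime generates); the acceptance script reports
  what the demo actually produces.
* Timing is reported on the sampling grid; coarse grids tie the appearance
  days of a parent clone and a nested contingent child, which is why the
  ground-truth timing study samples weekly.
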