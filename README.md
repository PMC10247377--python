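# preneo

Longitudinal clonal-evolution analysis for *TP53*-deficient gastric organoid
cultures — and, more generally, for any barcoded serial-passage evolution
experiment read out by shallow whole-genome sequencing (sWGS), lineage-barcode
amplicon sequencing and scRNA-seq.

The package is written for computational biologists who study how aneuploidy
and clonal dynamics unfold after a tumour-suppressor knockout: it covers the
full analysis chain from binned read counts to fishplots and
genotype-to-phenotype linkage, together with a stochastic simulator of the
experiment so that every stage can be validated against known ground truth
without any external data.

## What it computes

**Copy-number profiling (`preneo.cna`).** Binned read counts (50 kb windows
at ~0.2× coverage in the real experiment) are median-normalized to log₂
ratios, segmented per chromosome by recursive binary splitting (a split is
accepted when it lowers the residual sum of squares by more than
`penalty · σ²`, with σ estimated from the MAD of first differences), and
summarized as arm-level and focal event calls. Aneuploidy is quantified as
FGA (fraction of altered autosomal bins) and wGII (per-chromosome altered
fraction, equal chromosome weights).

**Event timing (`preneo.timing`).** An event is *persistent* when present at
the final sampled day; its time of appearance is the start of its persistent
suffix. Persistent appearance days are summarized across cultures into the
preferred temporal order (median + IQR per event).

**Subclone deconvolution (`preneo.subclones`).** On a diploid background, a
one-copy event in a fraction *f* of cells shifts the segment mean to
log₂((2 ± f)/2); inverting this gives per-event frequency trajectories, which
are grouped by complete-linkage clustering on L∞ distance, nested by
frequency containment into a fishplot-ready clone tree, and scanned for
clonal-interference and coexistence episodes.

**Barcode dynamics (`preneo.barcodes`).** Barcode × day count tables become
frequency trajectories, absolute growth curves (frequency × passage census),
Loess-smoothed log-abundance derivatives as fitness surrogates, Muller
tables, winner/dominance statistics and cross-replicate determinism metrics.
A lineage's selection coefficient is estimated by OLS on logit frequency:
under logistic competition, logit f(t) = logit f₀ + s·t.

**Single cells (`preneo.cells`).** Per-cell arm-level copy number from
expression dosage (moving-average log ratio versus a diploid reference, with
per-barcode consensus karyotypes), LSI (TF-IDF + truncated SVD) projection
onto a labeled reference with 25-nearest-neighbour cell-type frequencies,
two-sided Wilcoxon rank-sum differential expression with Bonferroni control,
and KS-statistic gene-set enrichment with Benjamini–Hochberg adjustment.

**Simulator (`preneo.sim`).** A discrete-day branching process over clones:
logistic growth, per-arm missegregation and focal fragile-site deletion,
multiplicative fitness with contingency ("preferred order") multipliers,
weekly passage bottlenecks, unique per-cell barcoding with replicate
splitting, and observation models for all three data streams (Poisson sWGS
bins, Dirichlet-multinomial barcode reads, negative-binomial scRNA counts
with dosage effects). Identical seeds give bit-identical histories.

## Worked example

```python
import numpy as np
from preneo import sim, cna, demo_genome
from preneo.barcodes import BarcodeCounts, fit_selection, winner_and_dominance

genome = demo_genome()                      # 22 scaled autosomes, 1 Mb bins
cfg = sim.SimulationConfig(genome=genome, seed=7, n_days=300)
history = sim.simulate_evolution(cfg)       # barcoded at day 108, split into 3

cov = sim.sample_swgs(history, day=300, mean_coverage=2.0, replicate=0, seed=7)
profile = cna.call_profile(cov, genome)
print("events:", sorted(profile.present_events()))
print(f"FGA = {cna.compute_fga(profile):.3f}, wGII = {cna.compute_wgii(profile):.3f}")

days = [115, 150, 200, 250, 300]
counts = sim.sample_barcode_counts(history, replicate=0, days=days, seed=7)
bc = BarcodeCounts("R1", counts)
res = winner_and_dominance(bc)
print("winner:", res["winner_id"], f"final frequency: {res['final_frequency']:.3f}")

traj = bc.frequencies.loc[res["winner_id"]]
keep = (traj > 0) & (traj < 1)
fit = fit_selection(np.array(days, float)[keep], traj[keep].to_numpy())
print(fit.summary())
```

Output:

```
events: ['13q-', '14p+', '3p-']
FGA = 0.070, wGII = 0.066
winner: BC01465 final frequency: 0.308
selection coefficient s = +0.0322/day (SE 0.0027, 95% CI [+0.0235, +0.0408], n = 5 days)
```

By day 300 this culture has fixed a 3p loss (FGA 7%), and the leading barcode
lineage — still mid-sweep at 31% — is expanding at an estimated ~3.2% per
day relative to the rest of the population.

The same chain runs from the shell:

```bash
preneo run-all --out demo_out --seed 7          # simulate → ... → cells
preneo call-cna --bins demo_out/bins_R1_d300.tsv --genome demo_out/genome.tsv --out cna/
preneo barcodes --counts demo_out/barcode_counts_R1.tsv \
                --counts demo_out/barcode_counts_R2.tsv \
                --counts demo_out/barcode_counts_R3.tsv \
                --census demo_out/census.tsv --out bars/
```

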