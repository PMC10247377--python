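"""Validation studies: self-contained simulation experiments that measure how
well each stage recovers known ground truth.

Every function here runs the package end to end on freshly simulated (or
freshly enumerated) inputs and returns the measured quantity; nothing is
cached or tabulated. They back both the acceptance test suite and
``scripts/acceptance.py``, and double as worked examples of the API.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from . import cna, timing
from .barcodes import fit_selection, winner_and_dominance
from .genome import GenomeModel, demo_genome
from .sim import SimulationConfig, sample_barcode_reads, simulate_evolution

BASE_GROWTH = 0.35

__all__ = [
    "fitness_multiplier",
    "segmentation_oracle_agreement",
    "selection_recovery",
    "winner_determinism",
    "neutral_concordance",
    "timing_order_study",
    "gsea_null_calibration",
    "knn_oracle_agreement",
]


def fitness_multiplier(s: float, base: float = BASE_GROWTH) -> float:
    """Per-event fitness coefficient giving log growth-rate advantage s/day."""
    return (np.exp(s) * (1 + base) - 1) / base


# ---------------------------------------------------------------------------
# segmentation vs exhaustive search
# ---------------------------------------------------------------------------


def _exhaustive_breakpoints(y: np.ndarray, max_k: int = 2) -> list[int] | None:
    """Smallest breakpoint set fitting noise-free data exactly (independent oracle)."""
    n = len(y)
    for k in range(max_k + 1):
        for bks in combinations(range(1, n), k):
            bounds = [0, *bks, n]
            rss = sum(
                float(((y[a:b] - y[a:b].mean()) ** 2).sum())
                for a, b in zip(bounds[:-1], bounds[1:])
            )
            if rss < 1e-18:
                return list(bks)
    return None


def segmentation_oracle_agreement(n_profiles: int = 500, seed: int = 0) -> float:
    """Fraction of random noise-free profiles (≤50 bins, ≤2 breakpoints) whose
    recursive-binary-segmentation boundaries equal the exhaustive optimum."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_profiles):
        n = int(rng.integers(6, 51))
        k = int(rng.integers(0, 3))
        while True:
            bks = sorted(rng.choice(np.arange(1, n), size=k, replace=False)) if k else []
            levels = rng.normal(0, 1, k + 1)
            if k == 0 or np.all(np.abs(np.diff(levels)) > 0.05):
                break
        y = np.concatenate(
            [np.full(b - a, lv) for a, b, lv in zip([0, *bks], [*bks, n], levels)]
        )
        got = cna._segment_chrom(y, penalty=10.0, sigma2=0.0)
        hits += got == _exhaustive_breakpoints(y) == list(map(int, bks))
    return hits / n_profiles


# ---------------------------------------------------------------------------
# selection-coefficient recovery
# ---------------------------------------------------------------------------


@dataclass
class RecoveryResult:
    s_true: float
    bias: float
    rmse: float
    n_runs: int


def selection_recovery(
    s_true: float,
    n_runs: int = 100,
    depth: int = 10_000,
    n_timepoints: int = 8,
    genome: GenomeModel | None = None,
    seed: int = 0,
) -> RecoveryResult:
    """Recover a known selection coefficient from simulated barcode reads.

    One clone with advantage ``s_true``/day starts at 5% of 400 barcoded
    founders; its aggregate read frequency over ``n_timepoints`` weekly
    samples at the given sequencing depth is fitted by logit-linear
    regression. Drift (weekly bottleneck of 1000 cells) and sampling noise
    are both present.
    """
    genome = genome or demo_genome()
    w = fitness_multiplier(s_true)
    days = np.arange(n_timepoints) * 7
    estimates = []
    base_seed = int(np.random.SeedSequence(seed).generate_state(1)[0] % 2**20)
    for run in range(n_runs):
        run_seed = base_seed + run
        cfg = SimulationConfig(
            genome=genome, n_founder=400,
            founder_clones=[((), 380), (("9p-",), 20)],
            fitness_table={"9p-": w}, contingency_table={},
            missegregation_rate=0.0, focal_deletion_rate=0.0,
            carrying_capacity=10**9, bottleneck_size=1_000,
            barcoding_day=0, split_day=0, n_replicates=1,
            n_days=int(days[-1]), seed=run_seed,
        )
        h = simulate_evolution(cfg)
        fit_bcs = {
            c.barcode_id for c in h.clones.values()
            if "9p-" in c.events and c.barcode_id is not None
        }
        traj = []
        for d in days:
            reads = sample_barcode_reads(h, 0, int(d), total_reads=depth, seed=run_seed)
            traj.append(float(reads[reads.index.isin(fit_bcs)].sum() / reads.sum()))
        estimates.append(fit_selection(days.astype(float), np.array(traj)).s)
    estimates = np.asarray(estimates)
    return RecoveryResult(
        s_true=s_true,
        bias=float(estimates.mean() - s_true),
        rmse=float(np.sqrt(((estimates - s_true) ** 2).mean())),
        n_runs=n_runs,
    )


# ---------------------------------------------------------------------------
# replicate winner determinism
# ---------------------------------------------------------------------------


def _triplet_config(genome: GenomeModel, seed: int, s: float | None) -> SimulationConfig:
    """20 barcoded founders split into 3 replicates; one founder carries the
    advantage when ``s`` is given (initial frequency 0.05)."""
    if s is None:
        founders, fitness = [((), 20)], {}
    else:
        founders = [((), 19), (("9p-",), 1)]
        fitness = {"9p-": fitness_multiplier(s)}
    return SimulationConfig(
        genome=genome, n_founder=20, founder_clones=founders,
        fitness_table=fitness, contingency_table={},
        missegregation_rate=0.0, focal_deletion_rate=0.0,
        barcoding_day=0, split_day=14, n_replicates=3, n_days=100, seed=seed,
    )


def _same_winner(history, depth: int, seed: int) -> bool | None:
    winners = []
    for rep in range(history.config.n_replicates):
        if rep in history.extinct:
            return None
        counts = sample_barcode_reads(history, rep, history.config.n_days,
                                      total_reads=depth, seed=seed)
        res = winner_and_dominance(_as_barcode_counts(counts, rep))
        winners.append(res["winner_id"])
    return len(set(winners)) == 1


def _as_barcode_counts(column: pd.Series, rep: int):
    from .barcodes import BarcodeCounts

    df = pd.DataFrame({0: column})
    return BarcodeCounts(f"R{rep}", df)


def winner_determinism(
    n_runs: int = 100,
    s: float = 0.1,
    genome: GenomeModel | None = None,
    seed: int = 0,
    depth: int = 100_000,
) -> float:
    """Fraction of simulated triplets in which the same barcode wins all three
    replicates, given one founder lineage with advantage ``s`` at 5%."""
    genome = genome or demo_genome()
    base_seed = int(np.random.SeedSequence(seed).generate_state(1)[0] % 2**20)
    same = 0
    n_valid = 0
    for run in range(n_runs):
        h = simulate_evolution(_triplet_config(genome, base_seed + run, s))
        result = _same_winner(h, depth, base_seed + run)
        if result is None:
            continue
        n_valid += 1
        same += result
    return same / n_valid


def neutral_concordance(
    n_triplets: int = 200,
    genome: GenomeModel | None = None,
    seed: int = 0,
    depth: int = 100_000,
) -> dict:
    """Drift-only winner concordance, estimated twice from independent halves.

    Returns the estimate from the first half (the simulated drift null), the
    concordant count in the second half, and the half size — the caller checks
    the count against a binomial interval around the null estimate.
    """
    genome = genome or demo_genome()
    base_seed = int(np.random.SeedSequence([seed, 1]).generate_state(1)[0] % 2**20)
    outcomes = []
    for run in range(n_triplets):
        h = simulate_evolution(_triplet_config(genome, base_seed + run, None))
        result = _same_winner(h, depth, base_seed + run)
        if result is not None:
            outcomes.append(result)
    half = len(outcomes) // 2
    first, second = outcomes[:half], outcomes[half:]
    return {
        "null_estimate": float(np.mean(first)),
        "observed_count": int(np.sum(second)),
        "n": len(second),
    }


# ---------------------------------------------------------------------------
# preferred temporal order of CNA events
# ---------------------------------------------------------------------------


class _TruthProfile:
    """Adapter exposing ground-truth event presence to the timing machinery."""

    def __init__(self, day: int, events: set[str]):
        self.day = day
        self._events = events

    def present_events(self) -> set[str]:
        return self._events


def timing_order_study(
    n_cultures: int = 50,
    n_days: int = 600,
    presence_threshold: float = 0.2,
    genome: GenomeModel | None = None,
    seed: int = 0,
) -> dict:
    """Preferred-order recovery under the shipped contingency fitness table.

    Each culture evolves with the default rates; an event counts as present at
    a sampled day when its true population frequency reaches
    ``presence_threshold``. Per culture, the median appearance day of the
    early events (9p−, 3p−) is compared with that of the late, contingent
    events (18q−, 20q+). Returns the fraction of cultures with strict early <
    late ordering plus pooled median appearance days.
    """
    genome = genome or demo_genome()
    sample_days = list(range(110, n_days + 1, 7))  # weekly: the passage rhythm
    early_ids, late_ids = ("9p-", "3p-"), ("18q-", "20q+")
    base_seed = int(np.random.SeedSequence([seed, 2]).generate_state(1)[0] % 2**20)
    ordered = 0
    n_valid = 0
    pooled: dict[str, list[int]] = {e: [] for e in early_ids + late_ids}
    for run in range(n_cultures):
        cfg = SimulationConfig(genome=genome, barcoding_day=None, n_days=n_days,
                               seed=base_seed + run)
        h = simulate_evolution(cfg)
        profiles = [
            _TruthProfile(
                d,
                set(
                    h.event_frequencies(d, None)
                    .pipe(lambda s: s[s >= presence_threshold])
                    .index
                ),
            )
            for d in sample_days
        ]
        apps: dict[str, int] = {}
        for ev in early_ids + late_ids:
            tl = timing.build_timeline(profiles, ev)
            if tl.persistent and tl.time_of_appearance is not None:
                apps[ev] = tl.time_of_appearance
                pooled[ev].append(tl.time_of_appearance)
        early = [apps[e] for e in early_ids if e in apps]
        late = [apps[e] for e in late_ids if e in apps]
        if early and late:
            n_valid += 1
            ordered += bool(np.median(early) < np.median(late))
    return {
        "fraction_ordered": ordered / n_valid if n_valid else 0.0,
        "n_valid": n_valid,
        "n_cultures": n_cultures,
        "median_appearance": {
            ev: float(np.median(days)) if days else None for ev, days in pooled.items()
        },
    }


# ---------------------------------------------------------------------------
# statistical calibration + kNN oracle
# ---------------------------------------------------------------------------


def gsea_null_calibration(
    n_draws: int = 2000,
    n_genes: int = 500,
    set_size: int = 30,
    seed: int = 0,
) -> float:
    """Fraction of null KS enrichment p-values below 0.05 (nominal 0.05)."""
    from .cells import gsea_ks

    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_genes)]
    below = 0
    scores = pd.Series(rng.normal(size=n_genes), index=genes)
    for i in range(n_draws):
        if i % 400 == 0:
            scores = pd.Series(rng.normal(size=n_genes), index=genes)
        members = list(rng.choice(genes, set_size, replace=False))
        p = float(gsea_ks(scores, {"null_set": members})["p"].iloc[0])
        below += p < 0.05
    return below / n_draws


def knn_oracle_agreement(
    n_reference: int = 200,
    n_query: int = 40,
    k: int = 25,
    genome: GenomeModel | None = None,
    seed: int = 0,
) -> float:
    """Max |indexed kNN type frequency − brute-force frequency| (expected 0)."""
    from .cells import fit_reference, knn_type_frequencies, project_cells
    from .sim import sample_cells_from_program, sample_typed_reference

    genome = genome or demo_genome()
    adata, programs = sample_typed_reference(
        genome, n_cells=n_reference, n_types=2, genes_per_arm=20, seed=seed
    )
    model = fit_reference(adata, adata.obs["cell_type"], n_dims=8, n_top_genes=300)
    query = sample_cells_from_program(programs[0], adata.var, n_cells=n_query,
                                      seed=seed + 1)
    coords, _ = project_cells(model, query)
    freq = knn_type_frequencies(coords, model, k=k)
    types = sorted(set(model.labels))
    brute = np.zeros((len(coords), len(types)))
    for i, c in enumerate(coords):
        d = np.linalg.norm(model.coordinates - c, axis=1)
        idx = np.argsort(d, kind="stable")[:k]
        for t_i, t in enumerate(types):
            brute[i, t_i] = (model.labels[idx] == t).mean()
    return float(np.abs(freq.loc["all"].to_numpy() - brute.mean(axis=0)).max())
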