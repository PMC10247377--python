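"""Stochastic simulator of barcoded organoid evolution under selection.

The generative model is a discrete-day branching process over clones (groups
of cells sharing a karyotype and, after barcoding, a lineage barcode):

* each cell divides once per day with probability
  ``base_growth_rate × fitness × (1 − N/K)``, where fitness is the product of
  per-event multiplicative coefficients and contingency multipliers;
* at each division every chromosome arm missegregates independently with a
  small probability (daughter gains or loses one copy, bounded to [0, 4]) and
  every fragile locus suffers a focal one-copy deletion with its own rate;
* every ``passage_interval_days`` the culture is passaged: the population is
  multinomially downsampled to ``bottleneck_size`` (genetic drift);
* at ``barcoding_day`` every cell receives a unique heritable barcode and the
  pool is split uniformly at random into replicates that evolve independently.

Observation models re-create the experiment's three data streams: binned
shallow-WGS read counts (Poisson), barcode amplicon counts
(Dirichlet-multinomial) and per-cell gene expression with copy-number dosage
(negative binomial).

All randomness flows from a single seed through named substreams
(``evolution`` / ``swgs`` / ``barcode`` / ``scrna``); an identical seed yields
a bit-identical :class:`TrueHistory`.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import GenomeModel, demo_genome

__all__ = [
    "SimulationConfig",
    "TrueHistory",
    "simulate_evolution",
    "sample_swgs",
    "sample_barcode_reads",
    "sample_barcode_counts",
    "sample_scrna",
    "sample_diploid_reference",
    "sample_typed_reference",
    "sample_cells_from_program",
    "derive_rng",
    "default_fitness_table",
    "default_contingency_table",
]

MAX_COPY = 4
PRE_SPLIT = "parental"


def derive_rng(seed: int, *names: str) -> np.random.Generator:
    """Deterministic child generator for a named stream of a global seed."""
    key = tuple(zlib.crc32(str(n).encode()) for n in names)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def default_fitness_table() -> dict[str, float]:
    """Intrinsic per-event fitness coefficients (1+s per event, multiplicative).

    Early arm losses (9p−, 3p−) and the focal fragile-site deletions carry an
    intrinsic advantage; other events are neutral unless a contingency applies.
    The two early losses share one coefficient: both appear first and at
    comparable times in the real cultures.
    """
    return {"9p-": 1.08, "3p-": 1.08, "FHIT-": 1.02, "CDKN2A-": 1.02}


def default_contingency_table() -> dict[tuple[str, str], float]:
    """Extra multipliers conditional on an earlier event being present.

    Encodes the preferred temporal order: 18q− and 20q+ only become
    advantageous on a background that already lost 9p or 3p.
    """
    out: dict[tuple[str, str], float] = {}
    for pre in ("9p-", "3p-"):
        for late in ("18q-", "20q+"):
            out[(pre, late)] = 1.08
    return out


@dataclass
class SimulationConfig:
    """Parameters of one in-silico serial-passage evolution experiment.

    Defaults emulate the study design: barcoding within the day 101–115
    window, three replicates, weekly passaging, and shallow 0.2× sequencing
    downstream. Population sizes are order-of-magnitude choices for an
    organoid culture (the effective sizes of the real cultures are unknown).
    """

    genome: GenomeModel = field(default_factory=demo_genome)
    n_founder: int = 100
    carrying_capacity: int = 30_000
    passage_interval_days: int = 7
    bottleneck_size: int = 1_000
    base_growth_rate: float = 0.35
    death_rate: float = 0.0
    missegregation_rate: float = 1e-3
    focal_deletion_rate: float = 2.5e-4
    fitness_table: dict[str, float] = field(default_factory=default_fitness_table)
    contingency_table: dict[tuple[str, str], float] = field(
        default_factory=default_contingency_table
    )
    barcoding_day: int | None = 108  # None: no barcoding, single unsplit culture
    split_day: int | None = None  # default: one passage interval after barcoding
    n_replicates: int = 3
    barcode_dropout_rate: float = 0.0
    n_days: int = 400
    seed: int = 0
    max_clones: int = 200_000
    founder_clones: list[tuple[tuple[str, ...], int]] | None = None

    def validate(self) -> None:
        for name in ("missegregation_rate", "focal_deletion_rate", "barcode_dropout_rate",
                     "base_growth_rate", "death_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]; got {v}")
        if self.bottleneck_size > self.carrying_capacity:
            raise ValueError("bottleneck_size must not exceed carrying_capacity")
        if any(w <= 0 for w in self.fitness_table.values()):
            raise ValueError("fitness coefficients must be positive")
        if any(w <= 0 for w in self.contingency_table.values()):
            raise ValueError("contingency multipliers must be positive")
        if self.barcoding_day is not None:
            if not (0 <= self.barcoding_day <= self.n_days):
                raise ValueError("barcoding_day must lie within the simulated range")
            if not (self.barcoding_day <= self.effective_split_day <= self.n_days):
                raise ValueError("split_day must lie between barcoding_day and n_days")
        if self.n_founder <= 0 or self.bottleneck_size <= 0 or self.n_replicates <= 0:
            raise ValueError("population sizes and replicate count must be positive")

    @property
    def effective_split_day(self) -> int | None:
        """Replicate-split day: barcoded cells expand for one passage interval
        (so every lineage is represented in every replicate) unless overridden."""
        if self.barcoding_day is None:
            return None
        if self.split_day is not None:
            return self.split_day
        return min(self.barcoding_day + self.passage_interval_days, self.n_days)


class CloneCapExceeded(RuntimeError):
    pass


@dataclass
class _Clone:
    clone_id: int
    parent_id: int | None
    events: tuple[str, ...]
    birth_day: int
    arm_cn: np.ndarray          # int8 per arm
    focal: frozenset[str]
    fitness: float
    barcode_id: int | None = None
    replicate: int | None = None


class TrueHistory:
    """Ground truth of one simulated experiment.

    Holds the full clone genealogy (with karyotypes and barcode labels), the
    clone-size trajectory for every simulated day, the pre-bottleneck passage
    census, the replicate split, and per-lineage barcode-silencing days.
    Phases are keyed ``"parental"`` (before the replicate split) and
    ``0 … n_replicates−1`` afterwards.
    """

    def __init__(self, config: SimulationConfig):
        self.config = config
        self.genome = config.genome
        self.clones: dict[int, _Clone] = {}
        # phase -> DataFrame (index clone_id, columns day)
        self.sizes: dict[object, pd.DataFrame] = {}
        # rows (phase, day, n_cells) pre-bottleneck
        self.passage_census: list[tuple[object, int, int]] = []
        self.replicate_assignments: dict[int, list[int]] = {}
        self.barcode_silenced: dict[int, int] = {}  # barcode_id -> silencing day
        self.extinct: dict[object, int] = {}        # phase -> extinction day

    # -- queries ------------------------------------------------------------

    def _phase(self, replicate: int | None) -> object:
        return PRE_SPLIT if replicate is None else replicate

    def days(self, replicate: int | None = None) -> np.ndarray:
        return self.sizes[self._phase(replicate)].columns.to_numpy()

    def sizes_at(self, day: int, replicate: int | None = None) -> pd.Series:
        """Nonzero clone sizes at a day (index clone_id)."""
        df = self.sizes[self._phase(replicate)]
        if day not in df.columns:
            raise ValueError(f"day {day} not recorded for phase {self._phase(replicate)}")
        col = df[day]
        return col[col > 0]

    def population_size(self, day: int, replicate: int | None = None) -> int:
        return int(self.sizes_at(day, replicate).sum())

    def bin_copy_number(self, day: int, replicate: int | None = None) -> np.ndarray:
        """Population-weighted mean copy number per genomic bin."""
        sizes = self.sizes_at(day, replicate)
        if sizes.empty:
            raise ValueError("population is empty at the requested day")
        g = self.genome
        codes = g.bin_arm_codes()
        total = float(sizes.sum())
        cn = np.zeros(g.n_bins)
        locus_masks = {loc.name: g.locus_bin_mask(loc.name) for loc in g.fragile_loci}
        for cid, n in sizes.items():
            clone = self.clones[cid]
            bins_cn = clone.arm_cn[codes].astype(float)
            for name in clone.focal:
                bins_cn[locus_masks[name]] = np.maximum(bins_cn[locus_masks[name]] - 1, 0)
            cn += (n / total) * bins_cn
        return cn

    def barcode_frequencies(
        self, day: int, replicate: int | None, readable_only: bool = False
    ) -> pd.Series:
        """True barcode frequencies at a day (``replicate=None``: the barcoded
        parental pool between barcoding and the replicate split)."""
        if self.config.barcoding_day is None:
            raise ValueError("this simulation was run without barcoding")
        if day < self.config.barcoding_day:
            raise ValueError(f"day {day} precedes barcoding_day {self.config.barcoding_day}")
        sizes = self.sizes_at(day, replicate)
        by_bc: dict[int, float] = {}
        for cid, n in sizes.items():
            bc = self.clones[cid].barcode_id
            if bc is None:
                continue
            if readable_only and bc in self.barcode_silenced and \
                    self.barcode_silenced[bc] <= day:
                continue
            by_bc[bc] = by_bc.get(bc, 0.0) + float(n)
        s = pd.Series(by_bc, dtype=float).sort_index()
        return s / s.sum() if s.sum() > 0 else s

    def event_frequencies(self, day: int, replicate: int | None = None) -> pd.Series:
        """Population frequency of every event present at a day."""
        sizes = self.sizes_at(day, replicate)
        total = float(sizes.sum())
        acc: dict[str, float] = {}
        for cid, n in sizes.items():
            for ev in set(self.clones[cid].events):
                acc[ev] = acc.get(ev, 0.0) + n / total
        return pd.Series(acc, dtype=float).sort_index()

    def clones_table(self) -> pd.DataFrame:
        rows = [
            {
                "clone_id": c.clone_id,
                "parent_id": c.parent_id if c.parent_id is not None else -1,
                "events": ",".join(c.events),
                "birth_day": c.birth_day,
                "barcode_id": c.barcode_id if c.barcode_id is not None else -1,
                "replicate": c.replicate if c.replicate is not None else -1,
                "fitness": c.fitness,
            }
            for c in self.clones.values()
        ]
        return pd.DataFrame(rows).sort_values("clone_id").reset_index(drop=True)

    def census_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.passage_census, columns=["phase", "day", "n_cells"])


# ---------------------------------------------------------------------------
# core branching process
# ---------------------------------------------------------------------------


def _event_fitness(events: Sequence[str], config: SimulationConfig) -> float:
    present = set(events)
    w = 1.0
    for ev in present:
        w *= config.fitness_table.get(ev, 1.0)
    for (pre, ev), mult in config.contingency_table.items():
        if pre in present and ev in present:
            w *= mult
    return w


class _Phase:
    """Mutable state of one growing population (parental line or a replicate)."""

    def __init__(self, history: TrueHistory, phase_key: object, replicate: int | None):
        self.h = history
        self.key = phase_key
        self.replicate = replicate
        self.ids: list[int] = []
        self.sizes: np.ndarray = np.zeros(0, dtype=np.int64)
        self.fitness: np.ndarray = np.zeros(0)
        self.records: list[tuple[int, np.ndarray, np.ndarray]] = []

    def add_clone(self, clone: _Clone, size: int) -> None:
        cfg = self.h.config
        if len(self.h.clones) >= cfg.max_clones:
            raise CloneCapExceeded(
                f"clone count exceeded the configured cap max_clones={cfg.max_clones}"
            )
        self.h.clones[clone.clone_id] = clone
        self.ids.append(clone.clone_id)
        self.sizes = np.append(self.sizes, size)
        self.fitness = np.append(self.fitness, clone.fitness)

    def record(self, day: int) -> None:
        self.records.append((day, np.array(self.ids), self.sizes.copy()))

    def prune(self) -> None:
        alive = self.sizes > 0
        if not alive.all():
            self.ids = [i for i, a in zip(self.ids, alive) if a]
            self.sizes = self.sizes[alive]
            self.fitness = self.fitness[alive]

    def finalize(self) -> None:
        all_ids = sorted({int(i) for _, ids, _ in self.records for i in ids})
        days = [d for d, _, _ in self.records]
        mat = np.zeros((len(all_ids), len(days)), dtype=np.int64)
        pos = {cid: r for r, cid in enumerate(all_ids)}
        for c, (_, ids, sizes) in enumerate(self.records):
            for cid, n in zip(ids, sizes):
                mat[pos[int(cid)], c] = n
        self.h.sizes[self.key] = pd.DataFrame(mat, index=all_ids, columns=days)


def _step_day(
    phase: _Phase,
    day: int,
    rng: np.random.Generator,
    next_id: list[int],
) -> None:
    """One day of growth, mutation and (if due) passaging."""
    h, cfg = phase.h, phase.h.config
    genome = cfg.genome
    arms = genome.arms
    n_arms = len(arms)
    loci = genome.fragile_loci

    N = int(phase.sizes.sum())
    if N == 0:
        return
    room = max(0.0, 1.0 - N / cfg.carrying_capacity)
    if cfg.death_rate > 0.0:
        phase.sizes = rng.binomial(phase.sizes, 1.0 - cfg.death_rate)
        if phase.sizes.sum() == 0:
            phase.record(day)
            return
    p_div = np.clip(cfg.base_growth_rate * phase.fitness * room, 0.0, 1.0)
    ndiv = rng.binomial(phase.sizes, p_div)

    new_cells = np.zeros_like(phase.sizes)
    children: list[tuple[int, _Clone, int]] = []  # (parent row, clone, size)

    def spawn(row: int, events_add: tuple[str, ...], cn: np.ndarray,
              focal: frozenset[str], k: int) -> None:
        parent = h.clones[phase.ids[row]]
        events = parent.events + events_add
        clone = _Clone(
            clone_id=next_id[0],
            parent_id=parent.clone_id,
            events=events,
            birth_day=day,
            arm_cn=cn,
            focal=focal,
            fitness=_event_fitness(events, cfg),
            barcode_id=parent.barcode_id,
            replicate=parent.replicate,
        )
        next_id[0] += 1
        children.append((row, clone, k))

    if cfg.missegregation_rate > 0.0 and ndiv.sum() > 0:
        muts = rng.binomial(ndiv[:, None], cfg.missegregation_rate, size=(len(ndiv), n_arms))
        for row, arm_i in zip(*np.nonzero(muts)):
            parent = h.clones[phase.ids[row]]
            cn0 = int(parent.arm_cn[arm_i])
            if cn0 == 0:
                continue
            k = int(muts[row, arm_i])
            n_gain = int(rng.binomial(k, 0.5))
            for sign, kk in ((+1, n_gain), (-1, k - n_gain)):
                if kk == 0:
                    continue
                cn1 = cn0 + sign
                if cn1 < 0 or cn1 > MAX_COPY:
                    continue
                cn = parent.arm_cn.copy()
                cn[arm_i] = cn1
                ev = f"{arms[arm_i]}{'+' if sign > 0 else '-'}"
                spawn(row, (ev,), cn, parent.focal, kk)

    if cfg.focal_deletion_rate > 0.0 and loci and ndiv.sum() > 0:
        fmuts = rng.binomial(ndiv[:, None], cfg.focal_deletion_rate,
                             size=(len(ndiv), len(loci)))
        for row, loc_i in zip(*np.nonzero(fmuts)):
            parent = h.clones[phase.ids[row]]
            loc = loci[loc_i]
            if loc.name in parent.focal:
                continue
            k = int(fmuts[row, loc_i])
            spawn(row, (f"{loc.name}-",), parent.arm_cn.copy(),
                  parent.focal | {loc.name}, k)

    mutated = np.zeros_like(phase.sizes)
    for row, _, k in children:
        mutated[row] += k
    # a division that mutated contributes its daughter to the child clone
    new_cells = ndiv - np.minimum(mutated, ndiv)
    phase.sizes = phase.sizes + new_cells
    for row, clone, k in children:
        phase.add_clone(clone, k)

    # passage bottleneck (multinomial downsampling) at the end of the day
    if (
        cfg.passage_interval_days > 0
        and day > 0
        and day % cfg.passage_interval_days == 0
        and phase.sizes.sum() > cfg.bottleneck_size
    ):
        total = int(phase.sizes.sum())
        h.passage_census.append((phase.key, day, total))
        phase.sizes = rng.multinomial(cfg.bottleneck_size, phase.sizes / total)
        if cfg.barcode_dropout_rate > 0.0 and phase.replicate is not None:
            barcodes = {
                h.clones[cid].barcode_id
                for cid, n in zip(phase.ids, phase.sizes)
                if n > 0 and h.clones[cid].barcode_id is not None
            }
            for bc in sorted(b for b in barcodes if b not in h.barcode_silenced):
                if rng.random() < cfg.barcode_dropout_rate:
                    h.barcode_silenced[bc] = day

    phase.record(day)
    phase.prune()


def simulate_evolution(config: SimulationConfig) -> TrueHistory:
    """Run the branching process and return the full ground-truth history.

    Population extinction is reported in ``TrueHistory.extinct`` (phase →
    day), not raised. Exceeding ``max_clones`` raises :class:`CloneCapExceeded`
    naming the cap.
    """
    config.validate()
    h = TrueHistory(config)
    genome = config.genome
    n_arms = len(genome.arms)
    rng = derive_rng(config.seed, "evolution")
    next_id = [0]

    parental = _Phase(h, PRE_SPLIT, None)
    founders = config.founder_clones or [((), config.n_founder)]
    for events, count in founders:
        cn = np.full(n_arms, 2, dtype=np.int8)
        focal: set[str] = set()
        arm_idx = genome.arm_index
        locus_names = {loc.name for loc in genome.fragile_loci}
        for ev in events:
            name, sign = ev[:-1], ev[-1]
            if name in arm_idx:
                cn[arm_idx[name]] = np.clip(cn[arm_idx[name]] + (1 if sign == "+" else -1),
                                            0, MAX_COPY)
            elif name in locus_names and sign == "-":
                focal.add(name)
            else:
                raise ValueError(f"unknown founder event: {ev}")
        clone = _Clone(next_id[0], None, tuple(events), 0, cn, frozenset(focal),
                       _event_fitness(events, config))
        next_id[0] += 1
        parental.add_clone(clone, count)
    if config.barcoding_day is None:
        parental.record(0)
        for day in range(1, config.n_days + 1):
            _step_day(parental, day, rng, next_id)
            if parental.sizes.sum() == 0:
                h.extinct[PRE_SPLIT] = day
                break
        parental.finalize()
        return h

    bday = config.barcoding_day
    split_day = config.effective_split_day

    if bday > 0:
        parental.record(0)
    for day in range(1, bday):
        _step_day(parental, day, rng, next_id)
        if parental.sizes.sum() == 0:
            h.extinct[PRE_SPLIT] = day
            parental.finalize()
            return h

    # --- barcoding at the start of barcoding_day: every cell gets a unique,
    # heritable barcode, i.e. every cell founds a lineage clone of size 1
    lineage_clones: list[_Clone] = []
    lineage_sizes: list[int] = []
    for cid, n in zip(parental.ids, parental.sizes):
        parent = h.clones[cid]
        for _ in range(int(n)):
            clone = _Clone(next_id[0], parent.clone_id, parent.events, bday,
                           parent.arm_cn, parent.focal, parent.fitness,
                           barcode_id=len(lineage_clones))
            next_id[0] += 1
            lineage_clones.append(clone)
            lineage_sizes.append(1)
    parental.ids = []
    parental.sizes = np.zeros(0, dtype=np.int64)
    parental.fitness = np.zeros(0)
    for clone, n in zip(lineage_clones, lineage_sizes):
        parental.add_clone(clone, n)
    if bday == 0:
        parental.record(0)

    # --- barcoded pool expands until the replicate split
    for day in range(max(bday, 1), split_day):
        _step_day(parental, day, rng, next_id)
        if parental.sizes.sum() == 0:
            h.extinct[PRE_SPLIT] = day
            parental.finalize()
            return h
    parental_ids = list(parental.ids)
    parental_sizes = parental.sizes.copy()
    parental_fitness = parental.fitness.copy()
    parental.finalize()

    # --- split: each clone's cells partitioned uniformly across replicates
    split = np.stack(
        [rng.multinomial(int(n), np.full(config.n_replicates, 1.0 / config.n_replicates))
         for n in parental_sizes]
    )
    phases = [_Phase(h, r, r) for r in range(config.n_replicates)]
    for r, ph in enumerate(phases):
        keep = split[:, r] > 0
        ph.ids = [cid for cid, k in zip(parental_ids, keep) if k]
        ph.sizes = split[keep, r].astype(np.int64)
        ph.fitness = parental_fitness[keep]
        h.replicate_assignments[r] = list(ph.ids)

    rep_rngs = [derive_rng(config.seed, "evolution", f"replicate-{r}")
                for r in range(config.n_replicates)]
    for ph, r_rng in zip(phases, rep_rngs):
        if ph.sizes.sum() == 0:
            h.extinct[ph.key] = split_day
            ph.record(split_day)
            ph.finalize()
            continue
        for day in range(split_day, config.n_days + 1):
            _step_day(ph, day, r_rng, next_id)
            if ph.sizes.sum() == 0:
                h.extinct[ph.key] = day
                break
        ph.finalize()
    return h


# ---------------------------------------------------------------------------
# observation models
# ---------------------------------------------------------------------------


def sample_swgs(
    history: TrueHistory,
    day: int,
    mean_coverage: float = 0.2,
    seed: int = 0,
    replicate: int | None = None,
    read_length: int = 100,
    sample_id: str | None = None,
):
    """Shallow-WGS observation: Poisson binned read counts at one day.

    Expected reads per bin are proportional to the population-weighted mean
    copy number ÷ 2, scaled so the genome-wide mean equals
    ``mean_coverage × bin_size / read_length`` (the read count a flat diploid
    genome would give at that coverage).
    """
    from .cna import BinnedCoverage

    cn = history.bin_copy_number(day, replicate)
    rel = cn / 2.0
    reads_per_bin = mean_coverage * history.genome.bin_size / read_length
    expected = reads_per_bin * rel / rel.mean()
    rng = derive_rng(seed, "swgs", str(replicate), str(day))
    counts = rng.poisson(expected)
    if sample_id is None:
        rep = "" if replicate is None else f"R{replicate + 1}_"
        sample_id = f"sim_{rep}d{day}"
    return BinnedCoverage(sample_id=sample_id, day=day, counts=counts)


def sample_barcode_reads(
    history: TrueHistory,
    replicate: int,
    day: int,
    total_reads: int = 100_000,
    overdispersion: float = 0.0,
    seed: int = 0,
) -> pd.Series:
    """Barcode amplicon counts for one replicate/day (Dirichlet-multinomial).

    ``overdispersion`` is 1/concentration: 0 gives exactly multinomial
    sampling around the true readable-barcode frequencies. Silenced lineages
    contribute zero reads.
    """
    freqs = history.barcode_frequencies(day, replicate, readable_only=True)
    rng = derive_rng(seed, "barcode", str(replicate), str(day))
    if freqs.empty:
        return pd.Series(dtype=np.int64)
    p = freqs.to_numpy()
    if overdispersion > 0.0:
        alpha = p / overdispersion
        p = rng.dirichlet(np.maximum(alpha, 1e-12))
    counts = rng.multinomial(total_reads, p)
    return pd.Series(counts, index=freqs.index, dtype=np.int64)


def sample_barcode_counts(
    history: TrueHistory,
    replicate: int,
    days: Sequence[int],
    total_reads: int = 100_000,
    overdispersion: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Barcode × day count table for one replicate (columns = days)."""
    cols = {}
    for day in days:
        cols[day] = sample_barcode_reads(
            history, replicate, day, total_reads, overdispersion, seed
        )
    df = pd.DataFrame(cols).fillna(0).astype(np.int64)
    df.index = [f"BC{int(i):05d}" for i in df.index]
    df.index.name = "barcode"
    return df


def _gene_table(genome: GenomeModel, genes_per_arm: int, n_mito_genes: int) -> pd.DataFrame:
    """Gene annotation: evenly spaced genes per arm plus MT genes off-genome."""
    rows = []
    for c in genome.chromosomes:
        for suffix, lo, hi in (("p", 0, c.centromere), ("q", c.centromere, c.length)):
            arm = f"{c.name}{suffix}"
            if arm not in genome.arm_index:
                continue
            pos = np.linspace(lo, hi, genes_per_arm + 2, dtype=np.int64)[1:-1]
            for j, p0 in enumerate(pos):
                rows.append((f"G_{arm}_{j:03d}", c.name, int(p0), arm))
    for j in range(n_mito_genes):
        rows.append((f"MT-{j}", "MT", j * 1000, "MT"))
    return pd.DataFrame(rows, columns=["name", "chrom", "start", "arm"]).set_index("name")


def _baseline_means(var: pd.DataFrame, seed: int) -> np.ndarray:
    """Per-gene baseline expression means, a function of the seed only, so that
    samples drawn at different days/replicates from one experiment share them."""
    rng = derive_rng(seed, "scrna", "baseline")
    baseline = rng.gamma(shape=2.0, scale=1.0, size=len(var)) + 0.2
    baseline[(var["chrom"] == "MT").to_numpy()] *= 5.0
    return baseline


def _nb_counts(
    mu: np.ndarray, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    counts = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    counts[pos] = rng.negative_binomial(dispersion, dispersion / (dispersion + mu[pos]))
    return counts


def sample_diploid_reference(
    genome: GenomeModel,
    n_cells: int = 200,
    genes_per_arm: int = 40,
    seed: int = 0,
    dispersion: float = 10.0,
    n_mito_genes: int = 5,
    baseline_scale: float = 1.0,
    stream: str = "diploid-reference",
):
    """Diploid reference cells for expression-based CNA inference.

    Shares the gene layout and seed-derived baselines with :func:`sample_scrna`
    called at the same ``seed`` and ``genes_per_arm`` (``baseline_scale``
    multiplies them, emulating deeper libraries). ``stream`` names the random
    substream so that independent diploid samples can be drawn.
    """
    import anndata as ad
    from scipy import sparse

    var = _gene_table(genome, genes_per_arm, n_mito_genes)
    baseline = _baseline_means(var, seed) * baseline_scale
    rng = derive_rng(seed, "scrna", stream)
    depth = rng.lognormal(mean=0.0, sigma=0.3, size=n_cells)
    mu = depth[:, None] * baseline[None, :]
    X = sparse.csr_matrix(_nb_counts(mu, dispersion, rng))
    obs = pd.DataFrame(
        {"sample_id": "reference", "day": -1, "clone_id": -1, "barcode_id": -1},
        index=pd.Index([f"ref_{i:05d}" for i in range(n_cells)], name="cell_id"),
    )
    return ad.AnnData(X=X, obs=obs, var=var.copy())


def sample_typed_reference(
    genome: GenomeModel,
    n_cells: int = 600,
    n_types: int = 3,
    genes_per_arm: int = 40,
    seed: int = 0,
    dispersion: float = 10.0,
    signature_fraction: float = 0.1,
    signature_fold: float = 5.0,
    n_mito_genes: int = 5,
):
    """Labeled reference for the LSI projection stage.

    Each of ``n_types`` cell types over-expresses its own disjoint block of
    signature genes (``signature_fraction`` of the vocabulary, ×``signature_fold``).
    Returns (AnnData with obs['cell_type'], per-type mean matrix) so tests can
    draw query cells from the same generative programs.
    """
    import anndata as ad
    from scipy import sparse

    var = _gene_table(genome, genes_per_arm, n_mito_genes)
    baseline = _baseline_means(var, seed)
    rng = derive_rng(seed, "scrna", "typed-reference")
    n_genes = len(var)
    n_sig = max(1, int(signature_fraction * n_genes))
    order = rng.permutation(n_genes)
    programs = np.tile(baseline, (n_types, 1))
    for t in range(n_types):
        block = order[t * n_sig: (t + 1) * n_sig]
        programs[t, block] *= signature_fold
    types = rng.integers(0, n_types, size=n_cells)
    depth = rng.lognormal(mean=0.0, sigma=0.3, size=n_cells)
    mu = depth[:, None] * programs[types]
    X = sparse.csr_matrix(_nb_counts(mu, dispersion, rng))
    obs = pd.DataFrame(
        {"cell_type": [f"type_{t}" for t in types], "sample_id": "atlas"},
        index=pd.Index([f"atlas_{i:05d}" for i in range(n_cells)], name="cell_id"),
    )
    return ad.AnnData(X=X, obs=obs, var=var.copy()), programs


def sample_cells_from_program(
    program: np.ndarray,
    var: pd.DataFrame,
    n_cells: int,
    seed: int = 0,
    dispersion: float = 10.0,
    stream: str = "program-cells",
):
    """Query cells drawn from one expression program (for projection tests)."""
    import anndata as ad
    from scipy import sparse

    rng = derive_rng(seed, "scrna", stream)
    depth = rng.lognormal(mean=0.0, sigma=0.3, size=n_cells)
    mu = depth[:, None] * np.asarray(program)[None, :]
    X = sparse.csr_matrix(_nb_counts(mu, dispersion, rng))
    obs = pd.DataFrame(
        {"sample_id": stream},
        index=pd.Index([f"{stream}_{i:05d}" for i in range(n_cells)], name="cell_id"),
    )
    return ad.AnnData(X=X, obs=obs, var=var.copy())


def sample_scrna(
    history: TrueHistory,
    day: int,
    n_cells: int,
    genes_per_arm: int = 40,
    baseline_means: np.ndarray | None = None,
    seed: int = 0,
    replicate: int | None = None,
    dispersion: float = 10.0,
    n_mito_genes: int = 5,
    low_quality_fraction: float = 0.0,
    sample_id: str | None = None,
):
    """scRNA-seq observation: negative-binomial counts with dosage effects.

    Cells are drawn proportional to clone sizes; a gene on an arm at copy
    number ``c`` in the sampled cell's clone has mean expression
    ``baseline × depth × c/2``. Mitochondrial genes (named ``MT-*``, placed on
    a dedicated ``MT`` contig) are unaffected by CNAs. A fraction of cells can
    be emitted as low-quality (depth collapsed to 3%) to exercise QC.
    """
    import anndata as ad
    from scipy import sparse

    genome = history.genome
    sizes = history.sizes_at(day, replicate)
    if sizes.empty:
        raise ValueError("population is empty at the requested day")
    if n_cells > int(sizes.sum()):
        raise ValueError(f"n_cells={n_cells} exceeds population size {int(sizes.sum())}")

    rng = derive_rng(seed, "scrna", str(replicate), str(day))
    var = _gene_table(genome, genes_per_arm, n_mito_genes)
    n_genes = len(var)

    if baseline_means is None:
        baseline = _baseline_means(var, seed)
    else:
        baseline = np.asarray(baseline_means, dtype=float)
        if baseline.shape != (n_genes,):
            raise ValueError("baseline_means length must equal the number of genes")

    obs_rows = []
    X = sparse.lil_matrix((n_cells, n_genes), dtype=np.int64)
    if n_cells > 0:
        clone_ids = sizes.index.to_numpy()
        probs = sizes.to_numpy() / sizes.sum()
        picks = rng.choice(len(clone_ids), size=n_cells, p=probs)
        depth = rng.lognormal(mean=0.0, sigma=0.3, size=n_cells)
        low_q = rng.random(n_cells) < low_quality_fraction
        depth[low_q] *= 0.03

        arm_codes = var["arm"].map(lambda a: genome.arm_index.get(a, -1)).to_numpy()
        locus_gene_masks = {
            loc.name: (
                (var["chrom"] == loc.chrom)
                & (var["start"] >= loc.start)
                & (var["start"] < loc.end)
            ).to_numpy()
            for loc in genome.fragile_loci
        }
        for k, (ci, cid) in enumerate(zip(picks, clone_ids[picks])):
            clone = history.clones[int(cid)]
            dosage = np.ones(n_genes)
            on_arm = arm_codes >= 0
            dosage[on_arm] = clone.arm_cn[arm_codes[on_arm]] / 2.0
            for name in clone.focal:
                m = locus_gene_masks[name]
                dosage[m] = np.maximum(dosage[m] - 0.5, 0.0)
            mu = baseline * depth[k] * dosage
            pos = mu > 0
            counts = np.zeros(n_genes, dtype=np.int64)
            counts[pos] = rng.negative_binomial(
                dispersion, dispersion / (dispersion + mu[pos])
            )
            X[k] = counts
            obs_rows.append(
                {
                    "cell_id": f"cell_{k:05d}",
                    "sample_id": sample_id
                    or f"sim_{'' if replicate is None else f'R{replicate + 1}_'}d{day}",
                    "day": day,
                    "clone_id": int(cid),
                    "barcode_id": -1 if clone.barcode_id is None else int(clone.barcode_id),
                    "low_quality": bool(low_q[k]),
                }
            )
    obs = pd.DataFrame(
        obs_rows,
        columns=["cell_id", "sample_id", "day", "clone_id", "barcode_id", "low_quality"],
    )
    if len(obs):
        obs = obs.set_index("cell_id")
    else:
        obs = obs.drop(columns="cell_id")
        obs.index = pd.Index([], name="cell_id", dtype=str)
    return ad.AnnData(X=X.tocsr(), obs=obs, var=var.copy())
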