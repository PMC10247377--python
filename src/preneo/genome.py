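"""Genome coordinate frame: chromosomes, arms, fixed-width bins, fragile loci.

Every stage of the package — the simulator, the shallow-WGS copy-number
caller and the expression-based per-cell inference — shares one
:class:`GenomeModel`. Coordinates are 0-based half-open throughout; only the
SEG writer converts to 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Chromosome", "FragileLocus", "GenomeModel", "demo_genome"]

SEX_CHROMOSOMES = {"X", "Y", "chrX", "chrY"}


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    centromere: int

    def __post_init__(self) -> None:
        if not (0 < self.centromere < self.length):
            raise ValueError(
                f"centromere of {self.name} must lie strictly inside (0, {self.length}); "
                f"got {self.centromere}"
            )


@dataclass(frozen=True)
class FragileLocus:
    """A named interval recurrently hit by focal deletions (e.g. FHIT, CDKN2A)."""

    name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid interval for locus {self.name}: [{self.start}, {self.end})")


@dataclass
class GenomeModel:
    """Chromosomes with arm boundaries plus a fixed-width binning.

    Bins tile each arm with full-width windows; a partial window at an arm
    end is dropped so that every bin lies entirely within one arm.
    """

    chromosomes: list[Chromosome]
    bin_size: int = 50_000
    fragile_loci: list[FragileLocus] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        chrom_set = set(names)
        seen: list[FragileLocus] = []
        for loc in self.fragile_loci:
            if loc.chrom not in chrom_set:
                raise ValueError(f"fragile locus {loc.name} on unknown chromosome {loc.chrom}")
            for other in seen:
                if other.chrom == loc.chrom and loc.start < other.end and other.start < loc.end:
                    raise ValueError(f"overlapping fragile loci: {other.name} and {loc.name}")
            seen.append(loc)
        self._bins: pd.DataFrame | None = None

    # -- derived structures -------------------------------------------------

    @property
    def bins(self) -> pd.DataFrame:
        """Bin table with columns (chrom, start, end, arm), sorted, non-overlapping."""
        if self._bins is None:
            rows = []
            for c in self.chromosomes:
                for arm_suffix, lo, hi in (("p", 0, c.centromere), ("q", c.centromere, c.length)):
                    n = (hi - lo) // self.bin_size
                    for i in range(n):
                        s = lo + i * self.bin_size
                        rows.append((c.name, s, s + self.bin_size, f"{c.name}{arm_suffix}"))
            self._bins = pd.DataFrame(rows, columns=["chrom", "start", "end", "arm"])
        return self._bins

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def arms(self) -> list[str]:
        """Arm identifiers in genome order (e.g. '1p', '1q', ...), arms with ≥1 bin."""
        return list(dict.fromkeys(self.bins["arm"]))

    @property
    def arm_index(self) -> dict[str, int]:
        return {a: i for i, a in enumerate(self.arms)}

    def bin_arm_codes(self) -> np.ndarray:
        """Per-bin integer arm index aligned with :attr:`arms`."""
        idx = self.arm_index
        return self.bins["arm"].map(idx).to_numpy()

    def autosome_mask(self) -> np.ndarray:
        return ~self.bins["chrom"].isin(SEX_CHROMOSOMES).to_numpy()

    def locus_bin_mask(self, name: str) -> np.ndarray:
        """Boolean mask of bins overlapping the named fragile locus."""
        for loc in self.fragile_loci:
            if loc.name == name:
                b = self.bins
                return (
                    (b["chrom"] == loc.chrom) & (b["start"] < loc.end) & (b["end"] > loc.start)
                ).to_numpy()
        raise KeyError(f"unknown fragile locus: {name}")

    def locus_arm(self, name: str) -> str:
        mask = self.locus_bin_mask(name)
        arms = self.bins.loc[mask, "arm"].unique()
        if len(arms) != 1:
            raise ValueError(f"fragile locus {name} does not lie within a single arm")
        return str(arms[0])


def demo_genome(bin_size: int = 1_000_000) -> GenomeModel:
    """A scaled-down 22-autosome genome used by the simulator and demos.

    Chromosome lengths are one tenth of the human assembly (rounded to 1 Mb)
    with centromeres at roughly their human relative positions, so that
    arm identities (3p, 9p, 18q, 20q, ...) carry over while the default
    1 Mb bins keep the genome at ~290 bins. FHIT (3p) and CDKN2A (9p) are
    included as fragile loci.
    """
    # (name, length Mb/10, centromere Mb/10) — scaled hg38
    spec = [
        ("1", 25, 12), ("2", 24, 9), ("3", 20, 9), ("4", 19, 5),
        ("5", 18, 5), ("6", 17, 6), ("7", 16, 6), ("8", 15, 4),
        ("9", 14, 4), ("10", 13, 4), ("11", 14, 5), ("12", 13, 4),
        ("13", 11, 2), ("14", 11, 2), ("15", 10, 2), ("16", 9, 4),
        ("17", 8, 2), ("18", 8, 2), ("19", 6, 3), ("20", 6, 3),
        ("21", 5, 1), ("22", 5, 2),
    ]
    mb = 1_000_000
    chroms = [Chromosome(n, int(l * mb), int(c * mb)) for n, l, c in spec]
    # FHIT at ~59-61 Mb on 3p and CDKN2A at ~21-22 Mb on 9p, scaled
    loci = [
        FragileLocus("FHIT", "3", int(5.9 * mb), int(6.1 * mb)),
        FragileLocus("CDKN2A", "9", int(2.1 * mb), int(2.3 * mb)),
    ]
    return GenomeModel(chroms, bin_size=bin_size, fragile_loci=loci)
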