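"""Format readers and writers shared by all stages, plus the pipeline config.

All tabular formats are tab-delimited with a header line and ``.`` for
missing values; coordinates are 0-based half-open except SEG output, which
follows the genome-viewer convention (1-based inclusive). The YAML pipeline
config rejects unknown keys and round-trips read → write → read identically.
"""

from __future__ import annotations

import copy
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cna import BinnedCoverage, CopyNumberProfile
from .genome import Chromosome, FragileLocus, GenomeModel

__all__ = [
    "read_genome_model",
    "write_genome_model",
    "read_binned_coverage",
    "write_binned_coverage",
    "write_seg",
    "read_seg",
    "write_events",
    "read_events",
    "write_metrics",
    "read_barcode_counts",
    "write_barcode_counts",
    "read_census",
    "write_census",
    "read_cell_matrix",
    "write_cell_matrix",
    "read_gmt",
    "write_gmt",
    "load_config",
    "write_config",
    "default_config",
]

MISSING = "."


# ---------------------------------------------------------------------------
# genome model
# ---------------------------------------------------------------------------

_GENOME_COLUMNS = ["record", "name", "chrom", "length", "centromere", "start", "end"]


def write_genome_model(genome: GenomeModel, path: str | Path) -> None:
    rows = []
    for c in genome.chromosomes:
        rows.append(["chromosome", c.name, MISSING, c.length, c.centromere, MISSING, MISSING])
    for loc in genome.fragile_loci:
        rows.append(["fragile_locus", loc.name, loc.chrom, MISSING, MISSING, loc.start, loc.end])
    with open(path, "w") as fh:
        fh.write(f"#bin_size={genome.bin_size}\n")
        fh.write("\t".join(_GENOME_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


def read_genome_model(path: str | Path, bin_size: int | None = None) -> GenomeModel:
    """Genome model from TSV: chromosome rows (name, length, centromere) and
    optional fragile-locus rows (name, chrom, start, end). A ``#bin_size=``
    header comment sets the bin width unless overridden."""
    chroms: list[Chromosome] = []
    loci: list[FragileLocus] = []
    file_bin_size = 50_000
    with open(path) as fh:
        lines = fh.readlines()
    header_seen = False
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        if line.startswith("#"):
            if line.startswith("#bin_size="):
                file_bin_size = int(line.split("=", 1)[1])
            continue
        fields = line.split("\t")
        if not header_seen:
            if fields != _GENOME_COLUMNS:
                raise ValueError(f"{path}: line {lineno}: unexpected header {fields}")
            header_seen = True
            continue
        if len(fields) != len(_GENOME_COLUMNS):
            raise ValueError(
                f"{path}: line {lineno}: expected {len(_GENOME_COLUMNS)} fields, "
                f"got {len(fields)}"
            )
        record, name, chrom, length, centromere, start, end = fields
        try:
            if record == "chromosome":
                chroms.append(Chromosome(name, int(length), int(centromere)))
            elif record == "fragile_locus":
                loci.append(FragileLocus(name, chrom, int(start), int(end)))
            else:
                raise ValueError(f"unknown record type {record!r}")
        except (ValueError, TypeError) as err:
            raise ValueError(f"{path}: line {lineno}: {err}") from None
    if not chroms:
        raise ValueError(f"{path}: no chromosome rows")
    return GenomeModel(chroms, bin_size=bin_size or file_bin_size, fragile_loci=loci)


# ---------------------------------------------------------------------------
# binned coverage (BED-like) and SEG
# ---------------------------------------------------------------------------


def write_binned_coverage(cov: BinnedCoverage, genome: GenomeModel, path: str | Path) -> None:
    df = genome.bins[["chrom", "start", "end"]].copy()
    df["count"] = cov.counts
    df.to_csv(path, sep="\t", index=False)


def read_binned_coverage(
    path: str | Path, genome: GenomeModel, sample_id: str = "", day: int = 0
) -> BinnedCoverage:
    df = pd.read_csv(path, sep="\t")
    expected = genome.bins[["chrom", "start", "end"]]
    got = df[["chrom", "start", "end"]].astype({"start": int, "end": int})
    if len(got) != len(expected) or not (
        (got["chrom"].astype(str).to_numpy() == expected["chrom"].astype(str).to_numpy()).all()
        and (got["start"].to_numpy() == expected["start"].to_numpy()).all()
    ):
        raise ValueError(f"{path}: bins do not match the genome model binning")
    return BinnedCoverage(sample_id=sample_id, day=day, counts=df["count"].to_numpy())


def write_seg(profiles: list[CopyNumberProfile], path: str | Path) -> None:
    """SEG output (1-based inclusive coordinates)."""
    rows = []
    for p in profiles:
        for _, seg in p.segments.iterrows():
            rows.append(
                {
                    "sample": p.sample_id,
                    "day": p.day,
                    "chrom": seg["chrom"],
                    "start": int(seg["start"]) + 1,
                    "end": int(seg["end"]),
                    "n_bins": int(seg["n_bins"]),
                    "seg_mean": float(seg["mean"]),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_seg(path: str | Path) -> pd.DataFrame:
    """SEG file back to 0-based half-open segment table."""
    df = pd.read_csv(path, sep="\t")
    df["start"] = df["start"].astype(int) - 1
    df["end"] = df["end"].astype(int)
    return df


def write_events(profiles: list[CopyNumberProfile], path: str | Path) -> None:
    rows = []
    for p in profiles:
        for ev in p.arm_events:
            rows.append(
                {
                    "sample": p.sample_id,
                    "day": p.day,
                    "event_id": ev.event_id,
                    "kind": "arm",
                    "direction": ev.direction,
                    "altered_fraction": ev.altered_fraction,
                    "present": ev.present,
                }
            )
        for name, direction in p.focal_events:
            rows.append(
                {
                    "sample": p.sample_id,
                    "day": p.day,
                    "event_id": f"{name}{'+' if direction == 'gain' else '-'}",
                    "kind": "focal",
                    "direction": direction,
                    "altered_fraction": np.nan,
                    "present": True,
                }
            )
    pd.DataFrame(
        rows,
        columns=["sample", "day", "event_id", "kind", "direction",
                 "altered_fraction", "present"],
    ).to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep=MISSING)


def read_events(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=MISSING)


def write_metrics(profiles: list[CopyNumberProfile], path: str | Path) -> None:
    from .cna import compute_fga, compute_wgii

    rows = [
        {"sample": p.sample_id, "day": p.day, "fga": compute_fga(p), "wgii": compute_wgii(p)}
        for p in profiles
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# barcode counts + census
# ---------------------------------------------------------------------------


def write_barcode_counts(counts: pd.DataFrame, path: str | Path) -> None:
    out = counts.copy()
    out.index.name = "barcode"
    out.to_csv(path, sep="\t")


def read_barcode_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="barcode")
    df.columns = [int(c) for c in df.columns]
    return df.astype(np.int64)


def write_census(census: pd.DataFrame, path: str | Path) -> None:
    census.to_csv(path, sep="\t", index=False)


def read_census(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# cell matrices (MTX + TSVs) and gene sets (GMT)
# ---------------------------------------------------------------------------


def write_cell_matrix(adata, out_dir: str | Path, prefix: str = "cells") -> None:
    """Sparse cell × gene matrix as MTX plus gene/cell metadata TSVs."""
    from scipy import io as spio
    from scipy import sparse

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    X = adata.X if sparse.issparse(adata.X) else sparse.csr_matrix(adata.X)
    spio.mmwrite(str(out / f"{prefix}_matrix.mtx"), X.astype(np.int64))
    adata.var.to_csv(out / f"{prefix}_genes.tsv", sep="\t")
    adata.obs.to_csv(out / f"{prefix}_cells.tsv", sep="\t")


def read_cell_matrix(out_dir: str | Path, prefix: str = "cells"):
    import anndata as ad
    from scipy import io as spio
    from scipy import sparse

    out = Path(out_dir)
    X = sparse.csr_matrix(spio.mmread(str(out / f"{prefix}_matrix.mtx")))
    var = pd.read_csv(out / f"{prefix}_genes.tsv", sep="\t", index_col=0)
    obs = pd.read_csv(out / f"{prefix}_cells.tsv", sep="\t", index_col=0)
    obs.index = obs.index.astype(str)
    return ad.AnnData(X=X, obs=obs, var=var)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: GMT rows need name, "
                                 "description and at least one gene")
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, MISSING, *genes]) + "\n")


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------


def default_config() -> dict:
    """Documented defaults for every pipeline stage (see docs/methods.md)."""
    return {
        "seed": 0,
        "out_dir": "preneo_out",
        "log_level": "INFO",
        "genome": {"file": None, "bin_size": 1_000_000},
        "simulate": {
            "n_founder": 100,
            "carrying_capacity": 30_000,
            "passage_interval_days": 7,
            "bottleneck_size": 1_000,
            "base_growth_rate": 0.35,
            "death_rate": 0.0,
            "missegregation_rate": 1e-3,
            "focal_deletion_rate": 2.5e-4,
            "barcoding_day": 108,
            "split_day": None,
            "n_replicates": 3,
            "barcode_dropout_rate": 0.0,
            "n_days": 300,
        },
        "swgs": {"days": [50, 108, 150, 200, 250, 300], "mean_coverage": 2.0,
                 "read_length": 100},
        "cna": {
            "penalty": 10.0,
            "loss_threshold": -0.15,
            "gain_threshold": 0.15,
            "arm_call_fraction": 0.5,
        },
        "timing": {"tolerance": 0},
        "deconvolve": {"distance_threshold": 0.1, "nesting_tolerance": 0.1},
        "barcodes": {
            "days": [108, 150, 200, 250, 300],
            "total_reads": 100_000,
            "overdispersion": 0.0,
            "min_reads": 100,
            "min_frequency": 0.001,
            "span": 0.75,
            "dominance_threshold": 0.5,
        },
        "scrna": {"day": 300, "n_cells": 300, "genes_per_arm": 30,
                  "n_reference_cells": 150},
        "cells": {
            "window_genes": 21,
            "arm_threshold": 0.1,
            "min_cells": 10,
            "n_dims": 10,
            "n_top_genes": 500,
            "k": 25,
        },
    }


def _merge_strict(defaults: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in override.items():
        if key not in defaults:
            raise ValueError(f"unknown config key: {path}{key}")
        if isinstance(defaults[key], dict) and not (
            key == "genome" and value is None
        ):
            if not isinstance(value, dict):
                raise ValueError(f"config key {path}{key} must be a mapping")
            out[key] = _merge_strict(defaults[key], value, path=f"{path}{key}.")
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Pipeline config: YAML merged over defaults, unknown keys rejected."""
    if path is None:
        return default_config()
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return _merge_strict(default_config(), user)


def write_config(config: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def write_run_report(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
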