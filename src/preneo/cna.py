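"""Shallow-WGS copy-number stage.

Binned read counts are median-normalized to log2 ratios, segmented per
chromosome by recursive binary splitting with a variance-scaled penalty,
and summarized as arm-level and focal event calls plus the two aneuploidy
metrics used throughout: FGA (fraction of genome altered) and wGII
(per-chromosome altered fraction averaged with equal chromosome weights).

Sex chromosomes are excluded from both metrics. GC/mappability correction is
not performed; a per-bin baseline-weight hook (e.g. a matched wild-type
sample) is accepted by :func:`normalize_bins` for data that need it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeModel, SEX_CHROMOSOMES

__all__ = [
    "BinnedCoverage",
    "ArmEventCall",
    "CopyNumberProfile",
    "normalize_bins",
    "segment_profile",
    "call_events",
    "compute_fga",
    "compute_wgii",
    "call_profile",
]

DEFAULT_LOSS_THRESHOLD = -0.15
DEFAULT_GAIN_THRESHOLD = 0.15
DEFAULT_ARM_CALL_FRACTION = 0.5
DEFAULT_PENALTY = 10.0


@dataclass
class BinnedCoverage:
    """Raw binned read counts for one sample/time point, aligned to a genome's bins."""

    sample_id: str
    day: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if (self.counts < 0).any():
            raise ValueError("bin counts must be non-negative")


@dataclass(frozen=True)
class ArmEventCall:
    arm_id: str
    direction: str  # "gain" | "loss"
    altered_fraction: float
    present: bool

    @property
    def event_id(self) -> str:
        return f"{self.arm_id}{'+' if self.direction == 'gain' else '-'}"


@dataclass
class CopyNumberProfile:
    """Per-bin log ratios + segmentation + event calls for one sample/time point."""

    sample_id: str
    day: int
    genome: GenomeModel
    log_ratios: np.ndarray
    imputed: np.ndarray
    segments: pd.DataFrame  # chrom, start, end, start_bin, end_bin, n_bins, mean, call
    arm_events: list[ArmEventCall] = field(default_factory=list)
    focal_events: list[tuple[str, str]] = field(default_factory=list)
    loss_threshold: float = DEFAULT_LOSS_THRESHOLD
    gain_threshold: float = DEFAULT_GAIN_THRESHOLD

    def bin_states(self) -> np.ndarray:
        """Per-bin call from segment means: −1 loss, 0 neutral, +1 gain."""
        states = np.zeros(self.genome.n_bins, dtype=np.int8)
        for _, seg in self.segments.iterrows():
            sl = slice(int(seg.start_bin), int(seg.end_bin))
            if seg["mean"] <= self.loss_threshold:
                states[sl] = -1
            elif seg["mean"] >= self.gain_threshold:
                states[sl] = 1
        return states

    def present_events(self) -> set[str]:
        out = {e.event_id for e in self.arm_events if e.present}
        out |= {f"{name}-" if call == "loss" else f"{name}+" for name, call in self.focal_events}
        return out


def normalize_bins(
    cov: BinnedCoverage, baseline: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Median-normalized log2 ratios per bin.

    Counts are divided by the supplied per-bin baseline weights if given
    (e.g. a matched wild-type sample), then by the library median of the
    nonzero ratios. Zero-count bins are imputed to half the smallest nonzero
    ratio and flagged in the returned boolean mask.
    """
    counts = cov.counts.astype(float)
    if not (counts > 0).any():
        raise ValueError("all-zero coverage cannot be normalized")
    if baseline is not None:
        baseline = np.asarray(baseline, dtype=float)
        if baseline.shape != counts.shape:
            raise ValueError("baseline length must match bin count")
        if (baseline <= 0).any():
            raise ValueError("baseline weights must be positive")
        counts = counts / baseline
    nonzero = counts > 0
    ratio = counts / np.median(counts[nonzero])
    imputed = ~nonzero
    if imputed.any():
        ratio[imputed] = ratio[nonzero].min() / 2.0
    return np.log2(ratio), imputed


def _best_split(y: np.ndarray) -> tuple[int, float]:
    """Best single changepoint of ``y``: (index, RSS reduction); first argmax on ties."""
    n = len(y)
    cs = np.cumsum(y)
    total = cs[-1]
    k = np.arange(1, n)
    left_mean = cs[:-1] / k
    right_mean = (total - cs[:-1]) / (n - k)
    gain = k * (n - k) / n * (left_mean - right_mean) ** 2
    tau = int(np.argmax(gain))
    return tau + 1, float(gain[tau])


def _segment_chrom(y: np.ndarray, penalty: float, sigma2: float) -> list[int]:
    """Recursive binary segmentation; returns sorted interior breakpoints."""
    breaks: list[int] = []

    def recurse(lo: int, hi: int) -> None:
        if hi - lo < 2:
            return
        tau, gain = _best_split(y[lo:hi])
        threshold = penalty * sigma2 if sigma2 > 0 else 1e-12
        if gain > threshold:
            breaks.append(lo + tau)
            recurse(lo, lo + tau)
            recurse(lo + tau, hi)

    recurse(0, len(y))
    return sorted(breaks)


def segment_profile(
    log_ratios: np.ndarray, genome: GenomeModel, penalty: float = DEFAULT_PENALTY
) -> pd.DataFrame:
    """Piecewise-constant segmentation of per-bin log ratios, per chromosome.

    A split is accepted iff it reduces the residual sum of squares by more
    than ``penalty × σ²``, with σ estimated per chromosome from the median
    absolute deviation of first differences (÷ √2, scaled to normal).
    Deterministic for fixed input; ties broken at the leftmost bin.
    """
    if penalty <= 0:
        raise ValueError("penalty must be positive")
    y = np.asarray(log_ratios, dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("log ratios must be finite after imputation")
    bins = genome.bins
    if len(y) != len(bins):
        raise ValueError("log_ratios length must equal the genome bin count")
    rows = []
    for chrom in dict.fromkeys(bins["chrom"]):
        idx = np.flatnonzero((bins["chrom"] == chrom).to_numpy())
        yc = y[idx]
        if len(yc) == 0:
            continue
        if len(yc) > 1:
            d = np.diff(yc)
            sigma = 1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0)
        else:
            sigma = 0.0
        breaks = _segment_chrom(yc, penalty, sigma**2) if len(yc) > 1 else []
        bounds = [0] + breaks + [len(yc)]
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            gbin_lo, gbin_hi = idx[lo], idx[hi - 1] + 1
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(bins["start"].iloc[gbin_lo]),
                    "end": int(bins["end"].iloc[gbin_hi - 1]),
                    "start_bin": int(gbin_lo),
                    "end_bin": int(gbin_hi),
                    "n_bins": hi - lo,
                    "mean": float(yc[lo:hi].mean()),
                }
            )
    return pd.DataFrame(rows)


def call_events(
    profile: CopyNumberProfile,
    loss_threshold: float = DEFAULT_LOSS_THRESHOLD,
    gain_threshold: float = DEFAULT_GAIN_THRESHOLD,
    arm_call_fraction: float = DEFAULT_ARM_CALL_FRACTION,
) -> tuple[list[ArmEventCall], list[tuple[str, str]]]:
    """Arm-level and focal event calls from a segmented profile.

    A bin is altered if its segment mean crosses a threshold; an arm event is
    present when the altered fraction of the arm's bins (in one direction)
    reaches ``arm_call_fraction``. A focal event is called when an altered
    segment overlaps a named fragile locus while the surrounding arm is not
    called in the same direction.
    """
    if not (loss_threshold < 0 < gain_threshold):
        raise ValueError("need loss_threshold < 0 < gain_threshold")
    if not (0 < arm_call_fraction <= 1):
        raise ValueError("arm_call_fraction must lie in (0, 1]")
    profile.loss_threshold = loss_threshold
    profile.gain_threshold = gain_threshold
    genome = profile.genome
    states = profile.bin_states()
    arm_col = genome.bins["arm"].to_numpy()

    arm_events: list[ArmEventCall] = []
    arm_called: dict[tuple[str, str], bool] = {}
    for arm in genome.arms:
        mask = arm_col == arm
        n = int(mask.sum())
        for direction, s in (("loss", -1), ("gain", 1)):
            frac = float((states[mask] == s).sum()) / n
            present = frac >= arm_call_fraction
            arm_called[(arm, direction)] = present
            if frac > 0:
                arm_events.append(ArmEventCall(arm, direction, frac, present))

    focal_events: list[tuple[str, str]] = []
    for loc in genome.fragile_loci:
        lmask = genome.locus_bin_mask(loc.name)
        if not lmask.any():
            continue
        arm = genome.locus_arm(loc.name)
        for direction, s in (("loss", -1), ("gain", 1)):
            if (states[lmask] == s).any() and not arm_called[(arm, direction)]:
                focal_events.append((loc.name, direction))
    profile.arm_events = arm_events
    profile.focal_events = focal_events
    return arm_events, focal_events


def compute_fga(profile: CopyNumberProfile) -> float:
    """Fraction of genome altered: altered bins ÷ total bins over autosomes."""
    auto = profile.genome.autosome_mask()
    states = profile.bin_states()
    return float((states[auto] != 0).sum() / auto.sum())


def compute_wgii(profile: CopyNumberProfile) -> float:
    """Weighted genome instability index: equal-weight mean over autosomes of
    each chromosome's altered-bin fraction."""
    bins = profile.genome.bins
    states = profile.bin_states()
    fractions = []
    for chrom in dict.fromkeys(bins["chrom"]):
        if chrom in SEX_CHROMOSOMES:
            continue
        mask = (bins["chrom"] == chrom).to_numpy()
        fractions.append((states[mask] != 0).mean())
    return float(np.mean(fractions))


def call_profile(
    cov: BinnedCoverage,
    genome: GenomeModel,
    baseline: np.ndarray | None = None,
    penalty: float = DEFAULT_PENALTY,
    loss_threshold: float = DEFAULT_LOSS_THRESHOLD,
    gain_threshold: float = DEFAULT_GAIN_THRESHOLD,
    arm_call_fraction: float = DEFAULT_ARM_CALL_FRACTION,
) -> CopyNumberProfile:
    """Full single-sample pipeline: normalize → segment → call events."""
    log_ratios, imputed = normalize_bins(cov, baseline)
    if imputed.mean() > 0.2:
        warnings.warn(
            f"{imputed.mean():.0%} of bins had zero coverage and were imputed",
            stacklevel=2,
        )
    segments = segment_profile(log_ratios, genome, penalty)
    profile = CopyNumberProfile(
        sample_id=cov.sample_id,
        day=cov.day,
        genome=genome,
        log_ratios=log_ratios,
        imputed=imputed,
        segments=segments,
    )
    call_events(profile, loss_threshold, gain_threshold, arm_call_fraction)
    seg_call = []
    for _, seg in profile.segments.iterrows():
        if seg["mean"] <= loss_threshold:
            seg_call.append("loss")
        elif seg["mean"] >= gain_threshold:
            seg_call.append("gain")
        else:
            seg_call.append("neutral")
    profile.segments = profile.segments.assign(call=seg_call)
    return profile
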