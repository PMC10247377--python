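"""Lineage-barcode dynamics.

Barcode amplicon counts per replicate are normalized to frequency
trajectories, converted to per-clone absolute growth curves using the
passage census, smoothed with a local-linear Loess whose local slope serves
as a fitness surrogate, and summarized as winner/dominance statistics,
cross-replicate concordance (the determinism signal of the experiment) and
Muller-plot tables. A logit-linear fit of a lineage's frequency trajectory
estimates its selection coefficient per day.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BarcodeCounts",
    "CloneGrowthCurve",
    "SelectionFit",
    "counts_to_frequencies",
    "loess_fit",
    "clone_growth",
    "winner_and_dominance",
    "replicate_concordance",
    "muller_table",
    "fit_selection",
]

OTHER = "other"


@dataclass
class BarcodeCounts:
    """Barcode × time-point read counts for one replicate."""

    replicate_id: str
    counts: pd.DataFrame  # index barcode, columns day (int)

    def __post_init__(self) -> None:
        self.counts = self.counts.copy()
        self.counts.columns = [int(c) for c in self.counts.columns]
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("barcode counts must be non-negative")

    @property
    def days(self) -> list[int]:
        return list(self.counts.columns)

    @property
    def frequencies(self) -> pd.DataFrame:
        colsum = self.counts.sum(axis=0)
        if (colsum == 0).any():
            raise ValueError("retained days must have positive column sums")
        return self.counts / colsum


def counts_to_frequencies(
    raw: pd.DataFrame,
    replicate_id: str = "",
    min_reads: int = 100,
    min_frequency: float = 0.001,
) -> BarcodeCounts:
    """Filtered, pooled barcode count table.

    Days whose total reads fall below ``min_reads`` are dropped (with a
    warning); barcodes that never reach ``min_frequency`` are pooled into an
    ``"other"`` row. Frequencies derived from the result are renormalized by
    construction.
    """
    counts = raw.copy()
    counts.columns = [int(c) for c in counts.columns]
    colsum = counts.sum(axis=0)
    keep = colsum >= min_reads
    if not keep.all():
        dropped = [int(d) for d in counts.columns[~keep]]
        warnings.warn(f"dropping days with < {min_reads} reads: {dropped}", stacklevel=2)
        counts = counts.loc[:, keep]
    if counts.shape[1] == 0:
        raise ValueError("all days fell below min_reads")
    freq = counts / counts.sum(axis=0)
    major = (freq >= min_frequency).any(axis=1)
    if (~major).any():
        pooled = counts.loc[~major].sum(axis=0)
        counts = counts.loc[major]
        if pooled.sum() > 0:
            counts.loc[OTHER] = pooled
    return BarcodeCounts(replicate_id=replicate_id, counts=counts.astype(np.int64))


def loess_fit(
    x: np.ndarray, y: np.ndarray, span: float = 0.75
) -> tuple[np.ndarray, np.ndarray]:
    """Local-linear regression with tricube weights; returns (fitted, derivative).

    At each point the ``ceil(span·n)`` nearest neighbours (by |Δx|) form the
    window; tricube weights are taken relative to the window radius and a
    weighted degree-1 fit provides both the smoothed value and the local
    slope. Exact on affine data; deterministic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("need at least four points")
    if len(np.unique(x)) != n:
        raise ValueError("x values must be distinct")
    if not (0 < span <= 1):
        raise ValueError("span must lie in (0, 1]")
    k = int(np.ceil(span * n))
    if k < 3:
        raise ValueError(f"span {span} covers only {k} points; need at least 3")
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    fitted = np.empty(n)
    slope = np.empty(n)
    for i in range(n):
        d = np.abs(xs - xs[i])
        idx = np.argsort(d, kind="stable")[:k]
        radius = d[idx].max()
        if radius == 0:
            fitted[i], slope[i] = ys[i], 0.0
            continue
        w = (1 - (d[idx] / radius) ** 3) ** 3
        if (w > 0).sum() < 2:
            w = np.ones_like(w)
        xw, yw = xs[idx], ys[idx]
        sw = w.sum()
        xbar = (w * xw).sum() / sw
        ybar = (w * yw).sum() / sw
        sxx = (w * (xw - xbar) ** 2).sum()
        if sxx == 0:
            fitted[i], slope[i] = ybar, 0.0
            continue
        b = (w * (xw - xbar) * (yw - ybar)).sum() / sxx
        fitted[i] = ybar + b * (xs[i] - xbar)
        slope[i] = b
    out_f = np.empty(n)
    out_s = np.empty(n)
    out_f[order] = fitted
    out_s[order] = slope
    return out_f, out_s


@dataclass
class CloneGrowthCurve:
    """Absolute growth curve of one barcode lineage with Loess fitness surrogate."""

    barcode_id: str
    days: np.ndarray
    abundance: np.ndarray       # frequency × interpolated census (cells)
    smoothed_log: np.ndarray    # Loess fit of log abundance
    derivative: np.ndarray      # d(log abundance)/d(day): fitness surrogate
    fold_change: np.ndarray     # abundance ratio vs previous sampled day (nan first)


def _interpolate_census(census: pd.DataFrame, days: list[int]) -> np.ndarray:
    """Total cell count at each requested day, log-linear between passages."""
    c = census.sort_values("day")
    if (c["n_cells"] <= 0).any():
        raise ValueError("census cell counts must be positive")
    return np.exp(
        np.interp(days, c["day"].to_numpy(dtype=float), np.log(c["n_cells"].to_numpy(dtype=float)))
    )


def clone_growth(
    bc: BarcodeCounts, census: pd.DataFrame, span: float = 0.75,
    pseudo_cells: float = 0.5,
) -> dict[str, CloneGrowthCurve]:
    """Per-barcode growth curve: abundance, Loess-smoothed log, derivative, FC.

    ``census`` has columns (day, n_cells): pre-bottleneck totals per passage,
    interpolated log-linearly to the sampled days. Zero abundances are floored
    at ``pseudo_cells`` before the log.
    """
    days = bc.days
    totals = _interpolate_census(census, days)
    freqs = bc.frequencies
    out = {}
    for barcode in freqs.index:
        ab = freqs.loc[barcode].to_numpy() * totals
        log_ab = np.log(np.maximum(ab, pseudo_cells))
        fitted, deriv = loess_fit(np.asarray(days, dtype=float), log_ab, span=span)
        fc = np.concatenate([[np.nan], ab[1:] / np.maximum(ab[:-1], pseudo_cells)])
        out[str(barcode)] = CloneGrowthCurve(
            barcode_id=str(barcode),
            days=np.asarray(days),
            abundance=ab,
            smoothed_log=fitted,
            derivative=deriv,
            fold_change=fc,
        )
    return out


def winner_and_dominance(
    bc: BarcodeCounts,
    dominance_threshold: float = 0.5,
    query_day: int | None = None,
) -> dict:
    """Final-day winner, first dominance day, and optional queried frequencies.

    Returns winner_id, final_frequency, dominance_day (first sampled day the
    winner holds ≥ threshold, or None), a tie flag, and — when ``query_day``
    is given — every barcode's frequency at the sampled day nearest to it
    (used for cross-culture medians such as dominant-clone frequency at a
    fixed day post transduction).
    """
    freqs = bc.frequencies
    final = freqs.iloc[:, -1]
    top = final.max()
    winners = sorted(final.index[final == top], key=str)
    winner = winners[0]
    traj = freqs.loc[winner]
    dom = traj[traj >= dominance_threshold]
    result = {
        "winner_id": str(winner),
        "final_frequency": float(top),
        "dominance_day": int(dom.index[0]) if len(dom) else None,
        "tie": len(winners) > 1,
    }
    if query_day is not None:
        days = np.asarray(bc.days)
        nearest = int(days[np.argmin(np.abs(days - query_day))])
        result["query_day"] = nearest
        result["query_frequencies"] = freqs[nearest].copy()
    return result


def replicate_concordance(
    replicates: list[BarcodeCounts], min_frequency: float = 0.001
) -> dict:
    """Cross-replicate determinism metrics.

    Winner identity across replicates; mean per-barcode Spearman correlation
    of frequency trajectories between replicate pairs (restricted to barcodes
    reaching ``min_frequency`` in any replicate, over shared days); and colour
    ranks ordering barcodes by their maximum frequency across replicates
    (rank 1 = the "red" subclone).
    """
    if len(replicates) < 2:
        raise ValueError("need at least two replicates")
    universes = [set(r.counts.index) - {OTHER} for r in replicates]
    shared_days = sorted(set.intersection(*(set(r.days) for r in replicates)))
    union = set.union(*universes)
    if not set.intersection(*universes):
        raise ValueError("replicates share no barcodes")

    freqs = []
    for r in replicates:
        f = r.frequencies.reindex(index=sorted(union), columns=shared_days).fillna(0.0)
        freqs.append(f)
    retained = sorted(
        b for b in union if any((f.loc[b] >= min_frequency).any() for f in freqs)
    )

    winners = [winner_and_dominance(r)["winner_id"] for r in replicates]
    same_winner = len(set(winners)) == 1

    pair_corr = {}
    for i in range(len(freqs)):
        for j in range(i + 1, len(freqs)):
            per_bc = []
            for b in retained:
                a, c = freqs[i].loc[b], freqs[j].loc[b]
                if a.std() == 0 or c.std() == 0:
                    continue
                rho = stats.spearmanr(a, c).statistic
                if np.isfinite(rho):
                    per_bc.append(rho)
            pair_corr[(replicates[i].replicate_id, replicates[j].replicate_id)] = (
                float(np.mean(per_bc)) if per_bc else np.nan
            )

    max_freq = pd.Series(
        {b: max(float(f.loc[b].max()) for f in freqs) for b in retained}
    ).sort_values(ascending=False, kind="stable")
    colour_ranks = pd.Series(
        np.arange(1, len(max_freq) + 1), index=max_freq.index, name="colour_rank"
    )
    return {
        "winners": winners,
        "same_winner": same_winner,
        "pairwise_correlations": pair_corr,
        "mean_correlation": float(np.nanmean(list(pair_corr.values()))),
        "colour_ranks": colour_ranks,
    }


def muller_table(bc: BarcodeCounts, nesting=None) -> pd.DataFrame:
    """Plot-ready long table (day, identity, parent, frequency).

    Without nesting every barcode is a root series. With a ``SubcloneSet``
    whose clone ids name barcodes (children as ``barcode/suffix``), nested
    clone series are emitted under their parent barcode with frequency
    ``barcode_frequency × nested relative frequency``. An empty "other" pool
    is omitted.
    """
    freqs = bc.frequencies
    rows = []
    for barcode in freqs.index:
        if barcode == OTHER and (freqs.loc[barcode] == 0).all():
            continue
        for day in freqs.columns:
            rows.append(
                {
                    "day": int(day),
                    "identity": str(barcode),
                    "parent": ".",
                    "frequency": float(freqs.loc[barcode, day]),
                }
            )
    table = pd.DataFrame(rows, columns=["day", "identity", "parent", "frequency"])
    if nesting is None:
        return table

    known = set(map(str, freqs.index))
    for cid, parent, _ in nesting.clones:
        root = str(cid).split("/")[0]
        if root not in known:
            raise ValueError(f"nesting references unknown barcode: {root}")
        if parent is None:
            continue  # the barcode series itself already emitted
        nested = nesting.frequencies.loc[cid]
        for day in freqs.columns:
            rel = float(nested.get(day, np.nan))
            if np.isnan(rel):
                continue
            host = float(freqs.loc[root, day]) if root in freqs.index else 0.0
            rows.append(
                {
                    "day": int(day),
                    "identity": str(cid),
                    "parent": str(parent),
                    "frequency": min(rel, 1.0) * host,
                }
            )
    return pd.DataFrame(rows, columns=["day", "identity", "parent", "frequency"])


@dataclass
class SelectionFit:
    """Logit-linear selection-coefficient estimate for one lineage."""

    s: float
    stderr: float
    ci_low: float
    ci_high: float
    n_days: int
    intercept: float
    confidence: float = 0.95

    def summary(self) -> str:
        return (
            f"selection coefficient s = {self.s:+.4f}/day "
            f"(SE {self.stderr:.4f}, {int(self.confidence * 100)}% CI "
            f"[{self.ci_low:+.4f}, {self.ci_high:+.4f}], n = {self.n_days} days)"
        )


def fit_selection(
    days: np.ndarray,
    frequencies: np.ndarray,
    reference: np.ndarray | None = None,
    confidence: float = 0.95,
) -> SelectionFit:
    """Selection coefficient from a frequency trajectory.

    Ordinary least squares of logit(f) on day: under logistic competition the
    logit is linear in time with slope s (per day). Days at exactly 0 or 1
    are uninformative and dropped. When ``reference`` (the frequency of the
    competing rest-of-population) is supplied, f is first renormalized to
    f/(f+reference).
    """
    days = np.asarray(days, dtype=float)
    f = np.asarray(frequencies, dtype=float)
    if reference is not None:
        ref = np.asarray(reference, dtype=float)
        f = f / (f + ref)
    keep = (f > 0) & (f < 1)
    if keep.sum() < 3:
        raise ValueError("need at least three days with frequency strictly inside (0, 1)")
    x, y = days[keep], np.log(f[keep] / (1 - f[keep]))
    res = stats.linregress(x, y)
    dof = keep.sum() - 2
    tcrit = stats.t.ppf(0.5 + confidence / 2, dof) if dof > 0 else np.nan
    return SelectionFit(
        s=float(res.slope),
        stderr=float(res.stderr),
        ci_low=float(res.slope - tcrit * res.stderr),
        ci_high=float(res.slope + tcrit * res.stderr),
        n_days=int(keep.sum()),
        intercept=float(res.intercept),
        confidence=confidence,
    )
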