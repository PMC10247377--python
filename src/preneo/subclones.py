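"""Subclone deconvolution from longitudinal bulk segment means.

Under a diploid background, the mean log2 ratio of a segment carrying a
one-copy change in a fraction *f* of cells is log2((2 ± f)/2); inverting that
mixture gives per-event clonal-fraction trajectories. Events whose
trajectories move together (L∞ distance) are grouped into subclones, nested
by frequency containment into a fishplot-ready clone tree, and scanned for
clonal-interference and extinction episodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

__all__ = [
    "SubcloneSet",
    "event_frequency",
    "forward_model",
    "arm_event_trajectories",
    "cluster_trajectories",
    "build_clone_tree",
    "detect_interference",
]

APPEARANCE_EPS = 0.02


@dataclass
class SubcloneSet:
    """Nested clones with event sets and frequency trajectories over time."""

    clones: list[tuple[str, str | None, frozenset[str]]]  # (id, parent or None, events)
    frequencies: pd.DataFrame  # index clone_id, columns days
    episodes: list[dict] = field(default_factory=list)
    resolved: bool = True
    violations: list[str] = field(default_factory=list)

    def parent_of(self, clone_id: str) -> str | None:
        for cid, parent, _ in self.clones:
            if cid == clone_id:
                return parent
        raise KeyError(clone_id)

    def ancestors_of(self, clone_id: str) -> set[str]:
        out: set[str] = set()
        p = self.parent_of(clone_id)
        while p is not None:
            out.add(p)
            p = self.parent_of(p)
        return out

    def to_fishplot_table(self) -> pd.DataFrame:
        """Long-format (clone, parent, day, frequency) table."""
        rows = []
        for cid, parent, _ in self.clones:
            for day in self.frequencies.columns:
                rows.append(
                    {
                        "clone": cid,
                        "parent": parent if parent is not None else ".",
                        "day": day,
                        "frequency": float(self.frequencies.loc[cid, day]),
                    }
                )
        return pd.DataFrame(rows)


def forward_model(f: float, copy_change: int) -> float:
    """Mean log2 ratio of a one-copy event at clonal fraction ``f`` (diploid background)."""
    if copy_change not in (1, -1):
        raise ValueError("copy_change must be +1 or -1")
    return float(np.log2((2.0 + copy_change * f) / 2.0))


def event_frequency(mean_log_ratio: float, copy_change: int) -> float:
    """Clonal fraction implied by a segment mean under the diploid mixture model.

    loss: f = 2(1 − R); gain: f = 2(R − 1) with R = 2^mean_log_ratio. Values
    outside [−0.05, 1.05] before clamping trigger an out-of-model warning.
    """
    if copy_change not in (1, -1):
        raise ValueError("copy_change must be +1 or -1")
    r = 2.0 ** float(mean_log_ratio)
    f = 2.0 * (1.0 - r) if copy_change == -1 else 2.0 * (r - 1.0)
    if f < -0.05 or f > 1.05:
        warnings.warn(
            f"mixture fraction {f:.3f} outside [0,1]+slack: segment mean "
            f"{mean_log_ratio:.3f} is out of the diploid one-copy model",
            stacklevel=2,
        )
    return float(np.clip(f, 0.0, 1.0))


def arm_event_trajectories(
    profiles: list, event_ids: list[str] | None = None
) -> pd.DataFrame:
    """Per-event clonal-fraction trajectories from time-ordered bulk profiles.

    For each arm event (e.g. ``"9p-"``), the arm's bin-weighted mean segment
    log ratio at each time point is inverted through :func:`event_frequency`.
    Defaults to every arm event called present at any time point. Returns a
    DataFrame (index event_id, columns day).
    """
    if event_ids is None:
        event_ids = sorted(
            {
                e.event_id
                for p in profiles
                for e in p.arm_events
                if e.present
            }
        )
    days = [p.day for p in profiles]
    out = pd.DataFrame(index=event_ids, columns=days, dtype=float)
    for p in profiles:
        genome = p.genome
        seg_mean_per_bin = np.zeros(genome.n_bins)
        for _, seg in p.segments.iterrows():
            seg_mean_per_bin[int(seg.start_bin): int(seg.end_bin)] = seg["mean"]
        arm_col = genome.bins["arm"].to_numpy()
        for ev in event_ids:
            arm, sign = ev[:-1], ev[-1]
            mask = arm_col == arm
            if not mask.any():
                raise ValueError(f"event {ev}: arm {arm} not in the genome model")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out.loc[ev, p.day] = event_frequency(
                    float(seg_mean_per_bin[mask].mean()), 1 if sign == "+" else -1
                )
    return out


def cluster_trajectories(
    trajectories: pd.DataFrame, distance_threshold: float = 0.1
) -> dict[str, list[str]]:
    """Group event trajectories by complete-linkage clustering on L∞ distance.

    ``trajectories``: index event_id, columns days (a common grid). Events in
    one group are interpreted as co-resident in one subclone. Deterministic:
    events are processed in lexicographic order and groups are named after
    their lexicographically smallest member.
    """
    if trajectories.shape[1] < 2:
        raise ValueError("need at least two time points per event")
    if trajectories.isna().any().any():
        raise ValueError("trajectories must share one day grid (no missing values)")
    tr = trajectories.sort_index()
    if len(tr) == 1:
        return {str(tr.index[0]): [str(tr.index[0])]}
    d = pdist(tr.to_numpy(), metric="chebyshev")
    labels = fcluster(linkage(d, method="complete"), t=distance_threshold,
                      criterion="distance")
    groups: dict[int, list[str]] = {}
    for ev, lab in zip(tr.index, labels):
        groups.setdefault(int(lab), []).append(str(ev))
    return {min(members): sorted(members) for members in groups.values()}


def build_clone_tree(
    groups: dict[str, list[str]],
    trajectories: pd.DataFrame,
    nesting_tolerance: float = 0.1,
) -> SubcloneSet:
    """Nest grouped trajectories into a clone tree by frequency containment.

    Group A can be an ancestor of B iff A's frequency dominates B's at every
    day within the tolerance and A appeared no later than B; the parent is the
    most-derived such candidate. A pigeonhole check flags sibling sets whose
    frequencies sum above their parent's. Inconsistencies do not raise: the
    returned set carries ``resolved=False`` and the list of violations.
    """
    days = list(trajectories.columns)
    freq = pd.DataFrame(
        {gid: trajectories.loc[members].mean(axis=0) for gid, members in groups.items()}
    ).T
    freq = freq.clip(0.0, 1.0)

    def first_day(gid: str) -> float:
        above = freq.loc[gid] > APPEARANCE_EPS
        return float(days[int(np.argmax(above.to_numpy()))]) if above.any() else np.inf

    # canonical order guarantees an acyclic parent assignment
    order = sorted(
        freq.index, key=lambda g: (first_day(g), -float(freq.loc[g].mean()), str(g))
    )
    rank = {g: i for i, g in enumerate(order)}

    def contains(a: str, b: str) -> bool:
        return bool((freq.loc[a] >= freq.loc[b] - nesting_tolerance).all())

    clones: list[tuple[str, str | None, frozenset[str]]] = []
    violations: list[str] = []
    parent_of: dict[str, str | None] = {}
    for gid in order:
        candidates = [a for a in order if rank[a] < rank[gid] and contains(a, gid)]
        parent = candidates[-1] if candidates else None  # most-derived container
        parent_of[gid] = parent
        clones.append((gid, parent, frozenset(groups[gid])))

    for parent in set(parent_of.values()):
        siblings = [g for g, p in parent_of.items() if p == parent]
        if len(siblings) < 2:
            continue
        total = freq.loc[siblings].sum(axis=0)
        cap = (freq.loc[parent] if parent is not None else pd.Series(1.0, index=freq.columns))
        excess = (total - cap - nesting_tolerance)
        if (excess > 0).any():
            day = excess.idxmax()
            violations.append(
                f"children of {parent or 'root'} sum to {total[day]:.3f} > "
                f"{'parent' if parent else 'root'} frequency {float(cap[day]):.3f} "
                f"+ tolerance at day {day}"
            )
    return SubcloneSet(
        clones=clones,
        frequencies=freq,
        resolved=not violations,
        violations=violations,
    )


def detect_interference(
    subclones: SubcloneSet,
    rise_threshold: float = 0.2,
    extinct_threshold: float = 0.02,
) -> list[dict]:
    """Interference/extinction episodes and long coexistence intervals.

    A clone that peaks at ≥ ``rise_threshold`` but ends ≤ ``extinct_threshold``
    while some non-ancestral clone's frequency rises over the same window is
    recorded as an interference episode. Intervals where two clones each hold
    ≥ ``rise_threshold`` simultaneously are recorded as coexistence.
    """
    freq = subclones.frequencies
    days = list(freq.columns)
    episodes: list[dict] = []
    for cid in freq.index:
        traj = freq.loc[cid]
        peak_i = int(np.argmax(traj.to_numpy()))
        peak = float(traj.iloc[peak_i])
        final = float(traj.iloc[-1])
        if peak >= rise_threshold and final <= extinct_threshold:
            blocked = subclones.ancestors_of(cid) | {cid}
            for other in freq.index:
                if other in blocked or cid in subclones.ancestors_of(other):
                    continue
                rise = float(freq.loc[other].iloc[-1]) - float(freq.loc[other].iloc[peak_i])
                if rise > 0:
                    episodes.append(
                        {
                            "kind": "interference",
                            "clone": cid,
                            "winner": other,
                            "peak_day": days[peak_i],
                            "peak_frequency": peak,
                        }
                    )
                    break
    ids = list(freq.index)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if b in subclones.ancestors_of(a) or a in subclones.ancestors_of(b):
                continue
            both = (freq.loc[a] >= rise_threshold) & (freq.loc[b] >= rise_threshold)
            if both.any():
                idx = np.flatnonzero(both.to_numpy())
                episodes.append(
                    {
                        "kind": "coexistence",
                        "clone_a": a,
                        "clone_b": b,
                        "start_day": days[int(idx[0])],
                        "duration_days": float(days[int(idx[-1])]) - float(days[int(idx[0])]),
                    }
                )
    subclones.episodes = episodes
    return episodes
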