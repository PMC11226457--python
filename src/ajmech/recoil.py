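"""Laser-ablation junction recoil: edge distance and initial recoil rate.

After a cell-cell junction is cut, its two severed edges recoil; the rate
of separation over the first 2 s after ablation (one frame interval) is the
initial recoil rate, a proxy for the tension the junction carried.  Inputs
are the tracked coordinates of the two cut edges over frames acquired every
2 s from 6 s before to 30 s after the cut.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from ._util import sanitize_f as _sanitize_f

__all__ = [
    "EdgeTrack",
    "RecoilResult",
    "edge_distance",
    "initial_recoil",
    "analyze_track",
    "compare_recoil",
]


@dataclass
class EdgeTrack:
    """Coordinates (µm) of the two cut edges per frame around ablation."""

    time_s: np.ndarray
    edge1_xy: np.ndarray  # (n_frames, 2)
    edge2_xy: np.ndarray  # (n_frames, 2)
    ablation_time_s: float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, float)
        e1 = np.asarray(self.edge1_xy, float)
        e2 = np.asarray(self.edge2_xy, float)
        if e1.shape != (t.size, 2) or e2.shape != (t.size, 2):
            raise ValueError("edge coordinates must be (n_frames, 2)")
        if not (np.all(np.isfinite(e1)) and np.all(np.isfinite(e2))):
            raise ValueError("edge coordinates must be finite")
        post = t >= self.ablation_time_s
        if post.sum() < 2 or (~post).sum() < 1:
            raise ValueError("need >= 1 pre- and >= 2 post-ablation frames")
        self.time_s, self.edge1_xy, self.edge2_xy = t, e1, e2


@dataclass
class RecoilResult:
    time_s: np.ndarray
    distance_um: np.ndarray
    initial_rate_um_s: float


def edge_distance(track: EdgeTrack) -> np.ndarray:
    """Euclidean inter-edge distance (µm) per frame."""
    return np.linalg.norm(track.edge1_xy - track.edge2_xy, axis=1)


def initial_recoil(track: EdgeTrack, interval_s: float = 2.0) -> float:
    """Initial recoil rate: secant of the inter-edge distance over the first
    ``interval_s`` seconds after ablation (µm/s).

    Uses the first frame at/after the ablation time and the frame one
    interval later; either missing (beyond half a frame interval) is an
    error naming the gap.
    """
    d = edge_distance(track)
    t = track.time_s
    tol = interval_s / 2.0

    post = np.nonzero(t >= track.ablation_time_s - 1e-9)[0]
    if post.size == 0:
        raise ValueError("no frame at or after the ablation time")
    i0 = post[0]
    t0 = t[i0]
    j = int(np.argmin(np.abs(t - (t0 + interval_s))))
    if j == i0 or abs(t[j] - (t0 + interval_s)) > tol:
        raise ValueError(
            f"no frame within {tol:.3g} s of t_ablation + {interval_s} s "
            f"(nearest at {t[j]:.3g} s)")
    return float((d[j] - d[i0]) / (t[j] - t0))


def analyze_track(track: EdgeTrack) -> RecoilResult:
    return RecoilResult(time_s=track.time_s, distance_um=edge_distance(track),
                        initial_rate_um_s=initial_recoil(track))


def compare_recoil(groups: dict[str, list[float]]):
    """One-way ANOVA over group initial-rate lists, with Sidak-adjusted
    pairwise Welch t-tests.

    Returns ``(table, anova, pairwise)``: per-group mean/SD/n, the overall
    F-test, and {(a, b): adjusted p}.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrays = {k: np.asarray(v, float) for k, v in groups.items()}
    for k, a in arrays.items():
        if a.size < 2:
            raise ValueError(f"group {k!r} has < 2 observations")
    table = {k: {"n": int(a.size), "mean": float(a.mean()),
                 "sd": float(a.std(ddof=1)),
                 "sem": float(a.std(ddof=1) / np.sqrt(a.size))}
             for k, a in arrays.items()}
    F, p = _sanitize_f(*stats.f_oneway(*arrays.values()))
    pairs = list(combinations(arrays, 2))
    m = len(pairs)
    pairwise = {}
    for a, b in pairs:
        _, praw = stats.ttest_ind(arrays[a], arrays[b], equal_var=False)
        pairwise[(a, b)] = float(1.0 - (1.0 - praw) ** m)  # Sidak
    return table, {"F": float(F), "p_value": float(p)}, pairwise
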