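"""FRAP double normalization and single-exponential recovery fitting.

Raw inputs are three mean-intensity time series: the bleached ROI
(``i_frap``), an unbleached reference ROI (``i_ref``, tracking acquisition
photobleaching), and the background outside the cell (``i_back``).  The
double-normalization step corrects the bleached-ROI signal for acquisition
photobleaching,

    i_norm(t) = [i_ref_pre / (i_ref(t) - i_back(t))]
              * [(i_frap(t) - i_back(t)) / i_frap_pre],

with the ``_pre`` terms the background-subtracted pre-bleach averages.  The
full-scale calibration then anchors the pre-bleach level at 1 and the bleach
frame at 0,

    i_norm1(t) = (i_norm(t) - i_norm(t_bleach)) / (i_norm_pre - i_norm(t_bleach)),

so the fitted plateau of I(t) = p (1 - e^{-k t}) is the mobile fraction
relative to total and the half-life is ln2 / k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from ._util import sanitize_f as _sanitize_f

__all__ = [
    "FrapTrace",
    "NormalizedTrace",
    "RecoveryFit",
    "double_normalize",
    "full_scale",
    "normalize",
    "fit_recovery",
    "summarize_groups",
]


@dataclass
class FrapTrace:
    """Raw three-signal FRAP series; ``bleach_index`` is the first
    post-bleach frame (default 4: bleach after the fourth acquisition)."""

    time_s: np.ndarray
    i_frap: np.ndarray
    i_ref: np.ndarray
    i_back: np.ndarray
    bleach_index: int = 4

    def __post_init__(self) -> None:
        arrs = [np.asarray(a, dtype=float) for a in
                (self.time_s, self.i_frap, self.i_ref, self.i_back)]
        if len({a.shape for a in arrs}) != 1:
            raise ValueError("all series must share one length")
        if not all(np.all(np.isfinite(a)) for a in arrs):
            raise ValueError("intensities and times must be finite")
        if not 1 <= self.bleach_index < arrs[0].size:
            raise ValueError("bleach_index must leave >= 1 pre-bleach frame")
        self.time_s, self.i_frap, self.i_ref, self.i_back = arrs


@dataclass
class NormalizedTrace:
    time_s: np.ndarray
    i_norm: np.ndarray
    i_norm1: np.ndarray
    bleach_index: int


@dataclass
class RecoveryFit:
    p: float
    k: float
    half_life_s: float
    residual_ss: float
    p_stderr: float
    k_stderr: float
    converged: bool
    flags: tuple = ()


def double_normalize(trace: FrapTrace) -> np.ndarray:
    """Photobleaching-corrected normalized intensity (the double-
    normalization formula above)."""
    pre = slice(0, trace.bleach_index)
    ref_bs = trace.i_ref - trace.i_back
    frap_bs = trace.i_frap - trace.i_back
    bad = np.nonzero(ref_bs <= 0)[0]
    if bad.size:
        raise ValueError(
            f"reference does not exceed background at frame {bad[0]}")
    i_ref_pre = float(np.mean(ref_bs[pre]))
    i_frap_pre = float(np.mean(frap_bs[pre]))
    if i_frap_pre == 0:
        raise ValueError("pre-bleach FRAP-ROI intensity is zero")
    return (i_ref_pre / ref_bs) * (frap_bs / i_frap_pre)


def full_scale(i_norm: np.ndarray, bleach_index: int) -> np.ndarray:
    """Full-scale calibration: pre-bleach average -> 1, bleach frame -> 0."""
    i_norm = np.asarray(i_norm, dtype=float)
    if not 1 <= bleach_index < i_norm.size:
        raise ValueError("bleach_index must leave >= 1 pre-bleach frame")
    i_pre = float(np.mean(i_norm[:bleach_index]))
    i_bleach = float(i_norm[bleach_index])
    depth = i_pre - i_bleach
    if depth == 0:
        raise ValueError("zero bleach depth: full-scale calibration undefined")
    return (i_norm - i_bleach) / depth


def normalize(trace: FrapTrace) -> NormalizedTrace:
    """Double normalization followed by full-scale calibration."""
    i_norm = double_normalize(trace)
    i_norm1 = full_scale(i_norm, trace.bleach_index)
    return NormalizedTrace(time_s=trace.time_s, i_norm=i_norm,
                           i_norm1=i_norm1, bleach_index=trace.bleach_index)


def fit_recovery(i_norm1: np.ndarray, time_s: np.ndarray,
                 bleach_index: int | None = None) -> RecoveryFit:
    """Fit I(t) = p (1 - e^{-k t}) to the post-bleach recovery.

    ``time_s`` may be either the full frame-time vector (then
    ``bleach_index`` selects the post-bleach segment and t is re-zeroed at
    the bleach frame) or a time-since-bleach vector matching ``i_norm1``.

    The plateau enters the model linearly, so it is profiled out: for each
    candidate rate, p(k) = sum(y m) / sum(m^2) with m = 1 - e^{-k t}, and
    the profiled sum of squares is minimised over k on a log grid followed
    by bounded scalar refinement.  This keeps the fit out of the flat
    large-p / small-k valley that traps a naive joint optimiser on noisy
    traces.  A Levenberg-Marquardt-class polish over (p, k) finishes; its
    covariance supplies the standard errors.  Bounds: p in [0, 1.5], k in
    (0, 10]; the k grid spans ln2/(10 x acquisition span) up to 10/s.
    """
    y = np.asarray(i_norm1, dtype=float)
    t = np.asarray(time_s, dtype=float)
    if bleach_index is not None:
        y = y[bleach_index:]
        t = t[bleach_index:] - t[bleach_index]
    if y.size < 5:
        raise ValueError("need >= 5 post-bleach frames to fit")

    def model(t, p, k):
        return p * (1.0 - np.exp(-k * t))

    def profiled(k):
        m = 1.0 - np.exp(-k * t)
        denom = float(np.dot(m, m))
        p = float(np.dot(y, m)) / denom if denom > 0 else 0.0
        p = min(max(p, 0.0), 1.5)
        r = y - p * m
        return float(np.dot(r, r)), p

    span = max(t[-1], 1.0)
    k_grid = np.geomspace(np.log(2) / (10 * span), 10.0, 60)
    ss = np.array([profiled(k)[0] for k in k_grid])
    kbest = k_grid[np.argmin(ss)]
    lo = k_grid[max(np.argmin(ss) - 1, 0)]
    hi = k_grid[min(np.argmin(ss) + 1, k_grid.size - 1)]
    res = optimize.minimize_scalar(lambda k: profiled(k)[0],
                                   bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-10})
    k0 = float(res.x)
    p0 = profiled(k0)[1]

    flags: list[str] = []
    try:
        popt, pcov = optimize.curve_fit(
            model, t, y, p0=[max(p0, 1e-6), k0],
            bounds=([0.0, 1e-8], [1.5, 10.0]), maxfev=10000)
        converged = True
    except RuntimeError:
        popt, pcov = np.array([np.nan, np.nan]), np.full((2, 2), np.nan)
        converged = False
        flags.append("no_convergence")
    p, k = map(float, popt)
    if converged:
        if p > 1.0:
            flags.append("plateau_above_1")
        if k >= 10.0 - 1e-6 or k <= 1e-8 * 1.01:
            flags.append("rate_at_bound")
    resid = y - model(t, p, k) if converged else y
    stderr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else (
        np.array([np.nan, np.nan]))
    return RecoveryFit(p=p, k=k,
                       half_life_s=float(np.log(2) / k) if converged else np.nan,
                       residual_ss=float(np.sum(resid ** 2)),
                       p_stderr=float(stderr[0]), k_stderr=float(stderr[1]),
                       converged=converged, flags=tuple(flags))


def summarize_groups(fits_by_condition: dict[str, list[RecoveryFit]]):
    """Per-condition summary of mobile fraction and half-life plus a
    one-way ANOVA (no multiple-comparison correction) on the mobile
    fraction, matching how mobile fractions are compared across conditions.

    Returns ``(table, anova)`` where ``table`` maps condition ->
    {n, p_mean, p_sd, p_sem, half_life_mean, half_life_sd, half_life_sem}
    and ``anova`` is {"F": ..., "p_value": ...}.
    """
    if len(fits_by_condition) < 2:
        raise ValueError("need >= 2 conditions to compare")
    table = {}
    groups = []
    for cond, fits in fits_by_condition.items():
        ps = np.array([f.p for f in fits if f.converged])
        hl = np.array([f.half_life_s for f in fits if f.converged])
        if ps.size < 2:
            raise ValueError(f"condition {cond!r} has < 2 converged fits")
        table[cond] = {
            "n": int(ps.size),
            "p_mean": float(ps.mean()), "p_sd": float(ps.std(ddof=1)),
            "p_sem": float(ps.std(ddof=1) / np.sqrt(ps.size)),
            "half_life_mean": float(hl.mean()),
            "half_life_sd": float(hl.std(ddof=1)),
            "half_life_sem": float(hl.std(ddof=1) / np.sqrt(hl.size)),
        }
        groups.append(ps)
    F, pval = stats.f_oneway(*groups)
    F, pval = _sanitize_f(F, pval)
    return table, {"F": F, "p_value": pval}
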