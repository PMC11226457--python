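"""Seeded synthetic-data generators for every pipeline input.

Each generator emulates one acquisition the analyses consume — SAIM angle
stacks (14 angles, 0°-52° in 4° steps), magnetic-tweezer force ramps
(1 pN/s load, -0.1 pN/s release, 0.01 s sampling), FRAP series (90 frames
at 1 s, bleach after the fourth), ablation edge tracks (2 s frames, -6 s to
+30 s), and migration velocity fields — with the statistical structure the
corresponding analysis assumes, and returns the ground truth alongside so
recovery tests read truth only from it.  All randomness flows from an
explicit seed; one top-level seed can be split into per-generator streams
with :func:`split_seed`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .frap import FrapTrace
from .recoil import EdgeTrack
from .saim import AngleSweep, LayerStack, _profiles_for_heights_per_pixel
from .migration import VelocityField
from .tweezer import ForceRamp, Trace, WLCParams, wlc_extension

__all__ = [
    "split_seed",
    "write_truth",
    "gen_saim_stack",
    "gen_tweezer_trace",
    "gen_frap_trace",
    "gen_recoil_track",
    "gen_velocity_fields",
]


def split_seed(seed: int, *labels: str) -> dict[str, int]:
    """Deterministically derive one independent sub-seed per label."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(labels))
    return {lab: int(c.generate_state(1)[0] % (2 ** 31))
            for lab, c in zip(labels, children)}


def write_truth(truth: dict, path) -> None:
    """Record a generator's ground truth as JSON."""
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        raise TypeError(type(o))

    Path(path).write_text(json.dumps(truth, indent=1, default=default))


# ---------------------------------------------------------------------------
# SAIM
# ---------------------------------------------------------------------------

def gen_saim_stack(height, sweep: AngleSweep | None = None,
                   stack: LayerStack | None = None,
                   amplitude: float = 500.0, offset: float = 50.0,
                   noise_frac: float = 0.02, shape: tuple[int, int] = (64, 64),
                   seed: int = 0):
    """Synthetic angle-scan image stack from the standing-wave forward model.

    ``height`` is a scalar (uniform field) or a 2D ground-truth height map
    (nm).  Per pixel, I_j = A * F_j(h) + B with multiplicative Gaussian
    noise of fractional sigma ``noise_frac``.  Returns ``(stack, truth)``
    with stack shaped (n_angles, rows, cols).
    """
    if noise_frac < 0:
        raise ValueError("noise_frac must be >= 0")
    sweep = sweep or AngleSweep()
    stack = stack or LayerStack()
    hmap = np.broadcast_to(np.asarray(height, dtype=float), shape).copy()
    F = _profiles_for_heights_per_pixel(hmap.ravel(), sweep, stack, "TE")
    clean = (amplitude * F + offset).T.reshape(len(sweep), *shape)
    rng = np.random.default_rng(seed)
    noisy = clean * (1.0 + noise_frac * rng.standard_normal(clean.shape))
    truth = {
        "kind": "saim_stack",
        "height_nm": hmap,
        "amplitude": amplitude, "offset": offset,
        "noise_frac": noise_frac, "seed": seed,
        "angles_deg": list(sweep.angles_deg),
        "wavelength_nm": stack.wavelength_nm,
        "oxide_thickness_nm": stack.oxide_thickness_nm,
    }
    return noisy, truth


# ---------------------------------------------------------------------------
# magnetic tweezers
# ---------------------------------------------------------------------------

def _ramp_profile(ramp: ForceRamp, n_cycles: int):
    """Force-vs-time for pull/release cycles."""
    t_up = (ramp.f_end - ramp.f_start) / ramp.load_rate_pN_s
    t_down = (ramp.f_end - ramp.f_start) / (-ramp.release_rate_pN_s)
    times, forces = [], []
    t0 = 0.0
    for _ in range(n_cycles):
        tu = np.arange(0.0, t_up, ramp.sample_dt_s)
        times.append(t0 + tu)
        forces.append(ramp.f_start + ramp.load_rate_pN_s * tu)
        t0 += t_up
        td = np.arange(0.0, t_down, ramp.sample_dt_s)
        times.append(t0 + td)
        forces.append(ramp.f_end + ramp.release_rate_pN_s * td)
        t0 += t_down
    return np.concatenate(times), np.concatenate(forces)


def gen_tweezer_trace(ramp: ForceRamp | None = None,
                      events: list[tuple[float, float]] = (),
                      n_cycles: int = 1, noise_nm: float = 5.0,
                      handle_contour_nm: float = 200.0,
                      wlc: WLCParams | None = None,
                      seed: int = 0,
                      detector_window: int = 50):
    """Synthetic bead-height force-ramp trace with planted step events.

    The baseline is the WLC extension of a ``handle_contour_nm`` tether
    (smooth in force); each (force, ΔH) event adds a permanent ΔH step at
    the first upward crossing of its force during a loading phase.  Gaussian
    height noise of sd ``noise_nm`` is added.  Events whose onsets fall
    within one ``detector_window`` of each other are rejected.  Returns
    ``(Trace, truth)``.
    """
    ramp = ramp or ForceRamp()
    wlc = wlc or WLCParams()
    for f_ev, dh in events:
        if not ramp.f_start < f_ev < ramp.f_end:
            raise ValueError("event force outside the ramp range")
    t, f = _ramp_profile(ramp, n_cycles)

    # smooth baseline: tether WLC extension, tabulated then interpolated
    f_grid = np.linspace(max(min(f), 1e-3), max(f), 200)
    x_grid = np.array([wlc_extension(fi, handle_contour_nm, wlc)
                       for fi in f_grid])
    baseline = np.interp(f, f_grid, x_grid)

    h = baseline.copy()
    onsets = []
    loading = np.concatenate([[True], np.diff(f) > 0])
    for f_ev, dh in sorted(events):
        crossing = np.nonzero((f >= f_ev) & loading)[0]
        if crossing.size == 0:
            raise ValueError(f"ramp never reaches event force {f_ev}")
        k = crossing[0]
        onsets.append(int(k))
        h[k:] += dh
    onsets_sorted = np.sort(onsets)
    if np.any(np.diff(onsets_sorted) < detector_window):
        raise ValueError("planted events overlap within one detector window")

    rng = np.random.default_rng(seed)
    h = h + noise_nm * rng.standard_normal(h.size)
    truth = {
        "kind": "tweezer_trace",
        "events": [{"force_pN": fe, "delta_h_nm": dh, "onset_index": k}
                   for (fe, dh), k in zip(sorted(events), onsets)],
        "noise_nm": noise_nm, "seed": seed, "n_cycles": n_cycles,
        "handle_contour_nm": handle_contour_nm,
    }
    return Trace(time_s=t, force_pN=f, bead_height_nm=h), truth


# ---------------------------------------------------------------------------
# FRAP
# ---------------------------------------------------------------------------

def gen_frap_trace(p: float, k: float, n_frames: int = 90, dt_s: float = 1.0,
                   bleach_index: int = 4, bleach_depth: float = 0.9,
                   photobleach_rate: float = 0.002,
                   background_level: float = 50.0,
                   frap_level: float = 1000.0, ref_level: float = 1000.0,
                   noise_sd: float = 0.05, seed: int = 0):
    """Synthetic three-signal FRAP series with known recovery parameters.

    The bleached-ROI model is 1 pre-bleach, then
    (1 - depth) + depth * p (1 - e^{-k t'}) after the bleach; both ROIs
    decay with acquisition photobleaching ``photobleach_rate`` per frame, so
    double normalization must remove it.  Noise is additive Gaussian with
    sd ``noise_sd`` times the instantaneous clean signal of each channel
    (shot-noise-like: dimmer frames are less noisy in absolute counts),
    which keeps the single-frame bleach anchor of the full-scale
    calibration meaningful at realistic noise levels.  Returns
    ``(FrapTrace, truth)``.
    """
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    if k <= 0:
        raise ValueError("k must be positive")
    if not 0 < bleach_depth <= 1:
        raise ValueError("bleach_depth must lie in (0, 1]")
    t = np.arange(n_frames) * dt_s
    model = np.ones(n_frames)
    post = np.arange(bleach_index, n_frames)
    tp = (post - bleach_index) * dt_s
    model[post] = (1.0 - bleach_depth) + bleach_depth * p * (1.0 - np.exp(-k * tp))
    decay = (1.0 - photobleach_rate) ** np.arange(n_frames)

    rng = np.random.default_rng(seed)
    frap_clean = frap_level * model * decay
    ref_clean = ref_level * decay
    i_frap = frap_clean * (1.0 + noise_sd * rng.standard_normal(n_frames)) \
        + background_level
    i_ref = ref_clean * (1.0 + noise_sd * rng.standard_normal(n_frames)) \
        + background_level
    i_back = background_level \
        * (1.0 + 0.1 * noise_sd * rng.standard_normal(n_frames))
    truth = {
        "kind": "frap_trace", "p": p, "k": k,
        "half_life_s": float(np.log(2) / k),
        "bleach_index": bleach_index, "bleach_depth": bleach_depth,
        "photobleach_rate": photobleach_rate, "noise_sd": noise_sd,
        "seed": seed,
    }
    return FrapTrace(time_s=t, i_frap=i_frap, i_ref=i_ref, i_back=i_back,
                     bleach_index=bleach_index), truth


# ---------------------------------------------------------------------------
# ablation recoil
# ---------------------------------------------------------------------------

def gen_recoil_track(ballistic_rate: float, saturation_tau: float = 10.0,
                     frame_dt_s: float = 2.0, n_pre: int = 3, n_post: int = 15,
                     d0_um: float = 1.0, noise_um: float = 0.0,
                     seed: int = 0):
    """Synthetic ablation edge track: ballistic recoil then saturation.

    The inter-edge separation grows linearly at ``ballistic_rate`` (µm/s)
    for the first two post-ablation frames, then relaxes exponentially with
    ``saturation_tau`` toward its asymptote; the two edges move
    symmetrically along x.  Positional Gaussian noise ``noise_um`` applies
    per coordinate.  Noiselessly, the first-2-s secant equals
    ``ballistic_rate`` by construction.  Returns ``(EdgeTrack, truth)``.
    """
    if ballistic_rate < 0 or saturation_tau <= 0:
        raise ValueError("rates must be >= 0 and tau positive")
    t = np.arange(-n_pre, n_post + 1) * frame_dt_s
    d = np.full(t.size, d0_um)
    post = t >= 0
    tp = t[post]
    t_ball = 2 * frame_dt_s
    d_post = np.where(
        tp <= t_ball,
        d0_um + ballistic_rate * tp,
        d0_um + ballistic_rate * t_ball
        + ballistic_rate * saturation_tau
        * (1.0 - np.exp(-(tp - t_ball) / saturation_tau)))
    d[post] = d_post

    e1 = np.column_stack([-d / 2, np.zeros_like(d)])
    e2 = np.column_stack([d / 2, np.zeros_like(d)])
    rng = np.random.default_rng(seed)
    e1 = e1 + noise_um * rng.standard_normal(e1.shape)
    e2 = e2 + noise_um * rng.standard_normal(e2.shape)
    truth = {
        "kind": "recoil_track", "ballistic_rate_um_s": ballistic_rate,
        "saturation_tau_s": saturation_tau, "d0_um": d0_um,
        "noise_um": noise_um, "seed": seed,
        "distance_um": d,
    }
    return EdgeTrack(time_s=t, edge1_xy=e1, edge2_xy=e2,
                     ablation_time_s=0.0), truth


# ---------------------------------------------------------------------------
# migration velocity fields
# ---------------------------------------------------------------------------

def gen_velocity_fields(mean_angle_deg: float = 0.0,
                        angular_concentration: float = 4.0,
                        speed_mean_um_h: float = 25.0,
                        speed_sd_um_h: float = 8.0,
                        static_fraction: float = 0.1,
                        grid: tuple[int, int] = (16, 16),
                        n_frames: int = 12, seed: int = 0):
    """Synthetic PIV-like velocity fields with a known flow direction.

    Angles are von Mises about ``mean_angle_deg`` with concentration kappa;
    speeds Gaussian truncated at 0; a ``static_fraction`` of vectors is
    drawn uniformly below the 10 µm/h noise-filter threshold.  Returns
    ``(fields, truth)``.
    """
    if angular_concentration < 0:
        raise ValueError("concentration must be >= 0")
    rng = np.random.default_rng(seed)
    ny, nx = grid
    xs = np.tile(np.arange(nx, dtype=float), (ny, 1)) * 32.0
    ys = np.tile(np.arange(ny, dtype=float)[:, None], (1, nx)) * 32.0
    fields = []
    for fr in range(n_frames):
        n = ny * nx
        if angular_concentration > 0:
            ang = rng.vonmises(np.deg2rad(mean_angle_deg),
                               angular_concentration, size=n)
        else:
            ang = rng.uniform(-np.pi, np.pi, size=n)
        speed = np.abs(rng.normal(speed_mean_um_h, speed_sd_um_h, size=n))
        static = rng.random(n) < static_fraction
        speed[static] = rng.uniform(0.0, 10.0, size=static.sum())
        u = (speed * np.cos(ang)).reshape(ny, nx)
        v = (speed * np.sin(ang)).reshape(ny, nx)
        fields.append(VelocityField(x_um=xs, y_um=ys, u_um_h=u, v_um_h=v,
                                    frame_time_h=fr / 3.0))
    truth = {
        "kind": "velocity_fields", "mean_angle_deg": mean_angle_deg,
        "angular_concentration": angular_concentration,
        "speed_mean_um_h": speed_mean_um_h, "speed_sd_um_h": speed_sd_um_h,
        "static_fraction": static_fraction, "seed": seed,
        "n_frames": n_frames,
    }
    return fields, truth
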