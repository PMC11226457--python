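"""Axial nanometry by scanning-angle interference microscopy (SAIM).

A fluorophore at height ``h`` above a silicon mirror (with a thermal-oxide
spacer) is excited by the standing wave formed between the direct beam and
its reflection.  Scanning the illumination incidence angle modulates the
standing-wave phase at the fluorophore, so the measured intensity-vs-angle
curve is a fingerprint of ``h``.  Fitting the forward model

    I_j = A * |1 + r(theta_j) * exp(i * phi_j)|**2 + B,
    phi_j = 4 * pi * n_medium * h * cos(theta_j) / lambda

per pixel recovers the height independent of brightness.  ``r`` is the
complex amplitude reflection coefficient of the medium/oxide/silicon stack
(single-film Airy summation, equivalent to the 2x2 transfer matrix).

Conventions
-----------
* Angles are propagation angles in the sample medium, in degrees.
* The silicon index is given in the absorbing engineering convention
  ``n - i*kappa`` (imaginary part <= 0); it is conjugated internally to the
  physics convention used by the transfer-matrix formulas.  An index given
  with a positive imaginary part is accepted and interpreted identically.
* Heights are in nm, measured from the oxide surface (z = 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "LayerStack",
    "AngleSweep",
    "FitConfig",
    "PixelFit",
    "ROIResult",
    "mirror_reflectance",
    "excitation_profile",
    "fit_pixel",
    "fit_stack",
    "roi_zcenter",
    "topographic_map",
]

Polarization = Literal["TE", "TM", "average"]

#: Textbook optical constants per excitation line (per-chip ellipsometry is
#: not available; all values overridable).
DEFAULT_INDICES = {
    488.0: {"n_medium": 1.33, "n_oxide": 1.463, "n_silicon": 4.37 - 0.08j},
    561.0: {"n_medium": 1.33, "n_oxide": 1.463, "n_silicon": 4.05 - 0.04j},
}


@dataclass(frozen=True)
class LayerStack:
    """Optical description of the medium / SiO2 spacer / silicon mirror."""

    wavelength_nm: float = 488.0
    oxide_thickness_nm: float = 500.0
    n_medium: float = 1.33
    n_oxide: float = 1.463
    n_silicon: complex = 4.37 - 0.08j

    def __post_init__(self) -> None:
        if not self.wavelength_nm > 0:
            raise ValueError("wavelength_nm must be positive")
        if self.oxide_thickness_nm < 0:
            raise ValueError("oxide_thickness_nm must be >= 0")
        for name in ("n_medium", "n_oxide", "n_silicon"):
            if np.real(getattr(self, name)) < 1:
                raise ValueError(f"real part of {name} must be >= 1")

    @classmethod
    def for_wavelength(cls, wavelength_nm: float, oxide_thickness_nm: float = 500.0,
                       **overrides) -> "LayerStack":
        base = dict(DEFAULT_INDICES.get(float(wavelength_nm),
                                        DEFAULT_INDICES[488.0]))
        base.update(overrides)
        return cls(wavelength_nm=wavelength_nm,
                   oxide_thickness_nm=oxide_thickness_nm, **base)


@dataclass(frozen=True)
class AngleSweep:
    """Ordered illumination incidence angles (degrees, in the sample medium)."""

    angles_deg: tuple = tuple(range(0, 53, 4))

    def __post_init__(self) -> None:
        a = np.asarray(self.angles_deg, dtype=float)
        if a.size < 3:
            raise ValueError("sweep needs >= 3 angles (fit has 3 parameters)")
        if np.any(np.diff(a) <= 0):
            raise ValueError("angles must be strictly increasing")
        if np.any((a < 0) | (a >= 90)):
            raise ValueError("angles must lie in [0, 90) degrees")
        object.__setattr__(self, "angles_deg", tuple(a))

    def __len__(self) -> int:
        return len(self.angles_deg)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.angles_deg, dtype=float)


@dataclass(frozen=True)
class FitConfig:
    """Height bounds and restart grid for the per-pixel fit.

    The default bounds [0, 200] nm bracket the 40-140 nm display range of
    junctional proteins with margin; restarts every 10 nm make the 1-D
    height search global within the bounds.
    """

    h_min_nm: float = 0.0
    h_max_nm: float = 200.0
    restart_step_nm: float = 10.0
    polish: bool = True
    polarization: Polarization = "TE"

    def __post_init__(self) -> None:
        if not self.h_min_nm < self.h_max_nm:
            raise ValueError("h_min_nm must be < h_max_nm")
        if self.restart_step_nm <= 0:
            raise ValueError("restart_step_nm must be positive")


@dataclass
class PixelFit:
    height_nm: float
    amplitude: float
    offset: float
    residual_ss: float
    converged: bool
    restart_index: int


@dataclass
class ROIResult:
    roi_id: str
    pixel_heights_nm: np.ndarray
    z_center_nm: float
    n_pixels: int


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def _physics_index(n: complex) -> complex:
    # physics convention: absorbing index has Im >= 0
    n = complex(n)
    return n.conjugate() if n.imag < 0 else n


def _cos_theta(n_in: complex, theta_rad: float, n_layer: complex):
    """Complex propagation cosine in a layer via Snell's law.

    For a lossless layer an evanescent solution (|sin| > 1) marks the
    total-internal-reflection regime and is rejected upstream.
    """
    s = n_in * np.sin(theta_rad) / n_layer
    return np.sqrt(1.0 + 0.0j - s * s)


def mirror_reflectance(theta_deg, stack: LayerStack,
                       polarization: Polarization = "TE"):
    """Complex amplitude reflection coefficient of the medium/oxide/silicon
    stack for light incident from the medium at ``theta_deg``.

    Single-film Airy formula: r = (r12 + r23 e^{2i beta}) / (1 + r12 r23
    e^{2i beta}) with beta the one-pass phase thickness of the oxide.
    Scalar or array ``theta_deg`` accepted; |r| <= 1 always.
    """
    theta = np.asarray(theta_deg, dtype=float)
    if np.any((theta < 0) | (theta >= 90)):
        raise ValueError("incidence angle must lie in [0, 90) degrees")
    if polarization == "average":
        r_te = mirror_reflectance(theta_deg, stack, "TE")
        r_tm = mirror_reflectance(theta_deg, stack, "TM")
        # amplitude average of the two eigenpolarizations
        return 0.5 * (r_te + r_tm)
    if polarization not in ("TE", "TM"):
        raise ValueError(f"unknown polarization {polarization!r}")

    n1 = complex(stack.n_medium)
    n2 = complex(stack.n_oxide)
    n3 = _physics_index(stack.n_silicon)
    th = np.deg2rad(theta)
    sin1 = n1 * np.sin(th)
    for n_layer in (n2, n3):
        if abs(n_layer.imag) < 1e-12 and np.any(np.abs(sin1 / n_layer.real) > 1):
            raise ValueError(
                "angle beyond the total-internal-reflection limit for a "
                "lossless layer; the Airy formula is not applicable there")
    c1 = np.cos(th).astype(complex)
    c2 = _cos_theta(n1, th, n2)
    c3 = _cos_theta(n1, th, n3)

    def fresnel(na, ca, nb, cb):
        if polarization == "TE":
            return (na * ca - nb * cb) / (na * ca + nb * cb)
        return (nb * ca - na * cb) / (nb * ca + na * cb)

    r12 = fresnel(n1, c1, n2, c2)
    r23 = fresnel(n2, c2, n3, c3)
    beta = 2.0 * np.pi * n2 * stack.oxide_thickness_nm * c2 / stack.wavelength_nm
    phase = np.exp(2j * beta)
    r = (r12 + r23 * phase) / (1.0 + r12 * r23 * phase)
    return r if r.shape else complex(r)


def excitation_profile(height_nm: float, sweep: AngleSweep, stack: LayerStack,
                       polarization: Polarization = "TE") -> np.ndarray:
    """Unit-amplitude standing-wave excitation intensity per sweep angle.

    F_j = |1 + r(theta_j) exp(i phi_j)|^2 with
    phi_j = 4 pi n_medium h cos(theta_j) / lambda.  Bounded in [0, 4].
    """
    if len(sweep) == 0:
        raise ValueError("empty angle sweep")
    if height_nm < 0:
        raise ValueError("height_nm must be >= 0")
    theta = sweep.as_array()
    r = np.asarray(mirror_reflectance(theta, stack, polarization))
    phi = (4.0 * np.pi * stack.n_medium * height_nm
           * np.cos(np.deg2rad(theta)) / stack.wavelength_nm)
    return np.abs(1.0 + r * np.exp(1j * phi)) ** 2


def _profiles_for_heights(heights_nm: np.ndarray, sweep: AngleSweep,
                          stack: LayerStack,
                          polarization: Polarization = "TE") -> np.ndarray:
    """Vectorised forward profiles, shape (len(heights), len(sweep))."""
    theta = sweep.as_array()
    r = np.asarray(mirror_reflectance(theta, stack, polarization))
    h = np.asarray(heights_nm, dtype=float)[..., None]
    phi = (4.0 * np.pi * stack.n_medium * h
           * np.cos(np.deg2rad(theta)) / stack.wavelength_nm)
    return np.abs(1.0 + r * np.exp(1j * phi)) ** 2


# ---------------------------------------------------------------------------
# inversion
# ---------------------------------------------------------------------------

def _linear_ab(F: np.ndarray, I: np.ndarray):
    """Solve min_{A,B} ||I - A F - B||^2 in closed form (A clipped to >= 0).

    Broadcasts over leading axes; F and I share the last (angle) axis.
    """
    m = F.shape[-1]
    sf = F.sum(axis=-1)
    sff = (F * F).sum(axis=-1)
    si = I.sum(axis=-1)
    sfi = (F * I).sum(axis=-1)
    det = m * sff - sf * sf
    with np.errstate(divide="ignore", invalid="ignore"):
        A = np.where(det > 0, (m * sfi - sf * si) / det, 0.0)
        B = np.where(det > 0, (sff * si - sf * sfi) / det, si / m)
    clipped = A < 0
    A = np.where(clipped, 0.0, A)
    B = np.where(clipped, si / m, B)
    resid = I - A[..., None] * F - B[..., None]
    ss = (resid * resid).sum(axis=-1)
    return A, B, ss, clipped


def _varpro_ss(heights_nm, intensities, sweep, stack, polarization):
    """Profiled sum of squares S(h) with A, B eliminated analytically."""
    F = _profiles_for_heights(np.atleast_1d(heights_nm), sweep, stack,
                              polarization)
    _, _, ss, _ = _linear_ab(F, np.asarray(intensities, dtype=float))
    return ss


def fit_pixel(intensities: Sequence[float], sweep: AngleSweep,
              stack: LayerStack, fit_config: FitConfig | None = None) -> PixelFit:
    """Fit the forward model I_j = A F_j(h) + B to one pixel's angle curve.

    Multi-start search over the restart grid of ``fit_config``: at each
    height the amplitude/offset subproblem is solved linearly (variable
    projection), the profiled objective S(h) is minimised within the restart
    bracket by bounded scalar minimisation, and the winning restart is
    polished by Levenberg-Marquardt-class least squares over (h, A, B).
    Restart ties are broken toward the lowest height.
    """
    cfg = fit_config or FitConfig()
    I = np.asarray(intensities, dtype=float)
    if I.shape != (len(sweep),):
        raise ValueError("intensities length must match the sweep")
    if not np.all(np.isfinite(I)):
        raise ValueError("intensities must be finite")

    if np.ptp(I) == 0.0:
        # constant curve: height unidentifiable
        return PixelFit(height_nm=np.nan, amplitude=0.0, offset=float(I[0]),
                        residual_ss=0.0, converged=False, restart_index=-1)

    starts = np.arange(cfg.h_min_nm, cfg.h_max_nm + 1e-9, cfg.restart_step_nm)
    half = cfg.restart_step_nm

    best = None  # (ss, h, restart_index)
    for idx, h0 in enumerate(starts):
        lo = max(cfg.h_min_nm, h0 - half)
        hi = min(cfg.h_max_nm, h0 + half)
        res = optimize.minimize_scalar(
            lambda h: float(_varpro_ss(h, I, sweep, stack, cfg.polarization)[0]),
            bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-6})
        cand = (float(res.fun), float(res.x), idx)
        if best is None or cand[0] < best[0] - 1e-12 or (
                abs(cand[0] - best[0]) <= 1e-12 and cand[1] < best[1]):
            best = cand
    ss, h, restart_index = best
    F = _profiles_for_heights(np.array([h]), sweep, stack, cfg.polarization)
    A, B, ss_arr, clipped = _linear_ab(F, I)
    A, B, ss = float(A[0]), float(B[0]), float(ss_arr[0])
    converged = not bool(clipped[0])

    if cfg.polish and converged:
        def resid(p):
            Fh = _profiles_for_heights(np.array([p[0]]), sweep, stack,
                                       cfg.polarization)[0]
            return p[1] * Fh + p[2] - I

        sol = optimize.least_squares(
            resid, x0=[h, A, B],
            bounds=([cfg.h_min_nm, 0.0, -np.inf],
                    [cfg.h_max_nm, np.inf, np.inf]),
            xtol=1e-12, ftol=1e-12, gtol=1e-12)
        if sol.cost * 2 <= ss + 1e-12:
            h, A, B = map(float, sol.x)
            ss = float(2 * sol.cost)
            converged = converged and bool(sol.success)

    return PixelFit(height_nm=h, amplitude=A, offset=B, residual_ss=ss,
                    converged=converged, restart_index=restart_index)


def fit_stack(image_stack: np.ndarray, sweep: AngleSweep, stack: LayerStack,
              mask: np.ndarray | None = None,
              fit_config: FitConfig | None = None,
              coarse_step_nm: float = 0.5):
    """Per-pixel height fit of an angle-scan stack (angles x rows x cols).

    Every masked pixel is fit independently with the same profiled objective
    as :func:`fit_pixel`, vectorised: a coarse height grid locates the
    global basin per pixel, then three grid-zoom refinement rounds bring the
    height to < 0.001 nm of the basin minimum.  Unmasked pixels are NaN.

    Returns ``(height_map, fits)`` where ``fits`` is a dict of per-pixel
    arrays (amplitude, offset, residual_ss, converged).
    """
    cfg = fit_config or FitConfig()
    img = np.asarray(image_stack, dtype=float)
    if img.ndim != 3 or img.shape[0] != len(sweep):
        raise ValueError("image_stack must be (n_angles, rows, cols) matching "
                         "the sweep")
    n_ang, nr, nc = img.shape
    if mask is None:
        mask = np.ones((nr, nc), dtype=bool)
    mask = np.asarray(mask).astype(bool)
    if mask.shape != (nr, nc):
        raise ValueError("mask shape must match the image frame")
    if not mask.any():
        raise ValueError("empty ROI mask")

    I = img.reshape(n_ang, -1).T[mask.ravel()]  # (n_pix, n_ang)
    n_pix = I.shape[0]

    # coarse pass: shared height grid, shared forward profiles
    h_grid = np.arange(cfg.h_min_nm, cfg.h_max_nm + coarse_step_nm / 2,
                       coarse_step_nm)
    F = _profiles_for_heights(h_grid, sweep, stack, cfg.polarization)
    ss = np.empty((n_pix, h_grid.size))
    chunk = 256  # keep the (chunk, n_h, n_ang) intermediate small
    for i0 in range(0, n_pix, chunk):
        Ic = I[i0:i0 + chunk][:, None, :]
        _, _, ss_c, _ = _linear_ab(F[None, :, :], Ic)
        ss[i0:i0 + chunk] = ss_c
    h_best = h_grid[np.argmin(ss, axis=1)]

    # grid-zoom refinement: per-pixel local grids, fully vectorised
    step = coarse_step_nm
    for _ in range(4):
        offsets = np.linspace(-step, step, 9)
        H = np.clip(h_best[:, None] + offsets[None, :],
                    cfg.h_min_nm, cfg.h_max_nm)  # (n_pix, 9)
        theta = sweep.as_array()
        r = np.asarray(mirror_reflectance(theta, stack, cfg.polarization))
        phi = (4.0 * np.pi * stack.n_medium * H[..., None]
               * np.cos(np.deg2rad(theta)) / stack.wavelength_nm)
        Floc = np.abs(1.0 + r * np.exp(1j * phi)) ** 2  # (n_pix, 9, n_ang)
        _, _, ss_loc, _ = _linear_ab(Floc, I[:, None, :])
        h_best = np.take_along_axis(
            H, np.argmin(ss_loc, axis=1)[:, None], axis=1)[:, 0]
        step /= 4.0  # new offsets bracket the previous grid spacing

    Ffin = _profiles_for_heights_per_pixel(h_best, sweep, stack,
                                           cfg.polarization)
    A, B, ss_fin, clipped = _linear_ab(Ffin, I)
    flat = np.ptp(I, axis=1) == 0.0
    converged = ~clipped & ~flat

    height_map = np.full((nr, nc), np.nan)
    height_map[mask] = np.where(flat, np.nan, h_best)
    def expand(v, fill=np.nan):
        out = np.full((nr, nc), fill, dtype=float)
        out[mask] = v
        return out
    fits = {
        "amplitude": expand(A),
        "offset": expand(B),
        "residual_ss": expand(ss_fin),
        "converged": expand(converged.astype(float), fill=0.0).astype(bool),
    }
    return height_map, fits


def _profiles_for_heights_per_pixel(h, sweep, stack, polarization):
    theta = sweep.as_array()
    r = np.asarray(mirror_reflectance(theta, stack, polarization))
    phi = (4.0 * np.pi * stack.n_medium * np.asarray(h)[:, None]
           * np.cos(np.deg2rad(theta)) / stack.wavelength_nm)
    return np.abs(1.0 + r * np.exp(1j * phi)) ** 2


# ---------------------------------------------------------------------------
# ROI summary and rendering
# ---------------------------------------------------------------------------

def roi_zcenter(height_map: np.ndarray, mask: np.ndarray,
                roi_id: str = "roi") -> ROIResult:
    """Median fitted height over the finite masked pixels (the z-center).

    The even-count median is the mean of the two central values.  Non-finite
    pixels (failed fits, unmasked) are excluded.
    """
    mask = np.asarray(mask).astype(bool)
    vals = np.asarray(height_map, dtype=float)[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError(f"ROI {roi_id!r} contains no finite fitted pixels")
    return ROIResult(roi_id=roi_id, pixel_heights_nm=vals,
                     z_center_nm=float(np.median(vals)), n_pixels=vals.size)


def topographic_map(height_map: np.ndarray,
                    color_range: tuple[float, float] = (40.0, 140.0),
                    cmap: str = "turbo") -> np.ndarray:
    """Hue-encode a height map over ``color_range`` (nm); returns RGB uint8.

    Heights outside the range clamp to the end colors; NaN renders black.
    The rendering is derived output — the stored float height map remains
    the primary data.
    """
    lo, hi = color_range
    if not lo < hi:
        raise ValueError("color_range min must be < max")
    import matplotlib

    h = np.asarray(height_map, dtype=float)
    norm = np.clip((h - lo) / (hi - lo), 0.0, 1.0)
    rgba = matplotlib.colormaps[cmap](norm)
    rgba[~np.isfinite(h)] = (0.0, 0.0, 0.0, 1.0)
    return (rgba[..., :3] * 255).astype(np.uint8)
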