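"""File I/O for the analysis pipeline: CSV traces, TIFF stacks, TOML config.

Formats are plain and diffable: multi-page TIFF for image stacks (one page
per angle, ascending), 32-bit float TIFF for height maps, CSV for tabular
traces and results, TOML for configuration sidecars, JSON for metadata.
"""

from __future__ import annotations

import json
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .frap import FrapTrace
from .recoil import EdgeTrack
from .migration import VelocityField
from .saim import AngleSweep, LayerStack
from .tweezer import Trace

__all__ = [
    "read_optics_toml", "read_stack_tiff", "read_mask_tiff",
    "write_height_map_tiff", "read_tweezer_csv", "write_events_csv",
    "read_frap_csv", "read_edge_track_csv", "read_velocity_fields_csv",
    "write_json",
]


def read_optics_toml(path) -> tuple[AngleSweep, LayerStack]:
    """Angle sweep and layer stack from a TOML sidecar.

    Keys: angles_deg (list), wavelength_nm, oxide_thickness_nm, and optional
    n_medium / n_oxide / n_silicon_real / n_silicon_imag overrides.
    """
    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    sweep = AngleSweep(tuple(cfg["angles_deg"]))
    wavelength = float(cfg.get("wavelength_nm", 488.0))
    overrides = {}
    for key in ("n_medium", "n_oxide"):
        if key in cfg:
            overrides[key] = float(cfg[key])
    if "n_silicon_real" in cfg:
        overrides["n_silicon"] = complex(cfg["n_silicon_real"],
                                         cfg.get("n_silicon_imag", 0.0))
    stack = LayerStack.for_wavelength(
        wavelength, oxide_thickness_nm=float(cfg.get("oxide_thickness_nm", 500.0)),
        **overrides)
    return sweep, stack


def read_stack_tiff(path) -> np.ndarray:
    arr = tifffile.imread(path)
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a multi-page (angle) stack")
    return arr.astype(float)


def read_mask_tiff(path) -> np.ndarray:
    return tifffile.imread(path) != 0


def write_height_map_tiff(path, height_map: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(height_map, dtype=np.float32))


def read_tweezer_csv(path) -> Trace:
    df = pd.read_csv(path)
    return Trace(time_s=df["time_s"].to_numpy(),
                 force_pN=df["force_pN"].to_numpy(),
                 bead_height_nm=df["height_nm"].to_numpy())


def write_tweezer_csv(path, trace: Trace) -> None:
    pd.DataFrame({"time_s": trace.time_s, "force_pN": trace.force_pN,
                  "height_nm": trace.bead_height_nm}).to_csv(path, index=False)


def write_events_csv(path, events) -> None:
    pd.DataFrame([{
        "time_s": ev.time_s, "force_pN": ev.force_pN,
        "force_err_pN": ev.force_err_pN, "delta_h_nm": ev.delta_h_nm,
        "class": ev.event_class.value if ev.event_class else "",
    } for ev in events]).to_csv(path, index=False)


def read_frap_csv(path, bleach_index: int = 4) -> FrapTrace:
    df = pd.read_csv(path)
    return FrapTrace(time_s=df["time_s"].to_numpy(),
                     i_frap=df["i_frap"].to_numpy(),
                     i_ref=df["i_ref"].to_numpy(),
                     i_back=df["i_back"].to_numpy(),
                     bleach_index=bleach_index)


def write_frap_csv(path, trace: FrapTrace) -> None:
    pd.DataFrame({"time_s": trace.time_s, "i_frap": trace.i_frap,
                  "i_ref": trace.i_ref, "i_back": trace.i_back}
                 ).to_csv(path, index=False)


def read_edge_track_csv(path, ablation_time_s: float | None = None) -> EdgeTrack:
    """Edge track CSV with columns time_s, e1x_um, e1y_um, e2x_um, e2y_um.

    The ablation time may come from an ``# ablation_time_s = X`` header
    comment or the ``ablation_time_s`` argument (argument wins).
    """
    header_time = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "ablation_time_s" in line:
                header_time = float(line.split("=")[1])
    df = pd.read_csv(path, comment="#")
    t_abl = ablation_time_s if ablation_time_s is not None else (
        header_time if header_time is not None else 0.0)
    return EdgeTrack(time_s=df["time_s"].to_numpy(),
                     edge1_xy=df[["e1x_um", "e1y_um"]].to_numpy(),
                     edge2_xy=df[["e2x_um", "e2y_um"]].to_numpy(),
                     ablation_time_s=t_abl)


def write_edge_track_csv(path, track: EdgeTrack) -> None:
    with open(path, "w") as fh:
        fh.write(f"# ablation_time_s = {track.ablation_time_s}\n")
        pd.DataFrame({
            "time_s": track.time_s,
            "e1x_um": track.edge1_xy[:, 0], "e1y_um": track.edge1_xy[:, 1],
            "e2x_um": track.edge2_xy[:, 0], "e2y_um": track.edge2_xy[:, 1],
        }).to_csv(fh, index=False)


def read_velocity_fields_csv(path) -> list[VelocityField]:
    """Long-format velocity CSV: frame, x_um, y_um, u_um_h, v_um_h, valid."""
    df = pd.read_csv(path)
    fields = []
    for frame, grp in df.groupby("frame"):
        fields.append(VelocityField(
            x_um=grp["x_um"].to_numpy(), y_um=grp["y_um"].to_numpy(),
            u_um_h=grp["u_um_h"].to_numpy(), v_um_h=grp["v_um_h"].to_numpy(),
            valid=grp["valid"].to_numpy().astype(bool)
            if "valid" in grp else None))
    return fields


def write_velocity_fields_csv(path, fields: list[VelocityField]) -> None:
    rows = []
    for i, f in enumerate(fields):
        rows.append(pd.DataFrame({
            "frame": i,
            "x_um": np.ravel(f.x_um), "y_um": np.ravel(f.y_um),
            "u_um_h": np.ravel(f.u_um_h), "v_um_h": np.ravel(f.v_um_h),
            "valid": np.ravel(f.valid).astype(int)}))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def write_json(path, obj: dict) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        if isinstance(o, Path):
            return str(o)
        raise TypeError(type(o))

    Path(path).write_text(json.dumps(obj, indent=1, default=default))
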