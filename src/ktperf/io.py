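"""Standard-format I/O: NIfTI image series, HDF5 k-t data, CSV curves and
metrics, JSON contours, YAML configuration."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Sequence

import h5py
import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .core import DynamicSeries, InputError, SICurve
from .ktspace import KtData, SamplingPattern
from .quant import PerfusionMetrics
from .sectors import Contour

__all__ = [
    "save_series",
    "load_series",
    "save_kt",
    "load_kt",
    "save_contours",
    "load_contours",
    "curves_to_frame",
    "save_curves",
    "load_curves",
    "metrics_to_frame",
    "save_metrics",
    "save_yaml",
    "load_yaml",
]


def save_series(series: DynamicSeries, path: str | Path, slice_mm: float = 1.5) -> Path:
    """Write a dynamic series as NIfTI-1 (x, y, z=1, t).

    Frame timing is stored in the time-axis spacing (pixdim[4], seconds).
    """
    path = Path(path)
    arr = np.ascontiguousarray(series.data.transpose(2, 1, 0)[:, :, None, :])
    affine = np.diag([series.pixel_mm, series.pixel_mm, slice_mm, 1.0])
    img = nib.Nifti1Image(arr, affine)
    dt = float(np.diff(series.frame_times_s)[0]) if series.n_frames > 1 else 1.0
    img.header.set_zooms((series.pixel_mm, series.pixel_mm, slice_mm, dt))
    img.header.set_xyzt_units(xyz="mm", t="sec")
    img.header["toffset"] = float(series.frame_times_s[0])
    nib.save(img, str(path))
    return path


def load_series(path: str | Path) -> DynamicSeries:
    """Load a NIfTI-1 dynamic series written by :func:`save_series`."""
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj)
    if arr.ndim != 4:
        raise InputError(f"{path}: expected a 4-D NIfTI (x, y, z, t), got shape {arr.shape}")
    if arr.shape[2] != 1:
        raise InputError(f"{path}: expected a single slice, got {arr.shape[2]}")
    zooms = img.header.get_zooms()
    if len(zooms) < 4 or zooms[3] <= 0:
        raise InputError(f"{path}: time-axis spacing (pixdim[4]) missing or nonpositive")
    dt = float(zooms[3])
    t0 = float(img.header["toffset"])
    data = arr[:, :, 0, :].transpose(2, 1, 0)
    times = t0 + np.arange(data.shape[0]) * dt
    return DynamicSeries(data=data, frame_times_s=times, pixel_mm=float(zooms[0]))


def save_kt(data: KtData, path: str | Path) -> Path:
    """Persist masked k-t data as HDF5 (complex data + boolean mask +
    pattern metadata as attributes)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("kspace", data=data.kspace)
        f.create_dataset("mask", data=data.mask)
        f.create_dataset("frame_times_s", data=data.frame_times_s)
        f.create_dataset("training_lines", data=data.pattern.training_lines)
        f.attrs["R"] = data.pattern.R
        f.attrs["n_train"] = data.pattern.n_train
        f.attrs["pf_fraction"] = data.pattern.pf_fraction
        f.attrs["pixel_mm"] = data.pixel_mm
        f.attrs["noise_sd"] = data.noise_sd
        f.attrs["seed"] = data.seed
    return path


def load_kt(path: str | Path) -> KtData:
    with h5py.File(path, "r") as f:
        mask = f["mask"][()].astype(bool)
        pattern = SamplingPattern(
            mask=mask,
            training_lines=f["training_lines"][()],
            R=int(f.attrs["R"]),
            n_train=int(f.attrs["n_train"]),
            pf_fraction=float(f.attrs["pf_fraction"]),
        )
        return KtData(
            kspace=f["kspace"][()],
            mask=mask,
            pattern=pattern,
            frame_times_s=f["frame_times_s"][()],
            pixel_mm=float(f.attrs["pixel_mm"]),
            noise_sd=float(f.attrs["noise_sd"]),
            seed=int(f.attrs["seed"]),
        )


def save_contours(contours: Sequence[Contour], path: str | Path, extra: dict | None = None) -> Path:
    path = Path(path)
    payload: dict[str, Any] = {
        "contours": [
            {"label": c.label, "points": c.points.tolist()} for c in contours
        ]
    }
    if extra:
        payload.update(extra)
    path.write_text(json.dumps(payload, indent=2))
    return path


def load_contours(path: str | Path) -> tuple[list[Contour], dict]:
    payload = json.loads(Path(path).read_text())
    contours = [Contour(np.array(c["points"]), label=c.get("label", "")) for c in payload["contours"]]
    extra = {k: v for k, v in payload.items() if k != "contours"}
    return contours, extra


def curves_to_frame(curves: Sequence[SICurve]) -> pd.DataFrame:
    """Wide table: frame, t_s, one SI column per ROI."""
    if not curves:
        raise InputError("no curves")
    t = curves[0].t_s
    for c in curves[1:]:
        if not np.allclose(c.t_s, t):
            raise InputError("curves do not share a time grid")
    df = pd.DataFrame({"frame": np.arange(len(t)), "t_s": t})
    for c in curves:
        df[c.roi_label or f"roi_{id(c)}"] = c.si
    return df


def save_curves(curves: Sequence[SICurve], path: str | Path) -> Path:
    path = Path(path)
    curves_to_frame(curves).to_csv(path, index=False)
    return path


def load_curves(path: str | Path) -> list[SICurve]:
    df = pd.read_csv(path)
    t = df["t_s"].to_numpy()
    return [
        SICurve(t_s=t, si=df[col].to_numpy(), roi_label=col)
        for col in df.columns
        if col not in ("frame", "t_s")
    ]


def metrics_to_frame(metrics: Sequence[PerfusionMetrics]) -> pd.DataFrame:
    rows = []
    for m in metrics:
        row = {
            "roi": m.roi_label,
            "n_pixels": m.n_pixels,
            "baseline_si": m.baseline_si,
            "peak_si": m.peak_si,
            "enhancement_ratio": m.enhancement_ratio,
            "max_upslope_per_s": m.max_upslope,
            "normalized_upslope": m.normalized_upslope,
            "mbf_ml_g_min": m.mbf_ml_g_min,
        }
        if m.fermi is not None:
            row.update(
                fermi_F_per_s=m.fermi.F_per_s,
                fermi_k_per_s=m.fermi.k_per_s,
                fermi_tau0_s=m.fermi.tau0_s,
                fermi_rss=m.fermi.rss,
                fermi_converged=m.fermi.converged,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def save_metrics(metrics: Sequence[PerfusionMetrics], path: str | Path) -> Path:
    path = Path(path)
    metrics_to_frame(metrics).to_csv(path, index=False)
    return path


def _to_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def save_yaml(obj: Any, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(_to_plain(obj), sort_keys=False))
    return path


def load_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text()) or {}
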