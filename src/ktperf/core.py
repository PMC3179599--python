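"""Core data containers shared across the pipeline.

The central exchange object is :class:`DynamicSeries`, a real-valued image
stack (frames x rows x cols) with frame times and isotropic in-plane pixel
spacing.  Signal-intensity/time curves for a region of interest are carried
as :class:`SICurve`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KtperfError",
    "ConfigurationError",
    "InputError",
    "GeometryError",
    "QuantificationError",
    "ReconstructionError",
    "DynamicSeries",
    "SICurve",
]


class KtperfError(Exception):
    """Base class for package errors."""


class ConfigurationError(KtperfError, ValueError):
    """A configuration value violates its documented invariants."""


class InputError(KtperfError, ValueError):
    """Runtime inputs (shapes, grids, masks) are inconsistent."""


class GeometryError(KtperfError, ValueError):
    """Contour or mask geometry is invalid (e.g. intersecting contours)."""


class QuantificationError(KtperfError, RuntimeError):
    """A perfusion metric cannot be computed from the given curves."""


class ReconstructionError(KtperfError, RuntimeError):
    """The reconstruction solver failed to produce a usable solution."""


@dataclass
class DynamicSeries:
    """Real-valued dynamic image series.

    Attributes
    ----------
    data
        Array of shape ``(n_frames, n_rows, n_cols)``; arbitrary signal
        units, finite and nonnegative (magnitude images).
    frame_times_s
        Monotonically increasing acquisition time of each frame in seconds.
        For one image per cardiac cycle, frame ``k`` is at
        ``k * 60 / heart_rate_bpm``.
    pixel_mm
        Isotropic in-plane pixel spacing (``fov_mm / grid_size``).
    """

    data: np.ndarray
    frame_times_s: np.ndarray
    pixel_mm: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.frame_times_s = np.asarray(self.frame_times_s, dtype=float)
        if self.data.ndim != 3:
            raise InputError(f"series data must be 3-D (frames, rows, cols), got {self.data.shape}")
        if self.frame_times_s.ndim != 1 or len(self.frame_times_s) != self.data.shape[0]:
            raise InputError(
                "frame_times_s length must equal the number of frames "
                f"({len(self.frame_times_s)} != {self.data.shape[0]})"
            )
        if len(self.frame_times_s) > 1 and not np.all(np.diff(self.frame_times_s) > 0):
            raise InputError("frame_times_s must be strictly increasing")
        if not np.all(np.isfinite(self.data)):
            raise InputError("series data contains non-finite values")
        if self.pixel_mm <= 0:
            raise ConfigurationError("pixel_mm must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class SICurve:
    """Signal-intensity vs frame-time curve for one region of interest."""

    t_s: np.ndarray
    si: np.ndarray
    roi_label: str = ""
    n_pixels: int = 1

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.si = np.asarray(self.si, dtype=float)
        if self.t_s.shape != self.si.shape or self.t_s.ndim != 1:
            raise InputError("t_s and si must be 1-D arrays of equal length")
        if self.n_pixels < 1:
            raise InputError("n_pixels must be >= 1")
        if not np.all(np.isfinite(self.si)):
            raise InputError("si contains non-finite values")

    def __len__(self) -> int:
        return len(self.si)

    @property
    def dt_s(self) -> float:
        """Frame spacing; raises if the grid is non-uniform."""
        d = np.diff(self.t_s)
        if len(d) == 0:
            raise InputError("curve has a single sample; no frame spacing")
        if not np.allclose(d, d[0], rtol=1e-8, atol=1e-12):
            raise InputError("curve is not on a uniform time grid")
        return float(d[0])

    def replace(self, **kw) -> "SICurve":
        out = {"t_s": self.t_s, "si": self.si, "roi_label": self.roi_label, "n_pixels": self.n_pixels}
        out.update(kw)
        return SICurve(**out)
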