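"""Synthetic dynamic mouse-heart perfusion phantom with known ground truth.

The phantom emulates a mid-ventricular short-axis first-pass perfusion scan
of a mouse on a clinical 3-T system: 25 x 25 mm field of view on a 128 x 128
matrix (0.2 mm pixels), one frame per cardiac cycle at ~495 beats/min, and a
saturation-recovery gradient-echo signal with a 100 ms preparation delay.

A gamma-variate arterial input function (AIF) stands in for the manually
injected Gd-DTPA bolus.  Myocardial tissue concentration follows from the
AIF by causal convolution with a Fermi-shaped impulse response whose initial
amplitude encodes myocardial blood flow (MBF):

    h(t) = F / (1 + exp(k (t - tau0))),   MBF = h(0) * 60 / rho,

with tissue density rho = 1.05 g/mL.  Concentration maps to signal through
the saturation-recovery exponential

    SI = s0 * (1 - exp(-TD * (1/T1 + r1 * C))),

which is deliberately nonlinear: at the LV peak the signal is compressed as
on a scanner, so downstream quantification sees a realistic saturation bias.

Geometry: an LV cavity disc, a myocardial annulus split into three sectors
counted counterclockwise from the anterior septal RV insertion, and an RV
crescent whose enhancement leads the LV by one mean transit time.  Noise, if
requested, is complex Gaussian in k-space so magnitude images acquire Rician
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .core import ConfigurationError, DynamicSeries, GeometryError, InputError
from .sectors import SECTOR_LABELS_3, Contour, SectorMasks, sector_partition

__all__ = [
    "AIFParams",
    "HeartGeometry",
    "PhantomConfig",
    "GroundTruth",
    "TISSUE_DENSITY_G_PER_ML",
    "aif_gamma_variate",
    "fermi_impulse_response",
    "fermi_mbf",
    "mbf_to_fermi_amplitude",
    "tissue_concentration",
    "signal_model",
    "render_phantom",
]

#: Myocardial tissue density used for the mL/g/min conversion.
TISSUE_DENSITY_G_PER_ML = 1.05


@dataclass
class AIFParams:
    """Normalized gamma-variate arterial input function.

    The curve is zero before ``onset_s`` and peaks at exactly
    ``amplitude_mM`` a time ``shape_alpha * shape_beta_s`` after onset.
    """

    onset_s: float = 0.606
    amplitude_mM: float = 1.13
    shape_alpha: float = 4.0
    shape_beta_s: float = 0.3

    def __post_init__(self) -> None:
        if self.amplitude_mM <= 0:
            raise ConfigurationError("AIF amplitude_mM must be > 0")
        if self.shape_alpha <= 0 or self.shape_beta_s <= 0:
            raise ConfigurationError("AIF shape parameters must be > 0")
        if self.onset_s < 0:
            raise ConfigurationError("AIF onset_s must be >= 0")


@dataclass
class HeartGeometry:
    """Short-axis heart geometry in millimetres (center of the grid)."""

    endo_radius_mm: float = 1.7
    epi_radius_mm: float = 2.9
    lv_roi_radius_mm: float = 1.0
    rv_insertion_angle_deg: float = 90.0
    rv_thickness_mm: float = 0.7
    rv_halfwidth_deg: float = 55.0
    rv_lead_s: float = 0.30
    n_contour_points: int = 72

    def __post_init__(self) -> None:
        if min(self.endo_radius_mm, self.epi_radius_mm, self.lv_roi_radius_mm) <= 0:
            raise ConfigurationError("all radii must be positive")
        if self.endo_radius_mm >= self.epi_radius_mm:
            raise ConfigurationError("endocardial radius must be smaller than epicardial radius")
        if self.lv_roi_radius_mm >= self.endo_radius_mm:
            raise ConfigurationError("LV blood-pool ROI must lie inside the cavity")


def _default_t1() -> dict[str, float]:
    # pre-contrast T1 at 3 T, seconds
    return {"blood": 1.9, "myocardium": 1.6, "background": 0.9}


@dataclass
class PhantomConfig:
    """Configuration of the dynamic phantom; defaults follow the in-vivo
    acquisition the phantom emulates (see module docstring)."""

    grid_size: int = 128
    fov_mm: float = 25.0
    heart_rate_bpm: float = 495.1
    n_frames: int = 60
    prep_delay_s: float = 0.100
    t1_pre_s: Mapping[str, float] = field(default_factory=_default_t1)
    relaxivity_per_mM_s: float = 3.7
    signal_scale: float = 1000.0
    aif: AIFParams = field(default_factory=AIFParams)
    sector_mbf_ml_g_min: tuple[float, float, float] = (7.3, 7.3, 7.3)
    fermi_k_per_s: float = 2.0
    fermi_tau0_s: float = 2.5
    geometry: HeartGeometry = field(default_factory=HeartGeometry)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_size <= 0:
            raise ConfigurationError("grid_size must be > 0")
        if self.n_frames < 10:
            raise ConfigurationError("n_frames must be >= 10")
        if self.heart_rate_bpm <= 0:
            raise ConfigurationError("heart_rate_bpm must be > 0")
        if self.prep_delay_s <= 0:
            raise ConfigurationError("prep_delay_s must be > 0")
        if any(v <= 0 for v in self.t1_pre_s.values()):
            raise ConfigurationError("all pre-contrast T1 values must be > 0")
        if self.relaxivity_per_mM_s <= 0:
            raise ConfigurationError("relaxivity must be > 0")
        if len(self.sector_mbf_ml_g_min) != 3:
            raise ConfigurationError("sector_mbf_ml_g_min needs exactly 3 values")
        if any(v < 0 for v in self.sector_mbf_ml_g_min):
            raise ConfigurationError("MBF values must be >= 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")

    @classmethod
    def control(cls, **kw) -> "PhantomConfig":
        """Healthy-control phantom: uniform MBF 7.3 mL/g/min in all sectors."""
        return cls(**kw)

    @classmethod
    def infarct(cls, **kw) -> "PhantomConfig":
        """Infarct phantom: anterolateral MBF reduced to 1.2 mL/g/min."""
        kw.setdefault("sector_mbf_ml_g_min", (7.3, 1.2, 7.3))
        return cls(**kw)

    @property
    def dt_s(self) -> float:
        return 60.0 / self.heart_rate_bpm

    @property
    def pixel_mm(self) -> float:
        return self.fov_mm / self.grid_size

    @property
    def frame_times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt_s


@dataclass
class GroundTruth:
    """Known truth behind a rendered phantom."""

    mbf_map: np.ndarray
    concentration_series: np.ndarray
    epi_contour: Contour
    endo_contour: Contour
    rv_insertion_angle_deg: float
    lv_roi_mask: np.ndarray
    sector_masks: SectorMasks
    sector_fermi: dict[str, tuple[float, float, float]]
    aif_mM: np.ndarray
    sector_mbf: dict[str, float]


def aif_gamma_variate(t_s: np.ndarray | float, p: AIFParams) -> np.ndarray:
    """Gamma-variate bolus concentration in mM at times ``t_s`` (seconds).

    Normalized so the curve peaks at exactly ``p.amplitude_mM`` at
    ``onset_s + shape_alpha * shape_beta_s``; zero at and before onset.
    """
    if p.shape_alpha <= 0 or p.shape_beta_s <= 0:
        raise ConfigurationError("AIF shape parameters must be > 0")
    t = np.asarray(t_s, dtype=float)
    t_peak = p.shape_alpha * p.shape_beta_s
    u = (t - p.onset_s) / t_peak
    up = np.maximum(u, 0.0)
    val = p.amplitude_mM * up**p.shape_alpha * np.exp(p.shape_alpha * (1.0 - up))
    return np.where(u > 0, val, 0.0)


def fermi_impulse_response(
    t_s: np.ndarray, F_per_s: float, k_per_s: float, tau0_s: float
) -> np.ndarray:
    """Fermi-shaped tissue impulse response h(t) = F / (1 + exp(k (t - tau0))).

    Non-increasing in t; h(0) = F / (1 + exp(-k tau0)) determines MBF.
    """
    if F_per_s < 0:
        raise ConfigurationError("F_per_s must be >= 0")
    if k_per_s <= 0:
        raise ConfigurationError("k_per_s must be > 0")
    if tau0_s < 0:
        raise ConfigurationError("tau0_s must be >= 0")
    t = np.asarray(t_s, dtype=float)
    x = np.clip(k_per_s * (t - tau0_s), -700, 700)
    return F_per_s / (1.0 + np.exp(x))


def fermi_mbf(F_per_s: float, k_per_s: float, tau0_s: float) -> float:
    """MBF in mL/g/min implied by Fermi parameters: h(0) * 60 / rho."""
    h0 = F_per_s / (1.0 + np.exp(-k_per_s * tau0_s))
    return float(h0 * 60.0 / TISSUE_DENSITY_G_PER_ML)


def mbf_to_fermi_amplitude(mbf_ml_g_min: float, k_per_s: float, tau0_s: float) -> float:
    """Invert :func:`fermi_mbf` for the amplitude F at fixed shape (k, tau0)."""
    h0 = mbf_ml_g_min * TISSUE_DENSITY_G_PER_ML / 60.0
    return float(h0 * (1.0 + np.exp(-k_per_s * tau0_s)))


def tissue_concentration(aif: np.ndarray, h: np.ndarray, dt_s: float) -> np.ndarray:
    """Causal discrete convolution of the AIF with an impulse response.

    ``c_t[n] = dt * sum_m aif[m] h[n - m]``, truncated to the input length.
    """
    aif = np.asarray(aif, dtype=float)
    h = np.asarray(h, dtype=float)
    if aif.shape != h.shape or aif.ndim != 1:
        raise InputError("aif and h must be 1-D arrays of equal length")
    if dt_s <= 0:
        raise InputError("dt_s must be > 0")
    return dt_s * np.convolve(aif, h)[: len(aif)]


def signal_model(
    c_mM: np.ndarray | float,
    t1_pre_s: float | np.ndarray,
    relaxivity_per_mM_s: float,
    prep_delay_s: float,
    s0: float,
) -> np.ndarray:
    """Saturation-recovery gradient-echo signal at preparation delay TD.

    ``SI = s0 * (1 - exp(-TD * (1/T1 + r1 * C)))``; strictly increasing in
    concentration and bounded above by ``s0``.  Readout-train relaxation and
    flip-angle history are neglected.
    """
    if np.any(np.asarray(t1_pre_s) <= 0) or relaxivity_per_mM_s <= 0 or prep_delay_s <= 0 or s0 <= 0:
        raise ConfigurationError("all physical parameters must be > 0")
    c = np.asarray(c_mM, dtype=float)
    if np.any(c < 0):
        raise InputError("concentration must be >= 0")
    r1 = 1.0 / np.asarray(t1_pre_s, dtype=float) + relaxivity_per_mM_s * c
    return s0 * (1.0 - np.exp(-prep_delay_s * r1))


def _circle_contour(center_px: np.ndarray, radius_px: float, n: int, label: str) -> Contour:
    th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    pts = np.column_stack([center_px[0] + radius_px * np.cos(th), center_px[1] + radius_px * np.sin(th)])
    return Contour(pts, label=label)


def render_phantom(cfg: PhantomConfig) -> tuple[DynamicSeries, GroundTruth]:
    """Render the dynamic series and its ground truth.

    Deterministic per seed; with ``noise_sd == 0`` the output is exactly the
    noiseless composite signal (bit-identical across runs).
    """
    g = cfg.geometry
    n = cfg.grid_size
    pix = cfg.pixel_mm
    if g.epi_radius_mm + g.rv_thickness_mm >= cfg.fov_mm / 2.0:
        raise GeometryError("heart geometry exceeds the field of view")

    center = np.array([(n - 1) / 2.0, (n - 1) / 2.0])  # (x, y) pixel-centered
    epi = _circle_contour(center, g.epi_radius_mm / pix, g.n_contour_points, "epicardial")
    endo = _circle_contour(center, g.endo_radius_mm / pix, g.n_contour_points, "endocardial")
    lv_roi_contour = _circle_contour(center, g.lv_roi_radius_mm / pix, g.n_contour_points, "lv_roi")

    shape = (n, n)
    sectors = sector_partition(epi, endo, g.rv_insertion_angle_deg, n_sectors=3, shape=shape)
    endo_mask = endo.to_mask(shape)
    lv_roi_mask = lv_roi_contour.to_mask(shape)

    cols, rows = np.meshgrid(np.arange(n), np.arange(n))
    r_mm = np.hypot(cols - center[0], rows - center[1]) * pix
    theta = np.degrees(np.arctan2(rows - center[1], cols - center[0]))
    # RV crescent hugs the septal wall, centered mid-septum
    rv_center = g.rv_insertion_angle_deg + 60.0
    dang = np.abs((theta - rv_center + 180.0) % 360.0 - 180.0)
    rv_mask = (
        (r_mm > g.epi_radius_mm)
        & (r_mm <= g.epi_radius_mm + g.rv_thickness_mm)
        & (dang <= g.rv_halfwidth_deg)
    )

    t = cfg.frame_times_s
    aif_c = aif_gamma_variate(t, cfg.aif)
    rv_c = aif_gamma_variate(t + g.rv_lead_s, cfg.aif)

    sector_fermi: dict[str, tuple[float, float, float]] = {}
    sector_conc: dict[str, np.ndarray] = {}
    sector_mbf: dict[str, float] = {}
    h_grid = np.arange(cfg.n_frames) * cfg.dt_s
    for label, mbf in zip(SECTOR_LABELS_3, cfg.sector_mbf_ml_g_min):
        F = mbf_to_fermi_amplitude(mbf, cfg.fermi_k_per_s, cfg.fermi_tau0_s)
        h = fermi_impulse_response(h_grid, F, cfg.fermi_k_per_s, cfg.fermi_tau0_s)
        sector_fermi[label] = (F, cfg.fermi_k_per_s, cfg.fermi_tau0_s)
        sector_conc[label] = tissue_concentration(aif_c, h, cfg.dt_s)
        sector_mbf[label] = float(mbf)

    conc = np.zeros((cfg.n_frames, n, n))
    conc[:, endo_mask] = aif_c[:, None]
    conc[:, rv_mask] = rv_c[:, None]
    t1_map = np.full(shape, cfg.t1_pre_s["background"])
    t1_map[endo_mask | rv_mask] = cfg.t1_pre_s["blood"]
    mbf_map = np.zeros(shape)
    for label in SECTOR_LABELS_3:
        m = sectors[label]
        conc[:, m] = sector_conc[label][:, None]
        t1_map[m] = cfg.t1_pre_s["myocardium"]
        mbf_map[m] = sector_mbf[label]

    si = signal_model(conc, t1_map[None], cfg.relaxivity_per_mM_s, cfg.prep_delay_s, cfg.signal_scale)

    if cfg.noise_sd > 0:
        from .ktspace import cfft2, cifft2  # local import to avoid cycles

        rng = np.random.default_rng(cfg.seed)
        k = cfft2(si.astype(complex))
        k += cfg.noise_sd * (rng.standard_normal(k.shape) + 1j * rng.standard_normal(k.shape))
        si = np.abs(cifft2(k))

    series = DynamicSeries(data=si, frame_times_s=t, pixel_mm=pix)
    gt = GroundTruth(
        mbf_map=mbf_map,
        concentration_series=conc,
        epi_contour=epi,
        endo_contour=endo,
        rv_insertion_angle_deg=g.rv_insertion_angle_deg,
        lv_roi_mask=lv_roi_mask,
        sector_masks=sectors,
        sector_fermi=sector_fermi,
        aif_mM=aif_c,
        sector_mbf=sector_mbf,
    )
    return series, gt
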