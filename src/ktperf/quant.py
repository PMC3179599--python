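"""Semiquantitative and Fermi-deconvolution perfusion quantification.

Works on signal-intensity/time curves (LV blood pool = arterial input,
myocardial sectors = tissue).  The processing chain mirrors standard
first-pass analysis: baseline correction, cropping to the first pass,
enhancement ratio, five-point maximal upslope, upslope normalized by the LV,
and absolute MBF by Fermi-constrained deconvolution,

    tissue(t) = dt * (lv (*) h)(t),    h(t) = F / (1 + exp(k (t - tau0))),

fitted by bounded nonlinear least squares with three deterministic starts;
MBF = h(0) * 60 / rho with rho = 1.05 g/mL.  Signal is treated as
proportional to concentration (no T1-saturation correction), as in direct
SI-based deconvolution practice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .core import InputError, QuantificationError, SICurve
from .phantom import TISSUE_DENSITY_G_PER_ML, fermi_impulse_response, fermi_mbf

__all__ = [
    "FermiFitResult",
    "PerfusionMetrics",
    "baseline_correct",
    "detect_arrival",
    "crop_first_pass",
    "first_pass_cut_index",
    "enhancement_ratio",
    "max_upslope",
    "normalized_upslope",
    "fermi_deconvolve",
    "quantify_rois",
]


@dataclass
class FermiFitResult:
    """Fitted Fermi impulse-response parameters and the implied MBF."""

    F_per_s: float
    k_per_s: float
    tau0_s: float
    mbf_ml_g_min: float
    rss: float
    converged: bool
    n_iter: int

    def __post_init__(self) -> None:
        if self.converged and self.mbf_ml_g_min < 0:
            raise QuantificationError("converged fit produced negative MBF")
        if self.rss < 0:
            raise QuantificationError("negative residual sum of squares")


@dataclass
class PerfusionMetrics:
    """Per-ROI perfusion readouts."""

    roi_label: str
    baseline_si: float
    peak_si: float
    enhancement_ratio: float
    max_upslope: float
    normalized_upslope: float | None = None
    mbf_ml_g_min: float | None = None
    fermi: FermiFitResult | None = None
    n_pixels: int = 1


def detect_arrival(curve: SICurve, threshold_sd: float = 5.0) -> int:
    """First frame where the curve exceeds baseline mean + ``threshold_sd`` SD.

    The provisional baseline is the first three frames; a tiny relative
    floor on the SD keeps the rule meaningful for noiseless curves.
    """
    si = curve.si
    if len(si) < 4:
        raise InputError("curve too short for arrival detection")
    m = si[:3].mean()
    s = si[:3].std()
    s = max(s, 1e-9 * (abs(m) + 1.0))
    above = np.nonzero(si > m + threshold_sd * s)[0]
    if len(above) == 0:
        raise QuantificationError("no contrast arrival detected")
    return int(above[0])


def baseline_correct(
    curve: SICurve,
    n_baseline: int | str = "auto",
    lv: SICurve | None = None,
    threshold_sd: float = 5.0,
) -> tuple[SICurve, float]:
    """Subtract the pre-arrival baseline from a curve.

    ``n_baseline="auto"`` detects the bolus arrival on the LV curve (or on
    the curve itself when no LV curve is given) as the first frame exceeding
    the baseline mean + ``threshold_sd`` standard deviations; the baseline is
    the mean of the frames before arrival.  An arrival earlier than frame 3
    leaves too few baseline frames and raises ``QuantificationError``.
    """
    if n_baseline == "auto":
        ref = lv if lv is not None else curve
        arrival = detect_arrival(ref, threshold_sd)
        if arrival < 3:
            raise QuantificationError(
                f"contrast arrival at frame {arrival}: fewer than 3 baseline frames"
            )
        nb = arrival
    else:
        nb = int(n_baseline)
        if nb < 1:
            raise InputError("n_baseline must be >= 1")
    if len(curve) < nb + 5:
        raise InputError(f"curve needs >= {nb + 5} frames for {nb} baseline frames")
    baseline = float(curve.si[:nb].mean())
    return curve.replace(si=curve.si - baseline), baseline


def first_pass_cut_index(lv: SICurve, fallback_fraction: float = 0.3) -> int:
    """Last frame of the first pass on the (baseline-corrected) LV curve.

    First local minimum after the global peak; if the curve decays
    monotonically (no recirculation trough), the first frame falling below
    ``fallback_fraction`` of the peak.
    """
    si = lv.si
    peak = int(np.argmax(si))
    if peak == len(si) - 1 or peak == 0:
        raise QuantificationError("LV curve has no interior peak; cannot crop first pass")
    for i in range(peak + 1, len(si) - 1):
        if si[i] < si[i - 1] and si[i] <= si[i + 1]:
            return i
    below = np.nonzero(si[peak + 1 :] < fallback_fraction * si[peak])[0]
    if len(below) > 0:
        return peak + 1 + int(below[0])
    return len(si) - 1


def crop_first_pass(curve: SICurve, lv_curve: SICurve) -> SICurve:
    """Truncate ``curve`` at the end of the LV first pass (inclusive).

    The cut index is computed on the LV curve only, so calling this for the
    LV and every tissue curve applies the identical cut.
    """
    if len(curve) != len(lv_curve) or not np.allclose(curve.t_s, lv_curve.t_s):
        raise InputError("curve and LV curve must share the time grid")
    cut = first_pass_cut_index(lv_curve)
    return curve.replace(t_s=curve.t_s[: cut + 1], si=curve.si[: cut + 1])


def enhancement_ratio(
    curve: SICurve,
    n_baseline: int | str = "auto",
    lv: SICurve | None = None,
) -> float:
    """(SI max - SI baseline) / SI baseline on the uncorrected curve."""
    _, baseline = baseline_correct(curve, n_baseline=n_baseline, lv=lv)
    if baseline <= 0:
        raise QuantificationError(f"nonpositive baseline {baseline}")
    return float((curve.si.max() - baseline) / baseline)


def max_upslope(curve: SICurve, window: int = 5) -> tuple[float, int]:
    """Maximal ordinary-least-squares slope over all contiguous windows.

    Returns (slope in SI units per second, start index of the best window).
    """
    if window < 2:
        raise InputError("window must be >= 2")
    n = len(curve)
    if n < window:
        raise InputError(f"curve has {n} points, needs >= {window}")
    t = curve.t_s
    y = curve.si
    n_win = n - window + 1
    idx = np.arange(window)[None, :] + np.arange(n_win)[:, None]
    tw = t[idx]
    yw = y[idx]
    tc = tw - tw.mean(axis=1, keepdims=True)
    yc = yw - yw.mean(axis=1, keepdims=True)
    slopes = (tc * yc).sum(axis=1) / (tc**2).sum(axis=1)
    best = int(np.argmax(slopes))
    return float(slopes[best]), best


def normalized_upslope(myo: SICurve, lv: SICurve, window: int = 5) -> float:
    """Maximal myocardial upslope divided by the maximal LV upslope.

    Curves are expected baseline-corrected and cropped to the first pass.
    Note: this is the plain dimensionless ratio (identical curves give 1);
    published perfusion indices often quote it on a percent scale.
    """
    lv_slope, _ = max_upslope(lv, window)
    if lv_slope <= 0:
        raise QuantificationError(f"LV upslope {lv_slope} is not positive")
    myo_slope, _ = max_upslope(myo, window)
    return float(myo_slope / lv_slope)


_MULTISTART_MBF = (1.0, 4.0, 8.0)  # slow / medium / fast flow starts


def fermi_deconvolve(
    lv: SICurve,
    tissue: SICurve,
    init: FermiFitResult | None = None,
    max_iter: int = 500,
    gtol: float = 1e-10,
) -> FermiFitResult:
    """Fit a Fermi impulse response linking the LV and tissue curves.

    Minimizes ``|| tissue - dt * (lv (*) h(F, k, tau0)) ||^2`` subject to
    F >= 0, k > 0, tau0 >= 0 by bounded trust-region least squares over
    three deterministic multi-starts (slow/medium/fast flow); ties are
    broken by lowest residual then lowest F.  Curves must be
    baseline-corrected, cropped to the first pass, and on a uniform grid.
    """
    if len(lv) != len(tissue) or not np.allclose(lv.t_s, tissue.t_s):
        raise InputError("LV and tissue curves must share the time grid")
    dt = lv.dt_s  # raises InputError on non-uniform grids
    n = len(lv)
    t_rel = np.arange(n) * dt
    t_end = t_rel[-1]
    aif = lv.si

    def model(theta: np.ndarray) -> np.ndarray:
        h = fermi_impulse_response(t_rel, theta[0], theta[1], theta[2])
        return dt * np.convolve(aif, h)[:n]

    def resid(theta: np.ndarray) -> np.ndarray:
        return model(theta) - tissue.si

    scale = np.abs(tissue.si).max()
    aif_area = float(np.trapezoid(np.abs(aif), dx=dt))
    f_guess = scale / aif_area if aif_area > 0 else 0.1

    starts: list[np.ndarray] = []
    if init is not None:
        starts.append(np.array([init.F_per_s, max(init.k_per_s, 1e-6), init.tau0_s]))
    for mbf in _MULTISTART_MBF:
        F0 = mbf * TISSUE_DENSITY_G_PER_ML / 60.0 * 2.0  # h(0)=F/2 at k*tau0=0 scale
        starts.append(np.array([max(F0, 0.1 * f_guess), 2.0, min(1.0, t_end / 2)]))

    lower = np.array([0.0, 1e-6, 0.0])
    upper = np.array([np.inf, np.inf, t_end])
    best = None
    for x0 in starts:
        x0 = np.clip(x0, lower, upper)
        res = least_squares(
            resid, x0, bounds=(lower, upper), method="trf", gtol=gtol,
            xtol=1e-12, ftol=1e-12, max_nfev=max_iter,
        )
        rss = float(np.sum(res.fun**2))
        key = (rss, res.x[0])
        if best is None or key < best[0]:
            best = (key, res)
    _, res = best
    F, k, tau0 = res.x
    return FermiFitResult(
        F_per_s=float(F),
        k_per_s=float(k),
        tau0_s=float(tau0),
        mbf_ml_g_min=fermi_mbf(F, k, tau0),
        rss=float(np.sum(res.fun**2)),
        converged=bool(res.status > 0),
        n_iter=int(res.nfev),
    )


def quantify_rois(
    lv_curve: SICurve,
    tissue_curves: list[SICurve],
    n_baseline: int | str = "auto",
    window: int = 5,
    threshold_sd: float = 5.0,
) -> list[PerfusionMetrics]:
    """Full semiquantitative + deconvolution analysis of one curve set.

    The LV curve defines the contrast arrival (baseline) and the first-pass
    cut applied to every curve.  Returns one :class:`PerfusionMetrics` per
    ROI; the LV row carries no normalized upslope or MBF.
    """
    lv_corr, lv_base = baseline_correct(lv_curve, n_baseline, lv=lv_curve, threshold_sd=threshold_sd)
    lv_crop = crop_first_pass(lv_corr, lv_corr)
    lv_slope, _ = max_upslope(lv_crop, window)

    out = [
        PerfusionMetrics(
            roi_label=lv_curve.roi_label or "lv_blood_pool",
            baseline_si=lv_base,
            peak_si=float(lv_curve.si.max()),
            enhancement_ratio=enhancement_ratio(lv_curve, n_baseline, lv=lv_curve),
            max_upslope=lv_slope,
            n_pixels=lv_curve.n_pixels,
        )
    ]
    for cur in tissue_curves:
        corr, base = baseline_correct(cur, n_baseline, lv=lv_curve, threshold_sd=threshold_sd)
        crop = crop_first_pass(corr, lv_corr)
        slope, _ = max_upslope(crop, window)
        fit = fermi_deconvolve(lv_crop, crop)
        out.append(
            PerfusionMetrics(
                roi_label=cur.roi_label,
                baseline_si=base,
                peak_si=float(cur.si.max()),
                enhancement_ratio=enhancement_ratio(cur, n_baseline, lv=lv_curve),
                max_upslope=slope,
                normalized_upslope=float(slope / lv_slope),
                mbf_ml_g_min=fit.mbf_ml_g_min,
                fermi=fit,
                n_pixels=cur.n_pixels,
            )
        )
    return out
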