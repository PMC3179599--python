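"""End-to-end pipeline: simulate -> encode -> reconstruct -> curves -> quantify.

Every stochastic component receives a child seed spawned deterministically
from the single global seed, so a run is reproducible bit-for-bit; the
manifest records per-stage checksums of the numeric outputs (computed over
the in-memory arrays, independent of container-format timestamps).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .core import DynamicSeries, KtperfError, SICurve
from .io import (
    metrics_to_frame,
    curves_to_frame,
    save_contours,
    save_curves,
    save_kt,
    save_metrics,
    save_series,
    save_yaml,
)
from .ktpca import PCBasis, ReconConfig, build_basis, nrmse, recon_reference, unfold
from .ktspace import KtData, encode, extract_training, make_pattern
from .phantom import GroundTruth, PhantomConfig, render_phantom
from .quant import PerfusionMetrics, quantify_rois
from .sectors import extract_curve, sector_partition

__all__ = ["PatternConfig", "QuantConfig", "RunConfig", "RunResult", "run_pipeline"]

log = logging.getLogger("ktperf")


@dataclass
class PatternConfig:
    """Acquisition settings for the k-t sampling stage."""

    R: int = 10
    n_train: int = 3
    pf_fraction: float = 1.0
    noise_sd: float = 5.0


@dataclass
class QuantConfig:
    """Quantification settings."""

    window: int = 5
    n_baseline: int | str = "auto"
    threshold_sd: float = 5.0


@dataclass
class RunConfig:
    """Full pipeline configuration; every field has a default."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    pattern: PatternConfig = field(default_factory=PatternConfig)
    recon: ReconConfig = field(default_factory=ReconConfig)
    quant: QuantConfig = field(default_factory=QuantConfig)
    output_dir: str = "ktperf_run"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        from .phantom import AIFParams, HeartGeometry

        d = dict(d)
        if "phantom" in d:
            p = dict(d["phantom"])
            if "aif" in p:
                p["aif"] = AIFParams(**p["aif"])
            if "geometry" in p:
                p["geometry"] = HeartGeometry(**p["geometry"])
            if "sector_mbf_ml_g_min" in p:
                p["sector_mbf_ml_g_min"] = tuple(p["sector_mbf_ml_g_min"])
            d["phantom"] = PhantomConfig(**p)
        if "pattern" in d:
            d["pattern"] = PatternConfig(**d["pattern"])
        if "recon" in d:
            d["recon"] = ReconConfig(**d["recon"])
        if "quant" in d:
            d["quant"] = QuantConfig(**d["quant"])
        return cls(**d)


@dataclass
class RunResult:
    """In-memory results of a pipeline run."""

    config: RunConfig
    series: DynamicSeries
    ground_truth: GroundTruth
    recon: DynamicSeries
    curves: list[SICurve]
    metrics: list[PerfusionMetrics]
    basis: PCBasis
    nrmse_vs_reference: float
    manifest: dict
    output_dir: Path | None


def _sha(arr: np.ndarray | bytes) -> str:
    if isinstance(arr, np.ndarray):
        arr = np.ascontiguousarray(arr).tobytes()
    return hashlib.sha256(arr).hexdigest()


class PipelineError(KtperfError):
    def __init__(self, stage: str, err: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {err}")


def run_pipeline(cfg: RunConfig, write: bool = True) -> RunResult:
    """Execute the full simulated acquisition and analysis.

    With ``write=True`` the run directory receives the phantom and
    reconstructed series (NIfTI), ground-truth contours (JSON), k-t data
    (HDF5), curves and metrics (CSV), the configuration (YAML) and a
    manifest with per-stage checksums (JSON).
    """
    logging.basicConfig(
        level=getattr(logging, cfg.log_level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
    out = Path(cfg.output_dir) if write else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        save_yaml(cfg, out / "config.yaml")

    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(cfg.seed).spawn(2)]
    checks: dict[str, str] = {}

    stage = "simulate"
    try:
        pcfg = dataclasses.replace(cfg.phantom, seed=seeds[0])
        series, gt = render_phantom(pcfg)
        checks["phantom"] = _sha(series.data)
        log.info("simulate: %dx%d, %d frames, dt=%.1f ms", *series.shape[1:], series.n_frames, 1e3 * pcfg.dt_s)
        if out is not None:
            save_series(series, out / "phantom.nii.gz")
            save_contours(
                [gt.epi_contour, gt.endo_contour],
                out / "contours.json",
                extra={
                    "rv_insertion_angle_deg": gt.rv_insertion_angle_deg,
                    "sector_mbf_ml_g_min": gt.sector_mbf,
                },
            )

        stage = "encode"
        pattern = make_pattern(
            series.data.shape[1], series.n_frames, cfg.pattern.R, cfg.pattern.n_train, cfg.pattern.pf_fraction
        )
        kt = encode(series, pattern, noise_sd=cfg.pattern.noise_sd, seed=seeds[1])
        checks["kt"] = _sha(kt.kspace)
        log.info(
            "encode: R=%d, %d training lines, net acceleration %.2f, noise_sd=%.2f",
            pattern.R, pattern.n_train, pattern.net_acceleration, cfg.pattern.noise_sd,
        )
        if out is not None:
            save_kt(kt, out / "ktdata.h5")

        stage = "recon"
        training = extract_training(kt, pattern)
        basis = build_basis(training, cfg.recon.n_pc)
        recon = unfold(kt, pattern, basis, cfg.recon)
        checks["recon"] = _sha(recon.data)
        full = encode(series, make_pattern(series.data.shape[1], series.n_frames, 1, 0), noise_sd=0.0)
        err = nrmse(recon, recon_reference(full))
        log.info("recon: n_pc=%d, NRMSE vs fully sampled reference %.4f", cfg.recon.n_pc, err)
        if out is not None:
            save_series(recon, out / "recon.nii.gz")

        stage = "curves"
        sectors = sector_partition(
            gt.epi_contour, gt.endo_contour, gt.rv_insertion_angle_deg, shape=recon.data.shape[1:]
        )
        lv_curve = extract_curve(recon, gt.lv_roi_mask, "lv_blood_pool")
        tissue = [extract_curve(recon, sectors[lab], lab) for lab in sectors.labels]
        curves = [lv_curve] + tissue
        checks["curves"] = _sha(curves_to_frame(curves).to_csv(index=False).encode())
        if out is not None:
            save_curves(curves, out / "curves.csv")

        stage = "quantify"
        metrics = quantify_rois(
            lv_curve, tissue,
            n_baseline=cfg.quant.n_baseline, window=cfg.quant.window, threshold_sd=cfg.quant.threshold_sd,
        )
        checks["metrics"] = _sha(metrics_to_frame(metrics).to_csv(index=False).encode())
        if out is not None:
            save_metrics(metrics, out / "metrics.csv")
        for m in metrics:
            log.info(
                "quantify: %-15s ER=%.2f upslope=%.1f/s MBF=%s",
                m.roi_label, m.enhancement_ratio, m.max_upslope,
                "-" if m.mbf_ml_g_min is None else f"{m.mbf_ml_g_min:.2f}",
            )
    except Exception as e:
        raise PipelineError(stage, e) from e

    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "stage_seeds": seeds,
        "config_sha256": _sha(json.dumps(_cfg_dict(cfg), sort_keys=True).encode()),
        "checksums": checks,
        "nrmse_vs_reference": err,
    }
    if out is not None:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return RunResult(
        config=cfg, series=series, ground_truth=gt, recon=recon, curves=curves,
        metrics=metrics, basis=basis, nrmse_vs_reference=err, manifest=manifest, output_dir=out,
    )


def _cfg_dict(cfg: RunConfig) -> dict:
    from .io import _to_plain

    return _to_plain(cfg)
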