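"""Stage composition: enhance -> detect -> refine -> evaluate, plus sweeps."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .phantom import GroundTruth
from .refine import refine_seeds
from .ridge_detect import REFINED, SeedSet, find_candidate_seeds
from .vesselness import (
    VesselnessImage,
    VesselnessParams,
    eigenfields_per_scale,
    multiscale_vesselness,
)

__all__ = ["PipelineConfig", "DetectionResult", "run_detect", "run_sweep"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    vesselness: VesselnessParams = field(default_factory=VesselnessParams)
    sigma_r: float = 1.0  # smoothing/derivative scale on the vesselness image
    omega: float = 3.0  # refinement sensitivity weight
    refine_source: str = "vesselness"  # or "raw"
    tau: float = 30.0  # NDSP response threshold

    def __post_init__(self) -> None:
        if self.refine_source not in ("vesselness", "raw"):
            raise ValueError(f"unknown refine source {self.refine_source!r}")
        if self.omega < 0:
            raise ValueError("omega must be >= 0")


@dataclass
class DetectionResult:
    vesselness: VesselnessImage
    seeds: SeedSet  # with refined/rejected statuses (candidate if none survive)
    threshold: float  # the adaptive refinement threshold T, nan if unused
    report: _metrics.DetectionReport | None


def run_detect(
    image: np.ndarray,
    config: PipelineConfig | None = None,
    truth: GroundTruth | None = None,
) -> DetectionResult:
    """Run the full seed-detection pipeline on a grayscale image.

    Stages: multiscale vesselness enhancement, ridge-cell candidate
    detection on the smoothed vesselness image, and adaptive median-MAD
    refinement.  If ``truth`` is supplied a full detection report is
    computed.  A constant or vessel-free image yields an empty seed set.
    """
    if config is None:
        config = PipelineConfig()
    image = np.asarray(image, dtype=float)

    t0 = time.perf_counter()
    ves = multiscale_vesselness(image, config.vesselness)
    t1 = time.perf_counter()
    logger.info("vesselness: %.2fs, raw max %.4g", t1 - t0, ves.raw_max)

    seeds = find_candidate_seeds(ves, sigma_r=config.sigma_r)
    t2 = time.perf_counter()
    logger.info("ridge detection: %.2fs, %d candidates", t2 - t1, len(seeds))

    threshold = float("nan")
    if len(seeds) == 0:
        logger.warning("no candidate seeds detected (flat or vessel-free image?)")
    else:
        source = ves.values if config.refine_source == "vesselness" else image
        seeds, threshold = refine_seeds(seeds, source, omega=config.omega)
        kept = int(np.sum(seeds.status == REFINED))
        logger.info(
            "refinement: T=%.3f, kept %d / rejected %d", threshold, kept, len(seeds) - kept
        )
        assert kept + int(np.sum(seeds.status == "rejected")) == len(seeds)

    report = None
    if truth is not None and len(seeds) > 0:
        report = _metrics.evaluate(seeds, truth, tau=config.tau)
    return DetectionResult(vesselness=ves, seeds=seeds, threshold=threshold, report=report)


def run_sweep(
    image: np.ndarray,
    truth: GroundTruth,
    alpha_grid: np.ndarray | None = None,
    beta_grid: np.ndarray | None = None,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """NDSP / NPSP / FDR over an (alpha, beta) grid.

    Defaults reproduce the sensitivity experiment: alpha in [0.25, 1] step
    0.05 (16 values) and beta in [5, 20] step 5 (4 values), 64 combinations.
    The per-scale image Hessians are computed once and reused, since alpha
    and beta only enter the eigenvalue-to-response map.  NDSP/NPSP are
    counted over candidate seeds (refinement is a later stage).
    """
    if config is None:
        config = PipelineConfig()
    if alpha_grid is None:
        alpha_grid = np.arange(0.25, 1.0 + 1e-9, 0.05)
    if beta_grid is None:
        beta_grid = np.arange(5.0, 20.0 + 1e-9, 5.0)
    alpha_grid = np.asarray(alpha_grid, dtype=float)
    beta_grid = np.asarray(beta_grid, dtype=float)
    if alpha_grid.size == 0 or beta_grid.size == 0:
        raise ValueError("alpha and beta grids must be non-empty")

    image = np.asarray(image, dtype=float)
    eigenfields = eigenfields_per_scale(image, config.vesselness)

    rows = []
    for alpha in alpha_grid:
        for beta in beta_grid:
            params = VesselnessParams(
                alpha=float(alpha),
                beta=float(beta),
                sigma_min=config.vesselness.sigma_min,
                sigma_max=config.vesselness.sigma_max,
                n_scales=config.vesselness.n_scales,
                rescale_255=config.vesselness.rescale_255,
            )
            ves = multiscale_vesselness(image, params, eigenfields=eigenfields)
            seeds = find_candidate_seeds(ves, sigma_r=config.sigma_r)
            ndsp = _metrics.count_ndsp(seeds, tau=config.tau)
            npsp = _metrics.count_npsp(seeds, truth.vessel_mask)
            ratio = ndsp / npsp if npsp > 0 else float("inf")
            rows.append(
                dict(alpha=float(alpha), beta=float(beta), NDSP=ndsp, NPSP=npsp, FDR=ratio)
            )
    return pd.DataFrame(rows)
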