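"""Frangi vesselness: single-scale response and multiscale maximum.

For dark vessels on a brighter background the across-vessel curvature of the
intensity is strongly positive at the centerline, so under magnitude ordering
the larger-magnitude eigenvalue ``lam2`` is positive inside vessels; pixels
with ``lam2 < 0`` (bright ridges, dark blobs' complements) get response 0.
The response at scale sigma is

    E(sigma) = exp(-lam1^2 / (2 alpha^2 lam2^2)) * (1 - exp(-(lam1^2 + lam2^2) / (2 beta^2)))

with ``alpha`` controlling blob suppression (the lam1/lam2 ratio) and ``beta``
controlling the structureness (second-derivative energy) needed for full
response.  The multiscale image is the pixel-wise maximum over a sampled set
of scales; gamma-normalized derivatives (see :mod:`angioseed.scale_space`)
make that maximum meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .scale_space import EigenField, eigen_decompose, gaussian_hessian

__all__ = [
    "VesselnessParams",
    "VesselnessImage",
    "scale_set",
    "frangi_single_scale",
    "eigenfields_per_scale",
    "multiscale_vesselness",
]


@dataclass
class VesselnessParams:
    """Filter parameters.

    alpha : blobness sensitivity (suppresses blob-like |lam1|~|lam2| pixels)
    beta : structureness sensitivity, in curvature units of the input image
    sigma_min, sigma_max : scale range in pixels, covering vessel radii
    n_scales : number of linearly spaced scales in [sigma_min, sigma_max]
    rescale_255 : linearly map the final response to [0, 255] (8-bit-like
        range, matching the response threshold tau = 30 used for counting)
    """

    alpha: float = 0.5
    beta: float = 10.0
    sigma_min: float = 1.0
    sigma_max: float = 4.0
    n_scales: int = 7
    rescale_255: bool = True

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if not (0 < self.sigma_min <= self.sigma_max):
            raise ValueError("require 0 < sigma_min <= sigma_max")
        if self.n_scales < 1:
            raise ValueError("n_scales must be >= 1")


@dataclass
class VesselnessImage:
    """Multiscale vesselness response with per-pixel winning scale."""

    values: np.ndarray
    best_sigma: np.ndarray
    params: VesselnessParams
    raw_max: float = field(default=0.0)  # pre-rescale maximum response


def scale_set(params: VesselnessParams) -> np.ndarray:
    """Linearly spaced scales in [sigma_min, sigma_max]."""
    return np.linspace(params.sigma_min, params.sigma_max, params.n_scales)


def frangi_single_scale(eigen: EigenField, params: VesselnessParams) -> np.ndarray:
    """Single-scale response from magnitude-ordered eigenvalue fields.

    Pixels where lam2 <= 0 return 0 (the lam2 = 0 case by the limit
    convention: zero structureness means zero response).
    """
    if eigen.ordering != "magnitude":
        raise ValueError(
            "frangi_single_scale requires magnitude-ordered eigenvalues, "
            f"got {eigen.ordering!r}"
        )
    lam1, lam2 = eigen.lam1, eigen.lam2
    pos = lam2 > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        blob = np.exp(-(lam1**2) / (2.0 * params.alpha**2 * lam2**2))
    struct = 1.0 - np.exp(-(lam1**2 + lam2**2) / (2.0 * params.beta**2))
    return np.where(pos, blob * struct, 0.0)


def eigenfields_per_scale(
    image: np.ndarray, params: VesselnessParams
) -> list[EigenField]:
    """Magnitude-ordered eigenfields of the image Hessian at each scale.

    Separated out so parameter sweeps over (alpha, beta) can reuse the
    expensive per-scale Hessians.
    """
    fields = []
    for sigma in scale_set(params):
        h = gaussian_hessian(np.asarray(image, dtype=float), float(sigma))
        fields.append(eigen_decompose(h, ordering="magnitude"))
    return fields


def multiscale_vesselness(
    image: np.ndarray,
    params: VesselnessParams | None = None,
    eigenfields: list[EigenField] | None = None,
) -> VesselnessImage:
    """Pixel-wise maximum of the single-scale response over the scale set.

    ``best_sigma`` records the scale achieving the maximum; ties go to the
    smallest scale (strict improvement required to switch), which keeps the
    output deterministic.  Precomputed ``eigenfields`` (one per scale, in
    scale order) may be supplied to amortize Hessian computation across
    parameter sweeps.
    """
    if params is None:
        params = VesselnessParams()
    sigmas = scale_set(params)
    if eigenfields is None:
        eigenfields = eigenfields_per_scale(image, params)
    if len(eigenfields) != len(sigmas):
        raise ValueError("eigenfields must have one entry per scale")

    best = None
    best_sigma = None
    for sigma, ef in zip(sigmas, eigenfields):
        resp = frangi_single_scale(ef, params)
        if best is None:
            best = resp
            best_sigma = np.full_like(resp, sigma)
        else:
            improve = resp > best
            best = np.where(improve, resp, best)
            best_sigma = np.where(improve, sigma, best_sigma)

    raw_max = float(best.max())
    if params.rescale_255 and raw_max > 0:
        best = best * (255.0 / raw_max)
    return VesselnessImage(
        values=best, best_sigma=best_sigma, params=replace(params), raw_max=raw_max
    )
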