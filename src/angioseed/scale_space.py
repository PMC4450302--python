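"""Gaussian scale-space derivatives and per-pixel Hessian eigen-analysis.

All derivative fields are computed by convolving the image with derivatives
of a Gaussian kernel of width ``sigma`` (truncated at 4*sigma, mirror-reflected
borders).  With ``normalized=True`` (the default) order-k derivatives are
multiplied by ``sigma**k`` — the gamma-normalization (gamma = 2) that makes
responses comparable across scales, which the multiscale maximum in
:mod:`angioseed.vesselness` requires.

Coordinate convention: ``(x, y) = (column, row)``, 0-based, pixel centres at
integer coordinates.  ``d/dx`` therefore differentiates along axis 1 of the
array and ``d/dy`` along axis 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "GradientField",
    "HessianField",
    "EigenField",
    "gaussian_derivatives",
    "gaussian_gradient",
    "gaussian_hessian",
    "eigen_decompose",
]

_TRUNCATE = 4.0  # kernel support in units of sigma
_BORDER = "mirror"


@dataclass
class GradientField:
    """First partial derivatives of an image at smoothing scale ``sigma``."""

    gx: np.ndarray
    gy: np.ndarray
    sigma: float


@dataclass
class HessianField:
    """Second partial derivatives of an image at smoothing scale ``sigma``.

    The mixed derivative is stored once (``ixy``); symmetry of second
    derivatives makes the (x,y) and (y,x) entries identical.
    """

    ixx: np.ndarray
    ixy: np.ndarray
    iyy: np.ndarray
    sigma: float


@dataclass
class EigenField:
    """Per-pixel eigenvalues and unit eigenvectors of a symmetric 2x2 field.

    ``ordering`` is either ``"algebraic"`` (lam1 <= lam2 everywhere, so lam1
    is the most negative — the across-ridge curvature needed by the ridge
    criterion) or ``"magnitude"`` (|lam1| <= |lam2|, the convention of the
    Frangi response).  ``degenerate`` flags pixels where the two eigenvalues
    coincide to numerical precision; there the eigenvector direction is
    undefined and the coordinate axes are substituted.
    """

    lam1: np.ndarray
    lam2: np.ndarray
    v1x: np.ndarray
    v1y: np.ndarray
    v2x: np.ndarray
    v2y: np.ndarray
    ordering: str
    degenerate: np.ndarray = field(default=None)  # type: ignore[assignment]


def _validate_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError(f"expected a 2D image, got shape {image.shape}")
    if image.shape[0] < 3 or image.shape[1] < 3:
        raise ValueError(f"image must be at least 3x3, got {image.shape}")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    return image


def _kernel1d(sigma: float, order: int) -> np.ndarray:
    """Sampled Gaussian-derivative correlation kernel with moment correction.

    The raw sampled kernels do not annihilate constants exactly (their sum is
    O(1e-4) at sigma = 1), which matters here: the ridge criterion tests the
    *sign* of derivative fields, so a tiny bias turns flat regions into fake
    curvature.  The order-1 and order-2 kernels are therefore corrected to
    have exactly zero sum and exact unit response to x and x^2/2
    respectively; the order-0 kernel is normalized to unit sum.
    """
    radius = int(_TRUNCATE * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=float)
    phi = np.exp(-(x**2) / (2.0 * sigma**2))
    phi /= phi.sum()
    if order == 0:
        return phi
    if order == 1:
        # correlation weights for d/dx: +x/sigma^2 * phi (convolution flips sign)
        w = x / sigma**2 * phi
        return w / np.sum(w * x)  # exact derivative of a ramp
    if order == 2:
        w = (x**2 - sigma**2) / sigma**4 * phi
        w = w - w.sum() * phi  # exact zero response to constants
        return w * (2.0 / np.sum(w * x**2))  # exact 2nd derivative of x^2
    raise ValueError(f"unsupported derivative order {order}")


def _deriv(image: np.ndarray, sigma: float, dx: int, dy: int) -> np.ndarray:
    out = ndimage.correlate1d(image, _kernel1d(sigma, dx), axis=1, mode=_BORDER)
    return ndimage.correlate1d(out, _kernel1d(sigma, dy), axis=0, mode=_BORDER)


def gaussian_derivatives(
    image: np.ndarray,
    sigma: float,
    orders: list[tuple[int, int]],
    normalized: bool = True,
) -> dict[tuple[int, int], np.ndarray]:
    """Derivative-of-Gaussian responses for the requested ``(dx, dy)`` orders.

    Returns a dict keyed by ``(dx, dy)``; with ``normalized`` each response is
    multiplied by ``sigma**(dx+dy)``.
    """
    image = _validate_image(image)
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    out: dict[tuple[int, int], np.ndarray] = {}
    for dx, dy in orders:
        d = _deriv(image, sigma, dx, dy)
        if normalized:
            d = d * sigma ** (dx + dy)
        out[(dx, dy)] = d
    return out


def gaussian_gradient(
    image: np.ndarray, sigma: float, normalized: bool = True
) -> GradientField:
    d = gaussian_derivatives(image, sigma, [(1, 0), (0, 1)], normalized)
    return GradientField(gx=d[(1, 0)], gy=d[(0, 1)], sigma=sigma)


def gaussian_hessian(
    image: np.ndarray, sigma: float, normalized: bool = True
) -> HessianField:
    d = gaussian_derivatives(image, sigma, [(2, 0), (1, 1), (0, 2)], normalized)
    return HessianField(ixx=d[(2, 0)], ixy=d[(1, 1)], iyy=d[(0, 2)], sigma=sigma)


def eigen_decompose(h: HessianField, ordering: str = "algebraic") -> EigenField:
    """Closed-form eigen-decomposition of the symmetric 2x2 Hessian per pixel.

    For a symmetric matrix ``[[a, b], [b, c]]`` the eigenvalues are
    ``(a+c)/2 +/- sqrt(((a-c)/2)**2 + b**2)`` and the eigenvectors are obtained
    from the off-diagonal structure; no iterative solver is needed and the
    result is exact to rounding.  Eigenvectors are unit length and mutually
    orthogonal by construction.
    """
    if ordering not in ("algebraic", "magnitude"):
        raise ValueError(f"unknown ordering {ordering!r}")
    a, b, c = h.ixx, h.ixy, h.iyy
    mean = 0.5 * (a + c)
    disc = np.sqrt((0.5 * (a - c)) ** 2 + b**2)
    lam_lo = mean - disc
    lam_hi = mean + disc

    scale = np.abs(a) + np.abs(c) + np.abs(b)
    degenerate = disc <= 1e-12 * np.maximum(scale, 1e-300)

    # eigenvector of lam_hi: candidates (b, lam_hi - a) and (lam_hi - c, b);
    # pick whichever has the larger norm (one of them vanishes when b = 0)
    n1 = np.hypot(b, lam_hi - a)
    n2 = np.hypot(lam_hi - c, b)
    use1 = n1 >= n2
    ux = np.where(use1, b, lam_hi - c)
    uy = np.where(use1, lam_hi - a, b)
    norm = np.hypot(ux, uy)
    ok = norm > 0
    vhx = np.where(ok, ux / np.where(ok, norm, 1.0), 1.0)
    vhy = np.where(ok, uy / np.where(ok, norm, 1.0), 0.0)
    # degenerate pixels: axis-aligned convention
    vhx = np.where(degenerate, 0.0, vhx)
    vhy = np.where(degenerate, 1.0, vhy)
    # eigenvector of lam_lo is the perpendicular
    vlx = -vhy
    vly = vhx

    if ordering == "algebraic":
        lam1, lam2 = lam_lo, lam_hi
        v1x, v1y, v2x, v2y = vlx, vly, vhx, vhy
    else:
        swap = np.abs(lam_lo) > np.abs(lam_hi)
        lam1 = np.where(swap, lam_hi, lam_lo)
        lam2 = np.where(swap, lam_lo, lam_hi)
        v1x = np.where(swap, vhx, vlx)
        v1y = np.where(swap, vhy, vly)
        v2x = np.where(swap, vlx, vhx)
        v2y = np.where(swap, vly, vhy)

    return EigenField(
        lam1=lam1, lam2=lam2,
        v1x=v1x, v1y=v1y, v2x=v2x, v2y=v2y,
        ordering=ordering, degenerate=degenerate,
    )
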