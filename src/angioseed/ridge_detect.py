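"""Candidate seed detection via the ridge-point existence criterion.

A ridge point of a smooth scalar field is a point where the gradient projected
onto the leading Hessian eigenvector vanishes, ``v1 . grad I = 0``, with
negative across-ridge curvature ``lam1 < 0`` (algebraic ordering).  Exact
zeros live at subpixel positions, so detection works on 2x2 pixel cells: if
the four corner values of ``v1 . grad I`` take both signs while ``lam1 < 0``
at all four corners, the intermediate value theorem puts a ridge point inside
the cell, and the cell's anchor pixel (its top-left corner) is emitted as a
seed.  This avoids any interpolation while keeping pixel-level accuracy.

Eigenvectors carry an arbitrary sign, so before the sign test the four corner
eigenvectors are aligned against the anchor corner's vector; without this the
corner-to-corner sign changes of ``v1 . grad I`` would be meaningless.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .scale_space import EigenField, GradientField, eigen_decompose, gaussian_gradient, gaussian_hessian
from .vesselness import VesselnessImage

__all__ = [
    "SeedSet",
    "smooth_vesselness",
    "align_eigenvectors",
    "detect_ridge_cells",
    "find_candidate_seeds",
]

logger = logging.getLogger(__name__)

CANDIDATE = "candidate"
REFINED = "refined"
REJECTED = "rejected"


@dataclass
class SeedSet:
    """Detected seed points in (x=column, y=row) pixel coordinates.

    ``response`` holds the vesselness value at each seed; ``status`` is one
    of ``candidate`` / ``refined`` / ``rejected``.  Points are unique and kept
    in row-major (y, then x) scan order.
    """

    x: np.ndarray
    y: np.ndarray
    response: np.ndarray
    status: np.ndarray

    def __len__(self) -> int:
        return len(self.x)

    def with_status(self, *statuses: str) -> "SeedSet":
        keep = np.isin(self.status, statuses)
        return SeedSet(self.x[keep], self.y[keep], self.response[keep], self.status[keep])

    @staticmethod
    def empty() -> "SeedSet":
        return SeedSet(
            np.empty(0, dtype=np.intp),
            np.empty(0, dtype=np.intp),
            np.empty(0, dtype=float),
            np.empty(0, dtype="<U9"),
        )


def _make_seedset(y: np.ndarray, x: np.ndarray, response_image: np.ndarray) -> SeedSet:
    if len(x) == 0:
        return SeedSet.empty()
    # row-major order, deduplicated
    flat = y.astype(np.int64) * response_image.shape[1] + x.astype(np.int64)
    flat = np.unique(flat)
    y = flat // response_image.shape[1]
    x = flat % response_image.shape[1]
    return SeedSet(
        x=x.astype(np.intp),
        y=y.astype(np.intp),
        response=response_image[y, x].astype(float),
        status=np.full(len(x), CANDIDATE, dtype="<U9"),
    )


def smooth_vesselness(v: VesselnessImage | np.ndarray, sigma_r: float) -> np.ndarray:
    """Gaussian-smooth the vesselness values; sigma_r = 0 is the identity.

    Smoothing restores the differential continuity that the cell criterion's
    intermediate-value argument assumes (the raw multiscale maximum has
    creases where the winning scale switches).
    """
    values = v.values if isinstance(v, VesselnessImage) else np.asarray(v, dtype=float)
    if sigma_r < 0:
        raise ValueError("sigma_r must be >= 0")
    if sigma_r == 0:
        return values.copy()
    return ndimage.gaussian_filter(values, sigma_r, mode="mirror", truncate=4.0)


def align_eigenvectors(vectors: np.ndarray) -> np.ndarray:
    """Flip eigenvector signs so all agree with the first vector.

    ``vectors`` is (n, 2); each row whose dot product with row 0 is negative
    is negated.  Rows exactly orthogonal to row 0 are left unchanged.
    """
    vectors = np.asarray(vectors, dtype=float)
    signs = np.where(vectors @ vectors[0] < 0, -1.0, 1.0)
    return vectors * signs[:, None]


def detect_ridge_cells(
    field: np.ndarray,
    eigen: EigenField,
    grad: GradientField,
    response_image: np.ndarray | None = None,
    rel_tol: float = 1e-9,
    min_response: float | None = None,
) -> SeedSet:
    """Scan every 2x2 cell of ``field``'s derivative data for ridge points.

    For the cell anchored at pixel (x, y) with corners (x,y), (x+1,y),
    (x,y+1), (x+1,y+1) the anchor is emitted as a candidate seed iff, after
    sign-aligning the corner eigenvectors to the anchor's,

        max(v1 . grad) > 0  and  min(v1 . grad) < 0  and  max(lam1) < 0

    over the four corners (strict inequalities).  A pixel where v1 . grad is
    zero (to numerical precision) with lam1 < 0 is itself a ridge point and
    is emitted directly.  Cells touching a degenerate-eigenvalue pixel are
    skipped.  ``response_image`` supplies the per-seed response value
    (defaults to ``field``).  With ``min_response`` set, anchors whose
    response is not strictly above it are suppressed — used by the
    vesselness pipeline to drop flat ridges of the zero-response region,
    where the enhancement itself asserts "not a vessel".

    Because the sign tests are amplitude-invariant, convolution roundoff in
    flat regions (relative ripples ~1e-15) would otherwise fire cells on
    machine noise; dot products and curvatures below ``rel_tol`` times their
    field-wide maximum magnitude are therefore snapped to zero first.
    """
    field = np.asarray(field, dtype=float)
    if eigen.ordering != "algebraic":
        raise ValueError("ridge detection requires algebraic eigenvalue ordering")
    for arr in (eigen.lam1, eigen.v1x, grad.gx, grad.gy):
        if arr.shape != field.shape:
            raise ValueError("field, eigen and gradient shapes must match")
    if response_image is None:
        response_image = field
    elif response_image.shape != field.shape:
        raise ValueError("response_image shape must match field")

    dot = eigen.v1x * grad.gx + eigen.v1y * grad.gy
    lam1 = eigen.lam1
    deg = eigen.degenerate

    # snap machine-noise values to zero (see docstring)
    dot_floor = rel_tol * np.abs(dot).max()
    lam_floor = rel_tol * np.abs(lam1).max()
    dot = np.where(np.abs(dot) <= dot_floor, 0.0, dot)
    lam1 = np.where(np.abs(lam1) <= lam_floor, 0.0, lam1)

    A = np.s_[:-1, :-1]
    B = np.s_[:-1, 1:]
    C = np.s_[1:, :-1]
    D = np.s_[1:, 1:]

    def aligned(corner):
        # sign of (v1 at corner) . (v1 at anchor); zero treated as +1
        s = eigen.v1x[A] * eigen.v1x[corner] + eigen.v1y[A] * eigen.v1y[corner]
        return np.where(s < 0, -dot[corner], dot[corner])

    dA = dot[A]
    dB = aligned(B)
    dC = aligned(C)
    dD = aligned(D)

    mx = np.maximum(np.maximum(dA, dB), np.maximum(dC, dD))
    mn = np.minimum(np.minimum(dA, dB), np.minimum(dC, dD))
    lmax = np.maximum(np.maximum(lam1[A], lam1[B]), np.maximum(lam1[C], lam1[D]))
    cell_deg = deg[A] | deg[B] | deg[C] | deg[D]

    fire = (mx > 0) & (mn < 0) & (lmax < 0) & ~cell_deg
    if min_response is not None:
        fire &= np.asarray(response_image, float)[A] > min_response
    n_deg = int((cell_deg & (mx > 0) & (mn < 0) & (lmax < 0)).sum())
    if n_deg:
        logger.info("skipped %d ridge cells with degenerate eigenvalues", n_deg)

    ys, xs = np.nonzero(fire)

    # pixels that are exact ridge points themselves
    exact = (dot == 0.0) & (lam1 < 0) & ~deg
    if min_response is not None:
        exact &= np.asarray(response_image, float) > min_response
    ey, ex = np.nonzero(exact)

    return _make_seedset(
        np.concatenate([ys, ey]), np.concatenate([xs, ex]), np.asarray(response_image, float)
    )


def find_candidate_seeds(
    vesselness: VesselnessImage | np.ndarray, sigma_r: float = 1.0
) -> SeedSet:
    """End-to-end candidate detection on a vesselness image.

    Gradient and Hessian of the vesselness values are taken as
    derivative-of-Gaussian responses at scale ``sigma_r`` (which subsumes the
    pre-smoothing step: differentiating the sigma_r-smoothed image equals
    convolving with the Gaussian derivative at sigma_r).  Seed responses are
    read from the unsmoothed vesselness values.
    """
    values = (
        vesselness.values
        if isinstance(vesselness, VesselnessImage)
        else np.asarray(vesselness, dtype=float)
    )
    if sigma_r <= 0:
        raise ValueError("sigma_r must be positive for derivative estimation")
    grad = gaussian_gradient(values, sigma_r)
    hess = gaussian_hessian(values, sigma_r)
    eigen = eigen_decompose(hess, ordering="algebraic")
    smoothed = smooth_vesselness(values, sigma_r)
    return detect_ridge_cells(
        smoothed, eigen, grad, response_image=values, min_response=0.0
    )
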