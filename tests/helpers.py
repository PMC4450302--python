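"""Shared analytic-field machinery for ridge-detection oracle tests.

A quadratic field f(x, y) = -a*u^2 + b*v^2 + c (with u, v rotated
coordinates) has an affine gradient and a constant Hessian, so Gaussian
derivative filters reproduce its gradient exactly and its Hessian up to an
additive constant in the diagonal that cancels in differences — making
quadratics the ideal ground truth: the analytic sub-sampling oracle and the
discrete detector see identical sign structure away from borders.
"""

from __future__ import annotations

import numpy as np


class QuadraticRidgeField:
    """f = -curv_u * u^2 + curv_v * v^2, u along (cos t, sin t) through (x0, y0)."""

    def __init__(self, x0: float, y0: float, theta: float, curv_u: float, curv_v: float = 0.0):
        self.x0, self.y0, self.theta = x0, y0, theta
        self.curv_u, self.curv_v = curv_u, curv_v

    def _uv(self, x, y):
        ct, st = np.cos(self.theta), np.sin(self.theta)
        dx, dy = x - self.x0, y - self.y0
        return ct * dx + st * dy, -st * dx + ct * dy

    def values(self, shape: tuple[int, int]) -> np.ndarray:
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
        u, v = self._uv(xx, yy)
        return -self.curv_u * u**2 + self.curv_v * v**2

    def hessian(self) -> np.ndarray:
        ct, st = np.cos(self.theta), np.sin(self.theta)
        rot = np.array([[ct, -st], [st, ct]])
        diag = np.diag([-2.0 * self.curv_u, 2.0 * self.curv_v])
        return rot @ diag @ rot.T

    def gradient(self, x, y):
        u, v = self._uv(x, y)
        ct, st = np.cos(self.theta), np.sin(self.theta)
        gu, gv = -2.0 * self.curv_u * u, 2.0 * self.curv_v * v
        return gu * ct - gv * st, gu * st + gv * ct

    def lam1_v1(self):
        """Algebraically smallest eigenvalue and its eigenvector."""
        w, vec = np.linalg.eigh(self.hessian())
        return w[0], vec[:, 0]


def oracle_ridge_cells(field: QuadraticRidgeField, shape: tuple[int, int], n_sub: int = 10):
    """Cells containing a zero of v1 . grad f with lam1 < 0, by dense sub-sampling.

    Evaluates the analytic v1 . grad f on an n_sub x n_sub grid inside every
    2x2 cell (corners included); a cell is marked when the samples take both
    signs (or an exact zero) and lam1 < 0.  Entirely independent of the
    discrete detector.
    """
    lam1, v1 = field.lam1_v1()
    h, w = shape
    marked = np.zeros((h - 1, w - 1), dtype=bool)
    if lam1 >= 0:
        return marked
    t = np.linspace(0.0, 1.0, n_sub)
    su, sv = np.meshgrid(t, t)
    for y in range(h - 1):
        for x in range(w - 1):
            gx, gy = field.gradient(x + su, y + sv)
            d = v1[0] * gx + v1[1] * gy
            if d.max() >= 0 and d.min() <= 0:
                marked[y, x] = True
    return marked


def fired_mask(seeds, shape: tuple[int, int]) -> np.ndarray:
    """Seed set -> boolean anchor-cell mask."""
    m = np.zeros((shape[0] - 1, shape[1] - 1), dtype=bool)
    inb = (seeds.y < shape[0] - 1) & (seeds.x < shape[1] - 1)
    m[seeds.y[inb], seeds.x[inb]] = True
    return m
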