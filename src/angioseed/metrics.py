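"""Evaluation of a seed set against a ground-truth vessel mask.

Counts and ratios:

* NDSP — number of detected seeds whose enhancement response exceeds a
  threshold tau (default 30 on the 0-255 rescaled vesselness).
* NPSP — number of pseudo seeds, i.e. detected seeds resting on background.
* FDR = NDSP / NPSP, used to pick enhancement parameters (its reciprocal,
  pseudo seeds per detected seed, is also reported since the ratio as
  defined grows with *better* detection).
* precision P = TP/(TP+FP), recall R = TP/(TP+FN), f-measure FM = 2PR/(P+R),
  where TP/FP split the refined (kept) seeds by the vessel mask and FN are
  the true (in-vessel) candidates that refinement wrongly discarded — recall
  therefore measures the refinement stage.
* N1 — number of refined seeds; N2 — number of distinct vessel branches
  containing at least one refined seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .phantom import GroundTruth
from .ridge_detect import REFINED, REJECTED, SeedSet

__all__ = [
    "MetricsParams",
    "DetectionReport",
    "count_ndsp",
    "count_npsp",
    "fdr",
    "precision_recall_fm",
    "f_measure",
    "branch_coverage",
    "seed_centerline_distances",
    "evaluate",
]


@dataclass
class MetricsParams:
    tau: float = 30.0  # response threshold for NDSP


@dataclass
class DetectionReport:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f_measure: float
    n1: int
    n2: int
    ndsp: int
    npsp: int
    fdr: float
    fdr_reciprocal: float
    tau: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)

    def rounded(self, ndigits: int = 3) -> dict:
        out = {}
        for k, v in self.__dict__.items():
            out[k] = round(v, ndigits) if isinstance(v, float) else v
        return out


def count_ndsp(seeds: SeedSet, tau: float = 30.0) -> int:
    """Seeds with response strictly above tau."""
    return int(np.sum(seeds.response > tau))


def count_npsp(seeds: SeedSet, vessel_mask: np.ndarray) -> int:
    """Seeds whose pixel lies outside the vessel mask."""
    vessel_mask = np.asarray(vessel_mask, dtype=bool)
    if len(seeds) == 0:
        return 0
    if seeds.y.max() >= vessel_mask.shape[0] or seeds.x.max() >= vessel_mask.shape[1]:
        raise ValueError("seed coordinates outside mask bounds")
    return int(np.sum(~vessel_mask[seeds.y, seeds.x]))


def fdr(ndsp: int, npsp: int) -> float:
    """FDR = NDSP / NPSP; NPSP = 0 yields infinity with a warning."""
    if npsp == 0:
        warnings.warn("NPSP is zero; FDR is undefined (reported as inf)")
        return math.inf
    return ndsp / npsp


def precision_recall_fm(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """P = TP/(TP+FP), R = TP/(TP+FN), FM = 2PR/(P+R)."""
    if tp + fp == 0 and tp + fn == 0:
        raise ValueError("precision and recall both undefined (no seeds)")
    p = tp / (tp + fp) if tp + fp > 0 else 0.0
    r = tp / (tp + fn) if tp + fn > 0 else 0.0
    return p, r, f_measure(p, r)


def f_measure(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both vanish."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def branch_coverage(seeds: SeedSet, branch_labels: np.ndarray, status: str = REFINED) -> tuple[int, int]:
    """(N1, N2): refined seed count and number of distinct branches hit."""
    branch_labels = np.asarray(branch_labels)
    sel = seeds.with_status(status) if status else seeds
    if len(sel) == 0:
        return 0, 0
    hit = branch_labels[sel.y, sel.x]
    return len(sel), int(len(np.unique(hit[hit > 0])))


def seed_centerline_distances(seeds: SeedSet, truth: GroundTruth) -> np.ndarray:
    """Euclidean distance from each seed to the nearest centerline point."""
    if len(seeds) == 0:
        return np.empty(0)
    if len(truth.centerline) == 0:
        return np.full(len(seeds), np.inf)
    tree = cKDTree(truth.centerline.astype(float))
    d, _ = tree.query(np.column_stack([seeds.x, seeds.y]).astype(float))
    return d


def evaluate(seeds: SeedSet, truth: GroundTruth, tau: float = 30.0) -> DetectionReport:
    """Full report from a refined seed set (statuses assigned) and truth.

    TP/FP classify the refined seeds by the vessel mask; FN counts in-vessel
    candidates that refinement rejected.  NDSP/NPSP/FDR are computed over the
    whole detected (candidate) set, since they characterize the enhancement
    and detection stages before refinement.
    """
    mask = np.asarray(truth.vessel_mask, dtype=bool)
    kept = seeds.with_status(REFINED)
    rejected = seeds.with_status(REJECTED)

    tp = len(kept) - count_npsp(kept, mask) if len(kept) else 0
    fp = len(kept) - tp
    fn = (len(rejected) - count_npsp(rejected, mask)) if len(rejected) else 0

    p, r, fm = precision_recall_fm(tp, fp, fn)
    n1, n2 = branch_coverage(seeds, truth.branch_labels)
    ndsp = count_ndsp(seeds, tau)
    npsp = count_npsp(seeds, mask)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ratio = fdr(ndsp, npsp)
    recip = npsp / ndsp if ndsp > 0 else math.inf
    return DetectionReport(
        tp=tp, fp=fp, fn=fn,
        precision=p, recall=r, f_measure=fm,
        n1=n1, n2=n2, ndsp=ndsp, npsp=npsp,
        fdr=ratio, fdr_reciprocal=recip, tau=tau,
    )
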