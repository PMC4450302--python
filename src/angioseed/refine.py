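"""Self-adaptive seed refinement with a median / MAD threshold.

Candidate ridge cells fire on background noise as well as on vessels
("pseudo seeds").  Refinement samples the response values P at all candidate
locations and keeps seeds at or above

    T = median(P) - omega * MAD(P),

where MAD(P) = median(|P - median(P)|).  Because vessel seeds dominate the
candidate set and carry much higher vesselness than background seeds, the
median anchors T in the vessel population and ``omega`` widens the accepted
band downwards; larger omega keeps more seeds (more sensitive, noisier).
"""

from __future__ import annotations

import numpy as np

from .ridge_detect import REFINED, REJECTED, SeedSet

__all__ = ["adaptive_threshold", "refine_seeds"]


def adaptive_threshold(values: np.ndarray, omega: float) -> float:
    """T = median(values) - omega * median(|values - median(values)|).

    Even-length medians are the midpoint of the two central order statistics
    (numpy convention).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot threshold an empty sample")
    if not np.all(np.isfinite(values)):
        raise ValueError("sample contains non-finite values")
    if omega < 0:
        raise ValueError("omega must be >= 0")
    m = float(np.median(values))
    s = float(np.median(np.abs(values - m)))
    return m - omega * s


def refine_seeds(
    seeds: SeedSet, image: np.ndarray, omega: float = 3.0
) -> tuple[SeedSet, float]:
    """Classify candidate seeds as refined (kept) or rejected.

    ``image`` is the scalar field sampled at the seed pixels to form P — the
    vesselness image by default in the pipeline, or the raw angiogram when
    refining on raw intensity.  Seeds with sampled value >= T keep status
    ``refined``; the rest become ``rejected`` but remain in the output so the
    classification is auditable.  Returns the new SeedSet and T.
    """
    if len(seeds) == 0:
        raise ValueError("cannot refine an empty seed set")
    image = np.asarray(image, dtype=float)
    p = image[seeds.y, seeds.x]
    t = adaptive_threshold(p, omega)
    status = np.where(p >= t, REFINED, REJECTED).astype("<U9")
    return SeedSet(seeds.x.copy(), seeds.y.copy(), seeds.response.copy(), status), t
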