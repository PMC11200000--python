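"""Shannon-entropy diversity statistics shared across the package.

Natural-log entropy of a discrete distribution is the package's single
diversity primitive: donor diversity of a cell cluster, within-donor
cluster heterogeneity, transcriptional-plasticity entropy of an
epigenotype, and TCR clonotype diversity are all instances of it applied
to different count vectors.
"""

from __future__ import annotations

import numpy as np


def shannon_entropy(counts, normalized: bool = False) -> float:
    """Shannon entropy H = -sum f_i ln f_i of a nonnegative count vector.

    Parameters
    ----------
    counts
        Nonnegative counts (or weights); zeros are ignored.
    normalized
        If True, divide by ln(K) over the K positive categories, mapping
        the result into [0, 1] (0 for a single category).

    Returns 0 exactly when one category carries all mass and ln(K)
    exactly for a uniform distribution over K categories.
    """
    c = np.asarray(counts, dtype=float)
    if c.size == 0:
        raise ValueError("entropy of an empty count vector is undefined")
    if (c < 0).any():
        raise ValueError("counts must be nonnegative")
    c = c[c > 0]
    if c.size == 0:
        raise ValueError("entropy undefined: all counts are zero")
    if c.size == 1:
        return 0.0
    f = c / c.sum()
    h = float(-(f * np.log(f)).sum())
    if normalized:
        h /= np.log(c.size)
    return h
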