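"""Independent oracles used by the acceptance tests: written directly from
the defining formulas, not via the package under test."""

import math

import numpy as np
from scipy import stats


def exhaustive_boundaries(x, min_width=3):
    """Recursive segmentation by exhaustive max-|t| search (pooled two-sample
    t via scipy at every admissible split), no significance gate."""
    bounds = {0, len(x)}

    def recurse(lo, hi):
        seg = x[lo:hi]
        n = len(seg)
        if n < 2 * min_width:
            return
        best_t, best_k = -1.0, None
        for k in range(min_width, n - min_width + 1):
            t = stats.ttest_ind(seg[:k], seg[k:], equal_var=True).statistic
            if np.isfinite(t) and abs(t) > best_t:
                best_t, best_k = abs(t), k
        if best_k is None:
            return
        bounds.add(lo + best_k)
        recurse(lo, lo + best_k)
        recurse(lo + best_k, hi)

    recurse(0, len(x))
    return sorted(bounds)


def wilson_closed_form(k, n, z=1.959963984540054):
    p = k / n
    denom = 1 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return center - half, center + half
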