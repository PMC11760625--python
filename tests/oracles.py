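"""Independent brute-force oracles used by the test suite.

These re-derive expected results with naive, loop-level transcriptions of
the algorithms' defining rules, sharing nothing with the package's
vectorized implementations except the published random-draw protocol (one
generator, N uniforms per scale row in increasing-k order), which is part
of the algorithm definition.
"""

from math import ceil

import numpy as np


def bruteforce_ampd_peaks(x, alpha=1.0, rng_seed=0):
    """Literal double-loop multiscale peak detection on a detrended segment.

    Builds the full local-maxima scalogram cell by cell, sums rows, selects
    the argmin scale and returns columns whose retained cells are all zero.
    """
    x = [float(v) for v in x]
    n = len(x)
    L = ceil(n / 2) - 1
    rng = np.random.default_rng(rng_seed)
    m = []
    for k in range(1, L + 1):
        r = rng.random(n)
        row = []
        for i in range(n):
            interior = k <= i <= n - k - 1
            if interior and x[i] > x[i - k] and x[i] > x[i + k]:
                row.append(0.0)
            else:
                row.append(r[i] + alpha)
        m.append(row)
    gamma = [float(np.sum(row)) for row in m]
    lam = int(np.argmin(gamma)) + 1
    return [
        i for i in range(n) if all(m[k][i] == 0.0 for k in range(lam))
    ]


def bruteforce_lms_zero_pattern(x, k):
    """Zero-pattern of one scalogram row by direct condition evaluation."""
    n = len(x)
    out = []
    for i in range(n):
        interior = k <= i <= n - k - 1
        out.append(bool(interior and x[i] > x[i - k] and x[i] > x[i + k]))
    return out


def printed_index_zero_pattern(x, k):
    """Zero-pattern under the alternative one-based indexing convention
    (test sample i-1 against i-k-1 and i+k-1), which shifts the centered
    pattern by one sample."""
    n = len(x)
    out = [False] * n
    # one-based i runs k+2 .. n-k+1; zero-based cell index j = i-1
    for i in range(k + 2, n - k + 2):
        j = i - 1
        c, lo, hi = i - 2, i - k - 2, i + k - 2  # zero-based sample indices
        if 0 <= lo and hi < n and j < n and x[c] > x[lo] and x[c] > x[hi]:
            out[j] = True
    return out


def exhaustive_local_maxima(x):
    """All strict three-point local maxima of a sequence."""
    return [
        i for i in range(1, len(x) - 1) if x[i - 1] < x[i] and x[i + 1] < x[i]
    ]
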