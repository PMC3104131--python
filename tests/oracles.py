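"""Independent reference computations used only by the test suite.

These deliberately avoid the code paths they check: state decoding by
exhaustive enumeration of all 3^n paths, and Fisher's exact test by exact
rational hypergeometric enumeration.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np

from cnvcall.calling import HmmModel


def enumerate_viterbi(model: HmmModel, z: np.ndarray) -> np.ndarray:
    """Most probable state path by scoring every possible path explicitly."""
    n = len(z)
    means = model.emission_means
    sds = model.emission_sds
    loge = (
        -0.5 * ((z[:, None] - means[None, :]) / sds[None, :]) ** 2
        - np.log(sds)[None, :]
        - 0.5 * np.log(2 * np.pi)
    )
    lt = np.log(model.transition_matrix)
    lpi = np.log(model.initial_distribution)
    # all 3^n paths as a (3^n, n) mixed-radix table
    radix = 3 ** np.arange(n - 1, -1, -1, dtype=np.int64)
    paths = (np.arange(3**n, dtype=np.int64)[:, None] // radix[None, :]) % 3
    scores = lpi[paths[:, 0]] + loge[np.arange(n)[None, :], paths].sum(axis=1)
    if n > 1:
        scores += lt[paths[:, :-1], paths[:, 1:]].sum(axis=1)
    return paths[int(np.argmax(scores))].astype(np.int8)


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact rational arithmetic over the full support."""
    n_total, row1, col1 = a + b + c + d, a + b, a + c
    denom = comb(n_total, row1)

    def mass(k: int) -> Fraction:
        return Fraction(comb(col1, k) * comb(n_total - col1, row1 - k), denom)

    observed = mass(a)
    k_lo = max(0, row1 - (n_total - col1))
    k_hi = min(row1, col1)
    total = sum((m for k in range(k_lo, k_hi + 1) if (m := mass(k)) <= observed), Fraction(0))
    return float(total)
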