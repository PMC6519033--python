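"""Deliberately naive, loop-based reference implementations of the summary
statistics, kept independent of the package's vectorized code paths."""

import itertools
import math

import numpy as np


def naive_haps(matrix, length_bp):
    n = matrix.shape[0]
    distinct = {tuple(row) for row in matrix}
    return len(distinct) / (n * length_bp)


def naive_watterson(matrix, length_bp):
    n, s = matrix.shape
    a_n = sum(1.0 / i for i in range(1, n))
    return s / (a_n * length_bp)


def naive_pairwise(matrix, length_bp):
    n = matrix.shape[0]
    dists = []
    for i, j in itertools.combinations(range(n), 2):
        d = sum(int(a != b) for a, b in zip(matrix[i], matrix[j]))
        dists.append(d / length_bp)
    mean = sum(dists) / len(dists)
    var = sum((d - mean) ** 2 for d in dists) / len(dists)
    return mean, var


def naive_hahe(matrix):
    n, s = matrix.shape
    if s == 0:
        return math.nan
    hs = []
    for j in range(s):
        counts = {}
        for a in matrix[:, j]:
            counts[a] = counts.get(a, 0) + 1
        h = 1.0 - sum((c / n) ** 2 for c in counts.values())
        hs.append(n / (n - 1) * h)
    return sum(hs) / s


def _compatible(col_a, col_b):
    gametes = {(a, b) for a, b in zip(col_a, col_b)}
    return len(gametes) < 4


def naive_nss(matrix):
    s = matrix.shape[1]
    if s < 2:
        return math.nan
    comp = [
        _compatible(matrix[:, j], matrix[:, j + 1]) for j in range(s - 1)
    ]
    return sum(comp) / len(comp)


def _chi2_2x2(a, b, c, d):
    n = a + b + c + d
    margins = [a + b, c + d, a + c, b + d]
    if any(m == 0 for m in margins):
        return 0.0
    num = n * (a * d - b * c) ** 2
    den = margins[0] * margins[1] * margins[2] * margins[3]
    return num / den


def naive_maxchi(matrix):
    n, s = matrix.shape
    if s < 2:
        return math.nan
    best = 0.0
    for i, j in itertools.combinations(range(n), 2):
        mism = [int(a != b) for a, b in zip(matrix[i], matrix[j])]
        for k in range(1, s):
            a = sum(mism[:k])
            b = k - a
            c = sum(mism[k:])
            d = (s - k) - c
            best = max(best, _chi2_2x2(a, b, c, d))
    return best


def naive_tajimas_d(matrix):
    """Textbook Tajima's D, constants written out independently."""
    n, s = matrix.shape
    if s == 0:
        return math.nan
    pi = 0.0
    npairs = 0
    for i, j in itertools.combinations(range(n), 2):
        pi += sum(int(a != b) for a, b in zip(matrix[i], matrix[j]))
        npairs += 1
    pi /= npairs
    a1 = sum(1.0 / k for k in range(1, n))
    a2 = sum(1.0 / k**2 for k in range(1, n))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n * n + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (pi - s / a1) / math.sqrt(e1 * s + e2 * s * (s - 1.0))


def random_alignment(rng, max_n=8, max_s=12, length_bp=100):
    """A random binary alignment guaranteed to have segregating columns."""
    from ldjump.alignment import HaplotypeAlignment

    n = int(rng.integers(2, max_n + 1))
    s = int(rng.integers(2, max_s + 1))
    while True:
        m = rng.integers(0, 2, size=(n, s)).astype(np.uint8)
        if np.all(m.min(axis=0) != m.max(axis=0)):
            break
    positions = np.sort(rng.choice(length_bp, size=s, replace=False))
    return HaplotypeAlignment(m, positions, length_bp)
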