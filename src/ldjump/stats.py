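"""Per-segment summary statistics of linkage and diversity.

These are the predictors of the recombination-rate regression: a normalized
haplotype count, Watterson's theta, mean and variance of pairwise differences,
haplotype heterozygosity, the neighbour similarity score (NSS) over the
four-gamete compatibility of adjacent sites, the maximal chi-squared statistic
(MaxChi) over putative recombination breakpoints, and optionally Tajima's D
for demography-aware models.

All statistics are per base pair where indicated, are invariant to haplotype
order and to allele relabeling within a site, and are computed on the binary
segregating-site matrix of a :class:`~ldjump.alignment.HaplotypeAlignment`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from .alignment import HaplotypeAlignment

__all__ = [
    "SummaryVector",
    "PREDICTORS",
    "haps",
    "watterson_theta_per_bp",
    "pairwise_diffs",
    "haplotype_heterozygosity",
    "nss",
    "maxchi",
    "tajimas_d",
    "summarize_segment",
]

#: Predictor order used throughout training and prediction.
PREDICTORS = ("haps", "vapw", "apwd", "wath", "hahe", "maxchi", "nss")


@dataclass(frozen=True)
class SummaryVector:
    """The per-segment predictor values; NaN marks an undefined statistic."""

    haps: float
    vapw: float
    apwd: float
    wath: float
    hahe: float
    maxchi: float
    nss: float
    tajd: float
    snp_count: int
    imputed: bool  # True when the segment has <= 1 SNP and must be imputed

    def values(self, include_tajd: bool = False) -> np.ndarray:
        names = PREDICTORS + (("tajd",) if include_tajd else ())
        return np.array([getattr(self, k) for k in names], dtype=float)


def _harmonic(n: int) -> float:
    return sum(1.0 / i for i in range(1, n))


def haps(aln: HaplotypeAlignment) -> float:
    """Number of distinct haplotypes per base pair and per sequence: H/(n*L)."""
    if aln.num_sites == 0:
        h = 1
    else:
        h = len(np.unique(aln.matrix, axis=0))
    return h / (aln.n * aln.length_bp)


def watterson_theta_per_bp(aln: HaplotypeAlignment) -> float:
    """Watterson's theta per bp: S / (a_n * L), a_n = sum_{i<n} 1/i."""
    if aln.n < 2:
        raise ValueError("need at least two haplotypes")
    return aln.num_sites / (_harmonic(aln.n) * aln.length_bp)


def pairwise_diffs(aln: HaplotypeAlignment) -> tuple[float, float]:
    """Mean and population variance of per-bp pairwise Hamming distances.

    Over all C(n,2) haplotype pairs, ``d_ij`` = number of mismatching sites
    divided by L; returns ``(apwd, vapw) = (mean d, var d)`` with the variance
    normalized by the number of pairs.
    """
    if aln.n < 2:
        raise ValueError("need at least two haplotypes")
    if aln.num_sites == 0:
        return 0.0, 0.0
    d = pdist(aln.matrix, metric="hamming") * aln.num_sites / aln.length_bp
    return float(d.mean()), float(d.var())


def haplotype_heterozygosity(aln: HaplotypeAlignment) -> float:
    """Mean per-site heterozygosity with the n/(n-1) small-sample factor.

    NaN when the segment has no segregating site.
    """
    if aln.num_sites == 0:
        return math.nan
    n = aln.n
    p = aln.matrix.mean(axis=0)
    h = n / (n - 1) * (1.0 - (p**2 + (1.0 - p) ** 2))
    return float(h.mean())


def _compatible_adjacent(m: np.ndarray) -> np.ndarray:
    """Four-gamete compatibility of columns (j, j+1); shape (S-1,) bool."""
    a, b = m[:, :-1], m[:, 1:]
    g = 2 * a.astype(np.int8) + b.astype(np.int8)
    present = np.stack([(g == v).any(axis=0) for v in range(4)])
    return present.sum(axis=0) < 4


def nss(aln: HaplotypeAlignment) -> float:
    """Neighbour similarity score: fraction of compatible adjacent site pairs.

    Two biallelic sites are compatible iff at most 3 of the 4 gametes occur
    (four-gamete test).  NaN when S < 2.
    """
    if aln.num_sites < 2:
        return math.nan
    return float(_compatible_adjacent(aln.matrix).mean())


def maxchi(aln: HaplotypeAlignment) -> float:
    """Maximal chi-squared over haplotype pairs and breakpoint positions.

    For each haplotype pair, the binary mismatch vector over the S ordered
    sites is split at every interior point k; the 2x2 chi-squared of
    (mismatches, matches) left vs right of k is computed without continuity
    correction (0 when a margin is empty).  Returns the maximum; NaN if S < 2.
    """
    if aln.num_sites < 2:
        return math.nan
    if aln.n < 2:
        raise ValueError("need at least two haplotypes")
    m = aln.matrix
    s = aln.num_sites
    iu = np.triu_indices(aln.n, k=1)
    mm = (m[iu[0]] != m[iu[1]]).astype(np.float64)  # (n_pairs, S)
    left = np.cumsum(mm, axis=1)[:, :-1]  # mismatches left of split k=1..S-1
    total = mm.sum(axis=1, keepdims=True)
    k = np.arange(1, s, dtype=np.float64)
    a = left  # mismatches left
    c = total - left  # mismatches right
    b = k[None, :] - a  # matches left
    d = (s - k)[None, :] - c  # matches right
    n1, n2 = a + b, c + d  # column sums: k, S-k (always > 0)
    r1, r2 = a + c, b + d  # row sums: mismatches, matches
    denom = n1 * n2 * r1 * r2
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = s * (a * d - b * c) ** 2 / denom
    chi2[denom == 0] = 0.0
    return float(chi2.max())


def tajimas_d(aln: HaplotypeAlignment) -> float:
    """Tajima's D with the canonical variance constants; NaN when S == 0."""
    n, s = aln.n, aln.num_sites
    if n < 4:
        raise ValueError("Tajima's D requires n >= 4")
    if s == 0:
        return math.nan
    a1 = _harmonic(n)
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    # mean pairwise differences (total, not per bp)
    d = pdist(aln.matrix, metric="hamming") * s
    pi = d.mean()
    var = e1 * s + e2 * s * (s - 1)
    return float((pi - s / a1) / math.sqrt(var))


def summarize_segment(aln: HaplotypeAlignment, include_tajd: bool = False) -> SummaryVector:
    """Assemble the full predictor vector for one segment.

    Segments with one or zero SNPs are flagged for imputation from their
    neighbours; their undefined statistics are NaN.
    """
    s = aln.num_sites
    apwd, vapw = pairwise_diffs(aln)
    tajd = math.nan
    if include_tajd and s >= 1 and aln.n >= 4:
        tajd = tajimas_d(aln)
    return SummaryVector(
        haps=haps(aln),
        vapw=vapw,
        apwd=apwd,
        wath=watterson_theta_per_bp(aln),
        hahe=haplotype_heterozygosity(aln),
        maxchi=maxchi(aln),
        nss=nss(aln),
        tajd=tajd,
        snp_count=s,
        imputed=s <= 1,
    )
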