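"""Binary haplotype alignments over segregating sites.

The central in-memory container: an ``n x S`` matrix of allele indices (0/1)
at the segregating sites of a sequence of total length ``length_bp``, together
with the 0-based bp position of each site.  Monomorphic columns are removed on
construction; multiallelic columns are kept only if the two most frequent
alleles cover every haplotype (recoded 0/1), otherwise the site is dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["HaplotypeAlignment"]


@dataclass(frozen=True)
class HaplotypeAlignment:
    matrix: np.ndarray  # (n, S) uint8 in {0, 1}
    positions: np.ndarray  # (S,) int64, strictly increasing, in [0, L)
    length_bp: int

    def __init__(self, matrix, positions, length_bp):
        matrix = np.ascontiguousarray(np.asarray(matrix, dtype=np.uint8))
        positions = np.asarray(positions, dtype=np.int64)
        length_bp = int(length_bp)
        if matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (haplotypes x sites)")
        if matrix.shape[1] != len(positions):
            raise ValueError("positions length must match number of sites")
        if len(positions) and (
            np.any(np.diff(positions) <= 0)
            or positions[0] < 0
            or positions[-1] >= length_bp
        ):
            raise ValueError("positions must be strictly increasing in [0, L)")
        if matrix.size and matrix.max() > 1:
            raise ValueError("matrix must be binary (0/1 allele indices)")
        # drop monomorphic columns
        if matrix.shape[1]:
            seg = (matrix.min(axis=0) != matrix.max(axis=0))
            matrix = matrix[:, seg]
            positions = positions[seg]
        object.__setattr__(self, "matrix", matrix)
        object.__setattr__(self, "positions", positions)
        object.__setattr__(self, "length_bp", length_bp)

    @property
    def n(self) -> int:
        """Number of haplotypes."""
        return self.matrix.shape[0]

    @property
    def num_sites(self) -> int:
        """Number of segregating sites S."""
        return self.matrix.shape[1]

    @classmethod
    def from_allele_matrix(cls, alleles, positions, length_bp) -> "HaplotypeAlignment":
        """Build from an ``n x S`` matrix of arbitrary allele codes.

        Sites whose two most frequent allele codes do not cover all haplotypes
        are dropped (multiallelic reduction policy).  The more frequent allele
        is coded 0; ties broken by allele code order.
        """
        alleles = np.asarray(alleles)
        positions = np.asarray(positions, dtype=np.int64)
        n, s = alleles.shape
        keep = []
        binary = np.zeros_like(alleles, dtype=np.uint8)
        for j in range(s):
            col = alleles[:, j]
            codes, counts = np.unique(col, return_counts=True)
            if len(codes) != 2:
                # monomorphic, or a third allele is carried by someone: drop
                continue
            minor = codes[np.argsort(-counts, kind="stable")[1]]
            binary[:, j] = (col == minor).astype(np.uint8)
            keep.append(j)
        keep = np.array(keep, dtype=int)
        return cls(binary[:, keep], positions[keep], length_bp)

    def slice_window(self, start: int, end: int) -> "HaplotypeAlignment":
        """Sites in ``[start, end)`` with window-local positions; L = end-start."""
        if not (0 <= start < end <= self.length_bp):
            raise ValueError("window outside sequence")
        lo, hi = np.searchsorted(self.positions, [start, end], side="left")
        return HaplotypeAlignment(
            self.matrix[:, lo:hi], self.positions[lo:hi] - start, end - start
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, HaplotypeAlignment):
            return NotImplemented
        return (
            self.length_bp == other.length_bp
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.matrix, other.matrix)
        )
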