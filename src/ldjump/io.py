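"""Readers and writers for the standard formats the tool touches.

Haplotype alignments come from FASTA (one record per haplotype) or phased
VCF; recombination maps are exchanged as 4-column BED-like text
(chrom, start, end, rho_per_bp).  Coordinates are 0-based half-open
internally and in BED output; VCF's 1-based positions are converted on read.
"""

from __future__ import annotations

import logging
import numpy as np
from Bio import SeqIO

from .alignment import HaplotypeAlignment
from .maps import RecombinationMap

__all__ = [
    "read_fasta_alignment",
    "write_fasta_alignment",
    "read_phased_vcf",
    "write_map_bed",
    "read_map_bed",
    "write_hotspots_bed",
    "alignment_from_sequences",
]

logger = logging.getLogger(__name__)

def alignment_from_sequences(
    sequences: list[str], length_bp: int | None = None
) -> HaplotypeAlignment:
    """Build an alignment from equal-length nucleotide strings.

    Sites with any missing character (N or gap) among the haplotypes are
    dropped (logged); multiallelic sites follow the two-most-frequent-allele
    reduction of :class:`HaplotypeAlignment`.
    """
    if len(sequences) < 2:
        raise ValueError("need at least two haplotypes")
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment: record lengths {sorted(lengths)}")
    L = lengths.pop()
    if length_bp is not None and length_bp != L:
        raise ValueError("declared length does not match the records")
    arr = np.frombuffer(
        "".join(s.upper() for s in sequences).encode("ascii"), dtype=np.uint8
    ).reshape(len(sequences), L)
    bad = ~np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8)).all(axis=0)
    n_missing = int(bad.sum())
    variable = (arr.min(axis=0) != arr.max(axis=0)) & ~bad
    if n_missing:
        logger.info("dropped %d sites containing missing or non-ACGT symbols",
                    int((bad & (arr.min(axis=0) != arr.max(axis=0))).sum()))
    positions = np.nonzero(variable)[0]
    return HaplotypeAlignment.from_allele_matrix(
        arr[:, positions], positions, L
    )


def read_fasta_alignment(path) -> HaplotypeAlignment:
    """Read a FASTA haplotype alignment (one record per haplotype)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: empty FASTA file")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate record ids")
    return alignment_from_sequences([str(r.seq) for r in records])


def write_fasta_alignment(records: list[tuple[str, str]], path) -> None:
    """Write ``(id, sequence)`` pairs as FASTA, 70 columns per line."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_phased_vcf(
    path,
    region: tuple[int, int] | None = None,
    samples: list[str] | None = None,
    allow_unphased: bool = False,
    seed: int = 0,
) -> HaplotypeAlignment:
    """Read phased biallelic SNPs into a haplotype alignment.

    Each diploid sample contributes two haplotypes.  ``region`` is a 0-based
    half-open (start, end) window; positions become region-local.  Unphased
    genotypes raise unless ``allow_unphased`` (then phase is randomized with
    the given seed, logged).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), samples=samples)
    rng = np.random.default_rng(seed)
    rows = []
    positions = []
    n_unphased = 0
    for var in vcf:
        if not var.is_snp or len(var.ALT) != 1:
            logger.info("skipping non-biallelic-SNP record at %s", var.POS)
            continue
        pos0 = var.POS - 1
        if region is not None and not region[0] <= pos0 < region[1]:
            continue
        col = []
        for g in var.genotypes:  # [allele0, allele1, phased]
            a, b, phased = g[0], g[1], bool(g[-1])
            if a < 0 or b < 0:
                col = None
                break
            if not phased and a != b:
                if not allow_unphased:
                    raise ValueError(
                        f"unphased genotype at position {var.POS}; pass "
                        "allow_unphased to randomize phase"
                    )
                n_unphased += 1
                if rng.integers(2):
                    a, b = b, a
            col.extend([a, b])
        if col is None:
            logger.info("dropping site %d with missing genotypes", var.POS)
            continue
        rows.append(col)
        positions.append(pos0)
    if region is None:
        length = (max(positions) + 1) if positions else 1
        offset = 0
    else:
        offset, end = region
        length = end - offset
    if n_unphased:
        logger.warning("randomized phase at %d heterozygous genotypes", n_unphased)
    matrix = (
        np.array(rows, dtype=np.int64).T
        if rows
        else np.zeros((2 * len(vcf.samples), 0), dtype=np.int64)
    )
    return HaplotypeAlignment.from_allele_matrix(
        matrix, np.array(positions, dtype=np.int64) - offset, length
    )


def write_map_bed(rec_map: RecombinationMap, path, chrom: str = "seq") -> None:
    """Write a map as BED-like text: chrom, start, end, rho_per_bp."""
    with open(path, "w") as fh:
        for start, end, rate in rec_map.blocks():
            fh.write(f"{chrom}\t{int(start)}\t{int(end)}\t{float(rate)!r}\n")


def read_map_bed(path) -> RecombinationMap:
    """Read a BED-like map written by :func:`write_map_bed` (lossless)."""
    starts, ends, rates = [], [], []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            _, s, e, r = line.split()[:4]
            starts.append(int(s))
            ends.append(int(e))
            rates.append(float(r))
    if not starts:
        raise ValueError(f"{path}: no intervals")
    for i in range(1, len(starts)):
        if starts[i] != ends[i - 1]:
            raise ValueError(f"{path}: intervals must tile the sequence in order")
    if starts[0] != 0:
        raise ValueError(f"{path}: map must start at 0")
    return RecombinationMap(ends[-1], np.array(ends[:-1], dtype=float), np.array(rates))


def write_hotspots_bed(
    hotspots: list[tuple[float, float]], path, chrom: str = "seq"
) -> None:
    with open(path, "w") as fh:
        for s, e in hotspots:
            fh.write(f"{chrom}\t{int(s)}\t{int(e)}\n")
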