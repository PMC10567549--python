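"""Desk-scale ungapped alignment with non-templated 3'-tail detection.

Reference genomes here are small (kilobases to tens of kilobases), so the
aligner scans every offset of every contig with a vectorised mismatch count
rather than building an FM-index. Alignments are reported for all positions
where the full sequence matches with at most ``max_mm`` mismatches; if the
full sequence is unmappable, the shortest trimming of the 3' end (up to
``max_tail`` nt, leaving a matched prefix of at least ``min_prefix`` nt) that
rescues an alignment is reported, with the trimmed bases recorded as a
non-templated tail.

Coordinates are 0-based, half-open (BED convention). The 5' end of a
minus-strand alignment is the last base of its footprint (``end - 1``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA sequence (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Alignment:
    """An ungapped placement of a (possibly 3'-trimmed) read on the reference."""

    chrom: str
    start: int  # 0-based inclusive
    end: int    # exclusive; end - start == matched length
    strand: str  # "+" or "-"
    mismatches: int
    tail_length: int = 0  # non-templated 3' nucleotides not in [start, end)

    @property
    def five_prime(self) -> int:
        """Genomic coordinate of the read's first nucleotide."""
        return self.start if self.strand == "+" else self.end - 1


class GenomeIndex:
    """Uppercased contigs plus their byte-array views for scanning."""

    def __init__(self, contigs: Mapping[str, str]):
        self.contigs: dict[str, str] = {name: str(seq).upper() for name, seq in contigs.items()}
        self._arrays = {
            name: np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
            for name, seq in self.contigs.items()
        }

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeIndex":
        from .preprocess import read_fasta

        return cls(read_fasta(path))

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    def sequence(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        seq = self.contigs[chrom][start:end]
        return seq if strand == "+" else revcomp(seq)


def _encode_query(seq: str) -> np.ndarray:
    # N in the query matches nothing: encode it as a byte absent from ACGTN
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    arr[arr == ord("N")] = 0
    return arr


def _scan(arr: np.ndarray, query: np.ndarray, max_mm: int) -> tuple[np.ndarray, np.ndarray]:
    k = len(query)
    if len(arr) < k:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    windows = sliding_window_view(arr, k)
    mm = (windows != query).sum(axis=1)
    pos = np.nonzero(mm <= max_mm)[0]
    return pos, mm[pos]


def align_ungapped(
    seq: str,
    genome: GenomeIndex | Mapping[str, str],
    max_mm: int = 1,
    min_prefix: int = 18,
    max_tail: int = 4,
) -> list[Alignment]:
    """All ungapped placements of ``seq`` on both strands of the reference.

    Returns an empty list when unmapped. When the full-length sequence has no
    placement, the smallest 3' trim (``tail_length``) that yields one is used;
    trims leaving fewer than ``min_prefix`` matched bases are not attempted.
    """
    gi = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)
    seq = seq.upper()
    n = len(seq)
    for tail in range(0, max_tail + 1):
        k = n - tail
        if k < 1 or (tail > 0 and k < min_prefix):
            break
        core = seq[:k]
        hits: list[Alignment] = []
        for chrom, arr in gi._arrays.items():
            for strand, pattern in (("+", core), ("-", revcomp(core))):
                pos, mm = _scan(arr, _encode_query(pattern), max_mm)
                hits.extend(
                    Alignment(chrom, int(p), int(p) + k, strand, int(m), tail)
                    for p, m in zip(pos, mm)
                )
        if hits:
            return hits
    return []


def align_species(
    sequences: Sequence[str],
    genome: GenomeIndex | Mapping[str, str],
    max_mm: int = 1,
    min_prefix: int = 18,
    max_tail: int = 4,
) -> dict[str, list[Alignment]]:
    """Align each distinct sequence once; returns sequence -> alignments."""
    gi = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)
    out: dict[str, list[Alignment]] = {}
    for seq in sequences:
        if seq not in out:
            out[seq] = align_ungapped(seq, gi, max_mm=max_mm, min_prefix=min_prefix, max_tail=max_tail)
    return out
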