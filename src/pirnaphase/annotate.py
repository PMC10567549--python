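"""Feature annotation, multi-mapper weighting, length profiles and
positional nucleotide composition of small-RNA species."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .align import Alignment

log = logging.getLogger(__name__)

#: Feature classes in decreasing assignment precedence.
CLASS_PRIORITY = {"pirna_locus": 0, "insertion": 1, "transposon": 2, "genic": 3}
_NONE_RANK = len(CLASS_PRIORITY)


@dataclass(frozen=True)
class FeatureInterval:
    """A 0-based half-open annotated interval."""

    chrom: str
    start: int
    end: int
    strand: str
    name: str
    feature_class: str

    def __post_init__(self):
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"bad interval {self.chrom}:{self.start}-{self.end}")

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return chrom == self.chrom and start < self.end and end > self.start


def read_bed(path: str | Path) -> list[FeatureInterval]:
    """Read a BED6+1 file (7th column = feature class)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            out.append(
                FeatureInterval(f[0], int(f[1]), int(f[2]), f[5] if len(f) > 5 else "+",
                                f[3], f[6] if len(f) > 6 else "genic")
            )
    return out


def write_bed(intervals: Iterable[FeatureInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{iv.strand}\t{iv.feature_class}\n")


def assign_feature(aln: Alignment, annotation: Sequence[FeatureInterval]) -> FeatureInterval | None:
    """The overlapping interval with the best (class precedence, overlap) rank.

    Returns ``None`` when the alignment overlaps no annotated interval.
    """
    best: tuple | None = None
    chosen = None
    for iv in annotation:
        if not iv.overlaps(aln.chrom, aln.start, aln.end):
            continue
        ov = min(aln.end, iv.end) - max(aln.start, iv.start)
        key = (CLASS_PRIORITY.get(iv.feature_class, _NONE_RANK), -ov, iv.start, iv.name)
        if best is None or key < best:
            best, chosen = key, iv
    return chosen


def weight_alignments(
    alignments: Sequence[Alignment],
    annotation: Sequence[FeatureInterval],
    policy: str = "fractional",
) -> list[tuple[Alignment, FeatureInterval | None, float]]:
    """Resolve multi-mapping: distribute one unit of weight over alignments.

    Alignments are first restricted to those with the fewest mismatches (and
    shortest tail), then to the best feature class. Under the default
    ``fractional`` policy the surviving alignments share weight 1/n; under
    ``unique`` only unambiguous (single-survivor) species receive weight.
    The total contributed weight per species is 1.0 (or 0 under ``unique``
    for ambiguous species), so read counts are conserved.
    """
    if not alignments:
        return []
    best_score = min((a.mismatches, a.tail_length) for a in alignments)
    kept = [a for a in alignments if (a.mismatches, a.tail_length) == best_score]
    assigned = [(a, assign_feature(a, annotation)) for a in kept]
    best_rank = min(
        CLASS_PRIORITY.get(iv.feature_class, _NONE_RANK) if iv else _NONE_RANK
        for _, iv in assigned
    )
    final = [
        (a, iv) for a, iv in assigned
        if (CLASS_PRIORITY.get(iv.feature_class, _NONE_RANK) if iv else _NONE_RANK) == best_rank
    ]
    if policy == "unique" and len(final) > 1:
        return [(a, iv, 0.0) for a, iv in final]
    w = 1.0 / len(final)
    return [(a, iv, w) for a, iv in final]


@dataclass(frozen=True)
class MappedSpecies:
    """A small-RNA species placed on the reference with a feature label."""

    sequence: str
    count: int
    alignment: Alignment
    feature: str  # interval name, or "none"
    feature_class: str  # class, or "none"
    weight: float = 1.0

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def five_prime(self) -> int:
        return self.alignment.five_prime

    @property
    def strand(self) -> str:
        return self.alignment.strand

    @property
    def chrom(self) -> str:
        return self.alignment.chrom


def length_profile(
    species: Iterable,
    feature: str | None = None,
    length_range: tuple[int, int] = (15, 54),
    normalize: bool = False,
) -> pd.Series:
    """Read counts (or fractions) per length for one feature (or all).

    Accepts anything with ``sequence`` and ``count`` attributes; when
    ``feature`` is given, objects must also expose ``feature``.
    """
    lo, hi = length_range
    counts = pd.Series(0.0, index=pd.RangeIndex(lo, hi + 1, name="length"))
    for sp in species:
        if feature is not None and getattr(sp, "feature", None) != feature:
            continue
        n = len(sp.sequence)
        if lo <= n <= hi:
            counts[n] += sp.count * getattr(sp, "weight", 1.0)
    if normalize and counts.sum() > 0:
        counts = counts / counts.sum()
    return counts


@dataclass
class CompositionSummary:
    """Read-weighted base fractions at requested 5'-anchored positions.

    ``position_fractions[p][base]`` is the fraction of reads whose base at
    1-based position ``p`` is ``base``; ``background[base]`` pools every
    position of every species (each read contributes ``length`` observations).
    ``excluded[p]`` counts species shorter than ``p``.
    """

    position_fractions: dict[int, dict[str, float]]
    background: dict[str, float]
    excluded: dict[int, int] = field(default_factory=dict)


def nt_composition(species: Sequence, positions: Iterable[int] = (1, 10)) -> CompositionSummary:
    """Positional nucleotide composition of a species set, weighted by count.

    In DNA space a 5'-uridine appears as T; report T fractions as U.
    """
    species = list(species)
    if not species:
        raise ValueError("species set is empty")
    positions = list(positions)
    pos_counts: dict[int, dict[str, float]] = {p: {} for p in positions}
    excluded = {p: 0 for p in positions}
    bg: dict[str, float] = {}
    for sp in species:
        seq, cnt = sp.sequence, sp.count
        for base in seq:
            bg[base] = bg.get(base, 0.0) + cnt
        for p in positions:
            if p > len(seq):
                excluded[p] += 1
                continue
            base = seq[p - 1]
            pos_counts[p][base] = pos_counts[p].get(base, 0.0) + cnt
    for p, n in excluded.items():
        if n:
            log.info("position %d: excluded %d species shorter than %d nt", p, n, p)

    def _norm(d: dict[str, float]) -> dict[str, float]:
        total = sum(d.values())
        return {b: v / total for b, v in d.items()} if total else {}

    return CompositionSummary(
        position_fractions={p: _norm(c) for p, c in pos_counts.items()},
        background=_norm(bg),
        excluded=excluded,
    )
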