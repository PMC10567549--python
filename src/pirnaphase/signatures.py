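"""Cleavage and phasing signatures.

The central diagnostics of piRNA-guided slicing and phased (Zucchini-driven)
piRNA production:

* the 0-20-nt 5'-5' overlap spectrum between opposite-strand 5' ends, and the
  standard score of the 10-nt overlap (Z10) against all other displayed
  offsets — PIWI slicing across from piRNA nucleotides g10/g11 leaves the
  product 5' end exactly 10 nt into the guide, so ping-pong partners and
  trigger/cleavage-product pairs enrich offset 10;
* merging of 5'-monophosphorylated long-RNA reads into species by their
  unique 5' ends, and identification of putative pre-pre-piRNAs (long 3'
  cleavage products poised for phased fragmentation) by their 5' position
  relative to an upstream transposon insertion;
* metaplots of piRNA 5'-end density along pre-pre-piRNAs and the
  autocorrelation of the median profile, whose first peak estimates the
  phasing period (~25-26 nt in fly germ cells).

For a plus-strand 5' end at P and a minus-strand 5' end at G on the same
reference, the overlap offset is o = G - P + 1 (o = 10 puts G across from
guide position 10).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy import stats as sps

from .annotate import FeatureInterval

log = logging.getLogger(__name__)


class End5(NamedTuple):
    """A weighted 5' end on the reference."""

    chrom: str
    strand: str
    pos: int
    weight: float = 1.0


class SignatureError(ValueError):
    pass


@dataclass(frozen=True)
class LongRnaSpecies:
    """A 5'-monophosphorylated long RNA, one record per distinct 5' end.

    ``start``/``end`` is the union of observed footprints (half-open);
    ``length`` is the longest observed extent.
    """

    chrom: str
    strand: str
    five_prime: int
    start: int
    end: int
    read_count: int

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def end5(self) -> End5:
        return End5(self.chrom, self.strand, self.five_prime, float(self.read_count))


def merge_long_rnas(records: Iterable[tuple[str, str, int, int, int]]) -> list[LongRnaSpecies]:
    """Merge read footprints sharing a 5' end into single RNA species.

    ``records`` are ``(chrom, strand, start, end, count)`` footprints
    (0-based half-open). The 5' end is ``start`` on plus, ``end - 1`` on
    minus; the merged extent is the union of footprints.
    """
    grouped: dict[tuple[str, str, int], list[tuple[int, int, int]]] = defaultdict(list)
    for chrom, strand, start, end, count in records:
        five = start if strand == "+" else end - 1
        grouped[(chrom, strand, five)].append((start, end, count))
    out = []
    for (chrom, strand, five), foots in grouped.items():
        start = min(f[0] for f in foots)
        end = max(f[1] for f in foots)
        out.append(LongRnaSpecies(chrom, strand, five, start, end, sum(f[2] for f in foots)))
    out.sort(key=lambda s: (s.chrom, s.strand, s.five_prime))
    return out


@dataclass
class OverlapSpectrum:
    """Counts of 0-20-nt 5'-5' overlaps between two opposite-strand sets."""

    counts: np.ndarray
    max_offset: int = 20
    weighting: str = "read"

    def scaled(self, k: float) -> "OverlapSpectrum":
        return OverlapSpectrum(self.counts * k, self.max_offset, self.weighting)


def _as_end5(items: Iterable) -> list[End5]:
    out = []
    for it in items:
        if isinstance(it, End5):
            out.append(it)
        elif isinstance(it, LongRnaSpecies):
            out.append(it.end5)
        else:
            out.append(End5(*it))
    return out


def overlap_spectrum(
    a_ends: Iterable,
    b_ends: Iterable,
    max_offset: int = 20,
    weighting: str = "read",
) -> OverlapSpectrum:
    """5'-5' overlap spectrum between set A and opposite-strand set B.

    Every (plus, minus) pair with offset ``o = G - P + 1`` in
    ``[0, max_offset]`` accumulates the product of the two weights
    (``weighting="read"``) or 1 per species pair (``weighting="species"``).
    Both orientations (A plus vs B minus, and A minus vs B plus) contribute.
    """
    if weighting not in ("read", "species"):
        raise ValueError(f"unknown weighting {weighting!r}")
    a = _as_end5(a_ends)
    b = _as_end5(b_ends)
    if weighting == "species":
        a = [e._replace(weight=1.0) for e in a]
        b = [e._replace(weight=1.0) for e in b]
    counts = np.zeros(max_offset + 1)

    def _accumulate(plus: list[End5], minus: list[End5]):
        index: dict[tuple[str, int], float] = defaultdict(float)
        for e in minus:
            index[(e.chrom, e.pos)] += e.weight
        for e in plus:
            for o in range(0, max_offset + 1):
                w = index.get((e.chrom, e.pos + o - 1))
                if w:
                    counts[o] += e.weight * w

    _accumulate([e for e in a if e.strand == "+"], [e for e in b if e.strand == "-"])
    _accumulate([e for e in b if e.strand == "+"], [e for e in a if e.strand == "-"])
    return OverlapSpectrum(counts, max_offset, weighting)


def z_score(spectrum: OverlapSpectrum, focus: int = 10) -> tuple[float, float]:
    """Standard score of the focus offset against all other displayed offsets.

    The background is every offset except ``focus``; z uses the population
    standard deviation of the background and p is the two-sided standard
    normal tail probability. A spectrum that is constant everywhere gives
    z = 0, p = 1; a degenerate background (zero spread but a deviating focus
    count) raises :class:`SignatureError`.
    """
    counts = np.asarray(spectrum.counts, dtype=float)
    background = np.delete(counts, focus)
    mean = background.mean()
    sd = background.std(ddof=0)
    if sd == 0:
        if counts[focus] == mean:
            return 0.0, 1.0
        raise SignatureError("degenerate_background")
    z = (counts[focus] - mean) / sd
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(p)


def call_cleavage_products(
    longs: Sequence[LongRnaSpecies],
    guides: Iterable,
    offset: int = 10,
) -> list[LongRnaSpecies]:
    """Long RNAs whose 5' end sits exactly ``offset`` into an antisense guide.

    A guide with 5' end G on the minus strand calls a plus-strand long RNA
    with 5' end P when G - P + 1 == offset (the long RNA's first nucleotide
    pairs guide position g10: the slicer geometry).
    """
    guide_pos: set[tuple[str, str, int]] = set()
    for g in _as_end5(guides):
        guide_pos.add((g.chrom, g.strand, g.pos))
    called = []
    for sp in longs:
        if sp.strand == "+":
            hit = (sp.chrom, "-", sp.five_prime + offset - 1) in guide_pos
        else:
            hit = (sp.chrom, "+", sp.five_prime - offset + 1) in guide_pos
        if hit:
            called.append(sp)
    return called


@dataclass(frozen=True)
class PrePrePiRnaCall:
    """A long RNA accepted as a putative pre-pre-piRNA at a locus junction."""

    species: LongRnaSpecies
    locus: str
    window_hit: bool = True


def identify_prepre(
    longs: Sequence[LongRnaSpecies],
    locus: FeatureInterval,
    insertion: FeatureInterval | None,
    window: int = 100,
    min_len: int = 200,
) -> list[PrePrePiRnaCall]:
    """Putative pre-pre-piRNAs: long RNAs whose 5' ends flank the junction.

    The junction is the insertion boundary abutting the locus body. A species
    is called when its observed length is >= ``min_len``, its footprint
    extends past the junction into the locus, and its 5' end lies in
    ``[junction - window, junction + window)``. Only the precursor strand
    (reading from insertion into locus) qualifies.
    """
    if insertion is None:
        raise SignatureError("no_insertion")
    if insertion.chrom != locus.chrom:
        raise SignatureError("no_insertion")
    if insertion.end <= locus.start:
        junction, strand = insertion.end, "+"
    elif insertion.start >= locus.end:
        junction, strand = insertion.start, "-"
    else:
        # insertion overlaps the locus record: use the boundary inside it
        junction, strand = insertion.end, "+"
    calls = []
    for sp in longs:
        if sp.chrom != locus.chrom or sp.strand != strand:
            continue
        if sp.length < min_len:
            continue
        if not (junction - window <= sp.five_prime < junction + window):
            continue
        spans = sp.end > junction if strand == "+" else sp.start < junction
        if not spans:
            continue
        calls.append(PrePrePiRnaCall(sp, locus.name))
    return calls


@dataclass
class PhasingProfile:
    """Per-permutation piRNA 5'-end density along pre-pre-piRNAs."""

    profiles: np.ndarray  # (n_permutations, L)
    median: np.ndarray
    iqr: np.ndarray
    all_zero: bool = False


def phasing_metaplot(
    prepre_sets: Sequence[Sequence[PrePrePiRnaCall | LongRnaSpecies]],
    pirna_sets: Sequence[Sequence],
    L: int = 150,
    weighting: str = "read",
) -> PhasingProfile:
    """Metaplot of piRNA 5'-end density along pre-pre-piRNA bodies.

    For every (piRNA dataset, long-RNA dataset) permutation, each
    pre-pre-piRNA contributes the vector of same-strand piRNA 5'-end weights
    at relative positions 0..L-1 downstream of its own 5' end, normalised to
    unit sum when non-zero (so one abundant precursor cannot dominate);
    vectors are averaged over precursors to give one profile per permutation.
    ``median``/``iqr`` are positionwise across permutations.
    """
    if not prepre_sets or not pirna_sets:
        raise ValueError("need at least one pre-pre-piRNA set and one piRNA set")
    profiles = []
    for pirnas in pirna_sets:
        ends = _as_end5(pirnas)
        if weighting == "species":
            ends = [e._replace(weight=1.0) for e in ends]
        index: dict[tuple[str, str, int], float] = defaultdict(float)
        for e in ends:
            index[(e.chrom, e.strand, e.pos)] += e.weight
        for prepres in prepre_sets:
            profile = np.zeros(L)
            n = 0
            for call in prepres:
                sp = call.species if isinstance(call, PrePrePiRnaCall) else call
                vec = np.zeros(L)
                sign = 1 if sp.strand == "+" else -1
                for rel in range(L):
                    w = index.get((sp.chrom, sp.strand, sp.five_prime + sign * rel))
                    if w:
                        vec[rel] = w
                total = vec.sum()
                if total > 0:
                    vec = vec / total
                profile += vec
                n += 1
            profiles.append(profile / max(n, 1))
    arr = np.array(profiles)
    all_zero = not np.any(arr)
    if all_zero:
        log.warning("phasing metaplot: all permutation profiles are zero")
    return PhasingProfile(
        profiles=arr,
        median=np.median(arr, axis=0),
        iqr=np.percentile(arr, 75, axis=0) - np.percentile(arr, 25, axis=0),
        all_zero=all_zero,
    )


def autocorrelate(profile: np.ndarray, max_lag: int = 50) -> np.ndarray:
    """Pearson autocorrelation of a density profile at lags 1..max_lag.

    Returns an array ``r`` with ``r[0] = 1``; a lag whose overlapping windows
    have zero variance is reported as NaN. Windows are overlapping segments
    of the profile (not circular): profiles are short and aperiodic at the
    edges.
    """
    x = np.asarray(profile, dtype=float)
    if len(x) <= max_lag + 2:
        raise ValueError("profile too short for requested max_lag")
    r = np.full(max_lag + 1, np.nan)
    r[0] = 1.0
    for lag in range(1, max_lag + 1):
        a, b = x[:-lag], x[lag:]
        if a.std() == 0 or b.std() == 0:
            continue
        r[lag] = float(np.corrcoef(a, b)[0, 1])
    return r


@dataclass(frozen=True)
class PeriodEstimate:
    """Phasing period from the autocorrelation peak."""

    period: int
    r_peak: float
    harmonic_ambiguous: bool


def estimate_period(
    autocorr: np.ndarray,
    search_range: tuple[int, int] = (15, 40),
) -> PeriodEstimate:
    """Lag of the maximum autocorrelation within ``search_range``.

    Ties break toward the smaller lag. If a divisor of the peak lag outside
    the search range carries comparable correlation, the reported peak may be
    a harmonic of a shorter true period; this is flagged, never silently
    resolved.
    """
    r = np.asarray(autocorr, dtype=float)
    lo, hi = search_range
    hi = min(hi, len(r) - 1)
    lags = [lag for lag in range(lo, hi + 1) if np.isfinite(r[lag])]
    if not lags:
        raise SignatureError("no_period")
    peak = max(lags, key=lambda lag: (r[lag], -lag))
    harmonic = False
    for div in (2, 3):
        h = int(round(peak / div))
        if 1 <= h < lo and np.isfinite(r[h]) and r[h] >= 0.9 * r[peak] > 0:
            harmonic = True
    return PeriodEstimate(period=peak, r_peak=float(r[peak]), harmonic_ambiguous=harmonic)
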