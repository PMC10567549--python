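"""Small-RNA library preprocessing.

The library scheme embeds two 9-nt unique molecular identifiers (UMIs) in the
adapters, split into N-triplets by fixed spacer triplets:

* the sequenced read starts with a 15-nt degenerate block from the 5' adapter,
  ``NNN CGA NNN TCA NNN`` (variant A) or ``NNN ATC NNN AGT NNN`` (variant B);
* the insert follows;
* a second 15-nt degenerate block, ``NNN GTC NNN TAG NNN``, precedes the
  constant 3' adapter ``TGGAATTCTCGGGTGCCAAGG``.

This module parses that grammar, collapses PCR duplicates on the
(insert, UMI5, UMI3) key, classifies species against rRNA and spike-in
references, and converts read counts to absolute molecule abundances using an
equimolar mix of six synthetic 5'-phosphorylated spike-in oligonucleotides.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from Bio import SeqIO

log = logging.getLogger(__name__)

#: Constant portion of the 3' adapter that follows the 3' UMI block.
ADAPTER3 = "TGGAATTCTCGGGTGCCAAGG"
#: Minimum stretch of the constant adapter that must be present in the read.
ADAPTER3_SEED = ADAPTER3[:10]
#: Length of each degenerate UMI block (three N-triplets + two spacer triplets).
UMI_BLOCK = 15
#: 5' adapter spacer triplets by adapter variant.
SPACERS5 = {"A": ("CGA", "TCA"), "B": ("ATC", "AGT")}
#: 3' adapter spacer triplets.
SPACERS3 = ("GTC", "TAG")

#: The six equimolar synthetic 5'-phosphorylated spike-in oligos (DNA form).
SPIKE_SEQUENCES: dict[str, str] = {
    "spike1": "TGCTAGTCTTATCGACCTCCTCATAG",
    "spike2": "TGCTAGTCTTCGATACCTCCTCATAG",
    "spike3": "TGCTAGTCTTGTCACGAACCTCATAG",
    "spike4": "TGCTAGTTATCGACCTTCATAG",
    "spike5": "TGCTAGTTCGATACCTTCATAG",
    "spike6": "TGCTAGTTGTCACGAATCATAG",
}


class ReadRejected(ValueError):
    """A read that does not conform to the adapter/UMI grammar.

    ``reason`` is one of ``"no_adapter"``, ``"bad_umi_structure"``,
    ``"empty_insert"``.
    """

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


class CalibrationError(ValueError):
    """Spike-in calibration is impossible (e.g. all spike counts are zero)."""


@dataclass(frozen=True)
class RawRead:
    """A sequencing read: identifier, sequence (ACGTN) and optional quality."""

    id: str
    sequence: str
    quality: str | None = None


@dataclass(frozen=True)
class ParsedInsert:
    """An insert extracted from a read, with its two 9-nt UMIs."""

    insert: str
    umi5: str
    umi3: str
    adapter_variant: str  # "A" or "B"


@dataclass(frozen=True)
class SpeciesCount:
    """A distinct insert sequence with its deduplicated read count."""

    sequence: str
    count: int


@dataclass
class ClassifiedSpecies:
    """Partition of species into spike-in, rRNA and retained sets."""

    retained: list[SpeciesCount] = field(default_factory=list)
    rrna: list[SpeciesCount] = field(default_factory=list)
    spikein: dict[str, int] = field(default_factory=dict)  # spike id -> count
    spike_species: list[tuple[SpeciesCount, str]] = field(default_factory=list)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def parse_small_rna_read(read: RawRead | str) -> ParsedInsert:
    """Extract the insert and both UMIs from a raw small-RNA read.

    The constant 3' adapter is located by an exact match of its first 10 nt;
    the four spacer triplets flanking the UMI N-triplets are validated
    allowing at most one mismatch in total across all of them (the 5' variant
    with the fewest mismatches is chosen).

    Raises
    ------
    ReadRejected
        With reason ``no_adapter``, ``empty_insert`` or ``bad_umi_structure``.
    """
    seq = (read.sequence if isinstance(read, RawRead) else str(read)).upper()
    # rightmost occurrence: a chance hit of the seed inside the insert must
    # not shadow the true adapter, which is always the last match in the read
    idx = seq.rfind(ADAPTER3_SEED)
    if idx < 2 * UMI_BLOCK:
        raise ReadRejected("no_adapter")
    if idx == 2 * UMI_BLOCK:
        raise ReadRejected("empty_insert")
    block5 = seq[:UMI_BLOCK]
    block3 = seq[idx - UMI_BLOCK : idx]
    insert = seq[UMI_BLOCK : idx - UMI_BLOCK]

    mm3 = _hamming(block3[3:6], SPACERS3[0]) + _hamming(block3[9:12], SPACERS3[1])
    best_variant, best_mm5 = None, None
    for variant in ("A", "B"):
        s1, s2 = SPACERS5[variant]
        mm = _hamming(block5[3:6], s1) + _hamming(block5[9:12], s2)
        if best_mm5 is None or mm < best_mm5:
            best_variant, best_mm5 = variant, mm
    if best_mm5 + mm3 > 1:
        raise ReadRejected("bad_umi_structure")

    umi5 = block5[0:3] + block5[6:9] + block5[12:15]
    umi3 = block3[0:3] + block3[6:9] + block3[12:15]
    return ParsedInsert(insert=insert, umi5=umi5, umi3=umi3, adapter_variant=best_variant)


def parse_reads(reads: Iterable[RawRead | str]) -> tuple[list[ParsedInsert], Counter]:
    """Parse many reads; return the parsed inserts and a rejection tally."""
    parsed: list[ParsedInsert] = []
    rejections: Counter = Counter()
    for read in reads:
        try:
            parsed.append(parse_small_rna_read(read))
        except ReadRejected as exc:
            rejections[exc.reason] += 1
    if rejections:
        log.info("rejected %d reads: %s", sum(rejections.values()), dict(rejections))
    return parsed, rejections


def deduplicate(parsed: Iterable[ParsedInsert]) -> list[SpeciesCount]:
    """Collapse PCR duplicates and count molecules per insert sequence.

    Records sharing (insert, umi5, umi3) collapse to a single molecule; the
    species count is the number of distinct UMI pairs observed for the insert.
    The result is independent of input order (sorted by descending count,
    then sequence).
    """
    umi_pairs: dict[str, set[tuple[str, str]]] = defaultdict(set)
    for p in parsed:
        umi_pairs[p.insert].add((p.umi5, p.umi3))
    species = [SpeciesCount(seq, len(pairs)) for seq, pairs in umi_pairs.items()]
    species.sort(key=lambda s: (-s.count, s.sequence))
    return species


def classify_reads(
    species: Sequence[SpeciesCount],
    rrna_refs: Mapping[str, str],
    spike_refs: Mapping[str, str] | None = None,
) -> ClassifiedSpecies:
    """Partition species into spike-in, rRNA and retained sets.

    A species identical to a spike-in oligo is a spike-in (exact match,
    precedence over rRNA); a species matching any rRNA reference on either
    strand with at most one mismatch is rRNA; everything else is retained.
    """
    # local import: align also provides the substring matcher used for rRNA
    from .align import GenomeIndex, align_ungapped

    if spike_refs is None:
        spike_refs = SPIKE_SEQUENCES
    if not rrna_refs:
        raise ValueError("rRNA reference set must be non-empty")
    spike_lookup = {seq.upper(): name for name, seq in spike_refs.items()}
    rrna_index = GenomeIndex(rrna_refs)

    out = ClassifiedSpecies(spikein={name: 0 for name in spike_refs})
    for sp in species:
        spike_id = spike_lookup.get(sp.sequence)
        if spike_id is not None:
            out.spikein[spike_id] += sp.count
            out.spike_species.append((sp, spike_id))
            continue
        if align_ungapped(sp.sequence, rrna_index, max_mm=1, max_tail=0):
            out.rrna.append(sp)
        else:
            out.retained.append(sp)
    log.info(
        "classified %d species: %d retained, %d rRNA, %d spike-in",
        len(species), len(out.retained), len(out.rrna), len(out.spike_species),
    )
    return out


@dataclass(frozen=True)
class SpikeCalibration:
    """Conversion factor from read counts to absolute molecule numbers.

    ``reads_per_molecule`` is the median spike-in read count divided by the
    number of molecules spiked per species (the median is robust to a single
    failed ligation among the six oligos). ``total_rna_pg`` is the mass of
    total RNA the spike mix was added to.
    """

    per_species_read_counts: tuple[float, ...]
    molecules_per_species: float
    total_rna_pg: float

    def __post_init__(self):
        if self.molecules_per_species <= 0 or self.total_rna_pg <= 0:
            raise CalibrationError("molecules_per_species and total_rna_pg must be positive")
        if not self.per_species_read_counts or not any(self.per_species_read_counts):
            raise CalibrationError("uncalibrated")

    @property
    def reads_per_molecule(self) -> float:
        return float(np.median(self.per_species_read_counts)) / self.molecules_per_species


def absolute_abundance(target_read_count: float, calib: SpikeCalibration) -> float:
    """Molecules per 10 pg total RNA for a target with the given read count."""
    molecules = target_read_count / calib.reads_per_molecule
    return molecules * (10.0 / calib.total_rna_pg)


def read_fastq(path: str | Path) -> Iterator[RawRead]:
    """Iterate over a FASTQ file (Sanger qualities) as :class:`RawRead`."""
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        yield RawRead(id=rec.id, sequence=str(rec.seq).upper(), quality=qual)


def write_fastq(reads: Iterable[RawRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = r.quality or "I" * len(r.sequence)
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
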