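"""Truth-tagged simulation of a Y-linked piRNA locus and its biogenesis.

The generator emulates the biology under study: a Y-like contig carries a
tandem array of repeats ~90% identical to the antisense of an X-linked
Ste-like gene, with a transposon insertion (1360/Hoppel-like) supplying the
5' leader of the precursor transcript. Maternally deposited trigger piRNAs,
antisense to the insertion, slice the precursor between target nucleotides
t10 and t11 (so a trigger whose minus-strand 5' end is at G creates a
plus-strand cleavage product starting at G - 9). Each cleavage product — a
pre-pre-piRNA — is then fragmented 5'-to-3' into tail-to-head phased
fragments with lengths ~Normal(phase_length_mean, phase_length_sd) and a
configurable probability that each fragment starts with uridine. Genic
control loci shed uniform decay fragments (both size classes) as negatives,
and six synthetic spike-in oligos with known molecule counts support
absolute quantification.

Every simulated molecule is recorded in a truth table; reads are wrapped in
the split-UMI adapter grammar of :mod:`pirnaphase.preprocess` so the entire
pipeline can be validated end to end. All randomness derives from a single
seed via per-stage substreams.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .align import revcomp
from .annotate import FeatureInterval
from .preprocess import ADAPTER3, SPACERS5, SPACERS3, SPIKE_SEQUENCES, RawRead

log = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: 2S rRNA-like reference (the 30-mer removed by the gel cut).
RRNA_2S = "TGCTTGGACTACATATGGTTGAGGGTTGTA"

SMALL_CLASSES = ("trigger", "phased", "responder", "decay", "rrna", "spikein", "deposited")
LONG_CLASSES = ("prepre_long", "decay_long")


@dataclass
class SimConfig:
    """Parameters of the simulated study conditions.

    Defaults reflect the modelled biology: four ~500-nt repeat units at 90%
    identity to the Ste-like gene, an ~800-nt upstream insertion with the
    transcription start inside it, ~25-26-nt phasing with a 77% 1U bias, and
    piRNA lengths confined to 23-29 nt.
    """

    seed: int = 0
    # genome
    repeat_units: int = 4
    repeat_unit_length: int = 500
    identity_to_ste: float = 0.90
    insertion_length: int = 800
    tss_offset: int = 300          # transcription start, relative to insertion start
    genic_locus_length: int = 1500
    n_genic_loci: int = 3
    # biogenesis
    trigger_pool_size: int = 30
    trigger_abundance: float = 120.0   # mean molecules per trigger species
    trigger_skew_sigma: float = 1.0    # log-normal sigma of trigger abundances
    prepre_molecules: float = 20.0     # mean molecules per cleavage-product species
    phased_abundance: float = 8.0      # mean molecules per phased fragment species
    phase_length_mean: float = 26.0
    phase_length_sd: float = 1.0
    u1_bias: float | None = 0.77       # P(fragment starts with U); None = no bias
    a10_bias: float = 0.37             # P(responder position 10 is A)
    responder_pool_size: int = 0       # ping-pong responders off by default
    responder_abundance: float = 15.0
    pirna_len_min: int = 23
    pirna_len_max: int = 29
    xxy_mode: bool = False             # maternally deposit mature locus piRNAs
    deposited_pool_size: int = 400
    deposited_abundance: float = 8.0
    # negatives and contaminants
    decay_small_per_locus: int = 100
    decay_small_abundance: float = 5.0
    decay_long_per_locus: int = 20
    decay_long_abundance: float = 10.0
    rrna_fragments: int = 10
    rrna_abundance: float = 50.0
    # library
    spike_molecules_per_species: float = 500.0
    total_rna_pg: float = 10.0
    small_depth: int = 50_000
    long_depth: int = 6_000
    n_small_replicates: int = 2
    n_long_replicates: int = 2
    read_length: int = 79
    long_core_length: int = 64     # genomic bases captured after the 5' block
    sequencing_error_rate: float = 0.001
    pcr_duplicate_rate: float = 0.15
    junction_window: int = 100

    def __post_init__(self):
        if not (0.5 < self.identity_to_ste <= 1.0):
            raise ValueError("bad_identity")
        for name in ("a10_bias", "sequencing_error_rate", "pcr_duplicate_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.u1_bias is not None and not (0.0 <= self.u1_bias <= 1.0):
            raise ValueError("u1_bias must be in [0, 1] or None")
        if self.insertion_length - self.tss_offset < self.junction_window + 20:
            raise ValueError("insertion_too_short")


def _rng(cfg: SimConfig, *tags: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(cfg.seed) % (2**31), *tags]))


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, seq: str, identity: float) -> str:
    """Substitute each position with probability (1 - identity)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(len(arr)) > identity)[0]
    for i in hit:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


@dataclass
class GenomeBuild:
    """Simulated reference: contigs, annotation and locus geometry."""

    contigs: dict[str, str]
    annotation: list[FeatureInterval]
    rrna: dict[str, str]
    spikes: dict[str, str]
    ste_unit: str
    tss: int
    junction: int
    insertion: FeatureInterval
    locus: FeatureInterval
    ste_gene: FeatureInterval
    genic_loci: list[FeatureInterval]
    precursor_end: int


def build_genome(cfg: SimConfig) -> GenomeBuild:
    """Emit the X-like and Y-like contigs, references and annotation."""
    rng = _rng(cfg, 1)

    ste_unit = _random_seq(rng, cfg.repeat_unit_length)

    # X-like contig: Ste-like gene then genic control loci
    x_parts, x_ann = [], []
    pos = 200
    x_parts.append(_random_seq(rng, 200))
    ste_gene = FeatureInterval("X_like", pos, pos + len(ste_unit), "+", "Ste_like", "genic")
    x_parts.append(ste_unit)
    pos = ste_gene.end
    genic_names = ["nos_like", "bam_like", "bgcn_like", "ctrl4", "ctrl5"]
    genic_loci = []
    for i in range(cfg.n_genic_loci):
        x_parts.append(_random_seq(rng, 200))
        pos += 200
        iv = FeatureInterval("X_like", pos, pos + cfg.genic_locus_length, "+",
                             genic_names[i % len(genic_names)], "genic")
        x_parts.append(_random_seq(rng, cfg.genic_locus_length))
        pos = iv.end
        genic_loci.append(iv)
    x_parts.append(_random_seq(rng, 100))

    # Y-like contig: flank + insertion-derived leader + repeat array + flank.
    # The precursor transcript runs on the plus strand, so each repeat unit is
    # the (mutated) reverse complement of the Ste-like gene: the precursor is
    # antisense to Ste.
    y_parts = [_random_seq(rng, 300)]
    ins_start = 300
    insertion_seq = _random_seq(rng, cfg.insertion_length)
    y_parts.append(insertion_seq)
    insertion = FeatureInterval("Y_like", ins_start, ins_start + cfg.insertion_length, "+",
                                "1360_like", "insertion")
    locus_start = insertion.end
    antisense_unit = revcomp(ste_unit)
    for _ in range(cfg.repeat_units):
        y_parts.append(_mutate(rng, antisense_unit, cfg.identity_to_ste))
    locus = FeatureInterval("Y_like", locus_start,
                            locus_start + cfg.repeat_units * cfg.repeat_unit_length, "+",
                            "SuSte_like", "pirna_locus")
    y_parts.append(_random_seq(rng, 300))

    contigs = {"X_like": "".join(x_parts), "Y_like": "".join(y_parts)}
    rrna = {"rRNA_2S_like": RRNA_2S, "rRNA_LSU_like": _random_seq(rng, 600)}
    annotation = [ste_gene, *genic_loci, insertion, locus]
    return GenomeBuild(
        contigs=contigs,
        annotation=annotation,
        rrna=rrna,
        spikes=dict(SPIKE_SEQUENCES),
        ste_unit=ste_unit,
        tss=ins_start + cfg.tss_offset,
        junction=insertion.end,
        insertion=insertion,
        locus=locus,
        ste_gene=ste_gene,
        genic_loci=genic_loci,
        precursor_end=locus.end,
    )


@dataclass(frozen=True)
class SimSpecies:
    """One distinct simulated RNA species with its true molecule count."""

    species_id: str
    cls: str
    chrom: str
    strand: str
    five_prime: int
    length: int
    sequence: str
    molecules: int


@dataclass(frozen=True)
class CutSite:
    trigger_id: str
    position: int  # plus-strand 5' end of the cleavage product


@dataclass
class SimTruth:
    """Full provenance of every simulated molecule."""

    species: list[SimSpecies]
    cut_sites: list[CutSite]
    fragments: list[tuple[str, int, int, bool]]  # (cut id, start, length, emitted)
    seed: int

    def by_class(self, *classes: str) -> list[SimSpecies]:
        return [sp for sp in self.species if sp.cls in classes]

    def molecules_by_class(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for sp in self.species:
            out[sp.cls] = out.get(sp.cls, 0) + sp.molecules
        return out

    def species_table(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(sp) for sp in self.species])


def _pick_position_with_base(
    rng: np.random.Generator,
    draw,
    base_at,
    want: bool,
    target: str,
    tries: int = 40,
    scan_center: int | None = None,
    scan_limit: int = 15,
) -> int:
    """Redraw a position until its base is (or is not) ``target``.

    Rejection sampling preserves the drawn distribution conditioned on the
    base identity. When every draw fails (no suitable base within the
    distribution's support), positions are scanned outward from
    ``scan_center`` and the nearest suitable one is taken, so the requested
    base identity is honoured whenever a suitable position exists nearby;
    otherwise the last draw is kept.
    """
    pos = draw()
    for _ in range(tries):
        if (base_at(pos) == target) == want:
            return pos
        pos = draw()
    if scan_center is not None:
        for d in range(scan_limit + 1):
            for q in (scan_center + d, scan_center - d):
                b = base_at(q)
                if b and (b == target) == want:
                    return q
    return pos


def simulate_biogenesis(cfg: SimConfig, gb: GenomeBuild) -> SimTruth:
    """Draw triggers, cleavage products, phased fragments and negatives."""
    rng = _rng(cfg, 2)
    yseq = gb.contigs["Y_like"]
    xseq = gb.contigs["X_like"]
    species: list[SimSpecies] = []
    cut_sites: list[CutSite] = []
    fragments: list[tuple[str, int, int, bool]] = []
    counter = [0]

    def add(cls, chrom, strand, five, length, seq, molecules):
        counter[0] += 1
        sp = SimSpecies(f"sp{counter[0]:05d}", cls, chrom, strand, five, length, seq,
                        max(1, int(molecules)))
        species.append(sp)
        return sp

    # --- triggers and the cut sites their slicing creates -------------------
    # Cleavage products start in the last `junction_window` nt of the
    # insertion so that they qualify as pre-pre-piRNAs at the locus junction.
    win = cfg.junction_window
    lo, hi = gb.junction - win, gb.junction - 10
    if hi - lo < cfg.trigger_pool_size:
        raise ValueError("insertion_too_short")
    cut_positions = np.sort(rng.choice(np.arange(lo, hi), size=cfg.trigger_pool_size,
                                       replace=False))
    # piRNA pools are strongly skewed; the mean stays at trigger_abundance
    rel_abund = rng.lognormal(mean=-cfg.trigger_skew_sigma**2 / 2,
                              sigma=cfg.trigger_skew_sigma,
                              size=len(cut_positions))
    phased_acc: dict[tuple[int, int], int] = {}
    for p, rel in zip(cut_positions, rel_abund):
        p = int(p)
        glen = int(rng.integers(cfg.pirna_len_min, cfg.pirna_len_max + 1))
        g = p + 9  # trigger minus-strand 5' end: slicing between t10 and t11
        trig_seq = revcomp(yseq[g - glen + 1 : g + 1])
        trig = add("trigger", "Y_like", "-", g, glen, trig_seq,
                   rng.poisson(cfg.trigger_abundance * rel))
        cut_sites.append(CutSite(trig.species_id, p))
        length = gb.precursor_end - p
        # slicing and fragmentation yields scale with the trigger's abundance
        add("prepre_long", "Y_like", "+", p, length, "",
            rng.poisson(cfg.prepre_molecules * rel))

        # --- 5'-to-3' phased fragmentation of the cleavage product ---------
        # the first fragment inherits the slice-defined 5' end; the 1U bias
        # conditions each fragment's length, i.e. where the next cut lands
        s = p
        while s + cfg.pirna_len_max < gb.precursor_end:
            if cfg.u1_bias is None:
                L = int(round(rng.normal(cfg.phase_length_mean, cfg.phase_length_sd)))
            else:
                want_u = bool(rng.random() < cfg.u1_bias)
                L = _pick_position_with_base(
                    rng,
                    draw=lambda: int(round(rng.normal(cfg.phase_length_mean,
                                                      cfg.phase_length_sd))),
                    base_at=lambda q: yseq[s + q] if 10 < q else "",
                    want=want_u,
                    target="T",
                    scan_center=int(round(cfg.phase_length_mean)),
                )
            L = max(L, 10)
            emitted = cfg.pirna_len_min <= L <= cfg.pirna_len_max
            fragments.append((trig.species_id, s, L, emitted))
            if emitted:
                phased_acc[(s, L)] = phased_acc.get((s, L), 0) + max(
                    1, rng.poisson(cfg.phased_abundance * rel))
            s += L

    for (s, L), mol in sorted(phased_acc.items()):
        add("phased", "Y_like", "+", s, L, yseq[s : s + L], mol)

    # --- maternally deposited mature locus piRNAs (XXY mode) ---------------
    if cfg.xxy_mode:
        for _ in range(cfg.deposited_pool_size):
            L = int(rng.integers(cfg.pirna_len_min, cfg.pirna_len_max + 1))
            if cfg.u1_bias is None:
                s = int(rng.integers(gb.locus.start, gb.locus.end - L))
            else:
                want_u = bool(rng.random() < cfg.u1_bias)
                s = _pick_position_with_base(
                    rng,
                    draw=lambda: int(rng.integers(gb.locus.start, gb.locus.end - L)),
                    base_at=lambda q: yseq[q],
                    want=want_u,
                    target="T",
                )
            add("deposited", "Y_like", "+", s, L, yseq[s : s + L],
                rng.poisson(cfg.deposited_abundance))

    # --- ping-pong responders from the sense Ste-like transcript -----------
    for _ in range(cfg.responder_pool_size):
        L = int(rng.integers(cfg.pirna_len_min, cfg.pirna_len_max + 1))
        want_a = bool(rng.random() < cfg.a10_bias)
        s = _pick_position_with_base(
            rng,
            draw=lambda: int(rng.integers(gb.ste_gene.start, gb.ste_gene.end - L)),
            base_at=lambda q: xseq[q + 9],
            want=want_a,
            target="A",
        )
        add("responder", "X_like", "+", s, L, xseq[s : s + L],
            rng.poisson(cfg.responder_abundance))

    # --- uniform decay negatives from the genic control loci ---------------
    for iv in gb.genic_loci:
        for _ in range(cfg.decay_small_per_locus):
            L = int(rng.integers(18, 30))
            start = int(rng.integers(iv.start, iv.end - L))
            strand = "+" if rng.random() < 0.5 else "-"
            seq = xseq[start : start + L]
            if strand == "-":
                seq = revcomp(seq)
            five = start if strand == "+" else start + L - 1
            add("decay", "X_like", strand, five, L, seq,
                rng.poisson(cfg.decay_small_abundance))
        for _ in range(cfg.decay_long_per_locus):
            start = int(rng.integers(iv.start, iv.end - 200))
            L = int(rng.integers(200, iv.end - start + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            five = start if strand == "+" else start + L - 1
            add("decay_long", "X_like", strand, five, L, "",
                rng.poisson(cfg.decay_long_abundance))

    # --- rRNA fragments and spike-ins --------------------------------------
    for name, ref in gb.rrna.items():
        for _ in range(cfg.rrna_fragments):
            L = int(rng.integers(18, min(30, len(ref) + 1)))
            start = int(rng.integers(0, len(ref) - L + 1))
            add("rrna", name, "+", start, L, ref[start : start + L],
                rng.poisson(cfg.rrna_abundance))
    for name, seq in gb.spikes.items():
        add("spikein", name, "+", 0, len(seq), seq, cfg.spike_molecules_per_species)

    log.info("simulated %d species, %d cut sites, %d fragments",
             len(species), len(cut_sites), len(fragments))
    return SimTruth(species=species, cut_sites=cut_sites, fragments=fragments, seed=cfg.seed)


@dataclass
class ReadSet:
    """Emitted reads for one replicate library, with a per-read truth table."""

    replicate: int
    small_reads: list[RawRead]
    long_pairs: list[tuple[RawRead, RawRead]]
    read_truth: pd.DataFrame  # read_id, cls, species_id, molecule_id
    small_species_reads: dict[str, int] = field(default_factory=dict)
    long_species_reads: dict[str, int] = field(default_factory=dict)


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hit:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def _umi_block(rng: np.random.Generator, spacers: tuple[str, str]) -> tuple[str, str]:
    umi = _random_seq(rng, 9)
    block = umi[0:3] + spacers[0] + umi[3:6] + spacers[1] + umi[6:9]
    return block, umi


def emit_reads(truth: SimTruth, cfg: SimConfig, gb: GenomeBuild, replicate: int = 0) -> ReadSet:
    """Sample one replicate library from the truth molecule counts.

    Read counts per species are a multinomial draw at the configured depth
    with probabilities proportional to molecule counts; every sampled read is
    a distinct molecule with independent random UMIs, and PCR duplicates
    (identical copies sharing the UMI pair) are added at
    ``pcr_duplicate_rate``. Substitution errors are applied across the whole
    read. Long RNAs are emitted as pairs: read 1 anchored at the species 5'
    end behind a 15-nt degenerate block, read 2 at the far end of a sequenced
    fragment of 200-400 nt.
    """
    rng = _rng(cfg, 3, replicate)
    small = truth.by_class(*SMALL_CLASSES)
    longs = truth.by_class(*LONG_CLASSES)

    small_reads: list[RawRead] = []
    long_pairs: list[tuple[RawRead, RawRead]] = []
    rows = []

    mols = np.array([sp.molecules for sp in small], dtype=float)
    counts = rng.multinomial(cfg.small_depth, mols / mols.sum()) if small else []
    small_species_reads: dict[str, int] = {}
    idx = 0
    for sp, c in zip(small, counts):
        if c:
            small_species_reads[sp.species_id] = int(c)
        for _ in range(int(c)):
            idx += 1
            variant = "A" if rng.random() < 0.5 else "B"
            block5, _ = _umi_block(rng, SPACERS5[variant])
            block3, _ = _umi_block(rng, SPACERS3)
            seq = block5 + sp.sequence + block3 + ADAPTER3
            seq = _apply_errors(rng, seq, cfg.sequencing_error_rate)[: cfg.read_length]
            copies = 2 if rng.random() < cfg.pcr_duplicate_rate else 1
            molecule = f"sm{replicate}_{idx:06d}"
            for k in range(copies):
                rid = molecule + (f"_dup{k}" if k else "")
                small_reads.append(RawRead(rid, seq))
                rows.append((rid, sp.cls, sp.species_id, molecule))

    mols_l = np.array([sp.molecules for sp in longs], dtype=float)
    counts_l = rng.multinomial(cfg.long_depth, mols_l / mols_l.sum()) if longs else []
    long_species_reads: dict[str, int] = {}
    core = cfg.long_core_length
    idx = 0
    for sp, c in zip(longs, counts_l):
        if c:
            long_species_reads[sp.species_id] = int(c)
        contig = gb.contigs[sp.chrom]
        for _ in range(int(c)):
            idx += 1
            frag = int(rng.integers(200, min(400, sp.length) + 1))
            if sp.strand == "+":
                r1_core = contig[sp.five_prime : sp.five_prime + core]
                far = sp.five_prime + frag
                r2 = revcomp(contig[far - core : far])
            else:
                r1_core = revcomp(contig[sp.five_prime - core + 1 : sp.five_prime + 1])
                far = sp.five_prime - frag + 1
                r2 = contig[far : far + core]
            r1 = _random_seq(rng, 15) + r1_core
            r1 = _apply_errors(rng, r1, cfg.sequencing_error_rate)[: cfg.read_length]
            r2 = _apply_errors(rng, r2, cfg.sequencing_error_rate)
            rid = f"lr{replicate}_{idx:06d}"
            long_pairs.append((RawRead(rid + "/1", r1), RawRead(rid + "/2", r2)))
            rows.append((rid, sp.cls, sp.species_id, rid))

    read_truth = pd.DataFrame(rows, columns=["read_id", "cls", "species_id", "molecule_id"])
    return ReadSet(replicate, small_reads, long_pairs, read_truth,
                   small_species_reads, long_species_reads)


def simulate(cfg: SimConfig) -> tuple[GenomeBuild, SimTruth, list[ReadSet]]:
    """Genome + biogenesis + one read set per replicate (convenience)."""
    gb = build_genome(cfg)
    truth = simulate_biogenesis(cfg, gb)
    n_rep = max(cfg.n_small_replicates, cfg.n_long_replicates)
    readsets = [emit_reads(truth, cfg, gb, replicate=r) for r in range(n_rep)]
    return gb, truth, readsets
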