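"""Run orchestration: simulate -> preprocess -> map -> signatures -> report.

Each stage is a plain function over in-memory objects so the library can be
driven without the command line; :func:`run_pipeline` wires them together,
writes flat TSV intermediates plus a JSON report into one directory per run,
and maintains a MANIFEST of completed stages. Identical configuration and
seed give identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .align import GenomeIndex, align_species
from .annotate import (FeatureInterval, MappedSpecies, length_profile,
                       nt_composition, weight_alignments, write_bed)
from .preprocess import (RawRead, SpeciesCount, SpikeCalibration,
                         absolute_abundance, classify_reads, deduplicate,
                         parse_reads, write_fasta, write_fastq)
from .signatures import (End5, LongRnaSpecies, autocorrelate, estimate_period,
                         identify_prepre, merge_long_rnas, overlap_spectrum,
                         phasing_metaplot, z_score)
from .simulate import SimConfig, build_genome, emit_reads, simulate_biogenesis

log = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "map", "signatures", "abundance")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Schema-validated run configuration (unknown keys are rejected)."""

    outdir: str = "pirnaphase_run"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    sim: SimConfig = field(default_factory=SimConfig)
    max_mm: int = 1
    min_prefix: int = 18
    max_tail: int = 4
    junction_window: int = 100
    min_long_len: int = 200
    metaplot_len: int = 150
    max_lag: int = 50
    period_range: tuple[int, int] = (15, 40)
    spectrum_weighting: str = "read"

    def __post_init__(self):
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if isinstance(self.sim, dict):
            self.sim = SimConfig(**self.sim)
        self.sim = dataclasses.replace(self.sim, seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        if "period_range" in data:
            data["period_range"] = tuple(data["period_range"])
        return cls(**data)


@dataclass
class PreprocessResult:
    species: list[SpeciesCount]          # retained, post-dedup
    spike_counts: dict[str, int]
    n_reads: int
    n_parsed: int
    n_rrna_species: int
    rejections: dict[str, int]


def preprocess_small(
    reads: Sequence[RawRead],
    rrna_refs: dict[str, str],
    spike_refs: dict[str, str] | None = None,
) -> PreprocessResult:
    """Adapter/UMI parsing, deduplication and reference classification."""
    parsed, rejections = parse_reads(reads)
    species = deduplicate(parsed)
    classified = classify_reads(species, rrna_refs, spike_refs)
    return PreprocessResult(
        species=classified.retained,
        spike_counts=classified.spikein,
        n_reads=len(reads),
        n_parsed=len(parsed),
        n_rrna_species=len(classified.rrna),
        rejections=dict(rejections),
    )


def map_small(
    species: Sequence[SpeciesCount],
    genome: GenomeIndex,
    annotation: Sequence[FeatureInterval],
    max_mm: int = 1,
    min_prefix: int = 18,
    max_tail: int = 4,
    policy: str = "fractional",
) -> list[MappedSpecies]:
    """Place species on the reference and attach feature labels/weights."""
    alns = align_species([sp.sequence for sp in species], genome,
                         max_mm=max_mm, min_prefix=min_prefix, max_tail=max_tail)
    mapped: list[MappedSpecies] = []
    for sp in species:
        for aln, iv, w in weight_alignments(alns[sp.sequence], annotation, policy=policy):
            if w == 0:
                continue
            mapped.append(MappedSpecies(
                sequence=sp.sequence, count=sp.count, alignment=aln,
                feature=iv.name if iv else "none",
                feature_class=iv.feature_class if iv else "none",
                weight=w,
            ))
    return mapped


def process_long(
    pairs: Sequence[tuple[RawRead, RawRead]],
    genome: GenomeIndex,
    max_mm: int = 1,
    umi_block: int = 15,
) -> list[LongRnaSpecies]:
    """5'-monophosphorylated long-RNA reads to merged 5'-end species.

    Read 1 carries a 15-nt degenerate 5' block followed by the RNA 5' end;
    read 2 is the reverse-complemented far end of the sequenced fragment.
    Only the degenerate block is removed (no 3' UMI in these libraries).
    Reads whose cores do not align uniquely are dropped. Footprints sharing
    a 5' end merge into one species.
    """
    core_counts: dict[tuple[str, str], int] = defaultdict(int)
    for r1, r2 in pairs:
        core_counts[(r1.sequence[umi_block:], r2.sequence)] += 1
    distinct = sorted({c for pair in core_counts for c in pair})
    alns = align_species(distinct, genome, max_mm=max_mm, max_tail=0)

    records = []
    dropped = 0
    for (c1, c2), n in core_counts.items():
        a1 = [a for a in alns[c1] if a.mismatches == min(x.mismatches for x in alns[c1])] if alns[c1] else []
        a2 = [a for a in alns[c2] if a.mismatches == min(x.mismatches for x in alns[c2])] if alns[c2] else []
        if len(a1) != 1 or len(a2) != 1 or a1[0].chrom != a2[0].chrom:
            dropped += n
            continue
        f1, f2 = a1[0], a2[0]
        start, end = min(f1.start, f2.start), max(f1.end, f2.end)
        records.append((f1.chrom, f1.strand, start, end, n))
    if dropped:
        log.info("process_long: dropped %d reads without a unique pair placement", dropped)
    return merge_long_rnas(records)


def _feature_intervals(annotation: Sequence[FeatureInterval]) -> dict[str, list[FeatureInterval]]:
    by_class: dict[str, list[FeatureInterval]] = defaultdict(list)
    for iv in annotation:
        by_class[iv.feature_class].append(iv)
    return by_class


def _ends_for(mapped: Sequence[MappedSpecies], feature_class: str,
              strand: str | None = None) -> list[End5]:
    return [
        End5(sp.chrom, sp.strand, sp.five_prime, sp.count * sp.weight)
        for sp in mapped
        if sp.feature_class == feature_class and (strand is None or sp.strand == strand)
    ]


def _longs_in(longs: Sequence[LongRnaSpecies], iv: FeatureInterval) -> list[LongRnaSpecies]:
    return [sp for sp in longs
            if sp.chrom == iv.chrom and iv.start <= sp.five_prime < iv.end]


def signature_report(
    mapped_sets: Sequence[Sequence[MappedSpecies]],
    long_sets: Sequence[Sequence[LongRnaSpecies]],
    annotation: Sequence[FeatureInterval],
    junction_window: int = 100,
    min_long_len: int = 200,
    metaplot_len: int = 150,
    max_lag: int = 50,
    period_range: tuple[int, int] = (15, 40),
    weighting: str = "read",
) -> dict:
    """Cleavage/phasing signature summary over all dataset permutations.

    For every (small-RNA dataset, long-RNA dataset) permutation: pre-pre-
    piRNA calls at the insertion/locus junction, the trigger-vs-pre-pre
    overlap spectrum with Z10, and a pooled genic-decay negative spectrum.
    The phasing metaplot pools permutations; its median profile feeds the
    autocorrelation and period estimate. Both the mean of per-permutation z
    values and the z of the mean spectrum are reported.
    """
    by_class = _feature_intervals(annotation)
    locus = by_class["pirna_locus"][0]
    insertion = by_class["insertion"][0] if by_class["insertion"] else None
    genic = by_class.get("genic", [])

    report: dict = {"permutations": []}
    spectra, zs, pvals, z_negs = [], [], [], []
    prepre_sets, pirna_sets = [], []
    for j, longs in enumerate(long_sets):
        calls = identify_prepre(longs, locus, insertion,
                                window=junction_window, min_len=min_long_len)
        prepre_sets.append(calls)
    for i, mapped in enumerate(mapped_sets):
        pirna_sets.append(_ends_for(mapped, "pirna_locus", strand=locus.strand))
    for i, mapped in enumerate(mapped_sets):
        trigger_ends = _ends_for(mapped, "insertion",
                                 strand="-" if locus.strand == "+" else "+")
        genic_small = _ends_for(mapped, "genic")
        for j, longs in enumerate(long_sets):
            calls = prepre_sets[j]
            spec = overlap_spectrum([c.species for c in calls], trigger_ends,
                                    weighting=weighting)
            z, p = z_score(spec)
            spectra.append(spec.counts)
            zs.append(z)
            pvals.append(p)
            genic_longs: list[LongRnaSpecies] = []
            for iv in genic:
                genic_longs.extend(sp for sp in _longs_in(longs, iv)
                                   if sp.length >= min_long_len)
            neg_spec = overlap_spectrum(genic_longs, genic_small, weighting=weighting)
            try:
                z_neg, _ = z_score(neg_spec)
            except Exception:
                z_neg = float("nan")
            z_negs.append(z_neg)
            report["permutations"].append({
                "small_dataset": i, "long_dataset": j,
                "n_prepre": len(calls), "z10": z, "p": p, "z10_genic": z_neg,
                "spectrum": [float(v) for v in spec.counts],
            })

    mean_spectrum = np.mean(spectra, axis=0)
    from .signatures import OverlapSpectrum
    z_mean_spec, p_mean_spec = z_score(OverlapSpectrum(mean_spectrum))
    report["z10_mean_of_permutations"] = float(np.mean(zs))
    report["p_mean_of_permutations"] = float(np.mean(pvals))
    report["z10_of_mean_spectrum"] = float(z_mean_spec)
    report["p_of_mean_spectrum"] = float(p_mean_spec)
    report["z10_genic_mean"] = float(np.nanmean(z_negs)) if z_negs else float("nan")
    report["mean_spectrum"] = [float(v) for v in mean_spectrum]
    report["n_prepre_total"] = int(sum(len(s) for s in prepre_sets))

    profile = phasing_metaplot(prepre_sets, pirna_sets, L=metaplot_len,
                               weighting=weighting)
    report["metaplot_median"] = [float(v) for v in profile.median]
    report["metaplot_iqr"] = [float(v) for v in profile.iqr]
    report["metaplot_all_zero"] = bool(profile.all_zero)
    if not profile.all_zero:
        ac = autocorrelate(profile.median, max_lag=max_lag)
        est = estimate_period(ac, search_range=period_range)
        report["autocorrelation"] = [None if not np.isfinite(v) else float(v) for v in ac]
        report["period_nt"] = int(est.period)
        report["period_r"] = float(est.r_peak)
        report["period_harmonic_ambiguous"] = bool(est.harmonic_ambiguous)
    return report


def composition_report(mapped_sets: Sequence[Sequence[MappedSpecies]],
                       locus_name: str) -> dict:
    """Per-replicate 1U / 10A composition of locus-derived piRNAs."""
    u1, a10, bg_u, bg_a = [], [], [], []
    for mapped in mapped_sets:
        locus_sp = [sp for sp in mapped if sp.feature == locus_name]
        if not locus_sp:
            continue
        comp = nt_composition(locus_sp, positions=(1, 10))
        u1.append(comp.position_fractions[1].get("T", 0.0))
        a10.append(comp.position_fractions[10].get("A", 0.0))
        bg_u.append(comp.background.get("T", 0.0))
        bg_a.append(comp.background.get("A", 0.0))
    def _ms(v):
        return {"mean": float(np.mean(v)), "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0}
    return {"u1": _ms(u1), "a10": _ms(a10), "background_u": _ms(bg_u),
            "background_a": _ms(bg_a)}


def abundance_report(
    pre_results: Sequence[PreprocessResult],
    mapped_sets: Sequence[Sequence[MappedSpecies]],
    locus_name: str,
    molecules_per_species: float,
    total_rna_pg: float,
) -> dict:
    """Spike-calibrated absolute abundance of locus piRNAs per replicate."""
    per_rep = []
    for pre, mapped in zip(pre_results, mapped_sets):
        calib = SpikeCalibration(
            per_species_read_counts=tuple(pre.spike_counts.values()),
            molecules_per_species=molecules_per_species,
            total_rna_pg=total_rna_pg,
        )
        target = sum(sp.count * sp.weight for sp in mapped if sp.feature == locus_name)
        per_rep.append(absolute_abundance(target, calib))
    return {
        "per_replicate": [float(v) for v in per_rep],
        "mean": float(np.mean(per_rep)),
        "sd": float(np.std(per_rep, ddof=1)) if len(per_rep) > 1 else 0.0,
    }


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the enabled stages in order and write the run directory."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    report: dict = {"software": "pirnaphase", "version": __version__,
                    "config": _config_echo(cfg)}

    def done(stage: str, *files: str):
        manifest.append(stage + ("\t" + "\t".join(files) if files else ""))
        (outdir / "MANIFEST").write_text("\n".join(manifest) + "\n")

    if not cfg.stages:
        (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        done("report", "report.json")
        return report

    gb = truth = readsets = None
    pre_results: list[PreprocessResult] = []
    mapped_sets: list[list[MappedSpecies]] = []
    long_sets: list[list[LongRnaSpecies]] = []

    stage = "simulate"
    try:
        if "simulate" in cfg.stages:
            gb = build_genome(cfg.sim)
            truth = simulate_biogenesis(cfg.sim, gb)
            n_rep = max(cfg.sim.n_small_replicates, cfg.sim.n_long_replicates)
            readsets = [emit_reads(truth, cfg.sim, gb, replicate=r) for r in range(n_rep)]
            write_fasta(gb.contigs, outdir / "genome.fa")
            write_fasta(gb.rrna, outdir / "rrna.fa")
            write_fasta(gb.spikes, outdir / "spikes.fa")
            write_bed(gb.annotation, outdir / "annotation.bed")
            truth.species_table().to_csv(outdir / "truth_species.tsv", sep="\t", index=False)
            for rs in readsets:
                write_fastq(rs.small_reads, outdir / f"small_r{rs.replicate}.fastq")
                write_fastq([r for p in rs.long_pairs for r in p],
                            outdir / f"long_r{rs.replicate}.fastq")
                rs.read_truth.to_csv(outdir / f"truth_reads_r{rs.replicate}.tsv",
                                     sep="\t", index=False)
            report["simulate"] = {
                "n_species": len(truth.species),
                "n_cut_sites": len(truth.cut_sites),
                "molecules_by_class": truth.molecules_by_class(),
            }
            done("simulate", "genome.fa", "annotation.bed", "truth_species.tsv")

        stage = "preprocess"
        if "preprocess" in cfg.stages:
            if readsets is None:
                raise ValueError("preprocess requires the simulate stage in this run mode")
            for rs in readsets[: cfg.sim.n_small_replicates]:
                pre = preprocess_small(rs.small_reads, gb.rrna, gb.spikes)
                pre_results.append(pre)
                pd.DataFrame([(s.sequence, s.count) for s in pre.species],
                             columns=["sequence", "count"]).to_csv(
                    outdir / f"species_r{rs.replicate}.tsv", sep="\t", index=False)
            report["preprocess"] = [
                {"n_reads": p.n_reads, "n_parsed": p.n_parsed,
                 "n_species": len(p.species), "spike_counts": p.spike_counts,
                 "rejections": p.rejections}
                for p in pre_results
            ]
            done("preprocess", *[f"species_r{i}.tsv" for i in range(len(pre_results))])

        stage = "map"
        if "map" in cfg.stages:
            gi = GenomeIndex(gb.contigs)
            for i, pre in enumerate(pre_results):
                mapped = map_small(pre.species, gi, gb.annotation,
                                   max_mm=cfg.max_mm, min_prefix=cfg.min_prefix,
                                   max_tail=cfg.max_tail)
                mapped_sets.append(mapped)
                _mapped_table(mapped).to_csv(outdir / f"mapped_r{i}.tsv", sep="\t", index=False)
            for rs in readsets[: cfg.sim.n_long_replicates]:
                longs = process_long(rs.long_pairs, gi, max_mm=cfg.max_mm)
                long_sets.append(longs)
                _long_table(longs).to_csv(outdir / f"longs_r{rs.replicate}.tsv",
                                          sep="\t", index=False)
            profiles = {}
            if mapped_sets:
                for name in sorted({m.feature for m in mapped_sets[0]} - {"none"}):
                    prof = length_profile(mapped_sets[0], feature=name,
                                          length_range=(18, 32))
                    profiles[name] = {int(k): float(v) for k, v in prof.items() if v}
            report["map"] = {
                "mapped_species": [len(m) for m in mapped_sets],
                "long_species": [len(l) for l in long_sets],
                "length_profiles": profiles,
            }
            done("map", *[f"mapped_r{i}.tsv" for i in range(len(mapped_sets))])

        stage = "signatures"
        if "signatures" in cfg.stages:
            report["signatures"] = signature_report(
                mapped_sets, long_sets, gb.annotation,
                junction_window=cfg.junction_window, min_long_len=cfg.min_long_len,
                metaplot_len=cfg.metaplot_len, max_lag=cfg.max_lag,
                period_range=cfg.period_range, weighting=cfg.spectrum_weighting)
            report["composition"] = composition_report(mapped_sets, gb.locus.name)
            done("signatures")

        stage = "abundance"
        if "abundance" in cfg.stages:
            report["abundance"] = abundance_report(
                pre_results, mapped_sets, gb.locus.name,
                molecules_per_species=cfg.sim.spike_molecules_per_species,
                total_rna_pg=cfg.sim.total_rna_pg)
            report["abundance"]["true_locus_molecules"] = int(sum(
                sp.molecules for sp in truth.by_class("phased", "deposited")))
            done("abundance")
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    done("report", "report.json")
    return report


def _config_echo(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["stages"] = list(cfg.stages)
    d["period_range"] = list(cfg.period_range)
    return d


def _mapped_table(mapped: Sequence[MappedSpecies]) -> pd.DataFrame:
    return pd.DataFrame(
        [(m.sequence, m.count, m.chrom, m.alignment.start, m.alignment.end,
          m.strand, m.alignment.mismatches, m.alignment.tail_length,
          m.feature, m.feature_class, m.weight) for m in mapped],
        columns=["sequence", "count", "chrom", "start", "end", "strand",
                 "mismatches", "tail", "feature", "feature_class", "weight"])


def _long_table(longs: Sequence[LongRnaSpecies]) -> pd.DataFrame:
    return pd.DataFrame(
        [(l.chrom, l.strand, l.five_prime, l.start, l.end, l.read_count)
         for l in longs],
        columns=["chrom", "strand", "five_prime", "start", "end", "read_count"])
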