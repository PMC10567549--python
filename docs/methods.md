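# Methods

## Scope and model

`pirnaphase` analyses two kinds of libraries from an animal germline:
small-RNA sequencing (piRNA-sized reads cloned with split UMIs and spike-in
oligos) and 5′-monophosphorylated long-RNA sequencing (a degradome-style
library that captures the 5′ ends of cleavage products ≥ 200 nt). Its core
statistics diagnose two linked biogenesis events:

1. **piRNA-directed slicing.** PIWI-clade Argonautes cut their target between
   the nucleotides paired to guide positions 10 and 11, so the 3′ cleavage
   product's first nucleotide sits exactly opposite guide position 10. For a
   plus-strand 5′ end at *P* and a minus-strand 5′ end at *G* the overlap
   offset is *o* = *G* − *P* + 1; slicing enriches *o* = 10. The overlap
   spectrum counts weighted 5′–5′ pairs at offsets 0–20 and summarises the
   enrichment as Z₁₀ = (c₁₀ − mean(bg)) / sd(bg), where the background is
   every displayed offset except 10, sd is the population standard
   deviation, and the P value is the two-sided standard-normal tail.
   Population sd keeps Z exactly invariant under rescaling all counts; the
   sample-sd alternative is one `ddof` change away in `z_score`.

2. **Phased (Zucchini-dependent) fragmentation.** A cleavage product — a
   pre-pre-piRNA — is fragmented 5′→3′ into tail-to-head pre-piRNAs of
   ~25–26 nt with a strong preference for uridine at each new 5′ end. The
   package identifies candidate pre-pre-piRNAs among merged long-RNA 5′-end
   species (length ≥ 200 nt, footprint crossing the insertion/locus
   junction, 5′ end within ±100 nt of the junction), plots piRNA 5′-end
   density along them (metaplot), and estimates the phasing period as the
   peak lag of the Pearson autocorrelation of the median profile, searched
   in 15–40 nt. A peak whose half- or third-lag carries comparable
   correlation outside the search range is flagged as a possible harmonic,
   never silently reinterpreted.

Composition statistics (1U at position 1 for phased loading, 10A at
position 10 for ping-pong responders) are read-count-weighted fractions at
5′-anchored positions against an all-position background.

## Library grammar and quantification

Small-RNA reads are parsed as: 15-nt degenerate 5′ block (`NNN CGA NNN TCA
NNN` or `NNN ATC NNN AGT NNN`), insert, 15-nt degenerate 3′ block (`NNN GTC
NNN TAG NNN`), constant 3′ adapter `TGGAATTCTCGGGTGCCAAGG`. The constant
adapter is located by the rightmost exact match of its first 10 nt (a chance
hit inside the insert cannot shadow the true adapter, which is always last);
the four spacer triplets are validated allowing ≤ 1 mismatch in total,
which retains reads carrying a single sequencing error in a spacer.
PCR duplicates collapse on the (insert, UMI5, UMI3) key *before* alignment;
the species count is the number of distinct UMI pairs per insert. Species
equal to one of six equimolar synthetic spike-in oligos are tallied per
oligo; species matching an rRNA reference on either strand with ≤ 1
mismatch are removed; the rest are retained.

Absolute quantification converts read counts to molecules via
reads-per-molecule = median(six spike counts) / molecules-per-species. The
median tolerates one failed ligation among the oligos; the spiked molar
amount and the total-RNA mass are configuration inputs
(`spike_molecules_per_species`, `total_rna_pg`), and abundances are reported
per 10 pg total RNA.

Long-RNA read 1 carries only a 15-nt degenerate 5′ block (no 3′ UMI); the
block is removed and the following bases anchor the RNA's 5′ end. Read 2
marks the far end of the sequenced fragment; both mates are aligned and
reads sharing a 5′ end merge into one species whose extent is the union of
footprints. The ≥ 200 nt filter therefore operates on observed fragment
extents, as it would on real libraries.

## Alignment

References here are small (kilobases), so the aligner scans every offset of
every contig with a vectorised mismatch count: all placements with ≤
`max_mm` (default 1) mismatches are reported; if the full length is
unmappable, the smallest 3′ trim (≤ `max_tail` = 4 nt, matched prefix ≥
`min_prefix` = 18 nt) that rescues a placement is applied and recorded as a
non-templated tail. Note the interaction between tails and mismatches: a
3-nt non-templated tail under `max_mm = 1` is reported as a 2-nt trim plus
one mismatch, because the smallest rescuing trim wins; under `max_mm = 0`
it is reported as a 3-nt tail. `N` in a read matches nothing. Coordinates
are 0-based half-open; the 5′ end of a minus-strand alignment is `end − 1`.
Multi-mappers are resolved by fewest mismatches, then best feature class
(piRNA locus > insertion > transposon > genic), then fractional 1/n weight
(a count-once `unique` policy is available); total assigned weight per
species is exactly its read count.

## The generator

The simulator embodies the biogenesis model so that every pipeline stage has
a known truth. The reference has an X-like contig (a 500-nt Ste-like gene
plus three 1.5-kb genic control loci) and a Y-like contig in which an
800-nt transposon-like insertion precedes four tandem repeats that are the
reverse complement of the Ste-like gene mutated to 90% identity — so the
plus-strand precursor, transcribed from a start inside the insertion, is
antisense to the Ste-like mRNA. Defaults (units; rationale):

| parameter | default | meaning |
|---|---|---|
| `trigger_pool_size` | 30 | distinct trigger piRNA species, cut sites in the last 100 nt of the insertion |
| `trigger_abundance` | 120 molecules | mean trigger abundance; per-species log-normal (σ = 1.0) skew, as in real piRNA pools |
| `prepre_molecules`, `phased_abundance` | 20, 8 molecules | slicing/fragmentation yields, scaled by each trigger's relative abundance (fragments derive from those molecules) |
| `phase_length_mean`, `phase_length_sd` | 26, 1 nt | phased fragment length |
| `u1_bias` | 0.77 | probability a phased fragment starts with U |
| `pirna_len_min/max` | 23–29 nt | sequencing gel window for piRNAs |
| `small_depth`, `long_depth` | 50 000, 6 000 reads | per-replicate depths; 2 + 2 replicates |
| `spike_molecules_per_species`, `total_rna_pg` | 500, 10 pg | calibration ground truth |
| `sequencing_error_rate`, `pcr_duplicate_rate` | 0.001, 0.15 | read-level noise |

Each trigger (minus-strand 5′ end *G*) creates a cut at *P* = *G* − 9 (the
t10/t11 rule), a pre-pre-piRNA species spanning from *P* to the precursor
end, and a 5′→3′ fragment walk. The first fragment inherits the
slice-defined 5′ end; for every subsequent fragment a Bernoulli(`u1_bias`)
draw decides whether its first base is U, realised by rejection-sampling the
length draw (which preserves the Normal length distribution and hence the
period) with a nearest-position scan fallback when the draw's support holds
no suitable base. This construction makes the *realised* 1U probability
equal `u1_bias` (measured 0.765 at 0.77 — the small deficit comes from
fragments whose fallback length leaves the 23–29 nt window), which is what
composition recovery tests require. `u1_bias=None` disables the
conditioning entirely; with `phase_length_sd = 0` that yields exactly
constant fragment lengths. Ping-pong responders (off by default) sample 5′
ends on the sense Ste-like transcript with position-10 A probability
`a10_bias` by the same rejection scheme; `xxy_mode` deposits mature
locus-derived piRNAs directly, emulating a mother who carries the locus.
Genic control loci shed uniform decay fragments on both strands in both
size classes as negatives. Reads are wrapped in the adapter/UMI grammar
with independent random UMIs; read counts per species are one multinomial
draw at the configured depth, PCR duplicates share the UMI pair, and the
per-read truth table records class, species and molecule identity.

All randomness flows from one seed through per-stage `SeedSequence`
substreams, so genome, truth and each replicate library are independently
reproducible.

## What the simulation does and does not show

The generator reproduces the *geometry* and *statistics* of the mechanism:
offset-10 enrichment of cleavage products against triggers, 1U-biased
~26-nt phasing, flat spectra for uniform decay, and spike-calibrated
recovery of absolute molecule counts. It does not model expression dynamics
across germline stages, transcription, RNA secondary structure, ligation
bias beyond the UMI scheme, or base-quality-dependent errors. Passing tests
therefore validate the analysis code and the detectability of the
signatures under realistic noise — not any property of a particular real
dataset.

A known limitation of the full-window metaplot: with ~30 cut sites inside
one 100-nt window, the phased lattices of different precursors overlap in
every metaplot window, and the per-RNA-normalised average can be dominated
by cut-spacing structure rather than the phasing period for some seeds.
Parameter-recovery tests for the period therefore resolve fragments to
their own precursor via the truth table (a resolution real data does not
offer); the pipeline-level estimate is reported as measured. Period
estimates from the autocorrelation peak are reliable to ±1 nt when a single
lattice dominates.

## Numerical choices

* Z₁₀ uses the population sd of the 20 background offsets; a constant
  spectrum returns z = 0, p = 1; a zero-spread background with a deviating
  focus raises `degenerate_background`.
* Overlap spectra default to read-count weighting (products of weights);
  species weighting is available. Both are checked against O(n²)
  enumeration.
* Metaplot vectors are normalised per RNA before averaging so one abundant
  precursor cannot dominate; median and IQR are positionwise across dataset
  permutations. Autocorrelation is Pearson on overlapping windows (not
  circular/FFT), with zero-variance windows reported as missing; period
  ties break toward the smaller lag.
* Mann–Whitney comparisons use the exact null for groups of ≤ 8 (typical
  library group sizes are 2–3) and the normal approximation above.
* ΔΔCt: ΔCt = mean Ct(target) − mean Ct(reference) per condition, σ
  propagated in quadrature at each subtraction (sample sd, ddof = 1); fold
  = 2^(−ΔΔCt), returned without σ when replicates are insufficient.
* Dedup happens before alignment (keyed on sequence + UMIs, not position),
  matching the library protocol's ordering.

## Problem sizes

Default runs use two small-RNA replicates of 50 000 reads and two long-RNA
replicates of 6 000 pairs over an ~13-kb reference — large enough for
Z₁₀ ≫ 3, ≥ 5 000 phased reads for composition, and stable spike
calibration, while a full pipeline run completes in well under a minute.
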