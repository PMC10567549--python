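"""Overlap spectra, Z10, cleavage-product calls, pre-pre-piRNA
identification, metaplots, autocorrelation and period estimation."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pirnaphase.annotate import FeatureInterval
from pirnaphase.signatures import (End5, LongRnaSpecies, OverlapSpectrum,
                                   SignatureError, autocorrelate,
                                   call_cleavage_products, estimate_period,
                                   identify_prepre, merge_long_rnas,
                                   overlap_spectrum, phasing_metaplot, z_score)


def brute_force_spectrum(a, b, max_offset=20, weighting="read"):
    """O(n^2) all-pairs enumeration of 5'-5' overlap offsets."""
    counts = np.zeros(max_offset + 1)
    for ea in a:
        for eb in b:
            if ea.chrom != eb.chrom or ea.strand == eb.strand:
                continue
            p, g = (ea.pos, eb.pos) if ea.strand == "+" else (eb.pos, ea.pos)
            o = g - p + 1
            if 0 <= o <= max_offset:
                w = 1.0 if weighting == "species" else ea.weight * eb.weight
                counts[o] += w
    return counts


def _random_ends(rng, n, chroms=("c1", "c2")):
    return [End5(rng.choice(chroms), rng.choice(["+", "-"]),
                 int(rng.integers(0, 400)), float(rng.integers(1, 20)))
            for _ in range(n)]


class TestMergeLongRnas:
    def test_same_five_prime_merges(self):
        recs = [("c", "+", 100, 310, 1), ("c", "+", 100, 350, 1), ("c", "+", 100, 400, 1)]
        (sp,) = merge_long_rnas(recs)
        assert sp.read_count == 3 and sp.length == 300 and sp.five_prime == 100

    def test_one_nt_offset_separates_species(self):
        recs = [("c", "+", 100, 400, 1), ("c", "+", 101, 400, 1)]
        assert len(merge_long_rnas(recs)) == 2

    def test_minus_strand_five_prime(self):
        (sp,) = merge_long_rnas([("c", "-", 100, 400, 2)])
        assert sp.five_prime == 399 and sp.strand == "-"

    def test_simulator_five_ends_equal_cut_sites(self, truth):
        """Merged degradome species at the simulated locus reproduce the
        truth cut-site set exactly."""
        longs = merge_long_rnas(
            (sp.chrom, sp.strand, sp.five_prime, sp.five_prime + sp.length, sp.molecules)
            for sp in truth.by_class("prepre_long"))
        assert {sp.five_prime for sp in longs} == {c.position for c in truth.cut_sites}


class TestOverlapSpectrum:
    def test_hand_enumeration(self):
        spec = overlap_spectrum(
            [End5("c", "+", 100)],
            [End5("c", "-", 109), End5("c", "-", 104), End5("c", "-", 95)])
        expected = np.zeros(21)
        expected[10] = expected[5] = 1  # offset -4 pair discarded
        assert np.array_equal(spec.counts, expected)

    def test_empty_b_set_all_zero(self):
        spec = overlap_spectrum([End5("c", "+", 100)], [])
        assert not spec.counts.any()

    @pytest.mark.parametrize("weighting", ["read", "species"])
    def test_matches_brute_force(self, rng, weighting):
        for _ in range(10):
            a = _random_ends(rng, int(rng.integers(10, 60)))
            b = _random_ends(rng, int(rng.integers(10, 60)))
            spec = overlap_spectrum(a, b, weighting=weighting)
            assert np.allclose(spec.counts, brute_force_spectrum(a, b, weighting=weighting))


class TestZScore:
    def test_analytic_background(self):
        counts = np.array([1.0] * 10 + [12.0] + [3.0] * 10)
        # background: ten 1s and ten 3s -> mean 2, population sd 1
        z, p = z_score(OverlapSpectrum(counts))
        assert z == pytest.approx(10.0)
        assert p == pytest.approx(2 * math.erfc(10 / math.sqrt(2)) / 2, rel=1e-6)

    def test_uniform_spectrum(self):
        assert z_score(OverlapSpectrum(np.full(21, 4.0))) == (0.0, 1.0)

    def test_degenerate_background_raises(self):
        counts = np.full(21, 2.0)
        counts[10] = 9.0
        with pytest.raises(SignatureError, match="degenerate_background"):
            z_score(OverlapSpectrum(counts))

    @given(st.floats(0.01, 1000.0))
    def test_scale_invariant(self, k):
        counts = np.array([1.0] * 10 + [12.0] + [3.0] * 10)
        z, _ = z_score(OverlapSpectrum(counts * k))
        assert z == pytest.approx(10.0)


class TestCallCleavageProducts:
    LONG = LongRnaSpecies("c", "+", 100, 100, 500, 5)

    def test_offset_ten_guide_calls(self):
        assert call_cleavage_products([self.LONG], [End5("c", "-", 109)]) == [self.LONG]

    def test_offset_nine_guide_does_not(self):
        assert call_cleavage_products([self.LONG], [End5("c", "-", 108)]) == []

    def test_no_guides_empty(self):
        assert call_cleavage_products([self.LONG], []) == []

    def test_every_truth_cut_site_is_called(self, truth):
        """Simulated slicing obeys the t10/t11 geometry: every cleavage
        product is called against the trigger set."""
        longs = [LongRnaSpecies(sp.chrom, sp.strand, sp.five_prime,
                                sp.five_prime, sp.five_prime + sp.length, sp.molecules)
                 for sp in truth.by_class("prepre_long")]
        guides = [End5(sp.chrom, sp.strand, sp.five_prime, sp.molecules)
                  for sp in truth.by_class("trigger")]
        assert call_cleavage_products(longs, guides) == longs


class TestIdentifyPrepre:
    LOCUS = FeatureInterval("c", 1100, 3100, "+", "locus", "pirna_locus")
    INSERTION = FeatureInterval("c", 900, 1100, "+", "ins", "insertion")

    def _long(self, five, length):
        return LongRnaSpecies("c", "+", five, five, five + length, 1)

    def test_junction_window_call(self):
        calls = identify_prepre([self._long(1050, 400)], self.LOCUS, self.INSERTION)
        assert len(calls) == 1 and calls[0].species.five_prime == 1050

    def test_five_prime_outside_window_rejected(self):
        assert identify_prepre([self._long(700, 900)], self.LOCUS, self.INSERTION) == []

    def test_short_species_rejected(self):
        assert identify_prepre([self._long(1050, 150)], self.LOCUS, self.INSERTION) == []

    def test_missing_insertion_raises(self):
        with pytest.raises(SignatureError, match="no_insertion"):
            identify_prepre([self._long(1050, 400)], self.LOCUS, None)

    def test_monotone_in_window_and_min_len(self, rng):
        longs = [self._long(int(rng.integers(900, 1400)), int(rng.integers(100, 800)))
                 for _ in range(60)]
        base = {c.species for c in identify_prepre(longs, self.LOCUS, self.INSERTION,
                                                   window=100, min_len=200)}
        tighter_w = {c.species for c in identify_prepre(longs, self.LOCUS, self.INSERTION,
                                                        window=40, min_len=200)}
        tighter_l = {c.species for c in identify_prepre(longs, self.LOCUS, self.INSERTION,
                                                        window=100, min_len=400)}
        assert tighter_w <= base and tighter_l <= base


class TestPhasingMetaplot:
    def test_single_prepre_density(self):
        prepre = [LongRnaSpecies("c", "+", 0, 0, 300, 1)]
        pirnas = [End5("c", "+", p) for p in (0, 26, 52)]
        prof = phasing_metaplot([prepre], [pirnas], L=60)
        expected = np.zeros(60)
        expected[[0, 26, 52]] = 1 / 3
        assert np.allclose(prof.profiles[0], expected)
        assert np.allclose(prof.median, expected)

    def test_identical_permutations_have_zero_iqr(self):
        prepre = [LongRnaSpecies("c", "+", 0, 0, 300, 1)]
        pirnas = [End5("c", "+", p) for p in (0, 26, 52)]
        prof = phasing_metaplot([prepre, prepre], [pirnas, pirnas], L=60)
        assert prof.profiles.shape == (4, 60)
        assert np.allclose(prof.iqr, 0.0)

    def test_all_zero_flagged(self):
        prepre = [LongRnaSpecies("c", "+", 0, 0, 300, 1)]
        prof = phasing_metaplot([prepre], [[End5("c", "-", 9000)]], L=60)
        assert prof.all_zero


class TestAutocorrelation:
    def test_comb_profile_peaks_at_its_period(self):
        profile = np.zeros(200)
        profile[::26] = 1.0
        r = autocorrelate(profile, max_lag=50)
        est = estimate_period(r)
        assert est.period == 26 and not est.harmonic_ambiguous

    def test_constant_profile_undefined(self):
        r = autocorrelate(np.ones(100), max_lag=30)
        assert np.isnan(r[1:]).all()
        with pytest.raises(SignatureError, match="no_period"):
            estimate_period(r)

    def test_matches_textbook_formula(self, rng):
        """Pearson r at each lag computed independently from the definition
        (sums of products of centred values)."""
        x = rng.normal(size=300)
        r = autocorrelate(x, max_lag=40)
        for lag in (1, 7, 23, 40):
            a, b = x[:-lag], x[lag:]
            am, bm = a.mean(), b.mean()
            num = float(((a - am) * (b - bm)).sum())
            den = math.sqrt(float(((a - am) ** 2).sum()) * float(((b - bm) ** 2).sum()))
            assert r[lag] == pytest.approx(num / den, abs=1e-9)

    def test_harmonic_of_short_period_flagged(self):
        profile = np.zeros(200)
        profile[::10] = 1.0
        r = autocorrelate(profile, max_lag=50)
        est = estimate_period(r, search_range=(15, 40))
        assert est.period == 20 and est.harmonic_ambiguous

    def test_too_short_profile_rejected(self):
        with pytest.raises(ValueError):
            autocorrelate(np.zeros(20), max_lag=30)
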