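"""Scoring kernels and dynamic-programming peak alignment."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vibralign.alignment import (
    Alignment,
    LegacyScoringConfig,
    ScoringConfig,
    align_multisource,
    align_peaks,
    legacy_pair_score,
    mollifier,
    normalize_intensities,
    pair_score,
    shift_theoretical,
)
from vibralign.spectra import Modality, PeakBand, PeakList


def band(x0, I=1.0, w=12.0, eta=0.5, source=Modality.IR, origin="experimental"):
    return PeakBand(x0=x0, I=I, w=w, eta=eta, source=source, origin=origin)


def peaklist(*bands, origin="experimental"):
    return PeakList(
        sorted((b if b.origin == origin else None for b in bands), key=lambda b: b.x0)
    ) if False else PeakList(sorted(bands, key=lambda b: b.x0))


def random_lists(rng, n_exp, n_theo):
    """Random exp/theo peak lists with attribute scales matching the defaults."""
    def make(n, origin):
        xs = np.sort(rng.uniform(1000.0, 1500.0, n))
        return PeakList(
            band(float(x), I=float(rng.uniform(0.1, 1.0)),
                 w=float(rng.uniform(8.0, 20.0)), origin=origin)
            for x in xs
        )
    return make(n_exp, "experimental"), make(n_theo, "theoretical")


def brute_force_optimum(exp, theo, cfg):
    """Enumerate every monotone matching explicitly; independent of the DP."""
    n, m = len(exp), len(theo)
    best = 0.0
    for k in range(0, min(n, m) + 1):
        for e_idx in itertools.combinations(range(n), k):
            for t_idx in itertools.combinations(range(m), k):
                total = sum(
                    pair_score(exp[i], theo[j], cfg) for i, j in zip(e_idx, t_idx)
                )
                best = max(best, total)
    return best / max(n, m) if cfg.normalize_score else best


class TestNormalizeIntensities:
    def test_divides_by_max(self):
        pl = peaklist(band(1100.0, I=2.0), band(1200.0, I=4.0))
        out = normalize_intensities(pl)
        assert [p.I for p in out] == [0.5, 1.0]

    def test_idempotent(self):
        pl = normalize_intensities(peaklist(band(1100.0, I=2.0), band(1200.0, I=4.0)))
        again = normalize_intensities(pl)
        assert [p.I for p in again] == [p.I for p in pl]

    def test_vcd_signs_preserved(self):
        pl = peaklist(band(1100.0, I=-3.0, source=Modality.VCD),
                      band(1200.0, I=1.5, source=Modality.VCD))
        out = normalize_intensities(pl)
        assert [p.I for p in out] == [-1.0, 0.5]

    def test_empty_list_errors(self):
        with pytest.raises(ValueError):
            normalize_intensities(PeakList([]))


class TestMollifier:
    def test_unity_at_zero(self):
        assert mollifier(0.0, 30.0) == 1.0

    def test_zero_at_and_beyond_cutoff(self):
        assert mollifier(30.0, 30.0) == 0.0
        assert mollifier(-45.0, 30.0) == 0.0

    def test_half_cutoff_closed_form(self):
        # exp(1 - 1/(1 - 1/4)) = exp(1 - 4/3)
        assert mollifier(15.0, 30.0) == pytest.approx(math.exp(1.0 - 4.0 / 3.0))

    @given(st.floats(0.001, 100.0), st.floats(-150.0, 150.0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_bounds_symmetry_monotonicity(self, cutoff, delta):
        v = mollifier(delta, cutoff)
        assert 0.0 <= v <= 1.0
        assert v == mollifier(-delta, cutoff)
        # decreasing inside the support (strict away from underflow at 0)
        if cutoff * 0.01 < abs(delta) < cutoff * 0.99:
            assert v < mollifier(delta * 0.5, cutoff)

    def test_bad_cutoff(self):
        with pytest.raises(ValueError):
            mollifier(1.0, 0.0)


class TestPairScore:
    CFG = ScoringConfig()

    def test_identical_peaks_score_one(self):
        a = band(1200.0, I=0.8, w=14.0)
        b = band(1200.0, I=0.8, w=14.0, origin="theoretical")
        assert pair_score(a, b, self.CFG) == pytest.approx(1.0)

    def test_zero_when_any_component_zero(self):
        e = band(1200.0, I=0.8, w=14.0)
        beyond_freq = band(1200.0 + self.CFG.C_nu, I=0.8, w=14.0, origin="theoretical")
        beyond_inten = band(1200.0, I=0.8 - self.CFG.C_I - 0.01, w=14.0, origin="theoretical")
        beyond_width = band(1200.0, I=0.8, w=14.0 + self.CFG.C_w, origin="theoretical")
        assert pair_score(e, beyond_freq, self.CFG) == 0.0
        assert pair_score(e, beyond_inten, self.CFG) == 0.0
        assert pair_score(e, beyond_width, self.CFG) == 0.0

    def test_product_of_component_kernels_at_half_cutoffs(self):
        cfg = self.CFG
        e = band(1200.0, I=0.9, w=14.0)
        t = band(1200.0 + cfg.C_nu / 2, I=0.9 - cfg.C_I / 2, w=14.0 + cfg.C_w / 2,
                 origin="theoretical")
        half = math.exp(1.0 - 4.0 / 3.0)
        assert pair_score(e, t, cfg) == pytest.approx(half**3)

    def test_mu_scaling_applied_to_theoretical_position(self):
        e = band(1170.0, I=0.5, w=12.0)
        t = band(1200.0, I=0.5, w=12.0, origin="theoretical")
        cfg = ScoringConfig(mu=0.975)
        assert pair_score(e, t, cfg) == pytest.approx(1.0)

    def test_vcd_sign_ignored_in_intensity_component(self):
        e = band(1200.0, I=0.7, w=12.0, source=Modality.VCD)
        t_pos = band(1200.0, I=0.7, w=12.0, source=Modality.VCD, origin="theoretical")
        t_neg = band(1200.0, I=-0.7, w=12.0, source=Modality.VCD, origin="theoretical")
        assert pair_score(e, t_neg, self.CFG) == pytest.approx(
            pair_score(e, t_pos, self.CFG)
        )

    def test_symmetry_at_unit_mu(self):
        a = band(1200.0, I=0.6, w=10.0)
        b = band(1210.0, I=0.8, w=16.0, origin="theoretical")
        assert pair_score(a, b, self.CFG) == pytest.approx(pair_score(b, a, self.CFG))

    def test_monotone_in_cutoffs(self):
        e = band(1200.0, I=0.9, w=10.0)
        t = band(1212.0, I=0.7, w=16.0, origin="theoretical")
        base = pair_score(e, t, ScoringConfig(C_nu=20.0, C_I=0.3, C_w=10.0))
        wider = pair_score(e, t, ScoringConfig(C_nu=40.0, C_I=0.6, C_w=20.0))
        assert wider >= base


class TestLegacyPairScore:
    CFG = LegacyScoringConfig(sigma1=0.3, sigma2=20.0)

    def test_identical_peaks_attain_maximum(self):
        a = band(1200.0, I=0.8)
        b = band(1200.0, I=0.8, origin="theoretical")
        top = legacy_pair_score(a, b, self.CFG)
        for t in (band(1210.0, I=0.8, origin="theoretical"),
                  band(1200.0, I=0.5, origin="theoretical")):
            assert legacy_pair_score(a, t, self.CFG) < top

    def test_frequency_term_vanishes_only_at_infinite_distance(self):
        a = band(1200.0, I=0.8)
        far = band(1480.0, I=0.8, origin="theoretical")
        v = legacy_pair_score(a, far, self.CFG)
        # the intensity term survives; the frequency term is tiny but nonzero
        assert v > 0.0
        assert v - 1.0 < 1e-10  # frequency contribution effectively gone

    def test_decreases_with_separation(self):
        a = band(1200.0, I=0.8)
        vals = [
            legacy_pair_score(a, band(1200.0 + d, I=0.8, origin="theoretical"), self.CFG)
            for d in (0.0, 10.0, 30.0, 80.0)
        ]
        assert all(x > y for x, y in zip(vals, vals[1:]))


class TestAlignPeaks:
    CFG = ScoringConfig()

    def test_self_alignment_scores_one(self):
        rng = np.random.default_rng(7)
        exp, _ = random_lists(rng, 5, 5)
        theo = PeakList(
            band(p.x0, I=p.I, w=p.w, origin="theoretical") for p in exp
        )
        aln = align_peaks(exp, theo, self.CFG)
        assert len(aln.pairs) == 5
        assert aln.total_score == pytest.approx(1.0)

    def test_all_gapped_when_beyond_cutoffs(self):
        exp = peaklist(band(1100.0, I=1.0))
        theo = PeakList([band(1400.0, I=1.0, origin="theoretical")])
        aln = align_peaks(exp, theo, self.CFG)
        assert aln.pairs == ()
        assert aln.exp_gaps == (0,) and aln.theo_gaps == (0,)
        assert aln.total_score == 0.0

    def test_empty_lists_error(self):
        exp = peaklist(band(1100.0))
        with pytest.raises(ValueError):
            align_peaks(PeakList([]), PeakList([]), self.CFG)
        with pytest.raises(ValueError):
            align_peaks(exp, PeakList([]), self.CFG)

    @pytest.mark.parametrize("seed", range(40))
    def test_dp_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n, m = int(rng.integers(1, 8)), int(rng.integers(1, 8))
        exp, theo = random_lists(rng, n, m)
        aln = align_peaks(exp, theo, self.CFG)
        assert aln.total_score == pytest.approx(brute_force_optimum(exp, theo, self.CFG))

    @pytest.mark.parametrize("seed", range(15))
    def test_order_preservation_and_partition(self, seed):
        rng = np.random.default_rng(100 + seed)
        exp, theo = random_lists(rng, int(rng.integers(2, 10)), int(rng.integers(2, 10)))
        aln = align_peaks(exp, theo, self.CFG)
        e_idx = [i for i, _, _ in aln.pairs]
        t_idx = [j for _, j, _ in aln.pairs]
        assert e_idx == sorted(set(e_idx))
        assert t_idx == sorted(set(t_idx))
        assert sorted(e_idx + list(aln.exp_gaps)) == list(range(len(exp)))
        assert sorted(t_idx + list(aln.theo_gaps)) == list(range(len(theo)))
        assert all(sc > 0 for _, _, sc in aln.pairs)
        assert 0.0 <= aln.total_score <= 1.0


class TestShiftTheoretical:
    CFG = ScoringConfig()

    def test_identity_when_matched_in_place(self):
        exp = peaklist(band(1100.0, I=0.5), band(1200.0, I=1.0))
        theo = PeakList(band(p.x0, I=p.I, origin="theoretical") for p in exp)
        aln = align_peaks(exp, theo, self.CFG)
        shifted = shift_theoretical(theo, aln, exp)
        assert [p.x0 for p in shifted] == [1100.0, 1200.0]

    def test_unmatched_follows_closest_matched_neighbor(self):
        # matched peaks shifted by +5 and -3; the unmatched one sits nearest
        # the first and must move by +5
        exp = peaklist(band(1105.0, I=0.5), band(1297.0, I=1.0))
        theo = PeakList([
            band(1100.0, I=0.5, origin="theoretical"),
            band(1130.0, I=0.2, origin="theoretical"),  # unmatched, nearest 1100
            band(1300.0, I=1.0, origin="theoretical"),
        ])
        aln = align_peaks(exp, theo, ScoringConfig(C_I=0.25))
        assert [(i, j) for i, j, _ in aln.pairs] == [(0, 0), (1, 2)]
        shifted = shift_theoretical(theo, aln, exp)
        assert [p.x0 for p in shifted] == pytest.approx([1105.0, 1135.0, 1297.0])

    def test_zero_matches_identity_shift_flagged(self):
        exp = peaklist(band(1100.0, I=1.0))
        theo = PeakList([band(1400.0, I=1.0, origin="theoretical")])
        aln = align_peaks(exp, theo, self.CFG)
        shifted = shift_theoretical(theo, aln, exp)
        assert [p.x0 for p in shifted] == [1400.0]
        assert all(p.flagged for p in shifted)

    @pytest.mark.parametrize("seed", range(10))
    def test_against_direct_rule_evaluation(self, seed):
        rng = np.random.default_rng(200 + seed)
        exp, theo = random_lists(rng, 6, 6)
        aln = align_peaks(exp, theo, self.CFG)
        if not aln.pairs:
            return
        shifted = shift_theoretical(theo, aln, exp)
        # independent re-implementation of the rule
        deltas = {j: exp[i].x0 - theo[j].x0 for i, j, _ in aln.pairs}
        expected = []
        for k, p in enumerate(theo):
            if k in deltas:
                expected.append(p.x0 + deltas[k])
            else:
                cands = sorted(
                    deltas, key=lambda t: (abs(theo[t].x0 - p.x0), theo[t].x0)
                )
                expected.append(p.x0 + deltas[cands[0]])
        assert sorted(p.x0 for p in shifted) == pytest.approx(sorted(expected))


class TestMultiSource:
    CFG = ScoringConfig()

    def _disjoint_sources(self, rng):
        def make(lo, hi, n, source, origin):
            xs = np.sort(rng.uniform(lo, hi, n))
            return PeakList(
                band(float(x), I=float(rng.uniform(0.1, 1.0)),
                     w=float(rng.uniform(8, 20)), source=source, origin=origin)
                for x in xs
            )
        exp = {Modality.IR: make(1000, 1190, 4, Modality.IR, "experimental"),
               Modality.RAMAN: make(1300, 1500, 4, Modality.RAMAN, "experimental")}
        theo = {Modality.IR: make(1000, 1190, 4, Modality.IR, "theoretical"),
                Modality.RAMAN: make(1300, 1500, 4, Modality.RAMAN, "theoretical")}
        return exp, theo

    @pytest.mark.parametrize("seed", range(10))
    def test_disjoint_ranges_equal_independent_alignments(self, seed):
        rng = np.random.default_rng(300 + seed)
        exp, theo = self._disjoint_sources(rng)
        multi = align_multisource(exp, theo, self.CFG)
        raw_sum = 0.0
        for mod in exp:
            solo = align_peaks(exp[mod], theo[mod], self.CFG)
            assert multi.by_source[mod].pairs == solo.pairs
            raw_sum += solo.raw_score
        assert multi.raw_score == pytest.approx(raw_sum)

    def test_cross_source_never_matches_even_at_same_frequency(self):
        exp = {
            Modality.IR: peaklist(band(1200.0, I=1.0, source=Modality.IR)),
            Modality.RAMAN: peaklist(band(1200.0, I=1.0, source=Modality.RAMAN)),
        }
        theo = {
            Modality.IR: PeakList([band(1200.0, I=1.0, source=Modality.IR,
                                        origin="theoretical")]),
            Modality.RAMAN: PeakList([band(1200.0, I=1.0, source=Modality.RAMAN,
                                           origin="theoretical")]),
        }
        multi = align_multisource(exp, theo, self.CFG)
        for mod in (Modality.IR, Modality.RAMAN):
            assert multi.by_source[mod].pairs == ((0, 0, pytest.approx(1.0)),)
        assert multi.total_score == pytest.approx(1.0)

    def test_one_sided_modality_errors(self):
        exp = {Modality.IR: peaklist(band(1200.0))}
        theo = {
            Modality.IR: PeakList([band(1200.0, origin="theoretical")]),
            Modality.RAMAN: PeakList([band(1200.0, source=Modality.RAMAN,
                                           origin="theoretical")]),
        }
        with pytest.raises(ValueError, match="RAMAN"):
            align_multisource(exp, theo, self.CFG)

    @pytest.mark.parametrize("seed", range(8))
    def test_per_source_alignments_are_monotone(self, seed):
        rng = np.random.default_rng(400 + seed)
        def make(n, source, origin):
            xs = np.sort(rng.uniform(1000, 1500, n))
            return PeakList(
                band(float(x), I=float(rng.uniform(0.1, 1.0)),
                     w=float(rng.uniform(8, 20)), source=source, origin=origin)
                for x in xs
            )
        exp = {Modality.IR: make(5, Modality.IR, "experimental"),
               Modality.RAMAN: make(5, Modality.RAMAN, "experimental")}
        theo = {Modality.IR: make(5, Modality.IR, "theoretical"),
                Modality.RAMAN: make(5, Modality.RAMAN, "theoretical")}
        multi = align_multisource(exp, theo, self.CFG)
        for mod, aln in multi.by_source.items():
            e_idx = [i for i, _, _ in aln.pairs]
            t_idx = [j for _, j, _ in aln.pairs]
            assert e_idx == sorted(set(e_idx))
            assert t_idx == sorted(set(t_idx))
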