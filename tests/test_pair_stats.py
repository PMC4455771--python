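import itertools
import math

import numpy as np
import pytest
from Bio.Seq import Seq

from pbrhet.codon_alignment import PbrMask
from pbrhet.pair_stats import (
    DivergenceParams,
    PairCounts,
    all_pair_counts,
    count_pair,
    count_sites,
    divergence_time,
    functional_constraint,
    relative_rate_statistic,
    relative_rate_test,
)

SENSE = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if str(Seq(a + b + c).translate()) != "*"
]


def oracle_sites(codon):
    """Independent fractional site count via exhaustive single-mutant enumeration."""
    aa = str(Seq(codon).translate())
    ls = 0.0
    for pos in range(3):
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            mut = codon[:pos] + nt + codon[pos + 1 :]
            if str(Seq(mut).translate()) == aa:
                ls += 1 / 3
    return ls, 3 - ls


def oracle_pathways(c1, c2):
    """Independent pathway average (syn, nonsyn) with stop-path exclusion."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0

    def classify(order, allow_stop):
        cur, syn, non = c1, 0, 0
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if str(Seq(nxt).translate()) == "*" and not allow_stop:
                return None
            if str(Seq(cur).translate()) == str(Seq(nxt).translate()):
                syn += 1
            else:
                non += 1
            cur = nxt
        return syn, non

    paths = [classify(o, False) for o in itertools.permutations(diff)]
    paths = [p for p in paths if p is not None]
    if not paths:
        paths = [classify(o, True) for o in itertools.permutations(diff)]
    return (
        sum(p[0] for p in paths) / len(paths),
        sum(p[1] for p in paths) / len(paths),
    )


class TestCountSites:
    def test_met_has_no_synonymous_sites(self):
        assert count_sites("ATG") == (0.0, 3.0)

    def test_phe_third_position(self):
        ls, ln = count_sites("TTT")
        assert ls == pytest.approx(1 / 3)
        assert ln == pytest.approx(8 / 3)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            count_sites("")

    @pytest.mark.parametrize("codon", SENSE[::7])
    def test_matches_exhaustive_oracle(self, codon):
        ls, ln = count_sites(codon)
        ols, oln = oracle_sites(codon)
        assert ls == pytest.approx(ols)
        assert ln == pytest.approx(oln)


class TestCountPair:
    def test_identical_sequences_all_zero(self):
        p = count_pair("ATGGGT", "ATGGGT", PbrMask((1,)))
        assert (p.K_S, p.K_N, p.K_B, p.m) == (0.0, 0.0, 0.0, 0.0)

    def test_single_synonymous_difference(self):
        p = count_pair("TTT", "TTC", None)
        assert (p.K_S, p.K_N, p.K_B, p.m) == (1.0, 0.0, 0.0, 1.0)

    def test_two_step_leucine_pathways_both_synonymous(self):
        p = count_pair("TTG", "CTA", None)
        assert p.K_S == pytest.approx(2.0)
        assert p.K_N == pytest.approx(0.0)

    def test_val_gly_flipflop_at_masked_codon(self):
        p = count_pair("GGT", "GTT", PbrMask((1,)))
        assert p.K_B == pytest.approx(1.0)
        assert p.K_N == 0.0
        assert p.Tv_pbr == 1.0 and p.Ts_pbr == 0.0

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            count_pair("ATG", "ATGATG", None)

    def test_symmetry(self, rng):
        codons = [SENSE[i] for i in rng.integers(0, len(SENSE), size=12)]
        a = "".join(codons[:6])
        b = "".join(codons[6:])
        mask = PbrMask((2, 5))
        p1 = count_pair(a, b, mask)
        p2 = count_pair(b, a, mask)
        for f in ("K_S", "K_N", "K_B", "L_S", "L_N", "Ts_pbr", "Tv_pbr"):
            assert getattr(p1, f) == pytest.approx(getattr(p2, f))

    def test_mask_moves_nonsyn_between_kn_and_kb_only(self, rng):
        codons_a = [SENSE[i] for i in rng.integers(0, len(SENSE), size=10)]
        codons_b = [SENSE[i] for i in rng.integers(0, len(SENSE), size=10)]
        a, b = "".join(codons_a), "".join(codons_b)
        totals = set()
        for mask in (None, PbrMask((1, 4, 9)), PbrMask(tuple(range(1, 11)))):
            p = count_pair(a, b, mask)
            totals.add((round(p.K_S, 9), round(p.K_N + p.K_B, 9)))
        assert len(totals) == 1

    def test_ts_tv_equal_nt_differences_at_masked_codons(self, rng):
        for _ in range(20):
            ca = SENSE[rng.integers(0, len(SENSE))]
            cb = SENSE[rng.integers(0, len(SENSE))]
            p = count_pair(ca, cb, PbrMask((1,)))
            ndiff = sum(x != y for x, y in zip(ca, cb))
            assert p.Ts_pbr + p.Tv_pbr == ndiff

    def test_ambiguous_codons_excluded_pairwise(self):
        p = count_pair("ATG--GTTT", "ATGGGGTTC", PbrMask((2,)))
        assert p.n_codons_skipped == 1
        assert p.K_S == 1.0  # TTT/TTC only


class TestFunctionalConstraint:
    def make(self, ks, kn, ls=100.0, ln=300.0):
        return PairCounts("a", "b", ks, kn, 0.0, ls, ln, 0, 0)

    def test_hand_example(self):
        # K_N/L_N = 0.005, K_S/L_S = 0.01 -> ratio 0.5
        f, n, excl = functional_constraint([self.make(1.0, 1.5)])
        assert f == pytest.approx((1.5 / 300) / (1.0 / 100))
        assert (n, excl) == (1, 0)

    def test_all_kn_zero_gives_zero(self):
        f, _, _ = functional_constraint([self.make(2.0, 0.0)])
        assert f == 0.0
        with pytest.raises(ValueError):
            DivergenceParams(f=f)

    def test_ks_zero_pairs_excluded(self):
        pairs = [self.make(1.0, 1.5), self.make(0.0, 5.0), self.make(2.0, 3.0)]
        f, n, excl = functional_constraint(pairs)
        expected = np.mean([(1.5 / 300) / (1 / 100), (3.0 / 300) / (2 / 100)])
        assert f == pytest.approx(expected)
        assert (n, excl) == (2, 1)

    def test_no_eligible_pair_errors(self):
        with pytest.raises(ValueError):
            functional_constraint([self.make(0.0, 1.0)])


class TestDivergenceTime:
    def test_identical_pair(self):
        p = PairCounts("a", "b", 0, 0, 0, 100, 300, 0, 0)
        d, t = divergence_time(p, DivergenceParams(f=0.5))
        assert (d, t) == (0.0, 0.0)

    def test_hand_example(self):
        p = PairCounts("a", "b", 4.0, 2.0, 0, 100.0, 300.0, 0, 0)
        d, t = divergence_time(p, DivergenceParams(f=0.5, mu=1e-9))
        assert d == pytest.approx(0.02)
        assert t == pytest.approx(1e7)

    def test_linear_in_counts_and_inverse_in_mu(self):
        base = PairCounts("a", "b", 4.0, 2.0, 0, 100.0, 300.0, 0, 0)
        double = PairCounts("a", "b", 8.0, 4.0, 0, 100.0, 300.0, 0, 0)
        params = DivergenceParams(f=0.5, mu=1e-9)
        d1, t1 = divergence_time(base, params)
        d2, t2 = divergence_time(double, params)
        assert d2 == pytest.approx(2 * d1)
        _, t_half_mu = divergence_time(base, DivergenceParams(f=0.5, mu=5e-10))
        assert t_half_mu == pytest.approx(2 * t1)


class TestRelativeRate:
    def test_equal_counts(self):
        stat, p = relative_rate_statistic(5, 5)
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_ten_vs_four(self):
        stat, p = relative_rate_statistic(10, 4)
        assert stat == pytest.approx(36 / 14)
        assert p == pytest.approx(0.1088, abs=5e-4)

    def test_zero_total_is_na(self):
        stat, p = relative_rate_statistic(0, 0)
        assert math.isnan(stat) and math.isnan(p)

    def test_sequence_interface_counts_unique_nonsyn_differences(self):
        # codon 1: a unique nonsynonymous; codon 2: b unique synonymous (not counted)
        out = "ATGTTT"
        a = "AGGTTT"  # M->R at codon 1
        b = "ATGTTC"  # synonymous third-position change at codon 2
        stat, p, n_a, n_b = relative_rate_test(a, b, out, None)
        assert (n_a, n_b) == (1, 0)
        assert stat == pytest.approx(1.0)


class TestCountingProperties:
    """Invariants of the partitioned counting, property-tested."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    codons = st.sampled_from(SENSE)

    @given(st.lists(codons, min_size=2, max_size=8),
           st.lists(codons, min_size=2, max_size=8))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_totals_are_mask_independent(self, ca, cb):
        n = min(len(ca), len(cb))
        a, b = "".join(ca[:n]), "".join(cb[:n])
        full = count_pair(a, b, None)
        masked = count_pair(a, b, PbrMask(tuple(range(1, n + 1, 2))))
        assert masked.K_S == pytest.approx(full.K_S)
        assert masked.K_N + masked.K_B == pytest.approx(full.K_N + full.K_B)

    @given(st.lists(codons, min_size=2, max_size=8))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_identical_sequences_count_zero(self, cs):
        s = "".join(cs)
        p = count_pair(s, s, PbrMask((1,)))
        assert (p.K_S, p.K_N, p.K_B, p.m) == (0.0, 0.0, 0.0, 0.0)

    @given(st.lists(codons, min_size=1, max_size=6))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_site_counts_partition_three_per_codon(self, cs):
        ls, ln = count_sites("".join(cs))
        assert ls + ln == pytest.approx(3.0 * len(cs))
        assert ls >= 0 and ln >= 0


class TestAllPairs:
    def test_pair_count_and_symmetric_names(self, tiny_alignment):
        pairs = all_pair_counts(tiny_alignment)
        assert len(pairs) == 6
        keys = {p.key() for p in pairs}
        assert len(keys) == 6
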