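"""Heterozygosity goodness-of-fit, allelic-imbalance categorization and
smoothing."""

import math

import numpy as np
import pytest

from cnaloh.coverage import ExomeStats
from cnaloh.loh import (AICall, CATEGORIES, LOHParams, SmoothingParams,
                        call_case_status, call_control_het, classify_fold,
                        het_binomial_p, smooth_calls)

EQ = ExomeStats(100.0, 100.0)


def binomial_p_oracle(k, n, p0=0.5):
    """Independent exact two-sided p: sum the pmf over outcomes no more
    likely than the observed one."""
    pmf = [math.comb(n, i) * p0 ** i * (1 - p0) ** (n - i)
           for i in range(n + 1)]
    obs = pmf[k]
    return sum(q for q in pmf if q <= obs * (1 + 1e-12))


class TestHetBinomial:
    @pytest.mark.parametrize("k1,k2", [(50, 50), (90, 10), (60, 40),
                                       (5, 5), (12, 3), (0, 7), (33, 31)])
    def test_matches_enumeration_oracle(self, k1, k2):
        assert het_binomial_p(k1, k2) == pytest.approx(
            binomial_p_oracle(k1, k1 + k2), rel=1e-9)

    def test_perfect_het_accepted(self):
        ok, p = call_control_het(("A", 50), ("G", 50), alpha=0.01)
        assert ok and p == 1.0

    def test_strong_imbalance_rejected(self):
        ok, p = call_control_het(("A", 90), ("G", 10), alpha=0.01)
        assert not ok
        assert p == pytest.approx(2.7e-16, rel=0.1)

    def test_mild_imbalance_accepted(self):
        ok, p = call_control_het(("A", 60), ("G", 40), alpha=0.01)
        assert ok
        assert p == pytest.approx(0.0569, abs=2e-3)

    def test_symmetric_in_alleles(self):
        _, p1 = call_control_het(("A", 70), ("G", 30))
        _, p2 = call_control_het(("G", 30), ("A", 70))
        assert p1 == p2

    def test_zero_total_gives_p_one(self):
        assert het_binomial_p(0, 0) == 1.0


class TestClassifyFold:
    @pytest.mark.parametrize("fold,category", [
        (0.0, "copy_loss"), (0.5, "copy_loss"), (0.75, "copy_loss"),
        (0.7500001, "copy_neutral_loh"), (1.0, "copy_neutral_loh"),
        (1.25, "copy_neutral_loh"), (1.2500001, "gain_1"), (1.5, "gain_1"),
        (1.75, "gain_1"), (1.7500001, "gain_2plus"), (3.0, "gain_2plus"),
    ])
    def test_boundaries(self, fold, category):
        assert classify_fold(fold) == category

    def test_exhaustive_and_exclusive_over_fold_axis(self):
        for fold in np.linspace(0.0, 4.0, 2001):
            cats = [c for c in CATEGORIES[1:]
                    if classify_fold(float(fold)) == c]
            assert len(cats) == 1


class TestCaseStatus:
    def _call(self, control, case, **kw):
        return call_case_status("1", 100, ("A", control[0]), ("G", control[1]),
                                ("A", case[0]), ("G", case[1]),
                                1.0, EQ, EQ, LOHParams(**kw))

    def test_near_perfect_case_conserved(self):
        c = self._call((50, 50), (48, 52))
        assert c.category == "conserved_het"

    def test_total_allele_loss_is_copy_loss(self):
        c = self._call((50, 50), (50, 0))
        assert c.category == "copy_loss"
        assert c.fold == pytest.approx(0.5)

    def test_one_copy_gain(self):
        c = self._call((50, 50), (100, 50))
        assert c.case_p < 1e-4  # het clearly rejected
        assert c.fold == pytest.approx(1.5)
        assert c.category == "gain_1"

    def test_uncovered_case_flagged_low_confidence(self):
        c = self._call((50, 50), (0, 0))
        assert c.category == "copy_loss" and c.fold == 0.0
        assert "low_confidence" in c.flags

    def test_band_guard_keeps_huge_depth_wobble_conserved(self):
        # 5300:4700 rejects at alpha 0.01 but the ratio 0.53 is biologically het
        c = self._call((5000, 5000), (5300, 4700))
        assert c.case_p < 0.01
        assert c.category == "conserved_het"
        assert "band_conserved" in c.flags

    def test_discordant_alleles_flagged(self):
        c = call_case_status("1", 100, ("A", 50), ("G", 50),
                             ("A", 60), ("T", 40), 1.0, EQ, EQ, LOHParams())
        assert "discordant_alleles" in c.flags

    def test_fold_uses_median_normalization(self):
        case_stats = ExomeStats(200.0, 200.0)  # case sequenced twice as deep
        c = call_case_status("1", 100, ("A", 50), ("G", 50),
                             ("A", 200), ("G", 0), 1.0, case_stats, EQ,
                             LOHParams())
        assert c.fold == pytest.approx(1.0)  # 200/200median vs 100/100median


def _ai(chrom, pos, category, flags=()):
    return AICall(chrom, pos, ("A", 50), ("G", 50), ("A", 50), ("G", 50),
                  1.0, 1.0, 0.5, 1.0, category, flags=tuple(flags))


class TestSmoothing:
    def test_majority_vote_flips_middle(self):
        calls = [_ai("1", p, c) for p, c in zip(
            range(100, 600, 100),
            ["copy_loss", "copy_loss", "conserved_het", "copy_loss",
             "copy_loss"])]
        out = smooth_calls(calls, SmoothingParams(enabled=True, window_size=3))
        assert out[2].smoothed_category == "copy_loss"
        assert out[2].category == "conserved_het"  # raw retained

    def test_uniform_input_unchanged(self):
        calls = [_ai("1", p, "gain_1") for p in range(100, 600, 100)]
        out = smooth_calls(calls, SmoothingParams(enabled=True, window_size=5))
        assert all(c.smoothed_category == "gain_1" for c in out)

    def test_disabled_is_identity(self):
        calls = [_ai("1", 100, "copy_loss"), _ai("1", 200, "conserved_het")]
        out = smooth_calls(calls, SmoothingParams(enabled=False))
        assert [c.smoothed_category for c in out] == \
               [c.category for c in out]

    def test_discordant_positions_do_not_vote(self):
        calls = [_ai("1", 100, "copy_loss"),
                 _ai("1", 200, "gain_2plus", flags=("discordant_alleles",)),
                 _ai("1", 300, "copy_loss")]
        out = smooth_calls(calls, SmoothingParams(enabled=True, window_size=3))
        assert out[1].smoothed_category == "gain_2plus"  # kept raw
        assert out[0].smoothed_category == "copy_loss"

    def test_even_or_tiny_window_rejected(self):
        with pytest.raises(ValueError):
            SmoothingParams(enabled=True, window_size=4)
        with pytest.raises(ValueError):
            SmoothingParams(enabled=True, window_size=1)
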