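"""Normalization, filters and seed/expand/merge segmentation."""

import numpy as np
import pandas as pd
import pytest

from cnaloh import PairedExome, resolve_preset
from cnaloh.cna import (CNAParams, apply_exon_filters, apply_sdf, call_cnas,
                        find_seeds, normalize)


def _paired(case, control, chrom="1", case_sd=None, control_sd=None):
    n = len(case)
    return pd.DataFrame({
        "exon_label": [f"{chrom}_ex{i}" for i in range(n)],
        "chrom": chrom, "start": np.arange(n) * 1000,
        "end": np.arange(n) * 1000 + 150,
        "case_cov": np.asarray(case, dtype=float),
        "control_cov": np.asarray(control, dtype=float),
        "case_sd": case_sd if case_sd is not None else np.zeros(n),
        "control_sd": control_sd if control_sd is not None else np.zeros(n),
    })


class TestNormalize:
    def test_identical_samples_zero_log2(self):
        df = _paired([80, 90, 100, 110], [80, 90, 100, 110])
        out = normalize(df, 95.0, 95.0, CNAParams(ccf=0.0))
        assert np.allclose(out["log2_ratio"], 0.0)

    def test_four_fold_imbalance_removed(self):
        df = _paired([25.0] * 10, [100.0] * 10)
        out = normalize(df, 25.0, 100.0, CNAParams(ccf=0.0))
        assert np.allclose(out["ratio"], 1.0)
        # both samples land on the same coverage-like scale
        assert np.allclose(out["case_norm"], 62.5)
        assert np.allclose(out["control_norm"], 62.5)

    def test_ccf_stabilizes_zero_coverage(self):
        df = _paired([0.0, 100.0], [0.0, 100.0])
        out = normalize(df, 100.0, 100.0, CNAParams(ccf=1.0))
        assert out["ratio"].iloc[0] == pytest.approx(1.0)
        assert out["log2_ratio"].iloc[0] == 0.0

    def test_zero_median_raises(self):
        with pytest.raises(ValueError):
            normalize(_paired([1], [1]), 0.0, 50.0, CNAParams())


class TestExonFilters:
    def test_coverage_floor_discards_pair(self):
        df = normalize(_paired([5.0, 100.0], [80.0, 100.0]), 100.0, 100.0,
                       CNAParams(ccf=0.0, coverage_floor=10.0))
        out = apply_exon_filters(df, CNAParams(coverage_floor=10.0))
        assert bool(out["excluded"].iloc[0])
        assert out["exclude_reason"].iloc[0] == "coverage_floor"
        assert not out["excluded"].iloc[1]

    def test_relative_sd_filter(self):
        df = normalize(_paired([10.0, 10.0], [10.0, 10.0],
                               case_sd=np.array([30.0, 1.0])),
                       10.0, 10.0, CNAParams(ccf=0.0, coverage_floor=0.0))
        out = apply_exon_filters(df, CNAParams(coverage_floor=0.0, resdf=1.0))
        assert bool(out["excluded"].iloc[0])  # relative SD 3.0 > 1.0
        assert not out["excluded"].iloc[1]

    def test_no_thresholds_nothing_excluded(self):
        df = normalize(_paired([1.0, 2.0], [3.0, 4.0]), 1.5, 3.5,
                       CNAParams(ccf=0.0, coverage_floor=0.0))
        out = apply_exon_filters(df, CNAParams(coverage_floor=0.0))
        assert not out["excluded"].any()


class TestPresets:
    def test_very_small_window(self):
        assert resolve_preset("very_small").window_size == 3

    def test_large_window(self):
        assert resolve_preset("large").window_size == 100

    def test_overrides_pass_through(self):
        p = resolve_preset("small", window_size=7, sdf=0.0)
        assert p.window_size == 7 and p.sdf == 0.0 and p.preset == "custom"

    def test_unknown_preset_raises(self):
        with pytest.raises(ValueError):
            resolve_preset("gigantic")

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            CNAParams(window_size=1)
        with pytest.raises(ValueError):
            CNAParams(p_threshold=0.0)


def _norm_chrom(case, control, params):
    df = normalize(_paired(case, control), float(np.median(case)),
                   float(np.median(control)), params)
    return apply_exon_filters(df, params)


class TestSeeds:
    def test_flat_identical_data_no_seeds(self):
        params = CNAParams(p_threshold=1e-3, window_size=10, ccf=0.0,
                           coverage_floor=0.0)
        rng = np.random.default_rng(0)
        control = rng.normal(100, 5, 200)
        df = _norm_chrom(control.copy(), control, params)
        assert find_seeds(df, params) == []

    def test_single_deviant_exon_cannot_seed(self):
        params = CNAParams(p_threshold=0.05, window_size=10, ccf=0.0,
                           coverage_floor=0.0)
        case = np.full(50, 100.0)
        case[25] = 400.0
        df = _norm_chrom(case, np.full(50, 100.0), params)
        # 9 zero-difference pairs are discarded; N_r=1 gives exact p=1
        assert find_seeds(df, params) == []

    def test_gain_region_seeds_tile_it(self):
        params = CNAParams(p_threshold=1e-4, window_size=20, ccf=0.0,
                           coverage_floor=0.0, sdf=0.0)
        rng = np.random.default_rng(1)
        control = rng.normal(100, 3, 300)
        case = control * (1 + rng.normal(0, 0.03, 300))
        case[100:180] *= 1.5
        df = _norm_chrom(case, control, params)
        seeds = find_seeds(df, params)
        assert seeds, "expected seeds over the gain region"
        assert all(s.direction == "gain" for s in seeds)
        inside = [s for s in seeds if s.lo >= 100 and s.hi < 180]
        assert len(inside) >= 50  # fully-inside windows are all significant

    def test_chromosome_shorter_than_window(self):
        params = CNAParams(window_size=10)
        df = _norm_chrom([100.0] * 5, [100.0] * 5, params)
        assert find_seeds(df, params) == []


class TestSegmentation:
    def _call(self, case, control, params):
        df = _norm_chrom(case, control, params)
        return call_cnas(df, params), df

    def test_recovers_gain_block(self):
        # window-20 p floor is ~9.2e-5 (all 20 signs aligned), so 1e-4
        # admits only fully-aligned windows
        params = CNAParams(p_threshold=1e-4, window_size=20, ccf=0.0,
                           coverage_floor=0.0, sdf=0.0)
        rng = np.random.default_rng(2)
        control = rng.normal(100, 3, 400)
        case = control * (1 + rng.normal(0, 0.03, 400))
        case[150:230] *= 1.5
        segs, _ = self._call(case, control, params)
        assert len(segs) == 1
        seg = segs[0]
        assert seg.direction == "gain"
        assert seg.first_exon <= 150 and seg.last_exon >= 229
        assert seg.p_value < params.p_threshold
        # expansion absorbs flanking noise until the pooled test decays,
        # so the region mean is diluted below the in-event log2(1.5)
        assert seg.mean_log2 > 0.1

    def test_two_nearby_same_direction_events_merge(self):
        params = CNAParams(p_threshold=3e-3, window_size=10, ccf=0.0,
                           coverage_floor=0.0, sdf=0.0)
        rng = np.random.default_rng(3)
        control = rng.normal(100, 2, 300)
        case = control * (1 + rng.normal(0, 0.02, 300))
        case[100:140] *= 1.6
        case[141:180] *= 1.6   # one neutral exon apart: expansion bridges it
        segs, _ = self._call(case, control, params)
        gains = [s for s in segs if s.direction == "gain"]
        assert len(gains) == 1
        assert gains[0].first_exon <= 100 and gains[0].last_exon >= 179

    def test_swap_antisymmetry(self):
        """Swapping case and control flips directions and negates log2."""
        params = CNAParams(p_threshold=1e-4, window_size=20, ccf=0.0,
                           coverage_floor=0.0, sdf=0.0)
        rng = np.random.default_rng(4)
        control = rng.normal(100, 3, 400)
        case = control * (1 + rng.normal(0, 0.03, 400))
        case[50:130] *= 1.5
        case[250:330] *= 0.5
        segs_fwd, df_fwd = self._call(case, control, params)
        segs_rev, df_rev = self._call(control, case, params)
        assert np.allclose(df_fwd["log2_ratio"], -df_rev["log2_ratio"])
        fwd = sorted((s.first_exon, s.last_exon, s.direction)
                     for s in segs_fwd)
        rev = sorted((s.first_exon, s.last_exon,
                      "gain" if s.direction == "loss" else "loss")
                     for s in segs_rev)
        assert fwd == rev
        for a, b in zip(sorted(segs_fwd, key=lambda s: s.first_exon),
                        sorted(segs_rev, key=lambda s: s.first_exon)):
            assert a.p_value == pytest.approx(b.p_value, rel=1e-9)

    def test_segments_non_overlapping_and_significant(self):
        params = CNAParams(p_threshold=3e-3, window_size=10, ccf=0.0,
                           coverage_floor=0.0, sdf=0.0)
        rng = np.random.default_rng(5)
        control = rng.normal(100, 4, 500)
        case = control * (1 + rng.normal(0, 0.03, 500))
        case[50:90] *= 1.5
        case[200:240] *= 0.5
        case[300:350] *= 1.5
        segs, _ = self._call(case, control, params)
        segs = sorted(segs, key=lambda s: s.first_exon)
        for a, b in zip(segs, segs[1:]):
            assert a.last_exon < b.first_exon
        for s in segs:
            assert s.p_value < params.p_threshold
            assert (s.mean_log2 > 0) == (s.direction == "gain")

    def test_determinism(self):
        params = resolve_preset("small")
        rng = np.random.default_rng(6)
        control = rng.normal(100, 5, 600)
        case = control * (1 + rng.normal(0, 0.05, 600))
        case[100:110] *= 1.5
        a, _ = self._call(case.copy(), control.copy(), params)
        b, _ = self._call(case.copy(), control.copy(), params)
        assert a == b


class TestSdf:
    def test_sdf_zero_keeps_everything(self):
        params = CNAParams(sdf=0.0, ccf=0.0, coverage_floor=0.0)
        rng = np.random.default_rng(7)
        control = rng.normal(100, 5, 100)
        df = _norm_chrom(control * 1.01, control, params)
        from cnaloh.cna import CNASegment
        seg = CNASegment("1", 0, 9, 0, 9150, "gain", 1e-4, 0.01, 10)
        assert apply_sdf([seg], df, params) == [seg]

    def test_weak_segment_discarded_on_noisy_chromosome(self):
        params = CNAParams(sdf=1.0, ccf=0.0, coverage_floor=0.0)
        rng = np.random.default_rng(8)
        control = np.full(200, 100.0)
        case = 100.0 * 2 ** rng.normal(0, 0.1, 200)  # log2 SD ~0.1
        df = _norm_chrom(case, control, params)
        from cnaloh.cna import CNASegment
        weak = CNASegment("1", 0, 9, 0, 9150, "gain", 1e-4, 0.05, 10)
        assert apply_sdf([weak], df, params) == []

    def test_whole_chromosome_loss_survives(self):
        params = CNAParams(sdf=1.0, ccf=0.0, coverage_floor=0.0)
        rng = np.random.default_rng(9)
        control = rng.normal(100, 5, 200)
        case = control * 0.5 * (1 + rng.normal(0, 0.05, 200))
        df = normalize(_paired(case, control), 100.0, 100.0, params)
        df = apply_exon_filters(df, params)
        from cnaloh.cna import CNASegment
        seg = CNASegment("1", 0, 199, 0, 199150, "loss", 1e-12,
                         float(df["log2_ratio"].mean()), 200)
        assert apply_sdf([seg], df, params) == [seg]
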