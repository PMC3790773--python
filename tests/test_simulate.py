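"""The paired-exome generator: determinism, noise bounds and truth layout."""

import numpy as np
import pandas as pd
import pytest

from cnaloh.simulate import (PRESETS, FixedEvent, SimConfig, _reflect,
                             preset_config, simulate_exome)


class TestCoverageModel:
    def test_zero_noise_no_events_exact_coverage(self):
        cfg = SimConfig(n_exons={"1": 50}, rnd_cn=0.0, seed=1,
                        base_cov_case=100.0, base_cov_control=80.0)
        sim = simulate_exome(cfg)
        assert np.allclose(sim.case_table["mean_cov"], 100.0)
        assert np.allclose(sim.control_table["mean_cov"], 80.0)

    def test_noise_amplitude_bound(self):
        cfg = SimConfig(n_exons={"1": 2000}, rnd_cn=0.4, seed=2)
        sim = simulate_exome(cfg)
        cov = sim.case_table["mean_cov"].to_numpy()
        assert cov.min() >= 100.0 * (2 - 0.4) / 2
        assert cov.max() <= 100.0 * (2 + 0.4) / 2

    def test_event_shifts_coverage(self):
        cfg = SimConfig(n_exons={"1": 300}, rnd_cn=0.0, seed=3,
                        fixed_events=(FixedEvent("1", 100, 50, 1),))
        sim = simulate_exome(cfg)
        cov = sim.case_table["mean_cov"].to_numpy()
        assert np.allclose(cov[100:150], 150.0)
        assert np.allclose(cov[:100], 100.0)
        assert np.allclose(sim.control_table["mean_cov"], 100.0)

    def test_seed_determinism(self):
        cfg = preset_config("t10", seed=11)
        a, b = simulate_exome(cfg), simulate_exome(cfg)
        pd.testing.assert_frame_equal(a.case_table, b.case_table)
        pd.testing.assert_frame_equal(a.het_table, b.het_table)
        assert [(t.chrom, t.first_exon, t.last_exon, t.delta_copies)
                for t in a.truth] == \
               [(t.chrom, t.first_exon, t.last_exon, t.delta_copies)
                for t in b.truth]

    def test_different_seeds_differ(self):
        a = simulate_exome(preset_config("t10", seed=1))
        b = simulate_exome(preset_config("t10", seed=2))
        assert not a.case_table["mean_cov"].equals(b.case_table["mean_cov"])

    def test_ratio_centered_on_one_outside_events(self):
        cfg = SimConfig(n_exons={"1": 4000}, rnd_cn=0.3, seed=4)
        sim = simulate_exome(cfg)
        ratio = sim.case_table["mean_cov"].to_numpy() / \
            sim.control_table["mean_cov"].to_numpy()
        se = ratio.std() / np.sqrt(len(ratio))
        # E[X/Y] carries the Jensen bias 1 + Var_rel(Y) + O(Var^2) for a
        # noisy denominator; the median is bias-free
        rel_var = (0.3 / 2) ** 2 / 3
        assert abs(ratio.mean() - (1.0 + rel_var)) < max(3 * se, 5e-3)
        assert abs(np.median(ratio) - 1.0) < 0.01

    def test_oversized_event_rejected(self):
        cfg = SimConfig(n_exons={"1": 50}, seed=5,
                        fixed_events=(FixedEvent("1", 10, 100, 1),))
        with pytest.raises(ValueError):
            simulate_exome(cfg)

    def test_events_non_overlapping_with_gap(self):
        cfg = SimConfig(n_exons={"1": 5000}, p_cn1=5e-3, event_size=10,
                        min_gap=30, seed=6)
        sim = simulate_exome(cfg)
        evs = sorted(sim.truth, key=lambda e: e.first_exon)
        assert len(evs) >= 2
        for a, b in zip(evs, evs[1:]):
            assert b.first_exon > a.last_exon + 30


class TestAllelicModel:
    def test_reflection_folds_into_bounds(self):
        assert _reflect(-3.0, 50.0) == 3.0
        assert _reflect(53.0, 50.0) == 47.0
        assert _reflect(20.0, 50.0) == 20.0
        assert _reflect(0.0, 0.0) == 0.0

    def test_zero_allelic_noise_centers_on_half(self):
        cfg = SimConfig(n_exons={"1": 3000}, rnd_cn=0.0, rnd_ai=0.0,
                        het_density=0.3, seed=7)
        sim = simulate_exome(cfg)
        het = sim.het_table
        assert len(het) > 500
        frac = het["case_c1"] / (het["case_c1"] + het["case_c2"])
        # top-allele fraction of a Binomial(100, 0.5): folded mean ~0.54
        assert 0.5 <= frac.mean() <= 0.56
        totals = het["case_c1"] + het["case_c2"]
        assert (totals == 100).all()

    def test_perturbed_expectation_respects_eq8_range(self):
        """The enforced allelic perturbation has amplitude cov*RndAI around
        n/2 before binomial sampling."""
        rng = np.random.default_rng(0)
        n, cov, r = 100.0, 100.0, 0.3
        mu = n * 0.5 + cov * r * (2 * rng.random(10000) - 1)
        p_obs = np.array([_reflect(m, n) / n for m in mu])
        assert p_obs.min() >= 0.5 - r - 1e-12
        assert p_obs.max() <= 0.5 + r + 1e-12
        assert abs(p_obs.mean() - 0.5) < 0.01

    def test_copy_states_drive_expected_fractions(self):
        cfg = SimConfig(
            n_exons={"4": 800}, rnd_cn=0.0, rnd_ai=0.0, seed=8,
            fixed_events=(FixedEvent("4", 50, 100, -1, n_het=40),
                          FixedEvent("4", 300, 100, 1, n_het=40),
                          FixedEvent("4", 600, 100, 2, n_het=40)))
        sim = simulate_exome(cfg)
        by_cat = {}
        for ev in sim.truth:
            for chrom, pos, cat in ev.het_positions:
                row = sim.het_table[(sim.het_table.chrom == chrom)
                                    & (sim.het_table.pos == pos)].iloc[0]
                by_cat.setdefault(cat, []).append(
                    (row.case_c1 + row.case_c2,
                     row.case_c1 / max(row.case_c1 + row.case_c2, 1)))
        totals = {c: np.mean([t for t, _ in v]) for c, v in by_cat.items()}
        fracs = {c: np.mean([f for _, f in v]) for c, v in by_cat.items()}
        assert totals["copy_loss"] == pytest.approx(50, abs=1)
        assert totals["gain_1"] == pytest.approx(150, abs=1)
        assert totals["gain_2plus"] == pytest.approx(200, abs=1)
        assert fracs["copy_loss"] == pytest.approx(1.0, abs=0.02)
        assert fracs["gain_1"] == pytest.approx(2 / 3, abs=0.03)
        assert fracs["gain_2plus"] == pytest.approx(3 / 4, abs=0.03)

    def test_ai_preset_layout(self):
        sim = simulate_exome(preset_config("ai_sweep", seed=0, rnd_ai=0.05))
        deltas = sorted(e.delta_copies for e in sim.truth)
        assert deltas == [-1, 1, 2]
        n_het = {e.delta_copies: len(e.het_positions) for e in sim.truth}
        assert n_het == {-1: 10, 1: 6, 2: 6}


class TestPresetCatalogue:
    @pytest.mark.parametrize("name", [p for p in PRESETS
                                      if p not in ("t8000",)])
    def test_presets_materialize(self, name):
        sim = simulate_exome(preset_config(name, seed=1))
        assert len(sim.case_table) == len(sim.control_table)

    def test_unknown_preset_raises(self):
        with pytest.raises(ValueError):
            preset_config("t12345")

    def test_imbalance_presets_coverages(self):
        a = preset_config("T100H25")
        assert (a.base_cov_case, a.base_cov_control) == (100.0, 25.0)
        b = preset_config("T25H100")
        assert (b.base_cov_case, b.base_cov_control) == (25.0, 100.0)
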