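"""Equilibrium isotherm fitting and tiled-segment screening statistics."""

import math

import numpy as np
import pytest
from scipy import stats

from latticebind import (
    LatticeModel,
    MassContext,
    SimConfig,
    SPRRecord,
    density_to_response,
    drift_correct,
    fit_equilibrium,
    flag_above_average,
    gen_redcat_panel,
    gen_spr_panel,
    screen_anova,
    screen_normalize,
    solve_binding_density,
    tukey_hsd,
)
from latticebind.simulate import concentration_series
from latticebind.spr import ScreenSegment


def noiseless_panel(model, ctx, cfg=SimConfig()):
    cfg_quiet = SimConfig(seed=0, spr_additive_sd_ru=0.0, spr_multiplicative_cv=0.0)
    return gen_spr_panel(model, ctx, cfg_quiet)


class TestFitEquilibrium:
    def test_noiseless_panel_recovers_generating_parameters(self, model_20bp, ctx_20bp):
        panel = noiseless_panel(model_20bp, ctx_20bp)
        fit = fit_equilibrium(panel, ctx_20bp)
        assert fit.n_best == 3
        assert fit.Kd == pytest.approx(0.92e-3, rel=1e-3)
        assert fit.rss < 1e-12

    def test_noisy_panel_recovers_within_tolerance(self, model_20bp, ctx_20bp):
        panel = gen_spr_panel(model_20bp, ctx_20bp, SimConfig(seed=7))
        fit = fit_equilibrium(panel, ctx_20bp)
        assert fit.n_best == 3
        assert fit.Kd == pytest.approx(0.92e-3, rel=0.10)
        assert fit.Kd_se > 0

    def test_underdetermined_panel_rejected(self, ctx_20bp):
        records = [
            SPRRecord(concentration=c, R_eq=r)
            for c, r in [(1e-4, 10.0), (1e-4, 11.0), (2e-4, 20.0), (2e-4, 21.0)]
        ]
        with pytest.raises(ValueError, match="distinct concentrations"):
            fit_equilibrium(records, ctx_20bp)

    def test_per_n_table_covers_grid_and_best_minimizes_rss(self, model_20bp, ctx_20bp):
        panel = noiseless_panel(model_20bp, ctx_20bp)
        fit = fit_equilibrium(panel, ctx_20bp, n_grid=range(1, 7))
        assert list(fit.per_n_table["n"]) == list(range(1, 7))
        ok = fit.per_n_table[fit.per_n_table["converged"]]
        assert fit.rss == pytest.approx(ok["rss"].min())

    def test_invariant_to_replicate_ordering(self, model_20bp, ctx_20bp):
        panel = gen_spr_panel(model_20bp, ctx_20bp, SimConfig(seed=3))
        shuffled = panel.sample(frac=1.0, random_state=0)
        a = fit_equilibrium(panel, ctx_20bp)
        b = fit_equilibrium(shuffled, ctx_20bp)
        assert a.Kd == pytest.approx(b.Kd, rel=1e-9)
        assert a.n_best == b.n_best

    def test_invariant_to_uniform_response_rescaling(self, model_20bp, ctx_20bp):
        # doubling both R_L and every R_eq leaves observed densities unchanged
        panel = gen_spr_panel(model_20bp, ctx_20bp, SimConfig(seed=4))
        scaled = panel.copy()
        scaled["R_eq_RU"] = scaled["R_eq_RU"] * 2.0
        ctx2 = MassContext(
            M_protein=ctx_20bp.M_protein, M_DNA=ctx_20bp.M_DNA, N=ctx_20bp.N, R_L=2 * ctx_20bp.R_L
        )
        a = fit_equilibrium(panel, ctx_20bp)
        b = fit_equilibrium(scaled, ctx2)
        assert a.Kd == pytest.approx(b.Kd, rel=1e-9)
        assert a.n_best == b.n_best


def make_segments(densities_ru, r_l=450.0, replicates=3):
    """Segments with fixed replicate responses (RU) per entry."""
    return [
        ScreenSegment(
            segment_id=f"S{i+1}", genome="g", position=25 * i, R_L=r_l,
            responses=[r] * replicates, cycle=i,
        )
        for i, r in enumerate(densities_ru)
    ]


class TestScreenNormalize:
    def test_zero_responses_give_zero_density(self, ctx_30bp):
        segs = screen_normalize(make_segments([0.0, 0.0]), ctx_30bp)
        assert all(s.density == 0.0 for s in segs)

    def test_density_inversely_proportional_to_annealed_dna(self, ctx_30bp):
        a = ScreenSegment("a", "g", 0, R_L=400.0, responses=[100.0])
        b = ScreenSegment("b", "g", 0, R_L=500.0, responses=[100.0])
        out = screen_normalize([a, b], ctx_30bp)
        assert out[0].density / out[1].density == pytest.approx(5 / 4, rel=1e-12)

    def test_negative_responses_clamped(self, ctx_30bp, caplog):
        seg = ScreenSegment("a", "g", 0, R_L=450.0, responses=[-2.0, 4.0])
        with caplog.at_level("WARNING"):
            out = screen_normalize([seg], ctx_30bp)
        assert out[0].replicate_densities[0] == 0.0
        assert out[0].replicate_densities[1] > 0.0
        assert "clamped" in caplog.text

    def test_missing_r_l_skipped_with_warning(self, ctx_30bp, caplog):
        segs = [
            ScreenSegment("a", "g", 0, R_L=float("nan"), responses=[1.0]),
            ScreenSegment("b", "g", 0, R_L=450.0, responses=[1.0]),
        ]
        with caplog.at_level("WARNING"):
            out = screen_normalize(segs, ctx_30bp)
        assert [s.segment_id for s in out] == ["b"]

    def test_generator_round_trip(self, ctx_30bp):
        base = LatticeModel(Ka=1 / 0.92e-3, n=3, N=30)
        cfg = SimConfig(seed=5)
        segs, truth = gen_redcat_panel(8, base, cfg=cfg, ctx=ctx_30bp)
        segs = screen_normalize(segs, ctx_30bp)
        v = solve_binding_density(cfg.screen_conc, base)
        expect = v * 30
        for s in segs:
            assert s.density == pytest.approx(expect, rel=0.1)
            assert s.density_per_bp == pytest.approx(s.density / 30, rel=1e-12)


class TestDriftCorrect:
    def test_stable_standard_leaves_panel_unchanged(self, ctx_30bp):
        segs = make_segments([50.0, 80.0, 50.0, 90.0, 50.0])
        for i in (0, 2, 4):
            segs[i].segment_id = "STD"
        segs = screen_normalize(segs, ctx_30bp)
        out = drift_correct(segs, "STD")
        for a, b in zip(segs, out):
            assert b.density == pytest.approx(a.density, rel=1e-12)

    def test_linear_drift_rescaled_block_by_block(self, ctx_30bp):
        # standard reads 10% high in the second block: that block shrinks by 1/1.1
        responses = [100.0, 80.0, 110.0, 88.0]  # STD, seg1 | STD*1.1, seg2
        segs = make_segments(responses)
        segs[0].segment_id = segs[2].segment_id = "STD"
        segs = screen_normalize(segs, ctx_30bp)
        out = drift_correct(segs, "STD")
        d = {s.cycle: s.density for s in out}
        grand_factor = (100 + 110) / 2
        assert d[1] == pytest.approx(segs[1].density * grand_factor / 100.0, rel=1e-12)
        assert d[3] == pytest.approx(segs[3].density * grand_factor / 110.0, rel=1e-12)
        # corrected standards sit exactly at their grand mean
        assert d[0] == pytest.approx(d[2], rel=1e-12)

    def test_single_standard_passes_through_with_warning(self, ctx_30bp, caplog):
        segs = screen_normalize(make_segments([50.0, 60.0]), ctx_30bp)
        with caplog.at_level("WARNING"):
            out = drift_correct(segs, "S1")
        assert "skipped" in caplog.text
        assert [s.density for s in out] == [s.density for s in segs]


class TestScreenAnova:
    def test_identical_groups_give_zero_f(self):
        groups = {"a": [1.0, 1.0, 1.0], "b": [1.0, 1.0, 1.0]}
        res = screen_anova(groups)
        assert res.F == 0.0

    def test_two_groups_equal_squared_t(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 6), rng.normal(0.5, 1, 6)
        res = screen_anova({"a": a, "b": b})
        t, _ = stats.ttest_ind(a, b)
        assert res.F == pytest.approx(t**2, rel=1e-10)

    def test_four_group_table_matches_textbook_formula(self):
        groups = {
            "a": [4.0, 5.0, 6.0],
            "b": [7.0, 8.0, 9.0],
            "c": [5.0, 5.5, 6.5],
            "d": [10.0, 11.0, 12.0],
        }
        vals = [np.array(v) for v in groups.values()]
        grand = np.mean(np.concatenate(vals))
        ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in vals)
        ss_within = sum(((v - v.mean()) ** 2).sum() for v in vals)
        f_hand = (ss_between / 3) / (ss_within / 8)
        res = screen_anova(groups)
        assert res.F == pytest.approx(f_hand, rel=1e-12)
        assert (res.df_between, res.df_within) == (3, 8)
        assert res.p_value == pytest.approx(stats.f.sf(f_hand, 3, 8), rel=1e-12)

    def test_singleton_group_excluded_with_warning(self, caplog):
        groups = {"a": [1.0, 2.0], "b": [1.5, 2.5], "c": [9.0]}
        with caplog.at_level("WARNING"):
            res = screen_anova(groups)
        assert res.df_between == 1
        assert "excluded" in caplog.text

    def test_null_rejection_rate_matches_alpha(self, ctx_30bp):
        # type-I calibration on a smaller batch; the full 500-panel run
        # lives in the acceptance suite
        base = LatticeModel(Ka=1 / 0.92e-3, n=3, N=30)
        rej = 0
        nsim = 100
        for s in range(nsim):
            segs, _ = gen_redcat_panel(16, base, cfg=SimConfig(seed=s), ctx=ctx_30bp)
            segs = screen_normalize(segs, ctx_30bp)
            rej += screen_anova(segs).p_value < 0.05
        se = math.sqrt(0.05 * 0.95 / nsim)
        assert abs(rej / nsim - 0.05) < 3 * se + 1e-9


class TestTukeyHsd:
    def test_identical_groups_nothing_significant(self):
        table = tukey_hsd({"a": [1.0, 1.0, 1.0], "b": [1.0, 1.0, 1.0], "c": [1.0, 1.0, 1.0]})
        assert not table["significant"].any()

    def test_large_shift_flags_all_pairs_with_that_group(self):
        rng = np.random.default_rng(1)
        groups = {k: rng.normal(0, 1, 5) for k in "abc"}
        groups["d"] = rng.normal(10 * 1.0, 1, 5)  # 10 pooled SDs away
        table = tukey_hsd(groups)
        with_d = table[(table["group1"] == "d") | (table["group2"] == "d")]
        without_d = table[(table["group1"] != "d") & (table["group2"] != "d")]
        assert with_d["significant"].all()
        assert not without_d["significant"].any()

    def test_significance_matches_studentized_range_threshold(self):
        rng = np.random.default_rng(2)
        groups = {k: rng.normal(mu, 1.0, 6) for k, mu in [("a", 0.0), ("b", 1.2), ("c", 3.0)]}
        table = tukey_hsd(groups, alpha=0.05)
        arrays = list(groups.values())
        df_w = sum(len(a) for a in arrays) - len(arrays)
        msw = sum(((a - a.mean()) ** 2).sum() for a in arrays) / df_w
        q_crit = stats.studentized_range.ppf(0.95, 3, df_w)
        hsd = q_crit * math.sqrt(msw / 6)  # equal group size 6
        for _, row in table.iterrows():
            assert row["significant"] == (abs(row["mean_diff"]) > hsd)
            assert row["q_crit"] == pytest.approx(q_crit, rel=1e-9)


class TestFlagAboveAverage:
    def test_uniform_panel_flags_nothing(self, ctx_30bp):
        segs = screen_normalize(make_segments([50.0] * 5), ctx_30bp)
        assert flag_above_average(segs).flagged == []

    def test_single_outlier_flagged(self, ctx_30bp):
        # one segment far above a tight baseline exceeds grand mean + 1 SD
        segs = screen_normalize(make_segments([50.0, 51.0, 49.0, 50.5, 120.0]), ctx_30bp)
        assert flag_above_average(segs).flagged == ["S5"]

    def test_planted_enhanced_segments_exactly_flagged(self, ctx_30bp):
        base = LatticeModel(Ka=1 / 0.92e-3, n=3, N=30)
        enhanced = {sid: 0.92e-3 / 5 for sid in ("P2", "F1", "F4")}
        segs, _ = gen_redcat_panel(16, base, enhanced=enhanced, cfg=SimConfig(seed=11), ctx=ctx_30bp)
        segs = screen_normalize(segs, ctx_30bp)
        assert sorted(flag_above_average(segs).flagged) == sorted(enhanced)

    def test_too_few_segments_rejected(self, ctx_30bp):
        segs = screen_normalize(make_segments([50.0, 60.0]), ctx_30bp)
        with pytest.raises(ValueError, match=">= 3 segments"):
            flag_above_average(segs)
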