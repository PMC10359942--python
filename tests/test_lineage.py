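import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import stats

from cyclefate import (
    SimConfig,
    align_to_mitosis,
    annotate_cohort,
    concordance_table,
    mother_daughter_correlation,
    mother_daughter_window_means,
    proliferation_vs_time,
    sibling_discrepancy,
    sibling_pairs_from_cohort,
    simulate_cohort,
    window_mean,
)
from cyclefate.config import P21Params
from cyclefate.lineage import SiblingPair

from conftest import zero_noise_config

series = hnp.arrays(
    np.float64,
    st.integers(3, 25),
    elements=st.floats(-100, 100, allow_nan=False, width=32),
)


class TestAlignToMitosis:
    def test_mother_occupies_negative_daughter_positive_time(
        self, small_clean_cohort
    ):
        coh = small_clean_cohort
        anchored, excluded = align_to_mitosis(coh.tracks, coh.lineage)
        roles = {a.cell_id: a for a in anchored}
        for t in coh.mothers:
            if t.cell_id not in roles:
                continue
            a = roles[t.cell_id]
            assert a.role == "mother"
            assert a.rel_times[-1] < 0
            assert a.rel_times[0] == pytest.approx(
                t.birth_time - t.truth["division_time"]
            )
        for t in coh.daughters:
            a = roles[t.cell_id]
            assert a.role == "daughter"
            assert a.rel_times[0] == 0.0

    def test_sample_counts_conserved(self, small_clean_cohort):
        coh = small_clean_cohort
        anchored, excluded = align_to_mitosis(coh.tracks, coh.lineage)
        total_before = sum(
            len(t.times) for t in coh.tracks if t.cell_id not in excluded
        )
        assert total_before == sum(len(a.rel_times) for a in anchored)

    def test_undivided_cells_excluded(self):
        coh = simulate_cohort(
            zero_noise_config(condition="glucose_depletion", n_mothers=20,
                              rng_seed=19)
        )
        quiescent = [
            t.cell_id for t in coh.daughters if t.truth["fate"] == "quiescent"
        ]
        # quiescent daughters never divide, but as daughters they are anchored
        # by their own birth; a track absent from the lineage is excluded
        orphan = coh.mothers[0]
        anchored, excluded = align_to_mitosis(
            [t for t in coh.tracks if t.cell_id != orphan.cell_id], coh.lineage
        )
        assert set(excluded) == set()
        anchored2, excluded2 = align_to_mitosis([orphan], coh.lineage.iloc[:0])
        assert excluded2 == [orphan.cell_id]

    def test_heatmap_row_order_matches_true_g1_ranking(self):
        """Sorting cells by measured G1 length reproduces the ground-truth
        ordering (mitosis-anchored heatmap layout)."""
        coh = simulate_cohort(
            zero_noise_config(condition="control", n_mothers=60, rng_seed=37)
        )
        anns = {a.cell_id: a for a in annotate_cohort(coh)}
        cells = [t for t in coh.mothers if np.isfinite(anns[t.cell_id].durations["d_G1"])]
        measured = np.array([anns[t.cell_id].durations["d_G1"] for t in cells])
        true = np.array([t.truth["t_G1S"] - t.birth_time for t in cells])
        rho = stats.spearmanr(measured, true).statistic
        assert rho > 0.99


class TestWindowMean:
    def test_constant_trace(self):
        t = np.arange(-10, 10.25, 0.25)
        v = np.full(len(t), 4.2)
        assert window_mean(t, v, "pre", 5.0) == pytest.approx(4.2)
        assert window_mean(t, v, "post", 3.0) == pytest.approx(4.2)

    def test_ramp_over_post_window(self):
        # p21 = t sampled at 0.25 h over (0, 5]: mean of 0.25..5.00 = 2.625
        t = np.arange(0, 48.25, 0.25)
        assert window_mean(t, t, "post", 5.0) == pytest.approx(2.625)

    def test_empty_window_is_nan(self):
        t = np.arange(0, 10.0, 0.25)
        assert np.isnan(window_mean(t, t, "pre", 5.0))

    def test_mother_pre_window_tracks_g2m_plateau(self):
        coh = simulate_cohort(
            zero_noise_config(condition="glucose_depletion", n_mothers=40,
                              rng_seed=41)
        )
        wm = mother_daughter_window_means(coh)
        g1 = wm[wm.group == "G1"]
        by_id = {t.cell_id: t for t in coh.tracks}
        # the pre-mitosis mean sits below the final plateau but scales with it
        levels = np.array([by_id[m].truth["p21_level"] for m in g1.mother_id])
        assert stats.pearsonr(levels, g1.pre_mean).statistic > 0.8


class TestMotherDaughterCorrelation:
    def test_exact_half_inheritance_gives_r_one(self, rng):
        pre = rng.lognormal(4, 0.5, 50)
        out = mother_daughter_correlation(pre, pre / 2.0)
        assert out["r"] == pytest.approx(1.0)

    def test_shuffled_pairing_destroys_correlation(self):
        coh = simulate_cohort(
            SimConfig(condition="glucose_depletion", n_mothers=400, rng_seed=43)
        )
        wm = mother_daughter_window_means(coh)
        g1 = wm[wm.group == "G1"]
        r_true = mother_daughter_correlation(g1.pre_mean, g1.post_mean)["r"]
        shuffled = np.random.default_rng(0).permutation(g1.post_mean.to_numpy())
        r_null = mother_daughter_correlation(g1.pre_mean, shuffled)["r"]
        assert r_true > 0.6
        assert abs(r_null) < 0.15

    def test_agrees_with_brute_force_covariance(self, rng):
        x, y = rng.random(200), rng.random(200)
        r = mother_daughter_correlation(x, y)["r"]
        brute = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert r == pytest.approx(brute, abs=1e-12)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            mother_daughter_correlation([1, 2], [3, 4])

    def test_zero_variance_flagged(self):
        out = mother_daughter_correlation([1, 1, 1], [1, 2, 3])
        assert out["flag"] == "zero variance"
        assert np.isnan(out["r"])


class TestSiblingDiscrepancy:
    def test_identical_series_give_zero(self, rng):
        x = rng.random(10)
        d, r2 = sibling_discrepancy(x, x)
        assert d == 0.0 and r2 == 1.0

    def test_reversed_triple_oracle(self):
        # sum (x-y)^2 = 8; denominators 2 + 2
        d, r2 = sibling_discrepancy([1, 2, 3], [3, 2, 1])
        assert d == pytest.approx(4.0)
        assert r2 == pytest.approx(-3.0)

    def test_both_constant_undefined(self):
        with pytest.raises(ValueError):
            sibling_discrepancy([2, 2, 2], [5, 5, 5])

    @settings(deadline=None, max_examples=60)
    @given(x=series, y=series)
    def test_invariances(self, x, y):
        n = min(len(x), len(y))
        x, y = x[:n], y[:n]
        denom = ((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()
        if n < 2 or denom < 1e-8:
            return
        d, _ = sibling_discrepancy(x, y)
        assert d >= 0.0
        # symmetry
        assert sibling_discrepancy(y, x)[0] == pytest.approx(d, rel=1e-9)
        # common additive shift
        assert sibling_discrepancy(x + 17.5, y + 17.5)[0] == pytest.approx(
            d, rel=1e-6, abs=1e-9
        )
        # common positive rescaling
        assert sibling_discrepancy(3.25 * x, 3.25 * y)[0] == pytest.approx(
            d, rel=1e-9
        )


class TestConcordance:
    def test_fate_pair_rules(self):
        qq = SiblingPair("p1", "a", "b", np.zeros(3), np.zeros(3),
                         "quiescent", "quiescent")
        qp = SiblingPair("p2", "c", "d", np.zeros(3), np.zeros(3),
                         "quiescent", "proliferative")
        assert qq.concordance == "concordant"
        assert qp.concordance == "discordant"
        table = concordance_table([qq, qp]).set_index("group")
        assert table.loc["all", "concordant"] == 1
        assert table.loc["all", "discordant"] == 1

    def test_shared_inheritance_forces_full_concordance_without_split_noise(self):
        coh = simulate_cohort(
            zero_noise_config(
                condition="glucose_depletion", n_mothers=120, rng_seed=47,
                p21_params=P21Params(split_sd=0.0),
            )
        )
        pairs = sibling_pairs_from_cohort(coh)
        g1 = [p for p in pairs if p.group == "G1"]
        assert g1
        assert all(p.concordance == "concordant" for p in g1)

    def test_s_group_discordance_matches_binomial_expectation(self):
        """Independent de-novo accumulation: discordant fraction converges to
        2 p (1 - p) with p = 0.5122."""
        disc = tot = 0
        for seed in range(6):
            coh = simulate_cohort(
                SimConfig(condition="glucose_depletion", n_mothers=200,
                          rng_seed=seed)
            )
            for p in sibling_pairs_from_cohort(coh):
                if p.group != "S":
                    continue
                tot += 1
                disc += p.concordance == "discordant"
        expected = 2 * 0.5122 * (1 - 0.5122)
        ci = stats.binomtest(disc, tot).proportion_ci(confidence_level=0.999)
        assert ci.low <= expected <= ci.high


class TestProliferationVsTime:
    def test_two_extreme_bins_give_unit_magnitude(self):
        ttm = list(np.linspace(0.1, 1.2, 10)) + list(np.linspace(5.3, 6.4, 10))
        fate = [True] * 10 + [False] * 10
        _, corr = proliferation_vs_time(ttm, fate, bin_width=1.3)
        assert abs(corr["r"]) == pytest.approx(1.0)

    def test_independent_fates_give_null_correlation(self, rng):
        rs = []
        for _ in range(20):
            ttm = rng.uniform(0, 20, 600)
            fate = rng.random(600) < 0.5
            _, corr = proliferation_vs_time(ttm, fate)
            rs.append(corr["r"])
        assert abs(np.mean(rs)) < 0.15

    def test_generator_coupling_produces_strong_inverse_relation(
        self, depletion_cohort
    ):
        coh = depletion_cohort
        div_of = dict(zip(coh.lineage.cell_id, coh.lineage.division_time_h))
        ttm, prolif = [], []
        for t in coh.daughters:
            ttm.append(div_of[t.cell_id])
            prolif.append(t.truth["fate"] == "proliferative")
        _, corr = proliferation_vs_time(ttm, prolif)
        assert abs(corr["r"]) >= 0.9
        assert corr["r"] < 0  # slower mothers -> fewer proliferating daughters

    def test_single_bin_flagged(self):
        _, corr = proliferation_vs_time([1.0, 1.1], [True, False])
        assert corr["flag"] == "correlation undefined"
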