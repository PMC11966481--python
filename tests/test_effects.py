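"""Covariate residualization and effect-size maps."""

import numpy as np
import pytest

from corticalmark import (
    DeficitPatternModel,
    SimulationConfig,
    cohens_d_map,
    flag_significant,
    residualize,
    simulate_regional_cohort,
    summarize_map,
)
from conftest import make_table


class TestResidualize:
    def test_perfect_age_fit_leaves_grand_mean(self):
        table = make_table([[1.0], [2.0], [3.0]], dx=[0, 0, 1], age=[1, 2, 3])
        adj, model = residualize(table, covariates=("age",))
        assert np.allclose(adj.measures["r0"], [2.0, 2.0, 2.0])
        assert model.coefficients.loc["age", "r0"] == pytest.approx(1.0)

    def test_singular_design_constant_sex(self):
        table = make_table([[1.0], [2.0], [3.0]], dx=[0, 0, 1], age=[1, 2, 3], sex=[1, 1, 1])
        with pytest.raises(ValueError, match="singular"):
            residualize(table, covariates=("age", "sex"))

    def test_orthogonality_and_scale_preservation(self, small_cohort):
        adj, model = residualize(small_cohort)
        age = small_cohort.subjects["age"].to_numpy()
        sex = small_cohort.subjects["sex"].to_numpy(float)
        for region in adj.measures.columns:
            resid = adj.measures[region].to_numpy() - adj.measures[region].mean()
            scale = np.abs(small_cohort.measures[region]).max()
            assert abs(np.inner(resid, age - age.mean())) < 1e-8 * scale * len(age)
            assert abs(np.inner(resid, sex - sex.mean())) < 1e-8 * scale * len(age)
        # re-centering keeps the measure scale
        assert np.allclose(
            adj.measures.mean(axis=0), small_cohort.measures.mean(axis=0), atol=0.05
        )

    def test_null_covariates_leave_measures_nearly_unchanged(self):
        cfg = SimulationConfig(n_cases=1000, n_controls=1000, region_count=4, seed=8)
        t = simulate_regional_cohort(cfg)
        adj, _ = residualize(t)
        dev = np.abs(adj.measures.to_numpy() - t.measures.to_numpy())
        assert dev.max() < 0.05  # fitted nuisance slopes shrink toward 0 with n

    def test_controls_only_mode_ignores_cases(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=40)
        age = rng.uniform(20, 70, 40)
        dx = np.repeat([0, 1], 20)
        t1 = make_table(y[:, None], dx=dx, age=age)
        y2 = y.copy()
        y2[dx == 1] += 100.0  # wildly different cases must not move the fit
        t2 = make_table(y2[:, None], dx=dx, age=age)
        _, m1 = residualize(t1, covariates=("age",), adjustment="controls_only")
        _, m2 = residualize(t2, covariates=("age",), adjustment="controls_only")
        assert np.allclose(m1.coefficients.to_numpy(), m2.coefficients.to_numpy())


class TestCohensD:
    def test_hand_example_d_one(self):
        table = make_table(
            np.array([[1.0], [2.0], [3.0], [0.0], [1.0], [2.0]]), dx=[1, 1, 1, 0, 0, 0]
        )
        row = cohens_d_map(table).iloc[0]
        assert row["d"] == pytest.approx(1.0)
        assert row["n_case"] == 3 and row["n_control"] == 3

    def test_identical_groups(self):
        table = make_table(np.array([[1.0], [2.0], [1.0], [2.0]]), dx=[1, 1, 0, 0])
        row = cohens_d_map(table).iloc[0]
        assert row["d"] == pytest.approx(0.0)
        assert row["p"] == pytest.approx(1.0)

    def test_zero_pooled_sd_warns_nan(self):
        table = make_table(np.array([[2.0], [2.0], [0.0], [0.0]]), dx=[1, 1, 0, 0])
        with pytest.warns(RuntimeWarning, match="pooled SD"):
            row = cohens_d_map(table).iloc[0]
        assert np.isnan(row["d"])

    def test_small_group_skipped(self):
        table = make_table(np.array([[1.0], [2.0], [3.0]]), dx=[1, 0, 0])
        with pytest.warns(RuntimeWarning, match="fewer than 2"):
            out = cohens_d_map(table)
        assert len(out) == 0

    def test_scale_invariance(self, small_cohort):
        base = cohens_d_map(small_cohort)
        scaled = small_cohort.with_measures(small_cohort.measures * 37.5)
        out = cohens_d_map(scaled)
        for col in ("d", "t", "p"):
            assert np.allclose(base[col], out[col])

    def test_case_deficit_is_negative(self):
        cfg = SimulationConfig(n_cases=400, n_controls=400, region_count=3, planted_d=-0.6, seed=1)
        d = cohens_d_map(simulate_regional_cohort(cfg))["d"]
        assert (d < 0).all()


class TestSummaryAndFlags:
    def test_mean_sd(self):
        table = make_table(np.zeros((4, 3)), dx=[0, 0, 1, 1])
        es = cohens_d_map(table).assign(d=[-0.2, -0.3, -0.4])
        s = summarize_map(es)
        assert s["mean_d"] == pytest.approx(-0.3)
        assert s["sd_d"] == pytest.approx(0.1)
        assert s["ranking"][0][0] == "r2"  # largest |d| first

    def test_single_region_error(self):
        table = make_table(np.zeros((4, 1)), dx=[0, 0, 1, 1])
        es = cohens_d_map(table).assign(d=[0.1])
        with pytest.raises(ValueError, match="at least 2"):
            summarize_map(es)

    def test_planted_mean_recovered_at_large_n(self):
        planted = np.full(6, -0.3)
        cfg = SimulationConfig(
            n_cases=2000, n_controls=2000, region_count=6, planted_d=planted, seed=12
        )
        s = summarize_map(cohens_d_map(simulate_regional_cohort(cfg)))
        assert s["mean_d"] == pytest.approx(-0.3, abs=0.02)

    @pytest.mark.parametrize(
        "p,expected",
        [(0.0014, True), (0.01, False)],  # 0.05/33 ~ 0.0015152
    )
    def test_bonferroni_threshold_33_regions(self, p, expected):
        table = make_table(np.zeros((4, 33)), dx=[0, 0, 1, 1])
        es = cohens_d_map(table)
        es["p"] = 0.5
        es.loc[0, "p"] = p
        flagged = flag_significant(es, alpha=0.05)
        assert bool(flagged.loc[0, "sig_bonferroni"]) is expected

    def test_single_region_reduces_to_plain_alpha(self):
        table = make_table(np.zeros((4, 1)), dx=[0, 0, 1, 1])
        es = cohens_d_map(table)
        es["p"] = 0.049
        assert flag_significant(es, alpha=0.05)["sig_bonferroni"].iloc[0]


def test_model_results_roundtrip(small_cohort, tmp_path):
    res = DeficitPatternModel(small_cohort).fit()
    assert set(res.effect_sizes.columns) >= {"region", "d", "t", "p", "sig_bonferroni"}
    assert "mean d" in res.summary()
    res.to_tsv(tmp_path / "es.tsv")
    assert (tmp_path / "es.tsv").read_text().startswith("region\t")
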