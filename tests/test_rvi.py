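"""Regional Vulnerability Index: reference, z-scoring, scoring, contrasts."""

import numpy as np
import pandas as pd
import pytest

from corticalmark import (
    RVIModel,
    SimulationConfig,
    TemplateVector,
    build_control_reference,
    residualize,
    rvi_group_contrast,
    rvi_scores,
    rvi_symptom_association,
    simulate_regional_cohort,
    zscore_subjects,
)
from conftest import make_table


def template(values, names=None):
    names = names or [f"r{j}" for j in range(len(values))]
    return TemplateVector(pd.Series(np.asarray(values, float), index=names))


class TestControlReference:
    def test_mean_and_sample_sd(self):
        t = make_table(np.array([[0.0], [2.0], [5.0]]), dx=[0, 0, 1])
        ref = build_control_reference(t)
        assert ref.mean["r0"] == pytest.approx(1.0)
        assert ref.sd["r0"] == pytest.approx(np.sqrt(2.0))

    def test_constant_region_excluded(self):
        t = make_table(np.array([[1.0, 0.0], [1.0, 2.0], [9.0, 9.0]]), dx=[0, 0, 1])
        with pytest.warns(RuntimeWarning, match="excluded"):
            ref = build_control_reference(t)
        assert ref.excluded == ["r0"]
        assert ref.regions == ["r1"]

    def test_cases_do_not_move_reference(self):
        base = np.array([[0.0], [2.0], [5.0]])
        shifted = base.copy()
        shifted[2] = 500.0
        r1 = build_control_reference(make_table(base, dx=[0, 0, 1]))
        r2 = build_control_reference(make_table(shifted, dx=[0, 0, 1]))
        assert r1.mean.equals(r2.mean) and r1.sd.equals(r2.sd)

    def test_too_few_controls(self):
        with pytest.raises(ValueError, match="2 controls"):
            build_control_reference(make_table(np.zeros((3, 2)), dx=[0, 1, 1]))


class TestZScores:
    def test_known_values(self):
        t = make_table(np.array([[0.0], [2.0], [1.0], [1.0 + np.sqrt(2)]]), dx=[0, 0, 1, 1])
        ref = build_control_reference(t)
        z = zscore_subjects(t, ref)
        assert z.iloc[2, 0] == pytest.approx(0.0)  # case at the control mean
        assert z.iloc[3, 0] == pytest.approx(1.0)  # mu + sigma

    def test_controls_standardized_exactly(self, small_cohort):
        ref = build_control_reference(small_cohort)
        z = zscore_subjects(small_cohort, ref)
        ctrl = z[(small_cohort.subjects["dx"] == 0).to_numpy()]
        assert np.abs(ctrl.mean(axis=0)).max() < 1e-10
        assert np.allclose(ctrl.std(axis=0, ddof=1), 1.0)

    def test_missing_region_error(self):
        t = make_table(np.zeros((4, 2)), dx=[0, 0, 1, 1])
        ref = build_control_reference(
            make_table(np.random.default_rng(0).normal(size=(4, 3)), dx=[0, 0, 1, 1])
        )
        with pytest.raises(ValueError, match="lacks"):
            zscore_subjects(t, ref)


class TestRVIScores:
    def test_proportional_row_scores_one(self):
        tpl = template([-0.5, -0.2, -0.1, -0.4])
        z = pd.DataFrame([2.0 * tpl.values.to_numpy()], columns=tpl.regions)
        assert rvi_scores(z, tpl).iloc[0] == pytest.approx(1.0)

    def test_negated_row_scores_minus_one(self):
        tpl = template([-0.5, -0.2, -0.1, -0.4])
        z = pd.DataFrame([-tpl.values.to_numpy()], columns=tpl.regions)
        assert rvi_scores(z, tpl).iloc[0] == pytest.approx(-1.0)

    def test_null_mean_over_10000_subjects(self):
        rng = np.random.default_rng(0)
        tpl = template(rng.uniform(-0.5, 0, 34), [f"g{j}" for j in range(34)])
        z = pd.DataFrame(rng.normal(size=(10_000, 34)), columns=tpl.regions)
        assert abs(rvi_scores(z, tpl).mean()) < 0.01

    def test_affine_template_invariance_and_sign_flip(self, rng):
        vals = rng.uniform(-0.5, 0, 8)
        tpl = template(vals)
        z = pd.DataFrame(rng.normal(size=(20, 8)), columns=tpl.regions)
        s0 = rvi_scores(z, tpl)
        s1 = rvi_scores(z, template(3.0 * vals + 0.7))
        s2 = rvi_scores(z, template(-vals))
        assert np.allclose(s0, s1)
        assert np.allclose(s0, -s2)

    def test_zero_variance_subject_nan(self):
        tpl = template([-0.5, -0.2, -0.1])
        z = pd.DataFrame([[1.0, 1.0, 1.0]], columns=tpl.regions)
        with pytest.warns(RuntimeWarning, match="zero deviation"):
            assert np.isnan(rvi_scores(z, tpl).iloc[0])

    def test_region_mismatch_lists_difference(self, rng):
        tpl = template([-0.5, -0.2, -0.1], ["a", "b", "c"])
        z = pd.DataFrame(rng.normal(size=(2, 3)), columns=["x", "y", "zz"])
        with pytest.raises(ValueError, match="mismatch"):
            rvi_scores(z, tpl)


class TestContrastAndAssociation:
    def test_equal_groups_zero_d(self):
        s = pd.Series([0.1, 0.2, 0.1, 0.2])
        out = rvi_group_contrast(s, [1, 1, 0, 0])
        assert out["cohen_d"] == pytest.approx(0.0)

    def test_severity_identity_r_one(self):
        s = pd.Series([0.1, 0.5, 0.3, 0.9])
        out = rvi_symptom_association(s, s.to_numpy())
        assert out["pearson_r"] == pytest.approx(1.0)
        assert out["n"] == 4

    def test_missing_severity_excluded(self, rng):
        s = pd.Series(rng.normal(size=10))
        sev = rng.normal(size=10)
        sev[:4] = np.nan
        assert rvi_symptom_association(s, sev)["n"] == 6

    def test_independent_severity_near_zero(self):
        rng = np.random.default_rng(2)
        s = pd.Series(rng.normal(size=10_000))
        out = rvi_symptom_association(s, rng.normal(size=10_000))
        assert abs(out["pearson_r"]) < 0.03


class TestRVIModel:
    def _cohort_and_template(self, strength=1.0, seed=0, n=500):
        rng = np.random.default_rng(seed)
        d = rng.uniform(-0.5, 0, 34)
        cfg = SimulationConfig(
            n_cases=n, n_controls=n, planted_d=strength * d, seed=seed, severity_link=0.4
        )
        table = simulate_regional_cohort(cfg)
        tpl = TemplateVector(pd.Series(d, index=cfg.region_names), "planted")
        return table, tpl

    def test_aligned_pattern_positive_contrast(self):
        table, tpl = self._cohort_and_template(seed=0)
        res = RVIModel(table, tpl).fit()
        assert res.group_contrast["cohen_d"] > 0.2
        assert res.symptom_association is not None
        assert res.symptom_association["pearson_r"] > 0.0

    def test_contrast_grows_with_pattern_strength(self):
        ds = []
        for strength in (0.25, 0.5, 1.0):
            table, tpl = self._cohort_and_template(strength=strength, seed=0)
            ds.append(RVIModel(table, tpl).fit().group_contrast["cohen_d"])
        assert ds[0] < ds[1] < ds[2]

    def test_decoupled_template_ci_covers_zero(self):
        table, tpl = self._cohort_and_template(seed=0)
        rng = np.random.default_rng(99)
        perm = rng.permutation(34)
        shuffled = TemplateVector(
            pd.Series(tpl.values.to_numpy()[perm], index=tpl.regions), "shuffled"
        )
        out = RVIModel(table, shuffled).fit().group_contrast
        se = np.sqrt(1 / out["n_case"] + 1 / out["n_control"])
        assert abs(out["cohen_d"]) < 1.96 * se
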