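import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tuberome import (fit_and_contrast, generate_assay, stage_sums,
                      estimated_marginal_means)
from tuberome.assay_stats import AssayError
import statsmodels.formula.api as smf


def _assay(stage_map, n=6, reps=(1, 2)):
    rows = []
    for treatment, stages in stage_map.items():
        for rep in reps:
            for d, s in enumerate(stages):
                rows.append(dict(disc_id=f"{treatment}_{rep}_{d}",
                                 treatment=treatment, variety="LC",
                                 repetition=rep, stage=s))
    return pd.DataFrame(rows)


class TestStageSums:
    def test_all_dormant_sum_zero(self):
        df = _assay({"TSB10": [0] * 6})
        sums, avg = stage_sums(df)
        assert (sums.stage_sum == 0).all() and avg["TSB10"] == 0

    def test_addition_and_repetition_average(self):
        df = pd.DataFrame([
            dict(treatment="t", repetition=1, stage=s)
            for s in [0, 1, 1, 2, 0, 3]] + [
            dict(treatment="t", repetition=2, stage=s)
            for s in [2, 2, 2, 3, 0, 0]])
        sums, avg = stage_sums(df)
        assert set(sums.stage_sum) == {7, 9}
        assert avg["t"] == 8

    def test_missing_column_rejected(self):
        with pytest.raises(AssayError):
            stage_sums(pd.DataFrame({"treatment": ["a"]}))

    def test_invalid_stage_rejected(self):
        df = _assay({"a": [0, 4, 0, 0, 0, 0]})
        with pytest.raises(AssayError, match="BBCH"):
            stage_sums(df)


class TestFitAndContrast:
    def test_balanced_contrast_equals_mean_difference(self):
        df = _assay({"TSB10": [2, 3, 2, 3, 2, 3], "x": [0, 1, 0, 1, 0, 1]})
        _, contrasts = fit_and_contrast(df)
        (c,) = contrasts
        diff = df[df.treatment == "x"].stage.mean() - \
            df[df.treatment == "TSB10"].stage.mean()
        assert c.estimate == pytest.approx(diff, abs=1e-12)

    def test_constant_response_f_zero_nothing_significant(self):
        df = _assay({"TSB10": [2] * 6, "x": [2] * 6})
        anova, contrasts = fit_and_contrast(df)
        assert anova.loc["C(treatment)", "F"] == 0
        assert all(c.p_adjusted > 0.05 and not c.inhibitor
                   and abs(c.estimate) < 1e-12 for c in contrasts)

    def test_inhibitor_detected_and_t_matches_pooled_formula(self):
        rng = np.random.default_rng(0)
        stages = {"TSB10": np.clip(np.round(rng.normal(2.0, 0.5, 12)), 0,
                                   3).astype(int),
                  "GA3": np.clip(np.round(rng.normal(2.5, 0.5, 12)), 0,
                                 3).astype(int),
                  "inhib": np.clip(np.round(rng.normal(0.2, 0.5, 12)), 0,
                                   3).astype(int)}
        stages = {k: np.where(np.isin(v, [4]), 3, v) for k, v in
                  stages.items()}
        df = pd.concat([pd.DataFrame(dict(
            treatment=k, variety="LC", repetition=1, stage=v))
            for k, v in stages.items()], ignore_index=True)
        _, contrasts = fit_and_contrast(df)
        inhib = next(c for c in contrasts if c.treatment == "inhib")
        assert inhib.estimate < 0 and inhib.p_adjusted < 0.05
        assert inhib.inhibitor
        # textbook check: t uses the pooled (all-groups) error variance
        model = smf.ols("stage ~ C(treatment)", data=df).fit()
        s2 = model.mse_resid
        a = df[df.treatment == "inhib"].stage.to_numpy()
        b = df[df.treatment == "TSB10"].stage.to_numpy()
        t_ref = (a.mean() - b.mean()) / np.sqrt(s2 * (1 / len(a)
                                                      + 1 / len(b)))
        assert inhib.t == pytest.approx(t_ref, abs=1e-10)

    def test_emms_equal_group_means_in_balanced_design(self):
        df = _assay({"TSB10": [2, 3, 1, 3, 2, 3], "x": [0, 1, 0, 2, 0, 1]})
        model = smf.ols("stage ~ C(treatment)", data=df).fit()
        emm = estimated_marginal_means(model, df)
        means = df.groupby("treatment").stage.mean()
        assert np.allclose(emm.loc[means.index], means, atol=1e-12)

    def test_dunnett_adjusted_never_below_unadjusted(self):
        df = generate_assay({"TSB10": 0.3, "a": 0.25, "b": 0.2, "c": 0.1},
                            seed=5)
        _, contrasts = fit_and_contrast(df)
        for c in contrasts:
            assert c.p_adjusted >= c.p_unadjusted - 1e-12

    def test_dunnett_matches_scipy_one_factor(self):
        rng = np.random.default_rng(1)
        groups = {k: rng.normal(m, 1, 8).round(0).clip(0, 3)
                  for k, m in [("TSB10", 1.5), ("a", 1.0), ("b", 2.0)]}
        df = pd.concat([pd.DataFrame(dict(treatment=k, variety="LC",
                                          repetition=1, stage=v))
                        for k, v in groups.items()], ignore_index=True)
        _, contrasts = fit_and_contrast(df)
        ref = stats.dunnett(groups["a"], groups["b"],
                            control=groups["TSB10"])
        mine = {c.treatment: c.p_adjusted for c in contrasts}
        assert mine["a"] == pytest.approx(ref.pvalue[0], abs=5e-3)
        assert mine["b"] == pytest.approx(ref.pvalue[1], abs=5e-3)

    def test_bonferroni_fallback(self):
        df = _assay({"TSB10": [2, 3, 2, 3, 2, 3], "x": [0, 1, 0, 1, 0, 1],
                     "y": [1, 2, 1, 2, 1, 2]})
        _, adj = fit_and_contrast(df, adjust="bonferroni")
        _, raw = fit_and_contrast(df, adjust="none")
        for a, r in zip(adj, raw):
            assert a.p_adjusted == pytest.approx(
                min(1.0, 2 * r.p_unadjusted))

    def test_missing_control_rejected(self):
        df = _assay({"a": [1] * 6, "b": [2] * 6})
        with pytest.raises(AssayError, match="TSB10"):
            fit_and_contrast(df)
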