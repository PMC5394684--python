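"""AVLT component derivation, impairment flagging and the split-plot ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from adsubtype import (
    classify_impairment,
    component_by_group_anova,
    derive_components,
    fit_norms,
    impairment_table,
)
from adsubtype.memory import ComponentAnova, PERFORMANCE_COMPONENTS


def _record(**kw):
    base = dict(avlt_t1=10, avlt_t2=10, avlt_t3=10, avlt_t4=10, avlt_t5=10,
                avlt_b=5, avlt_imm=8, avlt_del=6, avlt_rec=6)
    base.update(kw)
    return pd.DataFrame([base])


class TestDeriveComponents:
    def test_learning_is_trial_sum(self):
        comp = derive_components(_record())
        assert comp.loc[0, "learning"] == 50

    def test_gain_zero_when_equal(self):
        comp = derive_components(_record(avlt_del=6, avlt_rec=6))
        assert comp.loc[0, "gain"] == 0

    def test_gain_forty_points(self):
        comp = derive_components(_record(avlt_del=6, avlt_rec=12))
        assert comp.loc[0, "gain"] == pytest.approx(40.0)

    def test_gain_antisymmetric_under_swap(self):
        a = derive_components(_record(avlt_del=3, avlt_rec=11)).loc[0, "gain"]
        b = derive_components(_record(avlt_del=11, avlt_rec=3)).loc[0, "gain"]
        assert a == -b

    def test_missing_item_leaves_other_components(self):
        rec = _record().drop(columns=["avlt_del"])
        comp = derive_components(rec)
        assert np.isnan(comp.loc[0, "delayed"]) and np.isnan(comp.loc[0, "gain"])
        assert comp.loc[0, "learning"] == 50

    def test_idempotent_scale_exact(self):
        df = pd.concat([_record(avlt_del=d) for d in range(16)], ignore_index=True)
        c1 = derive_components(df)
        assert (c1["delayed_pct"] == 100 * df["avlt_del"] / 15).all()


class TestNorms:
    def test_mean_sd(self):
        ref = pd.DataFrame({"learning": [40.0, 50.0, 60.0]})
        norms = fit_norms(ref, components=("learning",))
        assert norms.mean["learning"] == 50
        assert norms.sd["learning"] == pytest.approx(10.0)

    def test_degenerate_reference_errors(self):
        with pytest.raises(ValueError, match="zero-variance"):
            fit_norms(pd.DataFrame({"learning": [50.0, 50.0, 50.0]}),
                      components=("learning",))
        with pytest.raises(ValueError, match="too small"):
            fit_norms(pd.DataFrame({"learning": [50.0]}), components=("learning",))

    def test_large_sample_recovery(self, rng):
        ref = pd.DataFrame({"delayed": rng.normal(8, 3, size=20_000)})
        norms = fit_norms(ref, components=("delayed",))
        assert abs(norms.mean["delayed"] - 8) < 0.1
        assert abs(norms.sd["delayed"] - 3) < 0.1


class TestImpairment:
    @pytest.fixture
    def norms(self):
        ref = pd.DataFrame({c: [45.0, 50.0, 55.0, 50.0] for c in PERFORMANCE_COMPONENTS}
                           | {"gain": [-5.0, 0.0, 5.0, 0.0]})
        return fit_norms(ref)

    def test_z_zero_not_impaired(self, norms):
        comp = pd.DataFrame([{c: 50.0 for c in PERFORMANCE_COMPONENTS} | {"gain": 0.0}])
        flags = classify_impairment(comp, norms)
        assert not flags.iloc[0].any()

    def test_boundary_inclusive(self):
        from adsubtype import ReferenceNorms
        cols = list(PERFORMANCE_COMPONENTS) + ["gain"]
        unit = ReferenceNorms(mean=pd.Series(0.0, index=cols),
                              sd=pd.Series(1.0, index=cols),
                              n=pd.Series(10, index=cols))
        comp = pd.DataFrame([{c: 0.0 for c in cols}])
        comp["learning"] = -1.5  # z exactly at the threshold counts as impaired
        assert classify_impairment(comp, unit).iloc[0]["learning"]

    def test_gain_flagged_in_positive_direction(self, norms):
        comp = pd.DataFrame([{c: 50.0 for c in PERFORMANCE_COMPONENTS}
                             | {"gain": 0.0 + 1.5 * norms.sd["gain"]}])
        flags = classify_impairment(comp, norms)
        assert flags.iloc[0]["gain"]
        comp["gain"] = -10.0  # large negative gain is not a retrieval problem
        assert not classify_impairment(comp, norms).iloc[0]["gain"]

    def test_normal_tail_rate(self, rng):
        ref = pd.DataFrame({"delayed": rng.normal(0, 1, 5000)})
        norms = fit_norms(ref, components=("delayed",))
        comp = pd.DataFrame({"delayed": rng.normal(0, 1, 100_000)})
        rate = classify_impairment(comp, norms).mean()["delayed"]
        assert rate == pytest.approx(stats.norm.cdf(-1.5), abs=0.01)

    def test_rate_non_increasing_in_threshold(self, rng):
        ref = pd.DataFrame({"delayed": rng.normal(0, 1, 5000)})
        norms = fit_norms(ref, components=("delayed",))
        comp = pd.DataFrame({"delayed": rng.normal(-1, 1, 5000)})
        rates = [classify_impairment(comp, norms, thr).mean()["delayed"]
                 for thr in (1.0, 1.5, 2.0, 2.5)]
        assert all(a >= b for a, b in zip(rates, rates[1:]))


class TestImpairmentTable:
    def test_all_at_reference_mean_zero_percent(self):
        ref = pd.DataFrame({c: np.r_[np.zeros(5), np.ones(5)] for c in PERFORMANCE_COMPONENTS})
        norms = fit_norms(ref)
        comp = pd.DataFrame({c: [0.5] * 6 for c in PERFORMANCE_COMPONENTS})
        labels = pd.Series(["typical"] * 3 + ["no_atrophy"] * 3)
        table = impairment_table(comp, labels, norms)
        assert (table["percent_impaired"] == 0).all()

    def test_two_sd_below_all_impaired(self):
        ref = pd.DataFrame({c: np.r_[np.zeros(5), np.ones(5)] for c in PERFORMANCE_COMPONENTS})
        norms = fit_norms(ref)
        comp = pd.DataFrame({c: [0.5 - 2 * norms.sd[c]] * 4 for c in PERFORMANCE_COMPONENTS})
        table = impairment_table(comp, pd.Series(["typical"] * 4), norms)
        assert (table["percent_impaired"] == 100).all()

    def test_selective_shift_shows_in_one_component(self, rng):
        n = 300
        ref = pd.DataFrame({c: rng.normal(0, 1, 500) for c in PERFORMANCE_COMPONENTS})
        norms = fit_norms(ref)
        comp = pd.DataFrame({c: rng.normal(0, 1, n) for c in PERFORMANCE_COMPONENTS})
        comp["learning"] = rng.normal(-2, 1, n)
        table = impairment_table(comp, pd.Series(["typical"] * n), norms).set_index("component")
        learn = table.loc["learning", "percent_impaired"]
        others = table.drop(index="learning")["percent_impaired"]
        assert learn > 50 and (others < 20).all()

    def test_unlabelled_rows_excluded(self):
        ref = pd.DataFrame({"learning": [0.0, 1, 2, 3]})
        norms = fit_norms(ref, components=("learning",))
        comp = pd.DataFrame({"learning": [1.0, 1.0]})
        table = impairment_table(comp, pd.Series(["typical", None]), norms)
        assert table["n"].sum() == 1


def _null_anova_data(rng, n_per_group=20, groups=("a", "b"), comps=("c1", "c2", "c3")):
    rows = []
    sid = 0
    for g in groups:
        for _ in range(n_per_group):
            rows.append({"id": f"s{sid}", "_group": g,
                         **{c: rng.normal() for c in comps}})
            sid += 1
    return pd.DataFrame(rows)


class TestComponentAnova:
    def _norms(self, comps, rng):
        ref = pd.DataFrame({c: rng.normal(0, 1, 200) for c in comps})
        return fit_norms(ref, components=comps)

    def test_single_group_errors(self, rng):
        df = _null_anova_data(rng, groups=("a",))
        norms = self._norms(("c1", "c2", "c3"), rng)
        with pytest.raises(ValueError, match="two groups"):
            component_by_group_anova(df, df["_group"], norms)

    def test_shifted_component_detected(self, rng):
        df = _null_anova_data(rng, n_per_group=80)
        df.loc[df["_group"] == "b", "c1"] += 1.5
        norms = self._norms(("c1", "c2", "c3"), rng)
        res = component_by_group_anova(df, df["_group"], norms)
        assert res.interaction_p < 1e-4
        sig = res.posthoc[(res.posthoc["component"] == "c1")]
        assert (sig["p_adj"] < 0.01).all()

    def test_null_type_one_error_rate(self):
        rng = np.random.default_rng(77)
        comps = ("c1", "c2", "c3")
        norms = self._norms(comps, rng)
        rejections = 0
        n_sims = 200
        for _ in range(n_sims):
            df = _null_anova_data(rng, n_per_group=15)
            res = ComponentAnova(df, df["_group"], norms).fit()
            rejections += res.interaction_p <= 0.05
        rate = rejections / n_sims
        assert 0.01 <= rate <= 0.10  # ~3 binomial SDs around 0.05

    def test_standardization_affine_invariance(self, rng):
        df = _null_anova_data(rng, n_per_group=40)
        comps = ("c1", "c2", "c3")
        ref = pd.DataFrame({c: rng.normal(0, 1, 200) for c in comps})
        res1 = ComponentAnova(df, df["_group"], fit_norms(ref, components=comps)).fit()
        df2, ref2 = df.copy(), ref.copy()
        df2["c2"] = df2["c2"] * 7 + 3
        ref2["c2"] = ref2["c2"] * 7 + 3
        res2 = ComponentAnova(df2, df2["_group"], fit_norms(ref2, components=comps)).fit()
        assert res1.interaction_F == pytest.approx(res2.interaction_F, rel=1e-10)

    def test_covariate_residualization_runs(self, rng):
        df = _null_anova_data(rng, n_per_group=30)
        norms = self._norms(("c1", "c2", "c3"), rng)
        cov = pd.DataFrame({"age": rng.normal(75, 5, len(df))})
        res = ComponentAnova(df, df["_group"], norms, covariates=cov).fit()
        assert np.isfinite(res.interaction_F)
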