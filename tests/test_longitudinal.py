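"""Mixed-effects trajectory models: recovery, contrasts, quadratic test."""

import numpy as np
import pandas as pd
import pytest

from adsubtype import CohortSpec, TrajectoryModel, generate_longitudinal, rating_trajectories
from adsubtype.simulate import GroupTrajectory

CDR_SLOPES = {"HC": 0.03, "typical": 0.29, "limbic_predominant": 0.28,
              "hippocampal_sparing": 0.16, "no_atrophy": 0.14}


def _noise_free_long(n=6):
    spec = CohortSpec(
        group_sizes={g: n for g in CDR_SLOPES},
        cdr_sigma=0.0, cdr_sigma_b=0.0, mmse_sigma=0.0, mmse_sigma_b=0.0, seed=1)
    return generate_longitudinal(spec)


class TestFit:
    def test_noise_free_exact_recovery(self):
        long = _noise_free_long()
        fit = TrajectoryModel(long, "cdr").fit()
        slopes = fit.group_slopes()["slope"]
        for g, truth in CDR_SLOPES.items():
            assert slopes[g] == pytest.approx(truth, abs=1e-8)

    def test_missing_reference_group_errors(self):
        long = _noise_free_long()
        with pytest.raises(ValueError, match="reference group"):
            TrajectoryModel(long, "cdr", reference="nope")

    def test_single_visit_subjects_tolerated(self):
        spec = CohortSpec(group_sizes={g: 30 for g in CDR_SLOPES}, seed=2)
        long = generate_longitudinal(spec)
        # strip follow-ups from a third of subjects
        ids = long["id"].unique()
        drop = set(ids[::3])
        long = long[~(long["id"].isin(drop) & (long["time_years"] > 0))]
        fit = TrajectoryModel(long, "cdr").fit()
        assert fit.converged

    def test_shift_invariance_and_scale_equivariance(self):
        spec = CohortSpec(group_sizes={g: 40 for g in CDR_SLOPES}, seed=5)
        long = generate_longitudinal(spec)
        base = TrajectoryModel(long, "cdr").fit().group_slopes()["slope"]
        shifted = long.assign(cdr=long["cdr"] + 10)
        s1 = TrajectoryModel(shifted, "cdr").fit().group_slopes()["slope"]
        assert np.allclose(base, s1, atol=1e-6)
        scaled = long.assign(cdr=long["cdr"] * 3)
        s2 = TrajectoryModel(scaled, "cdr").fit().group_slopes()["slope"]
        assert np.allclose(3 * base, s2, atol=1e-5)

    def test_converges_to_ols_when_random_intercept_vanishes(self):
        spec = CohortSpec(group_sizes={g: 60 for g in CDR_SLOPES},
                          cdr_sigma_b=0.0, cdr_sigma=0.3, seed=8)
        long = generate_longitudinal(spec)
        fit = TrajectoryModel(long, "cdr").fit()
        import statsmodels.api as sm
        exog, _ = fit.model._design(quadratic=False)
        ols = sm.OLS(long["cdr"].to_numpy(), exog).fit()
        assert np.allclose(fit.fe_params.to_numpy(), ols.params, atol=1e-3)


class TestSlopes:
    def test_group_slope_is_reference_plus_interaction(self):
        long = _noise_free_long()
        fit = TrajectoryModel(long, "cdr").fit()
        beta = fit.fe_params
        slopes = fit.group_slopes()["slope"]
        assert slopes["typical"] == pytest.approx(
            beta["time"] + beta["group[typical]:time"], abs=1e-12)
        assert slopes["HC"] == pytest.approx(beta["time"], abs=1e-12)

    def test_mmse_slopes_negative_in_ad_groups(self):
        spec = CohortSpec(group_sizes={g: 100 for g in CDR_SLOPES}, seed=13)
        long = generate_longitudinal(spec)
        slopes = TrajectoryModel(long, "mmse").fit().group_slopes()["slope"]
        for g in CDR_SLOPES:
            if g != "HC":
                assert slopes[g] < 0


class TestContrasts:
    def test_same_group_pair_is_null(self):
        long = _noise_free_long()
        fit = TrajectoryModel(long, "cdr").fit()
        row = fit.slope_contrasts(pairs=[("typical", "typical")]).iloc[0]
        assert row["difference"] == 0 and row["p_raw"] == 1.0

    def test_unknown_group_errors(self):
        fit = TrajectoryModel(_noise_free_long(), "cdr").fit()
        with pytest.raises(ValueError, match="unknown group"):
            fit.slope_contrasts(pairs=[("typical", "zzz")])

    def test_adjusted_p_monotone_in_raw_p(self):
        spec = CohortSpec(group_sizes={g: 80 for g in CDR_SLOPES}, seed=21)
        long = generate_longitudinal(spec)
        con = TrajectoryModel(long, "cdr").fit().slope_contrasts()
        assert (con["p_adj"] >= con["p_raw"] - 1e-15).all()
        srt = con.sort_values("p_raw")
        assert srt["p_adj"].is_monotonic_increasing

    def test_true_difference_detected(self):
        spec = CohortSpec(group_sizes={"HC": 100, "typical": 100}, seed=31)
        long = generate_longitudinal(spec)  # slopes 0.03 vs 0.29
        con = TrajectoryModel(long, "cdr").fit().slope_contrasts(
            pairs=[("HC", "typical")])
        assert con.iloc[0]["p_adj"] < 1e-6

    def test_null_rejection_rate_near_alpha(self):
        rng_seeds = range(120)
        rejections = 0
        for s in rng_seeds:
            spec = CohortSpec(
                group_sizes={"HC": 30, "typical": 30}, seed=1000 + s,
                trajectories={
                    "cdr": {"HC": GroupTrajectory(0.0, 0.1),
                            "typical": GroupTrajectory(0.0, 0.1)},
                    "mmse": {"HC": GroupTrajectory(29.0, 0.0),
                             "typical": GroupTrajectory(29.0, 0.0)},
                })
            long = generate_longitudinal(spec)
            con = TrajectoryModel(long, "cdr").fit().slope_contrasts(
                pairs=[("HC", "typical")], adjust=False)
            rejections += con.iloc[0]["p_raw"] <= 0.05
        rate = rejections / len(rng_seeds)
        assert 0.0 <= rate <= 0.13  # ~3 binomial SDs above nominal 0.05


class TestQuadratic:
    def test_linear_data_quadratic_not_significant(self):
        spec = CohortSpec(group_sizes={g: 80 for g in CDR_SLOPES}, seed=17)
        long = generate_longitudinal(spec)
        fit = TrajectoryModel(long, "cdr").fit()
        q = fit.compare_quadratic()
        assert q["p"] > 0.01

    def test_injected_curvature_detected(self):
        import dataclasses
        traj = {"cdr": {g: dataclasses.replace(t, quad=0.3)
                        for g, t in CohortSpec().trajectories["cdr"].items()},
                "mmse": CohortSpec().trajectories["mmse"]}
        spec = CohortSpec(group_sizes={g: 80 for g in CDR_SLOPES},
                          trajectories=traj, seed=19)
        long = generate_longitudinal(spec)
        q = TrajectoryModel(long, "cdr").fit().compare_quadratic()
        assert q["p"] < 1e-6

    def test_two_timepoints_error(self):
        spec = CohortSpec(group_sizes={"HC": 20, "typical": 20},
                          visit_times=(0.0, 1.0), seed=23)
        long = generate_longitudinal(spec)
        fit = TrajectoryModel(long, "cdr").fit()
        with pytest.raises(ValueError, match="3 distinct time points"):
            fit.compare_quadratic()


class TestRatingTrajectories:
    def test_constant_ratings_flat(self):
        rows = [dict(id=f"s{i}", group="typical", time_years=t,
                     mta_l=2, mta_r=3, pa=1, gca_f=0)
                for i in range(5) for t in (0, 1, 2)]
        tab = rating_trajectories(pd.DataFrame(rows))
        assert tab["mta_mean"].nunique() == 1
        assert tab["mta_mean"].iloc[0] == 2.5  # bilateral average

    def test_step_process_mean_increase(self, small_spec):
        from adsubtype import generate_cross_section, generate_rating_progression
        import dataclasses
        spec = dataclasses.replace(small_spec, rating_step_prob=0.5)
        cross = generate_cross_section(spec)
        prog = generate_rating_progression(spec, cross)
        tab = rating_trajectories(prog[prog["group"] == "no_atrophy"])
        # composite MTA starts low: one step of p=0.5 on each side raises the
        # composite by ~0.5 per visit until the ceiling interferes
        g = tab.sort_values("time_years")
        assert g["mta_mean"].iloc[1] > g["mta_mean"].iloc[0]

    def test_baseline_only_table(self):
        rows = [dict(id="a", group="HC", time_years=0.0, mta_l=1, mta_r=1, pa=0, gca_f=0)]
        tab = rating_trajectories(pd.DataFrame(rows))
        assert len(tab) == 1 and tab["n"].iloc[0] == 1
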