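"""Longitudinal mixed-effects trajectory modelling.

Two-year disease progression is modelled per outcome (CDR, MMSE, or a rating
score) with a linear mixed model:

    y_ij = alpha + group_g + (beta + delta_g) * t_ij + b_i + eps_ij

fixed effects: group, time and the group-by-time interaction (optionally
quadratic time and its interaction, optionally centered covariates); random
effect: a per-subject intercept. Estimation is REML; the linear-vs-quadratic
comparison refits both models by ML for a valid likelihood-ratio test. All
available observations contribute at each time point, so subjects with
missing follow-ups still inform the fit.

Per-group absolute slopes are the reference slope plus the group's
interaction offset; pairwise slope contrasts are Wald t tests with a
residual-df convention (n_obs − n_fixed) and Benjamini-Hochberg adjustment
across the requested family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .characterize import bh_adjust

__all__ = [
    "TrajectoryModel",
    "TrajectoryResults",
    "rating_trajectories",
]


class _ExactFit:
    """Stand-in results for noise-free (zero-residual) data."""

    def __init__(self, beta: np.ndarray, nobs: int, k: int):
        self.fe_params = beta
        self.bse = np.zeros(k)
        self.converged = True
        self.llf = np.inf
        self.nobs = nobs
        self._k = k

    def cov_params(self) -> np.ndarray:
        return np.zeros((self._k, self._k))


class TrajectoryModel:
    """Random-intercept trajectory model for one longitudinal outcome.

    Parameters
    ----------
    data : long-format DataFrame with one row per visit.
    outcome : outcome column name (e.g. ``"cdr"``).
    group, time, subject : column names (defaults ``group``/``time_years``/``id``).
    reference : reference group for the dummy coding (default ``"HC"``).
    quadratic : include time² and group:time² fixed effects.
    covariates : optional list of numeric covariate columns, centered on entry.
    random_slope : also give subjects a random slope on time (off by default).
    """

    def __init__(self, data: pd.DataFrame, outcome: str, *, group: str = "group",
                 time: str = "time_years", subject: str = "id",
                 reference: str = "HC", quadratic: bool = False,
                 covariates=None, random_slope: bool = False):
        cols = [subject, group, time, outcome] + list(covariates or [])
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        d = data[cols].dropna().copy()
        if d.empty:
            raise ValueError("no complete observations")
        levels = list(pd.unique(d[group]))
        if reference not in levels:
            raise ValueError(f"reference group {reference!r} not present in data")
        self.levels = [reference] + [g for g in levels if g != reference]
        self.data = d
        self.outcome, self.group, self.time, self.subject = outcome, group, time, subject
        self.reference = reference
        self.quadratic = quadratic
        self.covariates = list(covariates or [])
        self.random_slope = random_slope

    def _design(self, quadratic: bool) -> tuple:
        d = self.data
        t = d[self.time].to_numpy(dtype=float)
        cols = {"Intercept": np.ones(len(d))}
        for g in self.levels[1:]:
            cols[f"group[{g}]"] = (d[self.group] == g).to_numpy(dtype=float)
        cols["time"] = t
        for g in self.levels[1:]:
            cols[f"group[{g}]:time"] = cols[f"group[{g}]"] * t
        if quadratic:
            cols["time2"] = t ** 2
            for g in self.levels[1:]:
                cols[f"group[{g}]:time2"] = cols[f"group[{g}]"] * t ** 2
        for c in self.covariates:
            v = d[c].to_numpy(dtype=float)
            cols[c] = v - v.mean()
        names = list(cols)
        return np.column_stack([cols[k] for k in names]), names

    def _fit_mixed(self, quadratic: bool, reml: bool):
        import statsmodels.api as sm

        exog, names = self._design(quadratic)
        endog = self.data[self.outcome].to_numpy(dtype=float)
        groups = self.data[self.subject].to_numpy()
        # degenerate noise-free data (exact linear interpolation) leaves the
        # variance components unidentifiable; the GLS fixed effects then
        # coincide with OLS, which we return exactly
        beta, rss, *_ = np.linalg.lstsq(exog, endog, rcond=None)
        resid = endog - exog @ beta
        if float(resid @ resid) <= 1e-12 * max(1.0, float(endog @ endog)):
            return _ExactFit(beta, len(endog), len(names)), names
        exog_re = None
        if self.random_slope:
            exog_re = np.column_stack([np.ones(len(endog)),
                                       self.data[self.time].to_numpy(dtype=float)])
        model = sm.MixedLM(endog, exog, groups=groups, exog_re=exog_re)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = model.fit(reml=reml)
            except np.linalg.LinAlgError:
                res = model.fit(reml=reml, method="lbfgs")
        return res, names

    def fit(self, reml: bool = True) -> "TrajectoryResults":
        res, names = self._fit_mixed(self.quadratic, reml)
        return TrajectoryResults(self, res, names, reml=reml)


class TrajectoryResults:
    """Fitted trajectory model: estimates, slopes, contrasts, diagnostics."""

    def __init__(self, model: TrajectoryModel, sm_results, names, reml: bool):
        self.model = model
        self._res = sm_results
        self.names = names
        self.reml = reml
        k = len(names)
        self.fe_params = pd.Series(np.asarray(sm_results.fe_params)[:k], index=names)
        self.bse = pd.Series(np.asarray(sm_results.bse)[:k], index=names)
        self.cov_fe = pd.DataFrame(np.asarray(sm_results.cov_params())[:k, :k],
                                   index=names, columns=names)
        self.converged = bool(getattr(sm_results, "converged", True))
        self.llf = float(sm_results.llf)
        self.nobs = int(sm_results.nobs)
        self.df_resid = self.nobs - k

    def _require_converged(self):
        if not self.converged:
            raise RuntimeError("mixed model did not converge; refusing downstream use")

    def _slope_vector(self, group: str) -> np.ndarray:
        c = np.zeros(len(self.names))
        c[self.names.index("time")] = 1.0
        if group != self.model.reference:
            key = f"group[{group}]:time"
            if key not in self.names:
                raise ValueError(f"unknown group {group!r}")
            c[self.names.index(key)] = 1.0
        return c

    def group_slopes(self) -> pd.DataFrame:
        """Absolute per-group time slopes with standard errors."""
        self._require_converged()
        cov = self.cov_fe.to_numpy()
        rows = []
        for g in self.model.levels:
            c = self._slope_vector(g)
            est = float(c @ self.fe_params.to_numpy())
            se = float(np.sqrt(c @ cov @ c))
            rows.append(dict(group=g, slope=est, se=se))
        return pd.DataFrame(rows).set_index("group")

    def slope_contrasts(self, pairs=None, adjust: bool = True) -> pd.DataFrame:
        """Pairwise Wald t tests on slope differences (BH-adjusted family)."""
        self._require_converged()
        if pairs is None:
            from itertools import combinations
            pairs = list(combinations(self.model.levels, 2))
        cov = self.cov_fe.to_numpy()
        beta = self.fe_params.to_numpy()
        rows = []
        for a, b in pairs:
            c = self._slope_vector(a) - self._slope_vector(b)
            est = float(c @ beta)
            var = float(c @ cov @ c)
            if var <= 0:
                t, p = 0.0, 1.0
            else:
                t = est / np.sqrt(var)
                p = float(2 * stats.t.sf(abs(t), self.df_resid))
            rows.append(dict(group_a=a, group_b=b, difference=est,
                             t=t, df=self.df_resid, p_raw=p))
        out = pd.DataFrame(rows)
        if adjust and len(out):
            out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())
        return out

    def compare_quadratic(self) -> dict:
        """Likelihood-ratio test of quadratic time terms (ML refits).

        Returns the LR statistic, its df (one quadratic slope plus one
        interaction per non-reference group) and p-value. Requires at least
        three distinct time points, otherwise the quadratic is unidentifiable.
        """
        if self.model.data[self.model.time].nunique() < 3:
            raise ValueError("quadratic time requires >= 3 distinct time points")
        lin, _ = self.model._fit_mixed(quadratic=False, reml=False)
        quad, qnames = self.model._fit_mixed(quadratic=True, reml=False)
        df = sum(1 for n in qnames if "time2" in n)
        lr = float(2 * (quad.llf - lin.llf))
        lr = max(lr, 0.0)
        return dict(lr=lr, df=df, p=float(stats.chi2.sf(lr, df)))

    def summary(self) -> str:
        lines = [
            f"Mixed-effects trajectory model: {self.model.outcome} "
            f"({'REML' if self.reml else 'ML'}, n_obs = {self.nobs}, "
            f"converged = {self.converged})",
            "  fixed effects:",
        ]
        for name in self.names:
            lines.append(f"    {name:>28s}  {self.fe_params[name]: .4f} "
                         f"(se {self.bse[name]:.4f})")
        if self.converged:
            lines.append("  per-group slopes:")
            for g, row in self.group_slopes().iterrows():
                lines.append(f"    {g:>28s}  {row['slope']: .4f} (se {row['se']:.4f})")
        return "\n".join(lines)

    def plot_trajectories(self, ax=None):
        """Plot fitted group mean trajectories (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = np.linspace(self.model.data[self.model.time].min(),
                        self.model.data[self.model.time].max(), 50)
        beta = self.fe_params
        for g in self.model.levels:
            y = np.full_like(t, beta["Intercept"])
            if g != self.model.reference:
                y = y + beta[f"group[{g}]"]
                y = y + beta[f"group[{g}]:time"] * t
                if self.model.quadratic:
                    y = y + beta[f"group[{g}]:time2"] * t ** 2
            y = y + beta["time"] * t
            if self.model.quadratic:
                y = y + beta["time2"] * t ** 2
            ax.plot(t, y, label=g)
        ax.set_xlabel("time (years)")
        ax.set_ylabel(self.model.outcome)
        ax.legend()
        return ax


def rating_trajectories(long_ratings: pd.DataFrame, *, group: str = "group",
                        time: str = "time_years") -> pd.DataFrame:
    """Per-group mean visual-rating trajectories (bilateral MTA averaged).

    Returns a group x time table of mean composite MTA, PA and GCA-F with the
    number of contributing subjects per cell. Works on baseline-only data.
    """
    d = long_ratings.copy()
    if {"mta_l", "mta_r"}.issubset(d.columns):
        d["mta"] = (d["mta_l"] + d["mta_r"]) / 2.0
    value_cols = [c for c in ("mta", "pa", "gca_f") if c in d.columns]
    if not value_cols:
        raise ValueError("no rating columns found")
    agg = d.groupby([group, time]).agg(
        **{f"{c}_mean": (c, "mean") for c in value_cols},
        n=(value_cols[0], "count"),
    ).reset_index()
    return agg
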