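"""Backward regression and general dominance analysis with bootstrap stability.

Which non-memory cognitive functions drive a memory outcome? Two complementary
answers are computed and then reconciled:

1. :class:`BackwardSelection` — classical backward-elimination multiple linear
   regression: repeatedly drop the least significant predictor while its
   p-value exceeds the removal alpha, then report standardized coefficients of
   the final model.

2. :class:`DominanceAnalysis` — general dominance weights: the model R² is
   decomposed into one non-negative share per predictor by averaging the
   incremental R² of adding that predictor over all subsets of the others
   (equivalently, its Shapley value over predictor orderings). Weights sum to
   the full-model R² exactly. Bootstrap resampling of cases screens each
   weight for stability in small samples.

``reconcile`` intersects the two: a predictor is reported only when backward
elimination retains it *and* its dominance weight is bootstrap-stable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BackwardSelection",
    "BackwardSelectionResults",
    "DominanceAnalysis",
    "DominanceResults",
    "BootstrapStability",
    "reconcile",
]

MAX_DOMINANCE_PREDICTORS = 20


def _as_matrix(X) -> tuple:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X, [f"x{i}" for i in range(X.shape[1])]


def _check_rank(X: np.ndarray, names) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns involved in the deficiency by greedy elimination
        bad = []
        keep: list[int] = []
        for j in range(X.shape[1]):
            trial = keep + [j]
            if np.linalg.matrix_rank(X[:, trial]) < len(trial):
                bad.append(names[j])
            else:
                keep.append(j)
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


class BackwardSelection:
    """Backward-elimination multiple linear regression.

    Parameters
    ----------
    y, X : outcome vector and predictor table (DataFrame columns are used as
        predictor names). Complete cases only.
    removal_alpha : a predictor is removed while its p-value is >= this value
        (default 0.10, the classic backward-elimination convention).
    standardize : z-score outcome and predictors before the final fit so the
        reported coefficients are standardized betas (default True).
    """

    def __init__(self, y, X, removal_alpha: float = 0.10, standardize: bool = True):
        if not 0.0 < removal_alpha < 1.0:
            raise ValueError("removal_alpha must be in (0, 1)")
        Xm, names = _as_matrix(X)
        y = np.asarray(y, dtype=float).ravel()
        ok = ~np.isnan(y) & ~np.isnan(Xm).any(axis=1)
        self.y, self.X, self.names = y[ok], Xm[ok], names
        self.n_dropped = int((~ok).sum())
        if self.X.shape[0] <= self.X.shape[1] + 1:
            raise ValueError("need n > p + 1 complete cases")
        _check_rank(np.column_stack([np.ones(len(self.y)), self.X]), ["const"] + names)
        self.removal_alpha = removal_alpha
        self.standardize = standardize

    def fit(self) -> "BackwardSelectionResults":
        import statsmodels.api as sm

        idx = list(range(len(self.names)))
        steps = []
        while idx:
            model = sm.OLS(self.y, sm.add_constant(self.X[:, idx])).fit()
            pvals = model.pvalues[1:]
            worst = int(np.argmax(pvals))
            if pvals[worst] >= self.removal_alpha:
                steps.append((self.names[idx[worst]], float(pvals[worst])))
                idx.pop(worst)
            else:
                break
        retained = [self.names[j] for j in idx]
        if idx:
            if self.standardize:
                ys = (self.y - self.y.mean()) / self.y.std(ddof=1)
                Xs = self.X[:, idx]
                Xs = (Xs - Xs.mean(axis=0)) / Xs.std(axis=0, ddof=1)
            else:
                ys, Xs = self.y, self.X[:, idx]
            final = sm.OLS(ys, sm.add_constant(Xs)).fit()
            params = pd.Series(final.params[1:], index=retained)
            pvalues = pd.Series(final.pvalues[1:], index=retained)
            fvalue, f_df, f_p = float(final.fvalue), (int(final.df_model), int(final.df_resid)), float(final.f_pvalue)
            r2, r2adj = float(final.rsquared), float(final.rsquared_adj)
        else:
            params = pd.Series(dtype=float)
            pvalues = pd.Series(dtype=float)
            fvalue, f_df, f_p = np.nan, (0, len(self.y) - 1), np.nan
            r2 = r2adj = 0.0
        return BackwardSelectionResults(
            retained=retained, params=params, pvalues=pvalues,
            fvalue=fvalue, f_df=f_df, f_pvalue=f_p,
            rsquared=r2, rsquared_adj=r2adj,
            removal_alpha=self.removal_alpha, removal_steps=steps,
            nobs=len(self.y),
        )


@dataclass
class BackwardSelectionResults:
    retained: list
    params: pd.Series        # standardized betas of the final model
    pvalues: pd.Series
    fvalue: float
    f_df: tuple
    f_pvalue: float
    rsquared: float
    rsquared_adj: float
    removal_alpha: float
    removal_steps: list
    nobs: int

    def summary(self) -> str:
        lines = [f"Backward-elimination OLS (n = {self.nobs}, "
                 f"removal alpha = {self.removal_alpha:g})"]
        for name, p in self.removal_steps:
            lines.append(f"  removed {name} (p = {p:.3f})")
        if self.retained:
            lines.append(f"  final model: F({self.f_df[0]}, {self.f_df[1]}) = "
                         f"{self.fvalue:.3f}, p = {self.f_pvalue:.4g}, "
                         f"adj. R^2 = {100 * self.rsquared_adj:.0f}%")
            for name in self.retained:
                lines.append(f"    {name:>12s}  beta = {self.params[name]: .3f}  "
                             f"p = {self.pvalues[name]:.4g}")
        else:
            lines.append("  final model: empty (no predictor survived)")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# general dominance


def _subset_r2(y: np.ndarray, X: np.ndarray) -> dict:
    """R² of every predictor subset, by least squares on centered data."""
    n, p = X.shape
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    tss = float(yc @ yc)
    r2 = {frozenset(): 0.0}
    for size in range(1, p + 1):
        for subset in itertools.combinations(range(p), size):
            cols = Xc[:, subset]
            beta, *_ = np.linalg.lstsq(cols, yc, rcond=None)
            resid = yc - cols @ beta
            r2[frozenset(subset)] = 1.0 - float(resid @ resid) / tss
    return r2


class DominanceAnalysis:
    """General dominance decomposition of a linear model's R².

    For each predictor j the general dominance weight is the average over
    subset sizes k of the mean incremental R² obtained by adding j to each
    size-k subset of the other predictors (the empty set included). Computed
    by exhaustive enumeration of all 2^p subset OLS fits; p is capped at 20.
    """

    def __init__(self, y, X):
        Xm, names = _as_matrix(X)
        y = np.asarray(y, dtype=float).ravel()
        ok = ~np.isnan(y) & ~np.isnan(Xm).any(axis=1)
        self.y, self.X, self.names = y[ok], Xm[ok], names
        p = self.X.shape[1]
        if p > MAX_DOMINANCE_PREDICTORS:
            raise ValueError(
                f"{p} predictors imply 2^{p} subset fits; pre-screen predictors first")
        if self.X.shape[0] < p + 2:
            raise ValueError("too few complete cases for dominance analysis")

    def fit(self) -> "DominanceResults":
        weights, r2_full = self._weights(self.y, self.X)
        return DominanceResults(
            weights=pd.Series(weights, index=self.names),
            rsquared=r2_full, names=self.names, _y=self.y, _X=self.X,
        )

    @staticmethod
    def _weights(y: np.ndarray, X: np.ndarray) -> tuple:
        p = X.shape[1]
        r2 = _subset_r2(y, X)
        weights = np.zeros(p)
        others = [[i for i in range(p) if i != j] for j in range(p)]
        for j in range(p):
            by_size = []
            for size in range(p):
                incs = [r2[frozenset(s) | {j}] - r2[frozenset(s)]
                        for s in itertools.combinations(others[j], size)]
                by_size.append(np.mean(incs))
            weights[j] = float(np.mean(by_size))
        return weights, r2[frozenset(range(p))]


@dataclass
class DominanceResults:
    weights: pd.Series       # per-predictor variance fraction
    rsquared: float
    names: list
    _y: np.ndarray = field(repr=False, default=None)
    _X: np.ndarray = field(repr=False, default=None)

    def bootstrap(self, B: int = 1000, seed: int | None = None,
                  floor: float = 0.01, ci: float = 0.95) -> "BootstrapStability":
        """Bootstrap stability screening of the dominance weights.

        Rows are resampled with replacement ``B`` times and the weights
        recomputed; a predictor is *stable* when the lower bound of its
        ``ci`` percentile interval exceeds ``floor`` (default: 1% of outcome
        variance). Degenerate replicates (a zero-variance column) are skipped
        and counted.
        """
        if B < 1:
            raise ValueError("B must be >= 1")
        rng = np.random.default_rng(seed)
        n = len(self._y)
        reps = np.full((B, len(self.names)), np.nan)
        skipped = 0
        for b in range(B):
            rows = rng.integers(n, size=n)
            Xb, yb = self._X[rows], self._y[rows]
            if yb.std() == 0 or (Xb.std(axis=0) == 0).any():
                skipped += 1
                continue
            reps[b], _ = DominanceAnalysis._weights(yb, Xb)
        valid = reps[~np.isnan(reps).any(axis=1)]
        if len(valid) == 0:
            raise ValueError("all bootstrap replicates were degenerate")
        alpha = (1.0 - ci) / 2.0
        lo = np.percentile(valid, 100 * alpha, axis=0)
        hi = np.percentile(valid, 100 * (1 - alpha), axis=0)
        return BootstrapStability(
            conf_int=pd.DataFrame({"lower": lo, "upper": hi}, index=self.names),
            stable=pd.Series(lo > floor, index=self.names),
            mean_weights=pd.Series(valid.mean(axis=0), index=self.names),
            B=B, n_skipped=skipped, floor=floor, ci=ci, seed=seed,
        )

    def summary(self) -> str:
        lines = [f"General dominance decomposition (R^2 = {self.rsquared:.4f})"]
        for name, w in self.weights.items():
            lines.append(f"  {name:>12s}  weight = {w:.4f}  "
                         f"({100 * w:.1f}% of outcome variance)")
        return "\n".join(lines)


@dataclass
class BootstrapStability:
    conf_int: pd.DataFrame   # percentile interval per predictor
    stable: pd.Series
    mean_weights: pd.Series
    B: int
    n_skipped: int
    floor: float
    ci: float
    seed: int | None


def reconcile(fit: BackwardSelectionResults, stability: BootstrapStability) -> pd.DataFrame:
    """Intersect backward-retained predictors with bootstrap-stable weights.

    Returns one row per predictor appearing in either analysis with its
    status: ``reported`` (retained and stable), ``rejected_unstable``
    (retained but not stable), or ``not_retained``.
    """
    rows = []
    for name in stability.stable.index:
        retained = name in fit.retained
        stable = bool(stability.stable[name])
        if retained and stable:
            status = "reported"
        elif retained:
            status = "rejected_unstable"
        else:
            status = "not_retained"
        rows.append(dict(
            predictor=name, retained=retained, stable=stable, status=status,
            beta=(float(fit.params[name]) if retained else np.nan),
            weight=float(stability.mean_weights[name]),
            weight_lower=float(stability.conf_int.loc[name, "lower"]),
        ))
    return pd.DataFrame(rows)
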