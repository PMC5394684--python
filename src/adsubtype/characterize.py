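"""Group discriminability, rater reliability and multiplicity correction.

* :func:`rf_group_error` — can a random forest tell the study groups apart
  from a block of variables? Per-group out-of-bag classification error is
  compared with the analytic chance error 100·(1 − 1/G) for G groups; error
  near chance means the variables carry no group signal.
* :func:`weighted_kappa` — chance-corrected agreement between two ordinal
  rating vectors with distance-based disagreement weights (linear |i−j| or
  quadratic (i−j)²), the standard reliability statistic for visual rating
  scales.
* :func:`bh_adjust` — Benjamini-Hochberg step-up FDR adjustment used across
  all post-hoc families.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RFResult",
    "ReliabilityResult",
    "rf_group_error",
    "chance_error",
    "weighted_kappa",
    "bh_adjust",
]


def chance_error(n_groups: int) -> float:
    """Analytic chance classification error (%) for equally weighted groups."""
    if n_groups < 2:
        raise ValueError("need at least two groups")
    return 100.0 * (1.0 - 1.0 / n_groups)


@dataclass
class RFResult:
    per_group_error: pd.Series   # percent
    overall_error: float
    chance_error: float
    n_trees: int
    seed: int | None
    importances: pd.Series
    method: str

    def summary(self) -> str:
        lines = [f"Random forest ({self.n_trees} trees, {self.method}): "
                 f"overall error {self.overall_error:.1f}% "
                 f"(chance {self.chance_error:.1f}%)"]
        for g, e in self.per_group_error.items():
            lines.append(f"  {g:>24s}: {e:.1f}%")
        return "\n".join(lines)


def rf_group_error(features, labels, n_trees: int = 500, seed: int | None = None,
                   method: str = "oob", n_folds: int = 5) -> RFResult:
    """Per-group random-forest classification error.

    ``method='oob'`` (default) scores each sample with the trees that did not
    see it in their bootstrap; ``method='kfold'`` uses stratified k-fold
    cross-validated predictions instead. Hyperparameters beyond tree count
    follow library defaults (sqrt(p) features per split, unlimited depth).
    """
    from sklearn.ensemble import RandomForestClassifier

    X = (features.to_numpy(dtype=float) if isinstance(features, pd.DataFrame)
         else np.asarray(features, dtype=float))
    feat_names = (list(features.columns) if isinstance(features, pd.DataFrame)
                  else [f"x{i}" for i in range(X.shape[1])])
    y = np.asarray(labels, dtype=object)
    groups, counts = np.unique(y, return_counts=True)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    small = groups[counts < 2]
    if small.size:
        raise ValueError(f"groups with fewer than 2 members: {list(small)}")

    if method == "oob":
        clf = RandomForestClassifier(n_estimators=n_trees, oob_score=True,
                                     random_state=seed)
        clf.fit(X, y)
        proba = clf.oob_decision_function_
        # samples never left out-of-bag (rare for n_trees >= 100) get no vote
        voted = proba.sum(axis=1) > 0
        pred = np.asarray(clf.classes_)[np.argmax(proba, axis=1)]
        correct = (pred == y) & voted
        evaluated = voted
        importances = clf.feature_importances_
    elif method == "kfold":
        from sklearn.model_selection import StratifiedKFold

        pred = np.empty_like(y)
        importances = np.zeros(X.shape[1])
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        for train, test in skf.split(X, y):
            clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
            clf.fit(X[train], y[train])
            pred[test] = clf.predict(X[test])
            importances += clf.feature_importances_ / n_folds
        correct = pred == y
        evaluated = np.ones(len(y), dtype=bool)
    else:
        raise ValueError("method must be 'oob' or 'kfold'")

    per_group = {}
    for g in groups:
        mask = (y == g) & evaluated
        per_group[g] = 100.0 * (1.0 - correct[mask].mean()) if mask.any() else np.nan
    overall = 100.0 * (1.0 - correct[evaluated].mean())
    return RFResult(
        per_group_error=pd.Series(per_group),
        overall_error=float(overall),
        chance_error=chance_error(len(groups)),
        n_trees=n_trees, seed=seed,
        importances=pd.Series(importances, index=feat_names),
        method=method,
    )


@dataclass
class ReliabilityResult:
    kappa: float
    scheme: str
    confusion: pd.DataFrame

    def summary(self) -> str:
        return f"Weighted kappa ({self.scheme}): {self.kappa:.3f}"


def weighted_kappa(ratings_a, ratings_b, scheme: str = "linear",
                   categories=None) -> ReliabilityResult:
    """Weighted Cohen's kappa between two ordinal rating vectors.

    kappa = 1 − (Σ w_ij O_ij) / (Σ w_ij E_ij) with disagreement weights
    w_ij = |i−j| (linear) or (i−j)² (quadratic); E is the outer product of the
    marginals. ``categories`` fixes the ordered category set (defaults to the
    union observed); ratings outside it raise.
    """
    a = np.asarray(ratings_a).ravel()
    b = np.asarray(ratings_b).ravel()
    if a.shape != b.shape:
        raise ValueError(f"rating vectors differ in length: {a.size} vs {b.size}")
    if a.size == 0:
        raise ValueError("empty rating vectors")
    if categories is None:
        categories = np.unique(np.concatenate([a, b]))
    else:
        categories = np.asarray(categories)
        extra = np.setdiff1d(np.concatenate([a, b]), categories)
        if extra.size:
            raise ValueError(f"ratings outside the declared categories: {list(extra)}")
    k = len(categories)
    index = {c: i for i, c in enumerate(categories)}
    obs = np.zeros((k, k))
    for ai, bi in zip(a, b):
        obs[index[ai], index[bi]] += 1
    obs /= obs.sum()
    marg_a, marg_b = obs.sum(axis=1), obs.sum(axis=0)
    expected = np.outer(marg_a, marg_b)
    i, j = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
    if scheme == "linear":
        w = np.abs(i - j).astype(float)
    elif scheme == "quadratic":
        w = (i - j).astype(float) ** 2
    else:
        raise ValueError("scheme must be 'linear' or 'quadratic'")
    denom = float((w * expected).sum())
    kappa = 1.0 if denom == 0 else 1.0 - float((w * obs).sum()) / denom
    confusion = pd.DataFrame(obs * a.size, index=categories, columns=categories)
    return ReliabilityResult(kappa=float(kappa), scheme=scheme, confusion=confusion)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    p_(i) -> min over j >= i of (m/j) * p_(j), capped at 1, returned in the
    input order.
    """
    p = np.asarray(pvalues, dtype=float).ravel()
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out
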