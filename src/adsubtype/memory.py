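"""AVLT memory-component profiling and impairment flagging.

The Auditory Verbal Learning Test yields several memory components:

* learning — sum of the five list-A learning trials (0-75), learning capacity;
* interference — list-B recall, vulnerability to interference;
* immediate — free recall of list A right after list B;
* delayed — free recall of list A after a 30-minute delay;
* recognition — identification of list-A items among distractors;
* gain — recognition% − delayed% (percentage points): how much a subject
  benefits from retrieval cues. Stored-but-not-retrieved information shows up
  as a large positive gain, i.e. a retrieval rather than a consolidation
  problem.

Impairment is flagged against a reference group (typically the healthy
controls) at a z threshold of 1.5 SD: performance components are impaired
when z <= -1.5, gain when z >= +1.5 (higher gain = more retrieval problems).
Boundary values count as impaired.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PERFORMANCE_COMPONENTS",
    "COMPONENTS",
    "ReferenceNorms",
    "derive_components",
    "fit_norms",
    "classify_impairment",
    "impairment_table",
    "ComponentAnova",
    "component_by_group_anova",
]

AVLT_ITEMS = ("avlt_t1", "avlt_t2", "avlt_t3", "avlt_t4", "avlt_t5",
              "avlt_b", "avlt_imm", "avlt_del", "avlt_rec")
PERFORMANCE_COMPONENTS = ("learning", "interference", "immediate", "delayed", "recognition")
COMPONENTS = PERFORMANCE_COMPONENTS + ("gain",)
_WORDS = 15.0


def derive_components(records: pd.DataFrame) -> pd.DataFrame:
    """Derive memory components from raw AVLT item scores.

    Expects columns ``avlt_t1..avlt_t5, avlt_b, avlt_imm, avlt_del,
    avlt_rec``; any missing item leaves the dependent component(s) missing
    while the rest are computed. Percentages are relative to the 15-word list.
    Preserves an ``id`` column when present.
    """
    out = pd.DataFrame(index=records.index)
    if "id" in records.columns:
        out["id"] = records["id"]
    trials = [records.get(c) for c in AVLT_ITEMS[:5]]
    if all(t is not None for t in trials):
        out["learning"] = sum(trials)
    else:
        out["learning"] = np.nan
    out["interference"] = records.get("avlt_b", np.nan)
    out["immediate"] = records.get("avlt_imm", np.nan)
    out["delayed"] = records.get("avlt_del", np.nan)
    out["recognition"] = records.get("avlt_rec", np.nan)
    out["delayed_pct"] = 100.0 * out["delayed"] / _WORDS
    out["recognition_pct"] = 100.0 * out["recognition"] / _WORDS
    out["gain"] = out["recognition_pct"] - out["delayed_pct"]
    return out


@dataclass(frozen=True)
class ReferenceNorms:
    """Component-wise mean/SD (ddof=1) of the reference group."""

    mean: pd.Series
    sd: pd.Series
    n: pd.Series

    def zscore(self, components: pd.DataFrame) -> pd.DataFrame:
        cols = [c for c in self.mean.index if c in components.columns]
        return (components[cols] - self.mean[cols]) / self.sd[cols]


def fit_norms(reference: pd.DataFrame, components=COMPONENTS) -> ReferenceNorms:
    """Fit reference norms from a component table (e.g. healthy controls)."""
    cols = [c for c in components if c in reference.columns]
    if not cols:
        raise ValueError("no component columns found in reference table")
    sub = reference[cols]
    n = sub.notna().sum()
    if (n < 2).any():
        bad = list(n.index[n < 2])
        raise ValueError(f"reference group too small (<2 non-missing) for {bad}")
    sd = sub.std(ddof=1)
    if (sd <= 0).any():
        bad = list(sd.index[sd <= 0])
        raise ValueError(f"degenerate (zero-variance) reference for {bad}")
    return ReferenceNorms(mean=sub.mean(), sd=sd, n=n)


def classify_impairment(
    components: pd.DataFrame,
    norms: ReferenceNorms,
    threshold: float = 1.5,
) -> pd.DataFrame:
    """Flag clinical impairment per component at ``threshold`` SD.

    Performance components are impaired when z <= -threshold (inclusive);
    gain is impaired when z >= +threshold. Missing scores give missing flags
    (pandas nullable boolean).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    z = norms.zscore(components)
    flags = pd.DataFrame(index=components.index)
    if "id" in components.columns:
        flags["id"] = components["id"]
    for comp in PERFORMANCE_COMPONENTS:
        if comp in z.columns:
            flags[comp] = (z[comp] <= -threshold).where(z[comp].notna()).astype("boolean")
    if "gain" in z.columns:
        flags["gain"] = (z["gain"] >= threshold).where(z["gain"].notna()).astype("boolean")
    return flags


def impairment_table(
    components: pd.DataFrame,
    labels: pd.Series,
    norms: ReferenceNorms,
    threshold: float = 1.5,
) -> pd.DataFrame:
    """Percentage impaired per component per subtype (with denominators).

    ``labels`` aligns with ``components`` rows; unlabeled rows are excluded.
    Empty cells are reported as missing.
    """
    flags = classify_impairment(components, norms, threshold)
    flag_cols = [c for c in COMPONENTS if c in flags.columns]
    flags = flags[flag_cols].copy()
    flags["subtype"] = np.asarray(labels)
    flags = flags.dropna(subset=["subtype"])
    rows = []
    for subtype, grp in flags.groupby("subtype", sort=False):
        for comp in flag_cols:
            col = grp[comp].dropna()
            rows.append(dict(
                subtype=subtype, component=comp, n=len(col),
                percent_impaired=(100.0 * col.mean() if len(col) else np.nan),
            ))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# split-plot ANOVA: memory component (within) x subtype (between)


class ComponentAnova:
    """Split-plot ANOVA of memory components across subtypes.

    Components are z-standardized against reference norms before fitting so
    the within-subject factor levels share a scale; the interaction of
    interest is component x group. Optional covariates are residualized out
    of the standardized scores (per component, covariates centered) before
    the ANOVA.

    Parameters
    ----------
    components : DataFrame with an ``id`` column and component scores.
    groups : Series of group labels aligned with ``components``.
    norms : ReferenceNorms used for standardization.
    covariates : optional DataFrame (aligned) of numeric covariates.
    """

    def __init__(self, components, groups, norms, covariates=None,
                 use_components=None):
        self.components = components
        self.groups = np.asarray(groups, dtype=object)
        self.norms = norms
        self.covariates = covariates
        if use_components is None:
            use_components = [c for c in PERFORMANCE_COMPONENTS if c in components.columns]
            if not use_components:
                # generic component tables: any normed score column except
                # gain/percentages, which live on different scales of meaning
                use_components = [c for c in norms.mean.index
                                  if c in components.columns
                                  and c != "gain" and not c.endswith("_pct")]
        self.use_components = [c for c in use_components if c in components.columns]
        if len(self.use_components) < 2:
            raise ValueError("need at least two component columns")

    def _long_table(self) -> pd.DataFrame:
        z = self.norms.zscore(self.components)[self.use_components].copy()
        if self.covariates is not None:
            cov = np.asarray(self.covariates, dtype=float)
            cov = cov - np.nanmean(cov, axis=0)
            design = np.column_stack([np.ones(len(cov)), cov])
            for comp in self.use_components:
                y = z[comp].to_numpy(dtype=float)
                ok = ~np.isnan(y) & ~np.isnan(design).any(axis=1)
                beta, *_ = np.linalg.lstsq(design[ok], y[ok], rcond=None)
                y[ok] = y[ok] - design[ok] @ beta + beta[0]
                z[comp] = y
        ids = (self.components["id"] if "id" in self.components.columns
               else pd.Series(np.arange(len(z)), index=z.index).astype(str))
        long = z.assign(id=np.asarray(ids), group=self.groups).melt(
            id_vars=["id", "group"], var_name="component", value_name="score")
        long = long.dropna(subset=["score", "group"])
        # complete cases per subject across components keeps the design balanced
        counts = long.groupby("id")["component"].nunique()
        keep = counts[counts == len(self.use_components)].index
        return long[long["id"].isin(keep)]

    def fit(self, correction: bool = False) -> "ComponentAnovaResults":
        """Run the mixed (split-plot) ANOVA; ``correction=True`` applies the
        Greenhouse-Geisser sphericity correction to within-factor tests."""
        import pingouin as pg

        long = self._long_table()
        if long["group"].nunique() < 2:
            raise ValueError("at least two groups required for the interaction test")
        if long["component"].nunique() < 2:
            raise ValueError("at least two components per subject required")
        table = pg.mixed_anova(data=long, dv="score", within="component",
                               subject="id", between="group", correction=correction)
        inter = table[table["Source"] == "Interaction"].iloc[0]
        p_col = "p_unc" if "p_unc" in table.columns else "p-unc"
        posthoc = self._posthoc(long)
        return ComponentAnovaResults(
            anova_table=table,
            interaction_F=float(inter["F"]),
            interaction_df=(float(inter["DF1"]), float(inter["DF2"])),
            interaction_p=float(inter[p_col]),
            posthoc=posthoc,
            n_subjects=long["id"].nunique(),
        )

    def _posthoc(self, long: pd.DataFrame) -> pd.DataFrame:
        from itertools import combinations
        from scipy import stats

        from .characterize import bh_adjust

        rows = []
        groups = pd.unique(long["group"])
        for comp, sub in long.groupby("component", sort=False):
            for a, b in combinations(groups, 2):
                xa = sub.loc[sub["group"] == a, "score"]
                xb = sub.loc[sub["group"] == b, "score"]
                if len(xa) < 2 or len(xb) < 2:
                    continue
                t, p = stats.ttest_ind(xa, xb)
                rows.append(dict(component=comp, group_a=a, group_b=b,
                                 t=float(t), p_raw=float(p)))
        out = pd.DataFrame(rows)
        if len(out):
            out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())
        return out


@dataclass
class ComponentAnovaResults:
    anova_table: pd.DataFrame
    interaction_F: float
    interaction_df: tuple
    interaction_p: float
    posthoc: pd.DataFrame
    n_subjects: int

    def summary(self) -> str:
        d1, d2 = self.interaction_df
        lines = [
            "Split-plot ANOVA: memory component x group",
            f"  subjects (complete cases): {self.n_subjects}",
            f"  interaction: F({d1:g}, {d2:g}) = {self.interaction_F:.3f}, "
            f"p = {self.interaction_p:.4g}",
        ]
        if len(self.posthoc):
            sig = self.posthoc[self.posthoc["p_adj"] <= 0.05]
            lines.append(f"  post-hoc contrasts with adjusted p <= 0.05: {len(sig)}")
        return "\n".join(lines)


def component_by_group_anova(components, groups, norms, covariates=None,
                             correction: bool = False) -> ComponentAnovaResults:
    """Convenience wrapper: build and fit :class:`ComponentAnova`."""
    return ComponentAnova(components, groups, norms, covariates).fit(correction=correction)
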