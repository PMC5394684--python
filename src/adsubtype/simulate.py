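"""Synthetic ADNI-like cohort generation.

Builds cross-sectional and longitudinal cohorts with the statistical structure
the downstream analyses assume, so the whole pipeline can be exercised and
validated without access-controlled clinical data.

The generator works *backwards* relative to the analysis: each AD subject is
first assigned a true atrophy subtype, then visual ratings are drawn uniformly
from the admissible region of that subtype's decision rule given the subject's
age band. The rating-scale classifier therefore recovers the generating labels
with zero error by construction, which is what makes it testable.

Cognitive scores are generated on a standardized latent scale (zero mean, unit
variance, configurable predictor correlations and standardized regression
coefficients) and affinely mapped to test-score units afterwards; truncation
to valid test ranges is applied last and flagged. Longitudinal CDR and MMSE
follow a random-intercept linear (optionally quadratic) trajectory model with
group-specific slopes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ratings import (
    DEFAULT_CUTOFFS,
    CutoffTable,
    SubtypeLabel,
    mta_cutoff,
)

__all__ = [
    "GroupTrajectory",
    "MemoryStructure",
    "CohortSpec",
    "GeneratedCohort",
    "generate_cross_section",
    "generate_memory_battery",
    "generate_longitudinal",
    "generate_rating_progression",
    "generate_cohort",
]

HC = "HC"
GROUPS = (
    HC,
    SubtypeLabel.TYPICAL.value,
    SubtypeLabel.LIMBIC_PREDOMINANT.value,
    SubtypeLabel.HIPPOCAMPAL_SPARING.value,
    SubtypeLabel.NO_ATROPHY.value,
)

PREDICTORS = ("tmtb", "ds", "bnt", "vegetables", "learning")


@dataclass(frozen=True)
class GroupTrajectory:
    """Random-intercept trajectory parameters for one outcome in one group.

    y_ij = intercept + b_i + slope * t_ij + quad * t_ij^2 + eps_ij,
    b_i ~ N(0, sigma_b^2), eps ~ N(0, sigma^2).
    """

    intercept: float
    slope: float
    quad: float = 0.0


@dataclass
class MemoryStructure:
    """Standardized-latent structure of a memory outcome within one group.

    ``betas`` holds standardized coefficients for each named predictor; the
    outcome is Σ β_j x_j plus Gaussian noise completing unit variance, with
    predictors drawn from a joint with correlation ``corr`` (identity by
    default, i.e. orthogonal predictors).
    """

    betas: dict = field(default_factory=dict)
    corr: np.ndarray | None = None

    def beta_vector(self, predictors: Sequence[str] = PREDICTORS) -> np.ndarray:
        return np.array([float(self.betas.get(p, 0.0)) for p in predictors])


def _default_demographics() -> dict:
    # age mean/sd, years of education mean/sd, % female, baseline MMSE and CDR
    return {
        "HC": dict(age=(75.9, 5.0), education=(16.0, 2.9), pct_female=48.7,
                   mmse=(29.1, 1.0), cdr=(0.0, 0.05)),
        "typical": dict(age=(77.7, 6.4), education=(15.0, 3.4), pct_female=37.0,
                        mmse=(22.9, 2.1), cdr=(0.8, 0.2)),
        "limbic_predominant": dict(age=(72.3, 7.1), education=(14.6, 2.2), pct_female=57.6,
                                   mmse=(23.2, 1.9), cdr=(0.7, 0.2)),
        "hippocampal_sparing": dict(age=(78.2, 8.2), education=(14.9, 3.1), pct_female=48.6,
                                    mmse=(23.7, 2.2), cdr=(0.7, 0.3)),
        "no_atrophy": dict(age=(69.2, 6.9), education=(13.6, 3.7), pct_female=73.3,
                           mmse=(24.2, 1.5), cdr=(0.7, 0.2)),
    }


def _default_memory_structure() -> dict:
    # standardized coefficients of the delayed-free-recall models per group
    return {
        "HC": MemoryStructure({"learning": 0.744}),
        "typical": MemoryStructure({"ds": -0.249, "learning": 0.560}),
        "limbic_predominant": MemoryStructure({"learning": 0.483}),
        "hippocampal_sparing": MemoryStructure({"tmtb": 0.548, "vegetables": 0.455}),
        "no_atrophy": MemoryStructure({"ds": -0.336, "learning": 0.725}),
    }


def _default_trajectories() -> dict:
    # CDR worsens (positive slope), MMSE declines; the no-atrophy MMSE slope
    # is a calibration constant (see docs/methods.md)
    return {
        "cdr": {
            "HC": GroupTrajectory(0.0, 0.03),
            "typical": GroupTrajectory(0.8, 0.29),
            "limbic_predominant": GroupTrajectory(0.7, 0.28),
            "hippocampal_sparing": GroupTrajectory(0.7, 0.16),
            "no_atrophy": GroupTrajectory(0.7, 0.14),
        },
        "mmse": {
            "HC": GroupTrajectory(29.1, -0.01),
            "typical": GroupTrajectory(22.9, -2.69),
            "limbic_predominant": GroupTrajectory(23.2, -3.08),
            "hippocampal_sparing": GroupTrajectory(23.7, -1.48),
            "no_atrophy": GroupTrajectory(24.2, -1.60),
        },
    }


# raw-unit calibration of AVLT components and non-memory tests per group:
# (mean, sd) in native test units. Free constants chosen to give plausible
# separation between controls and patients.
_AVLT_CALIBRATION = {
    "HC": dict(learning=(45, 9), list_b=(6.0, 1.8), immediate=(9.0, 2.5),
               delayed=(8.0, 3.0), recognition=(13.0, 1.8)),
    "typical": dict(learning=(23, 7), list_b=(4.0, 1.8), immediate=(3.0, 2.0),
                    delayed=(1.5, 2.0), recognition=(7.0, 3.5)),
    "limbic_predominant": dict(learning=(24, 7), list_b=(4.0, 1.8), immediate=(3.5, 2.0),
                               delayed=(1.5, 2.0), recognition=(7.0, 3.5)),
    "hippocampal_sparing": dict(learning=(25, 7), list_b=(3.5, 1.8), immediate=(4.0, 2.0),
                                delayed=(2.0, 2.0), recognition=(8.0, 3.5)),
    "no_atrophy": dict(learning=(26, 7), list_b=(4.5, 1.8), immediate=(4.0, 2.0),
                       delayed=(2.5, 2.0), recognition=(9.5, 3.5)),
}

_NONMEM_CALIBRATION = {
    # tmtb is a completion time: larger = worse, so the ability latent enters
    # with a negative sign in the raw mapping
    "HC": dict(tmtb=(90, 35), ds=(45, 10), bnt=(27, 2.5), vegetables=(14, 4)),
    "typical": dict(tmtb=(190, 70), ds=(30, 10), bnt=(22, 5), vegetables=(8, 3.5)),
    "limbic_predominant": dict(tmtb=(185, 70), ds=(31, 10), bnt=(22, 5), vegetables=(8, 3.5)),
    "hippocampal_sparing": dict(tmtb=(195, 70), ds=(30, 10), bnt=(23, 5), vegetables=(8, 3.5)),
    "no_atrophy": dict(tmtb=(175, 70), ds=(32, 10), bnt=(23, 5), vegetables=(9, 3.5)),
}


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults reproduce the structure of the motivating ADNI-1 sample: group
    sizes 230/100/33/35/30 (controls / typical / limbic-predominant /
    hippocampal-sparing / no-atrophy), group demographics, standardized
    memory-model coefficients, and two-year random-intercept CDR/MMSE
    trajectories observed at 0/1/2 years.
    """

    group_sizes: dict = field(default_factory=lambda: {
        "HC": 230, "typical": 100, "limbic_predominant": 33,
        "hippocampal_sparing": 35, "no_atrophy": 30,
    })
    demographics: dict = field(default_factory=_default_demographics)
    memory_structure: dict = field(default_factory=_default_memory_structure)
    trajectories: dict = field(default_factory=_default_trajectories)
    cdr_sigma_b: float = 0.2
    cdr_sigma: float = 0.15
    mmse_sigma_b: float = 1.5
    mmse_sigma: float = 1.0
    visit_times: tuple = (0.0, 1.0, 2.0)
    followup_retention: float = 1.0
    rating_step_prob: float = 0.15
    round_cdr: bool = False
    cutoffs: CutoffTable = field(default_factory=CutoffTable)
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.group_sizes.items():
            if n <= 0:
                raise ValueError(f"group {g!r} must have positive size")
        if self.cdr_sigma_b < 0 or self.cdr_sigma < 0 or self.mmse_sigma_b < 0 or self.mmse_sigma < 0:
            raise ValueError("variance components must be non-negative")
        times = tuple(float(t) for t in self.visit_times)
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("visit times must be strictly increasing")
        self.visit_times = times
        if not 0.0 <= self.followup_retention <= 1.0:
            raise ValueError("followup_retention must be in [0, 1]")


@dataclass
class GeneratedCohort:
    """A simulated cohort: subject table, visit table and provenance."""

    cross_section: pd.DataFrame
    longitudinal: pd.DataFrame
    provenance: dict


def _rngs(seed: int, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# ratings consistent with an assigned subtype


def _mta_grid(threshold: float, abnormal: bool):
    grid = np.arange(0.0, 4.0 + 1e-9, 0.5)
    sel = grid >= threshold if abnormal else grid < threshold
    return grid[sel]


def _cortex_region(abnormal: bool):
    if abnormal:
        return [(pa, g) for pa in range(4) for g in range(4) if pa >= 1 or g >= 1]
    return [(0, 0)]


def _split_composite(composite: float, rng: np.random.Generator):
    total = int(round(2 * composite))
    pairs = [(l, total - l) for l in range(max(0, total - 4), min(4, total) + 1)]
    return pairs[rng.integers(len(pairs))]


def _draw_ratings(label: str, age: float, cutoffs: CutoffTable, rng: np.random.Generator):
    thr = mta_cutoff(age, cutoffs, clamp=True)
    mta_abn = label in ("typical", "limbic_predominant")
    cortex_abn = label in ("typical", "hippocampal_sparing")
    mta_choices = _mta_grid(thr, mta_abn)
    if mta_choices.size == 0:
        raise RuntimeError(
            f"no admissible MTA composite for label {label!r} at threshold {thr}"
        )
    composite = mta_choices[rng.integers(mta_choices.size)]
    mta_l, mta_r = _split_composite(composite, rng)
    cortex = _cortex_region(cortex_abn)
    pa, gca_f = cortex[rng.integers(len(cortex))]
    return mta_l, mta_r, pa, gca_f


# ---------------------------------------------------------------------------
# memory battery


def generate_memory_battery(
    n: int,
    betas: Mapping[str, float] | np.ndarray,
    *,
    predictors: Sequence[str] = PREDICTORS,
    corr: np.ndarray | None = None,
    rng: np.random.Generator | int | None = None,
    outcome_name: str = "outcome",
) -> pd.DataFrame:
    """Draw a standardized predictor battery and a linear outcome.

    Predictors are zero-mean unit-variance with correlation ``corr`` (identity
    if omitted); the outcome is ``Σ β_j x_j + ε`` with residual variance
    ``1 − βᵀΣβ`` so it is itself standardized in expectation. Raises if the
    requested coefficients imply explained variance >= 1.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    p = len(predictors)
    beta = (betas if isinstance(betas, np.ndarray)
            else np.array([float(betas.get(name, 0.0)) for name in predictors]))
    if beta.shape != (p,):
        raise ValueError("beta vector length must match predictors")
    sigma = np.eye(p) if corr is None else np.asarray(corr, dtype=float)
    if sigma.shape != (p, p) or not np.allclose(sigma, sigma.T):
        raise ValueError("corr must be a symmetric p x p matrix")
    eig = np.linalg.eigvalsh(sigma)
    if eig.min() < -1e-10:
        raise ValueError("corr must be positive semi-definite")
    explained = float(beta @ sigma @ beta)
    if explained >= 1.0:
        raise ValueError(
            f"implied explained variance {explained:.3f} >= 1; "
            "coefficients and correlations are inconsistent with a standardized outcome"
        )
    chol = np.linalg.cholesky(sigma + 1e-12 * np.eye(p))
    x = rng.standard_normal((n, p)) @ chol.T
    y = x @ beta + rng.standard_normal(n) * np.sqrt(1.0 - explained)
    out = pd.DataFrame(x, columns=list(predictors))
    out[outcome_name] = y
    return out


def _split_learning(total: int) -> tuple:
    """Split a learning total (0-75) into five trial scores (0-15 each).

    Deterministic, sums exactly to ``total``, and weights later trials more to
    mimic a learning curve.
    """
    weights = np.array([0.14, 0.17, 0.20, 0.23, 0.26])
    trials = np.floor(weights * total).astype(int)
    # distribute the remainder to later trials first
    for i in (4, 3, 2, 1, 0) * 4:
        if trials.sum() == total:
            break
        if trials[i] < 15:
            trials[i] += 1
    # cap at 15, pushing overflow to earlier trials
    for i in (4, 3, 2, 1, 0):
        if trials[i] > 15:
            overflow = trials[i] - 15
            trials[i] = 15
            for j in range(5):
                take = min(overflow, 15 - trials[j])
                trials[j] += take
                overflow -= take
                if overflow == 0:
                    break
    assert trials.sum() == total and trials.max() <= 15
    return tuple(int(t) for t in trials)


def _clip_round(x: np.ndarray, lo: float, hi: float):
    clipped = np.clip(np.round(x), lo, hi)
    return clipped, (clipped != np.round(x))


# ---------------------------------------------------------------------------
# cross-sectional generation


def generate_cross_section(spec: CohortSpec) -> pd.DataFrame:
    """Generate the baseline subject table.

    Columns: id, group, dx, true_subtype, age, sex, education, ratings
    (mta_l/mta_r/pa/gca_f), AVLT items (avlt_t1..t5, avlt_b, avlt_imm,
    avlt_del, avlt_rec), non-memory tests (tmtb, ds, bnt, vegetables),
    baseline mmse and cdr, apoe_e4/csf_abnormal flags, and a ``truncated``
    flag marking subjects whose scores hit a test floor/ceiling during the
    affine mapping to raw units.
    """
    rng_dem, rng_rat, rng_mem, _, _ = _rngs(spec.seed, 5)
    rows = []
    sid = 0
    for group in GROUPS:
        if group not in spec.group_sizes:
            continue
        n = spec.group_sizes[group]
        dem = spec.demographics[group]
        ages = np.clip(rng_dem.normal(*dem["age"], size=n),
                       spec.cutoffs.age_min, spec.cutoffs.age_max)
        edu = np.clip(np.round(rng_dem.normal(*dem["education"], size=n)), 6, 20)
        female = rng_dem.random(n) < dem["pct_female"] / 100.0
        mmse0, _ = _clip_round(rng_dem.normal(*dem["mmse"], size=n), 0, 30)
        cdr0 = np.clip(rng_dem.normal(*dem["cdr"], size=n), 0, 3)
        apoe = rng_dem.random(n) < (0.265 if group == HC else 0.65)
        csf = rng_dem.random(n) < (0.40 if group == HC else 0.90)

        structure = spec.memory_structure[group]
        battery = generate_memory_battery(
            n, structure.beta_vector(), corr=structure.corr,
            rng=rng_mem, outcome_name="delayed_z",
        )
        avlt_cal = _AVLT_CALIBRATION[group]
        nonmem_cal = _NONMEM_CALIBRATION[group]

        learning_raw, trunc_l = _clip_round(
            avlt_cal["learning"][0] + avlt_cal["learning"][1] * battery["learning"], 0, 75)
        delayed_raw, trunc_d = _clip_round(
            avlt_cal["delayed"][0] + avlt_cal["delayed"][1] * battery["delayed_z"], 0, 15)
        # remaining components share variance with the latent delayed score
        aux = rng_mem.standard_normal((n, 3))
        imm_z = 0.7 * battery["delayed_z"] + np.sqrt(1 - 0.49) * aux[:, 0]
        rec_z = 0.6 * battery["delayed_z"] + np.sqrt(1 - 0.36) * aux[:, 1]
        b_z = 0.4 * battery["learning"] + np.sqrt(1 - 0.16) * aux[:, 2]
        immediate_raw, trunc_i = _clip_round(
            avlt_cal["immediate"][0] + avlt_cal["immediate"][1] * imm_z, 0, 15)
        recognition_raw, trunc_r = _clip_round(
            avlt_cal["recognition"][0] + avlt_cal["recognition"][1] * rec_z, 0, 15)
        listb_raw, trunc_b = _clip_round(
            avlt_cal["list_b"][0] + avlt_cal["list_b"][1] * b_z, 0, 15)

        tmtb_raw = np.clip(nonmem_cal["tmtb"][0] - nonmem_cal["tmtb"][1] * battery["tmtb"], 20, 300)
        ds_raw = np.clip(np.round(nonmem_cal["ds"][0] + nonmem_cal["ds"][1] * battery["ds"]), 0, 93)
        bnt_raw = np.clip(np.round(nonmem_cal["bnt"][0] + nonmem_cal["bnt"][1] * battery["bnt"]), 0, 30)
        veg_raw = np.clip(np.round(nonmem_cal["vegetables"][0]
                                   + nonmem_cal["vegetables"][1] * battery["vegetables"]), 0, 40)

        truncated = trunc_l | trunc_d | trunc_i | trunc_r | trunc_b

        for i in range(n):
            label = None if group == HC else group
            if label is None:
                mta_l, mta_r, pa, gca_f = _draw_ratings("no_atrophy", ages[i],
                                                        spec.cutoffs, rng_rat)
            else:
                mta_l, mta_r, pa, gca_f = _draw_ratings(label, ages[i],
                                                        spec.cutoffs, rng_rat)
            trials = _split_learning(int(learning_raw[i]))
            rows.append(dict(
                id=f"S{sid:04d}", group=group,
                dx=("HC" if group == HC else "AD"),
                true_subtype=label,
                age=round(float(ages[i]), 1), sex=("F" if female[i] else "M"),
                education=int(edu[i]),
                mta_l=mta_l, mta_r=mta_r, pa=pa, gca_f=gca_f,
                avlt_t1=trials[0], avlt_t2=trials[1], avlt_t3=trials[2],
                avlt_t4=trials[3], avlt_t5=trials[4],
                avlt_b=int(listb_raw[i]), avlt_imm=int(immediate_raw[i]),
                avlt_del=int(delayed_raw[i]), avlt_rec=int(recognition_raw[i]),
                tmtb=round(float(tmtb_raw[i]), 1), ds=int(ds_raw[i]),
                bnt=int(bnt_raw[i]), vegetables=int(veg_raw[i]),
                mmse=int(mmse0[i]), cdr=round(float(cdr0[i]), 2),
                apoe_e4=bool(apoe[i]), csf_abnormal=bool(csf[i]),
                truncated=bool(truncated[i]),
            ))
            sid += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# longitudinal generation


def generate_longitudinal(spec: CohortSpec, cross_section: pd.DataFrame | None = None) -> pd.DataFrame:
    """Generate long-format CDR/MMSE visit records.

    Each subject follows ``y = α_g + b_i + β_g t + γ_g t² + ε`` with
    independent random intercepts per outcome. If ``cross_section`` is given
    its ids/groups are reused; otherwise ids are synthesised from the group
    sizes. Follow-up visits are independently retained with probability
    ``spec.followup_retention`` (baseline always kept).
    """
    _, _, _, rng, _ = _rngs(spec.seed, 5)
    if cross_section is not None:
        subjects = cross_section[["id", "group"]]
    else:
        recs = []
        sid = 0
        for group in GROUPS:
            for _ in range(spec.group_sizes.get(group, 0)):
                recs.append((f"S{sid:04d}", group))
                sid += 1
        subjects = pd.DataFrame(recs, columns=["id", "group"])

    times = np.array(spec.visit_times)
    rows = []
    for _, subj in subjects.iterrows():
        g = subj["group"]
        cdr_tr = spec.trajectories["cdr"][g]
        mmse_tr = spec.trajectories["mmse"][g]
        b_cdr = rng.normal(0.0, spec.cdr_sigma_b)
        b_mmse = rng.normal(0.0, spec.mmse_sigma_b)
        eps_cdr = rng.normal(0.0, spec.cdr_sigma, size=times.size)
        eps_mmse = rng.normal(0.0, spec.mmse_sigma, size=times.size)
        keep = rng.random(times.size) < spec.followup_retention
        keep[0] = True
        for j, t in enumerate(times):
            if not keep[j]:
                continue
            cdr = cdr_tr.intercept + b_cdr + cdr_tr.slope * t + cdr_tr.quad * t * t + eps_cdr[j]
            mmse = mmse_tr.intercept + b_mmse + mmse_tr.slope * t + mmse_tr.quad * t * t + eps_mmse[j]
            if spec.round_cdr:
                cdr = round(cdr * 2) / 2
            rows.append(dict(id=subj["id"], group=g, time_years=float(t),
                             cdr=float(cdr), mmse=float(mmse)))
    return pd.DataFrame(rows)


def generate_rating_progression(
    spec: CohortSpec,
    cross_section: pd.DataFrame,
    step_prob: float | Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Generate monotone non-decreasing longitudinal ratings.

    At each follow-up visit every scale independently steps up by one grade
    with the given probability (per scale if a mapping), capped at the scale
    maximum. Returns long-format rows id, group, time_years, mta_l, mta_r,
    pa, gca_f.
    """
    _, _, _, _, rng = _rngs(spec.seed, 5)
    if step_prob is None:
        step_prob = spec.rating_step_prob
    scales = {"mta_l": 4, "mta_r": 4, "pa": 3, "gca_f": 3}
    probs = ({s: float(step_prob) for s in scales}
             if np.isscalar(step_prob) else {s: float(step_prob[s]) for s in scales})
    rows = []
    for _, subj in cross_section.iterrows():
        current = {s: int(subj[s]) for s in scales}
        for t in spec.visit_times:
            if t != spec.visit_times[0]:
                for s, cap in scales.items():
                    if rng.random() < probs[s]:
                        current[s] = min(current[s] + 1, cap)
            rows.append(dict(id=subj["id"], group=subj["group"], time_years=float(t),
                             **current))
    return pd.DataFrame(rows)


def generate_cohort(spec: CohortSpec) -> GeneratedCohort:
    """Generate the full cohort: cross-section, CDR/MMSE visits and ratings."""
    cross = generate_cross_section(spec)
    longi = generate_longitudinal(spec, cross)
    ratings = generate_rating_progression(spec, cross)
    longi = longi.merge(ratings, on=["id", "group", "time_years"], how="left")
    prov = dict(seed=spec.seed, group_sizes=dict(spec.group_sizes),
                visit_times=list(spec.visit_times))
    return GeneratedCohort(cross_section=cross, longitudinal=longi, provenance=prov)
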