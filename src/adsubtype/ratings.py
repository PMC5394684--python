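"""Visual-rating-scale atrophy subtyping.

Classifies Alzheimer's disease patients into four atrophy-pattern subtypes
(typical, limbic-predominant, hippocampal-sparing, no-atrophy) from three
ordinal visual rating scales read off structural MRI:

* MTA  — medial temporal lobe atrophy (Scheltens), 0-4 per hemisphere;
* PA   — posterior atrophy (Koedam), 0-3;
* GCA-F — frontal subscale of the global cortical atrophy scale (Pasquier), 0-3.

MTA abnormality cutoffs are age-banded (atrophy of the medial temporal lobe is
common in normal ageing); PA and GCA-F use a single age-independent cutoff.
The subtype rule is a two-axis decision: is the medial temporal lobe abnormal,
and is the cortex (posterior and/or frontal) abnormal?
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SubtypeLabel",
    "VisualRatings",
    "CutoffTable",
    "DEFAULT_CUTOFFS",
    "mta_cutoff",
    "composite_mta",
    "is_abnormal",
    "classify_subtype",
    "classify_cohort",
]

MTA_MAX = 4
PA_MAX = 3
GCA_F_MAX = 3


class SubtypeLabel(str, enum.Enum):
    """Four mutually exclusive atrophy-pattern subtypes."""

    TYPICAL = "typical"
    LIMBIC_PREDOMINANT = "limbic_predominant"
    HIPPOCAMPAL_SPARING = "hippocampal_sparing"
    NO_ATROPHY = "no_atrophy"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def _check_rating(name: str, value, maximum: int) -> int:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        raise ValueError(f"{name} is missing")
    if float(value) != int(value):
        raise ValueError(f"{name} must be an integer rating, got {value!r}")
    v = int(value)
    if not 0 <= v <= maximum:
        raise ValueError(f"{name} must be in [0, {maximum}], got {v}")
    return v


@dataclass(frozen=True)
class VisualRatings:
    """One subject's ordinal atrophy ratings (0 denotes no atrophy)."""

    mta_left: int
    mta_right: int
    pa: int
    gca_f: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "mta_left", _check_rating("mta_left", self.mta_left, MTA_MAX))
        object.__setattr__(self, "mta_right", _check_rating("mta_right", self.mta_right, MTA_MAX))
        object.__setattr__(self, "pa", _check_rating("pa", self.pa, PA_MAX))
        object.__setattr__(self, "gca_f", _check_rating("gca_f", self.gca_f, GCA_F_MAX))


@dataclass(frozen=True)
class CutoffTable:
    """Abnormality cutoffs for the three scales.

    ``mta_age_bands`` is an ordered list of ``(age_low, age_high, threshold)``
    triples in years / rating units. Bands must be contiguous and
    non-overlapping with non-decreasing thresholds; within a band an MTA
    composite >= threshold is abnormal. PA and GCA-F cutoffs are age
    independent.
    """

    mta_age_bands: tuple = (
        (45.0, 64.0, 1.5),
        (65.0, 74.0, 1.5),
        (75.0, 84.0, 2.0),
        (85.0, 94.0, 2.5),
    )
    pa_threshold: float = 1.0
    gca_f_threshold: float = 1.0

    def __post_init__(self) -> None:
        bands = tuple(tuple(map(float, b)) for b in self.mta_age_bands)
        if not bands:
            raise ValueError("at least one MTA age band required")
        for lo, hi, _thr in bands:
            if lo >= hi:
                raise ValueError(f"band ({lo}, {hi}) has non-positive width")
        for (lo0, hi0, t0), (lo1, _hi1, t1) in zip(bands, bands[1:]):
            if lo1 < hi0:
                raise ValueError("MTA age bands overlap")
            if lo1 - hi0 > 1.0:
                raise ValueError("MTA age bands must be contiguous")
            if t1 < t0:
                raise ValueError("MTA thresholds must be non-decreasing with age")
        object.__setattr__(self, "mta_age_bands", bands)

    @property
    def age_min(self) -> float:
        return self.mta_age_bands[0][0]

    @property
    def age_max(self) -> float:
        return self.mta_age_bands[-1][1]


DEFAULT_CUTOFFS = CutoffTable()


def mta_cutoff(age: float, table: CutoffTable = DEFAULT_CUTOFFS, *, clamp: bool = False) -> float:
    """MTA abnormality threshold for a subject's age.

    Band membership is half-open on the right against the next band's lower
    edge so fractional ages between printed bands (e.g. 64.5) resolve to the
    younger band; the last band is closed at its upper edge.

    With ``clamp=True`` ages outside the configured span are clamped to the
    nearest band instead of raising.
    """
    age = float(age)
    if np.isnan(age):
        raise ValueError("age is missing")
    bands = table.mta_age_bands
    if age < table.age_min or age > table.age_max:
        if clamp:
            age = min(max(age, table.age_min), table.age_max)
        else:
            raise ValueError(
                f"age {age:g} outside configured span "
                f"[{table.age_min:g}, {table.age_max:g}] (pass clamp=True to clamp)"
            )
    for i, (lo, hi, thr) in enumerate(bands):
        upper = bands[i + 1][0] if i + 1 < len(bands) else hi
        if (lo <= age < upper) or (i + 1 == len(bands) and age <= hi):
            return thr
    raise ValueError(f"age {age:g} does not fall in any MTA band")  # pragma: no cover


def composite_mta(mta_left: int, mta_right: int, *, rule: str = "mean") -> float:
    """Combine the two hemispheric MTA grades into one score.

    ``rule='mean'`` (default) averages left and right, yielding the half-point
    grid {0, 0.5, ..., 4} that the age-banded cutoffs (1.5, 2.5) presume;
    ``rule='max'`` takes the worse hemisphere.
    """
    left = _check_rating("mta_left", mta_left, MTA_MAX)
    right = _check_rating("mta_right", mta_right, MTA_MAX)
    if rule == "mean":
        return (left + right) / 2.0
    if rule == "max":
        return float(max(left, right))
    raise ValueError(f"unknown MTA combination rule {rule!r} (expected 'mean' or 'max')")


def is_abnormal(score: float, threshold: float) -> bool:
    """Inclusive abnormality test: score >= threshold."""
    return bool(score >= threshold)


def classify_subtype(
    ratings: VisualRatings,
    age: float,
    table: CutoffTable = DEFAULT_CUTOFFS,
    *,
    clamp: bool = False,
    mta_rule: str = "mean",
) -> SubtypeLabel:
    """Assign the four-way atrophy-pattern subtype for one subject.

    typical              abnormal MTA and abnormal cortex (PA and/or GCA-F)
    limbic-predominant   abnormal MTA, normal cortex
    hippocampal-sparing  normal MTA, abnormal cortex
    no-atrophy           everything normal
    """
    mta = composite_mta(ratings.mta_left, ratings.mta_right, rule=mta_rule)
    mta_abn = is_abnormal(mta, mta_cutoff(age, table, clamp=clamp))
    cortex_abn = is_abnormal(ratings.pa, table.pa_threshold) or is_abnormal(
        ratings.gca_f, table.gca_f_threshold
    )
    if mta_abn and cortex_abn:
        return SubtypeLabel.TYPICAL
    if mta_abn:
        return SubtypeLabel.LIMBIC_PREDOMINANT
    if cortex_abn:
        return SubtypeLabel.HIPPOCAMPAL_SPARING
    return SubtypeLabel.NO_ATROPHY


_RATING_COLS = ("mta_l", "mta_r", "pa", "gca_f")


def classify_cohort(
    records: pd.DataFrame,
    table: CutoffTable = DEFAULT_CUTOFFS,
    *,
    clamp: bool = False,
    mta_rule: str = "mean",
    dx_col: str | None = "dx",
    ad_value: str = "AD",
):
    """Classify every AD subject in a cohort table.

    ``records`` needs columns ``id, age, mta_l, mta_r, pa, gca_f`` and
    optionally a diagnosis column (``dx_col``); when present only rows whose
    diagnosis equals ``ad_value`` receive a subtype — controls pass through
    with a missing label, mirroring clinical use where only patients are
    subtyped. Rows with missing or invalid ratings are skipped with a warning.

    Returns ``(labels, prevalence)``: a per-subject DataFrame ``id, subtype``
    and a prevalence table with counts and percentages over classified
    subjects.
    """
    labels = []
    for _, row in records.iterrows():
        if dx_col is not None and dx_col in records.columns and row[dx_col] != ad_value:
            labels.append((row["id"], None))
            continue
        try:
            vr = VisualRatings(row["mta_l"], row["mta_r"], row["pa"], row["gca_f"])
            lab = classify_subtype(vr, row["age"], table, clamp=clamp, mta_rule=mta_rule)
        except (ValueError, KeyError) as exc:
            warnings.warn(f"subject {row.get('id', '?')}: {exc}; skipped", stacklevel=2)
            labels.append((row.get("id"), None))
            continue
        labels.append((row["id"], lab.value))
    out = pd.DataFrame(labels, columns=["id", "subtype"])
    counted = out["subtype"].dropna()
    counts = counted.value_counts().reindex([s.value for s in SubtypeLabel], fill_value=0)
    prevalence = pd.DataFrame(
        {
            "count": counts,
            "percent": 100.0 * counts / counts.sum() if counts.sum() else 0.0,
        }
    )
    prevalence.index.name = "subtype"
    return out, prevalence
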