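"""Disease-index scoring for seedling and mature-leaf infection assays.

Seedlings are scored on an ordinal 0-4 leaf scale (0 dark green, 1 pale
green, 2 yellow, 3 brown spots, 4 dead) aggregated as a count-weighted mean
per observation.  A replicate's time course is summarized as ten times the
slope of a through-origin regression of the index on day ("standardized
10-day disease index").  Mature-leaf sections carry a separate 0 / 0.5 / 1
lesion score whose replicate mean feeds a 0-1 classification scale.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._util import round_half_up

logger = logging.getLogger(__name__)

__all__ = [
    "LeafCategoryCounts",
    "TimeCourse",
    "MatureLeafSection",
    "ClassificationThresholds",
    "IsolateAssayResult",
    "PathClass",
    "UnscoreableObservationError",
    "InsufficientDataError",
    "weighted_disease_index",
    "standardized_di_10day",
    "seedling_regression",
    "growth_rate",
    "mean_lesion_score",
    "classify_seedling",
    "classify_mature",
    "count_above_threshold",
    "read_seedling_table",
    "score_seedling_table",
    "score_mature_table",
]


class UnscoreableObservationError(ValueError):
    """Raised when an observation has no leaves to score (0/0 guard)."""


class InsufficientDataError(ValueError):
    """Raised when exclusion rules leave nothing to regress on."""


class PathClass(enum.IntEnum):
    """Pathogenicity class, ordered by severity."""

    NONPATHOGEN = 0
    WEAK_PATHOGEN = 1
    PATHOGEN = 2
    STRONG_PATHOGEN = 3

    @property
    def label(self) -> str:
        return _CLASS_LABELS[self]

    @classmethod
    def from_label(cls, label: str) -> "PathClass":
        try:
            return _LABEL_TO_CLASS[label.strip().lower()]
        except KeyError:
            raise ValueError(f"unknown pathogenicity class label: {label!r}") from None


_CLASS_LABELS = {
    PathClass.NONPATHOGEN: "Nonpathogen",
    PathClass.WEAK_PATHOGEN: "Weak Pathogen",
    PathClass.PATHOGEN: "Pathogen",
    PathClass.STRONG_PATHOGEN: "Strong Pathogen",
}
_LABEL_TO_CLASS = {v.lower(): k for k, v in _CLASS_LABELS.items()}


@dataclass(frozen=True)
class LeafCategoryCounts:
    """Leaf tallies for the five ordinal disease categories 0-4."""

    n0: int
    n1: int
    n2: int
    n3: int
    n4: int

    def __post_init__(self) -> None:
        for name in ("n0", "n1", "n2", "n3", "n4"):
            value = getattr(self, name)
            if int(value) != value or value < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {value!r}")

    @property
    def total(self) -> int:
        return self.n0 + self.n1 + self.n2 + self.n3 + self.n4

    def as_array(self) -> np.ndarray:
        return np.array([self.n0, self.n1, self.n2, self.n3, self.n4], dtype=float)


@dataclass(frozen=True)
class TimeCourse:
    """Dated leaf-category observations for a single assay replicate."""

    replicate_id: str
    observations: tuple[tuple[float, LeafCategoryCounts], ...]
    lineage: str = ""

    def __post_init__(self) -> None:
        obs = tuple(self.observations)
        object.__setattr__(self, "observations", obs)
        if not obs:
            raise ValueError("time course needs at least one observation")
        days = [day for day, _ in obs]
        if any(d < 0 for d in days):
            raise ValueError("observation days must be non-negative")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("observation days must be strictly increasing")

    @property
    def days(self) -> tuple[float, ...]:
        return tuple(day for day, _ in self.observations)


@dataclass(frozen=True)
class MatureLeafSection:
    """One scored 2x2 cm section of an inoculated mature leaf."""

    isolate_id: str
    lineage: str
    abraded: bool
    score: float

    def __post_init__(self) -> None:
        if self.score not in (0, 0.5, 1):
            raise ValueError(f"section score must be 0, 0.5 or 1, got {self.score!r}")


@dataclass(frozen=True)
class ClassificationThresholds:
    """All cut points for the two classification scales, in one place.

    ``seedling_*`` values act on the 0-4 standardized 10-day index,
    ``mature_*`` on the 0-1 mean lesion score.  ``symptom_floor`` is the
    index level attributable to background chlorosis rather than the
    inoculated microbe; ``minor_lesion_min`` is the weak-pathogen floor.
    """

    seedling_pathogen_min: float = 2.0
    seedling_strong_min: float = 4.1
    mature_weak_min: float = 0.2
    mature_pathogen_min: float = 0.5
    mature_strong_min: float = 0.8
    symptom_floor: float = 0.03
    minor_lesion_min: float = 0.1
    max_day: float = 16
    seedling_scale_max: float = 4.0
    mature_scale_max: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.symptom_floor < self.seedling_pathogen_min < self.seedling_strong_min):
            raise ValueError("need 0 <= symptom_floor < seedling_pathogen_min < seedling_strong_min")
        if not (0 < self.mature_weak_min < self.mature_pathogen_min < self.mature_strong_min <= self.mature_scale_max):
            raise ValueError("mature thresholds must be ordered within (0, scale max]")

    @classmethod
    def from_dict(cls, data: dict) -> "ClassificationThresholds":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
        return cls(**data)


DEFAULT_THRESHOLDS = ClassificationThresholds()


@dataclass
class IsolateAssayResult:
    """Per-isolate, per-lineage summary across the assays."""

    isolate_id: str
    lineage: str
    standardized_di_10day: float | None = None
    mean_lesion_score: float | None = None
    growth_rate: float | None = None
    seedling_class: PathClass | None = None
    mature_class: PathClass | None = None
    n_replicates: int = 0


@dataclass(frozen=True)
class SeedlingRegression:
    """Through-origin fit of disease index on day for one replicate."""

    slope: float
    standardized_raw: float
    standardized: float
    n_used: int


# ---------------------------------------------------------------------------
# scoring primitives


def weighted_disease_index(counts: LeafCategoryCounts) -> float:
    """Count-weighted mean disease category, in [0, 4].

    Computed as ``sum(k * n_k) / sum(n_k)`` over categories k = 0..4.
    """
    total = counts.total
    if total < 1:
        raise UnscoreableObservationError("no leaves recorded; observation is unscoreable")
    weights = np.arange(5, dtype=float)
    return float(weights @ counts.as_array() / total)


def _apply_exclusions(
    days: Sequence[float],
    dis: Sequence[float],
    extras: Sequence[float] | None,
    thresholds: ClassificationThresholds,
) -> tuple[np.ndarray, np.ndarray]:
    """Drop late observations and post-death duplicates.

    Rules, applied in day order: observations past ``max_day`` are removed,
    and once the index saturates at the scale maximum (plant dead), only the
    first two saturated observations are retained.  ``extras`` is an optional
    parallel series (e.g. leaf totals) filtered identically.
    """
    days = np.asarray(days, dtype=float)
    dis = np.asarray(dis, dtype=float)
    values = dis if extras is None else np.asarray(extras, dtype=float)

    keep = days <= thresholds.max_day
    days, dis, values = days[keep], dis[keep], values[keep]
    dead = np.isclose(dis, thresholds.seedling_scale_max)
    if dead.any():
        dead_rank = np.cumsum(dead)
        retain = ~(dead & (dead_rank > 2))
        days, values = days[retain], values[retain]
    return days, values


def _slope_through_origin(days: np.ndarray, values: np.ndarray) -> float:
    denom = float(np.sum(days * days))
    if denom == 0.0:
        raise InsufficientDataError("slope through origin undefined: all days are zero")
    return float(np.sum(days * values) / denom)


def seedling_regression(
    tc: TimeCourse, thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS
) -> SeedlingRegression:
    """Fit the standardized 10-day index for one replicate.

    Exclusion rules are applied first; the slope is the through-origin
    least-squares estimate ``sum(day*DI) / sum(day^2)``.  The standardized
    value is ``10 * slope``, reported both raw and clipped to the scale.
    """
    days = list(tc.days)
    dis = [weighted_disease_index(c) for _, c in tc.observations]
    days_f, dis_f = _apply_exclusions(days, dis, None, thresholds)
    if days_f.size == 0:
        raise InsufficientDataError(
            f"replicate {tc.replicate_id!r}: no observations remain after exclusions"
        )
    slope = _slope_through_origin(days_f, dis_f)
    raw = 10.0 * slope
    clipped = float(np.clip(raw, 0.0, thresholds.seedling_scale_max))
    return SeedlingRegression(slope=slope, standardized_raw=raw, standardized=clipped, n_used=int(days_f.size))


def standardized_di_10day(
    tc: TimeCourse,
    thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
    clip: bool = True,
) -> float:
    """Standardized 10-day disease index for one replicate (0-4 scale)."""
    fit = seedling_regression(tc, thresholds)
    return fit.standardized if clip else fit.standardized_raw


def growth_rate(
    tc: TimeCourse,
    thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
    through_origin: bool = True,
) -> float:
    """Leaf-production rate (leaves/day) under the same exclusion rules.

    Through-origin by default, mirroring the index standardization; set
    ``through_origin=False`` for an ordinary least-squares slope with
    intercept (seedlings start with at least one leaf).
    """
    days = list(tc.days)
    dis = [weighted_disease_index(c) for _, c in tc.observations]
    totals = [c.total for _, c in tc.observations]
    days_f, totals_f = _apply_exclusions(days, dis, totals, thresholds)
    if days_f.size == 0:
        raise InsufficientDataError(
            f"replicate {tc.replicate_id!r}: no observations remain after exclusions"
        )
    if through_origin:
        return _slope_through_origin(days_f, totals_f)
    if days_f.size < 2 or np.unique(days_f).size < 2:
        raise InsufficientDataError("ordinary least squares needs two distinct days")
    slope, _ = np.polyfit(days_f, totals_f, 1)
    return float(slope)


def mean_lesion_score(sections: Iterable[MatureLeafSection | float]) -> float:
    """Arithmetic mean lesion score over replicate leaf sections (0-1)."""
    scores = [s.score if isinstance(s, MatureLeafSection) else float(s) for s in sections]
    if not scores:
        raise ValueError("mean lesion score undefined for an empty section list")
    if any(s not in (0, 0.5, 1) for s in scores):
        raise ValueError("section scores must be 0, 0.5 or 1")
    if not 3 <= len(scores) <= 7:
        logger.warning("lesion score averaged over %d sections (expected 3-7)", len(scores))
    return float(np.mean(scores))


# ---------------------------------------------------------------------------
# classification


def classify_seedling(
    di: float, thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS
) -> PathClass:
    """Classify a standardized seedling index after half-up rounding to 1 dp.

    Values at or above the background-chlorosis floor but below the weak
    floor are still Nonpathogen; the Weak Pathogen band below the 2.0
    pathogen cut is an extension of the published 0-4 scale.
    """
    if di < 0:
        raise ValueError(f"disease index must be non-negative, got {di}")
    rounded = round_half_up(di, 1)
    if rounded >= thresholds.seedling_strong_min:
        return PathClass.STRONG_PATHOGEN
    if rounded >= thresholds.seedling_pathogen_min:
        return PathClass.PATHOGEN
    if rounded > thresholds.symptom_floor and rounded >= thresholds.minor_lesion_min:
        return PathClass.WEAK_PATHOGEN
    return PathClass.NONPATHOGEN


def classify_mature(
    score: float, thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS
) -> PathClass:
    """Classify a mean mature-leaf lesion score on half-open 0-1 bands.

    Bands: [0, weak), [weak, pathogen), [pathogen, strong), [strong, 1].
    The score is rounded half-up to two decimals first.
    """
    if not 0 <= score <= thresholds.mature_scale_max:
        raise ValueError(f"lesion score must lie in [0, {thresholds.mature_scale_max}], got {score}")
    rounded = round_half_up(score, 2)
    if rounded >= thresholds.mature_strong_min:
        return PathClass.STRONG_PATHOGEN
    if rounded >= thresholds.mature_pathogen_min:
        return PathClass.PATHOGEN
    if rounded >= thresholds.mature_weak_min:
        return PathClass.WEAK_PATHOGEN
    return PathClass.NONPATHOGEN


def count_above_threshold(
    results: Iterable[IsolateAssayResult],
    threshold: float,
    lineage: str | None = None,
) -> int:
    """Number of isolates whose standardized index meets ``threshold``."""
    count = 0
    for result in results:
        if lineage is not None and result.lineage != lineage:
            continue
        if result.standardized_di_10day is not None and result.standardized_di_10day >= threshold:
            count += 1
    return count


# ---------------------------------------------------------------------------
# table-level interface

SEEDLING_COLUMNS = ["isolate_id", "lineage", "replicate", "day", "n0", "n1", "n2", "n3", "n4"]
MATURE_COLUMNS = ["isolate_id", "lineage", "abraded", "section_score"]


def read_seedling_table(source) -> list[TimeCourse]:
    """Load per-replicate time courses from a seedling observation table.

    ``source`` is a CSV/TSV path or a DataFrame with columns
    ``isolate_id, lineage, replicate, day, n0..n4``.  Rows are grouped by
    (isolate, lineage, replicate) and sorted by day.
    """
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source, sep=None, engine="python")
    missing = set(SEEDLING_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"seedling table is missing columns: {sorted(missing)}")
    courses = []
    for (isolate, lineage, replicate), grp in df.groupby(
        ["isolate_id", "lineage", "replicate"], sort=True
    ):
        grp = grp.sort_values("day")
        obs = tuple(
            (float(row.day), LeafCategoryCounts(int(row.n0), int(row.n1), int(row.n2), int(row.n3), int(row.n4)))
            for row in grp.itertuples()
        )
        courses.append(TimeCourse(replicate_id=f"{isolate}:{lineage}:{replicate}", observations=obs, lineage=str(lineage)))
    return courses


def score_seedling_table(
    source,
    thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
    clip: bool = False,
) -> pd.DataFrame:
    """Score a seedling observation table to one row per isolate x lineage.

    Each replicate is regressed separately; replicate values are averaged,
    rounded half-up to one decimal, and classified.  Reported values are the
    raw standardized indices by default — a strong pathogen can exceed the
    4.0 leaf scale there, and the strong cut at 4.1 is only reachable
    unclipped — pass ``clip=True`` to bound them to the scale.
    """
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source, sep=None, engine="python")
    rows = []
    for (isolate, lineage), grp in df.groupby(["isolate_id", "lineage"], sort=True):
        courses = read_seedling_table(grp)
        dis, rates = [], []
        for tc in courses:
            dis.append(standardized_di_10day(tc, thresholds, clip=clip))
            rates.append(growth_rate(tc, thresholds))
        mean_di = round_half_up(float(np.mean(dis)), 1)
        rows.append(
            {
                "isolate_id": isolate,
                "lineage": lineage,
                "standardized_di": mean_di,
                "growth_rate": round_half_up(float(np.mean(rates)), 3),
                "n_replicates": len(courses),
                "class": classify_seedling(mean_di, thresholds).label,
            }
        )
    return pd.DataFrame(rows)


def score_mature_table(
    source,
    thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
    abraded_only: bool = True,
) -> pd.DataFrame:
    """Score a mature-leaf section table to one row per isolate x lineage."""
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source, sep=None, engine="python")
    missing = set(MATURE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"mature table is missing columns: {sorted(missing)}")
    if abraded_only:
        df = df[df["abraded"].astype(int) == 1]
    rows = []
    for (isolate, lineage), grp in df.groupby(["isolate_id", "lineage"], sort=True):
        mean = mean_lesion_score([float(s) for s in grp["section_score"]])
        rows.append(
            {
                "isolate_id": isolate,
                "lineage": lineage,
                "mean_lesion_score": round_half_up(mean, 3),
                "n_sections": len(grp),
                "class": classify_mature(mean, thresholds).label,
            }
        )
    return pd.DataFrame(rows)
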