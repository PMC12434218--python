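"""Episode data model and the cumulative nutritional-intensity score.

The score summarises the burden of dietetic intervention for one patient
over a fixed post-transplant window (by default the first 100 days,
represented as inclusive days 0..99, day 0 = infusion day).  Each support
level carries a weight reflecting escalating clinical effort -- routine
dietetic review (1), oral nutritional support (2), enteral nutrition (4),
parenteral nutrition (6), bespoke parenteral nutrition (7) -- and the score
is the sum over interventions of weight x days on that intervention within
the window.  Days with no dietetic contact contribute 0.

Two overlap conventions are supported for days on which several support
levels are documented simultaneously:

``additive``
    every active level contributes its weight for the day (faithful to a
    per-intervention sum); duplicate episodes of the *same* level on the
    same day are merged first so no day is double-billed within one level.
``max_per_day``
    only the single highest active level contributes.

For non-overlapping episodes the two conventions coincide.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "SupportLevel",
    "WeightScheme",
    "InterventionEpisode",
    "ScoreWindow",
    "PatientRecord",
    "ScoreResult",
    "DEFAULT_WINDOW",
    "clip_episode",
    "compute_patient_auc",
    "daily_level_profile",
    "pn_outcome_at",
    "validate_record",
    "filter_complete_followup",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when an input record violates the data-model invariants."""


class SupportLevel(enum.IntEnum):
    """Ordinal scale of nutritional-support intensity.

    ``NONE`` denotes absence of dietetic contact on a day; it is never
    stored in an episode.  The integer value is the ordinal rank, giving
    the total order NONE < ROUTINE < ORAL < ENTERAL < PN < BESPOKE_PN.
    """

    NONE = 0
    ROUTINE = 1
    ORAL = 2
    ENTERAL = 3
    PN = 4
    BESPOKE_PN = 5

    @classmethod
    def from_token(cls, token: str) -> "SupportLevel":
        """Parse a case-insensitive level token (``routine`` .. ``bespoke_pn``)."""
        try:
            return cls[token.strip().upper()]
        except KeyError:
            allowed = ", ".join(l.name.lower() for l in cls if l is not cls.NONE)
            raise ValidationError(
                f"unknown support level {token!r}; allowed tokens: {allowed}"
            ) from None

    @property
    def token(self) -> str:
        return self.name.lower()


#: Default level weights (points per day on that level).
DEFAULT_POINTS: dict[SupportLevel, float] = {
    SupportLevel.NONE: 0.0,
    SupportLevel.ROUTINE: 1.0,
    SupportLevel.ORAL: 2.0,
    SupportLevel.ENTERAL: 4.0,
    SupportLevel.PN: 6.0,
    SupportLevel.BESPOKE_PN: 7.0,
}


@dataclass(frozen=True)
class WeightScheme:
    """Map from support level to daily points.

    Weights must be strictly increasing with level rank among the five
    named levels, and NONE must map to exactly 0.  Defaults are the
    1/2/4/6/7 scheme; alternative institutional weightings may be supplied.
    """

    points_by_level: Mapping[SupportLevel, float] = field(
        default_factory=lambda: dict(DEFAULT_POINTS)
    )

    def __post_init__(self) -> None:
        pts = dict(self.points_by_level)
        pts.setdefault(SupportLevel.NONE, 0.0)
        missing = [l for l in SupportLevel if l not in pts]
        if missing:
            raise ValidationError(f"weights missing levels: {missing}")
        if pts[SupportLevel.NONE] != 0.0:
            raise ValidationError("NONE must carry weight 0")
        ranked = [pts[l] for l in sorted(SupportLevel) if l is not SupportLevel.NONE]
        if any(b <= a for a, b in zip(ranked, ranked[1:])):
            raise ValidationError("weights must increase strictly with level rank")
        if any(v < 0 for v in pts.values()):
            raise ValidationError("weights must be non-negative")
        object.__setattr__(self, "points_by_level", pts)

    def __getitem__(self, level: SupportLevel) -> float:
        return self.points_by_level[level]

    def as_array(self) -> np.ndarray:
        """Weights indexed by ordinal rank (position 0 = NONE)."""
        return np.array([self.points_by_level[l] for l in sorted(SupportLevel)])


@dataclass(frozen=True)
class ScoreWindow:
    """Inclusive day range [first_day, last_day] over which the score accrues."""

    first_day: int = 0
    last_day: int = 99

    def __post_init__(self) -> None:
        if self.last_day < self.first_day:
            raise ValidationError("window last_day must be >= first_day")

    @property
    def length(self) -> int:
        return self.last_day - self.first_day + 1

    def contains(self, day: int) -> bool:
        return self.first_day <= day <= self.last_day


DEFAULT_WINDOW = ScoreWindow()


@dataclass(frozen=True)
class InterventionEpisode:
    """One contiguous run of a support level for a patient.

    Days are integers post-transplant (day 0 = infusion day); ``end_day``
    is inclusive, so duration = end_day - start_day + 1 >= 1.
    """

    patient_id: str
    level: SupportLevel
    start_day: int
    end_day: int

    def __post_init__(self) -> None:
        if self.level is SupportLevel.NONE:
            raise ValidationError("episodes cannot carry level NONE")
        if self.start_day < 0:
            raise ValidationError("start_day must be >= 0")
        if self.end_day < self.start_day:
            raise ValidationError(
                f"end_day {self.end_day} < start_day {self.start_day}"
            )

    @property
    def duration_days(self) -> int:
        return self.end_day - self.start_day + 1


@dataclass
class PatientRecord:
    """Covariates plus intervention episodes for one patient.

    ``covariates`` is any object describing baseline characteristics (see
    :mod:`nutriscore.synthetic_cohort`); the scoring engine never inspects
    it.  ``pn_day100_override``, when set, replaces the trajectory-derived
    endpoint in :func:`pn_outcome_at` (used by simulated logistic outcomes).
    """

    patient_id: str
    episodes: list[InterventionEpisode] = field(default_factory=list)
    covariates: object | None = None
    followup_days: int = 100
    died_before_day100: bool = False
    pn_day100_override: bool | None = None


@dataclass(frozen=True)
class ScoreResult:
    """Cumulative intensity score and per-level day counts for one patient."""

    patient_id: str
    auc: float
    days_by_level: Mapping[SupportLevel, int]
    level_at_last_day: SupportLevel
    overlap_mode_used: str


def clip_episode(
    episode: InterventionEpisode, window: ScoreWindow = DEFAULT_WINDOW
) -> InterventionEpisode | None:
    """Intersect an episode with the scoring window; ``None`` if disjoint."""
    start = max(episode.start_day, window.first_day)
    end = min(episode.end_day, window.last_day)
    if end < start:
        return None
    return replace(episode, start_day=start, end_day=end)


def _level_masks(
    episodes: Iterable[InterventionEpisode], window: ScoreWindow
) -> dict[SupportLevel, np.ndarray]:
    """Boolean day-coverage mask per level, after same-level merging.

    Representing coverage as a per-day mask merges overlapping or duplicate
    episodes of the same level for free, so no day is counted twice within
    one level.
    """
    masks: dict[SupportLevel, np.ndarray] = {}
    for ep in episodes:
        clipped = clip_episode(ep, window)
        if clipped is None:
            continue
        mask = masks.setdefault(ep.level, np.zeros(window.length, dtype=bool))
        lo = clipped.start_day - window.first_day
        hi = clipped.end_day - window.first_day + 1
        mask[lo:hi] = True
    return masks


def daily_level_profile(
    record: PatientRecord, window: ScoreWindow = DEFAULT_WINDOW
) -> list[SupportLevel]:
    """Highest active support level on each window day.

    Position ``d`` holds the level on day ``window.first_day + d``;
    ``NONE`` where no episode covers the day.  This is the step curve the
    score integrates in ``max_per_day`` mode, and a plotting substrate.
    """
    ranks = np.zeros(window.length, dtype=np.int64)
    for level, mask in _level_masks(record.episodes, window).items():
        np.maximum(ranks, np.where(mask, int(level), 0), out=ranks)
    return [SupportLevel(r) for r in ranks]


def compute_patient_auc(
    record: PatientRecord,
    weights: WeightScheme | None = None,
    window: ScoreWindow = DEFAULT_WINDOW,
    overlap_mode: str = "additive",
) -> ScoreResult:
    """Cumulative nutritional-intensity score for one patient.

    In ``additive`` mode the score is the sum over levels of
    weight(level) x (days on that level within the window), after merging
    same-level overlaps.  In ``max_per_day`` mode each day contributes the
    weight of the single highest active level.  ``days_by_level`` reports
    per-level day counts under the chosen convention, and
    ``level_at_last_day`` the highest level active on the window's final
    day (NONE if uncovered).
    """
    if weights is None:
        weights = WeightScheme()
    if overlap_mode not in ("additive", "max_per_day"):
        raise ValueError(f"unknown overlap_mode {overlap_mode!r}")
    problems = validate_record(record)
    if problems:
        raise ValidationError("; ".join(problems))

    masks = _level_masks(record.episodes, window)
    days_by_level: dict[SupportLevel, int] = {
        l: 0 for l in SupportLevel if l is not SupportLevel.NONE
    }
    if overlap_mode == "additive":
        for level, mask in masks.items():
            days_by_level[level] = int(mask.sum())
    else:
        profile = daily_level_profile(record, window)
        for level in profile:
            if level is not SupportLevel.NONE:
                days_by_level[level] += 1
    auc = float(sum(weights[l] * d for l, d in days_by_level.items()))

    last = SupportLevel.NONE
    for level, mask in masks.items():
        if mask[-1] and level > last:
            last = level
    return ScoreResult(
        patient_id=record.patient_id,
        auc=auc,
        days_by_level=days_by_level,
        level_at_last_day=last,
        overlap_mode_used=overlap_mode,
    )


def pn_outcome_at(
    record: PatientRecord,
    day: int | None = None,
    window: ScoreWindow = DEFAULT_WINDOW,
) -> bool:
    """Whether the patient is on >= parenteral nutrition on ``day``.

    Defaults to the window's last day (Day +100 endpoint under the default
    window).  True iff the highest active level that day ranks at or above
    PN.  A day beyond the recorded follow-up raises: the patient is
    censored there and must be excluded, not scored false.
    """
    if day is None:
        day = window.last_day
    if day >= record.followup_days:
        raise ValidationError(
            f"day {day} beyond follow-up ({record.followup_days} days) for "
            f"patient {record.patient_id}: outcome is censored"
        )
    if record.pn_day100_override is not None:
        return record.pn_day100_override
    best = SupportLevel.NONE
    for ep in record.episodes:
        if ep.start_day <= day <= ep.end_day and ep.level > best:
            best = ep.level
    return best >= SupportLevel.PN


def validate_record(record: PatientRecord) -> list[str]:
    """Check data-model invariants; returns a (possibly empty) list of violations.

    Episode-level invariants (duration >= 1, level != NONE) are enforced at
    episode construction; this re-checks them defensively alongside the
    record-level rules so externally built objects are caught too.
    """
    problems: list[str] = []
    max_end = -1
    for i, ep in enumerate(record.episodes):
        if ep.patient_id != record.patient_id:
            problems.append(
                f"episode {i}: patient_id {ep.patient_id!r} != record "
                f"{record.patient_id!r}"
            )
        if ep.level is SupportLevel.NONE:
            problems.append(f"episode {i}: level NONE is not storable")
        if ep.end_day < ep.start_day:
            problems.append(
                f"episode {i}: duration rule violated (end_day {ep.end_day} < "
                f"start_day {ep.start_day})"
            )
        if ep.start_day < 0:
            problems.append(f"episode {i}: start_day {ep.start_day} < 0")
        max_end = max(max_end, ep.end_day)
    if record.episodes and record.followup_days < max_end:
        problems.append(
            f"followup_days {record.followup_days} < last episode day {max_end}"
        )
    return problems


def filter_complete_followup(
    records: Sequence[PatientRecord],
    window: ScoreWindow = DEFAULT_WINDOW,
    allow_truncated: bool = False,
) -> tuple[list[PatientRecord], list[PatientRecord]]:
    """Split records into (scoreable, excluded) by follow-up completeness.

    The default policy mirrors the cohort-entry rule: patients who died or
    were lost to follow-up before the window closed are excluded rather
    than scored on a truncated window.  With ``allow_truncated`` every
    record is kept and scored over whatever window it covers (a warning is
    emitted so silent truncation cannot slip through).
    """
    kept: list[PatientRecord] = []
    excluded: list[PatientRecord] = []
    for rec in records:
        complete = rec.followup_days >= window.length and not rec.died_before_day100
        if complete or allow_truncated:
            if not complete:
                warnings.warn(
                    f"patient {rec.patient_id}: scoring truncated follow-up "
                    f"({rec.followup_days} d < window {window.length} d)",
                    stacklevel=2,
                )
            kept.append(rec)
        else:
            excluded.append(rec)
    return kept, excluded
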