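"""Domain model for paired-Likert (Kano) questionnaire responses.

A Kano questionnaire asks, for every candidate need, a *positive*
(functional: "how would you feel if this were provided?") and a *negative*
(dysfunctional: "... if it were not provided?") question, each on a
five-point Likert scale.  The answer pair is mapped through a fixed 5x5
classification matrix to one of six attributes:

======  =============================================================
symbol  meaning
======  =============================================================
A       attractive — presence delights, absence does not dissatisfy
O       one-dimensional — satisfaction tracks fulfilment linearly
M       must-be — expected baseline; absence dissatisfies sharply
I       indifferent — little effect either way
R       reverse — fulfilment dissatisfies
Q       questionable — contradictory answer pair
======  =============================================================

This module holds the Likert/attribute vocabulary, the classification
matrix, respondent records with their demographic strata, and the
validity screening applied before any tabulation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum, IntEnum
from typing import Iterable, Mapping, Sequence

from .errors import ValidationError


class LikertLevel(IntEnum):
    """Five-point scale used for both question directions (1 = Like ... 5 = Dislike)."""

    LIKE = 1
    SHOULD_BE = 2
    DOES_NOT_MATTER = 3
    CAN_ACCEPT = 4
    DISLIKE = 5

    @property
    def label(self) -> str:
        return _LIKERT_LABELS[self]

    @classmethod
    def from_code(cls, code: int, *, field_name: str = "likert code") -> "LikertLevel":
        try:
            return cls(int(code))
        except (ValueError, TypeError) as exc:
            raise ValidationError(
                f"{field_name}: expected an integer 1-5, got {code!r}"
            ) from exc


_LIKERT_LABELS = {
    LikertLevel.LIKE: "Like",
    LikertLevel.SHOULD_BE: "Should be",
    LikertLevel.DOES_NOT_MATTER: "Does not matter",
    LikertLevel.CAN_ACCEPT: "Can accept",
    LikertLevel.DISLIKE: "Dislike",
}


class KanoAttribute(str, Enum):
    """The six Kano attributes; ``analyzable()`` are the coefficient-denominator four."""

    ATTRACTIVE = "A"
    ONE_DIMENSIONAL = "O"
    MUST_BE = "M"
    INDIFFERENT = "I"
    REVERSE = "R"
    QUESTIONABLE = "Q"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @classmethod
    def analyzable(cls) -> tuple["KanoAttribute", ...]:
        return (cls.ATTRACTIVE, cls.ONE_DIMENSIONAL, cls.MUST_BE, cls.INDIFFERENT)


#: Fixed priority order used for tie-breaking and reporting.
ATTRIBUTE_ORDER = (
    KanoAttribute.MUST_BE,
    KanoAttribute.ONE_DIMENSIONAL,
    KanoAttribute.ATTRACTIVE,
    KanoAttribute.INDIFFERENT,
    KanoAttribute.REVERSE,
    KanoAttribute.QUESTIONABLE,
)

# Rows indexed by the positive answer, columns by the negative answer,
# both in Likert order 1..5.  Loaders must not transpose.
_MATRIX_ROWS: dict[LikertLevel, str] = {
    LikertLevel.LIKE: "QAAAO",
    LikertLevel.SHOULD_BE: "RIIIM",
    LikertLevel.DOES_NOT_MATTER: "RIIIM",
    LikertLevel.CAN_ACCEPT: "RIIIM",
    LikertLevel.DISLIKE: "RRRRQ",
}

#: Expected multiset of cells in the canonical matrix.
_CELL_MULTISET = {"A": 3, "O": 1, "M": 3, "I": 9, "R": 7, "Q": 2}


@dataclass(frozen=True)
class ClassificationMatrix:
    """Total mapping (positive level, negative level) -> Kano attribute.

    The canonical matrix has row "Like" = [Q, A, A, A, O], rows
    "Should be"/"Does not matter"/"Can accept" = [R, I, I, I, M] and row
    "Dislike" = [R, R, R, R, Q]; the cell multiset {A:3, O:1, M:3, I:9,
    R:7, Q:2} is asserted at construction.
    """

    cells: Mapping[tuple[LikertLevel, LikertLevel], KanoAttribute]

    def __post_init__(self) -> None:
        if len(self.cells) != 25:
            raise ValidationError(
                f"classification matrix must define all 25 cells, got {len(self.cells)}"
            )
        tally = Counter(attr.value for attr in self.cells.values())
        if dict(tally) != _CELL_MULTISET:
            raise ValidationError(
                f"matrix cell multiset {dict(tally)} != expected {_CELL_MULTISET}"
            )

    def __getitem__(
        self, key: tuple[LikertLevel, LikertLevel]
    ) -> KanoAttribute:
        return self.cells[key]

    def cells_for(self, attribute: KanoAttribute) -> list[tuple[LikertLevel, LikertLevel]]:
        """All (positive, negative) pairs mapping to ``attribute``, row-major order."""
        return [pair for pair, attr in sorted(self.cells.items()) if attr == attribute]

    @classmethod
    def default(cls) -> "ClassificationMatrix":
        cells = {
            (pos, neg): KanoAttribute(row[neg - 1])
            for pos, row in _MATRIX_ROWS.items()
            for neg in LikertLevel
        }
        return cls(cells)


DEFAULT_MATRIX = ClassificationMatrix.default()


def classify_pair(
    positive: int | LikertLevel,
    negative: int | LikertLevel,
    matrix: ClassificationMatrix = DEFAULT_MATRIX,
) -> KanoAttribute:
    """Classify one positive/negative answer pair through the matrix.

    Deterministic and total over valid Likert codes; out-of-range codes
    raise :class:`ValidationError` naming the offending field.
    """
    pos = LikertLevel.from_code(positive, field_name="positive")
    neg = LikertLevel.from_code(negative, field_name="negative")
    return matrix[(pos, neg)]


# --------------------------------------------------------------------------
# demographics and respondent records
# --------------------------------------------------------------------------

#: Closed category sets for the six demographic strata.
DEMOGRAPHIC_CATEGORIES: dict[str, tuple[str, ...]] = {
    "region": ("Sichuan", "Chongqing"),
    "gender": ("Male", "Female"),
    "age_group": ("<=30", "31-50", ">=51"),
    "cdc_level": ("district/county", "municipal+"),
    "field_of_work": ("health technology", "administrative logistics"),
    "job_position": ("leader", "ordinary"),
}

DEMOGRAPHIC_FIELDS = tuple(DEMOGRAPHIC_CATEGORIES)


@dataclass(frozen=True)
class DemographicProfile:
    region: str
    gender: str
    age_group: str
    cdc_level: str
    field_of_work: str
    job_position: str

    def __post_init__(self) -> None:
        for name, allowed in DEMOGRAPHIC_CATEGORIES.items():
            value = getattr(self, name)
            if value not in allowed:
                raise ValidationError(
                    f"demographics.{name}: {value!r} not in {allowed}"
                )

    def as_dict(self) -> dict[str, str]:
        return {name: getattr(self, name) for name in DEMOGRAPHIC_FIELDS}


@dataclass(frozen=True)
class ItemResponse:
    """One need's positive/negative answer pair for one respondent."""

    need_id: str
    positive: LikertLevel
    negative: LikertLevel

    def __post_init__(self) -> None:
        object.__setattr__(self, "positive", LikertLevel.from_code(self.positive, field_name=f"{self.need_id}.positive"))
        object.__setattr__(self, "negative", LikertLevel.from_code(self.negative, field_name=f"{self.need_id}.negative"))


@dataclass(frozen=True)
class RespondentRecord:
    """One questionnaire: opaque id, demographic profile, one item per need.

    ``demographics`` may be None for data sources that omit them (long
    format); subgroup analysis then refuses the record.
    """

    respondent_id: str
    demographics: DemographicProfile | None
    items: tuple[ItemResponse, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(self.items))
        seen = [item.need_id for item in self.items]
        if len(set(seen)) != len(seen):
            raise ValidationError(
                f"respondent {self.respondent_id}: duplicate need ids in items"
            )

    def item(self, need_id: str) -> ItemResponse | None:
        for it in self.items:
            if it.need_id == need_id:
                return it
        return None


# --------------------------------------------------------------------------
# validity screening
# --------------------------------------------------------------------------

MISSING_ITEM = "MISSING_ITEM"
STRAIGHT_LINE_IDENTICAL = "STRAIGHT_LINE_IDENTICAL"
EXCESS_QUESTIONABLE = "EXCESS_QUESTIONABLE"


@dataclass(frozen=True)
class ScreeningConfig:
    """Operational questionnaire-validity rules.

    A respondent is excluded iff (a) any catalog need lacks an answer pair,
    (b) positive == negative on *every* item (straight-lining; the
    clearest form of the identical-options inconsistency), or
    (c) the fraction of items classifying to Q exceeds
    ``max_questionable_fraction``.  Single questionable items are retained:
    real samples keep per-item Q shares of a few percent.
    """

    require_all_items: bool = True
    exclude_straight_line: bool = True
    max_questionable_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_questionable_fraction <= 1.0:
            raise ValidationError(
                "max_questionable_fraction must lie in [0, 1], got "
                f"{self.max_questionable_fraction}"
            )


@dataclass(frozen=True)
class ScreeningResult:
    valid: tuple[RespondentRecord, ...]
    excluded: tuple[tuple[RespondentRecord, str], ...]
    effective_rate: float

    @property
    def n_collected(self) -> int:
        return len(self.valid) + len(self.excluded)

    def exclusion_reasons(self) -> Counter:
        return Counter(reason for _, reason in self.excluded)


def screen_respondents(
    records: Sequence[RespondentRecord],
    need_ids: Iterable[str],
    config: ScreeningConfig = ScreeningConfig(),
    matrix: ClassificationMatrix = DEFAULT_MATRIX,
) -> ScreeningResult:
    """Partition records into valid and excluded questionnaires.

    Returns the partition plus the effective rate |valid| / |input|.
    The first matching rule (missing item, straight-line, excess Q) supplies
    the exclusion reason code.
    """
    records = list(records)
    if not records:
        raise ValidationError("screen_respondents: no records supplied")
    need_ids = list(need_ids)
    if not need_ids:
        raise ValidationError("screen_respondents: empty need catalog")
    catalog_set = set(need_ids)

    valid: list[RespondentRecord] = []
    excluded: list[tuple[RespondentRecord, str]] = []
    for rec in records:
        unknown = [it.need_id for it in rec.items if it.need_id not in catalog_set]
        if unknown:
            raise ValidationError(
                f"respondent {rec.respondent_id}: unknown need ids {unknown}"
            )
        reason = _exclusion_reason(rec, need_ids, config, matrix)
        if reason is None:
            valid.append(rec)
        else:
            excluded.append((rec, reason))
    return ScreeningResult(
        valid=tuple(valid),
        excluded=tuple(excluded),
        effective_rate=len(valid) / len(records),
    )


def _exclusion_reason(
    rec: RespondentRecord,
    need_ids: list[str],
    config: ScreeningConfig,
    matrix: ClassificationMatrix,
) -> str | None:
    answered = {it.need_id for it in rec.items}
    if config.require_all_items and any(n not in answered for n in need_ids):
        return MISSING_ITEM
    items = [it for it in rec.items if it.need_id in set(need_ids)]
    if (
        config.exclude_straight_line
        and items
        and all(it.positive == it.negative for it in items)
    ):
        return STRAIGHT_LINE_IDENTICAL
    if items:
        n_q = sum(
            classify_pair(it.positive, it.negative, matrix) is KanoAttribute.QUESTIONABLE
            for it in items
        )
        if n_q / len(items) > config.max_questionable_fraction:
            return EXCESS_QUESTIONABLE
    return None
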