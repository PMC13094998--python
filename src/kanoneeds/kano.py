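"""Core Kano analysis: frequency tabulation, better/worse coefficients,
satisfaction sensitivity, centroid quadrant classification and ranking.

For a need with attribute counts A, O, M, I (R and Q excluded from the
denominator) the Berger coefficients are

    SI  = (A + O) / (A + O + M + I)          # better coefficient, [0, 1]
    DSI = -(O + M) / (A + O + M + I)         # worse coefficient, [-1, 0]

and the satisfaction sensitivity is the Euclidean distance of the point
(SI, |DSI|) from the origin, S = sqrt(SI^2 + DSI^2).  Needs are placed in
a four-quadrant plane relative to the centroid (mean SI, mean |DSI|):

    high SI, high |DSI|  -> O    (one-dimensional)
    high SI, low  |DSI|  -> A    (attractive)
    low  SI, high |DSI|  -> M    (must-be)
    low  SI, low  |DSI|  -> I    (indifferent)

Priority follows the hierarchy M > O > A > I, then descending S within
each attribute.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

from .errors import ReconstructionError, UndefinedCoefficientError, ValidationError
from .response import (
    ATTRIBUTE_ORDER,
    DEFAULT_MATRIX,
    ClassificationMatrix,
    KanoAttribute,
    RespondentRecord,
    classify_pair,
)

_A = KanoAttribute.ATTRACTIVE
_O = KanoAttribute.ONE_DIMENSIONAL
_M = KanoAttribute.MUST_BE
_I = KanoAttribute.INDIFFERENT

#: Quadrant labels ordered by the priority hierarchy.
QUADRANT_HIERARCHY = (_M, _O, _A, _I)


def round_half_up(x: float, ndigits: int = 3) -> float:
    """Round-half-up used for all displayed coefficients (matches hand tables)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class AttributeFrequency:
    """Per-need counts over the six attributes for n respondents."""

    need_id: str
    counts: Mapping[KanoAttribute, int]

    def __post_init__(self) -> None:
        counts = {attr: int(self.counts.get(attr, 0)) for attr in KanoAttribute}
        if any(c < 0 for c in counts.values()):
            raise ValidationError(f"{self.need_id}: negative attribute count")
        object.__setattr__(self, "counts", counts)

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    @property
    def percentages(self) -> dict[KanoAttribute, float]:
        n = self.n
        if n == 0:
            raise ValidationError(f"{self.need_id}: empty frequency table")
        return {attr: c / n for attr, c in self.counts.items()}

    def __getitem__(self, attr: KanoAttribute) -> int:
        return self.counts[attr]


@dataclass(frozen=True)
class KanoCoefficients:
    """Better (SI), worse (DSI) coefficients and sensitivity S for one need."""

    need_id: str
    si: float
    dsi: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.si <= 1.0:
            raise ValidationError(f"{self.need_id}: SI {self.si} outside [0, 1]")
        if not -1.0 <= self.dsi <= 0.0:
            raise ValidationError(f"{self.need_id}: DSI {self.dsi} outside [-1, 0]")

    @property
    def s(self) -> float:
        return satisfaction_sensitivity(self.si, self.dsi)


@dataclass(frozen=True)
class Centroid:
    """Mean SI and mean |DSI| over the analysed needs; the quadrant origin."""

    mean_si: float
    mean_abs_dsi: float


@dataclass(frozen=True)
class QuadrantClassification:
    need_id: str
    attribute: KanoAttribute
    s: float
    sensitivity_rank: int
    within_attribute_rank: int


# --------------------------------------------------------------------------
# tabulation
# --------------------------------------------------------------------------

def tabulate_need(
    records: Sequence[RespondentRecord],
    need_id: str,
    matrix: ClassificationMatrix = DEFAULT_MATRIX,
) -> AttributeFrequency:
    """Count the attribute classifications of one need over all respondents."""
    if not records:
        raise ValidationError("tabulate_need: no records")
    tally: Counter = Counter()
    for rec in records:
        item = rec.item(need_id)
        if item is None:
            raise ValidationError(
                f"respondent {rec.respondent_id} has no answer for {need_id}"
            )
        tally[classify_pair(item.positive, item.negative, matrix)] += 1
    return AttributeFrequency(need_id, tally)


def percentages_to_counts(
    percentages: Mapping[KanoAttribute, float], n: int
) -> dict[KanoAttribute, int]:
    """Reconstruct integer counts from published percentage rows.

    Each count is the nearest integer to p*n; raises
    :class:`ReconstructionError` when the reconstruction does not sum to n
    (the published row is then internally inconsistent at that n).
    """
    if n <= 0:
        raise ValidationError(f"n must be positive, got {n}")
    counts = {attr: int(round(percentages.get(attr, 0.0) * n)) for attr in KanoAttribute}
    total = sum(counts.values())
    if total != n:
        raise ReconstructionError(
            f"reconstructed counts sum to {total}, expected {n} (residual {total - n})"
        )
    return counts


# --------------------------------------------------------------------------
# coefficients
# --------------------------------------------------------------------------

def _analyzable_total(freq: AttributeFrequency) -> int:
    total = sum(freq[attr] for attr in KanoAttribute.analyzable())
    if total == 0:
        raise UndefinedCoefficientError(
            f"{freq.need_id}: all responses are R/Q; coefficients undefined"
        )
    return total


def better_coefficient(freq: AttributeFrequency) -> float:
    """SI = (A + O)/(A + O + M + I)."""
    return (freq[_A] + freq[_O]) / _analyzable_total(freq)


def worse_coefficient(freq: AttributeFrequency) -> float:
    """DSI = -(O + M)/(A + O + M + I)."""
    return -(freq[_O] + freq[_M]) / _analyzable_total(freq)


def satisfaction_sensitivity(si: float, dsi: float) -> float:
    """S = sqrt(SI^2 + DSI^2), the distance of (SI, |DSI|) from the origin."""
    if not 0.0 <= si <= 1.0:
        raise ValidationError(f"SI {si} outside [0, 1]")
    if not -1.0 <= dsi <= 1.0:
        raise ValidationError(f"DSI {dsi} outside [-1, 1]")
    return math.hypot(si, dsi)


def coefficients(freq: AttributeFrequency) -> KanoCoefficients:
    """Compute both Berger coefficients for one frequency table."""
    return KanoCoefficients(
        need_id=freq.need_id,
        si=better_coefficient(freq),
        dsi=worse_coefficient(freq),
    )


def compute_centroid(coeffs: Sequence[KanoCoefficients]) -> Centroid:
    """Arithmetic means of SI and |DSI| over the needs (>= 2 required)."""
    if len(coeffs) < 2:
        raise ValidationError("centroid needs at least two needs")
    return Centroid(
        mean_si=sum(c.si for c in coeffs) / len(coeffs),
        mean_abs_dsi=sum(abs(c.dsi) for c in coeffs) / len(coeffs),
    )


def assign_quadrant(coeff: KanoCoefficients, centroid: Centroid) -> KanoAttribute:
    """Quadrant label relative to the centroid; boundary points count as 'high'."""
    high_si = coeff.si >= centroid.mean_si
    high_dsi = abs(coeff.dsi) >= centroid.mean_abs_dsi
    if high_si and high_dsi:
        return _O
    if high_si:
        return _A
    if high_dsi:
        return _M
    return _I


def modal_attribute(freq: AttributeFrequency) -> KanoAttribute:
    """Attribute with the largest count; ties broken in the fixed order
    M > O > A > I > R > Q (deterministic, documented)."""
    if freq.n == 0:
        raise ValidationError(f"{freq.need_id}: empty frequency table")
    best = max(freq.counts.values())
    for attr in ATTRIBUTE_ORDER:
        if freq[attr] == best:
            return attr
    raise AssertionError("unreachable")  # pragma: no cover


# --------------------------------------------------------------------------
# ranking
# --------------------------------------------------------------------------

def rank_needs(
    coeffs: Sequence[KanoCoefficients],
    centroid: Centroid | None = None,
) -> list[QuadrantClassification]:
    """Classify every need against the centroid and attach both rank columns.

    ``sensitivity_rank`` ranks ALL needs by descending S (1 = most
    sensitive); ``within_attribute_rank`` restarts at 1 inside each
    quadrant attribute.  Ties in S are broken by input (catalog) order.
    Returns one entry per need, in the input order.
    """
    if not coeffs:
        raise ValidationError("rank_needs: no coefficients")
    if centroid is None:
        centroid = compute_centroid(coeffs)

    labelled = [
        (c.need_id, assign_quadrant(c, centroid), c.s, idx)
        for idx, c in enumerate(coeffs)
    ]
    by_s = sorted(labelled, key=lambda t: (-t[2], t[3]))
    global_rank = {t[0]: r for r, t in enumerate(by_s, start=1)}
    within_rank: dict[str, int] = {}
    for attr in QUADRANT_HIERARCHY:
        members = [t for t in by_s if t[1] is attr]
        for r, t in enumerate(members, start=1):
            within_rank[t[0]] = r
    return [
        QuadrantClassification(
            need_id=need_id,
            attribute=attr,
            s=s,
            sensitivity_rank=global_rank[need_id],
            within_attribute_rank=within_rank[need_id],
        )
        for need_id, attr, s, _ in labelled
    ]


def priority_order(classified: Sequence[QuadrantClassification]) -> list[str]:
    """Overall priority: attribute hierarchy M > O > A > I, then S rank within."""
    hier = {attr: i for i, attr in enumerate(QUADRANT_HIERARCHY)}
    return [
        c.need_id
        for c in sorted(
            classified, key=lambda c: (hier[c.attribute], c.within_attribute_rank)
        )
    ]


def analyze_needs(
    records: Sequence[RespondentRecord],
    need_ids: Sequence[str],
    matrix: ClassificationMatrix = DEFAULT_MATRIX,
) -> tuple[list[AttributeFrequency], list[KanoCoefficients], Centroid, list[QuadrantClassification]]:
    """Full chain: tabulate -> coefficients -> centroid -> quadrant ranking."""
    freqs = [tabulate_need(records, need_id, matrix) for need_id in need_ids]
    coeffs = [coefficients(f) for f in freqs]
    centroid = compute_centroid(coeffs)
    classified = rank_needs(coeffs, centroid)
    return freqs, coeffs, centroid, classified
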