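"""Subgroup comparison of Kano attribute distributions.

Splits valid respondents along one demographic field, recomputes the
per-group frequency table, Berger coefficients and modal attribute for a
need, and tests whether the attribute distribution differs between groups
with a Pearson chi-square test on the group x attribute contingency table.

The contingency construction is configurable because published analyses
rarely state it: the full six-attribute table, the table with the rare
R/Q columns dropped, or a 2 x 2 collapse of one target attribute against
the rest.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateTableError, ValidationError
from .kano import AttributeFrequency, KanoCoefficients, coefficients, modal_attribute, tabulate_need
from .response import (
    DEFAULT_MATRIX,
    DEMOGRAPHIC_FIELDS,
    ClassificationMatrix,
    KanoAttribute,
    RespondentRecord,
)

#: Supported contingency-table schemes for the chi-square comparison.
CATEGORY_SCHEMES = ("full", "drop_rq", "target_vs_rest")


@dataclass(frozen=True)
class SubgroupSplit:
    """Partition of respondents along one demographic field."""

    demographic_field: str
    groups: Mapping[str, tuple[RespondentRecord, ...]]

    def __post_init__(self) -> None:
        if self.demographic_field not in DEMOGRAPHIC_FIELDS:
            raise ValidationError(
                f"unknown demographic field {self.demographic_field!r}; "
                f"expected one of {DEMOGRAPHIC_FIELDS}"
            )
        if any(len(g) == 0 for g in self.groups.values()):
            raise ValidationError(f"{self.demographic_field}: empty subgroup")


@dataclass(frozen=True)
class GroupSummary:
    group: str
    frequency: AttributeFrequency
    coefficients: KanoCoefficients
    attribute: KanoAttribute


@dataclass(frozen=True)
class SubgroupComparison:
    demographic_field: str
    need_id: str
    summaries: tuple[GroupSummary, ...]
    chi2: float
    df: int
    p: float


def split_by(
    records: Sequence[RespondentRecord], demographic_field: str
) -> SubgroupSplit:
    """Group respondents by one demographic field (insertion-ordered)."""
    if not records:
        raise ValidationError("split_by: no records")
    groups: dict[str, list[RespondentRecord]] = {}
    for rec in records:
        if rec.demographics is None:
            raise ValidationError(
                f"respondent {rec.respondent_id} has no demographics; "
                "subgroup analysis needs the wide input format"
            )
        key = getattr(rec.demographics, demographic_field, None)
        if key is None:
            raise ValidationError(f"unknown demographic field {demographic_field!r}")
        groups.setdefault(key, []).append(rec)
    return SubgroupSplit(
        demographic_field=demographic_field,
        groups={k: tuple(v) for k, v in groups.items()},
    )


def subgroup_coefficients(
    split: SubgroupSplit,
    need_id: str,
    matrix: ClassificationMatrix = DEFAULT_MATRIX,
) -> list[GroupSummary]:
    """Per-group frequency, SI/DSI and modal attribute for one need."""
    out = []
    for group, members in split.groups.items():
        freq = tabulate_need(members, need_id, matrix)
        try:
            coeff = coefficients(freq)
        except Exception as exc:
            raise type(exc)(f"group {group!r}: {exc}") from exc
        out.append(
            GroupSummary(
                group=group,
                frequency=freq,
                coefficients=coeff,
                attribute=modal_attribute(freq),
            )
        )
    return out


def _contingency(
    freqs: Sequence[AttributeFrequency],
    scheme: str,
    target: KanoAttribute | None,
) -> np.ndarray:
    if scheme not in CATEGORY_SCHEMES:
        raise ValidationError(f"unknown category scheme {scheme!r}; use {CATEGORY_SCHEMES}")
    if scheme == "target_vs_rest":
        if target is None:
            raise ValidationError("target_vs_rest scheme requires a target attribute")
        table = np.array(
            [[f[target], f.n - f[target]] for f in freqs], dtype=float
        )
    else:
        attrs = list(KanoAttribute)
        if scheme == "drop_rq":
            attrs = list(KanoAttribute.analyzable())
        table = np.array([[f[a] for a in attrs] for f in freqs], dtype=float)
    # all-zero columns carry no information and break expected counts
    table = table[:, table.sum(axis=0) > 0]
    if table.shape[1] < 2:
        raise DegenerateTableError(
            "fewer than two non-empty categories; collapse the scheme"
        )
    return table


def chi_square_attributes(
    freqs: Sequence[AttributeFrequency],
    scheme: str = "full",
    target: KanoAttribute | None = None,
    yates: bool = False,
) -> tuple[float, int, float]:
    """Pearson chi-square on the groups x attribute-categories table.

    Returns (chi2, df, p) with df = (R-1)(C-1).  Zero expected counts
    raise :class:`DegenerateTableError` advising category collapse;
    Yates continuity correction is off by default (only meaningful 2x2).
    """
    if len(freqs) < 2:
        raise ValidationError("chi-square comparison needs at least two groups")
    table = _contingency(freqs, scheme, target)
    expected = stats.contingency.expected_freq(table)
    if np.any(expected == 0):
        raise DegenerateTableError(
            "zero expected count in the contingency table; collapse categories "
            "(scheme 'drop_rq' or 'target_vs_rest')"
        )
    chi2, p, df, _ = stats.chi2_contingency(table, correction=yates)
    return float(chi2), int(df), float(p)


def compare_subgroups(
    records: Sequence[RespondentRecord],
    demographic_field: str,
    need_id: str,
    matrix: ClassificationMatrix = DEFAULT_MATRIX,
    scheme: str = "full",
    target: KanoAttribute | None = None,
    yates: bool = False,
) -> SubgroupComparison:
    """Split, summarise and chi-square-test one need along one demographic field."""
    split = split_by(records, demographic_field)
    summaries = subgroup_coefficients(split, need_id, matrix)
    chi2, df, p = chi_square_attributes(
        [s.frequency for s in summaries], scheme=scheme, target=target, yates=yates
    )
    return SubgroupComparison(
        demographic_field=demographic_field,
        need_id=need_id,
        summaries=tuple(summaries),
        chi2=chi2,
        df=df,
        p=p,
    )
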