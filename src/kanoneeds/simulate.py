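"""Synthetic questionnaire generator.

Emulates the statistical structure the analysis assumes: each need has a
latent attribute mixture (default: the reference survey's per-need
attribute shares), each respondent independently draws one attribute per
need and then a positive/negative Likert pair uniformly from the matrix
cells of that attribute, demographics are drawn independently per field
from the reference marginals, and a small fraction of questionnaires is
overwritten as straight-line invalid records (identical answers on every
item) to exercise validity screening.

Defaults mirror the reference study: 117 collected questionnaires of
which 7/117 are invalid, leaving ~110 valid.  The generator returns the
latent per-need attribute tallies so recovery tests can compare what was
drawn with what the classification chain reconstructs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import reference
from .catalog import NeedCatalog, default_catalog
from .errors import ValidationError
from .response import (
    DEFAULT_MATRIX,
    DEMOGRAPHIC_CATEGORIES,
    ClassificationMatrix,
    DemographicProfile,
    ItemResponse,
    KanoAttribute,
    LikertLevel,
    RespondentRecord,
)

#: Likert level used on every item of an injected straight-line record.
STRAIGHT_LINE_LEVEL = LikertLevel.DOES_NOT_MATTER


@dataclass(frozen=True)
class NeedProfile:
    """Latent attribute mixture for one need."""

    need_id: str
    attribute_probs: Mapping[KanoAttribute, float]

    def __post_init__(self) -> None:
        probs = {attr: float(self.attribute_probs.get(attr, 0.0)) for attr in KanoAttribute}
        if any(p < 0 for p in probs.values()):
            raise ValidationError(f"{self.need_id}: negative attribute probability")
        total = sum(probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"{self.need_id}: attribute probabilities sum to {total}, not 1"
            )
        object.__setattr__(self, "attribute_probs", probs)


def reference_profiles() -> list[NeedProfile]:
    """Per-need mixtures matching the reference survey's attribute shares.

    Built from the reconstructed integer counts (each row sums exactly to
    the valid sample size), so probabilities sum to 1 exactly.
    """
    return [
        NeedProfile(
            f.need_id, {attr: c / f.n for attr, c in f.counts.items()}
        )
        for f in reference.reference_frequencies()
    ]


@dataclass(frozen=True)
class StudyDesign:
    """Full specification of a synthetic survey.

    Defaults are the reference study's conditions: 117 collected
    questionnaires, invalid fraction 7/117, per-need mixtures equal to the
    published attribute shares, demographic marginals equal to the
    published strata proportions.
    """

    n_respondents: int = reference.COLLECTED_SIZE
    profiles: tuple[NeedProfile, ...] = field(default_factory=lambda: tuple(reference_profiles()))
    demographic_marginals: Mapping[str, Mapping[str, float]] = field(
        default_factory=reference.demographic_marginals
    )
    invalid_fraction: float = 7.0 / reference.COLLECTED_SIZE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_respondents < 1:
            raise ValidationError("n_respondents must be >= 1")
        if not 0.0 <= self.invalid_fraction < 1.0:
            raise ValidationError("invalid_fraction must lie in [0, 1)")
        ids = [p.need_id for p in self.profiles]
        if len(set(ids)) != len(ids) or not ids:
            raise ValidationError("profiles must be non-empty with unique need ids")
        for fld, cats in self.demographic_marginals.items():
            allowed = DEMOGRAPHIC_CATEGORIES.get(fld)
            if allowed is None:
                raise ValidationError(f"unknown demographic field {fld!r}")
            if any(c not in allowed for c in cats):
                raise ValidationError(f"{fld}: categories {list(cats)} not all in {allowed}")
            total = sum(cats.values())
            if abs(total - 1.0) > 1e-9 or any(v < 0 for v in cats.values()):
                raise ValidationError(f"{fld}: marginals must be non-negative and sum to 1")

    @property
    def need_ids(self) -> tuple[str, ...]:
        return tuple(p.need_id for p in self.profiles)


@dataclass(frozen=True)
class StudyResult:
    records: tuple[RespondentRecord, ...]
    latent_tallies: dict[str, Counter]
    invalid_ids: tuple[str, ...]


def attribute_to_pair(
    attribute: KanoAttribute,
    matrix: ClassificationMatrix = DEFAULT_MATRIX,
    rng: np.random.Generator | None = None,
) -> tuple[LikertLevel, LikertLevel]:
    """Inverse-sample the matrix: a uniform cell among those mapping to
    ``attribute``; classifying the pair returns the attribute (roundtrip)."""
    rng = rng if rng is not None else np.random.default_rng()
    cells = matrix.cells_for(attribute)
    return cells[int(rng.integers(len(cells)))]


def generate_study(design: StudyDesign = StudyDesign()) -> StudyResult:
    """Draw a complete synthetic survey; reproducible given ``design.seed``.

    The latent tallies count the attributes drawn for records that were
    NOT overwritten as invalid, so with ``invalid_fraction = 0`` they
    match ``tabulate_need`` on the output exactly.
    """
    rng = np.random.default_rng(design.seed)
    n = design.n_respondents
    n_invalid = int(round(design.invalid_fraction * n))
    invalid_idx = set(
        rng.choice(n, size=n_invalid, replace=False).tolist()
    ) if n_invalid else set()

    demo_fields = {
        fld: (list(cats), np.array(list(cats.values())))
        for fld, cats in design.demographic_marginals.items()
    }
    attrs = list(KanoAttribute)
    profiles_p = {
        p.need_id: np.array([p.attribute_probs[a] for a in attrs])
        for p in design.profiles
    }

    records: list[RespondentRecord] = []
    tallies: dict[str, Counter] = {nid: Counter() for nid in design.need_ids}
    invalid_ids: list[str] = []
    width = len(str(n))
    for i in range(n):
        demo = DemographicProfile(**{
            fld: cats[int(rng.choice(len(cats), p=probs))]
            for fld, (cats, probs) in demo_fields.items()
        })
        items: list[ItemResponse] = []
        drawn: list[tuple[str, KanoAttribute]] = []
        for nid in design.need_ids:
            attr = attrs[int(rng.choice(len(attrs), p=profiles_p[nid]))]
            pos, neg = attribute_to_pair(attr, rng=rng)
            items.append(ItemResponse(nid, pos, neg))
            drawn.append((nid, attr))
        rid = f"R{i + 1:0{width}d}"
        if i in invalid_idx:
            items = [
                ItemResponse(nid, STRAIGHT_LINE_LEVEL, STRAIGHT_LINE_LEVEL)
                for nid in design.need_ids
            ]
            invalid_ids.append(rid)
        else:
            for nid, attr in drawn:
                tallies[nid][attr] += 1
        records.append(RespondentRecord(rid, demo, tuple(items)))
    return StudyResult(
        records=tuple(records),
        latent_tallies=tallies,
        invalid_ids=tuple(invalid_ids),
    )
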