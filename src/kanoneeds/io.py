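"""CSV interchange and report writers.

One interchange format: UTF-8 CSV, "." decimal point.  The wide schema is
one row per respondent::

    respondent_id, region, gender, age_group, cdc_level, field_of_work,
    job_position, q01_pos, q01_neg, ..., q13_pos, q13_neg

with integer Likert codes 1-5.  A long schema (respondent_id, need_id,
direction, code) is also read; it carries no demographics.  Report
writers emit frequency/coefficient, importance and subgroup tables with
both full-precision and display-rounded columns (percentages to 2 dp,
coefficients to 3 dp, half-up).  DSI is stored signed with an ASCII
hyphen.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .catalog import NeedCatalog
from .errors import ValidationError
from .kano import (
    AttributeFrequency,
    Centroid,
    KanoCoefficients,
    QuadrantClassification,
    round_half_up,
)
from .response import (
    DEMOGRAPHIC_FIELDS,
    DemographicProfile,
    ItemResponse,
    KanoAttribute,
    RespondentRecord,
    ScreeningConfig,
)
from .subgroups import CATEGORY_SCHEMES, SubgroupComparison

_ATTR_COLUMNS = ("A", "I", "M", "O", "Q", "R")  # report column order


def _item_column(need_id: str) -> str:
    """Q7 -> q07; any other id is lower-cased verbatim."""
    if need_id[:1].upper() == "Q" and need_id[1:].isdigit():
        return f"q{int(need_id[1:]):02d}"
    return need_id.lower()


# --------------------------------------------------------------------------
# respondent readers / writers
# --------------------------------------------------------------------------

def records_to_dataframe(
    records: Sequence[RespondentRecord], catalog: NeedCatalog
) -> pd.DataFrame:
    rows = []
    for rec in records:
        row: dict[str, object] = {"respondent_id": rec.respondent_id}
        if rec.demographics is not None:
            row.update(rec.demographics.as_dict())
        for nid in catalog.need_ids:
            item = rec.item(nid)
            if item is None:
                raise ValidationError(
                    f"respondent {rec.respondent_id}: no answer for {nid}"
                )
            col = _item_column(nid)
            row[f"{col}_pos"] = int(item.positive)
            row[f"{col}_neg"] = int(item.negative)
        rows.append(row)
    return pd.DataFrame(rows)


def write_responses_csv(
    records: Sequence[RespondentRecord], catalog: NeedCatalog, path: str | Path
) -> None:
    records_to_dataframe(records, catalog).to_csv(path, index=False)


def read_responses_csv(path: str | Path, catalog: NeedCatalog) -> list[RespondentRecord]:
    """Read the wide schema; schema violations name the row and column."""
    df = pd.read_csv(path, dtype={"respondent_id": str})
    if df.empty:
        raise ValidationError(f"{path}: no respondent rows")
    if "respondent_id" not in df.columns:
        raise ValidationError(f"{path}: missing column 'respondent_id'")
    missing = [
        f"{_item_column(nid)}_{suffix}"
        for nid in catalog.need_ids
        for suffix in ("pos", "neg")
        if f"{_item_column(nid)}_{suffix}" not in df.columns
    ]
    if missing:
        raise ValidationError(f"{path}: missing item columns {missing}")
    has_demo = all(f in df.columns for f in DEMOGRAPHIC_FIELDS)

    records = []
    for idx, row in df.iterrows():
        demo = None
        if has_demo:
            try:
                demo = DemographicProfile(**{f: str(row[f]) for f in DEMOGRAPHIC_FIELDS})
            except ValidationError as exc:
                raise ValidationError(f"{path} row {idx}: {exc}") from exc
        items = []
        for nid in catalog.need_ids:
            col = _item_column(nid)
            try:
                items.append(
                    ItemResponse(nid, int(row[f"{col}_pos"]), int(row[f"{col}_neg"]))
                )
            except (ValidationError, ValueError) as exc:
                raise ValidationError(f"{path} row {idx}, column {col}: {exc}") from exc
        records.append(RespondentRecord(str(row["respondent_id"]), demo, tuple(items)))
    return records


def read_responses_long(path: str | Path, catalog: NeedCatalog) -> list[RespondentRecord]:
    """Read the long schema (respondent_id, need_id, direction, code).

    ``direction`` is 'pos'/'positive' or 'neg'/'negative'.  The resulting
    records carry no demographics.
    """
    df = pd.read_csv(path, dtype={"respondent_id": str, "need_id": str, "direction": str})
    required = {"respondent_id", "need_id", "direction", "code"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path}: long format needs columns {sorted(required)}")
    records = []
    for rid, grp in df.groupby("respondent_id", sort=False):
        items = []
        for nid, pair in grp.groupby("need_id", sort=False):
            if nid not in catalog.need_ids:
                raise ValidationError(f"{path}: unknown need_id {nid!r}")
            codes = {}
            for _, row in pair.iterrows():
                d = str(row["direction"]).lower()
                if d in ("pos", "positive"):
                    codes["pos"] = int(row["code"])
                elif d in ("neg", "negative"):
                    codes["neg"] = int(row["code"])
                else:
                    raise ValidationError(f"{path}: bad direction {row['direction']!r}")
            if set(codes) != {"pos", "neg"}:
                raise ValidationError(
                    f"{path}: respondent {rid} need {nid} lacks a pos/neg pair"
                )
            items.append(ItemResponse(nid, codes["pos"], codes["neg"]))
        records.append(RespondentRecord(str(rid), None, tuple(items)))
    if not records:
        raise ValidationError(f"{path}: no respondent rows")
    return records


# --------------------------------------------------------------------------
# report tables
# --------------------------------------------------------------------------

def frequency_table(
    freqs: Sequence[AttributeFrequency],
    coeffs: Sequence[KanoCoefficients],
    centroid: Centroid,
) -> pd.DataFrame:
    """Per-need attribute shares plus SI/DSI, with an average row.

    Columns: percentage shares to 2 dp, display coefficients to 3 dp, and
    full-precision ``si_full``/``dsi_full``.
    """
    rows = []
    for f, c in zip(freqs, coeffs):
        row: dict[str, object] = {"need_id": f.need_id}
        for a in _ATTR_COLUMNS:
            row[f"{a}_pct"] = round_half_up(100 * f.percentages[KanoAttribute(a)], 2)
        row.update(
            SI=round_half_up(c.si, 3),
            DSI=round_half_up(c.dsi, 3),
            si_full=c.si,
            dsi_full=c.dsi,
        )
        rows.append(row)
    rows.append(
        {
            "need_id": "Average value",
            "SI": round_half_up(centroid.mean_si, 3),
            "DSI": round_half_up(-centroid.mean_abs_dsi, 3),
            "si_full": centroid.mean_si,
            "dsi_full": -centroid.mean_abs_dsi,
        }
    )
    return pd.DataFrame(rows)


def importance_table(classified: Sequence[QuadrantClassification]) -> pd.DataFrame:
    """Importance scale: attribute, S, global and within-attribute ranks,
    ordered by the priority hierarchy M > O > A > I."""
    from .kano import QUADRANT_HIERARCHY

    hier = {a: i for i, a in enumerate(QUADRANT_HIERARCHY)}
    ordered = sorted(classified, key=lambda c: (hier[c.attribute], c.within_attribute_rank))
    return pd.DataFrame(
        [
            {
                "need_id": c.need_id,
                "kano_attribute": c.attribute.value,
                "S": round_half_up(c.s, 3),
                "s_full": c.s,
                "sensitivity_rank": c.sensitivity_rank,
                "within_attribute_rank": c.within_attribute_rank,
            }
            for c in ordered
        ]
    )


def subgroup_table(comparisons: Sequence[SubgroupComparison]) -> pd.DataFrame:
    rows = []
    for comp in comparisons:
        for i, s in enumerate(comp.summaries):
            rows.append(
                {
                    "demographic_field": comp.demographic_field,
                    "need_id": comp.need_id,
                    "group": s.group,
                    "kano_attribute": s.attribute.value,
                    "SI": round_half_up(s.coefficients.si, 3),
                    "DSI": round_half_up(s.coefficients.dsi, 3),
                    "si_full": s.coefficients.si,
                    "dsi_full": s.coefficients.dsi,
                    "chi2": round_half_up(comp.chi2, 3) if i == 0 else None,
                    "df": comp.df if i == 0 else None,
                    "p": round_half_up(comp.p, 3) if i == 0 else None,
                }
            )
    return pd.DataFrame(rows)


def demographics_table(records: Sequence[RespondentRecord]) -> pd.DataFrame:
    """Stratum counts and shares among the given (valid) respondents."""
    rows = []
    n = len(records)
    for fld in DEMOGRAPHIC_FIELDS:
        values = [getattr(r.demographics, fld) for r in records if r.demographics]
        if not values:
            continue
        counts = pd.Series(values).value_counts()
        for cat, cnt in counts.items():
            rows.append(
                {
                    "demographic_field": fld,
                    "category": cat,
                    "n": int(cnt),
                    "percent": round_half_up(100 * cnt / n, 2),
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# pipeline configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """Everything the end-to-end pipeline needs; YAML round-trippable."""

    input_path: str = ""
    output_dir: str = "kano_report"
    catalog_path: str | None = None  # None -> bundled catalog
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)
    subgroup_fields: tuple[str, ...] = ("region", "field_of_work", "job_position")
    category_scheme: str = "full"
    yates: bool = False
    seed: int = 0
    coefficient_dp: int = 3
    percentage_dp: int = 2

    def __post_init__(self) -> None:
        if self.category_scheme not in CATEGORY_SCHEMES:
            raise ValidationError(
                f"category_scheme {self.category_scheme!r} not in {CATEGORY_SCHEMES}"
            )
        for fld in self.subgroup_fields:
            if fld not in DEMOGRAPHIC_FIELDS:
                raise ValidationError(f"unknown subgroup field {fld!r}")

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["screening"] = asdict(self.screening)
        data["subgroup_fields"] = list(self.subgroup_fields)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if "screening" in data and isinstance(data["screening"], dict):
            data["screening"] = ScreeningConfig(**data["screening"])
        if "subgroup_fields" in data:
            data["subgroup_fields"] = tuple(data["subgroup_fields"])
        return cls(**data)

    def with_(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)
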