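"""End-to-end orchestration: read -> screen -> analyse -> write report bundle."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import io as kio
from .catalog import NeedCatalog, default_catalog
from .errors import DegenerateTableError, ValidationError
from .kano import (
    AttributeFrequency,
    Centroid,
    KanoCoefficients,
    QuadrantClassification,
    analyze_needs,
    priority_order,
)
from .plotting import quadrant_scatter
from .response import RespondentRecord, ScreeningResult, screen_respondents
from .subgroups import SubgroupComparison, compare_subgroups

log = logging.getLogger("kanoneeds")


@dataclass(frozen=True)
class ReportBundle:
    screening: ScreeningResult
    frequencies: list[AttributeFrequency]
    coefficients: list[KanoCoefficients]
    centroid: Centroid
    classified: list[QuadrantClassification]
    subgroups: list[SubgroupComparison]
    tables: dict[str, pd.DataFrame]


def analyze_records(
    records: Sequence[RespondentRecord],
    catalog: NeedCatalog,
    config: kio.PipelineConfig,
) -> ReportBundle:
    """Screen and analyse in-memory records; deterministic given input+config."""
    screening = screen_respondents(
        records, catalog.need_ids, config.screening
    )
    if not screening.valid:
        raise ValidationError("no valid questionnaires after screening")
    log.info(
        "screening: %d collected, %d excluded (%s), effective rate %.2f%%",
        screening.n_collected,
        len(screening.excluded),
        dict(screening.exclusion_reasons()) or "none",
        100 * screening.effective_rate,
    )
    valid = list(screening.valid)
    freqs, coeffs, centroid, classified = analyze_needs(valid, catalog.need_ids)
    log.info("centroid: mean SI %.3f, mean |DSI| %.3f", centroid.mean_si, centroid.mean_abs_dsi)
    for c in classified:
        log.info("%s -> %s (S=%.3f, rank %d)", c.need_id, c.attribute.value, c.s, c.sensitivity_rank)

    comparisons: list[SubgroupComparison] = []
    has_demo = all(r.demographics is not None for r in valid)
    if has_demo:
        for fld in config.subgroup_fields:
            for nid in catalog.need_ids:
                try:
                    comparisons.append(
                        compare_subgroups(
                            valid, fld, nid,
                            scheme=config.category_scheme, yates=config.yates,
                        )
                    )
                except DegenerateTableError as exc:
                    log.warning("subgroup %s/%s skipped: %s", fld, nid, exc)
    else:
        log.warning("records lack demographics; subgroup comparison skipped")

    tables = {
        "frequencies": kio.frequency_table(freqs, coeffs, centroid),
        "importance": kio.importance_table(classified),
        "subgroups": kio.subgroup_table(comparisons),
    }
    if has_demo:
        tables["demographics"] = kio.demographics_table(valid)
    return ReportBundle(
        screening=screening,
        frequencies=freqs,
        coefficients=coeffs,
        centroid=centroid,
        classified=classified,
        subgroups=comparisons,
        tables=tables,
    )


def write_bundle(
    bundle: ReportBundle, catalog: NeedCatalog, outdir: str | Path
) -> dict[str, Path]:
    """Write CSV tables, the quadrant plot and a JSON run log; returns paths."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, df in bundle.tables.items():
        paths[name] = out / f"{name}.csv"
        df.to_csv(paths[name], index=False)
    paths["quadrant_plot"] = quadrant_scatter(
        bundle.coefficients, bundle.centroid, out / "quadrant_plot.png"
    )
    run_log = {
        "n_collected": bundle.screening.n_collected,
        "n_valid": len(bundle.screening.valid),
        "n_excluded": len(bundle.screening.excluded),
        "exclusion_reasons": dict(bundle.screening.exclusion_reasons()),
        "effective_rate": bundle.screening.effective_rate,
        "centroid": {
            "mean_si": bundle.centroid.mean_si,
            "mean_abs_dsi": bundle.centroid.mean_abs_dsi,
        },
        "classification": {
            c.need_id: c.attribute.value for c in bundle.classified
        },
        "priority_order": priority_order(bundle.classified),
    }
    paths["run_log"] = out / "run_log.json"
    paths["run_log"].write_text(json.dumps(run_log, indent=2), encoding="utf-8")
    return paths


def run_pipeline(config: kio.PipelineConfig) -> ReportBundle:
    """Full pipeline from a wide/long CSV to a written report bundle."""
    catalog = (
        NeedCatalog.from_csv(config.catalog_path)
        if config.catalog_path
        else default_catalog()
    )
    path = Path(config.input_path)
    if not path.exists():
        raise ValidationError(f"input not found: {path}")
    header = pd.read_csv(path, nrows=0).columns
    if {"need_id", "direction", "code"}.issubset(header):
        records = kio.read_responses_long(path, catalog)
    else:
        records = kio.read_responses_csv(path, catalog)
    bundle = analyze_records(records, catalog, config)
    write_bundle(bundle, catalog, config.output_dir)
    return bundle
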