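"""Need catalog: the ordered indicator system the questionnaire covers.

The default catalog is the 13-item collaborative-development needs system
for grassroots CDCs (4 primary needs, secondary needs numbered Q1..Q13),
bundled as an editable CSV so downstream studies can swap in their own
indicator set without touching code.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterator

from .errors import ValidationError


@dataclass(frozen=True)
class NeedEntry:
    need_id: str
    primary_need: str
    secondary_need: str


@dataclass(frozen=True)
class NeedCatalog:
    """Ordered, duplicate-free list of needs."""

    needs: tuple[NeedEntry, ...]

    def __post_init__(self) -> None:
        ids = [n.need_id for n in self.needs]
        if not ids:
            raise ValidationError("need catalog is empty")
        if len(set(ids)) != len(ids):
            raise ValidationError(f"duplicate need ids in catalog: {ids}")

    @property
    def need_ids(self) -> tuple[str, ...]:
        return tuple(n.need_id for n in self.needs)

    @property
    def primary_needs(self) -> tuple[str, ...]:
        out: list[str] = []
        for n in self.needs:
            if n.primary_need not in out:
                out.append(n.primary_need)
        return tuple(out)

    def __len__(self) -> int:
        return len(self.needs)

    def __iter__(self) -> Iterator[NeedEntry]:
        return iter(self.needs)

    def __getitem__(self, need_id: str) -> NeedEntry:
        for n in self.needs:
            if n.need_id == need_id:
                return n
        raise KeyError(need_id)

    @classmethod
    def from_csv(cls, path: str | Path) -> "NeedCatalog":
        with open(path, newline="", encoding="utf-8") as fh:
            return cls._from_reader(csv.DictReader(fh), source=str(path))

    @classmethod
    def default(cls) -> "NeedCatalog":
        ref = resources.files("kanoneeds.data").joinpath("need_catalog.csv")
        with ref.open(newline="", encoding="utf-8") as fh:
            return cls._from_reader(csv.DictReader(fh), source="bundled catalog")

    @classmethod
    def _from_reader(cls, reader: csv.DictReader, source: str) -> "NeedCatalog":
        required = {"need_id", "primary_need", "secondary_need"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValidationError(
                f"{source}: catalog CSV must have columns {sorted(required)}"
            )
        entries = tuple(
            NeedEntry(row["need_id"].strip(), row["primary_need"].strip(), row["secondary_need"].strip())
            for row in reader
        )
        return cls(entries)


def default_catalog() -> NeedCatalog:
    """The bundled 13-need catalog (cached per call site; cheap to re-read)."""
    return NeedCatalog.default()
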