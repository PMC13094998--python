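"""Shared fixtures: catalog, reference tables, and record builders."""

from __future__ import annotations

import itertools

import pytest

from kanoneeds import (
    DemographicProfile,
    ItemResponse,
    RespondentRecord,
    coefficients,
    default_catalog,
)
from kanoneeds import reference

_DEMO = DemographicProfile(
    region="Sichuan",
    gender="Female",
    age_group="31-50",
    cdc_level="district/county",
    field_of_work="health technology",
    job_position="ordinary",
)

_counter = itertools.count()


def make_record(pairs, respondent_id=None, demographics=_DEMO, need_ids=None):
    """Build a RespondentRecord from {need_id: (pos, neg)} or a single pair
    applied to every catalog need."""
    if need_ids is None:
        need_ids = default_catalog().need_ids
    if isinstance(pairs, tuple):
        pairs = {nid: pairs for nid in need_ids}
    rid = respondent_id or f"T{next(_counter):04d}"
    items = tuple(ItemResponse(nid, p, n) for nid, (p, n) in pairs.items())
    return RespondentRecord(rid, demographics, items)


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def reference_freqs():
    return reference.reference_frequencies()


@pytest.fixture(scope="session")
def reference_coeffs(reference_freqs):
    return [coefficients(f) for f in reference_freqs]


@pytest.fixture
def demo_profile():
    return _DEMO
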