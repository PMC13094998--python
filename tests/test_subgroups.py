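"""Subgroup splits, chi-square comparison, and its brute-force oracle."""

import numpy as np
import pytest

from kanoneeds import (
    AttributeFrequency,
    DegenerateTableError,
    DemographicProfile,
    KanoAttribute,
    ValidationError,
    chi_square_attributes,
    coefficients,
    compare_subgroups,
    split_by,
    subgroup_coefficients,
    tabulate_need,
)

from conftest import make_record

A, O, M, I = (KanoAttribute(s) for s in "AOMI")


def freq(need_id="X", **counts):
    return AttributeFrequency(need_id, {KanoAttribute(k): v for k, v in counts.items()})


def chi2_brute_force(table):
    """Independent Pearson chi-square: literal sum of (obs-exp)^2/exp."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    chi2 = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            exp = table[i].sum() * table[:, j].sum() / total
            chi2 += (table[i, j] - exp) ** 2 / exp
    return chi2


def _demo(**overrides):
    base = dict(
        region="Sichuan",
        gender="Female",
        age_group="31-50",
        cdc_level="district/county",
        field_of_work="health technology",
        job_position="ordinary",
    )
    base.update(overrides)
    return DemographicProfile(**base)


def test_identical_distributions_give_zero_chi2():
    f1 = freq(A=10, O=20, M=30)
    f2 = freq(A=10, O=20, M=30)
    chi2, df, p = chi_square_attributes([f1, f2])
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_textbook_2x2_table():
    # [[10, 20], [20, 10]]: chi2 = 20/3 by hand, df = 1
    f1 = freq(A=10, O=20)
    f2 = freq(A=20, O=10)
    chi2, df, p = chi_square_attributes([f1, f2])
    assert chi2 == pytest.approx(20 / 3, abs=1e-10)
    assert df == 1


def test_chi2_matches_brute_force_oracle():
    rng = np.random.default_rng(42)
    for _ in range(20):
        t = rng.integers(1, 40, size=(2, 6))
        freqs = [
            freq(**dict(zip("AOMIRQ", row.tolist()))) for row in t
        ]
        chi2, df, _ = chi_square_attributes(freqs)
        assert chi2 == pytest.approx(chi2_brute_force(t), abs=1e-10)
        assert df == 5


def test_chi2_symmetric_and_scales_with_n():
    f1, f2 = freq(A=5, O=15, M=10), freq(A=12, O=6, M=9)
    chi2_ab, _, _ = chi_square_attributes([f1, f2])
    chi2_ba, _, _ = chi_square_attributes([f2, f1])
    assert chi2_ab == pytest.approx(chi2_ba, abs=1e-12)
    doubled = [freq(A=10, O=30, M=20), freq(A=24, O=12, M=18)]
    chi2_2x, _, _ = chi_square_attributes(doubled)
    assert chi2_2x == pytest.approx(2 * chi2_ab, abs=1e-9)


def test_target_vs_rest_collapse():
    f1 = freq(M=10, A=10, O=10)
    f2 = freq(M=20, A=5, O=5)
    chi2, df, _ = chi_square_attributes([f1, f2], scheme="target_vs_rest", target=M)
    assert df == 1
    assert chi2 == pytest.approx(chi2_brute_force([[10, 20], [20, 10]]), abs=1e-10)


def test_degenerate_table_raises():
    with pytest.raises(DegenerateTableError):
        chi_square_attributes([freq(A=5), freq(A=7)])  # single non-empty category


def test_unknown_scheme_rejected():
    with pytest.raises(ValidationError):
        chi_square_attributes([freq(A=1, O=1), freq(A=1, O=1)], scheme="bogus")


# --------------------------------------------------------------------------
# subgroup splits
# --------------------------------------------------------------------------

def test_subgroup_coefficients_trivial_groups(catalog):
    sichuan = [make_record((2, 5), demographics=_demo(region="Sichuan")) for _ in range(5)]
    chongqing = [make_record((1, 3), demographics=_demo(region="Chongqing")) for _ in range(5)]
    split = split_by(sichuan + chongqing, "region")
    summaries = {s.group: s for s in subgroup_coefficients(split, "Q1")}
    assert summaries["Sichuan"].coefficients.si == 0.0
    assert summaries["Sichuan"].coefficients.dsi == -1.0
    assert summaries["Sichuan"].attribute is M
    assert summaries["Chongqing"].coefficients.si == 1.0
    assert summaries["Chongqing"].coefficients.dsi == 0.0
    assert summaries["Chongqing"].attribute is A


def test_pooled_groups_equal_full_sample(catalog):
    rng = np.random.default_rng(7)
    records = []
    for i in range(30):
        pos, neg = int(rng.integers(1, 6)), int(rng.integers(1, 6))
        records.append(
            make_record(
                (pos, neg),
                demographics=_demo(gender="Male" if i % 2 else "Female"),
            )
        )
    full = coefficients(tabulate_need(records, "Q3"))
    split = split_by(records, "gender")
    pooled = AttributeFrequency(
        "Q3",
        {
            attr: sum(
                tabulate_need(list(grp), "Q3").counts[attr]
                for grp in split.groups.values()
            )
            for attr in KanoAttribute
        },
    )
    assert coefficients(pooled).si == pytest.approx(full.si)
    assert coefficients(pooled).dsi == pytest.approx(full.dsi)


def test_compare_subgroups_end_to_end(catalog):
    leaders = [make_record((1, 5), demographics=_demo(job_position="leader")) for _ in range(12)]
    workers = [make_record((3, 4), demographics=_demo(job_position="ordinary")) for _ in range(12)]
    comp = compare_subgroups(leaders + workers, "job_position", "Q7")
    assert comp.df == 1  # only O and I columns are non-empty
    assert comp.p < 0.001
    attrs = {s.group: s.attribute for s in comp.summaries}
    assert attrs == {"leader": O, "ordinary": I}


def test_split_requires_demographics(catalog):
    rec = make_record((1, 5), demographics=None)
    with pytest.raises(ValidationError, match="demographics"):
        split_by([rec], "region")
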