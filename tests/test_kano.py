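"""Coefficients, sensitivity, centroid, quadrants and ranking."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kanoneeds import (
    AttributeFrequency,
    Centroid,
    KanoAttribute,
    KanoCoefficients,
    ReconstructionError,
    UndefinedCoefficientError,
    ValidationError,
    assign_quadrant,
    better_coefficient,
    coefficients,
    compute_centroid,
    modal_attribute,
    percentages_to_counts,
    priority_order,
    rank_needs,
    satisfaction_sensitivity,
    tabulate_need,
    worse_coefficient,
)
from kanoneeds import reference

from conftest import make_record

A, O, M, I, R, Q = (KanoAttribute(s) for s in "AOMIRQ")


def freq(need_id="X", **counts):
    return AttributeFrequency(need_id, {KanoAttribute(k): v for k, v in counts.items()})


# --------------------------------------------------------------------------
# tabulation and count reconstruction
# --------------------------------------------------------------------------

def test_tabulate_all_one_dimensional(catalog):
    records = [make_record((1, 5)) for _ in range(110)]
    f = tabulate_need(records, "Q1")
    assert f.counts[O] == 110 and f.n == 110
    assert sum(v for k, v in f.counts.items() if k is not O) == 0


def test_tabulate_matches_hand_tally(catalog):
    # 10 hand-written answer pairs for Q1; tally done by eye against the matrix
    pairs = [(1, 5), (1, 5), (1, 2), (2, 5), (2, 5), (2, 5), (2, 2), (5, 1), (1, 1), (3, 4)]
    records = [make_record({"Q1": p}, need_ids=("Q1",)) for p in pairs]
    f = tabulate_need(records, "Q1")
    assert f.counts == {O: 2, A: 1, M: 3, I: 2, R: 1, Q: 1}


def test_tabulate_missing_need_errors(catalog):
    rec = make_record({"Q1": (1, 5)}, need_ids=("Q1",))
    with pytest.raises(ValidationError, match="Q2"):
        tabulate_need([rec], "Q2")


@pytest.mark.parametrize(
    "need_id, expected",
    [
        ("Q1", {A: 12, I: 8, M: 60, O: 25, Q: 2, R: 3}),
        ("Q8", {A: 12, I: 15, M: 30, O: 48, Q: 2, R: 3}),
    ],
)
def test_percentages_to_counts_reference_rows(need_id, expected):
    counts = percentages_to_counts(reference.ATTRIBUTE_PERCENTAGES[need_id], 110)
    assert counts == expected
    assert sum(counts.values()) == 110


def test_percentages_to_counts_degenerate():
    assert percentages_to_counts({A: 1.0}, 50)[A] == 50


def test_percentages_to_counts_reports_residual():
    with pytest.raises(ReconstructionError, match="residual"):
        percentages_to_counts({A: 0.5, O: 0.4}, 100)  # sums to 90


# --------------------------------------------------------------------------
# coefficients
# --------------------------------------------------------------------------

def test_better_coefficient_q1():
    assert better_coefficient(freq(A=12, O=25, M=60, I=8)) == pytest.approx(37 / 105)


def test_better_coefficient_zero_when_no_positive_mass():
    assert better_coefficient(freq(M=7, I=3)) == 0.0


def test_better_coefficient_q6():
    assert better_coefficient(freq(A=36, O=40, M=20, I=9)) == pytest.approx(76 / 105)


def test_worse_coefficient_q1_and_q8():
    assert worse_coefficient(freq(A=12, O=25, M=60, I=8)) == pytest.approx(-85 / 105)
    assert worse_coefficient(freq(A=12, O=48, M=30, I=15)) == pytest.approx(-78 / 105)


def test_worse_coefficient_zero_without_o_or_m():
    assert worse_coefficient(freq(A=4, I=6)) == 0.0


def test_coefficients_undefined_when_all_reverse_questionable():
    with pytest.raises(UndefinedCoefficientError):
        better_coefficient(freq(R=5, Q=5))


@pytest.mark.parametrize(
    "si, dsi, expected",
    [
        (0.5714, -0.7429, 0.937),
        (0.3524, -0.8095, 0.883),
        (0.0, 0.0, 0.0),
        (1.0, -1.0, math.sqrt(2)),
    ],
)
def test_satisfaction_sensitivity(si, dsi, expected):
    assert satisfaction_sensitivity(si, dsi) == pytest.approx(expected, abs=5e-4)


def test_sensitivity_consistent_with_dataclass():
    c = KanoCoefficients("X", 0.3, -0.4)
    assert c.s == pytest.approx(0.5, abs=1e-12)


# --------------------------------------------------------------------------
# centroid and quadrants
# --------------------------------------------------------------------------

def test_centroid_of_published_pairs_matches_average_row():
    pairs = [
        KanoCoefficients(n, si, dsi)
        for n, (si, dsi) in reference.PUBLISHED_COEFFICIENTS.items()
    ]
    c = compute_centroid(pairs)
    assert c.mean_si == pytest.approx(reference.PUBLISHED_CENTROID[0], abs=5e-4)
    assert c.mean_abs_dsi == pytest.approx(reference.PUBLISHED_CENTROID[1], abs=5e-4)


def test_centroid_of_repeated_pair():
    pairs = [KanoCoefficients("X", 0.3, -0.7)] * 5
    c = compute_centroid(pairs)
    assert (c.mean_si, c.mean_abs_dsi) == (pytest.approx(0.3), pytest.approx(0.7))


def test_centroid_three_hand_pairs():
    pairs = [
        KanoCoefficients("a", 0.2, -0.1),
        KanoCoefficients("b", 0.4, -0.5),
        KanoCoefficients("c", 0.6, -0.9),
    ]
    c = compute_centroid(pairs)
    assert c.mean_si == pytest.approx(0.4)
    assert c.mean_abs_dsi == pytest.approx(0.5)


def test_centroid_requires_two_needs():
    with pytest.raises(ValidationError):
        compute_centroid([KanoCoefficients("a", 0.2, -0.1)])


CENTROID = Centroid(0.482, 0.586)


@pytest.mark.parametrize(
    "si, dsi, expected",
    [
        (0.571, -0.743, "O"),
        (0.352, -0.810, "M"),
        (0.288, -0.298, "I"),
        (0.724, -0.571, "A"),
    ],
)
def test_assign_quadrant_reference_points(si, dsi, expected):
    c = KanoCoefficients("X", si, dsi)
    assert assign_quadrant(c, CENTROID) is KanoAttribute(expected)


def test_assign_quadrant_boundary_counts_high():
    on_centroid = KanoCoefficients("X", 0.482, -0.586)
    assert assign_quadrant(on_centroid, CENTROID) is O


def test_modal_attribute_and_tie_order():
    assert modal_attribute(freq(A=12, I=8, M=60, O=25, Q=2, R=3)) is M
    assert modal_attribute(freq(O=48, M=30, A=12, I=15)) is O
    uniform = freq(A=2, O=2, M=2, I=2, R=2, Q=2)
    assert modal_attribute(uniform) is M  # tie broken M > O > A > I > R > Q


# --------------------------------------------------------------------------
# ranking
# --------------------------------------------------------------------------

def test_rank_needs_reference_orderings(reference_coeffs):
    classified = rank_needs(reference_coeffs)
    by_id = {c.need_id: c for c in classified}
    assert by_id["Q8"].sensitivity_rank == 1
    within_m = sorted(
        (c for c in classified if c.attribute is M),
        key=lambda c: c.within_attribute_rank,
    )
    assert [c.need_id for c in within_m] == ["Q1", "Q11", "Q3", "Q5"]
    ranks = sorted(c.sensitivity_rank for c in classified)
    assert ranks == list(range(1, 14))


def test_rank_ties_broken_by_input_order():
    pairs = [
        KanoCoefficients("first", 0.6, -0.8),
        KanoCoefficients("second", 0.6, -0.8),
        KanoCoefficients("third", 0.1, -0.1),
    ]
    classified = rank_needs(pairs, Centroid(0.4, 0.5))
    by_id = {c.need_id: c for c in classified}
    assert by_id["first"].sensitivity_rank == 1
    assert by_id["second"].sensitivity_rank == 2


def test_priority_order_follows_hierarchy(reference_coeffs):
    classified = rank_needs(reference_coeffs)
    order = priority_order(classified)
    assert order[:4] == ["Q1", "Q11", "Q3", "Q5"]       # must-be block first
    assert order[4:7] == ["Q8", "Q2", "Q12"]            # then one-dimensional
    assert order[7:10] == ["Q6", "Q9", "Q7"]            # then attractive
    assert order[10:] == ["Q13", "Q10", "Q4"]           # indifferent last


# --------------------------------------------------------------------------
# algebraic properties
# --------------------------------------------------------------------------

counts_strategy = st.fixed_dictionaries(
    {attr: st.integers(min_value=0, max_value=60) for attr in "AOMI"}
).filter(lambda d: sum(d.values()) > 0)


@settings(max_examples=60, derandomize=True)
@given(counts=counts_strategy)
def test_si_dsi_decomposition(counts):
    f = freq(**counts)
    total = sum(counts.values())
    lhs = better_coefficient(f) + abs(worse_coefficient(f))
    rhs = (counts["A"] + 2 * counts["O"] + counts["M"]) / total
    assert lhs == pytest.approx(rhs, abs=1e-12)


@settings(max_examples=60, derandomize=True)
@given(counts=counts_strategy)
def test_adding_o_raises_both_adding_i_lowers_both(counts):
    f = freq(**counts)
    plus_o = freq(**{**counts, "O": counts["O"] + 1})
    plus_i = freq(**{**counts, "I": counts["I"] + 1})
    assert better_coefficient(plus_o) >= better_coefficient(f)
    assert abs(worse_coefficient(plus_o)) >= abs(worse_coefficient(f))
    assert better_coefficient(plus_i) <= better_coefficient(f)
    assert abs(worse_coefficient(plus_i)) <= abs(worse_coefficient(f))


@settings(max_examples=60, derandomize=True)
@given(counts=counts_strategy, k=st.integers(min_value=2, max_value=9))
def test_scale_invariance(counts, k):
    f = freq(**counts)
    scaled = freq(**{key: v * k for key, v in counts.items()})
    assert better_coefficient(scaled) == pytest.approx(better_coefficient(f), abs=1e-12)
    assert worse_coefficient(scaled) == pytest.approx(worse_coefficient(f), abs=1e-12)


def test_quadrant_partition(reference_coeffs):
    classified = rank_needs(reference_coeffs)
    labels = [c.attribute for c in classified]
    assert all(label in (M, O, A, I) for label in labels)
    assert len(classified) == len(reference_coeffs)
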