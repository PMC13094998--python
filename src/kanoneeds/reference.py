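"""Published summary tables from the Chengdu-Chongqing grassroots-CDC
collaborative-development needs survey (n = 110 valid of 117 collected).

The survey's raw questionnaires are not public, but its printed per-need
attribute frequency distribution is complete, so every downstream
coefficient follows deterministically from these rows.  They are bundled
as the package's reference dataset: the default profiles of the synthetic
generator, the fixture for regression tests, and the input for the
reproduction script.

``ATTRIBUTE_PERCENTAGES`` holds the printed per-need attribute shares
(fractions), ``PUBLISHED_COEFFICIENTS`` the printed SI/DSI pairs, and
``PUBLISHED_IMPORTANCE`` the printed importance scale (quadrant
attribute, sensitivity S, global sensitivity rank, within-attribute
priority rank).

Known blemish: the printed Q10 coefficients (0.298, -0.362) are not
reproducible from Q10's own printed percentages at n = 110 under any
integer reconstruction (which gives 31/103 = 0.301 and -37/103 = -0.359);
the remaining 12 rows reproduce exactly, and Q10's sensitivity, quadrant
and ranks are unaffected.
"""

from __future__ import annotations

from .kano import AttributeFrequency, percentages_to_counts
from .response import KanoAttribute

_A = KanoAttribute.ATTRACTIVE
_I = KanoAttribute.INDIFFERENT
_M = KanoAttribute.MUST_BE
_O = KanoAttribute.ONE_DIMENSIONAL
_Q = KanoAttribute.QUESTIONABLE
_R = KanoAttribute.REVERSE

#: Valid questionnaires behind the published tables.
SAMPLE_SIZE = 110
#: Questionnaires collected before validity screening.
COLLECTED_SIZE = 117

#: Printed per-need attribute shares, columns (A, I, M, O, Q, R), as fractions.
ATTRIBUTE_PERCENTAGES: dict[str, dict[KanoAttribute, float]] = {
    need: dict(zip((_A, _I, _M, _O, _Q, _R), (v / 100.0 for v in row)))
    for need, row in {
        "Q1": (10.91, 7.27, 54.55, 22.73, 1.82, 2.73),
        "Q2": (9.09, 13.64, 34.55, 38.18, 3.64, 0.91),
        "Q3": (18.18, 10.91, 43.64, 22.73, 2.73, 1.82),
        "Q4": (4.55, 61.82, 5.45, 22.73, 4.55, 0.91),
        "Q5": (16.36, 13.64, 47.27, 18.18, 3.64, 0.91),
        "Q6": (32.73, 8.18, 18.18, 36.36, 2.73, 1.82),
        "Q7": (38.18, 22.73, 11.82, 22.73, 2.73, 1.82),
        "Q8": (10.91, 13.64, 27.27, 43.64, 1.82, 2.73),
        "Q9": (31.82, 18.18, 15.45, 30.00, 2.73, 1.82),
        "Q10": (7.27, 52.73, 12.73, 20.91, 3.63, 2.73),
        "Q11": (16.36, 13.64, 38.18, 27.27, 2.73, 1.82),
        "Q12": (25.45, 9.09, 35.45, 25.45, 2.73, 1.82),
        "Q13": (13.64, 31.82, 18.18, 31.82, 2.73, 1.82),
    }.items()
}

#: Printed better/worse coefficient pairs (SI, DSI).
PUBLISHED_COEFFICIENTS: dict[str, tuple[float, float]] = {
    "Q1": (0.352, -0.810),
    "Q2": (0.495, -0.762),
    "Q3": (0.429, -0.695),
    "Q4": (0.288, -0.298),
    "Q5": (0.362, -0.686),
    "Q6": (0.724, -0.571),
    "Q7": (0.638, -0.362),
    "Q8": (0.571, -0.743),
    "Q9": (0.648, -0.476),
    "Q10": (0.298, -0.362),
    "Q11": (0.457, -0.686),
    "Q12": (0.533, -0.638),
    "Q13": (0.476, -0.524),
}

#: Printed average row: mean SI and mean |DSI| (the quadrant origin).
PUBLISHED_CENTROID = (0.482, 0.586)

#: Printed importance scale: attribute, S, global rank, within-attribute rank.
PUBLISHED_IMPORTANCE: dict[str, tuple[KanoAttribute, float, int, int]] = {
    "Q1": (_M, 0.883, 4, 1),
    "Q11": (_M, 0.824, 6, 2),
    "Q3": (_M, 0.817, 7, 3),
    "Q5": (_M, 0.775, 9, 4),
    "Q8": (_O, 0.937, 1, 1),
    "Q2": (_O, 0.909, 3, 2),
    "Q12": (_O, 0.832, 5, 3),
    "Q6": (_A, 0.922, 2, 1),
    "Q9": (_A, 0.804, 8, 2),
    "Q7": (_A, 0.734, 10, 3),
    "Q13": (_I, 0.708, 11, 1),
    "Q10": (_I, 0.469, 12, 2),
    "Q4": (_I, 0.415, 13, 3),
}

#: Demographic category counts among the 110 valid respondents.
DEMOGRAPHIC_COUNTS: dict[str, dict[str, int]] = {
    "region": {"Sichuan": 49, "Chongqing": 61},
    "gender": {"Male": 44, "Female": 66},
    "age_group": {"<=30": 42, "31-50": 64, ">=51": 4},
    "cdc_level": {"district/county": 85, "municipal+": 25},
    "field_of_work": {"health technology": 90, "administrative logistics": 20},
    "job_position": {"leader": 33, "ordinary": 77},
}


def demographic_marginals() -> dict[str, dict[str, float]]:
    """Demographic category proportions among the valid respondents."""
    return {
        field: {cat: c / SAMPLE_SIZE for cat, c in cats.items()}
        for field, cats in DEMOGRAPHIC_COUNTS.items()
    }


def reference_frequencies() -> list[AttributeFrequency]:
    """Integer attribute counts reconstructed from the printed shares at n = 110.

    Nearest-integer reconstruction; every row sums to 110 exactly.
    """
    return [
        AttributeFrequency(need, percentages_to_counts(pcts, SAMPLE_SIZE))
        for need, pcts in ATTRIBUTE_PERCENTAGES.items()
    ]
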