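# Methods

## Classification model

Each need is judged twice per respondent: a positive (functional) and a
negative (dysfunctional) question, both on the 1–5 Likert scale
(Like / Should be / Does not matter / Can accept / Dislike). The pair is
mapped through the canonical 5×5 Kano matrix (rows = positive answer,
columns = negative answer): row "Like" = [Q, A, A, A, O], rows
"Should be"/"Does not matter"/"Can accept" = [R, I, I, I, M], row
"Dislike" = [R, R, R, R, Q]. The cell multiset {A:3, O:1, M:3, I:9, R:7,
Q:2} is asserted at matrix construction, and loaders never transpose.

## Coefficients and prioritisation

With per-need counts over the six attributes, the Berger better/worse
coefficients use only the four analyzable attributes in the denominator:
SI = (A+O)/(A+O+M+I), DSI = −(O+M)/(A+O+M+I). R and Q are excluded from
the denominators but always reported in frequency outputs. Satisfaction
sensitivity is S = √(SI² + |DSI|²), the distance of the point (SI, |DSI|)
from the origin.

Quadrant classification is defined on the semantics high/low SI × high/low
|DSI| relative to the centroid (mean SI, mean |DSI|), which is invariant
to plotting orientation; the bundled scatter plot draws SI on the y-axis
and |DSI| on the x-axis, the orientation under which the four quadrants
read O (first), A (second), I (third), M (fourth). Points exactly on a
centroid line count as "high" (deterministic; no reference point lies on
the boundary). The global sensitivity rank orders all needs by descending
S; the within-attribute rank restarts inside each quadrant attribute; the
overall priority order is the attribute hierarchy M > O > A > I, then the
within-attribute rank. Ties in S are broken by catalog order — an
explicit convention, since none occur in the reference tables.

All coefficients are computed at full precision; reports show half-up
rounding to 3 dp (coefficients) and 2 dp (percentages), and report files
carry both the rounded and full-precision columns.

## Validity screening

The screening principle (drop logically inconsistent questionnaires and
those with identical positive/negative options) is operationalised as:
exclude a respondent iff (a) any catalog item is missing, (b) positive ==
negative on **all** items (straight-lining), or (c) the fraction of items
classifying to Q exceeds 0.5. A single questionable item never excludes a
questionnaire — real samples retain per-item Q shares of a few percent —
and all three rules are configurable (`ScreeningConfig`). The exact rule
used in the reference study is unpublished; these defaults are a
documented approximation that reproduces its screening arithmetic
(110 valid of 117, 94.02 %).

## Subgroup comparison and psychometrics

Subgroup analysis recomputes the frequency table, SI/DSI and the modal
attribute (tie order M > O > A > I > R > Q) per demographic group and
compares attribute distributions with a Pearson chi-square test
(scipy). Because published analyses rarely state the contingency
construction, the category scheme is configurable: full six-attribute
table (default), R/Q dropped, or one target attribute vs the rest (2×2);
all-zero columns are removed, zero expected counts raise an error
advising collapse, and the Yates correction is off by default. χ² scales
with n (doubling all counts doubles χ²) — this is expected and tested,
not a defect.

Cronbach's α, KMO and Bartlett's sphericity operate on a respondents ×
items score matrix; for a Kano instrument the caller chooses the scoring
(positive codes, negative codes, or concatenation — the package does not
presume which fed a published reliability figure). α uses unbiased
variances; KMO uses anti-image partial correlations from the inverse
correlation matrix (singular matrices and the all-orthogonal 0/0 case are
explicit error paths); Bartlett's χ² = −(n−1−(2k+5)/6)·ln det R with
df = k(k−1)/2. No installed package provides KMO or this sphericity test,
so they are implemented here; α is cross-checked against pingouin in the
test suite.

## Delphi statistics

Kendall's W uses mid-ranks with the ties correction
W = 12S / (m²(n³−n) − mΣTᵢ); a panel in which every expert is fully tied
has zero denominator and returns W = 0 (no agreement signal).
Significance uses χ² = m(n−1)W on n−1 df; for fewer than 8 ranked objects
the result is flagged `small_sample` rather than refused. The expert
authority coefficient follows the standard construction Cr = (Ca + Cs)/2
with the judgment-basis and familiarity components supplied as data (no
hard-coded sub-scales), panel Cr = mean over experts, flagged against the
0.70 high-authority threshold. Indicator revisions between rounds are
bookkeeping (`RoundLedger`: kept/merged/deleted/added with rationale),
not automated decisions.

## Synthetic generator

`StudyDesign` defaults are the reference survey's conditions: 117
questionnaires collected, invalid fraction 7/117, per-need latent
attribute mixtures equal to the published attribute shares (via the exact
integer reconstruction, so each mixture sums to 1 exactly), and
demographic marginals equal to the published strata proportions.
Respondents draw one attribute per need independently, then a Likert pair
uniformly among that attribute's matrix cells (a pluggable choice; no
empirical within-cell response model is available). Demographic fields
are independent (only marginals are published). Invalid records are
straight-line pairs at level 3 ("Does not matter"), which unambiguously
triggers the screening rule. The generator returns the latent attribute
tallies so recovery tests can compare the drawn truth with the
reconstructed classification.

What the generator does **not** emulate: respondent-level correlation
across needs, demographic–response dependence, and any within-attribute
cell preference. Tests passing on synthetic data therefore validate the
computational chain and its sampling behaviour, not these aspects of real
survey data.

## Numerical choices and problem sizes

Coefficient comparisons against 3-dp published values use |Δ| ≤ 5e-4.
The count reconstruction from published percentages is nearest-integer
with an exact sum-to-n check. Test simulations use n in the hundreds
(e.g. attribute-recovery: mixtures with 0.6 dominant mass, n = 200, 200
replicates), sizes at which binomial error is small relative to the
effects tested while the suite stays fast.

## Known limitations

- The published Q10 coefficient pair (0.298, −0.362) is internally
  inconsistent with Q10's own published percentage row at n = 110: no
  integer counts reproduce both values to 3 dp (the reconstruction gives
  0.301, −0.359). Q10's sensitivity still rounds to the published 0.469
  and its quadrant and ranks are unaffected; the regression test for that
  single pair documents the discrepancy rather than masking it.
- Published subgroup χ² values and per-round Kendall's W cannot be
  reproduced without the raw questionnaires and the unstated contingency
  scheme / per-round indicator counts; these stages are validated by
  oracle equivalence and property tests instead.
- The quadrant method assigns every need a label even when its
  coefficients sit near the centroid; no uncertainty on the labels is
  computed.
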