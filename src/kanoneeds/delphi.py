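"""Delphi expert-consultation statistics.

Covers the quantitative side of a Delphi round: Kendall's coefficient of
concordance W (with the mid-rank ties correction) and its chi-square
significance test, the expert authority coefficient Cr = (Ca + Cs)/2
(judgment basis + familiarity, averaged over the panel), and a round
ledger recording which indicators were kept, merged, deleted or added.
The qualitative content of revisions stays with the analyst; the ledger
only checks the bookkeeping is consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError

#: Conventional threshold above which a panel counts as highly authoritative.
HIGH_AUTHORITY_THRESHOLD = 0.70

#: Minimum number of ranked objects for the chi-square approximation to W.
CHI2_APPROX_MIN_N = 8


@dataclass(frozen=True)
class ExpertRatingMatrix:
    """Experts x indicators ordinal score matrix for one consultation round."""

    round_id: str
    ratings: np.ndarray
    expert_ids: tuple[str, ...] = ()
    indicator_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        ratings = np.asarray(self.ratings, dtype=float)
        if ratings.ndim != 2:
            raise ValidationError(f"ratings must be 2-D, got shape {ratings.shape}")
        m, n = ratings.shape
        if m < 2 or n < 2:
            raise ValidationError(f"need >=2 experts and >=2 indicators, got {m} x {n}")
        if np.isnan(ratings).any():
            raise ValidationError("ratings matrix has missing cells")
        object.__setattr__(self, "ratings", ratings)
        if self.expert_ids and len(self.expert_ids) != m:
            raise ValidationError("expert_ids length mismatch")
        if self.indicator_ids and len(self.indicator_ids) != n:
            raise ValidationError("indicator_ids length mismatch")

    @property
    def n_experts(self) -> int:
        return self.ratings.shape[0]

    @property
    def n_indicators(self) -> int:
        return self.ratings.shape[1]


def kendalls_w(ratings: ExpertRatingMatrix | np.ndarray) -> float:
    """Kendall's coefficient of concordance with mid-rank ties correction.

    Each expert's scores are converted to mid-ranks; with rank sums R_j,

        W = 12 S / (m^2 (n^3 - n) - m sum_i T_i),
        S = sum_j (R_j - mean R)^2,
        T_i = sum over tie groups of expert i of (t^3 - t).

    W = 0 means no agreement, W = 1 identical rankings.  A fully tied
    expert row contributes only through its ties term.
    """
    if not isinstance(ratings, ExpertRatingMatrix):
        ratings = ExpertRatingMatrix(round_id="adhoc", ratings=ratings)
    x = ratings.ratings
    m, n = x.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, x)
    rank_sums = ranks.sum(axis=0)
    s = float(((rank_sums - rank_sums.mean()) ** 2).sum())
    ties = 0.0
    for row in x:
        _, counts = np.unique(row, return_counts=True)
        ties += float((counts**3 - counts).sum())
    denom = m**2 * (n**3 - n) - m * ties
    if denom == 0:
        # every expert fully tied: rank sums are all equal, no disagreement signal
        return 0.0
    return 12.0 * s / denom


@dataclass(frozen=True)
class WSignificance:
    chi2: float
    df: int
    p: float
    small_sample: bool


def w_significance(w: float, m: int, n: int) -> WSignificance:
    """Chi-square significance of W: chi2 = m (n - 1) W on n - 1 df.

    The approximation is reliable for n >= 8 ranked objects; smaller n is
    flagged via ``small_sample`` rather than refused.
    """
    if not 0.0 <= w <= 1.0 + 1e-12:
        raise ValidationError(f"W must lie in [0, 1], got {w}")
    if m < 2 or n < 2:
        raise ValidationError("need m >= 2 experts and n >= 2 indicators")
    chi2 = m * (n - 1) * w
    df = n - 1
    return WSignificance(
        chi2=float(chi2),
        df=int(df),
        p=float(stats.chi2.sf(chi2, df)),
        small_sample=n < CHI2_APPROX_MIN_N,
    )


@dataclass(frozen=True)
class AuthorityComponents:
    """One expert's judgment-basis (Ca) and familiarity (Cs) coefficients."""

    expert_id: str
    ca: float
    cs: float

    def __post_init__(self) -> None:
        for name in ("ca", "cs"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{self.expert_id}.{name} = {v} outside [0, 1]")

    @property
    def cr(self) -> float:
        return (self.ca + self.cs) / 2.0


@dataclass(frozen=True)
class PanelAuthority:
    per_expert: dict[str, float]
    panel_cr: float
    high_authority: bool


def authority_coefficient(components: Sequence[AuthorityComponents]) -> PanelAuthority:
    """Per-expert Cr = (Ca + Cs)/2 and the panel mean, flagged against 0.70."""
    if not components:
        raise ValidationError("authority_coefficient: empty panel")
    per_expert = {c.expert_id: c.cr for c in components}
    panel = sum(per_expert.values()) / len(per_expert)
    return PanelAuthority(
        per_expert=per_expert,
        panel_cr=panel,
        high_authority=panel >= HIGH_AUTHORITY_THRESHOLD,
    )


@dataclass(frozen=True)
class RoundLedger:
    """Bookkeeping of indicator revisions between consultation rounds."""

    round_id: str
    before: tuple[str, ...]
    actions: tuple[tuple[str, str, str], ...] = field(default_factory=tuple)
    # each action: (indicator, action in {kept, merged, deleted, added}, rationale)

    _ACTIONS = ("kept", "merged", "deleted", "added")

    def __post_init__(self) -> None:
        for indicator, action, _ in self.actions:
            if action not in self._ACTIONS:
                raise ValidationError(
                    f"round {self.round_id}: unknown action {action!r} for {indicator!r}"
                )
            if action != "added" and indicator not in self.before:
                raise ValidationError(
                    f"round {self.round_id}: action on unknown indicator {indicator!r}"
                )

    @property
    def after(self) -> tuple[str, ...]:
        """Indicator set after the round, derived from before + actions.

        Indicators without an explicit action are kept; 'merged' removes the
        named indicator (the merge target is the surviving or added one).
        """
        removed = {i for i, a, _ in self.actions if a in ("merged", "deleted")}
        added = [i for i, a, _ in self.actions if a == "added"]
        return tuple([i for i in self.before if i not in removed] + added)
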