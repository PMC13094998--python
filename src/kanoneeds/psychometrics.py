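"""Questionnaire adequacy statistics: Cronbach's alpha, the
Kaiser-Meyer-Olkin measure of sampling adequacy, and Bartlett's test of
sphericity.

These operate on a plain respondents x items score matrix.  For a Kano
instrument the default scoring feeds the positive-question Likert codes
(configurable at the call site); the statistics themselves are
scale-agnostic.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .errors import SingularMatrixError, ValidationError


def _as_matrix(item_scores, min_items: int = 2, min_rows: int = 2) -> np.ndarray:
    x = np.asarray(item_scores, dtype=float)
    if x.ndim != 2:
        raise ValidationError(f"expected a 2-D respondents x items matrix, got shape {x.shape}")
    n, k = x.shape
    if k < min_items or n < min_rows:
        raise ValidationError(
            f"need at least {min_rows} respondents and {min_items} items, got {n} x {k}"
        )
    if np.isnan(x).any():
        raise ValidationError("score matrix contains missing values")
    return x


def cronbach_alpha(item_scores) -> float:
    """Internal-consistency reliability.

    alpha = k/(k-1) * (1 - sum of item variances / variance of row totals),
    with unbiased (ddof=1) variances.  Undefined when the total score has
    zero variance.
    """
    x = _as_matrix(item_scores)
    k = x.shape[1]
    item_var = x.var(axis=0, ddof=1).sum()
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValidationError("total score has zero variance; alpha undefined")
    return k / (k - 1) * (1.0 - item_var / total_var)


def _correlation(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValidationError("an item has zero variance; remove it first")
    return np.corrcoef(x, rowvar=False)


def kmo_measure(item_scores) -> float:
    """Kaiser-Meyer-Olkin sampling adequacy.

    KMO = sum r^2 / (sum r^2 + sum q^2) over off-diagonal entries, where q
    are the anti-image partial correlations obtained from the inverse
    correlation matrix.  Values near 1 indicate that partial correlations
    are small and the items share common factors.
    """
    x = _as_matrix(item_scores, min_items=2)
    r = _correlation(x)
    try:
        r_inv = np.linalg.inv(r)
    except np.linalg.LinAlgError as exc:
        raise SingularMatrixError(
            "correlation matrix is singular; remove collinear items"
        ) from exc
    d = np.sqrt(np.outer(np.diag(r_inv), np.diag(r_inv)))
    partial = -r_inv / d
    off = ~np.eye(r.shape[0], dtype=bool)
    sum_r2 = float((r[off] ** 2).sum())
    sum_q2 = float((partial[off] ** 2).sum())
    if sum_r2 + sum_q2 == 0:
        raise ValidationError(
            "all off-diagonal correlations are zero; KMO undefined (0/0)"
        )
    return sum_r2 / (sum_r2 + sum_q2)


def bartlett_sphericity(item_scores) -> tuple[float, int, float]:
    """Bartlett's test that the correlation matrix is the identity.

    chi2 = -(n - 1 - (2k + 5)/6) * ln det(R), df = k(k-1)/2; returns
    (chi2, df, p).  Requires n > k and a positive-definite R.
    """
    x = _as_matrix(item_scores)
    n, k = x.shape
    if n <= k:
        raise ValidationError(f"need more respondents ({n}) than items ({k})")
    r = _correlation(x)
    sign, logdet = np.linalg.slogdet(r)
    if sign <= 0:
        raise SingularMatrixError("correlation matrix is not positive definite")
    chi2 = -(n - 1 - (2 * k + 5) / 6.0) * logdet
    df = k * (k - 1) // 2
    p = float(stats.chi2.sf(chi2, df))
    return float(chi2), int(df), p
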