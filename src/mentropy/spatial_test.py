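"""Chi-square goodness-of-fit test for spatial correlation on a CpG segment.

Under the null of no spatial correlation the pattern distribution factorizes
into per-site Bernoulli terms; plugging the per-site methylation levels into
that product form gives expected pattern counts E_i = m * q_i, and the
Pearson statistic

    chi2 = sum_i (O_i - E_i)**2 / E_i

is referred to a chi-square distribution with 2**k - 1 - k degrees of
freedom, k being the number of sites whose estimated methylation level lies
strictly inside (0, 1) (one df is lost per estimated marginal).  Degenerate
sites carry no information about correlation and are dropped; a segment
with fewer than two informative sites is reported untestable, never an
error.

The structured variant tests against a *specified* correlation (e.g.
exchangeable r = 0.7) by replacing the product-form null with the
latent-Gaussian pattern distribution at that correlation; r is fixed by the
hypothesis, not estimated, so the degrees of freedom are unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import reduce

import numpy as np
from scipy.special import chdtrc

from .corr_bernoulli import BernoulliParams, ReadMatrix, pattern_distribution

__all__ = [
    "GofResult",
    "expected_counts_independent",
    "chi_square_spatial_test",
    "chi_square_structured_test",
]


@dataclass(frozen=True)
class GofResult:
    """Outcome of the goodness-of-fit test for spatial correlation."""

    observed: np.ndarray
    expected: np.ndarray
    statistic: float
    df: int
    p_value: float
    k: int
    testable: bool
    min_expected: float
    alpha: float = 0.05
    reason: str | None = None

    @property
    def significant(self) -> bool:
        return self.testable and self.p_value < self.alpha


def _pattern_counts(x: np.ndarray) -> np.ndarray:
    n = x.shape[1]
    weights = 1 << np.arange(n - 1, -1, -1)
    return np.bincount(x @ weights, minlength=2 ** n).astype(float)


def _product_q(phat: np.ndarray) -> np.ndarray:
    return reduce(np.kron, [np.array([1.0 - p, p]) for p in phat])


def expected_counts_independent(reads: ReadMatrix) -> np.ndarray:
    """Expected pattern counts E_i = m * q_i under independence, with the
    per-site methylation levels plugged into the product form."""
    phat = reads.x.mean(axis=0)
    return reads.m * _product_q(phat)


def _untestable(x: np.ndarray, m: int, keep: np.ndarray, alpha: float,
                reason: str) -> GofResult:
    k = int(keep.sum())
    sub = x[:, keep] if k else np.zeros((m, 0), dtype=np.int8)
    O = _pattern_counts(sub) if k else np.array([float(m)])
    E = m * _product_q(sub.mean(axis=0)) if k else np.array([float(m)])
    return GofResult(
        observed=O, expected=E, statistic=float("nan"), df=max(0, 2 ** k - 1 - k),
        p_value=float("nan"), k=k, testable=False,
        min_expected=float(E.min()), alpha=alpha, reason=reason,
    )


def _gof(O: np.ndarray, E: np.ndarray, k: int, alpha: float) -> GofResult:
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(E > 0.0, (O - E) ** 2 / np.where(E > 0.0, E, 1.0), 0.0)
        stat = float(terms.sum())
        if np.any((E == 0.0) & (O > 0.0)):
            stat = float("inf")
    df = 2 ** k - 1 - k
    p = float(chdtrc(df, stat)) if df > 0 else 1.0
    return GofResult(
        observed=O, expected=E, statistic=stat, df=df, p_value=p, k=k,
        testable=True, min_expected=float(E.min()), alpha=alpha,
    )


def chi_square_spatial_test(reads: ReadMatrix, alpha: float = 0.05) -> GofResult:
    """Pearson chi-square test of H0: no spatial correlation (R = I)."""
    x, m = reads.x, reads.m
    phat = x.mean(axis=0)
    keep = (phat > 0.0) & (phat < 1.0)
    k = int(keep.sum())
    if k < 2:
        return _untestable(x, m, keep, alpha,
                           "fewer than two non-degenerate sites")
    sub = x[:, keep]
    O = _pattern_counts(sub)
    E = m * _product_q(phat[keep])
    return _gof(O, E, k, alpha)


def chi_square_structured_test(reads: ReadMatrix, structure: str, r: float,
                               alpha: float = 0.05) -> GofResult:
    """Chi-square test of H0: spatial correlation follows the given
    structure ('exchangeable' or 'ar1') at the specified r.

    Expected counts come from the latent-Gaussian pattern distribution at
    the plug-in marginals; infeasible r for those marginals yields an
    untestable result carrying the reason.
    """
    if structure not in ("exchangeable", "ar1"):
        raise ValueError(f"unknown correlation structure {structure!r}")
    x, m = reads.x, reads.m
    phat = x.mean(axis=0)
    keep = (phat > 0.0) & (phat < 1.0)
    k = int(keep.sum())
    if k < 2:
        return _untestable(x, m, keep, alpha,
                           "fewer than two non-degenerate sites")
    n = x.shape[1]
    idx = np.arange(n)
    if structure == "exchangeable":
        R = np.full((n, n), float(r))
    else:  # AR(1) distances keep the original site indexing
        R = float(r) ** np.abs(idx[:, None] - idx[None, :])
    np.fill_diagonal(R, 1.0)
    sel = np.flatnonzero(keep)
    try:
        params = BernoulliParams(phat[sel], R[np.ix_(sel, sel)])
        q = pattern_distribution(params).q
    except ValueError as exc:
        return _untestable(x, m, keep, alpha, f"infeasible null: {exc}")
    sub = x[:, keep]
    O = _pattern_counts(sub)
    E = m * q
    return _gof(O, E, k, alpha)
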