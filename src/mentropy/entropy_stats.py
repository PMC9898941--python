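"""Methylation entropy and its sample statistics.

Parameter side: the methylation entropy (ME) of an n-CpG segment is the
Shannon entropy, in bits, of the joint distribution of the 2**n methylation
patterns,

    S = -sum_i q_i log2(q_i),        0 * log 0 := 0,

which under independent sites reduces to a sum of per-site binary entropies
and, for homogeneous p, to ``-n [(1-p) log2(1-p) + p log2 p]``.

Statistic side: the observed methylation entropy (OME) is the plug-in
entropy of the empirical pattern frequencies O_i / m among m reads; the
per-site methylation level (ML) is the column mean of the read matrix and
the mean methylation level (MML) its grand mean.
"""

from __future__ import annotations

import numpy as np

from .corr_bernoulli import (
    BernoulliParams,
    PatternDistribution,
    ReadMatrix,
    pattern_distribution,
)

__all__ = [
    "methylation_entropy",
    "me_independent",
    "observed_me",
    "methylation_levels",
    "me_exchangeable",
    "me_curve",
    "DEFAULT_P_GRID",
]

#: Default methylation-probability grid for entropy curves: fine enough for
#: smooth curves while keeping p strictly inside (0, 1).
DEFAULT_P_GRID = np.round(np.arange(0.005, 0.9951, 0.005), 10)


def _plugin_entropy(weights: np.ndarray) -> float:
    w = np.asarray(weights, dtype=float)
    w = w[w > 0.0]
    return float(-(w * np.log2(w)).sum())


def methylation_entropy(dist: PatternDistribution) -> float:
    """Shannon entropy of a methylation-pattern distribution, in bits."""
    return _plugin_entropy(dist.q)


def me_independent(p) -> float:
    """ME of independent CpG sites: the sum of per-site binary entropies."""
    p = np.atleast_1d(np.asarray(p, dtype=float))
    if np.any((p < 0.0) | (p > 1.0)):
        raise ValueError("methylation probabilities must lie in [0, 1]")
    total = 0.0
    for pi in p:
        total += _plugin_entropy([1.0 - pi, pi])
    return total


def observed_me(reads: ReadMatrix) -> float:
    """Plug-in entropy of the observed pattern frequencies, in bits."""
    counts = reads.pattern_counts()
    return _plugin_entropy(counts / reads.m)


def methylation_levels(reads: ReadMatrix) -> tuple[np.ndarray, float]:
    """Per-site methylation levels (column means) and their grand mean."""
    ml = reads.x.mean(axis=0)
    return ml, float(ml.mean())


# -- theoretical ME-vs-MP curves under exchangeable correlation -------------

_me_cache: dict[tuple[int, float, float], float] = {}


def me_exchangeable(n: int, p: float, r: float) -> float:
    """ME of a homogeneous n-CpG segment with exchangeable correlation r.

    r = 0 uses the independent-sites closed form; r = 1 collapses to the
    binary entropy of p (all sites move together); intermediate r goes
    through the latent-Gaussian pattern distribution.  Degenerate p gives 0.
    """
    if not 0.0 <= r <= 1.0:
        raise ValueError("exchangeable correlation must lie in [0, 1]")
    if not 0.0 <= p <= 1.0:
        raise ValueError("methylation probability must lie in [0, 1]")
    if p in (0.0, 1.0):
        return 0.0
    key = (n, round(float(p), 12), round(float(r), 12))
    if key not in _me_cache:
        if r == 0.0:
            val = me_independent(np.full(n, p))
        elif r == 1.0:
            val = _plugin_entropy([1.0 - p, p])
        else:
            dist = pattern_distribution(BernoulliParams.exchangeable(p, r, n))
            val = methylation_entropy(dist)
        _me_cache[key] = val
    return _me_cache[key]


def me_curve(n: int, r: float, p_grid=None) -> np.ndarray:
    """Theoretical ME-vs-MP curve: array of (p, S) rows.

    Evaluated under homogeneous methylation and exchangeable correlation r;
    at r = 0 this is the independent-sites closed form, and the curve is
    symmetric about p = 0.5 where it is maximized.
    """
    grid = DEFAULT_P_GRID if p_grid is None else np.asarray(p_grid, dtype=float)
    return np.array([[p, me_exchangeable(n, float(p), r)] for p in grid])
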