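"""Bipolar methylated locus classification and two-sample comparisons.

A segment is a *bipolar methylated locus* when its reads concentrate on the
all-methylated and all-unmethylated patterns: the mean methylation level is
non-extreme (inside an (0.2, 0.8) window by default) while the observed
methylation entropy falls below the theoretical entropy of a strongly
co-methylated segment (exchangeable correlation r_threshold, 0.6 by
default) at that methylation level.  Low entropy at intermediate
methylation is the signature of allele- or cell-type-specific methylation
in a mixed cell population.

Differentially methylated regions (DMRs) between two samples are called by
a Pearson chi-square (1 df, no continuity correction) on methylated vs.
unmethylated call counts pooled over all sites and reads of the segment,
and the association between bipolar loci and DMRs is quantified with
Fisher's exact test (two-sided) and the conditional-MLE odds ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import chdtrc
from scipy.stats import fisher_exact
from scipy.stats.contingency import odds_ratio as _scipy_odds_ratio

from .entropy_stats import me_exchangeable

__all__ = [
    "BipolarCriteria",
    "ContingencyTable2x2",
    "FisherResult",
    "DmrResult",
    "classify_bipolar",
    "dmr_test",
    "fisher_exact_2x2",
    "association_analysis",
]


@dataclass(frozen=True)
class BipolarCriteria:
    """Thresholds of the bipolar classification."""

    mml_low: float = 0.2
    mml_high: float = 0.8
    r_threshold: float = 0.6
    n: int = 4
    require_spatial_significance: bool = False  # strict mode
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.mml_low < self.mml_high <= 1.0:
            raise ValueError("need 0 <= mml_low < mml_high <= 1")
        if not 0.0 <= self.r_threshold <= 1.0:
            raise ValueError("r_threshold must lie in [0, 1]")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Cell counts of a 2x2 table; rows index the first condition."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table total must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass(frozen=True)
class FisherResult:
    """Two-sided Fisher exact p-value and conditional-MLE odds ratio.

    The odds ratio may be 0 or ``inf`` when a margin cell is empty."""

    p_two_sided: float
    odds_ratio: float


@dataclass(frozen=True)
class DmrResult:
    """Two-sample methylation comparison on pooled per-call counts."""

    statistic: float
    p_value: float
    degenerate: bool
    table: ContingencyTable2x2

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def classify_bipolar(stats=None, criteria: BipolarCriteria | None = None, *,
                     mml: float | None = None, ome: float | None = None,
                     chi2_p: float | None = None) -> bool:
    """Bipolar flag: non-extreme MML and OME below the r_threshold entropy
    curve evaluated at the segment's MML.

    Accepts either a SegmentStats-like object (with ``mml``, ``ome`` and
    optionally ``chi2_p`` attributes) or explicit ``mml=``/``ome=`` values.
    In strict mode the spatial test must additionally reject independence.
    """
    criteria = criteria or BipolarCriteria()
    if stats is not None:
        mml = stats.mml
        ome = stats.ome
        chi2_p = getattr(stats, "chi2_p", chi2_p)
    if mml is None or ome is None:
        raise ValueError("need a stats record or explicit mml= and ome=")
    if not criteria.mml_low < mml < criteria.mml_high:
        return False
    if ome >= me_exchangeable(criteria.n, mml, criteria.r_threshold):
        return False
    if criteria.require_spatial_significance:
        if chi2_p is None or not chi2_p < criteria.alpha:
            return False
    return True


def dmr_test(segment_a, segment_b) -> DmrResult:
    """DMR chi-square between two samples of the same segment.

    Pools methylated/unmethylated call counts over all n sites and all
    reads of each sample into a 2x2 table and applies the Pearson
    chi-square with 1 df, no continuity correction.  A zero margin (e.g.
    both samples fully methylated) gives p = 1, flagged degenerate.
    """
    counts = []
    for seg in (segment_a, segment_b):
        x = seg.reads.x if hasattr(seg, "reads") else seg.x
        meth = int(x.sum())
        counts.append((meth, x.size - meth))
    (a, b), (c, d) = counts
    table = ContingencyTable2x2(a, b, c, d)
    n_total = a + b + c + d
    margins = ((a + b), (c + d), (a + c), (b + d))
    if min(margins) == 0:
        return DmrResult(statistic=0.0, p_value=1.0, degenerate=True,
                         table=table)
    stat = n_total * (a * d - b * c) ** 2 / np.prod(
        [float(mgn) for mgn in margins]
    )
    return DmrResult(statistic=float(stat), p_value=float(chdtrc(1, stat)),
                     degenerate=False, table=table)


def fisher_exact_2x2(table: ContingencyTable2x2) -> FisherResult:
    """Fisher's exact test (two-sided, probability-mass definition) with
    the conditional maximum-likelihood odds ratio."""
    arr = table.as_array()
    p = float(fisher_exact(arr, alternative="two-sided")[1])
    or_cmle = float(_scipy_odds_ratio(arr, kind="conditional").statistic)
    return FisherResult(p_two_sided=min(p, 1.0), odds_ratio=or_cmle)


def association_analysis(flags_a, flags_b) -> tuple[ContingencyTable2x2,
                                                    FisherResult]:
    """Cross-tabulate two per-segment flag vectors and test association.

    ``flags_a`` and ``flags_b`` must be aligned on the same segment list.
    The table rows index ``flags_b`` (yes first) and the columns
    ``flags_a`` (yes first): with ``flags_a`` = bipolar and ``flags_b`` =
    DMR the cells read [[bipolar&DMR, non-bipolar&DMR],
    [bipolar&non-DMR, non-bipolar&non-DMR]].
    """
    fa = np.asarray(flags_a, dtype=bool)
    fb = np.asarray(flags_b, dtype=bool)
    if fa.shape != fb.shape:
        raise ValueError(
            f"flag vectors must align: {fa.shape} vs {fb.shape}"
        )
    table = ContingencyTable2x2(
        a=int((fa & fb).sum()), b=int((~fa & fb).sum()),
        c=int((fa & ~fb).sum()), d=int((~fa & ~fb).sum()),
    )
    return table, fisher_exact_2x2(table)
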