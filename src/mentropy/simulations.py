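"""Simulation studies and synthetic data generation.

Two studies validate the spatial-correlation machinery:

* **Type-I error / power of the chi-square test.**  A hypothetical n-CpG
  segment (n = 2, 3, 4) is covered by m = 20..100 reads.  Under the null
  each site's methylation probability is drawn fresh per replicate from
  Unif(0.3, 0.7) (nonhomogeneous) and reads are independent Bernoulli;
  under the alternative reads come from the correlated Bernoulli sampler
  with exchangeable or AR(1) correlation at r = 0.3 or 0.4.  10,000 null /
  1,000 alternative replicates per cell.

* **OME vs. MML.**  500 hypothetical 4-CpG segments with homogeneous
  p ~ Unif(0, 1) and exchangeable r ~ Unif(0, 1), 10% of segments having no
  spatial correlation; reads are drawn independently at each depth in
  {20, 40, 60, 80, 100} and the per-segment MML, OME, and spatial-test
  p-value recorded.

A two-sample generator plants cell-type-specific methylation: "signal"
segments are nearly fully methylated in sample A and nearly unmethylated in
sample B, so the pooled reads form a bipolar locus and the two samples a
DMR; "null" segments methylate independently at p = 0.5 in both samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .corr_bernoulli import BernoulliParams, ReadMatrix, sample_reads
from .entropy_stats import methylation_levels, observed_me
from .segments_io import ReadRecord
from .spatial_test import chi_square_spatial_test

__all__ = [
    "Sim1Config",
    "Sim2Config",
    "simulate_type1",
    "simulate_power",
    "simulate_ome_mml",
    "significant_counts",
    "simulate_two_sample_reads",
]


@dataclass(frozen=True)
class Sim1Config:
    """Study conditions for the spatial-test calibration/power simulation."""

    n_values: tuple[int, ...] = (2, 3, 4)
    m_values: tuple[int, ...] = (20, 40, 60, 80, 100)
    structure: str = "independent"   # 'independent' | 'exchangeable' | 'ar1'
    r: float | None = None           # basic correlation for power runs
    replicates: int | None = None    # default: 10,000 null / 1,000 power
    mp_low: float = 0.3
    mp_high: float = 0.7
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.mp_low < self.mp_high < 1.0:
            raise ValueError("need 0 < mp_low < mp_high < 1")
        if self.replicates is not None and self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass(frozen=True)
class Sim2Config:
    """Study conditions for the OME-vs-MML simulation."""

    n_segments: int = 500
    n: int = 4
    frac_null: float = 0.1
    m_values: tuple[int, ...] = (20, 40, 60, 80, 100)
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_null <= 1.0:
            raise ValueError("frac_null must lie in [0, 1]")
        if self.n_segments < 1:
            raise ValueError("n_segments must be >= 1")


def _cell_rng(seed: int, *cell) -> np.random.Generator:
    """Per-cell generator: the master seed plus the cell coordinates feed a
    SeedSequence, so every cell is independently reproducible."""
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF,
                                                         *map(int, cell)]))


def simulate_type1(config: Sim1Config) -> pd.DataFrame:
    """Empirical type-I error of the spatial test by (n, m).

    Each replicate draws per-site methylation probabilities from
    Unif(mp_low, mp_high), samples m independent Bernoulli reads, and
    records rejection at level alpha (untestable replicates count as
    non-rejections).  Returns a DataFrame indexed by n with m columns.
    """
    if config.structure != "independent":
        raise ValueError("type-I simulation runs under independent sites")
    reps = config.replicates or 10_000
    table = pd.DataFrame(index=pd.Index(config.n_values, name="n"),
                         columns=pd.Index(config.m_values, name="m"),
                         dtype=float)
    for n in config.n_values:
        for m in config.m_values:
            rng = _cell_rng(config.seed, 1, n, m)
            rejections = 0
            for _ in range(reps):
                p = rng.uniform(config.mp_low, config.mp_high, size=n)
                x = (rng.random((m, n)) < p).astype(np.int8)
                res = chi_square_spatial_test(ReadMatrix(x), alpha=config.alpha)
                rejections += res.significant
            table.loc[n, m] = rejections / reps
    table.attrs["config"] = config
    return table


def _draw_feasible_params(rng: np.random.Generator, n: int, structure: str,
                          r: float, mp_low: float, mp_high: float,
                          max_tries: int = 100) -> BernoulliParams:
    ctor = (BernoulliParams.exchangeable if structure == "exchangeable"
            else BernoulliParams.ar1)
    for _ in range(max_tries):
        p = rng.uniform(mp_low, mp_high, size=n)
        try:
            return ctor(p, r)
        except ValueError:
            continue  # infeasible (p, r) draw; re-draw the MP vector
    raise RuntimeError(
        f"no feasible MP vector for {structure} r={r} in {max_tries} draws"
    )


def simulate_power(config: Sim1Config) -> pd.DataFrame:
    """Empirical power of the spatial test by (n, m) for the configured
    correlation structure and basic correlation r."""
    if config.structure not in ("exchangeable", "ar1"):
        raise ValueError("power simulation needs structure exchangeable|ar1")
    if config.r is None:
        raise ValueError("power simulation needs the basic correlation r")
    reps = config.replicates or 1_000
    sid = 2 if config.structure == "exchangeable" else 3
    table = pd.DataFrame(index=pd.Index(config.n_values, name="n"),
                         columns=pd.Index(config.m_values, name="m"),
                         dtype=float)
    for n in config.n_values:
        for m in config.m_values:
            rng = _cell_rng(config.seed, sid, int(round(config.r * 1000)), n, m)
            rejections = 0
            for _ in range(reps):
                params = _draw_feasible_params(
                    rng, n, config.structure, config.r,
                    config.mp_low, config.mp_high,
                )
                reads = sample_reads(params, m, rng)
                res = chi_square_spatial_test(reads, alpha=config.alpha)
                rejections += res.significant
            table.loc[n, m] = rejections / reps
    table.attrs["config"] = config
    return table


def simulate_ome_mml(config: Sim2Config) -> pd.DataFrame:
    """Per-segment OME/MML records of the scatter simulation.

    Each segment draws one homogeneous p ~ Unif(0, 1); correlated segments
    draw an exchangeable r ~ Unif(0, 1) while the null fraction keeps
    r = 0.  Reads are redrawn independently at every depth in m_values.
    Returns one row per (segment, m) with the true parameters, MML, OME,
    and the spatial-test outcome.
    """
    rng = _cell_rng(config.seed, 4)
    n_null = int(round(config.frac_null * config.n_segments))
    rows = []
    for seg in range(config.n_segments):
        null = seg < n_null
        p = float(rng.uniform())
        r = 0.0 if null else float(rng.uniform())
        params = (BernoulliParams.independent(p, config.n) if r == 0.0
                  else BernoulliParams.exchangeable(p, r, config.n))
        for m in config.m_values:
            reads = sample_reads(params, m, rng)
            _, mml = methylation_levels(reads)
            ome = observed_me(reads)
            res = chi_square_spatial_test(reads, alpha=config.alpha)
            rows.append({
                "segment": seg, "true_p": p, "true_r": r, "null": null,
                "m": m, "mml": mml, "ome": ome,
                "p_value": res.p_value, "testable": res.testable,
                "significant": res.significant,
            })
    df = pd.DataFrame(rows)
    df.attrs["config"] = config
    return df


def significant_counts(records: pd.DataFrame,
                       correlated_only: bool = True) -> pd.Series:
    """Number of segments with a significant spatial test at each depth
    (by default among the truly correlated segments only)."""
    sub = records[~records["null"]] if correlated_only else records
    return sub.groupby("m")["significant"].sum().astype(int)


# ---------------------------------------------------------------------------
# Two-sample synthetic data with planted bipolar/DMR structure
# ---------------------------------------------------------------------------

def simulate_two_sample_reads(
    n_signal: int = 40,
    n_null: int = 40,
    m_per_sample: int = 100,
    n_sites: int = 4,
    signal_high: float = 0.98,
    null_p: float = 0.5,
    site_spacing: int = 10,
    segment_gap: int = 500,
    chrom: str = "chrSim",
    seed: int = 0,
) -> tuple[list[ReadRecord], list[ReadRecord], pd.DataFrame]:
    """Synthetic two-sample methylation calls with planted structure.

    Signal segments emulate cell-type-specific methylation: sample A reads
    methylate each site at ``signal_high`` and sample B at
    ``1 - signal_high``, so pooling the samples yields a bipolar locus and
    comparing them a DMR.  Null segments methylate independently at
    ``null_p`` in both samples.  Every read covers all ``n_sites`` sites of
    its segment; segments are separated by ``segment_gap`` bases so windows
    never straddle two segments.

    Returns (records_a, records_b, truth) where ``truth`` has one row per
    segment with its first-site coordinate (0-based) and planted flag.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 5]))
    records_a: list[ReadRecord] = []
    records_b: list[ReadRecord] = []
    truth_rows = []
    for seg in range(n_signal + n_null):
        signal = seg < n_signal
        first = 1000 + seg * segment_gap
        sites = tuple(first + j * site_spacing for j in range(n_sites))
        p_a = signal_high if signal else null_p
        p_b = (1.0 - signal_high) if signal else null_p
        for sample, p, bucket in (("A", p_a, records_a), ("B", p_b, records_b)):
            states = (rng.random((m_per_sample, n_sites)) < p).astype(int)
            for i in range(m_per_sample):
                bucket.append(ReadRecord(
                    read_id=f"seg{seg}_{sample}_{i}",
                    chrom=chrom,
                    sites=sites,
                    states=tuple(int(v) for v in states[i]),
                ))
        truth_rows.append({"segment": seg, "chrom": chrom, "start": first,
                           "planted": signal})
    return records_a, records_b, pd.DataFrame(truth_rows)
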