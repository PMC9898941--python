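"""Read-level methylation call I/O and CpG-segment extraction.

Input is a per-read TSV ("epiread-like") dialect with columns

    read_id  chrom  positions  states

where ``positions`` is a comma-separated, strictly ascending list of
1-based CpG cytosine positions on the forward strand and ``states`` is a
same-length string over {0, 1}.  Lines starting with '#' are comments.
Coordinates are 0-based internally and in BED output (half-open).

Segments are windows of n consecutive distinct CpG coordinates; a read
contributes to a window only if it covers every site in it, and a window is
emitted only when at least ``min_depth`` reads fully cover it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, TextIO

from .bipolar_pipeline import BipolarCriteria, classify_bipolar
from .corr_bernoulli import ReadMatrix
from .entropy_stats import me_exchangeable, methylation_levels, observed_me
from .spatial_test import chi_square_spatial_test

import numpy as np

__all__ = [
    "ReadRecord",
    "Segment",
    "SegmentStats",
    "read_methylation_calls",
    "extract_segments",
    "segment_statistics",
    "write_segment_stats",
    "read_segment_stats",
    "write_bipolar_bed",
]

STATS_COLUMNS = (
    "chrom", "start", "end", "n_sites", "depth", "site_ml", "mml", "ome",
    "chi2_stat", "chi2_df", "chi2_p", "testable", "threshold_entropy",
    "bipolar",
)


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read's methylation calls (0-based site coordinates)."""

    read_id: str
    chrom: str
    sites: tuple[int, ...]
    states: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sites) != len(self.states):
            raise ValueError("sites and states must have equal length")
        if any(b - a <= 0 for a, b in zip(self.sites, self.sites[1:])):
            raise ValueError("site coordinates must be strictly increasing")
        if any(s not in (0, 1) for s in self.states):
            raise ValueError("states must be 0/1")


@dataclass(frozen=True)
class Segment:
    """An n-CpG window together with the reads fully covering it."""

    chrom: str
    sites: tuple[int, ...]
    reads: ReadMatrix

    @property
    def n(self) -> int:
        return len(self.sites)

    @property
    def depth(self) -> int:
        return self.reads.m


@dataclass(frozen=True)
class SegmentStats:
    """Per-segment summary statistics.

    ``start``/``end`` are 0-based half-open and span the first to the last
    CpG dinucleotide, including both bases of the terminal CpG (a window
    with 1-based cytosines 101 and 110 spans [100, 111))."""

    chrom: str
    start: int
    end: int
    n_sites: int
    depth: int
    site_ml: tuple[float, ...]
    mml: float
    ome: float
    chi2_stat: float
    chi2_df: int
    chi2_p: float
    testable: bool
    threshold_entropy: float
    bipolar: bool


def read_methylation_calls(path_or_handle) -> Iterator[ReadRecord]:
    """Stream ReadRecords from a per-read TSV file (path or open handle).

    1-based input positions become 0-based.  Malformed lines raise
    ``ValueError`` naming the line number; '#' comments and blank lines are
    skipped.
    """
    if isinstance(path_or_handle, (str, bytes)) or hasattr(path_or_handle, "__fspath__"):
        handle: TextIO = open(path_or_handle)
        close = True
    else:
        handle = path_or_handle
        close = False
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(
                    f"line {lineno}: expected 4 tab-separated fields, "
                    f"got {len(fields)}"
                )
            read_id, chrom, pos_str, states_str = fields
            try:
                sites1 = tuple(int(p) for p in pos_str.split(","))
            except ValueError:
                raise ValueError(f"line {lineno}: unparsable positions {pos_str!r}")
            if len(states_str) != len(sites1):
                raise ValueError(
                    f"line {lineno}: {len(sites1)} positions but "
                    f"{len(states_str)} states"
                )
            if any(c not in "01" for c in states_str):
                raise ValueError(
                    f"line {lineno}: non-binary state character in "
                    f"{states_str!r}"
                )
            if any(b <= a for a, b in zip(sites1, sites1[1:])):
                raise ValueError(f"line {lineno}: positions not ascending")
            if any(p < 1 for p in sites1):
                raise ValueError(f"line {lineno}: positions must be >= 1")
            yield ReadRecord(
                read_id=read_id,
                chrom=chrom,
                sites=tuple(p - 1 for p in sites1),
                states=tuple(int(c) for c in states_str),
            )
    finally:
        if close:
            handle.close()


def extract_segments(records: Iterable[ReadRecord], n: int = 4,
                     min_depth: int = 20, mode: str = "sliding") -> list[Segment]:
    """Extract n-CpG segments fully covered at the depth threshold.

    Windows advance over the sorted distinct CpG coordinates of each
    chromosome: step 1 in 'sliding' mode, step n in 'disjoint' mode.  A read
    joins a window only when its site set contains every window coordinate.
    Output order is deterministic (chrom, then start), independent of input
    read order.
    """
    if mode not in ("sliding", "disjoint"):
        raise ValueError(f"unknown extraction mode {mode!r}")
    by_chrom: dict[str, list[ReadRecord]] = {}
    for rec in records:
        by_chrom.setdefault(rec.chrom, []).append(rec)
    segments: list[Segment] = []
    step = 1 if mode == "sliding" else n
    for chrom in sorted(by_chrom):
        recs = by_chrom[chrom]
        coords = sorted({s for rec in recs for s in rec.sites})
        lookups = [dict(zip(rec.sites, rec.states)) for rec in recs]
        # stable read order for reproducible matrices regardless of input order
        order = sorted(range(len(recs)),
                       key=lambda i: (recs[i].sites, recs[i].read_id,
                                      recs[i].states))
        for start_idx in range(0, max(0, len(coords) - n + 1), step):
            window = coords[start_idx:start_idx + n]
            if len(window) < n:
                break
            rows = [
                [lookups[i][c] for c in window]
                for i in order
                if all(c in lookups[i] for c in window)
            ]
            if len(rows) >= min_depth:
                segments.append(Segment(
                    chrom=chrom,
                    sites=tuple(window),
                    reads=ReadMatrix(np.array(rows, dtype=np.int8),
                                     sites=tuple(window), chrom=chrom),
                ))
    return segments


def segment_statistics(segment: Segment, r_threshold: float = 0.6,
                       mml_window: tuple[float, float] = (0.2, 0.8)) -> SegmentStats:
    """Compose MML/OME, the spatial test, the theoretical entropy threshold
    at the segment's MML, and the bipolar classification into one record."""
    ml, mml = methylation_levels(segment.reads)
    ome = observed_me(segment.reads)
    gof = chi_square_spatial_test(segment.reads)
    threshold = me_exchangeable(segment.n, mml, r_threshold)
    criteria = BipolarCriteria(mml_low=mml_window[0], mml_high=mml_window[1],
                               r_threshold=r_threshold, n=segment.n)
    return SegmentStats(
        chrom=segment.chrom,
        start=segment.sites[0],
        end=segment.sites[-1] + 2,  # through the G of the terminal CpG
        n_sites=segment.n,
        depth=segment.depth,
        site_ml=tuple(float(v) for v in ml),
        mml=mml,
        ome=ome,
        chi2_stat=gof.statistic,
        chi2_df=gof.df,
        chi2_p=gof.p_value,
        testable=gof.testable,
        threshold_entropy=threshold,
        bipolar=classify_bipolar(mml=mml, ome=ome, criteria=criteria),
    )


def _fmt(value: float) -> str:
    return f"{value:.6g}"


def write_segment_stats(stats: Iterable[SegmentStats], path_or_handle) -> None:
    """Write segment statistics as TSV with a fixed column order.

    Floats use 6 significant digits so identical input yields byte-identical
    output.
    """
    rows = [_stats_row(s) for s in stats]
    text = "\t".join(STATS_COLUMNS) + "\n" + "".join(rows)
    _write_text(path_or_handle, text)


def _stats_row(s: SegmentStats) -> str:
    fields = [
        s.chrom, str(s.start), str(s.end), str(s.n_sites), str(s.depth),
        ",".join(_fmt(v) for v in s.site_ml), _fmt(s.mml), _fmt(s.ome),
        _fmt(s.chi2_stat), str(s.chi2_df), _fmt(s.chi2_p),
        "1" if s.testable else "0", _fmt(s.threshold_entropy),
        "1" if s.bipolar else "0",
    ]
    return "\t".join(fields) + "\n"


def read_segment_stats(path_or_handle) -> list[SegmentStats]:
    """Read back a segment-stats TSV written by ``write_segment_stats``."""
    text = _read_text(path_or_handle)
    lines = text.splitlines()
    if not lines or lines[0].split("\t") != list(STATS_COLUMNS):
        raise ValueError("not a segment-stats TSV (bad header)")
    out = []
    for line in lines[1:]:
        f = line.split("\t")
        out.append(SegmentStats(
            chrom=f[0], start=int(f[1]), end=int(f[2]), n_sites=int(f[3]),
            depth=int(f[4]), site_ml=tuple(float(v) for v in f[5].split(",")),
            mml=float(f[6]), ome=float(f[7]), chi2_stat=float(f[8]),
            chi2_df=int(f[9]), chi2_p=float(f[10]), testable=f[11] == "1",
            threshold_entropy=float(f[12]), bipolar=f[13] == "1",
        ))
    return out


def write_bipolar_bed(stats: Iterable[SegmentStats], path_or_handle) -> None:
    """BED6 of bipolar loci: 0-based half-open span of the window's CpGs,
    name 'bipolar', score = round(1000 * (1 - OME / n))."""
    lines = []
    for s in stats:
        if not s.bipolar:
            continue
        score = int(round(1000 * (1.0 - s.ome / s.n_sites)))
        lines.append(
            f"{s.chrom}\t{s.start}\t{s.end}\tbipolar\t{score}\t.\n"
        )
    _write_text(path_or_handle, "".join(lines))


def _write_text(path_or_handle, text: str) -> None:
    if isinstance(path_or_handle, (str, bytes)) or hasattr(path_or_handle, "__fspath__"):
        with open(path_or_handle, "w") as fh:
            fh.write(text)
    else:
        path_or_handle.write(text)


def _read_text(path_or_handle) -> str:
    if isinstance(path_or_handle, (str, bytes)) or hasattr(path_or_handle, "__fspath__"):
        with open(path_or_handle) as fh:
            return fh.read()
    return path_or_handle.read()
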