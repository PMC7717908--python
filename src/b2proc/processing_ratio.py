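"""Per-sample B2 RNA processing ratio and group comparison.

The processing ratio contrasts the abundance of processed B2 fragments
(short-RNA-seq 5' ends in the element window 95-110, normalized to tRNA
reads and short-library depth) with the abundance of full-length B2
transcripts (long-RNA-seq reads over B2 loci, normalized to long-library
depth):

    ratio = [ F / (T / Ns) ] / [ B / Nl ]          (literal mode)

with F = fragment-window 5' ends, T = tRNA-window short reads, Ns / Nl the
short / long library sizes, B = long reads over B2 loci. The literal form
scales with Ns, so a depth-invariant variant is also provided:

    ratio = ( F / T ) / ( B / Nl )                 (trna_relative mode)

Cross-depth comparisons should prefer ``trna_relative``; cohorts sequenced
at equal depths are ordered identically by both modes.
"""

from __future__ import annotations

import json
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .core import (
    DEFAULT_WINDOW,
    GenomicInterval,
    ReadAlignment,
    RepeatLocus,
    SampleEntry,
    SampleManifest,
    logger,
)
from . import annotations_io
from .metagene import FivePrimeEvent, extract_events

FRAGMENT_WINDOW = (95, 110)  # element positions, 1-based inclusive
TRNA_WINDOW = (-5, 15)  # offsets from the tRNA start, 0 = first base


class InsufficientNormalizerError(ValueError):
    """A normalizer count (tRNA reads or full-length B2 reads) is zero."""


@dataclass(frozen=True, slots=True)
class ProcessingCounts:
    """The five counts entering the processing-ratio formula."""

    F: int  # short-read 5' ends in the fragment window
    T: int  # short reads at tRNA loci
    Ns: int  # short-library total reads
    B: int  # long reads overlapping B2 loci
    Nl: int  # long-library total reads

    def __post_init__(self) -> None:
        for name in ("F", "T", "Ns", "B", "Nl"):
            if getattr(self, name) < 0:
                raise ValueError(f"count {name} must be non-negative")
        if self.F > self.Ns:
            logger.warning(
                "fragment count F=%d exceeds short-library size Ns=%d", self.F, self.Ns
            )


@dataclass(frozen=True, slots=True)
class ProcessingRatioResult:
    sample_id: str
    counts: ProcessingCounts
    ratio: float
    mode: str


@dataclass(frozen=True, slots=True)
class GroupComparison:
    groups: tuple[str, str]
    means: tuple[float, float]
    sds: tuple[float, float]
    n: tuple[int, int]
    t: float
    df: float
    p: float
    sided: str
    variance: str

    def to_json(self, path) -> None:
        with open(path, "wt") as fh:
            json.dump(
                {
                    "groups": list(self.groups),
                    "means": list(self.means),
                    "sds": list(self.sds),
                    "n": list(self.n),
                    "t": self.t,
                    "df": self.df,
                    "p": self.p,
                    "sided": self.sided,
                    "variance": self.variance,
                },
                fh,
                indent=2,
            )


def count_fragment_window(
    events: Iterable[FivePrimeEvent],
    lo: int = FRAGMENT_WINDOW[0],
    hi: int = FRAGMENT_WINDOW[1],
) -> int:
    """Count 5'-end events inside the processed-fragment window (inclusive)."""
    if lo > hi:
        raise ValueError("fragment window requires lo <= hi")
    return sum(1 for ev in events if lo <= ev.position <= hi)


def count_trna_short_reads(
    alignments: Iterable[ReadAlignment],
    trna_loci: Sequence[GenomicInterval],
    lo: int = TRNA_WINDOW[0],
    hi: int = TRNA_WINDOW[1],
) -> int:
    """Count primary short reads whose 5' base starts at a tRNA locus.

    A read is counted once when its 5' base falls within [lo, hi] of any
    tRNA start, offsets measured in the tRNA's own orientation (0 = first
    annotated base).
    """
    # genomic windows per (chrom): the offset window mapped through strand
    windows: dict[str, list[tuple[int, int]]] = {}
    for t in trna_loci:
        if t.strand == "+":
            g_lo, g_hi = t.start + lo, t.start + hi
        elif t.strand == "-":
            g_lo, g_hi = t.end - 1 - hi, t.end - 1 - lo
        else:
            raise ValueError("tRNA loci must be stranded")
        windows.setdefault(t.chrom, []).append((g_lo, g_hi))
    for spans in windows.values():
        spans.sort()
    starts = {c: [s for s, _ in spans] for c, spans in windows.items()}

    n = 0
    for aln in alignments:
        if not aln.is_primary:
            continue
        spans = windows.get(aln.interval.chrom)
        if not spans:
            continue
        g5 = aln.five_prime
        i = bisect_right(starts[aln.interval.chrom], g5)
        # every window has length hi-lo, so only windows starting within
        # that distance upstream of g5 can contain it
        hit = False
        width = hi - lo
        for s, e in reversed(spans[:i]):
            if s < g5 - width:
                break
            if s <= g5 <= e:
                hit = True
                break
        if hit:
            n += 1
    return n


def count_long_full_length(
    long_alignments: Iterable[ReadAlignment],
    loci: Sequence[RepeatLocus],
) -> int:
    """Count distinct primary long reads overlapping >=1 B2 locus by >=1 bp.

    A read spanning multiple loci counts once (deduplicated; a per-locus
    sum would double-count tandem copies).
    """
    by_chrom: dict[str, tuple[list[int], list[int]]] = {}
    buckets: dict[str, list[tuple[int, int]]] = {}
    for loc in loci:
        buckets.setdefault(loc.interval.chrom, []).append(
            (loc.interval.start, loc.interval.end)
        )
    max_len = {c: max(e - s for s, e in v) for c, v in buckets.items()}
    for c, spans in buckets.items():
        spans.sort()
        by_chrom[c] = ([s for s, _ in spans], [e for _, e in spans])

    counted: set[str] = set()
    n = 0
    for aln in long_alignments:
        if not aln.is_primary or aln.read_id in counted:
            continue
        entry = by_chrom.get(aln.interval.chrom)
        if entry is None:
            continue
        starts, ends = entry
        lo = bisect_left(starts, aln.interval.start - max_len[aln.interval.chrom])
        hi = bisect_right(starts, aln.interval.end)
        if any(
            starts[i] < aln.interval.end and aln.interval.start < ends[i]
            for i in range(lo, hi)
        ):
            counted.add(aln.read_id)
            n += 1
    return n


def compute_ratio(
    counts: ProcessingCounts,
    mode: str = "literal",
    sample_id: str = "",
) -> ProcessingRatioResult:
    """Evaluate the processing-ratio formula on the five counts."""
    if mode not in ("literal", "trna_relative"):
        raise ValueError(f"unknown ratio mode {mode!r}")
    for name in ("T", "B"):
        if getattr(counts, name) == 0:
            raise InsufficientNormalizerError(
                f"cannot form a processing ratio: normalizer count {name} is zero"
            )
    if counts.Ns <= 0 or counts.Nl <= 0:
        raise ValueError("library sizes Ns and Nl must be positive")
    if mode == "literal":
        ratio = (counts.F / (counts.T / counts.Ns)) / (counts.B / counts.Nl)
    else:
        ratio = (counts.F / counts.T) / (counts.B / counts.Nl)
    return ProcessingRatioResult(sample_id, counts, ratio, mode)


def compute_sample_counts(
    short_alignments: Iterable[ReadAlignment],
    long_alignments: Iterable[ReadAlignment],
    loci: Sequence[RepeatLocus],
    trna_loci: Sequence[GenomicInterval],
    Ns: int,
    Nl: int,
    W: int = DEFAULT_WINDOW,
    fragment_window: tuple[int, int] = FRAGMENT_WINDOW,
    trna_window: tuple[int, int] = TRNA_WINDOW,
    sample_id: str = "",
) -> ProcessingCounts:
    """Derive the five ratio counts from in-memory alignment streams."""
    short_alignments = list(short_alignments)
    events = extract_events(short_alignments, loci, W=W, sample_id=sample_id)
    F = count_fragment_window(events, *fragment_window)
    T = count_trna_short_reads(short_alignments, trna_loci, *trna_window)
    B = count_long_full_length(long_alignments, loci)
    counts = ProcessingCounts(F=F, T=T, Ns=Ns, B=B, Nl=Nl)
    logger.info(
        "sample %s counts: F=%d T=%d Ns=%d B=%d Nl=%d",
        sample_id or "<unnamed>",
        F,
        T,
        Ns,
        B,
        Nl,
    )
    return counts


def compute_sample(
    sample: SampleEntry,
    loci: Sequence[RepeatLocus],
    trna_loci: Sequence[GenomicInterval],
    W: int = DEFAULT_WINDOW,
    fragment_window: tuple[int, int] = FRAGMENT_WINDOW,
    trna_window: tuple[int, int] = TRNA_WINDOW,
    mode: str = "literal",
) -> ProcessingRatioResult:
    """Full per-sample pipeline from manifest paths to a ratio."""
    short = list(annotations_io.read_alignments(sample.short_path, "short"))
    long_alns = annotations_io.read_alignments(sample.long_path, "long")
    counts = compute_sample_counts(
        short,
        long_alns,
        loci,
        trna_loci,
        Ns=sample.short_library_size,
        Nl=sample.long_library_size,
        W=W,
        fragment_window=fragment_window,
        trna_window=trna_window,
        sample_id=sample.sample_id,
    )
    return compute_ratio(counts, mode=mode, sample_id=sample.sample_id)


def results_to_tsv(results: Sequence[ProcessingRatioResult], path) -> None:
    with open(path, "wt") as fh:
        fh.write("sample_id\tF\tT\tNs\tB\tNl\tmode\tratio\n")
        for r in results:
            c = r.counts
            fh.write(
                f"{r.sample_id}\t{c.F}\t{c.T}\t{c.Ns}\t{c.B}\t{c.Nl}\t{r.mode}\t{r.ratio:.10g}\n"
            )


def compare_groups(
    results: Sequence[ProcessingRatioResult],
    manifest: SampleManifest,
    sided: str = "two",
    variance: str = "pooled",
    group_order: tuple[str, str] | None = None,
) -> GroupComparison:
    """Unpaired t-test on per-sample ratios between two groups.

    ``sided='greater'`` tests whether the first group of ``group_order``
    exceeds the second. Default variance model is Student pooled; Welch is
    available.
    """
    if sided not in ("two", "greater", "less"):
        raise ValueError(f"unknown sidedness {sided!r}")
    if variance not in ("pooled", "welch"):
        raise ValueError(f"unknown variance model {variance!r}")
    group_of = {s.sample_id: s.group for s in manifest}
    by_group: dict[str, list[float]] = {}
    for r in results:
        if r.sample_id not in group_of:
            raise ValueError(f"sample {r.sample_id} not in manifest")
        by_group.setdefault(group_of[r.sample_id], []).append(r.ratio)
    if len(by_group) != 2:
        raise ValueError(f"exactly two groups required, got {sorted(by_group)}")
    if group_order is None:
        group_order = tuple(sorted(by_group))
    g1, g2 = group_order
    a = np.asarray(by_group[g1], dtype=float)
    b = np.asarray(by_group[g2], dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2 for an unpaired t-test")
    alternative = {"two": "two-sided", "greater": "greater", "less": "less"}[sided]
    res = stats.ttest_ind(a, b, equal_var=(variance == "pooled"), alternative=alternative)
    if variance == "pooled":
        df = float(len(a) + len(b) - 2)
    else:
        df = float(res.df)
    return GroupComparison(
        groups=(g1, g2),
        means=(float(a.mean()), float(b.mean())),
        sds=(float(a.std(ddof=1)), float(b.std(ddof=1))),
        n=(len(a), len(b)),
        t=float(res.statistic),
        df=df,
        p=float(res.pvalue),
        sided=sided,
        variance=variance,
    )
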