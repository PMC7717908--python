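"""5'-end fragment metagene over repeat loci.

Short-read alignments are converted into element-relative 5'-end events:
every repeat copy is anchored at its element start (position +1, strand
aware) and the position of each fragment's first transcribed base is
expressed in element coordinates. Aggregating events over all copies gives
the metagene profile whose peaks are the RNA processing points.

Positions are element-start offsets, not consensus-corrected: per-copy
indels are ignored, which matches a metagene built over genomic element
starts and is documented as an approximation.
"""

from __future__ import annotations

import json
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .core import DEFAULT_WINDOW, ReadAlignment, RepeatLocus


@dataclass(frozen=True, slots=True)
class FivePrimeEvent:
    """One fragment 5' end in element coordinates (1-based, +1 = start)."""

    locus_id: str
    position: int
    sample_id: str = ""


@dataclass
class MetageneProfile:
    """Aggregated 5'-end counts over positions +1..W.

    ``normalization`` is one of ``raw`` (event tallies), ``unit`` (sums to
    one) or ``per_million`` (scaled by the short-library size).
    """

    counts: np.ndarray
    n_events: int
    normalization: str = "raw"
    W: int = DEFAULT_WINDOW

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (self.W,):
            raise ValueError("counts must have one entry per position 1..W")

    def count_at(self, position: int) -> float:
        return float(self.counts[position - 1])

    def to_tsv(self, path) -> None:
        with open(path, "wt") as fh:
            fh.write("position\tcount\n")
            for p in range(1, self.W + 1):
                fh.write(f"{p}\t{self.counts[p - 1]:.10g}\n")

    def to_json(self, path) -> None:
        with open(path, "wt") as fh:
            json.dump(
                {
                    "W": self.W,
                    "n_events": self.n_events,
                    "normalization": self.normalization,
                    "counts": self.counts.tolist(),
                },
                fh,
            )


@dataclass(frozen=True, slots=True)
class KSResult:
    """Two-sample Kolmogorov-Smirnov comparison of positional distributions.

    D is the supremum ECDF difference and is the primary quantity; with tied
    integer positions the asymptotic p-value is approximate.
    """

    D: float
    p: float
    n1: int
    n2: int


@dataclass
class ProcessingPointSet:
    """Called processing points (peak positions) of a metagene profile."""

    positions: list[int]
    scores: list[float]

    def __post_init__(self) -> None:
        if sorted(self.positions) != list(self.positions):
            raise ValueError("positions must be sorted")


def five_prime_position(
    aln: ReadAlignment,
    locus: RepeatLocus,
    W: int = DEFAULT_WINDOW,
    sense_only: bool = True,
) -> int | None:
    """Element-relative 1-based position of a read's 5' base, or None.

    Returns None for antisense reads (directional protocol; override with
    ``sense_only=False``) and for 5' bases outside positions +1..W in
    element orientation. Reads whose 5' base lies upstream of +1 are
    discarded, not clamped.
    """
    if sense_only and aln.strand != locus.interval.strand:
        return None
    g5 = aln.five_prime
    if locus.interval.strand == "+":
        pos = g5 - locus.interval.start + 1
    else:
        pos = locus.interval.end - g5
    if 1 <= pos <= W:
        return pos
    return None


class _LocusIndex:
    """Per-strand sorted index of loci for nearest-element-start lookup."""

    def __init__(self, loci: Sequence[RepeatLocus], W: int):
        self.W = W
        self._index: dict[tuple[str, str], tuple[list[int], list[RepeatLocus]]] = {}
        buckets: dict[tuple[str, str], list[tuple[int, RepeatLocus]]] = {}
        for loc in loci:
            key = (loc.interval.strand, loc.interval.chrom)
            buckets.setdefault(key, []).append((loc.element_start, loc))
        for key, pairs in buckets.items():
            pairs.sort(key=lambda t: (t[0], t[1].locus_id))
            self._index[key] = ([p[0] for p in pairs], [p[1] for p in pairs])
        # maximum genomic reach of a window from an element start
        self._reach = W

    def candidates(self, aln: ReadAlignment) -> list[RepeatLocus]:
        entry = self._index.get((aln.strand, aln.interval.chrom))
        if entry is None:
            return []
        starts, loci = entry
        g5 = aln.five_prime
        lo = bisect_left(starts, g5 - self._reach)
        hi = bisect_right(starts, g5 + self._reach)
        out = []
        for loc in loci[lo:hi]:
            if not loc.interval.overlaps(aln.interval):
                continue
            if five_prime_position(aln, loc, self.W) is not None:
                out.append(loc)
        return out


def extract_events(
    alignments: Iterable[ReadAlignment],
    loci: Sequence[RepeatLocus],
    W: int = DEFAULT_WINDOW,
    sample_id: str = "",
    sense_only: bool = True,
) -> list[FivePrimeEvent]:
    """Convert primary short-read alignments into 5'-end events.

    Each primary read contributes at most one event: if it overlaps several
    loci it is assigned to the locus whose element start is nearest its 5'
    base (ties broken by lexicographically smallest locus id).
    """
    if W < 1:
        raise ValueError("window width W must be >= 1")
    index = _LocusIndex(loci, W)
    events: list[FivePrimeEvent] = []
    for aln in alignments:
        if not aln.is_primary:
            continue
        if sense_only:
            cands = index.candidates(aln)
        else:
            cands = [
                loc
                for loc in loci
                if loc.interval.chrom == aln.interval.chrom
                and loc.interval.overlaps(aln.interval)
                and five_prime_position(aln, loc, W, sense_only=False) is not None
            ]
        if not cands:
            continue
        g5 = aln.five_prime
        best = min(cands, key=lambda loc: (abs(loc.element_start - g5), loc.locus_id))
        pos = five_prime_position(aln, best, W, sense_only=sense_only)
        events.append(FivePrimeEvent(best.locus_id, pos, sample_id))
    return events


def build_profile(
    events: Iterable[FivePrimeEvent],
    W: int = DEFAULT_WINDOW,
    normalization: str = "raw",
    Ns: int | None = None,
) -> MetageneProfile:
    """Tally events into a metagene profile with the requested scaling."""
    if normalization not in ("raw", "unit", "per_million"):
        raise ValueError(f"unknown normalization {normalization!r}")
    if normalization == "per_million" and Ns is None:
        raise ValueError("per_million normalization requires the library size Ns")
    counts = np.zeros(W, dtype=float)
    n = 0
    for ev in events:
        if not 1 <= ev.position <= W:
            raise ValueError(f"event position {ev.position} outside 1..{W}")
        counts[ev.position - 1] += 1
        n += 1
    if normalization == "unit" and n > 0:
        counts /= n
    elif normalization == "per_million":
        counts *= 1e6 / Ns
    return MetageneProfile(counts, n_events=n, normalization=normalization, W=W)


def compare_profiles(
    a_events: Sequence[FivePrimeEvent], b_events: Sequence[FivePrimeEvent]
) -> KSResult:
    """Two-sample KS test on the raw element-position samples."""
    a = np.array([e.position for e in a_events])
    b = np.array([e.position for e in b_events])
    if a.size == 0 or b.size == 0:
        raise ValueError("both event samples must be non-empty for a KS test")
    res = stats.ks_2samp(a, b, method="asymp")
    return KSResult(float(res.statistic), float(min(res.pvalue, 1.0)), a.size, b.size)


def call_processing_points(
    profile: MetageneProfile,
    min_frac: float = 0.1,
    flank: int = 2,
) -> ProcessingPointSet:
    """Call peaks of the 5'-end profile as processing points.

    A position qualifies when it is maximal within +-``flank`` (window
    clipped at the edges) and reaches ``min_frac`` of the profile maximum.
    Runs of equal-count qualifying neighbours (plateaus) report only their
    smallest position.
    """
    if profile.normalization not in ("raw", "unit"):
        raise ValueError("processing points are called on raw or unit profiles")
    c = profile.counts
    m = float(c.max(initial=0.0))
    if m <= 0:
        return ProcessingPointSet([], [])
    qual = []
    for i in range(profile.W):
        lo, hi = max(0, i - flank), min(profile.W, i + flank + 1)
        if c[i] >= c[lo:hi].max() and c[i] >= min_frac * m:
            qual.append(i)
    positions: list[int] = []
    scores: list[float] = []
    prev = None
    for i in qual:
        if prev is not None and i == prev + 1 and c[i] == c[prev]:
            prev = i  # continuation of a plateau already reported
            continue
        positions.append(i + 1)
        scores.append(float(c[i]))
        prev = i
    return ProcessingPointSet(positions, scores)


def diff_processing_points(
    a: ProcessingPointSet,
    b: ProcessingPointSet,
    tol: int = 1,
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Match two point sets within a positional tolerance.

    Pairs within ``tol`` are matched greedily nearest-first; returns
    (shared pairs, unmatched in a, unmatched in b).
    """
    pairs = sorted(
        ((abs(pa - pb), pa, pb) for pa in a.positions for pb in b.positions if abs(pa - pb) <= tol),
    )
    used_a: set[int] = set()
    used_b: set[int] = set()
    shared: list[tuple[int, int]] = []
    for _, pa, pb in pairs:
        if pa in used_a or pb in used_b:
            continue
        shared.append((pa, pb))
        used_a.add(pa)
        used_b.add(pb)
    only_a = [p for p in a.positions if p not in used_a]
    only_b = [p for p in b.positions if p not in used_b]
    shared.sort()
    return shared, only_a, only_b


def events_to_bed(events: Iterable[FivePrimeEvent], loci: Sequence[RepeatLocus], path) -> None:
    """Export events as 1-bp BED6 intervals at the genomic 5' base."""
    by_id = {loc.locus_id: loc for loc in loci}
    with open(path, "wt") as fh:
        for ev in events:
            loc = by_id[ev.locus_id]
            iv = loc.interval
            if iv.strand == "+":
                g = iv.start + ev.position - 1
            else:
                g = iv.end - ev.position
            fh.write(f"{iv.chrom}\t{g}\t{g + 1}\t{ev.locus_id}\t0\t{iv.strand}\n")
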