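"""Expression-vs-processing-ratio correlation and peak-TSS profiling.

For every gene, the Pearson correlation between its expression across
samples and the per-sample B2 RNA processing ratio is computed; genes are
excluded when not expressed in every sample or when the correlation is not
significant (two-sided p from the t transform, n-2 df). Classified genes
are binned by signed r: strong (r >= 0.5), weak (0.25 <= r < 0.5), none
(r < 0.25) — negative correlations fall in the "none" bin by construction.

No multiple-testing correction is applied to the per-gene significance
filter by default; Benjamini-Hochberg FDR is available via ``fdr=True``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import ExpressionTable, GeneSet, GenomicInterval, logger
from .metagene import KSResult

STRONG_THRESHOLD = 0.5
WEAK_THRESHOLD = 0.25
ALPHA = 0.05


@dataclass(frozen=True, slots=True)
class GeneCorrelation:
    gene: str
    r: float
    p: float
    n: int
    status: str  # classified | excluded_low_expression | excluded_nonsignificant

    @property
    def correlation_class(self) -> str | None:
        """strong / weak / none for classified genes, else None."""
        if self.status != "classified":
            return None
        return classify_r(self.r)


def classify_r(
    r: float, strong: float = STRONG_THRESHOLD, weak: float = WEAK_THRESHOLD
) -> str:
    if r >= strong:
        return "strong"
    if r >= weak:
        return "weak"
    return "none"


@dataclass
class CorrelationClassSummary:
    n_strong: int
    n_weak: int
    n_none: int
    n_excluded: int
    pct_strong: float
    pct_weak: float
    pct_none: float
    thresholds: tuple[float, float] = (STRONG_THRESHOLD, WEAK_THRESHOLD)
    alpha: float = ALPHA

    @property
    def n_classified(self) -> int:
        return self.n_strong + self.n_weak + self.n_none

    def to_json(self, path) -> None:
        with open(path, "wt") as fh:
            json.dump(self.__dict__ | {"n_classified": self.n_classified}, fh, indent=2)


def correlate_gene(
    expression_row: Sequence[float],
    ratios: Sequence[float],
    gene: str = "",
    min_expr: float = 0.0,
    alpha: float = ALPHA,
) -> GeneCorrelation:
    """Pearson correlation of one gene's expression with the processing ratio.

    Genes with any sample at or below ``min_expr`` are excluded as not
    sufficiently expressed; zero-variance vectors are excluded with a logged
    reason since r is undefined for them.
    """
    x = np.asarray(expression_row, dtype=float)
    y = np.asarray(ratios, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"gene {gene}: expression and ratio vectors differ in length")
    n = x.size
    if n < 3:
        raise ValueError("at least 3 samples are required for a correlation")
    if (x <= min_expr).any():
        return GeneCorrelation(gene, math.nan, math.nan, n, "excluded_low_expression")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.info("gene %s: zero variance, correlation undefined; excluded", gene)
        return GeneCorrelation(gene, math.nan, math.nan, n, "excluded_low_expression")
    res = stats.pearsonr(x, y)
    r, p = float(res.statistic), float(res.pvalue)
    status = "classified" if p <= alpha else "excluded_nonsignificant"
    return GeneCorrelation(gene, r, p, n, status)


def correlate_table(
    expression: ExpressionTable,
    ratios_by_sample: dict[str, float],
    min_expr: float = 0.0,
    alpha: float = ALPHA,
    fdr: bool = False,
) -> list[GeneCorrelation]:
    """Correlate every gene of an expression table against sample ratios."""
    samples = [s for s in expression.samples if s in ratios_by_sample]
    missing = set(expression.samples) - set(samples)
    if missing:
        logger.warning("samples without a ratio are dropped: %s", sorted(missing))
    y = np.array([ratios_by_sample[s] for s in samples])
    sub = expression.values[samples]
    out = [
        correlate_gene(sub.loc[g].to_numpy(), y, gene=g, min_expr=min_expr, alpha=alpha)
        for g in expression.genes
    ]
    if fdr:
        testable = [c for c in out if not math.isnan(c.p)]
        if testable:
            rej, qvals, *_ = multipletests([c.p for c in testable], alpha=alpha, method="fdr_bh")
            adjusted = {}
            for c, q, keep in zip(testable, qvals, rej):
                status = "classified" if keep else "excluded_nonsignificant"
                adjusted[c.gene] = GeneCorrelation(c.gene, c.r, float(q), c.n, status)
            out = [adjusted.get(c.gene, c) for c in out]
    return out


def classify_correlations(
    correlations: Iterable[GeneCorrelation],
    strong: float = STRONG_THRESHOLD,
    weak: float = WEAK_THRESHOLD,
) -> CorrelationClassSummary:
    """Bin classified genes by correlation strength and report percentages.

    Percentages are over classified genes only, rounded conventionally to
    one decimal in exports. An all-excluded input yields NaN percentages.
    """
    if not (0 < weak < strong <= 1):
        raise ValueError("thresholds must satisfy 0 < weak < strong <= 1")
    n_strong = n_weak = n_none = n_excl = 0
    for c in correlations:
        if c.status != "classified":
            n_excl += 1
        else:
            cls = classify_r(c.r, strong, weak)
            if cls == "strong":
                n_strong += 1
            elif cls == "weak":
                n_weak += 1
            else:
                n_none += 1
    total = n_strong + n_weak + n_none
    if total == 0:
        logger.warning("no classified genes; percentages undefined")
        pcts = (math.nan, math.nan, math.nan)
    else:
        pcts = tuple(100.0 * k / total for k in (n_strong, n_weak, n_none))
    return CorrelationClassSummary(
        n_strong, n_weak, n_none, n_excl, pcts[0], pcts[1], pcts[2], (strong, weak)
    )


def correlations_to_tsv(correlations: Sequence[GeneCorrelation], path) -> None:
    rows = [
        {
            "gene": c.gene,
            "r": c.r,
            "p": c.p,
            "n": c.n,
            "status": c.status,
            "class": c.correlation_class or "",
        }
        for c in correlations
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def overlap_gene_sets(a: GeneSet, b: GeneSet) -> tuple[int, list[str]]:
    """Exact intersection of two gene sets, case-normalized symbols."""
    ia = {m.upper() for m in a.members}
    ib = {m.upper() for m in b.members}
    common = sorted(ia & ib)
    return len(common), common


@dataclass
class PeakTSSProfile:
    """Signed strand-aware offsets of peak midpoints around gene TSSs."""

    offsets: np.ndarray
    density: np.ndarray
    bin_edges: np.ndarray
    gene_set: str = ""

    def to_tsv(self, path) -> None:
        centers = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        with open(path, "wt") as fh:
            fh.write("bin_center\tdensity\n")
            for c, d in zip(centers, self.density):
                fh.write(f"{c:.10g}\t{d:.10g}\n")


def peak_tss_profile(
    peaks: Sequence[GenomicInterval],
    tss: Sequence[tuple[str, int, str]],
    half_window: int = 5000,
    bins: int = 100,
    gene_set: str = "",
) -> PeakTSSProfile:
    """Relative-density metagene of peak midpoints around TSSs.

    For every (peak midpoint, TSS) pair within ``half_window``, the signed
    offset is recorded with downstream of the TSS positive in the gene's
    orientation (sign flipped on minus-strand genes). The density histogram
    is normalized to sum to one.
    """
    if half_window <= 0:
        raise ValueError("half_window must be positive")
    offsets = []
    for chrom, pos, strand in tss:
        for pk in peaks:
            if pk.chrom != chrom:
                continue
            mid = (pk.start + pk.end - 1) // 2
            off = mid - pos
            if strand == "-":
                off = -off
            if abs(off) <= half_window:
                offsets.append(off)
    offsets = np.asarray(offsets, dtype=float)
    hist, edges = np.histogram(offsets, bins=bins, range=(-half_window, half_window))
    density = hist / hist.sum() if hist.sum() > 0 else hist.astype(float)
    return PeakTSSProfile(offsets, density, edges, gene_set)


def compare_peak_profiles(a: PeakTSSProfile, b: PeakTSSProfile) -> KSResult:
    """Two-sample KS on the raw offset samples (not the binned densities)."""
    if a.offsets.size == 0 or b.offsets.size == 0:
        raise ValueError("both peak-TSS profiles must be non-empty")
    res = stats.ks_2samp(a.offsets, b.offsets, method="asymp")
    return KSResult(float(res.statistic), float(min(res.pvalue, 1.0)), a.offsets.size, b.offsets.size)
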