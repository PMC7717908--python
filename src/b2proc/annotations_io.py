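"""Readers and writers for every external input.

Accepted dialects
-----------------
* Repeat / tRNA / genic / peak annotations: BED6 (name column = subfamily
  for repeats) or the RepeatMasker ``.out`` table (auto-detected by header).
* Alignments: SAM/BAM via pysam, or ``bamToBed``-style BED6 where the name
  column is the read id.
* Expression: TSV, genes in rows, samples in columns.
* Gene sets: one gene id per line.
* Sample manifest: TSV with columns sample_id, group, short_path, long_path,
  short_library_size, long_library_size; extra columns become covariates.

All text readers transparently accept gzip-compressed files.
"""

from __future__ import annotations

import gzip
import io as _io
import os
from typing import Iterable, Iterator

import pandas as pd
import pysam

from .core import (
    DEFAULT_SUBFAMILIES,
    GeneSet,
    GenomicInterval,
    ReadAlignment,
    RepeatLocus,
    SampleEntry,
    SampleManifest,
    ExpressionTable,
    logger,
    make_locus_id,
)


class AnnotationError(ValueError):
    """Malformed or empty annotation input."""


def _open_text(path: str | os.PathLike) -> _io.TextIOBase:
    path = os.fspath(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _parse_bed6(line: str, path: str, lineno: int) -> tuple[GenomicInterval, str]:
    fields = line.split("\t") if "\t" in line else line.split()
    if len(fields) < 6:
        raise AnnotationError(
            f"{path}:{lineno}: expected >=6 BED columns, got {len(fields)}"
        )
    try:
        iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]), fields[5])
    except ValueError as exc:
        raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
    return iv, fields[3]


def _looks_like_repeatmasker(first_lines: list[str]) -> bool:
    if not first_lines:
        return False
    head = first_lines[0].split()
    return bool(head) and head[0] in ("SW", "score") or (
        len(head) > 1 and head[0] == "SW"
    )


def read_repeat_annotation(
    path: str | os.PathLike,
    subfamilies: Iterable[str] = DEFAULT_SUBFAMILIES,
) -> list[RepeatLocus]:
    """Load repeat element copies, keeping only the requested subfamilies.

    BED6 (name = subfamily) and RepeatMasker ``.out`` dialects are
    auto-detected from the header. Locus ids are assigned deterministically
    as ``chrom:start-end:strand``. Raises :class:`AnnotationError` on
    malformed lines (with line number) and when no locus survives the
    subfamily filter.
    """
    subfamilies = set(subfamilies)
    with _open_text(path) as fh:
        lines = fh.read().splitlines()
    spath = os.fspath(path)

    loci: list[RepeatLocus] = []
    if _looks_like_repeatmasker(lines[:1]):
        # RepeatMasker .out: two header lines then whitespace-separated rows;
        # columns 5-7 are chrom, begin (1-based), end; 9 strand (+/C); 10 name.
        for lineno, line in enumerate(lines, 1):
            if lineno <= 2 or not line.strip():
                continue
            f = line.split()
            if len(f) < 11:
                raise AnnotationError(
                    f"{spath}:{lineno}: expected >=11 RepeatMasker columns"
                )
            try:
                start, end = int(f[5]) - 1, int(f[6])
                strand = "+" if f[8] == "+" else "-"
                iv = GenomicInterval(f[4], start, end, strand)
            except ValueError as exc:
                raise AnnotationError(f"{spath}:{lineno}: {exc}") from exc
            name = f[9]
            if name in subfamilies:
                loci.append(RepeatLocus(iv, name, make_locus_id(iv)))
    else:
        for lineno, line in enumerate(lines, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            iv, name = _parse_bed6(line, spath, lineno)
            if iv.strand not in ("+", "-"):
                raise AnnotationError(f"{spath}:{lineno}: repeat loci must be stranded")
            if name in subfamilies:
                loci.append(RepeatLocus(iv, name, make_locus_id(iv)))

    if not loci:
        raise AnnotationError(
            f"{spath}: no loci left after filtering to subfamilies {sorted(subfamilies)}"
        )
    return loci


def read_intervals(path: str | os.PathLike) -> list[GenomicInterval]:
    """Read a BED3/BED6 file of plain intervals (genic regions, peaks, tRNAs)."""
    out: list[GenomicInterval] = []
    spath = os.fspath(path)
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t") if "\t" in line else line.split()
            if len(f) < 3:
                raise AnnotationError(f"{spath}:{lineno}: expected >=3 BED columns")
            strand = f[5] if len(f) >= 6 else "."
            try:
                out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
            except ValueError as exc:
                raise AnnotationError(f"{spath}:{lineno}: {exc}") from exc
    return out


def write_loci_bed(loci: Iterable[RepeatLocus], path: str | os.PathLike) -> None:
    with open(path, "wt") as fh:
        for loc in loci:
            iv = loc.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{loc.subfamily}\t0\t{iv.strand}\n"
            )


def write_intervals_bed(
    intervals: Iterable[GenomicInterval], path: str | os.PathLike, name: str = "."
) -> None:
    with open(path, "wt") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def categorize_loci(
    loci: list[RepeatLocus], genic: list[GenomicInterval]
) -> list[RepeatLocus]:
    """Split repeat copies into genic vs intergenic.

    A locus is genic iff it overlaps at least one genic interval by >=1 bp,
    strand-blind; everything else is intergenic. Input order is preserved.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for g in genic:
        by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
    for spans in by_chrom.values():
        spans.sort()

    out = []
    for loc in loci:
        spans = by_chrom.get(loc.interval.chrom, [])
        hit = any(s < loc.interval.end and loc.interval.start < e for s, e in spans)
        out.append(loc.with_category("genic" if hit else "intergenic"))
    return out


def _alignments_from_sam(
    path: str, library: str, count_secondary: bool
) -> Iterator[ReadAlignment]:
    mode = "rb" if path.endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode, check_sq=False) as bam:
        for rec in bam:
            if rec.is_unmapped:
                continue
            primary = not (rec.is_secondary or rec.is_supplementary)
            if not primary and not count_secondary:
                # still carried downstream with is_primary=False: counting
                # stages filter on the flag, so yield them for completeness
                pass
            iv = GenomicInterval(
                rec.reference_name,
                rec.reference_start,
                rec.reference_end if rec.reference_end is not None else rec.reference_start + 1,
                "-" if rec.is_reverse else "+",
            )
            yield ReadAlignment(
                rec.query_name,
                iv,
                "-" if rec.is_reverse else "+",
                is_primary=primary,
                library=library,
            )


def _alignments_from_bed(path: str, library: str) -> Iterator[ReadAlignment]:
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.split("\t") if "\t" in line else line.split()
            if len(f) < 6 or f[5] not in ("+", "-"):
                raise AnnotationError(
                    f"{path}:{lineno}: alignment BED requires 6 columns with strand"
                )
            iv = GenomicInterval(f[0], int(f[1]), int(f[2]), f[5])
            yield ReadAlignment(f[3], iv, f[5], is_primary=True, library=library)


def read_alignments(
    path: str | os.PathLike, library: str, count_secondary: bool = False
) -> Iterator[ReadAlignment]:
    """Stream mapped reads from SAM/BAM or bamToBed-style BED6.

    Unmapped records are skipped; secondary/supplementary records are yielded
    with ``is_primary=False`` so downstream counters can apply the
    primary-only policy uniformly.
    """
    spath = os.fspath(path)
    if not os.path.exists(spath):
        raise FileNotFoundError(f"alignment file not found: {spath}")
    base = spath[:-3] if spath.endswith(".gz") else spath
    if base.endswith((".sam", ".bam", ".cram")):
        return _alignments_from_sam(spath, library, count_secondary)
    if base.endswith(".bed"):
        return _alignments_from_bed(spath, library)
    raise AnnotationError(
        f"{spath}: unknown alignment format; accepted dialects are SAM/BAM "
        "and bamToBed-style BED6"
    )


def read_expression_table(path: str | os.PathLike, unit: str = "TPM") -> ExpressionTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        logger.warning(
            "expression table %s: %d duplicate gene ids, keeping last occurrence",
            path,
            int(df.index.duplicated().sum()),
        )
        df = df[~df.index.duplicated(keep="last")]
    if (df.to_numpy() < 0).any():
        raise AnnotationError(f"{path}: negative expression values")
    return ExpressionTable(df, unit=unit)


def write_expression_table(table: ExpressionTable, path: str | os.PathLike) -> None:
    table.values.to_csv(path, sep="\t", index_label="gene")


def read_gene_set(path: str | os.PathLike, name: str | None = None) -> GeneSet:
    with _open_text(path) as fh:
        members = frozenset(line.strip() for line in fh if line.strip())
    if name is None:
        name = os.path.basename(os.fspath(path)).rsplit(".", 1)[0]
    return GeneSet(name, members)


_MANIFEST_REQUIRED = ("sample_id", "group", "short_library_size", "long_library_size")


def read_sample_manifest(path: str | os.PathLike) -> SampleManifest:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _MANIFEST_REQUIRED if c not in df.columns]
    if missing:
        raise AnnotationError(f"{path}: manifest missing columns {missing}")
    known = set(_MANIFEST_REQUIRED) | {"short_path", "long_path"}
    entries = []
    for _, row in df.iterrows():
        covars = {c: row[c] for c in df.columns if c not in known}
        entries.append(
            SampleEntry(
                sample_id=row["sample_id"],
                group=row["group"],
                short_path=row.get("short_path", "") or "",
                long_path=row.get("long_path", "") or "",
                short_library_size=int(row["short_library_size"]),
                long_library_size=int(row["long_library_size"]),
                covariates=covars,
            )
        )
    return SampleManifest(entries)


def write_sample_manifest(manifest: SampleManifest, path: str | os.PathLike) -> None:
    covar_keys = sorted({k for s in manifest for k in s.covariates})
    rows = []
    for s in manifest:
        row = {
            "sample_id": s.sample_id,
            "group": s.group,
            "short_path": s.short_path,
            "long_path": s.long_path,
            "short_library_size": s.short_library_size,
            "long_library_size": s.long_library_size,
        }
        row.update({k: s.covariates.get(k, "") for k in covar_keys})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def count_fastq_records(path: str | os.PathLike) -> int:
    """Convenience library-size counter for when Ns/Nl are not in the manifest."""
    n = 0
    with _open_text(path) as fh:
        for i, _ in enumerate(fh):
            n = i + 1
    if n % 4:
        raise AnnotationError(f"{path}: FASTQ line count {n} is not a multiple of 4")
    return n // 4
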