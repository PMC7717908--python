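"""Core data model shared by every pipeline stage.

Coordinates are 0-based half-open throughout (BED convention). SAM/BAM
1-based inclusive coordinates are converted at read time and never leak
into the data model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("b2proc")

#: RepeatMasker subfamilies of the mouse SINE B2 family quantified by default.
DEFAULT_SUBFAMILIES = frozenset({"B2_Mm1a", "B2_Mm1t", "B2_Mm2"})

#: Length of the B2 consensus sequence (nt).
B2_CONSENSUS_LENGTH = 188

#: Default metagene window width (nt): positions +1..W downstream of the
#: element start, chosen below the consensus length to exclude reads mapping
#: partially within the window or downstream of truncated copies.
DEFAULT_WINDOW = 120

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Strand-blind >=1 bp overlap (half-open: touching is no overlap)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True, slots=True)
class RepeatLocus:
    """One annotated repeat element copy.

    ``category`` records whether the copy falls inside a genic/exonic
    interval (``genic``), outside all of them (``intergenic``), or has not
    been classified yet (``unclassified``).
    """

    interval: GenomicInterval
    subfamily: str
    locus_id: str
    category: str = "unclassified"

    def __post_init__(self) -> None:
        if self.category not in ("genic", "intergenic", "unclassified"):
            raise ValueError(f"bad category {self.category!r}")
        if self.interval.strand not in ("+", "-"):
            raise ValueError("repeat loci must be stranded")

    @property
    def element_start(self) -> int:
        """Genomic coordinate of element position +1 (strand-aware)."""
        return self.interval.start if self.interval.strand == "+" else self.interval.end - 1

    def with_category(self, category: str) -> "RepeatLocus":
        return replace(self, category=category)


def make_locus_id(interval: GenomicInterval) -> str:
    return f"{interval.chrom}:{interval.start}-{interval.end}:{interval.strand}"


@dataclass(frozen=True, slots=True)
class ReadAlignment:
    """A mapped read, the consumption contract for upstream aligners."""

    read_id: str
    interval: GenomicInterval
    strand: str
    is_primary: bool = True
    library: str = "short"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("aligned reads must be stranded")
        if self.library not in ("short", "long"):
            raise ValueError(f"library must be 'short' or 'long', got {self.library!r}")

    @property
    def five_prime(self) -> int:
        """Genomic coordinate of the read's 5' base."""
        return self.interval.start if self.strand == "+" else self.interval.end - 1


@dataclass
class ExpressionTable:
    """Gene x sample expression matrix in TPM or FPKM units."""

    values: pd.DataFrame  # index = genes, columns = samples
    unit: str = "TPM"

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True, slots=True)
class SampleEntry:
    """One row of the sample manifest.

    ``short_library_size`` / ``long_library_size`` are the total read counts
    of the small-RNA and long-RNA fastq files (the depth normalizers Ns, Nl).
    """

    sample_id: str
    group: str
    short_path: str = ""
    long_path: str = ""
    short_library_size: int = 0
    long_library_size: int = 0
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.short_library_size <= 0 or self.long_library_size <= 0:
            raise ValueError(
                f"sample {self.sample_id}: library sizes Ns, Nl must be positive"
            )


@dataclass
class SampleManifest:
    samples: list[SampleEntry]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate sample ids in manifest: {sorted(dupes)}")

    def __iter__(self):
        return iter(self.samples)

    def __len__(self) -> int:
        return len(self.samples)

    def __getitem__(self, sample_id: str) -> SampleEntry:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    @property
    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for s in self.samples:
            out.setdefault(s.group, []).append(s.sample_id)
        return out


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.members)
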