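"""Ground-truth simulator for the whole pipeline.

Generates a toy chromosome carrying diverged SINE B2 copies (consensus-
derived with SNPs, deletions and 3' truncations), tRNA loci as the
normalizer class, and a dedicated background zone; emits directional
short-read fragments whose 5' ends concentrate at discrete cleavage
positions (by default the prominent sites 99 and 33 plus the minor sites
90 and 47), full-length long reads over B2 copies, tRNA-anchored short
reads, and uniform background in both libraries. Every generator is a pure
function of its seed and parameters, and the realized counts entering the
processing ratio are recorded as ground truth at emission time.

Alignments are emitted directly (SAM or in-memory records) rather than via
a FASTQ -> aligner round trip, so tests need no external aligner; FASTA /
FASTQ writers are provided for exercising real aligners out-of-band.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pysam

from .core import (
    B2_CONSENSUS_LENGTH,
    GenomicInterval,
    ReadAlignment,
    RepeatLocus,
    SampleEntry,
    SampleManifest,
    ExpressionTable,
    logger,
    make_locus_id,
)
from . import annotations_io
from .processing_ratio import FRAGMENT_WINDOW

#: Default cleavage landscape: position -> probability a processed fragment
#: starts there (before +-1 jitter).
DEFAULT_CLEAVAGE_SITES = {99: 0.5, 33: 0.3, 90: 0.1, 47: 0.1}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = dict(zip(b"ACGT", b"TGCA"))


def _revcomp(seq: np.ndarray) -> np.ndarray:
    table = np.zeros(256, dtype=np.uint8)
    for a, b in _COMP.items():
        table[a] = b
    return table[seq][::-1]


@dataclass
class SyntheticGenome:
    """Toy chromosome with planted repeat copies, genes, tRNAs."""

    chrom: str
    length: int
    loci: list[RepeatLocus]
    genic: list[GenomicInterval]
    trna_loci: list[GenomicInterval]
    background: GenomicInterval
    sequence: np.ndarray  # uint8 ASCII
    seed: int

    def write_fasta(self, path) -> None:
        with open(path, "wt") as fh:
            fh.write(f">{self.chrom}\n")
            s = self.sequence.tobytes().decode()
            for i in range(0, len(s), 80):
                fh.write(s[i : i + 80] + "\n")


@dataclass
class SimulatedSample:
    sample_id: str
    short: list[ReadAlignment]
    long: list[ReadAlignment]
    truth: dict  # realized F, T, B, Ns, Nl, n_fragments, processing_fraction


@dataclass
class SimulationTruth:
    """Everything the generator knows that the pipeline must recover."""

    groups: dict = field(default_factory=dict)
    samples: dict = field(default_factory=dict)
    cleavage_site_probs: dict = field(default_factory=dict)
    gene_r_targets: dict = field(default_factory=dict)
    seed: int = 0

    def to_json(self, path) -> None:
        payload = {
            "groups": self.groups,
            "samples": self.samples,
            "cleavage_site_probs": {str(k): v for k, v in self.cleavage_site_probs.items()},
            "gene_r_targets": self.gene_r_targets,
            "seed": self.seed,
        }
        with open(path, "wt") as fh:
            json.dump(payload, fh, indent=2)


@dataclass
class SimulatedCohort:
    manifest: SampleManifest
    genome: SyntheticGenome
    samples: dict[str, SimulatedSample]
    truth: SimulationTruth
    expression: ExpressionTable | None = None
    seed: int = 0

    @property
    def loci(self) -> list[RepeatLocus]:
        return self.genome.loci

    @property
    def trna_loci(self) -> list[GenomicInterval]:
        return self.genome.trna_loci

    def write(self, outdir) -> SampleManifest:
        """Write BED/SAM/TSV/JSON artifacts and a path-bearing manifest."""
        os.makedirs(outdir, exist_ok=True)
        annotations_io.write_loci_bed(self.genome.loci, os.path.join(outdir, "b2_loci.bed"))
        annotations_io.write_intervals_bed(
            self.genome.trna_loci, os.path.join(outdir, "trna_loci.bed"), name="tRNA"
        )
        annotations_io.write_intervals_bed(
            self.genome.genic, os.path.join(outdir, "genic.bed"), name="gene"
        )
        entries = []
        for entry in self.manifest:
            sim = self.samples[entry.sample_id]
            short_path = os.path.join(outdir, f"{entry.sample_id}.short.sam")
            long_path = os.path.join(outdir, f"{entry.sample_id}.long.sam")
            write_sam(sim.short, self.genome, short_path)
            write_sam(sim.long, self.genome, long_path)
            entries.append(
                SampleEntry(
                    sample_id=entry.sample_id,
                    group=entry.group,
                    short_path=short_path,
                    long_path=long_path,
                    short_library_size=entry.short_library_size,
                    long_library_size=entry.long_library_size,
                    covariates=entry.covariates,
                )
            )
        manifest = SampleManifest(entries)
        annotations_io.write_sample_manifest(manifest, os.path.join(outdir, "manifest.tsv"))
        self.truth.to_json(os.path.join(outdir, "truth.json"))
        if self.expression is not None:
            annotations_io.write_expression_table(
                self.expression, os.path.join(outdir, "expression.tsv")
            )
        return manifest


def simulate_repeat_loci(
    n_loci: int,
    consensus_length: int = B2_CONSENSUS_LENGTH,
    snp_rate: float = 0.05,
    del_rate: float = 0.01,
    truncation_prob: float = 0.2,
    genic_fraction: float = 0.5,
    seed: int = 0,
    spacing: int = 1000,
    min_length: int = 120,
    n_trna: int = 20,
    trna_length: int = 72,
    background_length: int = 30000,
    chrom: str = "chrSim",
) -> SyntheticGenome:
    """Plant diverged repeat copies on a toy chromosome.

    Copies derive from a random consensus with per-base SNPs and deletions;
    with probability ``truncation_prob`` the 3' end is shortened by a
    geometric number of bases (mean 30), floored at ``min_length``. Loci are
    non-overlapping with >= ``spacing`` bp gaps; ``genic_fraction`` of them
    are wrapped by a synthetic gene interval. tRNA loci and a background
    zone (where background reads are placed) follow the repeat region.
    """
    for name, rate in (("snp_rate", snp_rate), ("del_rate", del_rate),
                       ("truncation_prob", truncation_prob), ("genic_fraction", genic_fraction)):
        if not 0 <= rate <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    if n_loci < 1:
        raise ValueError("need at least one locus")
    rng = np.random.default_rng(seed)
    consensus = rng.choice(_BASES, size=consensus_length)

    placements: list[tuple[int, np.ndarray, str]] = []
    cursor = 1000
    genic: list[GenomicInterval] = []
    for _ in range(n_loci):
        copy = consensus.copy()
        snps = rng.random(copy.size) < snp_rate
        if snps.any():
            copy[snps] = rng.choice(_BASES, size=int(snps.sum()))
        keep = rng.random(copy.size) >= del_rate
        copy = copy[keep]
        if rng.random() < truncation_prob:
            cut = int(rng.geometric(1 / 30))
            copy = copy[: max(min_length, copy.size - cut)]
        if copy.size < min_length:
            copy = copy[:min_length] if copy.size >= min_length else np.concatenate(
                [copy, rng.choice(_BASES, size=min_length - copy.size)]
            )
        strand = "+" if rng.random() < 0.5 else "-"
        start = cursor + spacing + int(rng.integers(0, 1000))
        placements.append((start, copy, strand))
        cursor = start + copy.size
        if rng.random() < genic_fraction:
            pad5 = int(rng.integers(100, 500))
            pad3 = int(rng.integers(100, 500))
            genic.append(GenomicInterval(chrom, start - pad5, cursor + pad3, strand))

    trna: list[tuple[int, str]] = []
    cursor += 2000
    for _ in range(n_trna):
        start = cursor + 200 + int(rng.integers(0, 400))
        strand = "+" if rng.random() < 0.5 else "-"
        trna.append((start, strand))
        cursor = start + trna_length
    bg_start = cursor + 2000
    length = bg_start + background_length + 1000

    sequence = rng.choice(_BASES, size=length)
    loci = []
    for start, copy, strand in placements:
        planted = copy if strand == "+" else _revcomp(copy)
        sequence[start : start + copy.size] = planted
        iv = GenomicInterval(chrom, start, start + copy.size, strand)
        loci.append(RepeatLocus(iv, "B2_Mm2", make_locus_id(iv)))
    trna_loci = [
        GenomicInterval(chrom, s, s + trna_length, strand) for s, strand in trna
    ]
    background = GenomicInterval(chrom, bg_start, bg_start + background_length, ".")
    return SyntheticGenome(chrom, length, loci, genic, trna_loci, background, sequence, seed)


def simulate_sample(
    genome: SyntheticGenome,
    processing_fraction: float,
    cleavage_site_probs: dict[int, float] | None = None,
    n_b2_transcripts: int = 2000,
    n_trna_reads: int = 500,
    n_background_short: int = 1000,
    n_background_long: int = 1000,
    fragment_length_range: tuple[int, int] = (18, 45),
    jitter: int = 1,
    sample_id: str = "S",
    seed: int = 0,
) -> SimulatedSample:
    """Emit one sample's short and long alignments with realized truth.

    Each B2 transcript is processed into a short 5' fragment with
    probability ``processing_fraction`` (5' end drawn from the cleavage
    landscape with +-``jitter`` positional jitter on a random sense-strand
    copy), otherwise emitted as a full-length long read. tRNA reads start
    within +-2 bp of tRNA starts; background reads fall uniformly in the
    off-locus background zone. Realized F (fragment-window 5' ends), T, B,
    Ns, Nl are recorded from the emitted reads.
    """
    if not 0 <= processing_fraction <= 1:
        raise ValueError("processing_fraction must be in [0, 1]")
    if not genome.loci:
        raise ValueError("locus list is empty")
    sites = dict(cleavage_site_probs or DEFAULT_CLEAVAGE_SITES)
    probs = np.array(list(sites.values()), dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("cleavage site probabilities must sum to 1")
    site_pos = np.array(list(sites.keys()), dtype=int)
    rng = np.random.default_rng(seed)
    chrom = genome.chrom

    short: list[ReadAlignment] = []
    long_reads: list[ReadAlignment] = []
    flo, fhi = fragment_length_range
    F = 0

    loc_idx = rng.integers(0, len(genome.loci), size=n_b2_transcripts)
    processed = rng.random(n_b2_transcripts) < processing_fraction
    site_draw = rng.choice(site_pos, size=n_b2_transcripts, p=probs)
    jit = rng.integers(-jitter, jitter + 1, size=n_b2_transcripts) if jitter else np.zeros(
        n_b2_transcripts, dtype=int
    )
    flen = rng.integers(flo, fhi + 1, size=n_b2_transcripts)
    for i in range(n_b2_transcripts):
        loc = genome.loci[int(loc_idx[i])]
        iv = loc.interval
        if processed[i]:
            p = int(np.clip(site_draw[i] + jit[i], 1, iv.length))
            if iv.strand == "+":
                g5 = iv.start + p - 1
                read_iv = GenomicInterval(chrom, g5, g5 + int(flen[i]), "+")
            else:
                g5 = iv.end - p
                read_iv = GenomicInterval(chrom, g5 - int(flen[i]) + 1, g5 + 1, "-")
            short.append(
                ReadAlignment(f"{sample_id}.frag{i}", read_iv, iv.strand, library="short")
            )
            if FRAGMENT_WINDOW[0] <= p <= FRAGMENT_WINDOW[1]:
                F += 1
        else:
            long_reads.append(
                ReadAlignment(
                    f"{sample_id}.fl{i}",
                    GenomicInterval(chrom, iv.start, iv.end, iv.strand),
                    iv.strand,
                    library="long",
                )
            )
    B = len(long_reads)

    trna_idx = rng.integers(0, len(genome.trna_loci), size=n_trna_reads)
    offs = rng.integers(-2, 3, size=n_trna_reads)
    tlen = rng.integers(55, 76, size=n_trna_reads)
    for i in range(n_trna_reads):
        t = genome.trna_loci[int(trna_idx[i])]
        if t.strand == "+":
            g5 = t.start + int(offs[i])
            iv = GenomicInterval(chrom, g5, g5 + int(tlen[i]), "+")
        else:
            g5 = t.end - 1 - int(offs[i])
            iv = GenomicInterval(chrom, g5 - int(tlen[i]) + 1, g5 + 1, "-")
        short.append(ReadAlignment(f"{sample_id}.t{i}", iv, t.strand, library="short"))
    T = n_trna_reads

    bg = genome.background
    bs = rng.integers(bg.start, bg.end - fhi - 1, size=n_background_short)
    blens = rng.integers(flo, fhi + 1, size=n_background_short)
    bstr = rng.random(n_background_short) < 0.5
    for i in range(n_background_short):
        iv = GenomicInterval(chrom, int(bs[i]), int(bs[i] + blens[i]), "+" if bstr[i] else "-")
        short.append(
            ReadAlignment(f"{sample_id}.bs{i}", iv, iv.strand, library="short")
        )
    ls = rng.integers(bg.start, bg.end - 1100, size=n_background_long)
    llen = rng.integers(200, 1001, size=n_background_long)
    lstr = rng.random(n_background_long) < 0.5
    for i in range(n_background_long):
        iv = GenomicInterval(chrom, int(ls[i]), int(ls[i] + llen[i]), "+" if lstr[i] else "-")
        long_reads.append(
            ReadAlignment(f"{sample_id}.bl{i}", iv, iv.strand, library="long")
        )

    truth = {
        "F": F,
        "T": T,
        "B": B,
        "Ns": len(short),
        "Nl": len(long_reads),
        "n_fragments": int(processed.sum()),
        "processing_fraction": processing_fraction,
    }
    return SimulatedSample(sample_id, short, long_reads, truth)


def simulate_cohort(
    group_specs: list[tuple[str, int, float]],
    genome: SyntheticGenome | None = None,
    n_loci: int = 30,
    cleavage_site_probs: dict[int, float] | None = None,
    seed: int = 0,
    **sample_kwargs,
) -> SimulatedCohort:
    """Simulate a multi-group cohort with per-sample seeds off a master seed.

    ``group_specs`` is a list of (group name, n samples, processing
    fraction); depth settings are shared across samples via
    ``sample_kwargs`` (see :func:`simulate_sample`).
    """
    if not group_specs:
        raise ValueError("at least one group spec is required")
    sites = dict(cleavage_site_probs or DEFAULT_CLEAVAGE_SITES)
    if genome is None:
        genome = simulate_repeat_loci(n_loci, seed=seed)
    ss = np.random.SeedSequence(seed)
    truth = SimulationTruth(cleavage_site_probs=sites, seed=seed)
    entries: list[SampleEntry] = []
    samples: dict[str, SimulatedSample] = {}
    n_total = sum(n for _, n, _ in group_specs)
    child_seeds = ss.spawn(n_total)
    k = 0
    for group, n_samples, pf in group_specs:
        truth.groups[group] = {"processing_fraction": pf, "n_samples": n_samples}
        for j in range(n_samples):
            sid = f"{group}_{j + 1}"
            sim = simulate_sample(
                genome,
                pf,
                cleavage_site_probs=sites,
                sample_id=sid,
                seed=child_seeds[k],
                **sample_kwargs,
            )
            k += 1
            samples[sid] = sim
            truth.samples[sid] = dict(sim.truth, group=group)
            entries.append(
                SampleEntry(
                    sample_id=sid,
                    group=group,
                    short_library_size=sim.truth["Ns"],
                    long_library_size=sim.truth["Nl"],
                )
            )
    return SimulatedCohort(SampleManifest(entries), genome, samples, truth, seed=seed)


def simulate_expression(
    n_genes: int,
    ratios: np.ndarray,
    r_targets: np.ndarray,
    base_expression: float = 100.0,
    noise_sd: float = 10.0,
    seed: int = 0,
    sample_ids: list[str] | None = None,
) -> tuple[ExpressionTable, dict[str, float]]:
    """Expression table whose genes target given population correlations.

    Gene g is ``base + beta_g * z(ratio) + eps`` with
    ``beta = noise_sd * r / sqrt(1 - r^2)`` so the population Pearson
    correlation with the ratio equals ``r_targets[g]`` (exact signal for
    |r| = 1). Negative draws are clamped at zero with a logged count.
    """
    ratios = np.asarray(ratios, dtype=float)
    if ratios.size < 3:
        raise ValueError("at least 3 samples are required")
    r_targets = np.broadcast_to(np.asarray(r_targets, dtype=float), (n_genes,))
    if (np.abs(r_targets) > 1).any():
        raise ValueError("target correlations must lie in [-1, 1]")
    if np.ptp(ratios) == 0:
        raise ValueError("ratio vector has zero variance")
    rng = np.random.default_rng(seed)
    z = (ratios - ratios.mean()) / ratios.std()
    rows = np.empty((n_genes, ratios.size))
    for g in range(n_genes):
        r = r_targets[g]
        if abs(r) == 1.0:
            rows[g] = base_expression + np.sign(r) * z * max(noise_sd, 1.0)
        else:
            beta = noise_sd * r / np.sqrt(1 - r * r)
            rows[g] = base_expression + beta * z + rng.normal(0, noise_sd, ratios.size)
    clamped = int((rows < 0).sum())
    if clamped:
        logger.info("clamped %d negative expression draws to zero", clamped)
        rows = np.clip(rows, 0, None)
    import pandas as pd

    genes = [f"gene{g + 1}" for g in range(n_genes)]
    cols = sample_ids or [f"S{i + 1}" for i in range(ratios.size)]
    table = ExpressionTable(pd.DataFrame(rows, index=genes, columns=cols))
    return table, dict(zip(genes, (float(r) for r in r_targets)))


def write_sam(reads: list[ReadAlignment], genome: SyntheticGenome, path) -> None:
    """Write alignments as plain-text SAM against the toy chromosome."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": genome.chrom, "LN": genome.length}],
    }
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for r in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.read_id
            a.flag = 16 if r.strand == "-" else 0
            a.reference_id = 0
            a.reference_start = r.interval.start
            a.mapping_quality = 60
            a.cigartuples = [(0, r.interval.length)]
            out.write(a)


def write_fastq(reads: list[ReadAlignment], genome: SyntheticGenome, path) -> None:
    """Write reads as FASTQ with sequence sliced from the toy genome."""
    with open(path, "wt") as fh:
        for r in reads:
            seq = genome.sequence[r.interval.start : r.interval.end]
            if r.strand == "-":
                seq = _revcomp(seq)
            s = seq.tobytes().decode()
            fh.write(f"@{r.read_id}\n{s}\n+\n{'I' * len(s)}\n")
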