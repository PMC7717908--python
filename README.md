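# b2proc

Quantification of SINE B2 RNA processing from paired short- and
long-RNA-seq data.

Mouse SINE B2 elements (~188 nt consensus, RepeatMasker subfamilies
B2_Mm1a, B2_Mm1t, B2_Mm2) are transcribed by RNA Pol III into B2 RNAs that
bind and suppress RNA Pol II at stress response genes (SRGs). During stress
the B2 RNA is cleaved at discrete positions — most prominently around
positions 99 and 33 of the element — releasing Pol II and activating the
SRGs. `b2proc` quantifies this processing from sequencing data:

* **5′-end metagene** — short-read 5′ ends are mapped into element
  coordinates (position +1 = element start, strand-aware) and aggregated
  over all B2 copies into a metagene profile; peaks of the profile are
  called as *processing points* and point sets from different conditions
  can be compared within a positional tolerance.
* **Processing ratio** — per sample,

  `ratio = [ F / (T / Ns) ] / [ B / Nl ]`

  where `F` = short-read 5′ ends at element positions 95–110, `T` = short
  reads starting within −5..+15 bp of annotated tRNA starts (a Pol III
  normalizer class), `Ns`/`Nl` = short/long library sizes, and `B` = long
  reads overlapping B2 loci (full-length transcripts). A depth-invariant
  variant `(F/T)/(B/Nl)` is available as `trna_relative` mode.
* **Condition comparisons** — two-sample Kolmogorov–Smirnov tests on the
  positional distributions, and unpaired t-tests (pooled or Welch,
  directional or not) on per-sample ratios between groups.
* **Expression–ratio correlation** — per-gene Pearson correlation of
  expression (TPM/FPKM) against the per-sample processing ratio, with
  significance filtering (two-sided p ≤ 0.05 via the t transform) and
  classification into strong (r ≥ 0.5), weak (0.25 ≤ r < 0.5) and no
  correlation (r < 0.25); plus gene-set overlaps and peak–TSS
  relative-density metagenes.
* **Ground-truth simulator** — a toy chromosome with diverged B2 copies,
  tRNA loci, directional short fragments drawn from a configurable cleavage
  landscape, full-length long reads, multi-group cohorts and expression
  tables with target correlations, all with recorded ground truth for
  end-to-end validation.

Inputs are standard formats: BED6 or RepeatMasker `.out` annotations,
SAM/BAM or BED6 alignments, TSV expression tables and manifests, one-id-
per-line gene sets (all optionally gzipped).

## Worked example

```python
import b2proc as bp

# a two-group cohort: wild-type at 5% processing, disease model at 15%
genome = bp.simulate_repeat_loci(30, seed=7)
cohort = bp.simulate_cohort([("WT", 4, 0.05), ("APP", 4, 0.15)],
                            genome=genome, seed=1)

results = []
for sid, sim in cohort.samples.items():
    counts = bp.compute_sample_counts(
        sim.short, sim.long, genome.loci, genome.trna_loci,
        Ns=sim.truth["Ns"], Nl=sim.truth["Nl"], sample_id=sid)
    results.append(bp.compute_ratio(counts, sample_id=sid))

comp = bp.compare_groups(results, cohort.manifest, sided="greater",
                         group_order=("APP", "WT"))
print(f"mean ratio APP={comp.means[0]:.0f} WT={comp.means[1]:.0f} "
      f"t={comp.t:.2f} p={comp.p:.2g}")
```

prints

```
mean ratio APP=791 WT=268 t=19.45 p=6e-07
```

the estimated processing ratio is ~3× higher in the APP group (matching the
3× simulated processing fraction) and the directional pooled t-test detects
the difference. The same pipeline runs from files via the CLI:

```sh
b2proc simulate --out cohort/ --seed 1
b2proc report --cohort cohort/ --out report/ --sided greater
```

Metagene profiles and processing points:

```python
events = bp.extract_events(cohort.samples["APP_1"].short, genome.loci)
profile = bp.build_profile(events)
print(bp.call_processing_points(profile).positions)  # [34, 47, 89, 98] (each within 1 of a true site)
```

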