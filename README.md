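# sweepkit

Selective-sweep scans for pooled resequencing cohorts, built around the
analysis style of livestock-domestication studies: a small panel of
deeply sequenced animals from several breeds plus wild relatives, and a
hunt for genomic windows whose variation pattern betrays artificial
selection.

The package implements, as tested reusable components:

- **SNP deserts** — per-breed SNP rates in 10-kb windows normalized by
  the callable (≥ 8×) length, lowest-decile seeding, ≤ 10-kb gap
  joining, and **SAG**s (genes > 30% covered by deserts), with the
  > 100-kb and top-10 desert reports.
- **Sweep scans** — pooled heterozygosity
  `Hp = 2·ΣnMAJ·ΣnMIN/(ΣnMAJ+ΣnMIN)²` from pooled read counts and
  windowed Hudson Fst (Weir–Cockerham optional) in 100-kb windows,
  Z-transformed genome-wide; **DAG**s from ZHp ≤ −3 OR ZFst ≥ 3
  (domestic vs wild).
- **XP-EHH** — from-scratch EHH/iHH on phased haplotypes and
  cross-population XP-EHH with genome-wide normalization; **TAG**s from
  breed-vs-others ZFst ≥ 4 AND top-1% window XP-EHH, cross-referenced
  against QTL intervals.
- **Variant QC** — the depth-8 / four-reads-per-het SNP rule, the
  quality/homopolymer/length indel rules, MAF and per-individual
  heterozygosity summaries, and cross-sample CNV-region merging.
- **Effect annotation** — intergenic/intronic/coding partition and
  synonymous vs nonsynonymous calls with NS/S by MAF bin.
- **A forward-time Wright–Fisher simulator** (recombination, infinite
  sites, additive selection, multi-population splits, Poisson ~29×
  depth emulation with base errors) that generates every input the
  pipeline needs — phased VCF, callable BED, GFF3 genes, QTL BED,
  group TSV, FASTA — with known ground truth for parameter-recovery
  testing. Populations are rescaled (small N, scaled μ/r/s) so breed-
  scale scenarios run on a desk; see `docs/methods.md`.

## Worked example

`examples/05_xpehh_tags.py` plants a hard sweep (real s = 0.1 under the
simulator's rescaling) in the dairy breed of a simulated 5-Mb cohort,
then runs the per-breed TAG scan:

```
$ python examples/05_xpehh_tags.py
selected site 2,550,000; final dairy frequency 1.00 (conditioned on fixation)
sweep window ZFst = 6.08, window XP-EHH = 6.64 (normalized; genome mean 0, sd 1)
TAG windows flagged: 1 of 50 -> sweep window recovered: True
top XP-EHH windows:
  start     end      zfst    xpehh
2500000 2600000  6.075679 6.644640
2400000 2500000  1.131331 3.500944
1200000 1300000 -0.011404 3.233524
```

The swept window carries both an extreme breed-vs-others ZFst (the
dairy animals are fixed for the hitchhiking haplotype) and the genome's
top XP-EHH (dairy haplotypes stay identical far beyond where the other
breeds' homozygosity has decayed), so the AND rule flags exactly that
window and the genes inside it become TAG candidates.

The other scripts in `examples/` walk through cohort simulation, the
QC filters, desert/SAG detection, the domestic-vs-wild DAG scan, and
the end-to-end pipeline. The pipeline is also a thin CLI:

```bash
sweepkit run-all --config config.yaml    # simulate -> qc -> ... -> classify -> report
sweepkit report --run-dir runs/demo
```

with one strictly validated YAML config whose defaults are the printed
study parameters (10-kb/100-kb windows, 10% quantile, ≤ 10-kb join,
> 30% overlap, ZHp −3, ZFst 3 and 4, top 1%).

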