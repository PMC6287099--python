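# Methods

## Overview

`sweepkit` implements the selection-scan toolkit used in livestock
resequencing studies of domestication: SNP-desert detection from
windowed SNP rates, pooled-heterozygosity and windowed-Fst sweep scans
with genome-wide Z-thresholds, cross-population extended haplotype
homozygosity (XP-EHH), and the gene-classification rules that turn
flagged windows into candidate gene lists (SAGs, DAGs, TAGs). Because
a real multi-breed resequencing cohort is far beyond desk scale, the
package ships a forward-time Wright–Fisher simulator that generates a
complete synthetic cohort — phased VCF with allelic depths, callable
mask, gene models, QTL intervals, group table — with known ground
truth, and the test suite exercises every scan end-to-end against it.

## Statistics

**SNP rate and deserts.** Per 10-kb window, the SNP rate is the SNP
count divided by the *callable* length inside the window (bases covered
at ≥ 8×, supplied as a BED mask), not the window span; windows with
under 1 kb callable are rejected. Desert seeds are the qc-passing
windows whose rate lies in the lowest decile, computed by ceiling-rank
selection on the sorted rates (ties at the threshold all included —
the paper-style "lowest 10%" rule has no interpolation scheme, and rank
selection is exactly reproducible). Seeds on a chromosome separated by
≤ 10 kb are joined; a joined desert's length spans end−start including
the gaps. A gene whose span (introns included) is strictly more than
30% covered by deserts is a SNP-desert-associated gene (SAG).

**Pooled heterozygosity.** Per 100-kb window,

    Hp = 2 · ΣnMAJ · ΣnMIN / (ΣnMAJ + ΣnMIN)²

where nMAJ and nMIN are the read counts of the most and least abundant
allele at each SNP, summed over the pooled samples, and the outer sums
run over SNPs in the window. When allelic depths are absent the counts
fall back to genotype allele counts (logged). Hp ∈ [0, 0.5].

**Windowed Fst.** The default estimator is Hudson's, accumulated as a
ratio of averages over the window's usable sites:

    num = (p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1)
    den = p₁(1−p₂) + p₂(1−p₁),          Fst = Σnum / Σden

with p the sample allele frequencies and n the haplotype counts.
Hudson's estimator is insensitive to unequal sample sizes (4 wild vs 15
domestic); Weir–Cockerham (1984, two-allele variance components with
observed heterozygosity) is available as an option. Sites need ≥ 2
called diploids per group; sites monomorphic across both groups are
skipped.

**Z-transforms and classification.** Hp and Fst are Z-transformed over
all scored windows using the sample (n−1) standard deviation; NaN
windows (no SNPs) are excluded from the moments. A window is a
domestication candidate when ZHp ≤ −3 OR ZFst ≥ 3 (domestic pool vs
wild); genes overlapping flagged windows are DAGs. Per breed, a window
is a trait candidate when the breed-vs-pooled-others ZFst ≥ 4 AND the
window's XP-EHH is in the top 1%; overlapping genes are TAGs.
Thresholds are read inclusively. The top-1% set contains exactly
k = ceil(0.01 · scored windows) windows, ties broken by genomic
position, so the flagged fraction can never exceed k.

**EHH / iHH / XP-EHH.** EHH at flanking site x is the probability that
two haplotypes drawn without replacement are identical over all sites
strictly between the core and x inclusive of x:
EHH(x) = Σ_h C(n_h,2)/C(n,2) over haplotype identity groups. Groups are
formed over *all* haplotypes of a panel (combined-core convention —
cross-population comparison does not condition on the core allele), so
EHH at the core is 1 by construction. Walks extend outward site by
site and truncate when EHH < 0.05 or at 1 Mb; a core whose EHH has not
decayed when the panel runs out of sites is skipped (chromosome-edge
bias). iHH is the trapezoidal integral of EHH against physical distance
(no goat genetic map is assumed), left plus right. XP-EHH is
ln(iHH_focal/iHH_reference) per core, normalized genome-wide to mean 0
and sd 1 over all scored cores (no frequency-bin normalization — the
simplest defensible reading; both panels truncate independently, which
preserves exact antisymmetry under population swap). Window XP-EHH is
the max of member core scores (mean optional).

**Effect annotation.** SNPs partition into intergenic / intronic /
coding by the representative transcript (longest CDS) of each gene;
coding SNPs become synonymous/nonsynonymous via codon substitution in
the spliced CDS, reverse-complemented for minus-strand genes, with stop
gains/losses folded into nonsynonymous (flagged). UTR-like exonic
non-coding sites are tallied separately so the three-way partition
stays reproducible; when exon features are absent, non-CDS genic sites
count as intronic. NS/S is reported overall and in MAF bins of width
0.05 over (0, 0.5]; bins with zero synonymous counts report NaN, never
infinity.

**Variant QC.** A SNP site is dropped when any individual's summed
depth is below 8 (configurable to the permissive "all individuals"
reading); a heterozygous call with fewer than 4 reads behind either
allele is demoted to missing, and the site is dropped if no non-
reference allele remains observed. Indels are dropped for caller
quality < 20, reference homopolymer longer than 10 bp, or indel length
over 5 bp; the two-reads-per-strand rule applies only when per-strand
counts exist (skipped with a warning otherwise). Filters are idempotent
and report per-criterion tallies. CNV regions from different samples
merge only on strict overlap (book-ended intervals stay separate).

## The simulator and its rescaling

Discrete generations, 2N haplotypes per diploid population, Poisson
crossovers per gamete, infinite-sites mutation on integer positions
(collisions redrawn), additive selection (fitness 1, 1+s/2, 1+s).
Demography: ancestral → (wild, domestic) → domestic splits into dairy,
cashmere and meat breeds; an optional hard sweep starts at the breed
split in one breed and is conditioned on fixation by resimulation
(populations exchange no migrants after a split, so conditioning
retries re-run only the swept population). Sequencing emulation: depth
~ Poisson(29) per sample-site, reads split Binomial(d, ½) between the
two haplotype alleles, each read miscalled to a uniform other base with
probability 0.001 (miscalls landing on unlisted bases leave the AD
counts). The callable mask punches random holes in the genome so that
callable-length normalization is genuinely exercised.

Simulating breed-scale effective sizes directly is not desk-feasible,
so the simulator works in rescaled units (the standard forward-in-time
device): with factor λ, population sizes shrink by λ while μ, r and s
grow by λ and epoch durations shrink by λ, preserving the
population-scaled compound parameters 4Nμ, 4Nr and 2Ns that the scan
statistics actually respond to. The frozen sweep-study condition
(`sweep_power_config`) is the λ ≈ 22 image of a domestication
scenario: real Ne ≈ 4,400 per breed, μ ≈ 1.3e-8 and r ≈ 9e-8 per bp
per generation, breed epochs of a few hundred generations, and a real
selection coefficient s = 0.1 — simulated as N = 200 ancestral / 400
per breed, μ = 2.8e-7, r = 2e-6, s = 2.2 on a 5-Mb chromosome with
three 5-animal breeds. An *unrescaled* s = 0.1 at N = 200 corresponds
to 2Ns ≈ 40 — a drift-dominated weak sweep that leaves almost no
footprint and that no windowed scan should be expected to find; the
rescaled condition is the faithful desk-scale image of the study
regime. The planted selected site sits at the center of its 100-kb
window (a site on a window boundary splits its footprint between two
windows and misstates any single-window recovery measure).

Burn-in is 500 generations from a monomorphic start (≈ 71% of
equilibrium diversity at 2N = 400; the scans compare windows against
each other, so the absolute diversity level is immaterial). The
desert-study condition (`desert_study_config`) is a neutral N = 100
genome with μ = 1.4e-6 and a finely holed mask (20% holes of mean
500 bp), giving ~15–25 SNPs per 10-kb window and essentially tie-free
SNP rates, so the decile rule is tested away from degenerate ties.

Under the generator's neutral uniform point-mutation model, the coding
NS/S ratio reflects codon structure alone (roughly 3–4 nonsynonymous
opportunities per synonymous one); real cohorts report NS/S near or
below 1 because purifying selection removes nonsynonymous variants, a
force the generator deliberately omits. The NS/S machinery is therefore
validated against an exhaustive-mutation oracle, not against a
real-data value.

**What the generator does not emulate:** alignment and variant-calling
artifacts (mapping bias, paralog collapse), indel/CNV mutational
processes (indel and CNV records are exercised through hand-built
fixtures instead), linkage maps with hotspots, migration/admixture
after splits, overlapping genes and isoform diversity, and X-vs-autosome
differences (one autosome-like chromosome). Passing tests therefore
demonstrate correctness of the statistics and rules on clean, truth-
known data — not robustness to real-data artifacts.

## Numerical and design choices

- All internal coordinates 0-based half-open; VCF/GFF3 shifted on
  read/write. One convention everywhere prevents off-by-one drift.
- Multi-allelic records are kept intact; biallelic-only operations skip
  them explicitly (splitting would distort the depth semantics Hp uses).
- Windows tile from coordinate 0 without overlap by default; the step
  is configurable where a sliding scan is wanted.
- Sample standard deviation (n−1) in every Z-transform; zero variance
  or fewer than 2 finite values is a contract error, not a NaN.
- Desert quantile: ceiling-rank selection, ties included; joining is
  order-independent and idempotent.
- EHH truncation at min EHH 0.05 and 1 Mb; trapezoid integration over
  physical bp; edge-undetermined cores skipped rather than integrated
  short (which would bias iHH downward near chromosome ends).
- The Hp fallback from read counts to genotype counts is per-site and
  logged once.
- Degenerate inputs: empty VCF bodies, windows with no SNPs, masks with
  no intervals on a chromosome, and all-missing sites are all defined
  (empty table, NaN window, zero overlap, excluded-and-tallied).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| desert window / step | 10 kb / 10 kb | SNP-rate bins |
| callable minimum | 1 kb | window QC threshold |
| desert quantile | 0.10 | lowest-decile seeding |
| join gap | ≤ 10 kb | desert joining |
| SAG overlap | > 0.30 | desert cover of gene span |
| large-desert cut | > 100 kb | reported subset; top-10 list |
| sweep window | 100 kb | Hp/Fst/XP-EHH bins |
| ZHp / ZFst cuts | −3 / +3 | DAG rule (OR, inclusive) |
| per-breed ZFst cut | +4 | TAG rule (AND with XP-EHH) |
| XP-EHH top fraction | 0.01 | TAG rule |
| min EHH / max extension | 0.05 / 1 Mb | EHH truncation |
| SNP min depth / het reads | 8 / 4 | depth filter |
| indel quality / homopolymer / length | 20 / 10 / 5 | indel filter |
| mean depth / base error | 29× / 0.001 | sequencing emulation |

## Known limitations

- With 50 windows on a 5-Mb genome, the top-1% XP-EHH set is a single
  window; sweep-recovery power is inherently sensitive to footprint
  spill into a neighboring window (~5–10% of replicates). Genome-scale
  data (25,000 windows, top-250 sets) does not share this quantization.
- Hudson Fst can be slightly negative for undifferentiated windows;
  values are reported unclamped (clamping is presentation-layer only).
- XP-EHH normalization is global, not frequency-binned; cores near
  fixation in the pooled panel are rare by construction but are not
  reweighted.
- The simulator's infinite-sites model emits strictly biallelic SNPs;
  multi-allelic handling is exercised only through file-format fixtures.
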