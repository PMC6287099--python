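"""SNP effect classification: intergenic / intronic / coding, and
synonymous vs nonsynonymous for coding changes, with NS/S spectra by MAF.

Coding effects are computed from the representative transcript's spliced
CDS; minus-strand genes are handled by reverse complement. Stop gains
and losses are folded into the nonsynonymous class (flagged), matching
the binary NS/S bookkeeping of resequencing surveys.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .errors import ContractError, DataError
from .io_formats import GeneModel, VariantSite, reverse_complement

INTERGENIC = "intergenic"
INTRONIC = "intronic"
SYNONYMOUS = "synonymous"
NONSYNONYMOUS = "nonsynonymous"
OTHER_CODING = "other-coding"
GENIC_NONCODING = "genic-noncoding"  # UTR/exonic non-coding, reported separately

_STOPS = set(standard_dna_table.stop_codons)


def _translate_codon(codon: str) -> str:
    if codon in _STOPS:
        return "*"
    return standard_dna_table.forward_table.get(codon, "X")


@dataclass
class EffectCall:
    chrom: str
    pos: int
    category: str
    gene_id: str | None = None
    codon_ref: str | None = None
    codon_alt: str | None = None
    aa_ref: str | None = None
    aa_alt: str | None = None
    stop_change: bool = False


class GeneIndex:
    """Interval lookup of gene models per chromosome."""

    def __init__(self, genes):
        from intervaltree import IntervalTree

        self._trees: dict = {}
        for g in genes:
            self._trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g)

    def overlapping(self, chrom: str, start: int, end: int | None = None):
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = tree.overlap(start, end) if end is not None else tree.at(start)
        return sorted((h.data for h in hits), key=lambda g: (g.start, g.gene_id))


def classify_effect(
    site: VariantSite, genes, reference: dict
) -> EffectCall:
    """Classify one biallelic SNP against gene models and the reference.

    ``genes`` may be a list of GeneModel or a prebuilt GeneIndex.
    Raises DataError when the reference base disagrees with the site's
    ref allele. A SNP whose codon is truncated by a contig edge or a
    partial CDS is classified ``other-coding``.
    """
    if not site.is_biallelic_snp:
        raise ContractError(f"classify_effect needs a biallelic SNP, got {site.kind}")
    chrom_seq = reference[site.chrom]
    if chrom_seq[site.pos].upper() != site.ref:
        raise DataError(
            f"reference base {chrom_seq[site.pos]!r} != VCF ref {site.ref!r} "
            f"at {site.chrom}:{site.pos}"
        )
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    for gene in index.overlapping(site.chrom, site.pos):
        if gene.in_cds(site.pos):
            return _coding_effect(site, gene, chrom_seq)
        if gene.exons and gene.in_exon(site.pos):
            return EffectCall(site.chrom, site.pos, GENIC_NONCODING, gene.gene_id)
        return EffectCall(site.chrom, site.pos, INTRONIC, gene.gene_id)
    return EffectCall(site.chrom, site.pos, INTERGENIC)


def _coding_effect(site: VariantSite, gene: GeneModel, chrom_seq: str) -> EffectCall:
    cds_seq = gene.cds_sequence(chrom_seq).upper()
    cds_pos = gene.cds_coordinate(site.pos)
    codon_i = cds_pos // 3
    if gene.partial or (codon_i + 1) * 3 > len(cds_seq):
        return EffectCall(site.chrom, site.pos, OTHER_CODING, gene.gene_id)
    codon_ref = cds_seq[codon_i * 3 : codon_i * 3 + 3]
    within = cds_pos % 3
    base_alt = site.alts[0]
    if gene.strand == "-":
        base_alt = reverse_complement(base_alt)
    codon_alt = codon_ref[:within] + base_alt + codon_ref[within + 1 :]
    aa_ref, aa_alt = _translate_codon(codon_ref), _translate_codon(codon_alt)
    stop_change = (aa_ref == "*") != (aa_alt == "*")
    category = SYNONYMOUS if aa_ref == aa_alt else NONSYNONYMOUS
    return EffectCall(
        site.chrom, site.pos, category, gene.gene_id,
        codon_ref, codon_alt, aa_ref, aa_alt, stop_change,
    )


def classify_effects(table, genes, reference: dict) -> list:
    """Vector form of classify_effect over a table's biallelic SNPs."""
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    return [
        classify_effect(s, index, reference)
        for s in table.sites
        if s.is_biallelic_snp
    ]


def effects_to_frame(effects) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (e.chrom, e.pos, e.category, e.gene_id or "", e.aa_ref or "", e.aa_alt or "")
            for e in effects
        ],
        columns=["chrom", "pos", "category", "gene_id", "aa_ref", "aa_alt"],
    )


def category_totals(effects) -> dict:
    """Counts and the three-way partition fractions (coding = S + NS + other).

    genic-noncoding sites are tallied separately and excluded from the
    three-way fractions so the partition stays reproducible.
    """
    counts: dict = {}
    for e in effects:
        counts[e.category] = counts.get(e.category, 0) + 1
    coding = sum(counts.get(c, 0) for c in (SYNONYMOUS, NONSYNONYMOUS, OTHER_CODING))
    three_way_total = counts.get(INTERGENIC, 0) + counts.get(INTRONIC, 0) + coding
    out = {"counts": counts, "total": len(effects)}
    if three_way_total:
        out["fractions"] = {
            "intergenic": counts.get(INTERGENIC, 0) / three_way_total,
            "intronic": counts.get(INTRONIC, 0) / three_way_total,
            "coding": coding / three_way_total,
        }
    ns, s = counts.get(NONSYNONYMOUS, 0), counts.get(SYNONYMOUS, 0)
    out["ns_s"] = ns / s if s else None
    return out


def ns_s_spectrum(effects, summaries, bin_width: float = 0.05) -> pd.DataFrame:
    """NS/S counts and ratio per MAF bin over (0, 0.5], plus an overall row.

    ``summaries`` are SiteSummary records; effects and summaries are
    joined on (chrom, pos). Bins with zero synonymous counts report a
    ratio of NaN (undefined), never infinity.
    """
    maf_by_site = {(s.chrom, s.pos): s.maf for s in summaries}
    edges = np.arange(0.0, 0.5 + bin_width / 2, bin_width)
    rows = []
    ns_tot = s_tot = 0
    binned = {i: [0, 0] for i in range(len(edges) - 1)}
    for e in effects:
        if e.category not in (SYNONYMOUS, NONSYNONYMOUS):
            continue
        maf = maf_by_site.get((e.chrom, e.pos))
        if maf is None or maf <= 0:
            continue
        i = min(int(np.searchsorted(edges, maf, side="left")) - 1, len(edges) - 2)
        i = max(i, 0)
        if e.category == NONSYNONYMOUS:
            binned[i][0] += 1
            ns_tot += 1
        else:
            binned[i][1] += 1
            s_tot += 1
    for i in range(len(edges) - 1):
        ns, s = binned[i]
        rows.append((edges[i], edges[i + 1], ns, s, ns / s if s else np.nan))
    rows.append((0.0, 0.5, ns_tot, s_tot, ns_tot / s_tot if s_tot else np.nan))
    df = pd.DataFrame(rows, columns=["maf_low", "maf_high", "ns", "s", "ns_s"])
    df["bin"] = [f"({lo:.2f},{hi:.2f}]" for lo, hi in zip(df.maf_low, df.maf_high)]
    df.loc[df.index[-1], "bin"] = "overall"
    return df
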