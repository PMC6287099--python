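"""Variant filters and per-cohort summaries.

The SNP depth filter mirrors a resequencing-study convention: a locus is
kept only when read depth reaches 8 in the cohort's individuals, and a
heterozygous call needs at least 4 reads behind each allele. Indels are
filtered on caller quality, reference homopolymer context and length.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ContractError
from .io_formats import SNP, SampleGroups, VariantSite, VariantTable

log = logging.getLogger(__name__)


@dataclass
class FilterReport:
    """Per-criterion tallies of what a filter did."""

    counts: dict = field(default_factory=dict)

    def add(self, criterion: str, n: int = 1) -> None:
        self.counts[criterion] = self.counts.get(criterion, 0) + n

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            sorted(self.counts.items()), columns=["criterion", "count"]
        ).to_csv(path, sep="\t", index=False)


def _site_depths(site: VariantSite) -> list:
    """Summed read depth per sample; None where AD absent with genotype absent."""
    out = []
    for i, ad in enumerate(site.allele_depths):
        if ad is None:
            if site.genotypes[i] is not None:
                raise ContractError(
                    f"AD absent for genotyped sample index {i} at {site.chrom}:{site.pos}"
                )
            out.append(None)
        else:
            out.append(int(sum(ad)))
    return out


def filter_snps_by_depth(
    table: VariantTable,
    min_total_depth: int = 8,
    min_het_allele_reads: int = 4,
    depth_mode: str = "any",
) -> tuple[VariantTable, FilterReport]:
    """Depth-filter SNP sites; non-SNP records pass through untouched.

    ``depth_mode='any'`` (default, conservative) drops a site when ANY
    individual's summed depth is below ``min_total_depth``; ``'all'`` drops
    it only when every individual is. Heterozygous calls whose minor-read
    support is below ``min_het_allele_reads`` are demoted to missing; a
    site is then dropped if no non-reference allele remains observed.
    """
    if depth_mode not in ("any", "all"):
        raise ContractError(f"depth_mode must be 'any' or 'all', got {depth_mode!r}")
    report = FilterReport()
    kept = []
    for site in table.sites:
        if site.kind != SNP:
            kept.append(site)
            report.add("non_snp_passthrough")
            continue
        depths = _site_depths(site)
        observed = [d for d in depths if d is not None]
        if observed:
            low = [d < min_total_depth for d in observed]
            fail = any(low) if depth_mode == "any" else all(low)
        else:
            fail = True
        if fail:
            report.add("snp_removed_low_depth")
            continue
        genotypes = list(site.genotypes)
        demoted = 0
        for i, gt in enumerate(genotypes):
            if gt is None or gt[0] == gt[1]:
                continue
            ad = site.allele_depths[i]
            if min(ad[gt[0]], ad[gt[1]]) < min_het_allele_reads:
                genotypes[i] = None
                demoted += 1
        if demoted:
            report.add("het_calls_demoted", demoted)
        new_site = VariantSite(
            chrom=site.chrom, pos=site.pos, ref=site.ref, alts=site.alts,
            genotypes=genotypes, phased=list(site.phased),
            allele_depths=list(site.allele_depths), qual=site.qual,
            homopolymer_len=site.homopolymer_len, kind=site.kind,
            strand_support=site.strand_support,
        )
        if new_site.alt_allele_count() == 0:
            report.add("snp_removed_monomorphic_after_demotion")
            continue
        report.add("snp_retained")
        kept.append(new_site)
    return VariantTable(table.samples, kept), report


def filter_indels(
    table: VariantTable,
    max_len: int = 5,
    min_quality: float = 20,
    max_homopolymer: int = 10,
    require_strand_support: bool = True,
    min_strand_reads: int = 2,
) -> tuple[VariantTable, FilterReport]:
    """Drop indels failing quality/homopolymer/length rules.

    Boundaries follow the rules as stated: quality below ``min_quality``
    fails, homopolymer strictly longer than ``max_homopolymer`` fails,
    indel strictly longer than ``max_len`` fails. The two-reads-per-strand
    rule is applied only when per-strand counts are present; otherwise it
    is skipped once with a warning.
    """
    report = FilterReport()
    kept = []
    warned = False
    for site in table.sites:
        if site.kind not in ("insertion", "deletion"):
            kept.append(site)
            report.add("non_indel_passthrough")
            continue
        if site.qual is not None and site.qual < min_quality:
            report.add("indel_removed_low_quality")
            continue
        if site.homopolymer_len is not None and site.homopolymer_len > max_homopolymer:
            report.add("indel_removed_homopolymer")
            continue
        if site.indel_length() > max_len:
            report.add("indel_removed_too_long")
            continue
        if require_strand_support:
            if site.strand_support is None:
                if not warned:
                    log.warning("per-strand read counts absent; strand rule skipped")
                    warned = True
            elif min(site.strand_support) < min_strand_reads:
                report.add("indel_removed_strand_support")
                continue
        report.add("indel_retained")
        kept.append(site)
    return VariantTable(table.samples, kept), report


@dataclass
class SiteSummary:
    chrom: str
    pos: int
    maf: float
    monomorphic: bool
    group_alt_counts: dict       # group -> (alt alleles, called alleles)
    het_indicator: list          # per sample: True het / False hom / None missing


def site_summaries(
    table: VariantTable, groups: SampleGroups
) -> tuple[list, pd.DataFrame]:
    """Per-site MAF and group counts, plus per-individual heterozygosity.

    Only biallelic SNPs enter; sites with every genotype missing are
    excluded (tallied in the QC column of the returned frame). The
    per-individual heterozygosity fraction divides het calls by that
    individual's called (callable) sites.
    """
    groups.validate_against(table.samples)
    gidx = {label: [table.sample_index(n) for n in groups[label]] for label in groups.labels()}
    summaries = []
    n_samples = len(table.samples)
    het_counts = np.zeros(n_samples, dtype=np.int64)
    called_counts = np.zeros(n_samples, dtype=np.int64)
    n_all_missing = 0
    for site in table.sites:
        if not site.is_biallelic_snp:
            continue
        called = [gt for gt in site.genotypes if gt is not None]
        if not called:
            n_all_missing += 1
            continue
        alt = sum(a for gt in called for a in gt)
        total = 2 * len(called)
        p = alt / total
        maf = min(p, 1.0 - p)
        het = []
        for i, gt in enumerate(site.genotypes):
            if gt is None:
                het.append(None)
            else:
                is_het = gt[0] != gt[1]
                het.append(is_het)
                het_counts[i] += is_het
                called_counts[i] += 1
        group_counts = {}
        for label, idxs in gidx.items():
            g_alt = sum(a for i in idxs if site.genotypes[i] is not None for a in site.genotypes[i])
            g_tot = 2 * sum(1 for i in idxs if site.genotypes[i] is not None)
            group_counts[label] = (g_alt, g_tot)
        summaries.append(
            SiteSummary(site.chrom, site.pos, maf, alt in (0, total), group_counts, het)
        )
    with np.errstate(invalid="ignore"):
        frac = np.where(called_counts > 0, het_counts / np.maximum(called_counts, 1), np.nan)
    per_individual = pd.DataFrame(
        {
            "sample": table.samples,
            "het_sites": het_counts,
            "called_sites": called_counts,
            "het_fraction": frac,
            "sites_all_missing": n_all_missing,
        }
    )
    return summaries, per_individual


@dataclass
class CnvRegion:
    chrom: str
    start: int
    end: int
    sample: str
    state: str  # gain | loss

    def __post_init__(self):
        if self.start >= self.end:
            raise ContractError(f"empty CNV interval {self.chrom}:{self.start}-{self.end}")


def merge_cnv_regions(regions, cohort_size: int | None = None) -> pd.DataFrame:
    """Union strictly-overlapping CNV intervals across samples.

    Book-ended (adjacent) intervals are NOT merged. Each merged region
    lists supporting samples and their states; frequency = supporting
    samples / cohort size (default: distinct samples seen in the input).
    """
    if cohort_size is None:
        cohort_size = len({r.sample for r in regions}) or 1
    by_chrom: dict = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    rows = []
    for chrom in sorted(by_chrom):
        rs = sorted(by_chrom[chrom], key=lambda r: (r.start, r.end))
        cur = [rs[0]]
        cur_end = rs[0].end
        for r in rs[1:]:
            if r.start < cur_end:  # strict overlap only
                cur.append(r)
                cur_end = max(cur_end, r.end)
            else:
                rows.append(_cnv_row(chrom, cur, cohort_size))
                cur, cur_end = [r], r.end
        rows.append(_cnv_row(chrom, cur, cohort_size))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "samples", "states", "frequency"]
    )


def _cnv_row(chrom, members, cohort_size):
    samples = sorted({m.sample for m in members})
    states = ",".join(f"{m.sample}:{m.state}" for m in sorted(members, key=lambda m: (m.sample, m.start)))
    return (
        chrom,
        min(m.start for m in members),
        max(m.end for m in members),
        ",".join(samples),
        states,
        len(samples) / cohort_size,
    )
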