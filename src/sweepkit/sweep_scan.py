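"""Windowed sweep statistics and gene classification.

Pooled heterozygosity Hp is computed from pooled read counts:
Hp = 2*sum(nMAJ)*sum(nMIN) / (sum(nMAJ) + sum(nMIN))^2, where nMAJ/nMIN
are per-site read counts of the most/least abundant allele summed over
the pooled samples, and the outer sums run over SNPs in a 100-kb window.
Windowed Fst uses the Hudson estimator (ratio of averages) by default,
Weir-Cockerham optionally. Both are Z-transformed genome-wide; windows
with ZHp <= -3 OR ZFst >= 3 flag domestication-associated genes (DAGs),
and per-breed windows with ZFst >= 4 AND a top-1% XP-EHH flag
trait-associated genes (TAGs).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, ContractError
from .effect_annotation import GeneIndex
from .io_formats import SampleGroups, VariantTable

log = logging.getLogger(__name__)


def tile_windows(chrom_lengths: dict, window: int = 100_000, step: int | None = None) -> list:
    """(chrom, start, end) tiles from 0 per chromosome."""
    if window <= 0:
        raise ConfigError(f"window must be positive, got {window}")
    step = step or window
    out = []
    for chrom in sorted(chrom_lengths):
        for start in range(0, chrom_lengths[chrom], step):
            out.append((chrom, start, start + window))
    return out


def _pooled_site_counts(table: VariantTable, samples, use_depths: bool = True):
    """Per biallelic-SNP site: (chrom, pos, nMAJ, nMIN) over the pooled samples."""
    idx = [table.sample_index(s) for s in samples]
    warned = False
    rows = []
    for site in table.sites:
        if not site.is_biallelic_snp:
            continue
        c_ref = c_alt = 0
        if use_depths and all(site.allele_depths[i] is not None for i in idx):
            for i in idx:
                ad = site.allele_depths[i]
                c_ref += ad[0]
                c_alt += ad[1]
        else:
            if use_depths and not warned:
                log.warning("allele depths missing; Hp falls back to genotype allele counts")
                warned = True
            for i in idx:
                gt = site.genotypes[i]
                if gt is not None:
                    c_alt += (gt[0] > 0) + (gt[1] > 0)
                    c_ref += (gt[0] == 0) + (gt[1] == 0)
        rows.append((site.chrom, site.pos, max(c_ref, c_alt), min(c_ref, c_alt)))
    return rows


def pooled_heterozygosity(
    table: VariantTable, samples, windows, use_depths: bool = True
) -> np.ndarray:
    """Per-window Hp aligned with ``windows``; NaN where a window has no SNPs."""
    if not windows:
        raise ConfigError("window list is empty")
    counts = _pooled_site_counts(table, samples, use_depths)
    return _window_ratio(
        windows, counts,
        lambda maj, mi: 2.0 * maj * mi / (maj + mi) ** 2 if (maj + mi) > 0 else np.nan,
    )


def _window_ratio(windows, site_rows, combine):
    by_chrom: dict = {}
    for chrom, pos, a, b in site_rows:
        by_chrom.setdefault(chrom, []).append((pos, a, b))
    arrays = {}
    for chrom, rows in by_chrom.items():
        rows.sort()
        arrays[chrom] = (
            np.array([r[0] for r in rows], dtype=np.int64),
            np.array([r[1] for r in rows], dtype=np.float64),
            np.array([r[2] for r in rows], dtype=np.float64),
        )
    out = np.full(len(windows), np.nan)
    for wi, (chrom, start, end) in enumerate(windows):
        if chrom not in arrays:
            continue
        pos, a, b = arrays[chrom]
        lo, hi = np.searchsorted(pos, start), np.searchsorted(pos, end)
        if hi > lo:
            out[wi] = combine(float(a[lo:hi].sum()), float(b[lo:hi].sum()))
    return out


def hudson_fst_components(p1, n1, p2, n2):
    """Per-site numerator/denominator of the Hudson (1992) estimator.

    p are sample allele frequencies, n haplotype counts. The window value
    is sum(num)/sum(den) (ratio of averages).
    """
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def wc_fst_components(p1, n1d, h1, p2, n2d, h2):
    """Weir-Cockerham (1984) a and a+b+c variance components for two
    populations; n are diploid counts, h observed heterozygote frequencies."""
    r = 2.0
    n_bar = (n1d + n2d) / r
    n_c = (r * n_bar - (n1d**2 + n2d**2) / (r * n_bar)) / (r - 1)
    p_bar = (n1d * p1 + n2d * p2) / (r * n_bar)
    s2 = (n1d * (p1 - p_bar) ** 2 + n2d * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
    h_bar = (n1d * h1 + n2d * h2) / (r * n_bar)
    pq = p_bar * (1 - p_bar)
    a = (n_bar / n_c) * (s2 - (pq - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1))
    b = (n_bar / (n_bar - 1)) * (pq - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
    c = h_bar / 2
    return a, a + b + c


def fst_windows(
    table: VariantTable,
    group_a,
    group_b,
    windows,
    estimator: str = "hudson",
) -> np.ndarray:
    """Per-window Fst between two sample groups, aligned with ``windows``.

    Sites need >= 2 non-missing diploid calls per group; sites
    monomorphic across both groups are skipped. NaN where no usable site.
    """
    if estimator not in ("hudson", "wc"):
        raise ConfigError(f"unknown Fst estimator {estimator!r}")
    ia = [table.sample_index(s) for s in group_a]
    ib = [table.sample_index(s) for s in group_b]
    rows = []
    for site in table.sites:
        if not site.is_biallelic_snp:
            continue
        stats = []
        for idx in (ia, ib):
            gts = [site.genotypes[i] for i in idx if site.genotypes[i] is not None]
            if len(gts) < 2:
                break
            alt = sum(a for gt in gts for a in gt)
            n_hap = 2 * len(gts)
            het = sum(1 for gt in gts if gt[0] != gt[1]) / len(gts)
            stats.append((alt / n_hap, n_hap, het, len(gts)))
        if len(stats) < 2:
            continue
        (p1, n1, h1, n1d), (p2, n2, h2, n2d) = stats
        if p1 == p2 and p1 in (0.0, 1.0):
            continue
        if estimator == "hudson":
            num, den = hudson_fst_components(p1, n1, p2, n2)
        else:
            num, den = wc_fst_components(p1, n1d, h1, p2, n2d, h2)
        rows.append((site.chrom, site.pos, num, den))
    return _window_ratio(
        windows, rows, lambda num, den: num / den if den != 0 else np.nan
    )


def z_transform(values) -> np.ndarray:
    """(x - mean) / sd with the sample (n-1) standard deviation.

    NaN entries are ignored for the moments and stay NaN in the output.
    """
    x = np.asarray(values, dtype=np.float64)
    finite = x[np.isfinite(x)]
    if finite.size < 2:
        raise ContractError("z_transform needs >= 2 finite values")
    sd = float(np.std(finite, ddof=1))
    if sd == 0:
        raise ContractError("z_transform: zero variance")
    return (x - float(np.mean(finite))) / sd


@dataclass
class SweepCall:
    chrom: str
    start: int
    end: int
    kind: str                     # "DAG-candidate" | "TAG-candidate"
    rules: list = field(default_factory=list)
    genes: list = field(default_factory=list)

    def __post_init__(self):
        if not self.rules:
            raise ContractError("a sweep call must list at least one triggering rule")


def _genes_in(index: GeneIndex, chrom, start, end):
    return [g.gene_id for g in index.overlapping(chrom, start, end)]


def classify_dags(
    window_stats: pd.DataFrame,
    genes,
    zhp_cut: float = -3.0,
    zfst_cut: float = 3.0,
    sag_gene_sets: dict | None = None,
) -> tuple[list, pd.DataFrame]:
    """Flag windows with zhp <= zhp_cut OR zfst >= zfst_cut; a DAG is any
    gene overlapping a flagged window.

    ``window_stats`` needs columns chrom/start/end/zhp/zfst. When
    ``sag_gene_sets`` (label -> set of gene ids) is given, each DAG row
    reports which SAG sets contain it.
    """
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    calls = []
    gene_rows: dict = {}
    for row in window_stats.itertuples():
        rules = []
        if np.isfinite(row.zhp) and row.zhp <= zhp_cut:
            rules.append(f"zhp<={zhp_cut}")
        if np.isfinite(row.zfst) and row.zfst >= zfst_cut:
            rules.append(f"zfst>={zfst_cut}")
        if not rules:
            continue
        hit_genes = _genes_in(index, row.chrom, row.start, row.end)
        calls.append(SweepCall(row.chrom, row.start, row.end, "DAG-candidate", rules, hit_genes))
        for gid in hit_genes:
            gene_rows.setdefault(gid, set()).update(rules)
    rows = []
    for gid in sorted(gene_rows):
        in_sags = sorted(
            label for label, s in (sag_gene_sets or {}).items() if gid in s
        )
        rows.append((gid, ",".join(sorted(gene_rows[gid])), ",".join(in_sags)))
    return calls, pd.DataFrame(rows, columns=["gene_id", "rules", "sag_sets"])


def top_fraction_threshold(values: np.ndarray, frac: float) -> tuple[float, int]:
    """Value of the k-th largest score with k = ceil(frac * n_scored)."""
    finite = np.sort(values[np.isfinite(values)])[::-1]
    if finite.size == 0:
        raise ContractError("no scored windows for top-fraction ranking")
    k = max(1, math.ceil(frac * finite.size))
    return float(finite[k - 1]), k


def classify_tags(
    window_stats: pd.DataFrame,
    genes,
    zfst_cut: float = 4.0,
    xpehh_top_frac: float = 0.01,
) -> tuple[list, pd.DataFrame]:
    """Per-breed TAG rule: zfst >= cut AND window XP-EHH in the top 1%.

    ``window_stats`` needs chrom/start/end/zfst/xpehh (xpehh NaN where the
    window had no scored core; such windows are excluded from ranking).
    The top set is exactly k = ceil(frac * scored) windows, ties broken
    by genomic position, so the flagged fraction never exceeds k.
    """
    if "xpehh" not in window_stats.columns:
        raise ContractError(
            "window XP-EHH column absent; run the haplotype_ehh scan "
            "(xpehh_scan + window_xpehh) before classify_tags"
        )
    xp = window_stats["xpehh"].to_numpy(dtype=np.float64)
    _, k = top_fraction_threshold(xp, xpehh_top_frac)
    scored = window_stats[np.isfinite(xp)]
    top = scored.sort_values(
        ["xpehh", "chrom", "start"], ascending=[False, True, True], kind="mergesort"
    ).head(k)
    top_keys = {(r.chrom, r.start) for r in top.itertuples()}
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    calls = []
    gene_ids = set()
    for row in window_stats.itertuples():
        if not (np.isfinite(row.zfst) and row.zfst >= zfst_cut):
            continue
        if (row.chrom, row.start) not in top_keys:
            continue
        hit = _genes_in(index, row.chrom, row.start, row.end)
        calls.append(
            SweepCall(
                row.chrom, row.start, row.end, "TAG-candidate",
                [f"zfst>={zfst_cut}", f"xpehh_top_{xpehh_top_frac:g}"], hit,
            )
        )
        gene_ids.update(hit)
    return calls, pd.DataFrame({"gene_id": sorted(gene_ids)})


def crossref_qtl(genes, qtl_intervals: pd.DataFrame) -> pd.DataFrame:
    """Per gene, the overlapping QTL interval names (same chromosome,
    nonzero genomic overlap)."""
    from intervaltree import IntervalTree

    trees: dict = {}
    for chrom, start, end, name in qtl_intervals[["chrom", "start", "end", "name"]].itertuples(index=False):
        trees.setdefault(chrom, IntervalTree()).addi(start, end, name)
    rows = []
    for g in genes:
        tree = trees.get(g.chrom)
        hits = sorted(h.data for h in tree.overlap(g.start, g.end)) if tree else []
        rows.append((g.gene_id, ",".join(str(h) for h in hits), len(hits)))
    return pd.DataFrame(rows, columns=["gene_id", "qtl_ids", "n_qtl"])


def shared_genes(set_a, set_b) -> list:
    """Sorted intersection helper for SAG/DAG/TAG/QTL set comparisons."""
    return sorted(set(set_a) & set(set_b))
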