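"""SNP-desert detection.

SNP rates are computed in fixed genomic windows and normalized by the
callable (>=8-fold aligned) length inside each window, not the window
span; windows with under 1 kb of callable sequence are rejected. Windows
in the lowest decile of rates seed deserts, and seeds separated by at
most 10 kb are joined into longer regions. Genes more than 30% covered
by deserts are SNP-desert-associated genes (SAGs).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, ContractError
from .io_formats import SNP, CallableMask, VariantTable

log = logging.getLogger(__name__)

MIN_CALLABLE_BP = 1_000


@dataclass
class GenomicWindow:
    chrom: str
    start: int
    end: int
    callable_bp: int
    n_snps: int
    qc_pass: bool
    snp_rate: float | None  # per callable bp; None when qc fails

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class DesertRegion:
    chrom: str
    start: int
    end: int
    windows: list = field(default_factory=list)
    mean_rate: float = 0.0

    @property
    def length(self) -> int:
        return self.end - self.start


def snp_rate_windows(
    table: VariantTable,
    mask: CallableMask,
    window: int = 10_000,
    step: int = 10_000,
    chrom_lengths: dict | None = None,
) -> list:
    """Tile each chromosome from 0 and rate = SNPs / callable bp.

    Chromosome extents default to the larger of the mask end and the last
    SNP position + 1. A window passes QC only with >= 1 kb callable.
    """
    if window <= 0 or step <= 0:
        raise ConfigError(f"window and step must be positive (got {window}, {step})")
    snp_pos: dict = {}
    for site in table.sites:
        if site.kind == SNP:
            snp_pos.setdefault(site.chrom, []).append(site.pos)
    chroms = sorted(set(snp_pos) | set(mask.chroms()) | set(chrom_lengths or {}))
    windows = []
    for chrom in chroms:
        positions = np.asarray(sorted(snp_pos.get(chrom, [])), dtype=np.int64)
        extent = max(
            mask.end(chrom),
            int(positions[-1]) + 1 if len(positions) else 0,
            (chrom_lengths or {}).get(chrom, 0),
        )
        for start in range(0, extent, step):
            end = start + window
            callable_bp = mask.overlap_length(chrom, start, end)
            n = int(np.searchsorted(positions, end) - np.searchsorted(positions, start))
            ok = callable_bp >= MIN_CALLABLE_BP
            windows.append(
                GenomicWindow(
                    chrom, start, end, callable_bp, n, ok,
                    (n / callable_bp) if ok else None,
                )
            )
    return windows


def desert_rate_threshold(windows, quantile: float = 0.10) -> tuple[float, list]:
    """Empirical lower-quantile threshold by ceiling-rank selection.

    Returns (threshold, qc-passing windows). Ties at the threshold are
    all included downstream.
    """
    passing = [w for w in windows if w.qc_pass]
    if len(passing) < 10:
        raise ContractError(f"need >= 10 qc-passing windows, got {len(passing)}")
    rates = sorted(w.snp_rate for w in passing)
    k = max(1, math.ceil(quantile * len(rates)))
    return rates[k - 1], passing


def call_deserts(
    windows, quantile: float = 0.10, join_gap: int = 10_000
) -> list:
    """Seed = qc-passing window with rate <= lowest-``quantile`` threshold;
    seeds on a chromosome are joined while inter-seed gaps are <= ``join_gap``.

    Desert length spans end-start of the joined region (gaps included).
    Returns an empty list with a warning when no window passes QC.
    """
    if not any(w.qc_pass for w in windows):
        log.warning("all windows failed QC; no deserts callable")
        return []
    threshold, passing = desert_rate_threshold(windows, quantile)
    seeds = [w for w in passing if w.snp_rate <= threshold]
    seeds.sort(key=lambda w: (w.chrom, w.start))
    regions = []
    current = [seeds[0]]
    for w in seeds[1:]:
        prev = current[-1]
        if w.chrom == prev.chrom and w.start - prev.end <= join_gap:
            current.append(w)
        else:
            regions.append(_region(current))
            current = [w]
    regions.append(_region(current))
    return regions


def _region(members) -> DesertRegion:
    return DesertRegion(
        chrom=members[0].chrom,
        start=members[0].start,
        end=members[-1].end,
        windows=list(members),
        mean_rate=float(np.mean([w.snp_rate for w in members])),
    )


def classify_sags(
    deserts, genes, min_overlap_frac: float = 0.30
) -> pd.DataFrame:
    """Per-gene desert coverage; SAG iff covered fraction strictly > 30%.

    The denominator is the full gene span, introns included.
    """
    desert_mask = CallableMask.from_intervals(
        (d.chrom, d.start, d.end) for d in deserts
    ) if deserts else CallableMask({})
    rows = []
    for g in genes:
        covered = desert_mask.overlap_length(g.chrom, g.start, g.end)
        frac = covered / g.span_length() if g.span_length() else 0.0
        rows.append((g.gene_id, g.chrom, g.start, g.end, covered, frac, frac > min_overlap_frac))
    return pd.DataFrame(
        rows,
        columns=["gene_id", "chrom", "start", "end", "desert_bp", "overlap_frac", "is_sag"],
    )


def large_deserts(deserts, min_length: int = 100_000) -> list:
    """The > ``min_length`` subset (strictly longer)."""
    return [d for d in deserts if d.length > min_length]


def top_deserts(deserts, k: int = 10) -> list:
    """The k largest deserts by genomic length (ties by position)."""
    return sorted(deserts, key=lambda d: (-d.length, d.chrom, d.start))[:k]


def windows_to_frame(windows) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (w.chrom, w.start, w.end, w.callable_bp, w.n_snps, w.qc_pass,
             w.snp_rate if w.snp_rate is not None else np.nan)
            for w in windows
        ],
        columns=["chrom", "start", "end", "callable_bp", "n_snps", "qc_pass", "snp_rate"],
    )


def deserts_to_frame(deserts) -> pd.DataFrame:
    return pd.DataFrame(
        [(d.chrom, d.start, d.end, d.length, len(d.windows), d.mean_rate) for d in deserts],
        columns=["chrom", "start", "end", "length", "n_windows", "mean_rate"],
    )
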