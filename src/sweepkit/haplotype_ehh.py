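"""Extended haplotype homozygosity (EHH), iHH and cross-population XP-EHH.

EHH at a flanking site x is the probability that two haplotypes drawn at
random from the panel are identical over all sites between the core and
x: EHH(x) = sum_h C(n_h, 2) / C(n, 2) over the haplotype identity groups
h. Groups are formed over ALL haplotypes of a panel (the combined-core
convention used by cross-population comparisons), so EHH at the core
itself is 1. iHH integrates the EHH decay curve over physical distance
by trapezoids, left plus right; XP-EHH is ln(iHH_focal / iHH_reference)
at each usable core, normalized genome-wide to mean 0 and sd 1. Positive
normalized scores mean longer haplotypes, hence a more recent/stronger
sweep, in the focal population.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ContractError
from .io_formats import VariantTable

MIN_EHH = 0.05
MAX_EXTENSION_BP = 1_000_000


@dataclass
class HaplotypePanel:
    """Phased binary allele matrix (haplotypes x sites) for one population."""

    label: str
    positions: np.ndarray        # strictly increasing, 0-based bp
    haplotypes: np.ndarray       # (n_hap, n_sites) in {0, 1}
    map_cm: np.ndarray | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[1] != self.positions.size:
            raise ContractError("haplotype matrix shape does not match positions")
        if self.n_hap < 4:
            raise ContractError(f"need >= 4 haplotypes, got {self.n_hap}")
        if np.any(np.diff(self.positions) <= 0):
            raise ContractError("positions must be strictly increasing")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ContractError("panel must be biallelic 0/1 with no missing alleles")

    @property
    def n_hap(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.positions.size

    def polymorphic(self) -> np.ndarray:
        counts = self.haplotypes.sum(axis=0)
        return (counts > 0) & (counts < self.n_hap)


def panel_from_table(
    table: VariantTable, samples, label: str, chrom: str | None = None
) -> HaplotypePanel:
    """Build a panel from phased biallelic SNP genotypes.

    Sites with any missing or unphased genotype among the chosen samples
    are excluded upstream of the EHH math, as are non-SNP records.
    """
    idx = [table.sample_index(s) for s in samples]
    positions, columns = [], []
    for site in table.sites:
        if chrom is not None and site.chrom != chrom:
            continue
        if not site.is_biallelic_snp:
            continue
        gts = [site.genotypes[i] for i in idx]
        if any(g is None for g in gts):
            continue
        if any(g[0] != g[1] and not site.phased[i] for i, g in zip(idx, gts)):
            raise ContractError(f"unphased heterozygote at {site.chrom}:{site.pos}")
        positions.append(site.pos)
        columns.append([a for g in gts for a in g])
    return HaplotypePanel(
        label, np.asarray(positions, dtype=np.int64),
        np.asarray(columns, dtype=np.int8).T.copy() if columns else np.zeros((2 * len(idx), 0), np.int8),
    )


def paired_panels(
    table: VariantTable, samples_a, samples_b, label_a: str, label_b: str,
    chrom: str | None = None,
) -> tuple["HaplotypePanel", "HaplotypePanel"]:
    """Two panels over the shared site set: biallelic SNPs fully called
    (and phased) in BOTH sample groups, so positions line up for XP-EHH."""
    ia = [table.sample_index(s) for s in samples_a]
    ib = [table.sample_index(s) for s in samples_b]
    keep = []
    for site in table.sites:
        if chrom is not None and site.chrom != chrom:
            continue
        if not site.is_biallelic_snp:
            continue
        if all(site.genotypes[i] is not None for i in ia + ib):
            keep.append(site)
    sub = VariantTable(table.samples, keep)
    return (
        panel_from_table(sub, samples_a, label_a, chrom),
        panel_from_table(sub, samples_b, label_b, chrom),
    )


@dataclass
class EhhProfile:
    core_index: int
    left_dist: np.ndarray        # bp from core, increasing, starts at 0
    left_ehh: np.ndarray         # EHH at those distances, starts at 1
    right_dist: np.ndarray
    right_ehh: np.ndarray
    edge_truncated: bool         # ran off the data before decaying

    @property
    def ihh(self) -> float:
        return self.ihh_left + self.ihh_right

    @property
    def ihh_left(self) -> float:
        return float(np.trapezoid(self.left_ehh, self.left_dist))

    @property
    def ihh_right(self) -> float:
        return float(np.trapezoid(self.right_ehh, self.right_dist))


def _homozygosity(labels: np.ndarray) -> float:
    n = labels.size
    counts = np.bincount(labels)
    return float((counts * (counts - 1)).sum() / (n * (n - 1)))


def ehh_profile(
    panel: HaplotypePanel,
    core_index: int,
    min_ehh: float = MIN_EHH,
    max_extension_bp: int = MAX_EXTENSION_BP,
) -> EhhProfile:
    """EHH decay outward from a core site, truncated at ``min_ehh`` or
    ``max_extension_bp``; flags cores whose EHH never decayed before the
    panel's first/last site (chromosome-edge bias)."""
    if not 0 <= core_index < panel.n_sites:
        raise ContractError(f"core index {core_index} out of range")
    core_pos = int(panel.positions[core_index])
    edge = False
    curves = []
    for direction in (-1, +1):
        dists, ehhs = [0.0], [1.0]
        labels = np.zeros(panel.n_hap, dtype=np.int64)
        j = core_index
        decayed = False
        while True:
            j += direction
            if j < 0 or j >= panel.n_sites:
                break
            dist = abs(int(panel.positions[j]) - core_pos)
            if dist > max_extension_bp:
                decayed = True  # capped, not an edge artifact
                break
            col = panel.haplotypes[:, j]
            pair = labels * 2 + col
            counts = np.bincount(pair)
            e = float((counts * (counts - 1)).sum()) / (panel.n_hap * (panel.n_hap - 1))
            # compact relabel keeps pair values bounded across steps
            remap = np.cumsum(counts > 0) - 1
            labels = remap[pair]
            dists.append(float(dist))
            ehhs.append(e)
            if e < min_ehh:
                decayed = True
                break
        if not decayed:
            edge = True
        curves.append((np.asarray(dists), np.asarray(ehhs)))
    (ld, le), (rd, re) = curves
    return EhhProfile(core_index, ld, le, rd, re, edge)


@dataclass
class XpehhScore:
    chrom: str
    pos: int
    raw: float
    normalized: float = np.nan


def xpehh_scan(
    panel_focal: HaplotypePanel,
    panel_reference: HaplotypePanel,
    chrom: str = "chr1",
    min_ehh: float = MIN_EHH,
    max_extension_bp: int = MAX_EXTENSION_BP,
) -> tuple[list, dict]:
    """XP-EHH at every core polymorphic in the pooled panels.

    Panels must share positions. Cores where either panel's profile is
    edge-truncated or has zero iHH are skipped (tallied). Scores are
    normalized to mean 0, sd 1 over the scanned cores.
    """
    if panel_focal.n_sites != panel_reference.n_sites or np.any(
        panel_focal.positions != panel_reference.positions
    ):
        raise ContractError("panels must share site positions")
    pooled = np.vstack([panel_focal.haplotypes, panel_reference.haplotypes])
    counts = pooled.sum(axis=0)
    usable = np.flatnonzero((counts > 0) & (counts < pooled.shape[0]))
    scores: list = []
    tally = {"cores": int(usable.size), "skipped_edge": 0, "skipped_zero_ihh": 0}
    for core in usable:
        pf = ehh_profile(panel_focal, int(core), min_ehh, max_extension_bp)
        pr = ehh_profile(panel_reference, int(core), min_ehh, max_extension_bp)
        if pf.edge_truncated or pr.edge_truncated:
            tally["skipped_edge"] += 1
            continue
        if pf.ihh == 0 or pr.ihh == 0:
            tally["skipped_zero_ihh"] += 1
            continue
        scores.append(
            XpehhScore(chrom, int(panel_focal.positions[core]), float(np.log(pf.ihh / pr.ihh)))
        )
    if not scores:
        raise ContractError("no usable XP-EHH cores (all skipped)")
    raw = np.array([s.raw for s in scores])
    if raw.size >= 2 and np.std(raw, ddof=1) > 0:
        norm = (raw - raw.mean()) / np.std(raw, ddof=1)
    else:
        norm = np.zeros_like(raw)
    for s, z in zip(scores, norm):
        s.normalized = float(z)
    return scores, tally


def window_xpehh(scores, windows, aggregate: str = "max") -> np.ndarray:
    """Per-window aggregate of normalized XP-EHH, aligned with
    ``windows`` [(chrom, start, end)]; NaN for windows without cores."""
    if aggregate not in ("max", "mean"):
        raise ContractError(f"unknown aggregate {aggregate!r}")
    agg = np.max if aggregate == "max" else np.mean
    by_chrom: dict = {}
    for s in scores:
        by_chrom.setdefault(s.chrom, []).append((s.pos, s.normalized))
    arrays = {
        c: (np.array([p for p, _ in sorted(v)]), np.array([z for _, z in sorted(v)]))
        for c, v in by_chrom.items()
    }
    out = np.full(len(windows), np.nan)
    for wi, (chrom, start, end) in enumerate(windows):
        if chrom not in arrays:
            continue
        pos, z = arrays[chrom]
        lo, hi = np.searchsorted(pos, start), np.searchsorted(pos, end)
        if hi > lo:
            out[wi] = float(agg(z[lo:hi]))
    return out


def scores_to_frame(scores) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.chrom, s.pos, s.raw, s.normalized) for s in scores],
        columns=["chrom", "pos", "raw", "normalized"],
    )
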