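"""Forward-time Wright-Fisher cohort simulator.

Generates every input the scan pipeline consumes — phased VCF with
allelic depths, callable-mask BED, gene models (GFF3 + FASTA reference),
QTL BED and a sample->group table — with known ground truth.

The model: discrete non-overlapping generations, 2N haplotypes per
diploid population, per-offspring Poisson crossovers and infinite-sites
mutation on integer positions (collisions redrawn). Selection is
additive on a single site (fitness 1, 1+s/2, 1+s). The demography
emulates a domestication cohort: an ancestral population splits into a
wild and a domestic line, and the domestic line later splits into three
breeds (dairy, cashmere, meat); an optional hard sweep runs in one breed
from the breed split onward, conditioned on fixation by resimulation.
Because populations exchange no migrants after a split, each epoch is
evolved per population independently; conditioning retries therefore
re-run only the swept population. Sequencing is emulated per sample and
site: total depth ~ Poisson(mean_depth), reads split evenly between the
two haplotype alleles, and each read miscalled to a uniformly random
other base with probability base_error (reads landing on unlisted bases
drop out of the AD counts).

The reference sequence plays the ancestral allele at every site, so
mutations fixed cohort-wide appear as ALT-fixed records.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numba
import numpy as np

from .errors import ConfigError, SweepkitError
from .io_formats import (
    CallableMask,
    GeneModel,
    SampleGroups,
    VariantSite,
    VariantTable,
    reverse_complement,
    write_fasta,
    write_gff3,
)

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS and a + b + c != "ATG"
]

BREEDS = ("dairy", "cashmere", "meat")


@dataclass
class SimConfig:
    """Simulation parameters, in rescaled (desk-scale) units.

    Populations of a few hundred stand in for breed effective sizes in
    the thousands via the standard forward-simulation rescaling: with
    factor lambda, mu, r and s are multiplied by lambda and epoch
    durations divided by it, preserving 4*N*mu, 4*N*r and 2*N*s. The
    defaults encode lambda ~ 22 applied to a domestication scenario
    (real Ne ~ 4,400, mu ~ 1.3e-8, r ~ 9e-8 per bp, breed epochs of a
    few hundred generations).
    """

    seed: int = 0
    chrom: str = "chr1"
    chrom_length: int = 5_000_000
    mu: float = 2.8e-7               # per bp per generation (rescaled)
    rec_rate: float = 2e-6           # per bp per generation (rescaled)
    n_ancestral: int = 200
    n_wild: int = 200
    n_domestic: int = 400
    n_breed: int = 400
    burnin_generations: int = 500
    domestic_generations: int = 150
    breed_generations: int = 25
    s: float = 0.0                   # rescaled; 2.2 ~ real s = 0.1 at lambda = 22
    selected_pos: int | None = None  # default: center of the middle 100-kb window
    sweep_population: str = "dairy"
    condition_on_fixation: bool = True
    max_retries: int = 200
    sample_sizes: dict = field(
        default_factory=lambda: {"dairy": 5, "cashmere": 5, "meat": 5, "wild": 4}
    )
    mean_depth: float = 29.0
    base_error: float = 0.001
    n_genes: int = 30
    n_sweep_genes: int = 2
    n_qtl: int = 8
    mask_hole_fraction: float = 0.10
    mask_hole_mean_len: int = 2_000

    def validate(self) -> None:
        if min(self.mu, self.rec_rate, self.s, self.mean_depth) < 0:
            raise ConfigError("rates, s and mean_depth must be >= 0")
        if not 0 <= self.base_error < 0.25:
            raise ConfigError("base_error must be in [0, 0.25)")
        if self.chrom_length <= 0:
            raise ConfigError("chrom_length must be positive")
        pop_of = {"wild": self.n_wild, **{b: self.n_breed for b in BREEDS}}
        for name, n in self.sample_sizes.items():
            if name not in pop_of:
                raise ConfigError(f"unknown sampled population {name!r}")
            if n > pop_of[name]:
                raise ConfigError(f"sample size {n} exceeds population {name} size")
        if self.s > 0 and self.sweep_population not in BREEDS:
            raise ConfigError("sweep_population must be one of the breeds")



def default_selected_pos(chrom_length: int, window: int = 100_000) -> int:
    """Center of the 100-kb window nearest the chromosome midpoint, so a
    planted sweep's footprint concentrates in one scan window instead of
    straddling a window boundary."""
    mid = chrom_length // 2
    return (mid // window) * window + window // 2


class _Pop:
    """One population's haplotypes over its own segregating columns."""

    __slots__ = ("haps", "positions", "fixed")

    def __init__(self, n_hap: int):
        self.haps = np.zeros((n_hap, 0), dtype=np.int8)
        self.positions = np.zeros(0, dtype=np.int64)
        self.fixed: set = set()

    def copy(self) -> "_Pop":
        p = _Pop(self.haps.shape[0])
        p.haps = self.haps.copy()
        p.positions = self.positions.copy()
        p.fixed = set(self.fixed)
        return p

    def freq_at(self, pos: int) -> float:
        if pos in self.fixed:
            return 1.0
        hit = np.flatnonzero(self.positions == pos)
        if hit.size == 0:
            return 0.0
        return float(self.haps[:, hit[0]].mean())

    def compact(self) -> None:
        if self.haps.shape[1] == 0:
            return
        freq = self.haps.sum(axis=0)
        n = self.haps.shape[0]
        fixed_cols = np.flatnonzero(freq == n)
        self.fixed.update(int(p) for p in self.positions[fixed_cols])
        keep = np.flatnonzero((freq > 0) & (freq < n))
        self.haps = self.haps[:, keep]
        self.positions = self.positions[keep]


@numba.njit(cache=True)
def _crossover_segments(out, haps, rows_b, bnd, offs, S):  # pragma: no cover - jit
    """Overwrite the odd crossover segments of each pre-copied gamete row
    with the other parental chromosome (bnd holds sorted-on-the-fly
    breakpoint column indices per gamete via offs)."""
    for o in range(offs.size - 1):
        lo_off, hi_off = offs[o], offs[o + 1]
        k = hi_off - lo_off
        if k == 0:
            continue
        b = np.sort(bnd[lo_off:hi_off])
        rb = rows_b[o]
        for j in range(0, k, 2):
            lo = b[j]
            hi = b[j + 1] if j + 1 < k else S
            for t in range(lo, hi):
                out[o, t] = haps[rb, t]


def _draw_positions(rng, count: int, length: int, used: set, journal=None) -> np.ndarray:
    out = []
    while len(out) < count:
        for p in rng.integers(0, length, size=count - len(out)):
            p = int(p)
            if p not in used:
                used.add(p)
                out.append(p)
    if journal is not None:
        journal.extend(out)
    return np.asarray(out, dtype=np.int64)


def _evolve(
    pop: _Pop,
    n_diploid: int,
    generations: int,
    cfg: SimConfig,
    rng,
    used: set,
    selected_pos: int | None = None,
    s: float = 0.0,
    stop_if_lost: bool = False,
    journal=None,
) -> bool:
    """Evolve ``pop`` for ``generations``; offspring count is 2*n_diploid.

    Returns False if the selected allele was lost and stop_if_lost is set.
    """
    L = cfg.chrom_length
    xover_rate = cfg.rec_rate * L
    n_off = 2 * n_diploid
    for gen in range(generations):
        n_parent_dip = pop.haps.shape[0] // 2
        S = pop.haps.shape[1]
        # fitness-weighted parent choice (additive: 1, 1+s/2, 1+s)
        if selected_pos is not None and s > 0:
            sel_col = np.flatnonzero(pop.positions == selected_pos)
            if sel_col.size:
                cnt = pop.haps[0::2, sel_col[0]] + pop.haps[1::2, sel_col[0]]
                w = 1.0 + (s / 2.0) * cnt
                probs = w / w.sum()
            elif selected_pos in pop.fixed:
                probs = None
            else:
                if stop_if_lost:
                    return False
                probs = None
        else:
            probs = None
        parents = rng.choice(n_parent_dip, size=(n_diploid, 2), p=probs)
        starts = rng.integers(0, 2, size=(n_diploid, 2))
        n_xo = rng.poisson(xover_rate, size=(n_diploid, 2))
        n_mut = int(rng.poisson(n_off * cfg.mu * L))
        new_pos = _draw_positions(rng, n_mut, L, used, journal) if n_mut else np.zeros(0, np.int64)
        mut_rows = rng.integers(0, n_off, size=n_mut) if n_mut else None

        next_haps = np.empty((n_off, S + n_mut), dtype=np.int8)
        if n_mut:
            next_haps[:, S:] = 0
        rows_a = (2 * parents + starts).ravel()        # starting chromosome per gamete
        rows_b = (2 * parents + 1 - starts).ravel()
        k_flat = n_xo.ravel().astype(np.int64)
        if S == 0:
            k_flat[:] = 0
        # positions are kept sorted, so a crossover gamete is a few slice
        # copies; breakpoints for the whole generation are mapped to column
        # indices with one searchsorted, assembly is a jitted kernel
        total_k = int(k_flat.sum())
        bnd = np.searchsorted(pop.positions, rng.uniform(0, L, total_k)) if total_k else np.zeros(0, np.int64)
        offs = np.concatenate([[0], np.cumsum(k_flat)])
        next_haps[:, :S] = pop.haps[rows_a]
        _crossover_segments(next_haps, pop.haps, rows_b, bnd.astype(np.int64), offs, S)
        if n_mut:
            next_haps[mut_rows, S + np.arange(n_mut)] = 1
            positions = np.concatenate([pop.positions, new_pos])
            order = np.argsort(positions, kind="stable")
            pop.positions = positions[order]
            pop.haps = next_haps[:, order]
        else:
            pop.haps = next_haps
        if selected_pos is not None and s > 0 and stop_if_lost:
            if pop.freq_at(selected_pos) == 0.0:
                return False
        if gen % 5 == 4 or gen == generations - 1:
            pop.compact()
    return True


@dataclass
class SimTruth:
    """Ground truth of one simulated cohort."""

    config: SimConfig
    positions: np.ndarray            # cohort variant positions, sorted
    haplotypes: np.ndarray           # (n_sample_haps, n_sites) derived-allele matrix
    sample_names: list
    sample_group: dict               # sample -> population label
    selected_pos: int | None
    sweep_population: str | None
    selected_freq: dict              # population -> final derived frequency
    pop_allele_freq: dict            # population -> per-site sampled frequency array

    def sweep_window(self, window: int = 100_000) -> tuple[int, int] | None:
        if self.selected_pos is None:
            return None
        start = (self.selected_pos // window) * window
        return start, start + window

    def to_json(self, path) -> None:
        payload = {
            "config": asdict(self.config),
            "positions": self.positions.tolist(),
            "haplotypes": ["".join(map(str, row)) for row in self.haplotypes],
            "sample_names": self.sample_names,
            "sample_group": self.sample_group,
            "selected_pos": self.selected_pos,
            "sweep_population": self.sweep_population,
            "selected_freq": self.selected_freq,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


@dataclass
class SimCohort:
    """In-memory bundle of everything simulate_cohort produces."""

    truth: SimTruth
    table: VariantTable
    mask: CallableMask
    genes: list
    qtl: "object"                    # DataFrame chrom/start/end/name
    groups: SampleGroups
    reference: dict
    contig_lengths: dict


def simulate_cohort(config: SimConfig) -> SimCohort:
    """Run the demography, draw the sample, emulate sequencing."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    L, chrom = config.chrom_length, config.chrom
    used: set = set()

    reference = rng.choice(np.frombuffer(b"ACGT", np.uint8), size=L)
    genes, qtl = plant_genes(config, rng, reference)
    ref_seq = reference.tobytes().decode("ascii")

    # --- demography -------------------------------------------------------
    anc = _Pop(2 * config.n_ancestral)
    _evolve(anc, config.n_ancestral, config.burnin_generations, config, rng, used)

    sampled = set(config.sample_sizes)
    domestic = anc.copy()
    wild = None
    if "wild" in sampled:
        wild = anc.copy()
        _evolve(
            wild, config.n_wild,
            config.domestic_generations + config.breed_generations, config, rng, used,
        )
    _evolve(domestic, config.n_domestic, config.domestic_generations, config, rng, used)

    selected_pos = None
    if config.s > 0:
        selected_pos = (
            config.selected_pos if config.selected_pos is not None
            else default_selected_pos(L)
        )
        while selected_pos in used:
            selected_pos += 1
        used.add(selected_pos)

    pops: dict = {}
    for breed in BREEDS:
        if breed not in sampled:
            continue
        start_state = domestic.copy()
        if config.s > 0 and breed == config.sweep_population:
            pops[breed] = _run_sweep(start_state, selected_pos, config, rng, used)
        else:
            _evolve(start_state, config.n_breed, config.breed_generations, config, rng, used)
            pops[breed] = start_state
    if wild is not None:
        pops["wild"] = wild

    # --- sampling ---------------------------------------------------------
    sample_names, sample_group, hap_blocks, pos_sets = [], {}, {}, []
    pop_sample_rows: dict = {}
    for name in ("wild", *BREEDS):
        if name not in config.sample_sizes:
            continue
        n = config.sample_sizes[name]
        chosen = rng.choice(pops[name].haps.shape[0] // 2, size=n, replace=False)
        rows = np.sort(np.concatenate([[2 * c, 2 * c + 1] for c in chosen]))
        pop_sample_rows[name] = pops[name].haps[rows]
        for j in range(n):
            sid = f"{name}_{j + 1}"
            sample_names.append(sid)
            sample_group[sid] = name

    # union of positions carried by any sampled haplotype, plus fixed sets
    carried: set = set()
    for name, block in pop_sample_rows.items():
        pop = pops[name]
        if block.shape[1]:
            seen = np.flatnonzero(block.sum(axis=0) > 0)
            carried.update(int(p) for p in pop.positions[seen])
        carried.update(pop.fixed)
    all_positions = np.array(sorted(carried), dtype=np.int64)

    n_sites = all_positions.size
    hap_rows = []
    pop_freq: dict = {}
    for name in ("wild", *BREEDS):
        if name not in pop_sample_rows:
            continue
        pop = pops[name]
        block = pop_sample_rows[name]
        mat = np.zeros((block.shape[0], n_sites), dtype=np.int8)
        if pop.positions.size and n_sites:
            col_of = np.searchsorted(all_positions, pop.positions)
            present = (col_of < n_sites) & (all_positions[np.minimum(col_of, n_sites - 1)] == pop.positions)
            mat[:, col_of[present]] = block[:, np.flatnonzero(present)]
        if pop.fixed and n_sites:
            fixed_idx = np.searchsorted(all_positions, np.array(sorted(pop.fixed), dtype=np.int64))
            mat[:, fixed_idx] = 1
        hap_rows.append(mat)
        pop_freq[name] = mat.mean(axis=0) if n_sites else np.zeros(0)
    haplotypes = np.vstack(hap_rows) if hap_rows else np.zeros((0, n_sites), np.int8)

    selected_freq = {
        name: pops[name].freq_at(selected_pos) if selected_pos is not None else 0.0
        for name in pops
    }

    truth = SimTruth(
        config=config,
        positions=all_positions,
        haplotypes=haplotypes,
        sample_names=sample_names,
        sample_group=sample_group,
        selected_pos=selected_pos,
        sweep_population=config.sweep_population if config.s > 0 else None,
        selected_freq=selected_freq,
        pop_allele_freq=pop_freq,
    )

    # --- sequencing emulation + VCF table --------------------------------
    alts = _draw_alt_bases(rng, reference, all_positions)
    ad = emulate_depths(haplotypes, config.mean_depth, config.base_error, rng)
    table = _build_table(chrom, all_positions, reference, alts, haplotypes, ad, sample_names)

    mask = _random_mask(config, rng)
    groups = SampleGroups(
        {name: [s for s in sample_names if sample_group[s] == name]
         for name in ("dairy", "cashmere", "meat", "wild")
         if any(sample_group[s] == name for s in sample_names)}
    )
    return SimCohort(
        truth=truth, table=table, mask=mask, genes=genes, qtl=qtl,
        groups=groups, reference={chrom: ref_seq}, contig_lengths={chrom: L},
    )


def _run_sweep(state: _Pop, selected_pos: int, cfg: SimConfig, rng, used: set) -> _Pop:
    for _ in range(cfg.max_retries):
        attempt = state.copy()
        journal: list = []
        carrier = int(rng.integers(0, attempt.haps.shape[0]))
        ins = int(np.searchsorted(attempt.positions, selected_pos))
        attempt.positions = np.insert(attempt.positions, ins, selected_pos)
        attempt.haps = np.insert(attempt.haps, ins, 0, axis=1)
        attempt.haps[carrier, ins] = 1
        ok = _evolve(
            attempt, cfg.n_breed, cfg.breed_generations, cfg, rng, used,
            selected_pos=selected_pos, s=cfg.s, stop_if_lost=True, journal=journal,
        )
        freq = attempt.freq_at(selected_pos)
        if ok and (not cfg.condition_on_fixation or freq == 1.0):
            if cfg.condition_on_fixation or freq > 0:
                return attempt
        used.difference_update(journal)
    raise SweepkitError(
        f"selected allele not fixed within {cfg.max_retries} attempts; "
        "raise breed_generations, s or max_retries"
    )


def emulate_depths(haplotypes: np.ndarray, mean_depth: float, base_error: float, rng) -> np.ndarray:
    """(n_sites, n_samples, 2) read counts per (ref, alt) allele.

    Haplotype rows pair up into diploid samples (0,1), (2,3)...
    """
    n_hap, n_sites = haplotypes.shape
    n_samples = n_hap // 2
    a1 = haplotypes[0::2].T.astype(np.int64)   # (sites, samples)
    a2 = haplotypes[1::2].T.astype(np.int64)
    depth = rng.poisson(mean_depth, size=(n_sites, n_samples))
    from_h1 = rng.binomial(depth, 0.5)
    alt_true = from_h1 * a1 + (depth - from_h1) * a2
    ref_true = depth - alt_true
    eps = base_error
    ref_kept = rng.binomial(ref_true, 1 - eps)
    alt_kept = rng.binomial(alt_true, 1 - eps)
    ref_to_alt = rng.binomial(ref_true - ref_kept, 1.0 / 3.0)
    alt_to_ref = rng.binomial(alt_true - alt_kept, 1.0 / 3.0)
    ad = np.stack([ref_kept + alt_to_ref, alt_kept + ref_to_alt], axis=2)
    return ad


def _draw_alt_bases(rng, reference: np.ndarray, positions: np.ndarray) -> list:
    alts = []
    for p in positions:
        ref = chr(reference[p])
        others = [b for b in "ACGT" if b != ref]
        alts.append(others[int(rng.integers(0, 3))])
    return alts


def _build_table(chrom, positions, reference, alts, haplotypes, ad, sample_names) -> VariantTable:
    sites = []
    n_samples = len(sample_names)
    for i, pos in enumerate(positions):
        genotypes = [
            (int(haplotypes[2 * j, i]), int(haplotypes[2 * j + 1, i]))
            for j in range(n_samples)
        ]
        sites.append(
            VariantSite(
                chrom=chrom,
                pos=int(pos),
                ref=chr(reference[pos]),
                alts=(alts[i],),
                genotypes=genotypes,
                phased=[True] * n_samples,
                allele_depths=[tuple(int(x) for x in ad[i, j]) for j in range(n_samples)],
                qual=100.0,
            )
        )
    return VariantTable(list(sample_names), sites)


def _random_mask(cfg: SimConfig, rng) -> CallableMask:
    """Complement of random low-depth holes over [0, L)."""
    L = cfg.chrom_length
    n_holes = int(cfg.mask_hole_fraction * L / max(cfg.mask_hole_mean_len, 1))
    holes = []
    for _ in range(n_holes):
        start = int(rng.integers(0, L))
        length = 1 + int(rng.exponential(cfg.mask_hole_mean_len))
        holes.append((start, min(start + length, L)))
    if not holes:
        return CallableMask({cfg.chrom: np.array([[0, L]], dtype=np.int64)})
    merged = CallableMask.from_intervals((cfg.chrom, s, e) for s, e in holes)
    callable_ivs, cursor = [], 0
    for s, e in merged.intervals[cfg.chrom]:
        if s > cursor:
            callable_ivs.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < L:
        callable_ivs.append((cursor, L))
    return CallableMask({cfg.chrom: np.array(callable_ivs, dtype=np.int64)})


# ---------------------------------------------------------------------------
# gene planting


def plant_genes(cfg: SimConfig, rng, reference: np.ndarray):
    """Place non-overlapping genes (valid CDS, both strands) and QTL.

    When a sweep is configured, ``n_sweep_genes`` genes are planted inside
    the 100-kb window containing the selected site so sweep classifiers
    have a known truth set; QTL intervals cover those genes plus random
    background. The reference array is modified in place so each CDS
    translates without internal stop codons.
    """
    import pandas as pd

    L, chrom = cfg.chrom_length, cfg.chrom
    sel = cfg.selected_pos if cfg.selected_pos is not None else default_selected_pos(L)
    window_start = (sel // 100_000) * 100_000

    spans = []  # reserved (start, end)
    genes = []

    def try_place(start, structure):
        end = start + structure["span"]
        if end > L or start < 0:
            return False
        for s, e in spans:
            if start < e and s < end:
                return False
        spans.append((start, end))
        genes.append(_make_gene(cfg, rng, reference, chrom, start, structure, len(genes)))
        return True

    n_in_sweep = cfg.n_sweep_genes if cfg.s > 0 else 0
    placed_sweep = 0
    for _ in range(200):
        if placed_sweep >= n_in_sweep:
            break
        structure = _gene_structure(rng)
        lo = window_start
        hi = max(lo + 1, window_start + 100_000 - structure["span"])
        if try_place(int(rng.integers(lo, hi)), structure):
            placed_sweep += 1
    if placed_sweep < n_in_sweep:
        raise ConfigError("could not place sweep genes; window too crowded or genome too small")

    target = cfg.n_genes
    attempts = 0
    while len(genes) < target:
        attempts += 1
        if attempts > 100 * target:
            raise ConfigError("genome too small for requested gene count")
        structure = _gene_structure(rng)
        if structure["span"] >= L:
            continue
        try_place(int(rng.integers(0, L - structure["span"])), structure)

    genes.sort(key=lambda g: g.start)

    qtl_rows = []
    for i, g in enumerate(genes):
        if placed_sweep and window_start <= g.start < window_start + 100_000 and len(qtl_rows) < 2:
            pad = int(rng.integers(1_000, 20_000))
            qtl_rows.append((chrom, max(0, g.start - pad), min(L, g.end + pad), f"qtl_sweep{len(qtl_rows) + 1}"))
    while len(qtl_rows) < cfg.n_qtl:
        start = int(rng.integers(0, max(1, L - 50_000)))
        length = int(rng.integers(20_000, 120_000))
        qtl_rows.append((chrom, start, min(start + length, L), f"qtl{len(qtl_rows) + 1}"))
    qtl = pd.DataFrame(qtl_rows, columns=["chrom", "start", "end", "name"])
    return genes, qtl


def _gene_structure(rng) -> dict:
    n_exons = int(rng.integers(1, 4))
    exon_codons = [int(rng.integers(40, 150)) for _ in range(n_exons)]
    introns = [int(rng.integers(200, 1_500)) for _ in range(n_exons - 1)]
    span = sum(c * 3 for c in exon_codons) + sum(introns)
    return {"n_exons": n_exons, "exon_codons": exon_codons, "introns": introns, "span": span}


def _make_gene(cfg, rng, reference, chrom, start, structure, index) -> GeneModel:
    strand = "+" if rng.integers(0, 2) == 0 else "-"
    total_codons = sum(structure["exon_codons"])
    codons = ["ATG"] + [
        _NON_STOP_CODONS[int(rng.integers(0, len(_NON_STOP_CODONS)))]
        for _ in range(total_codons - 2)
    ] + [("TAA", "TAG", "TGA")[int(rng.integers(0, 3))]]
    cds_nt = "".join(codons)

    blocks, cursor = [], start
    for i, n_codons in enumerate(structure["exon_codons"]):
        blocks.append((cursor, cursor + n_codons * 3))
        cursor += n_codons * 3
        if i < len(structure["introns"]):
            cursor += structure["introns"][i]
    end = blocks[-1][1]

    # write CDS into the reference in transcription order
    tx_blocks = blocks if strand == "+" else list(reversed(blocks))
    offset = 0
    cds_frames = []
    for s, e in tx_blocks:
        chunk = cds_nt[offset : offset + (e - s)]
        genomic = chunk if strand == "+" else reverse_complement(chunk)
        reference[s:e] = np.frombuffer(genomic.encode("ascii"), np.uint8)
        cds_frames.append((s, e, (3 - offset % 3) % 3))
        offset += e - s
    cds_frames.sort()
    return GeneModel(
        gene_id=f"gene{index + 1:03d}",
        chrom=chrom,
        start=start,
        end=end,
        strand=strand,
        cds=cds_frames,
        exons=[(s, e) for s, e, _ in cds_frames],
    )


# ---------------------------------------------------------------------------
# writing the bundle


def write_cohort(cohort: SimCohort, outdir) -> dict:
    """Write VCF, mask BED, GFF3, QTL BED, groups TSV, FASTA and truth JSON.

    Returns the mapping of logical name -> path.
    """
    import os

    from .io_formats import write_vcf

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "vcf": os.path.join(outdir, "cohort.vcf"),
        "mask": os.path.join(outdir, "callable.bed"),
        "genes": os.path.join(outdir, "genes.gff3"),
        "qtl": os.path.join(outdir, "qtl.bed"),
        "groups": os.path.join(outdir, "groups.tsv"),
        "reference": os.path.join(outdir, "reference.fa"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    write_vcf(cohort.table, paths["vcf"], cohort.contig_lengths)
    cohort.mask.to_bed(paths["mask"])
    write_gff3(cohort.genes, paths["genes"])
    with open(paths["qtl"], "w") as fh:
        for row in cohort.qtl.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.name}\n")
    cohort.groups.to_tsv(paths["groups"])
    write_fasta(cohort.reference, paths["reference"])
    cohort.truth.to_json(paths["truth"])
    return paths


def pairwise_diversity_per_bp(haplotypes: np.ndarray, length: int) -> float:
    """Mean pairwise difference per bp among sampled haplotypes (an
    estimate of theta = 4*N*mu under neutrality)."""
    n = haplotypes.shape[0]
    if n < 2:
        return 0.0
    freq = haplotypes.mean(axis=0)
    # sum over sites of 2p(1-p) * n/(n-1) equals mean pairwise differences
    return float((2 * freq * (1 - freq) * n / (n - 1)).sum() / length)


# ---------------------------------------------------------------------------
# frozen study conditions


def sweep_power_config(seed: int) -> SimConfig:
    """The hard-sweep study condition: a real s = 0.1 sweep in the dairy
    breed (lambda = 22 rescaling -> scaled s = 2.2) on a 5-Mb chromosome,
    sampled as three breeds of five animals each. The wild population is
    not sampled (the per-breed scan does not use it)."""
    return SimConfig(
        seed=seed,
        s=2.2,
        selected_pos=default_selected_pos(5_000_000),
        sample_sizes={"dairy": 5, "cashmere": 5, "meat": 5},
    )


def neutral_scan_config(seed: int) -> SimConfig:
    """The matched neutral condition (no sweep) for false-positive rates."""
    return SimConfig(seed=seed, s=0.0, sample_sizes={"dairy": 5, "cashmere": 5, "meat": 5})


def desert_study_config(seed: int) -> SimConfig:
    """Neutral N = 100 genome for the SNP-desert rule: high marker density
    (~15-25 SNPs per 10-kb window) and a finely holed callable mask so
    window SNP rates are essentially tie-free."""
    return SimConfig(
        seed=seed,
        n_ancestral=100,
        n_wild=100,
        n_domestic=100,
        n_breed=100,
        mu=1.4e-6,
        rec_rate=2e-6,
        burnin_generations=500,
        domestic_generations=100,
        breed_generations=25,
        s=0.0,
        mask_hole_fraction=0.20,
        mask_hole_mean_len=500,
    )
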