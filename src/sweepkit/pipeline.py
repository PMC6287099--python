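"""End-to-end orchestration: simulate -> qc -> annotate -> desert ->
sweep -> ehh -> classify -> report, driven by one validated config.

Each stage reads its inputs from, and writes its outputs under, a run
directory, so stages can be re-run individually from the CLI. A manifest
records the config hash, seed and output checksums; a rerun with the
same config reproduces identical tables.
"""
from __future__ import annotations

import hashlib
import json
import logging
import os
from typing import Optional

import numpy as np
import pandas as pd
import pysam
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from . import desert_scan, effect_annotation, haplotype_ehh, simdata, sweep_scan, variant_qc
from .errors import ConfigError, ContractError
from .io_formats import (
    SampleGroups,
    read_bed,
    read_fasta,
    read_gff3,
    read_groups,
    read_intervals,
    read_vcf,
    write_vcf,
)

log = logging.getLogger(__name__)


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateConfig(_Section):
    enabled: bool = True
    seed: int = 0
    chrom_length: int = 5_000_000
    mu: float = 2.8e-7
    rec_rate: float = 2e-6
    n_ancestral: int = 200
    n_wild: int = 200
    n_domestic: int = 400
    n_breed: int = 400
    burnin_generations: int = 500
    domestic_generations: int = 150
    breed_generations: int = 25
    s: float = 0.0
    selected_pos: Optional[int] = None
    sweep_population: str = "dairy"
    mean_depth: float = 29.0
    base_error: float = 0.001
    n_genes: int = 30
    mask_hole_fraction: float = 0.10


class InputsConfig(_Section):
    vcf: Optional[str] = None
    mask: Optional[str] = None
    genes: Optional[str] = None
    qtl: Optional[str] = None
    groups: Optional[str] = None
    reference: Optional[str] = None


class QcConfig(_Section):
    min_total_depth: int = 8
    min_het_allele_reads: int = 4
    depth_mode: str = "any"
    indel_max_len: int = 5
    indel_min_quality: float = 20
    indel_max_homopolymer: int = 10


class AnnotateConfig(_Section):
    maf_bin_width: float = 0.05


class DesertConfig(_Section):
    window: int = 10_000
    step: int = 10_000
    quantile: float = 0.10
    join_gap: int = 10_000
    sag_min_overlap: float = 0.30
    large_desert_min_length: int = 100_000
    top_k: int = 10


class SweepConfig(_Section):
    window: int = 100_000
    zhp_cut: float = -3.0
    zfst_cut: float = 3.0
    tag_zfst_cut: float = 4.0
    xpehh_top_frac: float = 0.01
    fst_estimator: str = "hudson"
    wild_group: str = "wild"


class EhhConfig(_Section):
    min_ehh: float = 0.05
    max_extension_bp: int = 1_000_000
    aggregate: str = "max"


class RunConfig(_Section):
    run_dir: str
    simulate: SimulateConfig = SimulateConfig()
    inputs: InputsConfig = InputsConfig()
    qc: QcConfig = QcConfig()
    annotate: AnnotateConfig = AnnotateConfig()
    desert: DesertConfig = DesertConfig()
    sweep: SweepConfig = SweepConfig()
    ehh: EhhConfig = EhhConfig()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            return cls(**raw)
        except ValidationError as exc:
            raise ConfigError(str(exc)) from None

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _p(cfg: RunConfig, *parts) -> str:
    path = os.path.join(cfg.run_dir, *parts)
    os.makedirs(os.path.dirname(path), exist_ok=True)
    return path


def _input_path(cfg: RunConfig, key: str, simulated_name: str) -> str:
    override = getattr(cfg.inputs, key)
    if override:
        return override
    path = os.path.join(cfg.run_dir, "sim", simulated_name)
    if not os.path.exists(path):
        raise ContractError(
            f"no {key!r} input: provide inputs.{key} or run the simulate stage first"
        )
    return path


def _contig_lengths(vcf_path) -> dict:
    vf = pysam.VariantFile(str(vcf_path))
    return {name: ctg.length for name, ctg in vf.header.contigs.items()}


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: RunConfig) -> dict:
    sim = cfg.simulate
    sc = simdata.SimConfig(
        seed=sim.seed, chrom_length=sim.chrom_length, mu=sim.mu, rec_rate=sim.rec_rate,
        n_ancestral=sim.n_ancestral, n_wild=sim.n_wild, n_domestic=sim.n_domestic,
        n_breed=sim.n_breed, burnin_generations=sim.burnin_generations,
        domestic_generations=sim.domestic_generations,
        breed_generations=sim.breed_generations, s=sim.s, selected_pos=sim.selected_pos,
        sweep_population=sim.sweep_population, mean_depth=sim.mean_depth,
        base_error=sim.base_error, n_genes=sim.n_genes,
        mask_hole_fraction=sim.mask_hole_fraction,
    )
    cohort = simdata.simulate_cohort(sc)
    return simdata.write_cohort(cohort, os.path.join(cfg.run_dir, "sim"))


def stage_qc(cfg: RunConfig) -> dict:
    table = read_vcf(_input_path(cfg, "vcf", "cohort.vcf"))
    contigs = _contig_lengths(_input_path(cfg, "vcf", "cohort.vcf"))
    snp_filtered, snp_report = variant_qc.filter_snps_by_depth(
        table, cfg.qc.min_total_depth, cfg.qc.min_het_allele_reads, cfg.qc.depth_mode
    )
    filtered, indel_report = variant_qc.filter_indels(
        snp_filtered, cfg.qc.indel_max_len, cfg.qc.indel_min_quality,
        cfg.qc.indel_max_homopolymer,
    )
    out_vcf = _p(cfg, "qc", "filtered.vcf")
    write_vcf(filtered, out_vcf, contigs)
    report = variant_qc.FilterReport({**snp_report.counts, **indel_report.counts})
    report.to_tsv(_p(cfg, "qc", "filter_report.tsv"))
    groups = read_groups(_input_path(cfg, "groups", "groups.tsv"))
    _, per_ind = variant_qc.site_summaries(filtered.snps(), groups)
    per_ind.to_csv(_p(cfg, "qc", "heterozygosity.tsv"), sep="\t", index=False)
    return {"vcf": out_vcf}


def stage_annotate(cfg: RunConfig) -> dict:
    table = read_vcf(_p(cfg, "qc", "filtered.vcf"))
    genes = read_gff3(_input_path(cfg, "genes", "genes.gff3"))
    reference = read_fasta(_input_path(cfg, "reference", "reference.fa"))
    groups = read_groups(_input_path(cfg, "groups", "groups.tsv"))
    effects = effect_annotation.classify_effects(table, genes, reference)
    effect_annotation.effects_to_frame(effects).to_csv(
        _p(cfg, "annotate", "effects.tsv"), sep="\t", index=False
    )
    summaries, _ = variant_qc.site_summaries(table.snps(), groups)
    effect_annotation.ns_s_spectrum(effects, summaries, cfg.annotate.maf_bin_width).to_csv(
        _p(cfg, "annotate", "ns_s_by_maf.tsv"), sep="\t", index=False, float_format="%.6g"
    )
    with open(_p(cfg, "annotate", "categories.json"), "w") as fh:
        json.dump(effect_annotation.category_totals(effects), fh, indent=1, sort_keys=True)
    return {}


def _breed_labels(groups: SampleGroups, wild_group: str) -> list:
    return [g for g in groups.labels() if g != wild_group]


def stage_desert(cfg: RunConfig) -> dict:
    table = read_vcf(_p(cfg, "qc", "filtered.vcf"))
    mask = read_bed(_input_path(cfg, "mask", "callable.bed"))
    genes = read_gff3(_input_path(cfg, "genes", "genes.gff3"))
    groups = read_groups(_input_path(cfg, "groups", "groups.tsv"))
    contigs = _contig_lengths(_p(cfg, "qc", "filtered.vcf"))
    sag_sets = {}
    for breed in _breed_labels(groups, cfg.sweep.wild_group):
        sub = table.subset_samples(groups[breed])
        breed_sites = type(sub)(sub.samples, [s for s in sub.sites if s.alt_allele_count() > 0])
        windows = desert_scan.snp_rate_windows(
            breed_sites, mask, cfg.desert.window, cfg.desert.step, contigs
        )
        deserts = desert_scan.call_deserts(windows, cfg.desert.quantile, cfg.desert.join_gap)
        sags = desert_scan.classify_sags(deserts, genes, cfg.desert.sag_min_overlap)
        desert_scan.windows_to_frame(windows).to_csv(
            _p(cfg, "desert", f"windows_{breed}.tsv"), sep="\t", index=False, float_format="%.6g"
        )
        desert_scan.deserts_to_frame(deserts).to_csv(
            _p(cfg, "desert", f"deserts_{breed}.bed"), sep="\t", index=False, float_format="%.6g"
        )
        sags.to_csv(_p(cfg, "desert", f"sags_{breed}.tsv"), sep="\t", index=False, float_format="%.6g")
        top = desert_scan.deserts_to_frame(desert_scan.top_deserts(deserts, cfg.desert.top_k))
        top.to_csv(_p(cfg, "desert", f"top_deserts_{breed}.tsv"), sep="\t", index=False, float_format="%.6g")
        sag_sets[breed] = set(sags[sags.is_sag].gene_id)
    with open(_p(cfg, "desert", "sag_sets.json"), "w") as fh:
        json.dump({k: sorted(v) for k, v in sag_sets.items()}, fh, indent=1, sort_keys=True)
    return {}


def _scan_windows(cfg: RunConfig, contigs: dict) -> list:
    return sweep_scan.tile_windows(contigs, cfg.sweep.window)


def stage_sweep(cfg: RunConfig) -> dict:
    table = read_vcf(_p(cfg, "qc", "filtered.vcf"))
    genes = read_gff3(_input_path(cfg, "genes", "genes.gff3"))
    groups = read_groups(_input_path(cfg, "groups", "groups.tsv"))
    contigs = _contig_lengths(_p(cfg, "qc", "filtered.vcf"))
    windows = _scan_windows(cfg, contigs)
    wild = cfg.sweep.wild_group
    breeds = _breed_labels(groups, wild)
    domestic = [s for b in breeds for s in groups[b]]

    hp = sweep_scan.pooled_heterozygosity(table, domestic, windows)
    fst = sweep_scan.fst_windows(table, domestic, groups[wild], windows, cfg.sweep.fst_estimator)
    stats = pd.DataFrame(windows, columns=["chrom", "start", "end"])
    stats["hp"] = hp
    stats["fst"] = fst
    stats["zhp"] = sweep_scan.z_transform(hp)
    stats["zfst"] = sweep_scan.z_transform(fst)
    stats.to_csv(_p(cfg, "sweep", "window_stats.tsv"), sep="\t", index=False, float_format="%.6g")

    with open(_p(cfg, "desert", "sag_sets.json")) as fh:
        sag_sets = {k: set(v) for k, v in json.load(fh).items()}
    calls, dags = sweep_scan.classify_dags(
        stats, genes, cfg.sweep.zhp_cut, cfg.sweep.zfst_cut, sag_sets
    )
    dags.to_csv(_p(cfg, "sweep", "dags.tsv"), sep="\t", index=False)
    with open(_p(cfg, "sweep", "dag_calls.bed"), "w") as fh:
        for c in calls:
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{';'.join(c.rules)}\t{','.join(c.genes)}\n")

    # per-breed Fst (breed vs pooled others) for the TAG arm
    for breed in breeds:
        others = [s for b in breeds if b != breed for s in groups[b]]
        bf = sweep_scan.fst_windows(table, groups[breed], others, windows, cfg.sweep.fst_estimator)
        bdf = pd.DataFrame(windows, columns=["chrom", "start", "end"])
        bdf["fst"] = bf
        bdf["zfst"] = sweep_scan.z_transform(bf)
        bdf.to_csv(_p(cfg, "sweep", f"fst_{breed}.tsv"), sep="\t", index=False, float_format="%.6g")
    _manhattan_plot(stats, _p(cfg, "sweep", "manhattan.png"), cfg)
    return {}


def stage_ehh(cfg: RunConfig) -> dict:
    table = read_vcf(_p(cfg, "qc", "filtered.vcf"))
    groups = read_groups(_input_path(cfg, "groups", "groups.tsv"))
    breeds = _breed_labels(groups, cfg.sweep.wild_group)
    for chrom in table.chroms():
        for breed in breeds:
            others = [s for b in breeds if b != breed for s in groups[b]]
            focal, ref = haplotype_ehh.paired_panels(
                table, groups[breed], others, breed, f"not_{breed}", chrom
            )
            scores, tally = haplotype_ehh.xpehh_scan(
                focal, ref, chrom, cfg.ehh.min_ehh, cfg.ehh.max_extension_bp
            )
            haplotype_ehh.scores_to_frame(scores).to_csv(
                _p(cfg, "ehh", f"xpehh_{breed}_{chrom}.tsv"), sep="\t",
                index=False, float_format="%.6g",
            )
            with open(_p(cfg, "ehh", f"tally_{breed}_{chrom}.json"), "w") as fh:
                json.dump(tally, fh, sort_keys=True)
    return {}


def stage_classify(cfg: RunConfig) -> dict:
    genes = read_gff3(_input_path(cfg, "genes", "genes.gff3"))
    groups = read_groups(_input_path(cfg, "groups", "groups.tsv"))
    qtl = read_intervals(_input_path(cfg, "qtl", "qtl.bed"))
    contigs = _contig_lengths(_p(cfg, "qc", "filtered.vcf"))
    windows = _scan_windows(cfg, contigs)
    breeds = _breed_labels(groups, cfg.sweep.wild_group)

    qtl_table = sweep_scan.crossref_qtl(genes, qtl)
    qtl_table.to_csv(_p(cfg, "classify", "qtl_crossref.tsv"), sep="\t", index=False)
    qtl_genes = set(qtl_table[qtl_table.n_qtl > 0].gene_id)
    with open(_p(cfg, "desert", "sag_sets.json")) as fh:
        sag_sets = {k: set(v) for k, v in json.load(fh).items()}

    shared_rows = []
    for breed in breeds:
        bdf = pd.read_csv(_p(cfg, "sweep", f"fst_{breed}.tsv"), sep="\t")
        scores = []
        for chrom in sorted(contigs):
            path = os.path.join(cfg.run_dir, "ehh", f"xpehh_{breed}_{chrom}.tsv")
            if not os.path.exists(path):
                raise ContractError(
                    f"XP-EHH scores for {breed}/{chrom} absent; run the ehh stage first"
                )
            df = pd.read_csv(path, sep="\t")
            scores.extend(
                haplotype_ehh.XpehhScore(r.chrom, r.pos, r.raw, r.normalized)
                for r in df.itertuples()
            )
        bdf["xpehh"] = haplotype_ehh.window_xpehh(scores, windows, cfg.ehh.aggregate)
        calls, tags = sweep_scan.classify_tags(
            bdf, genes, cfg.sweep.tag_zfst_cut, cfg.sweep.xpehh_top_frac
        )
        bdf.to_csv(_p(cfg, "classify", f"tag_windows_{breed}.tsv"), sep="\t", index=False, float_format="%.6g")
        tags.to_csv(_p(cfg, "classify", f"tags_{breed}.tsv"), sep="\t", index=False)
        with open(_p(cfg, "classify", f"tag_calls_{breed}.bed"), "w") as fh:
            for c in calls:
                fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{';'.join(c.rules)}\t{','.join(c.genes)}\n")
        shared_rows.append(
            (breed,
             len(sweep_scan.shared_genes(sag_sets.get(breed, set()), qtl_genes)),
             len(sweep_scan.shared_genes(set(tags.gene_id), qtl_genes)))
        )
    pd.DataFrame(shared_rows, columns=["breed", "sag_qtl_shared", "tag_qtl_shared"]).to_csv(
        _p(cfg, "classify", "qtl_shared_counts.tsv"), sep="\t", index=False
    )
    return {}


def _manhattan_plot(stats: pd.DataFrame, path: str, cfg: RunConfig) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 1, figsize=(10, 5), sharex=True)
    mid = (stats.start + stats.end) / 2 / 1e6
    axes[0].scatter(mid, stats.zhp, s=8, c="steelblue")
    axes[0].axhline(cfg.sweep.zhp_cut, color="red", lw=1)
    axes[0].set_ylabel("ZHp")
    axes[1].scatter(mid, stats.zfst, s=8, c="darkorange")
    axes[1].axhline(cfg.sweep.zfst_cut, color="red", lw=1)
    axes[1].set_ylabel("ZFst")
    axes[1].set_xlabel("position (Mb)")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


STAGES = {
    "simulate": stage_simulate,
    "qc": stage_qc,
    "annotate": stage_annotate,
    "desert": stage_desert,
    "sweep": stage_sweep,
    "ehh": stage_ehh,
    "classify": stage_classify,
}
STAGE_ORDER = ["simulate", "qc", "annotate", "desert", "sweep", "ehh", "classify"]


def run_pipeline(cfg: RunConfig) -> str:
    """Run all stages in dependency order and write the manifest."""
    os.makedirs(cfg.run_dir, exist_ok=True)
    for name in STAGE_ORDER:
        if name == "simulate" and not cfg.simulate.enabled:
            continue
        log.info("stage %s", name)
        STAGES[name](cfg)
    write_manifest(cfg)
    report_summary(cfg.run_dir)
    return cfg.run_dir


_TEXT_EXT = (".tsv", ".bed", ".vcf", ".json", ".fa", ".gff3")


def output_checksums(run_dir: str) -> dict:
    """sha256 of every text output, keyed by path relative to run_dir."""
    sums = {}
    for root, _, files in os.walk(run_dir):
        for f in sorted(files):
            if f.endswith(_TEXT_EXT) and f not in ("manifest.json", "summary.json"):
                path = os.path.join(root, f)
                with open(path, "rb") as fh:
                    sums[os.path.relpath(path, run_dir)] = hashlib.sha256(fh.read()).hexdigest()
    return sums


def write_manifest(cfg: RunConfig) -> None:
    manifest = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.simulate.seed,
        "config": cfg.model_dump(),
        "outputs": output_checksums(cfg.run_dir),
    }
    with open(os.path.join(cfg.run_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def report_summary(run_dir: str) -> dict:
    """Machine-readable counts over a completed run directory.

    When the simulator's truth file is present, also reports
    precision/recall of TAG windows against the true sweep window.
    """
    summary: dict = {"missing": []}

    def _maybe(path):
        full = os.path.join(run_dir, path)
        if not os.path.exists(full):
            summary["missing"].append(path)
            return None
        return full

    fr = _maybe("qc/filter_report.tsv")
    if fr:
        report = pd.read_csv(fr, sep="\t")
        counts = dict(zip(report.criterion, report["count"]))
        summary["snps_retained"] = int(counts.get("snp_retained", 0))
        summary["snps_removed_low_depth"] = int(counts.get("snp_removed_low_depth", 0))
    sag_json = _maybe("desert/sag_sets.json")
    if sag_json:
        with open(sag_json) as fh:
            sag_sets = json.load(fh)
        summary["sag_counts"] = {k: len(v) for k, v in sag_sets.items()}
        for breed in sag_sets:
            path = _maybe(f"desert/deserts_{breed}.bed")
            if path:
                df = pd.read_csv(path, sep="\t")
                summary.setdefault("desert_counts", {})[breed] = int(len(df))
                summary.setdefault("desert_total_mb", {})[breed] = float(df.length.sum() / 1e6)
    dags = _maybe("sweep/dags.tsv")
    if dags:
        summary["dag_count"] = int(len(pd.read_csv(dags, sep="\t")))
    tag_counts = {}
    truth_path = os.path.join(run_dir, "sim", "truth.json")
    truth = None
    if os.path.exists(truth_path):
        with open(truth_path) as fh:
            truth = json.load(fh)
    for f in sorted(os.listdir(run_dir + "/classify")) if os.path.isdir(run_dir + "/classify") else []:
        if f.startswith("tags_") and f.endswith(".tsv"):
            breed = f[5:-4]
            tag_counts[breed] = int(len(pd.read_csv(os.path.join(run_dir, "classify", f), sep="\t")))
    if tag_counts:
        summary["tag_counts"] = tag_counts
    if truth and truth.get("selected_pos") is not None:
        breed = truth["sweep_population"]
        calls_path = _maybe(f"classify/tag_calls_{breed}.bed")
        if calls_path and os.path.getsize(calls_path):
            calls = pd.read_csv(calls_path, sep="\t", header=None,
                                names=["chrom", "start", "end", "rules", "genes"])
        else:
            calls = pd.DataFrame(columns=["chrom", "start", "end", "rules", "genes"])
        sel = truth["selected_pos"]
        hit = ((calls.start <= sel) & (sel < calls.end)).any() if len(calls) else False
        summary["sweep_recovery"] = {
            "recall": float(bool(hit)),
            "precision": float(
                ((calls.start <= sel) & (sel < calls.end)).sum() / len(calls)
            ) if len(calls) else 0.0,
            "n_tag_windows": int(len(calls)),
        }
    with open(os.path.join(run_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    with open(os.path.join(run_dir, "summary.txt"), "w") as fh:
        for k in sorted(summary):
            fh.write(f"{k}\t{summary[k]}\n")
    return summary
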