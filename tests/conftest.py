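"""Shared fixtures: hand-built variant sites, a tiny text VCF, and one
small simulated cohort reused across modules (session-scoped; all inputs
are generated programmatically)."""
from __future__ import annotations

import numpy as np
import pytest

from sweepkit.io_formats import VariantSite, VariantTable
from sweepkit.simdata import SimConfig, simulate_cohort


def make_site(
    pos,
    gts,
    ads=None,
    chrom="chr1",
    ref="A",
    alts=("G",),
    qual=100.0,
    homopolymer_len=None,
    phased=True,
    strand_support=None,
):
    """Terse VariantSite builder for tests."""
    n = len(gts)
    return VariantSite(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alts=tuple(alts),
        genotypes=list(gts),
        phased=[phased] * n,
        allele_depths=list(ads) if ads is not None else [None] * n,
        qual=qual,
        homopolymer_len=homopolymer_len,
        strand_support=strand_support,
    )


def make_table(sites, samples=None):
    n = max(len(s.genotypes) for s in sites) if sites else 2
    samples = samples or [f"s{i + 1}" for i in range(n)]
    return VariantTable(samples, list(sites))


VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=1000000>
##contig=<ID=chr2,length=1000000>
##INFO=<ID=HRUN,Number=1,Type=Integer,Description="Reference homopolymer length">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Read depth per allele">
"""


def write_vcf_text(path, rows, samples=("s1", "s2")):
    """rows: list of tab-joined VCF body lines (1-based positions)."""
    header = VCF_HEADER + "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n"
    path.write_text(header + "".join(r + "\n" for r in rows))
    return path


@pytest.fixture(scope="session")
def small_cohort():
    """A small neutral simulated cohort (1 Mb, N = 100) shared by IO,
    annotation and scan tests."""
    cfg = SimConfig(
        seed=42,
        chrom_length=1_000_000,
        mu=8e-7,
        rec_rate=2e-6,
        n_ancestral=100,
        n_wild=100,
        n_domestic=100,
        n_breed=100,
        burnin_generations=400,
        domestic_generations=80,
        breed_generations=20,
        n_genes=12,
    )
    return simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
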