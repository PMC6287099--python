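"""Effect classification: codon changes, strand handling, NS/S spectra.

The minus-strand and strand-invariance checks use a whole-CDS
translation oracle: translate the full mutated CDS with Biopython and
compare protein sequences, independent of the codon-index arithmetic
under test.
"""
import numpy as np
import pytest
from Bio.Seq import Seq

from sweepkit.effect_annotation import (
    GENIC_NONCODING,
    INTERGENIC,
    INTRONIC,
    NONSYNONYMOUS,
    SYNONYMOUS,
    category_totals,
    classify_effect,
    classify_effects,
    ns_s_spectrum,
)
from sweepkit.errors import DataError
from sweepkit.io_formats import GeneModel, reverse_complement
from sweepkit.simdata import SimConfig, plant_genes
from sweepkit.variant_qc import site_summaries
from sweepkit.io_formats import SampleGroups

from conftest import make_site, make_table


def _ref(seq):
    return {"chr1": seq}


PLUS_GENE = GeneModel("g1", "chr1", 10, 40, "+", cds=[(10, 40, 0)])


def _seq_with(cds, at=10, total=60):
    pad = "T" * at
    seq = pad + cds
    return seq + "A" * (total - len(seq))


class TestClassifyEffect:
    def test_third_position_nonsynonymous(self):
        # ATG ATG ... change 3rd pos of codon 2: ATG->ATA = Met->Ile
        seq = _seq_with("ATG" + "ATG" * 9)
        site = make_site(15, [(0, 1)], ref="G", alts=("A",))
        call = classify_effect(site, [PLUS_GENE], _ref(seq))
        assert call.category == NONSYNONYMOUS
        assert (call.aa_ref, call.aa_alt) == ("M", "I")

    def test_synonymous(self):
        seq = _seq_with("ATG" + "GCT" * 9)      # GCT->GCC  Ala->Ala
        site = make_site(15, [(0, 1)], ref="T", alts=("C",))
        call = classify_effect(site, [PLUS_GENE], _ref(seq))
        assert call.category == SYNONYMOUS

    def test_intergenic_and_intronic(self):
        gene = GeneModel("g2", "chr1", 10, 40, "+", cds=[(10, 19, 0), (31, 40, 0)])
        seq = "A" * 60
        assert classify_effect(make_site(5, [(0, 1)], ref="A", alts=("G",)),
                               [gene], _ref(seq)).category == INTERGENIC
        assert classify_effect(make_site(25, [(0, 1)], ref="A", alts=("G",)),
                               [gene], _ref(seq)).category == INTRONIC

    def test_utr_like_exonic_noncoding_reported_separately(self):
        gene = GeneModel("g3", "chr1", 10, 40, "+", cds=[(16, 40, 0)],
                         exons=[(10, 40)])
        seq = "A" * 60
        call = classify_effect(make_site(12, [(0, 1)], ref="A", alts=("G",)), [gene], _ref(seq))
        assert call.category == GENIC_NONCODING

    def test_reference_mismatch_raises(self):
        seq = "A" * 60
        with pytest.raises(DataError):
            classify_effect(make_site(5, [(0, 1)], ref="C", alts=("G",)), [], _ref(seq))

    def test_minus_strand_matches_whole_cds_translation_oracle(self, rng):
        """Random minus-strand gene, every possible SNP in its CDS: the
        syn/nonsyn call equals translating the full mutated CDS."""
        cds_fwd = "ATG" + "".join(
            rng.choice([c for c in _codons() if c not in ("TAA", "TAG", "TGA")])
            for _ in range(8)
        ) + "TAA"
        genomic = reverse_complement(cds_fwd)              # gene on minus strand
        seq = "T" * 10 + genomic + "A" * 10
        gene = GeneModel("gm", "chr1", 10, 10 + len(genomic), "-",
                         cds=[(10, 10 + len(genomic), 0)])
        for pos in range(10, 10 + len(genomic)):
            ref_base = seq[pos]
            for alt in "ACGT":
                if alt == ref_base:
                    continue
                site = make_site(pos, [(0, 1)], ref=ref_base, alts=(alt,))
                call = classify_effect(site, [gene], _ref(seq))
                mutated = seq[:pos] + alt + seq[pos + 1 :]
                prot_ref = str(Seq(cds_fwd).translate())
                prot_alt = str(
                    Seq(reverse_complement(mutated[10 : 10 + len(genomic)])).translate()
                )
                expected = SYNONYMOUS if prot_ref == prot_alt else NONSYNONYMOUS
                assert call.category == expected, (pos, alt)


def _codons():
    return [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]


class TestGenomeLevel:
    def test_category_counts_sum_and_strand_invariance(self, rng):
        """Reverse-complementing the genome and annotations leaves every
        syn/nonsyn call unchanged (50-gene simulated genome)."""
        cfg = SimConfig(seed=3, chrom_length=300_000, n_genes=50, s=0.0)
        reference = rng.choice(np.frombuffer(b"ACGT", np.uint8), size=cfg.chrom_length)
        genes, _ = plant_genes(cfg, np.random.default_rng(5), reference)
        seq = reference.tobytes().decode()
        L = cfg.chrom_length

        sites = []
        for _ in range(400):
            pos = int(rng.integers(0, L))
            ref_base = seq[pos]
            alt = rng.choice([b for b in "ACGT" if b != ref_base])
            sites.append(make_site(pos, [(0, 1), (0, 0)], ref=ref_base, alts=(str(alt),)))
        table = make_table(sites)
        effects = classify_effects(table, genes, {"chr1": seq})
        totals = category_totals(effects)
        assert totals["total"] == len(effects) == len(sites)
        assert sum(totals["counts"].values()) == totals["total"]

        # mirror the genome
        seq_rc = reverse_complement(seq)
        genes_rc = [
            GeneModel(
                g.gene_id, g.chrom, L - g.end, L - g.start,
                "-" if g.strand == "+" else "+",
                cds=sorted((L - e, L - s, f) for s, e, f in g.cds),
                exons=sorted((L - e, L - s) for s, e in g.exons),
            )
            for g in genes
        ]
        # frames must be recomputed in the mirrored transcription order
        for g in genes_rc:
            blocks = g.cds if g.strand == "+" else list(reversed(g.cds))
            off = 0
            fixed = []
            for s, e, _ in blocks:
                fixed.append((s, e, (3 - off % 3) % 3))
                off += e - s
            g.cds = sorted(fixed)
        sites_rc = [
            make_site(L - 1 - s.pos, [(0, 1), (0, 0)],
                      ref=reverse_complement(s.ref), alts=(reverse_complement(s.alts[0]),))
            for s in sites
        ]
        effects_rc = classify_effects(make_table(sites_rc), genes_rc, {"chr1": seq_rc})
        for e_fwd, e_rc in zip(effects, effects_rc):
            assert e_fwd.category == e_rc.category, (e_fwd.pos, e_fwd.category, e_rc.category)


class TestNsSSpectrum:
    def _summaries(self, spec):
        """spec: list of (pos, maf)."""
        groups = SampleGroups({"g": ["s1", "s2"]})
        sites = []
        for pos, maf in spec:
            # one het in 4 alleles -> maf 0.25; two -> 0.5
            n_alt = round(maf * 4)
            gts = {0: [(0, 0), (0, 0)], 1: [(0, 1), (0, 0)], 2: [(0, 1), (0, 1)]}[n_alt]
            sites.append(make_site(pos, gts))
        summaries, _ = site_summaries(make_table(sites), groups)
        return summaries

    def test_equal_counts_give_ratio_one(self):
        from sweepkit.effect_annotation import EffectCall

        effects = [EffectCall("chr1", p, NONSYNONYMOUS) for p in range(10)] + [
            EffectCall("chr1", 100 + p, SYNONYMOUS) for p in range(10)
        ]
        summaries = self._summaries([(p, 0.25) for p in range(10)] +
                                    [(100 + p, 0.25) for p in range(10)])
        df = ns_s_spectrum(effects, summaries)
        overall = df[df.bin == "overall"].iloc[0]
        assert overall.ns_s == pytest.approx(1.0)

    def test_zero_synonymous_bin_is_nan_not_inf(self):
        from sweepkit.effect_annotation import EffectCall

        effects = [EffectCall("chr1", 0, NONSYNONYMOUS)]
        summaries = self._summaries([(0, 0.25)])
        df = ns_s_spectrum(effects, summaries)
        assert np.isnan(df[df.bin == "overall"].ns_s.iloc[0])
        assert not np.isinf(df.ns_s.dropna()).any()

    def test_genome_ns_s_approaches_exhaustive_mutation_oracle(self, small_cohort):
        """With per-site-uniform mutations, the observed NS/S in simulated
        coding SNPs approaches the expectation from enumerating all point
        mutations of the CDS set."""
        genes = small_cohort.genes
        seq = small_cohort.reference["chr1"]
        ns = s = 0
        for g in genes:
            cds = g.cds_sequence(seq)
            prot = str(Seq(cds).translate())
            for i in range(len(cds)):
                codon_i = i // 3
                codon = cds[codon_i * 3 : codon_i * 3 + 3]
                for alt in "ACGT":
                    if alt == cds[i]:
                        continue
                    mutated = codon[: i % 3] + alt + codon[i % 3 + 1 :]
                    aa_ref = prot[codon_i]
                    aa_alt = str(Seq(mutated).translate())
                    if aa_ref == aa_alt:
                        s += 1
                    else:
                        ns += 1
        expected = ns / s

        # simulate many uniform coding SNPs and classify them
        rng = np.random.default_rng(11)
        sites = []
        for g in genes:
            for s0, e0, _ in g.cds:
                for pos in range(s0, e0, 2):
                    ref_base = seq[pos]
                    alt = "ACGT"[(("ACGT".index(ref_base)) + int(rng.integers(1, 4))) % 4]
                    sites.append(make_site(pos, [(0, 1), (0, 0)], ref=ref_base, alts=(alt,)))
        effects = classify_effects(make_table(sites), genes, small_cohort.reference)
        counts = category_totals(effects)["counts"]
        observed = counts[NONSYNONYMOUS] / counts[SYNONYMOUS]
        assert observed == pytest.approx(expected, rel=0.25)
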