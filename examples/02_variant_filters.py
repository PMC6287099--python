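"""Apply the resequencing QC rules to a hand-built variant table.

SNPs need depth >= 8 in every individual; a heterozygous call needs >= 4
reads behind each allele (otherwise it is demoted to missing). Indels
are dropped for caller quality < 20, reference homopolymer > 10 bp, or
length > 5 bp.
"""
from sweepkit import VariantSite, VariantTable, filter_indels, filter_snps_by_depth


def site(pos, gts, ads, ref="A", alts=("G",), qual=100.0, hrun=None):
    return VariantSite(chrom="chr1", pos=pos, ref=ref, alts=alts,
                       genotypes=list(gts), phased=[True] * len(gts),
                       allele_depths=list(ads), qual=qual, homopolymer_len=hrun)


table = VariantTable(["goat1", "goat2"], [
    site(100, [(0, 1), (0, 0)], [(4, 3), (20, 0)]),          # depth 7 -> site removed
    site(200, [(0, 1), (0, 1)], [(4, 4), (12, 9)]),          # het with 4+4 reads: kept
    site(300, [(0, 1), (0, 1)], [(5, 3), (6, 6)]),           # 3 alt reads: call demoted
    site(400, [(0, 1), (0, 0)], [(10, 10), (20, 0)], ref="A", alts=("AGTGTA",)),  # 5-bp ins
    site(500, [(0, 1), (0, 0)], [(10, 10), (20, 0)], ref="A", alts=("AG",), qual=19.0),
])

snps, snp_report = filter_snps_by_depth(table)
both, indel_report = filter_indels(snps)
print("SNP filter tallies:", dict(sorted(snp_report.counts.items())))
print("indel filter tallies:", dict(sorted(indel_report.counts.items())))
print(f"retained sites: {[s.pos for s in both.sites]} "
      "(positions 200/300 pass the depth rule; the het at 300 is now missing; "
      "the 5-bp insertion at 400 sits exactly on the length boundary and is kept)")
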