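"""Readers/writers for VCF, BED, GFF3, FASTA and group tables.

Every coordinate inside the package is 0-based half-open. VCF (1-based)
and GFF3 (1-based inclusive) positions are shifted on read and restored
on write, so the single internal convention never leaks.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .errors import ContractError, DataError, FormatError, SampleLookupError

SNP = "snp"
INSERTION = "insertion"
DELETION = "deletion"
OTHER = "other"

_BASES = frozenset("ACGT")

#: genotype of one diploid sample: allele indices into (ref, *alts), or None if missing
Genotype = "tuple[int, int] | None"


def classify_kind(ref: str, alts: tuple[str, ...]) -> str:
    """SNP / insertion / deletion / other, judged on the site's alleles.

    A site is a SNP only if the reference and every alternate allele are
    single bases; mixed multi-allelic records fall into ``other`` and are
    skipped by type-specific filters.
    """
    if len(ref) == 1 and all(len(a) == 1 for a in alts):
        return SNP
    if all(len(a) > len(ref) for a in alts):
        return INSERTION
    if all(len(a) < len(ref) for a in alts):
        return DELETION
    return OTHER


@dataclass
class VariantSite:
    """One VCF record in internal coordinates.

    ``pos`` is 0-based. ``genotypes[i]`` is a pair of allele indices for
    sample i (None when missing); ``allele_depths[i]`` has one read count
    per allele (ref first) or is None when AD was absent.
    """

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    genotypes: list
    phased: list
    allele_depths: list
    qual: float | None = None
    homopolymer_len: int | None = None
    kind: str = ""
    strand_support: tuple[int, int] | None = None  # (fwd, rev) reads for non-ref allele

    def __post_init__(self):
        if not self.kind:
            self.kind = classify_kind(self.ref, self.alts)

    @property
    def n_alleles(self) -> int:
        return 1 + len(self.alts)

    @property
    def is_biallelic_snp(self) -> bool:
        return self.kind == SNP and len(self.alts) == 1

    def indel_length(self) -> int:
        """Inserted/deleted bases, judged against the longest alt."""
        return max(abs(len(a) - len(self.ref)) for a in self.alts)

    def validate(self) -> None:
        if self.pos < 0:
            raise DataError(f"negative position {self.pos} on {self.chrom}")
        for allele in (self.ref, *self.alts):
            if not allele or set(allele) - _BASES:
                raise DataError(f"bad allele {allele!r} at {self.chrom}:{self.pos}")
        for i, gt in enumerate(self.genotypes):
            if gt is not None and any(a >= self.n_alleles for a in gt):
                raise DataError(
                    f"genotype {gt} references missing allele at {self.chrom}:{self.pos}"
                )
            ad = self.allele_depths[i]
            if ad is not None and len(ad) != self.n_alleles:
                raise DataError(
                    f"AD length {len(ad)} != {self.n_alleles} alleles at {self.chrom}:{self.pos}"
                )

    def alt_allele_count(self) -> int:
        """Called non-reference alleles across all samples."""
        return sum(a for gt in self.genotypes if gt is not None for a in gt if a > 0)

    def called_allele_total(self) -> int:
        return 2 * sum(1 for gt in self.genotypes if gt is not None)


@dataclass
class VariantTable:
    """Ordered collection of sites sharing one sample panel."""

    samples: list
    sites: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self):
        return iter(self.sites)

    def sort(self) -> None:
        self.sites.sort(key=lambda s: (s.chrom, s.pos))

    def chroms(self) -> list:
        return sorted({s.chrom for s in self.sites})

    def snps(self) -> "VariantTable":
        return VariantTable(self.samples, [s for s in self.sites if s.kind == SNP])

    def indels(self) -> "VariantTable":
        return VariantTable(
            self.samples, [s for s in self.sites if s.kind in (INSERTION, DELETION)]
        )

    def sample_index(self, name: str) -> int:
        try:
            return self.samples.index(name)
        except ValueError:
            raise SampleLookupError(f"sample {name!r} not in table") from None

    def subset_samples(self, names) -> "VariantTable":
        idx = [self.sample_index(n) for n in names]
        sites = []
        for s in self.sites:
            sites.append(
                VariantSite(
                    chrom=s.chrom,
                    pos=s.pos,
                    ref=s.ref,
                    alts=s.alts,
                    genotypes=[s.genotypes[i] for i in idx],
                    phased=[s.phased[i] for i in idx],
                    allele_depths=[s.allele_depths[i] for i in idx],
                    qual=s.qual,
                    homopolymer_len=s.homopolymer_len,
                    kind=s.kind,
                    strand_support=s.strand_support,
                )
            )
        return VariantTable(list(names), sites)


@dataclass
class SampleGroups:
    """Ordered mapping group label -> sample identifiers."""

    groups: dict

    def __post_init__(self):
        seen = set()
        for label, names in self.groups.items():
            for n in names:
                if n in seen:
                    raise DataError(f"sample {n!r} assigned to more than one group")
                seen.add(n)

    def __getitem__(self, label: str) -> list:
        try:
            return self.groups[label]
        except KeyError:
            raise SampleLookupError(f"group {label!r} unknown") from None

    def labels(self) -> list:
        return list(self.groups)

    def all_samples(self) -> list:
        return [n for names in self.groups.values() for n in names]

    def validate_against(self, samples) -> None:
        missing = [n for n in self.all_samples() if n not in set(samples)]
        if missing:
            raise SampleLookupError(f"group samples absent from VCF header: {missing}")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("sample\tgroup\n")
            for label, names in self.groups.items():
                for n in names:
                    fh.write(f"{n}\t{label}\n")


def read_groups(path) -> SampleGroups:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["sample", "group"]:
        raise FormatError(f"{path}: expected header 'sample\\tgroup'")
    groups: dict = {}
    for _, row in df.iterrows():
        groups.setdefault(str(row["group"]), []).append(str(row["sample"]))
    return SampleGroups(groups)


# ---------------------------------------------------------------------------
# interval masks / BED


def _merge_sorted(intervals: np.ndarray) -> np.ndarray:
    """Union of intervals (n,2); overlapping or book-ended runs are merged."""
    if len(intervals) == 0:
        return intervals.reshape(0, 2)
    order = np.lexsort((intervals[:, 1], intervals[:, 0]))
    ivs = intervals[order]
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out, dtype=np.int64)


class CallableMask:
    """Per-chromosome disjoint sorted intervals of callable (>=8x) sequence."""

    def __init__(self, intervals: dict):
        self.intervals = {c: np.asarray(v, dtype=np.int64).reshape(-1, 2) for c, v in intervals.items()}
        for c, ivs in self.intervals.items():
            if len(ivs) and (np.any(ivs[:, 0] >= ivs[:, 1]) or np.any(np.diff(ivs[:, 0]) < 0)
                             or np.any(ivs[1:, 0] < ivs[:-1, 1])):
                raise DataError(f"mask intervals on {c} not sorted/disjoint")

    @classmethod
    def from_intervals(cls, triples) -> "CallableMask":
        per_chrom: dict = {}
        for chrom, start, end in triples:
            if start >= end:
                raise FormatError(f"empty/inverted interval {chrom}:{start}-{end}")
            per_chrom.setdefault(chrom, []).append((start, end))
        return cls({c: _merge_sorted(np.asarray(v, dtype=np.int64)) for c, v in per_chrom.items()})

    def chroms(self) -> list:
        return sorted(self.intervals)

    def total_length(self, chrom: str | None = None) -> int:
        if chrom is not None:
            ivs = self.intervals.get(chrom)
            return int((ivs[:, 1] - ivs[:, 0]).sum()) if ivs is not None and len(ivs) else 0
        return sum(self.total_length(c) for c in self.intervals)

    def overlap_length(self, chrom: str, start: int, end: int) -> int:
        """Callable bases inside [start, end)."""
        ivs = self.intervals.get(chrom)
        if ivs is None or len(ivs) == 0 or start >= end:
            return 0
        lo = np.clip(ivs[:, 0], start, end)
        hi = np.clip(ivs[:, 1], start, end)
        return int(np.maximum(hi - lo, 0).sum())

    def contains(self, chrom: str, pos: int) -> bool:
        ivs = self.intervals.get(chrom)
        if ivs is None or len(ivs) == 0:
            return False
        i = int(np.searchsorted(ivs[:, 0], pos, side="right")) - 1
        return i >= 0 and pos < ivs[i, 1]

    def end(self, chrom: str) -> int:
        ivs = self.intervals.get(chrom)
        return int(ivs[-1, 1]) if ivs is not None and len(ivs) else 0

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in self.chroms():
                for s, e in self.intervals[chrom]:
                    fh.write(f"{chrom}\t{s}\t{e}\n")


def read_bed(path) -> CallableMask:
    """BED3+ -> merged CallableMask (overlaps and book-ends unioned)."""
    df = read_intervals(path)
    return CallableMask.from_intervals(df[["chrom", "start", "end"]].itertuples(index=False))


def read_intervals(path) -> pd.DataFrame:
    """BED3/BED6 -> raw interval DataFrame (chrom, start, end[, name]); no merging."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: fewer than 3 BED columns")
            start, end = int(parts[1]), int(parts[2])
            if start >= end:
                raise FormatError(f"{path}:{ln}: start >= end ({start} >= {end})")
            rows.append((parts[0], start, end, parts[3] if len(parts) > 3 else f"iv{ln}"))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


# ---------------------------------------------------------------------------
# gene models / GFF3


@dataclass
class GeneModel:
    """A gene span with the CDS structure of one representative transcript.

    ``cds`` holds (start, end, frame) triples in genomic order; ``exons``
    is optional and only used to tell UTR/exonic-noncoding sites apart
    from intronic ones.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    cds: list = field(default_factory=list)
    exons: list = field(default_factory=list)
    partial: bool = False

    def __post_init__(self):
        for s, e, _ in self.cds:
            if s < self.start or e > self.end:
                raise DataError(f"CDS outside span for {self.gene_id}")
        if self.cds_length() % 3 != 0:
            self.partial = True

    def span_length(self) -> int:
        return self.end - self.start

    def cds_length(self) -> int:
        return sum(e - s for s, e, _ in self.cds)

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def in_cds(self, pos: int) -> bool:
        return any(s <= pos < e for s, e, _ in self.cds)

    def in_exon(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.exons)

    def cds_coordinate(self, pos: int) -> int | None:
        """0-based offset of genomic ``pos`` within the spliced CDS, in
        transcription order (5'->3' of the mRNA). None if not in CDS."""
        offset = 0
        blocks = self.cds if self.strand == "+" else list(reversed(self.cds))
        for s, e, _ in blocks:
            if s <= pos < e:
                return offset + (pos - s if self.strand == "+" else e - 1 - pos)
            offset += e - s
        return None

    def cds_sequence(self, chrom_seq: str) -> str:
        """Spliced CDS in transcription order (reverse-complemented for -)."""
        parts = [chrom_seq[s:e] for s, e, _ in self.cds]
        seq = "".join(parts)
        if self.strand == "-":
            seq = reverse_complement(seq)
        return seq


_COMPLEMENT = str.maketrans("ACGTacgtN", "TGCAtgcaN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def read_gff3(path) -> list:
    """Parse gene/mRNA/CDS(+exon) features; keep the longest-CDS transcript.

    Coordinates are converted from 1-based inclusive to 0-based half-open.
    A CDS without a gene ancestor is a format error.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    gene_ids = {f.id for f in db.features_of_type("gene")}
    # orphan check: every CDS must trace to a gene
    for cds in db.features_of_type("CDS"):
        parents = list(db.parents(cds, featuretype="gene"))
        if not parents:
            direct = list(db.parents(cds))
            if not any(p.id in gene_ids for p in direct):
                raise FormatError(f"CDS {cds.id} at {cds.seqid}:{cds.start} has no parent gene")

    genes = []
    for g in db.features_of_type("gene"):
        transcripts = list(db.children(g, featuretype="mRNA"))
        candidates = transcripts if transcripts else [g]
        best_cds, best_len, best_parent = [], -1, None
        for t in candidates:
            cds = sorted(db.children(t, featuretype="CDS"), key=lambda f: f.start)
            total = sum(f.end - f.start + 1 for f in cds)
            if total > best_len:
                best_cds, best_len, best_parent = cds, total, t
        exons = []
        if best_parent is not None:
            exons = sorted(db.children(best_parent, featuretype="exon"), key=lambda f: f.start)
        genes.append(
            GeneModel(
                gene_id=g.id,
                chrom=g.seqid,
                start=g.start - 1,
                end=g.end,
                strand=g.strand if g.strand in "+-" else "+",
                cds=[(f.start - 1, f.end, int(f.frame) if f.frame in "012" else 0) for f in best_cds],
                exons=[(f.start - 1, f.end) for f in exons],
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def write_gff3(genes, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            fh.write(
                f"{g.chrom}\tsweepkit\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            tid = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chrom}\tsweepkit\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={tid};Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\tsweepkit\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\tID={tid}.exon{i};Parent={tid}\n"
                )
            for i, (s, e, frame) in enumerate(g.cds, 1):
                fh.write(
                    f"{g.chrom}\tsweepkit\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t{frame}\tID={tid}.cds{i};Parent={tid}\n"
                )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict:
    import pyfaidx

    fa = pyfaidx.Fasta(str(path))
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(seqs: dict, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path, sample_subset=None) -> VariantTable:
    """VCF 4.x -> VariantTable; positions shifted to 0-based.

    Honors GT (required), AD, QUAL and the HRUN info tag (reference
    homopolymer length, used by the indel filters). Multi-allelic records
    are kept intact.
    """
    vf = pysam.VariantFile(str(path))
    if "GT" not in vf.header.formats:
        raise FormatError(f"{path}: VCF has no GT FORMAT field")
    header_samples = list(vf.header.samples)
    if sample_subset is not None:
        missing = [s for s in sample_subset if s not in header_samples]
        if missing:
            raise SampleLookupError(f"samples absent from VCF header: {missing}")
        samples = list(sample_subset)
    else:
        samples = header_samples

    sites = []
    for rec in vf:
        genotypes, phased, depths = [], [], []
        for name in samples:
            call = rec.samples[name]
            gt = call.get("GT")
            if gt is None or any(a is None for a in gt):
                genotypes.append(None)
                phased.append(False)
            else:
                genotypes.append(tuple(int(a) for a in gt))
                phased.append(bool(call.phased))
            ad = call.get("AD")
            if ad is None or all(x is None for x in ad):
                depths.append(None)
            else:
                depths.append(tuple(int(x) if x is not None else 0 for x in ad))
        hrun = rec.info.get("HRUN")
        if isinstance(hrun, tuple):
            hrun = hrun[0]
        site = VariantSite(
            chrom=rec.chrom,
            pos=rec.start,  # pysam start is already 0-based
            ref=rec.ref,
            alts=tuple(rec.alts or ()),
            genotypes=genotypes,
            phased=phased,
            allele_depths=depths,
            qual=float(rec.qual) if rec.qual is not None else None,
            homopolymer_len=int(hrun) if hrun is not None else None,
        )
        sites.append(site)
    table = VariantTable(samples, sites)
    table.sort()
    return table


def write_vcf(table: VariantTable, path, contig_lengths: dict) -> None:
    """Serialize a VariantTable as plain-text VCF 4.2 (1-based positions)."""
    header = pysam.VariantHeader()
    for chrom, length in contig_lengths.items():
        header.contigs.add(chrom, length=length)
    header.info.add("HRUN", 1, "Integer", "Reference homopolymer length")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer", "Read depth per allele")
    for s in table.samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for site in table.sites:
            rec = out.new_record(
                contig=site.chrom,
                start=site.pos,
                alleles=(site.ref, *site.alts),
                qual=site.qual,
            )
            if site.homopolymer_len is not None:
                rec.info["HRUN"] = site.homopolymer_len
            for i, name in enumerate(table.samples):
                call = rec.samples[name]
                gt = site.genotypes[i]
                call["GT"] = gt if gt is not None else (None, None)
                call.phased = site.phased[i]
                if site.allele_depths[i] is not None:
                    call["AD"] = tuple(site.allele_depths[i])
            out.write(rec)
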