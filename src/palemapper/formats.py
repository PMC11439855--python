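"""Readers and writers for the standard formats the pipeline touches.

Coordinate conventions are strict and centralized here:

* VCF and GFF3 positions are 1-based, closed intervals (the formats'
  native convention).
* BED output and genomic bins are 0-based, half-open.

The conversion between the two lives in a single function pair
(:func:`to_zero_based_start` / :func:`to_one_based_start`) so that no
other module does coordinate arithmetic on its own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

_NUCLEOTIDES = frozenset("ACGT")


def to_zero_based_start(pos_1based: int) -> int:
    """Convert a 1-based closed start coordinate to 0-based half-open."""
    return pos_1based - 1


def to_one_based_start(pos_0based: int) -> int:
    """Convert a 0-based half-open start coordinate to 1-based closed."""
    return pos_0based + 1


class FormatError(ValueError):
    """Raised when an input file violates the minimal format contract."""


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic SNV with per-pool allele depths.

    Parameters
    ----------
    chrom : str
        Chromosome name.
    pos : int
        1-based genomic position.
    ref, alt : str
        Single-nucleotide reference and alternate alleles.
    ad_mut, ad_wt : tuple[int, int]
        (ref_depth, alt_depth) for the mutant-like and wild-type-like
        pools respectively.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    ad_mut: tuple[int, int]
    ad_wt: tuple[int, int]

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError("only biallelic SNVs are representable")
        if self.ref not in _NUCLEOTIDES or self.alt not in _NUCLEOTIDES:
            raise ValueError(f"non-ACGT allele at {self.chrom}:{self.pos}")
        if min(*self.ad_mut, *self.ad_wt) < 0:
            raise ValueError("allele depths must be non-negative")

    @property
    def depth_mut(self) -> int:
        return self.ad_mut[0] + self.ad_mut[1]

    @property
    def depth_wt(self) -> int:
        return self.ad_wt[0] + self.ad_wt[1]


@dataclass(frozen=True)
class GeneModel:
    """A single-transcript gene model: exon and CDS intervals.

    Intervals are 1-based closed ``(start, end)`` tuples, non-overlapping
    and sorted by genomic position regardless of strand.  The spliced CDS
    is read in transcription order: ascending intervals on ``+``,
    descending (and reverse-complemented) on ``-``.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_intervals: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        for name, ivs in (("exons", self.exons), ("cds_intervals", self.cds_intervals)):
            prev_end = 0
            for start, end in ivs:
                if start > end:
                    raise ValueError(f"{name}: interval ({start}, {end}) reversed")
                if start <= prev_end:
                    raise ValueError(f"{name}: intervals overlap or are unsorted")
                prev_end = end
        if not self.cds_intervals:
            raise ValueError("gene model requires at least one CDS interval")
        if self.cds_length % 3 != 0:
            raise ValueError(
                f"CDS length {self.cds_length} of {self.gene_id} not divisible by 3"
            )

    @property
    def cds_length(self) -> int:
        return sum(end - start + 1 for start, end in self.cds_intervals)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic (start, end) of the gene, 1-based closed."""
        return self.exons[0][0], self.exons[-1][1]


@dataclass
class GenomeMap:
    """Ordered chromosome-name -> length (bp) map."""

    lengths: dict[str, int]

    def __post_init__(self) -> None:
        for name, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def __getitem__(self, chrom: str) -> int:
        return self.lengths[chrom]

    @property
    def chromosomes(self) -> list[str]:
        return list(self.lengths)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenomeMap":
        """Read a two-column ``chrom<TAB>length`` table (``#`` comments allowed)."""
        lengths: dict[str, int] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            name, length = line.split("\t")[:2]
            lengths[name] = int(length)
        return cls(lengths)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# chrom\tlength_bp\n")
            for name, length in self.lengths.items():
                fh.write(f"{name}\t{length}\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">
##source=palemapper
"""


def read_vcf_minimal(
    path: str | Path,
    sample_names: tuple[str, str] = ("mut_pool", "wt_pool"),
) -> tuple[list[VariantRecord], dict[str, int]]:
    """Parse a minimal VCF with AD fields for two pool samples.

    Multiallelic sites and indels are skipped; the returned counter
    reports how many of each.  Records are returned sorted by
    (chrom, pos).

    Parameters
    ----------
    path : path to a VCF 4.2 text file.
    sample_names : (mutant-pool, wild-type-pool) sample column names.

    Returns
    -------
    (records, skipped) where ``skipped`` has keys ``multiallelic`` and
    ``indel``.
    """
    mut_name, wt_name = sample_names
    records: list[VariantRecord] = []
    skipped = {"multiallelic": 0, "indel": 0}
    mut_idx = wt_idx = None

    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                samples = cols[9:]
                for name in (mut_name, wt_name):
                    if name not in samples:
                        raise FormatError(
                            f"sample {name!r} not in VCF; available: {samples}"
                        )
                mut_idx = 9 + samples.index(mut_name)
                wt_idx = 9 + samples.index(wt_name)
                continue
            if mut_idx is None:
                raise FormatError(f"line {line_no}: data before #CHROM header")
            cols = line.split("\t")
            chrom, pos, _, ref, alt = cols[0], int(cols[1]), cols[2], cols[3], cols[4]
            if "," in alt:
                skipped["multiallelic"] += 1
                continue
            if len(ref) != 1 or len(alt) != 1 or alt == ".":
                skipped["indel"] += 1
                continue
            fmt = cols[8].split(":")
            if "AD" not in fmt:
                raise FormatError(f"line {line_no}: FORMAT lacks AD")
            ad_i = fmt.index("AD")

            def _ad(col: str) -> tuple[int, int]:
                fields = col.split(":")
                ref_d, alt_d = fields[ad_i].split(",")[:2]
                return int(ref_d), int(alt_d)

            records.append(
                VariantRecord(
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    ad_mut=_ad(cols[mut_idx]),
                    ad_wt=_ad(cols[wt_idx]),
                )
            )
    if skipped["multiallelic"] or skipped["indel"]:
        logger.info(
            "skipped %d multiallelic and %d indel records",
            skipped["multiallelic"],
            skipped["indel"],
        )
    records.sort(key=lambda r: (r.chrom, r.pos))
    return records, skipped


def write_vcf_minimal(
    records: Iterable[VariantRecord],
    path: str | Path,
    sample_names: tuple[str, str] = ("mut_pool", "wt_pool"),
) -> None:
    """Write records as minimal VCF 4.2 with AD per pool sample."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_names)
            + "\n"
        )
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t.\tAD\t"
                f"{r.ad_mut[0]},{r.ad_mut[1]}\t{r.ad_wt[0]},{r.ad_wt[1]}\n"
            )


def write_variants_tsv(records: Iterable[VariantRecord], path: str | Path) -> None:
    """TSV equivalent of the minimal VCF (positions 1-based)."""
    with open(path, "w") as fh:
        fh.write("# coordinates: 1-based\n")
        fh.write("chrom\tpos\tref\talt\tref_mut\talt_mut\tref_wt\talt_wt\n")
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.pos}\t{r.ref}\t{r.alt}\t"
                f"{r.ad_mut[0]}\t{r.ad_mut[1]}\t{r.ad_wt[0]}\t{r.ad_wt[1]}\n"
            )


def read_variants_tsv(path: str | Path) -> list[VariantRecord]:
    records = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "chrom\t")):
            continue
        c, p, ref, alt, rm, am, rw, aw = line.split("\t")
        records.append(
            VariantRecord(c, int(p), ref, alt, (int(rm), int(am)), (int(rw), int(aw)))
        )
    records.sort(key=lambda r: (r.chrom, r.pos))
    return records


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------


def read_gene_model(
    gff3_path: str | Path, fasta_path: str | Path, gene_id: str
) -> tuple[GeneModel, str]:
    """Load a gene model from GFF3 and assemble its spliced CDS from FASTA.

    The CDS is returned in transcription order; minus-strand genes are
    reverse-complemented.  A CDS length not divisible by 3 is an error;
    a CDS not starting with ATG only logs a warning (non-canonical starts
    exist).
    """
    db = gffutils.create_db(
        str(gff3_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    try:
        gene = db[gene_id]
    except gffutils.FeatureNotFoundError as exc:
        raise KeyError(f"gene {gene_id!r} not found in {gff3_path}") from exc

    exons = sorted(
        (f.start, f.end) for f in db.children(gene, featuretype="exon")
    )
    cds = sorted((f.start, f.end) for f in db.children(gene, featuretype="CDS"))
    if not exons:
        exons = cds
    model = GeneModel(
        gene_id=gene_id,
        chrom=gene.seqid,
        strand=gene.strand,
        exons=tuple(exons),
        cds_intervals=tuple(cds),
    )

    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    if model.chrom not in seqs:
        raise KeyError(f"sequence {model.chrom!r} not in {fasta_path}")
    chrom_seq = seqs[model.chrom]
    pieces = [chrom_seq[start - 1 : end] for start, end in model.cds_intervals]
    cds_seq = "".join(pieces)
    if model.strand == "-":
        cds_seq = str(Seq(cds_seq).reverse_complement())
    if len(cds_seq) != model.cds_length:
        raise FormatError(
            f"CDS sequence length {len(cds_seq)} != model cds_length {model.cds_length}"
        )
    if not cds_seq.startswith("ATG"):
        logger.warning("CDS of %s does not start with ATG", gene_id)
    return model, cds_seq


def write_gene_model_gff3(
    model: GeneModel, path: str | Path, source: str = "palemapper"
) -> None:
    """Write a one-gene GFF3 (gene + exon + CDS features)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        start, end = model.span
        attrs = f"ID={model.gene_id}"
        fh.write(
            f"{model.chrom}\t{source}\tgene\t{start}\t{end}\t.\t{model.strand}\t.\t{attrs}\n"
        )
        for i, (s, e) in enumerate(model.exons, start=1):
            fh.write(
                f"{model.chrom}\t{source}\texon\t{s}\t{e}\t.\t{model.strand}\t.\t"
                f"ID={model.gene_id}.exon{i};Parent={model.gene_id}\n"
            )
        for i, (s, e) in enumerate(model.cds_intervals, start=1):
            fh.write(
                f"{model.chrom}\t{source}\tCDS\t{s}\t{e}\t.\t{model.strand}\t0\t"
                f"ID={model.gene_id}.cds{i};Parent={model.gene_id}\n"
            )


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED / bins TSV
# ---------------------------------------------------------------------------


def write_region_bed(regions: Sequence, path: str | Path) -> None:
    """Write candidate regions as BED (0-based half-open).

    ``regions`` carry 1-based closed (start, end); the BED start is the
    1-based start minus one and the BED end is the 1-based end unchanged.
    """
    with open(path, "w") as fh:
        fh.write("# coordinates: 0-based half-open (BED)\n")
        for region in regions:
            fh.write(
                f"{region.chrom}\t{to_zero_based_start(region.start)}\t{region.end}\n"
            )


def write_bins_tsv(bins: Sequence, path: str | Path) -> None:
    """Write per-bin summaries; empty bins get NA frequency columns."""
    with open(path, "w") as fh:
        fh.write("# coordinates: 0-based half-open bins\n")
        fh.write(
            "chrom\tbin_start\tbin_end\tn_variants\tmean_af_mut\tmean_af_wt\tfrac_high_mut\n"
        )
        for b in bins:
            if b.n_variants == 0:
                means = "NA\tNA\tNA"
            else:
                means = f"{b.mean_af_mut:.6g}\t{b.mean_af_wt:.6g}\t{b.frac_high_mut:.6g}"
            fh.write(
                f"{b.chrom}\t{b.bin_start}\t{b.bin_start + b.bin_width}\t"
                f"{b.n_variants}\t{means}\n"
            )
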