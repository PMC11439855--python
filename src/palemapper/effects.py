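"""Codon-level consequence calling of SNVs against a gene model.

The annotator maps a genomic position into the spliced CDS (transcription
order; minus-strand genes count from the highest genomic CDS coordinate),
substitutes the allele into the affected codon, translates both codons
with the standard nuclear genetic code and classifies the change.
An EMS-type flag marks G>A / C>T transitions — the signature of
ethyl-methanesulfonate mutagenesis — which are the prime candidates in
an EMS mutant screen.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio.Seq import Seq

from palemapper.formats import GeneModel, VariantRecord
from palemapper.mapping import CandidateRegion

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

THREE_LETTER = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
    "*": "Ter",
}

CODING_CLASSES = frozenset({"synonymous", "missense", "nonsense", "stop_loss"})


@dataclass(frozen=True)
class EffectCall:
    """The codon-level consequence of one SNV on one gene model."""

    gene_id: str
    genomic_pos: int
    cds_pos: int | None
    codon_index: int | None  # 1-based
    codon_offset: int | None  # position within codon, 1..3
    ref_codon: str | None
    alt_codon: str | None
    ref_aa: str | None
    alt_aa: str | None
    effect_class: str
    label: str | None  # e.g. "R298K"; only for coding changes
    is_ems_type: bool

    def three_letter_label(self) -> str | None:
        """Render the label with three-letter amino-acid codes (Arg298Lys)."""
        if self.label is None:
            return None
        return (
            THREE_LETTER[self.ref_aa] + str(self.codon_index) + THREE_LETTER[self.alt_aa]
        )


def genomic_to_cds(model: GeneModel, genomic_pos: int) -> int | None:
    """1-based offset of a genomic position along the spliced CDS, or None.

    Transcription order: ascending genomic coordinates on the plus
    strand; on the minus strand CDS position 1 is the highest genomic
    CDS coordinate.
    """
    offset = 0
    if model.strand == "+":
        for start, end in model.cds_intervals:
            if start <= genomic_pos <= end:
                return offset + (genomic_pos - start) + 1
            offset += end - start + 1
    else:
        for start, end in reversed(model.cds_intervals):
            if start <= genomic_pos <= end:
                return offset + (end - genomic_pos) + 1
            offset += end - start + 1
    return None


def cds_to_genomic(model: GeneModel, cds_pos: int) -> int:
    """Inverse of :func:`genomic_to_cds`; exact round trip guaranteed."""
    if not 1 <= cds_pos <= model.cds_length:
        raise ValueError(f"cds_pos {cds_pos} outside [1, {model.cds_length}]")
    remaining = cds_pos - 1
    if model.strand == "+":
        for start, end in model.cds_intervals:
            size = end - start + 1
            if remaining < size:
                return start + remaining
            remaining -= size
    else:
        for start, end in reversed(model.cds_intervals):
            size = end - start + 1
            if remaining < size:
                return end - remaining
            remaining -= size
    raise AssertionError("unreachable")  # pragma: no cover


def annotate_variant(
    model: GeneModel, cds_sequence: str, variant: VariantRecord
) -> EffectCall:
    """Classify one SNV against a gene model.

    VCF alleles are given on the plus strand of the reference; for
    minus-strand genes they are complemented before the codon
    substitution.  The reference allele must match the modelled CDS base
    at that position (a mismatch means the inputs disagree and is an
    error, not a call).
    """
    cds_sequence = cds_sequence.upper()
    if len(cds_sequence) != model.cds_length:
        raise ValueError("cds_sequence length does not match the model")
    is_ems = (variant.ref, variant.alt) in {("G", "A"), ("C", "T")}

    cds_pos = genomic_to_cds(model, variant.pos)
    if cds_pos is None:
        lo, hi = model.span
        effect = "intronic" if lo <= variant.pos <= hi else "utr_or_intergenic"
        return EffectCall(
            gene_id=model.gene_id,
            genomic_pos=variant.pos,
            cds_pos=None,
            codon_index=None,
            codon_offset=None,
            ref_codon=None,
            alt_codon=None,
            ref_aa=None,
            alt_aa=None,
            effect_class=effect,
            label=None,
            is_ems_type=is_ems,
        )

    if model.strand == "+":
        ref_coding, alt_coding = variant.ref, variant.alt
    else:
        ref_coding = _COMPLEMENT[variant.ref]
        alt_coding = _COMPLEMENT[variant.alt]

    if cds_sequence[cds_pos - 1] != ref_coding:
        raise ValueError(
            f"reference allele mismatch at {variant.chrom}:{variant.pos}: "
            f"VCF says {variant.ref} (coding-strand {ref_coding}), model CDS has "
            f"{cds_sequence[cds_pos - 1]} at CDS position {cds_pos}"
        )

    codon_index = math.ceil(cds_pos / 3)
    codon_offset = (cds_pos - 1) % 3 + 1
    codon_start = (codon_index - 1) * 3
    ref_codon = cds_sequence[codon_start : codon_start + 3]
    alt_codon = (
        ref_codon[: codon_offset - 1] + alt_coding + ref_codon[codon_offset:]
    )
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())

    if ref_aa == alt_aa:
        effect = "synonymous"
    elif alt_aa == "*":
        effect = "nonsense"
    elif ref_aa == "*":
        effect = "stop_loss"
    else:
        effect = "missense"
    if codon_index == 1 and effect != "synonymous":
        logger.warning(
            "start-codon change at %s:%d reported as %s of codon 1",
            variant.chrom,
            variant.pos,
            effect,
        )
    label = f"{ref_aa}{codon_index}{alt_aa}"
    return EffectCall(
        gene_id=model.gene_id,
        genomic_pos=variant.pos,
        cds_pos=cds_pos,
        codon_index=codon_index,
        codon_offset=codon_offset,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        effect_class=effect,
        label=label,
        is_ems_type=is_ems,
    )


def screen_region(
    models: Mapping[str, GeneModel],
    cds_sequences: Mapping[str, str],
    variants: Sequence[VariantRecord],
    region: CandidateRegion,
) -> list[EffectCall]:
    """Annotate every variant inside a candidate region against every
    overlapping gene model.

    Output is sorted with EMS-type coding changes first, then by
    (gene, cds_pos).  Variants inside the region but outside every gene
    are not reported.
    """
    calls: list[EffectCall] = []
    in_region = [
        v for v in variants if v.chrom == region.chrom and v.pos in region
    ]
    overlapping = {
        gid: m
        for gid, m in models.items()
        if m.chrom == region.chrom
        and m.span[0] <= region.end
        and m.span[1] >= region.start
    }
    if not overlapping:
        logger.info("no gene models overlap %s:%d-%d", region.chrom, region.start, region.end)
        return []
    for gid, model in overlapping.items():
        lo, hi = model.span
        for v in in_region:
            if lo <= v.pos <= hi:
                calls.append(annotate_variant(model, cds_sequences[gid], v))
    calls.sort(
        key=lambda c: (
            not (c.is_ems_type and c.effect_class in CODING_CLASSES),
            c.gene_id,
            c.cds_pos if c.cds_pos is not None else float("inf"),
        )
    )
    return calls
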