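"""Variant-effect prediction for CDS SNVs and the gene/site exclusion rules.

Implements the subset of effect annotation the McDonald-Kreitman counting
needs: synonymous vs non-synonymous classification under the standard nuclear
genetic code (translation table 1), plus the disqualifying effects — stop
gained, stop lost, start lost and non-synonymous start variants — that remove
a gene from selection inference entirely. Each SNV is evaluated independently
against the reference codon; co-occurring SNVs in one codon are flagged in
logs, not combined.
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict
from typing import Iterable, Mapping, Optional, Sequence

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .io_formats import GeneModel, VariantRecord

__all__ = [
    "SiteEffect",
    "predict_effect",
    "effect_for_substitution",
    "gene_exclusion",
    "drop_triallelic",
]

DISQUALIFYING_EFFECTS = ("stop_lost", "stop_gained", "start_lost", "nonsyn_start")
# order fixed so exclusion reasons are deterministic: warnings first, then effects
EXCLUSION_ORDER = (
    "incomplete_transcript",
    "multiple_stop_codons",
    "no_start_codon",
) + DISQUALIFYING_EFFECTS

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclasses.dataclass
class SiteEffect:
    gene_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    effect: str
    codon_index: int
    within_codon_pos: int


def _translate_codon(codon: str) -> str:
    if codon in standard_dna_table.stop_codons:
        return "*"
    return standard_dna_table.forward_table[codon]


def effect_for_substitution(
    gene: GeneModel,
    genome: Mapping[str, str],
    pos: int,
    base_from: str,
    base_to: str,
) -> Optional[SiteEffect]:
    """Effect of a base_from -> base_to substitution (genomic strand) at pos.

    Returns None when pos is outside the gene's CDS. The codon context comes
    from the reference genome; ``base_from`` replaces the reference base in
    the "from" codon, which lets the pipeline annotate rare sites where
    neither observed allele matches the reference. Genes whose CDS length is
    not divisible by 3 are flagged ``incomplete_transcript`` and produce no
    effects (codon arithmetic would be meaningless).
    """
    if gene.cds_length % 3 != 0:
        gene.warnings.add("incomplete_transcript")
        return None
    positions = gene.cds_positions()  # coding order
    try:
        offset = positions.index(pos)
    except ValueError:
        return None

    cds = gene.cds_sequence(genome)
    codon_index = offset // 3
    within = offset % 3
    context = cds[codon_index * 3 : codon_index * 3 + 3]

    if gene.strand == "+":
        from_base, to_base = base_from, base_to
    else:
        from_base = base_from.translate(_COMPLEMENT)
        to_base = base_to.translate(_COMPLEMENT)
    from_codon = context[:within] + from_base + context[within + 1 :]
    to_codon = context[:within] + to_base + context[within + 1 :]

    from_aa = _translate_codon(from_codon)
    to_aa = _translate_codon(to_codon)

    if from_aa == to_aa:
        effect = "synonymous"
    elif codon_index == 0:
        # ATG is the only Met codon, so any non-synonymous change in an ATG
        # start destroys it; nonsyn_start covers annotated non-ATG starts.
        effect = "start_lost" if from_codon == "ATG" else "nonsyn_start"
    elif to_aa == "*":
        effect = "stop_gained"
    elif from_aa == "*":
        effect = "stop_lost"
    else:
        effect = "nonsynonymous"

    return SiteEffect(
        gene_id=gene.gene_id,
        chrom=gene.chrom,
        pos=pos,
        ref_allele=base_from,
        alt_allele=base_to,
        effect=effect,
        codon_index=codon_index,
        within_codon_pos=within,
    )


def predict_effect(
    variant: VariantRecord,
    gene: GeneModel,
    genome: Mapping[str, str],
    alt: Optional[str] = None,
) -> Optional[SiteEffect]:
    """Predict the coding effect of a single-ALT SNV on one gene.

    Returns None when the position falls outside the gene's CDS; raises when
    the record's REF disagrees with the attached genome.
    """
    if alt is None:
        if len(variant.alts) != 1:
            raise ValueError(
                f"{variant.chrom}:{variant.pos}: predict_effect needs a single ALT"
            )
        alt = variant.alts[0]
    if len(variant.ref) != 1 or len(alt) != 1:
        raise ValueError(f"{variant.chrom}:{variant.pos}: not an SNV")
    if variant.chrom != gene.chrom:
        return None
    genome_base = genome[gene.chrom][variant.pos - 1]
    if gene.cds_length % 3 == 0 and variant.pos in set(gene.cds_positions()):
        if genome_base != variant.ref:
            raise ValueError(
                f"{gene.gene_id} {variant.chrom}:{variant.pos}: reference allele "
                f"{variant.ref} does not match genome base {genome_base}"
            )
    return effect_for_substitution(gene, genome, variant.pos, variant.ref, alt)


def gene_exclusion(
    gene: GeneModel, effects: Sequence[SiteEffect]
) -> tuple[bool, Optional[str]]:
    """Decide whether a gene survives annotation-level exclusion.

    A gene is excluded if it carries any model warning (incomplete
    transcript, multiple stop codons, no start codon) or any variant with a
    disqualifying effect (stop gained/lost, start lost, non-synonymous
    start). Returns (keep, reason); reason is the first matching rule in the
    fixed order.
    """
    present = set(gene.warnings) | {
        e.effect for e in effects if e.gene_id == gene.gene_id
    }
    for reason in EXCLUSION_ORDER:
        if reason in present:
            return (False, reason)
    return (True, None)


def drop_triallelic(
    focal: Sequence[VariantRecord], outgroup: Sequence[VariantRecord]
) -> tuple[list[VariantRecord], list[VariantRecord], set[tuple[str, int]]]:
    """Remove sites whose observed-allele union across both species exceeds 2.

    An allele counts toward the union only if it has at least one called
    genotype copy in either species; an ALT listed in a VCF but never called
    does not make a site triallelic. Returns the kept focal records, kept
    outgroup records, and the removed (chrom, pos) keys.
    """
    union: dict[tuple[str, int], set[str]] = defaultdict(set)
    for rec in list(focal) + list(outgroup):
        union[(rec.chrom, rec.pos)] |= rec.observed_alleles()
    removed = {key for key, alleles in union.items() if len(alleles) > 2}
    keep_f = [r for r in focal if (r.chrom, r.pos) not in removed]
    keep_o = [r for r in outgroup if (r.chrom, r.pos) not in removed]
    return keep_f, keep_o, removed
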