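"""Effect prediction against a brute-force translate-and-diff oracle."""

import numpy as np
import pytest
from Bio.Seq import Seq

from mksel.effect_annotation import (
    drop_triallelic,
    effect_for_substitution,
    gene_exclusion,
    predict_effect,
)
from mksel.io_formats import GeneModel, VariantRecord


def make_gene(cds, strand="+", offset=10, gene_id="g"):
    """Embed a CDS in a padded chromosome; returns (gene, genome)."""
    genomic = cds if strand == "+" else str(Seq(cds).reverse_complement())
    chrom = "N" * offset + genomic + "N" * 10
    gene = GeneModel(gene_id, "chr1", strand, [(offset + 1, offset + len(cds))])
    return gene, {"chr1": chrom}


def snv(pos, ref, alt):
    return VariantRecord("chr1", pos, ref, [alt], [(0, 1)], [30])


class TestCodonExamples:
    def test_third_position_synonymous(self):
        gene, genome = make_gene("ATGGCTTAA")  # M A *
        eff = predict_effect(snv(16, "T", "C"), gene, genome)  # GCT -> GCC
        assert eff.effect == "synonymous"
        assert (eff.codon_index, eff.within_codon_pos) == (1, 2)

    def test_second_position_nonsynonymous(self):
        gene, genome = make_gene("ATGGCTTAA")
        eff = predict_effect(snv(15, "C", "T"), gene, genome)  # GCT -> GTT, Ala->Val
        assert eff.effect == "nonsynonymous"

    def test_stop_gained(self):
        gene, genome = make_gene("ATGTGGTAA")  # M W *
        eff = predict_effect(snv(16, "G", "A"), gene, genome)  # TGG -> TGA
        assert eff.effect == "stop_gained"

    def test_stop_lost(self):
        gene, genome = make_gene("ATGGCTTAA")
        eff = predict_effect(snv(17, "T", "C"), gene, genome)  # TAA -> CAA
        assert eff.effect == "stop_lost"

    def test_start_lost_and_nonsyn_start(self):
        gene, genome = make_gene("ATGGCTTAA")
        eff = predict_effect(snv(11, "A", "G"), gene, genome)  # ATG -> GTG
        assert eff.effect == "start_lost"
        # annotated non-ATG start: codon-0 change that is non-synonymous
        gene2, genome2 = make_gene("GTGGCTTAA")
        eff2 = predict_effect(snv(13, "G", "C"), gene2, genome2)  # GTG -> GTC, V->V? no: GTC is Val
        # GTG->GTC is synonymous (both Val); use position 1 instead
        eff3 = predict_effect(snv(12, "T", "C"), gene2, genome2)  # GTG -> GCG, V->A
        assert eff2.effect == "synonymous"
        assert eff3.effect == "nonsyn_start"

    def test_position_outside_cds_returns_none(self):
        gene, genome = make_gene("ATGGCTTAA")
        assert predict_effect(snv(5, "N", "A"), gene, genome) is None

    def test_incomplete_transcript_no_effects(self):
        gene, genome = make_gene("ATGGCTTA")  # length 8
        assert predict_effect(snv(14, "G", "A"), gene, genome) is None
        assert "incomplete_transcript" in gene.warnings


def _random_gene(rng, n_codons=30, strand="+"):
    body_choices = [
        c
        for c in ("".join(p) for p in __import__("itertools").product("ACGT", repeat=3))
        if c not in ("TAA", "TAG", "TGA")
    ]
    body = "".join(rng.choice(body_choices) for _ in range(n_codons))
    return make_gene("ATG" + body + "TAA", strand=strand)


def brute_force_effect(gene, genome, pos, alt):
    """Oracle: substitute the base in the genome, re-splice, translate the
    whole mutant CDS and diff the proteins."""
    chrom = genome[gene.chrom]
    mutant = {gene.chrom: chrom[: pos - 1] + alt + chrom[pos:]}
    ref_prot = str(Seq(gene.cds_sequence(genome)).translate())
    alt_prot = str(Seq(gene.cds_sequence(mutant)).translate())
    diffs = [(i, a, b) for i, (a, b) in enumerate(zip(ref_prot, alt_prot)) if a != b]
    if not diffs:
        return "synonymous", None
    (i, a, b) = diffs[0]
    if i == 0:
        return ("start_lost" if ref_prot[0] == "M" else "nonsyn_start"), i
    if b == "*":
        return "stop_gained", i
    if a == "*":
        return "stop_lost", i
    return "nonsynonymous", i


def test_agrees_with_brute_force_oracle_on_random_snvs():
    rng = np.random.default_rng(11)
    checked = 0
    while checked < 1000:
        strand = "+" if rng.random() < 0.5 else "-"
        gene, genome = _random_gene(rng, strand=strand)
        positions = gene.cds_positions()
        pos = int(positions[rng.integers(len(positions))])
        ref = genome[gene.chrom][pos - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        expected, codon_idx = brute_force_effect(gene, genome, pos, alt)
        eff = predict_effect(snv(pos, ref, alt), gene, genome)
        assert eff is not None
        assert eff.effect == expected, (strand, pos, ref, alt)
        if codon_idx is not None:
            assert eff.codon_index == codon_idx
        checked += 1


def test_strand_symmetry_mirror_gene_same_labels():
    """A gene and its reverse-complement mirror give identical effects."""
    rng = np.random.default_rng(4)
    gene_p, genome_p = _random_gene(rng, strand="+")
    cds = gene_p.cds_sequence(genome_p)
    gene_m, genome_m = make_gene(cds, strand="-")
    pos_p = gene_p.cds_positions()
    pos_m = gene_m.cds_positions()
    comp = str.maketrans("ACGT", "TGCA")
    for k in range(0, len(pos_p), 7):
        ref_p = genome_p[gene_p.chrom][pos_p[k] - 1]
        alt_p = "A" if ref_p != "A" else "G"
        eff_p = predict_effect(snv(pos_p[k], ref_p, alt_p), gene_p, genome_p)
        ref_m = genome_m[gene_m.chrom][pos_m[k] - 1]
        alt_m = alt_p.translate(comp)
        eff_m = predict_effect(snv(pos_m[k], ref_m, alt_m), gene_m, genome_m)
        assert eff_p.effect == eff_m.effect
        assert eff_p.codon_index == eff_m.codon_index


class TestGeneExclusion:
    def test_warning_excludes(self):
        gene, genome = make_gene("ATGGCTTAA")
        gene.warnings.add("multiple_stop_codons")
        keep, reason = gene_exclusion(gene, [])
        assert not keep and reason == "multiple_stop_codons"

    def test_clean_gene_kept(self):
        gene, genome = make_gene("ATGGCTTAA")
        eff = predict_effect(snv(16, "T", "C"), gene, genome)
        keep, reason = gene_exclusion(gene, [eff])
        assert keep and reason is None

    def test_disqualifying_effect_excludes(self):
        gene, genome = make_gene("ATGTGGTAA")
        eff = predict_effect(snv(16, "G", "A"), gene, genome)
        keep, reason = gene_exclusion(gene, [eff])
        assert not keep and reason == "stop_gained"


class TestDropTriallelic:
    def _rec(self, pos, ref, alts, gts):
        return VariantRecord("chr1", pos, ref, alts, gts, [30] * len(gts))

    def test_cross_species_union_exceeding_two_removed(self):
        focal = [self._rec(5, "A", ["G"], [(0, 1)])]
        outg = [self._rec(5, "A", ["T"], [(1, 1)])]
        kf, ko, removed = drop_triallelic(focal, outg)
        assert removed == {("chr1", 5)}
        assert kf == [] and ko == []

    def test_shared_biallelic_kept(self):
        focal = [self._rec(5, "A", ["G"], [(0, 1)])]
        outg = [self._rec(5, "A", ["G"], [(1, 1)])]
        kf, ko, removed = drop_triallelic(focal, outg)
        assert removed == set() and len(kf) == 1 and len(ko) == 1

    def test_uncalled_alt_does_not_count(self):
        # second ALT T declared but no genotype carries allele 2
        focal = [self._rec(5, "A", ["G", "T"], [(0, 1), (0, 0)])]
        outg = [self._rec(5, "A", ["G"], [(1, 1)])]
        _, _, removed = drop_triallelic(focal, outg)
        assert removed == set()

    def test_order_independent(self):
        focal = [self._rec(5, "A", ["G"], [(0, 1)]), self._rec(9, "C", ["T"], [(0, 1)])]
        outg = [self._rec(5, "A", ["T"], [(1, 1)])]
        r1 = drop_triallelic(focal, outg)[2]
        r2 = drop_triallelic(focal[::-1], outg)[2]
        assert r1 == r2 == {("chr1", 5)}
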