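"""End-to-end orchestration: filter -> annotate -> classify -> MK tables.

The pipeline consumes two per-species VCFs plus a genome, gene models, an
optional homology mask and a per-CDS-base depth table, and produces per-gene
MK tables together with a run manifest whose stage counts reconcile (the
records leaving one stage are the records entering the next).

A site present in only one species' VCF is treated as fixed for the
reference in the other species (the joint-calling convention); a site
removed by the quality filters in either species is removed entirely.
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict
from typing import Mapping, Optional, Sequence

from . import mk_tables as mk
from .effect_annotation import (
    SiteEffect,
    drop_triallelic,
    effect_for_substitution,
    gene_exclusion,
)
from .io_formats import GeneModel, VariantRecord, attach_warnings
from .mk_tables import MKTable, build_mk_table, classify_site
from .variant_filtering import FilterConfig, Removal, apply_site_filters, gene_coverage_filter

__all__ = ["PipelineResult", "run_variant_pipeline"]


@dataclasses.dataclass
class PipelineResult:
    tables: list[MKTable]
    kept_genes: list[str]
    excluded_genes: dict[str, str]  # gene_id -> reason
    removals: dict[str, list[Removal]]  # per species
    site_classes: dict[tuple[str, int], str]
    effects: list[SiteEffect]
    manifest: dict


def _split_indels(
    records: Sequence[VariantRecord],
) -> tuple[list[VariantRecord], list[Removal]]:
    snvs, removed = [], []
    for r in records:
        if r.is_snv:
            snvs.append(r)
        else:
            removed.append(Removal(r.chrom, r.pos, "indel"))
    return snvs, removed


def _species_alleles(rec: Optional[VariantRecord], ref: str) -> list[str]:
    """Called allele strings for one species; absent record = fixed reference."""
    if rec is None:
        return [ref, ref]
    alleles = [rec.ref] + list(rec.alts)
    out = [alleles[a] for gt in rec.genotypes for a in gt if a is not None]
    return out


def run_variant_pipeline(
    genome: Mapping[str, str],
    genes: Sequence[GeneModel],
    focal_records: Sequence[VariantRecord],
    outgroup_records: Sequence[VariantRecord],
    focal_config: Optional[FilterConfig] = None,
    outgroup_config: Optional[FilterConfig] = None,
    per_base_depth: Optional[Mapping[tuple[str, int], float]] = None,
) -> PipelineResult:
    """Run filtering, annotation, site classification and MK table assembly."""
    focal_config = focal_config or FilterConfig(max_missing_fraction=0.2)
    outgroup_config = outgroup_config or FilterConfig(max_missing_fraction=0.0)

    manifest: dict = {"stages": {}}
    manifest["stages"]["input"] = {
        "focal_records": len(focal_records),
        "outgroup_records": len(outgroup_records),
        "genes": len(genes),
    }

    # 1. indels out, then per-species site filters
    focal_snv, focal_indel = _split_indels(focal_records)
    out_snv, out_indel = _split_indels(outgroup_records)
    focal_kept, focal_removed = apply_site_filters(focal_snv, focal_config)
    out_kept, out_removed = apply_site_filters(out_snv, outgroup_config)
    removals = {
        "focal": focal_indel + focal_removed,
        "outgroup": out_indel + out_removed,
    }
    # a site failing filters in either species is dropped from both
    bad_sites = {(r.chrom, r.pos) for rs in removals.values() for r in rs}
    n_focal_before, n_out_before = len(focal_kept), len(out_kept)
    focal_kept = [r for r in focal_kept if (r.chrom, r.pos) not in bad_sites]
    out_kept = [r for r in out_kept if (r.chrom, r.pos) not in bad_sites]
    manifest["stages"]["site_filters"] = {
        "focal_kept": len(focal_kept),
        "outgroup_kept": len(out_kept),
        "removed_focal": len(removals["focal"]),
        "removed_outgroup": len(removals["outgroup"]),
        "cross_dropped_focal": n_focal_before - len(focal_kept),
        "cross_dropped_outgroup": n_out_before - len(out_kept),
    }

    # 2. cross-species triallelic removal
    focal_kept, out_kept, triallelic_sites = drop_triallelic(focal_kept, out_kept)
    manifest["stages"]["triallelic"] = {
        "removed_sites": len(triallelic_sites),
        "focal_kept": len(focal_kept),
        "outgroup_kept": len(out_kept),
    }

    # 3. gene warnings and coverage exclusion
    for g in genes:
        attach_warnings(g, genome)
    excluded: dict[str, str] = {}
    if per_base_depth is not None:
        for gid in sorted(gene_coverage_filter(genes, per_base_depth, focal_config)):
            excluded.setdefault(gid, "low_coverage")

    # 4. merge per site, classify, annotate
    by_site: dict[tuple[str, int], dict[str, VariantRecord]] = defaultdict(dict)
    for r in focal_kept:
        by_site[(r.chrom, r.pos)]["focal"] = r
    for r in out_kept:
        by_site[(r.chrom, r.pos)]["outgroup"] = r

    gene_by_pos: dict[tuple[str, int], GeneModel] = {}
    for g in genes:
        for p in g.cds_positions():
            gene_by_pos[(g.chrom, p)] = g

    site_classes: dict[tuple[str, int], str] = {}
    effects: list[SiteEffect] = []
    per_gene_sites: dict[str, list[tuple[str, Optional[str]]]] = defaultdict(list)

    for key in sorted(by_site):
        recs = by_site[key]
        any_rec = recs.get("focal") or recs.get("outgroup")
        ref = any_rec.ref
        focal_alleles = _species_alleles(recs.get("focal"), ref)
        out_alleles = _species_alleles(recs.get("outgroup"), ref)
        site_class = classify_site(focal_alleles, out_alleles, ref=ref)
        site_classes[key] = site_class

        gene = gene_by_pos.get(key)
        if gene is None:
            continue
        observed = set(focal_alleles) | set(out_alleles)
        non_ref = sorted(observed - {ref})
        effect: Optional[SiteEffect] = None
        if len(non_ref) == 1:
            effect = effect_for_substitution(gene, genome, key[1], ref, non_ref[0])
        elif len(non_ref) == 2:
            # neither observed allele is the reference; annotate the change
            # between the two observed states (codon context from genome)
            effect = effect_for_substitution(
                gene, genome, key[1], non_ref[0], non_ref[1]
            )
        if effect is not None:
            effects.append(effect)
        effect_label = effect.effect if effect is not None else None
        if effect_label in ("synonymous", "nonsynonymous") or effect_label is None:
            per_gene_sites[gene.gene_id].append((site_class, effect_label))
        else:
            # disqualifying effect: gene will be excluded; site not counted
            per_gene_sites[gene.gene_id].append((mk.INVARIANT, None))

    # 5. gene-level exclusion by warnings and disqualifying effects
    for g in genes:
        if g.gene_id in excluded:
            continue
        keep, reason = gene_exclusion(g, effects)
        if not keep:
            excluded[g.gene_id] = reason

    # 6. MK tables for surviving genes
    tables: list[MKTable] = []
    kept_genes: list[str] = []
    for g in genes:
        if g.gene_id in excluded:
            continue
        kept_genes.append(g.gene_id)
        classified = [
            (sc, eff)
            for sc, eff in per_gene_sites.get(g.gene_id, [])
            if not (sc in (mk.POLYMORPHISM, mk.DIVERGENCE) and eff is None)
        ]
        tables.append(build_mk_table(g.gene_id, classified))

    manifest["stages"]["genes"] = {
        "input": len(genes),
        "excluded": len(excluded),
        "kept": len(kept_genes),
    }
    sf = manifest["stages"]["site_filters"]
    tri = manifest["stages"]["triallelic"]
    manifest["reconciles"] = (
        manifest["stages"]["genes"]["input"]
        == manifest["stages"]["genes"]["excluded"] + manifest["stages"]["genes"]["kept"]
        and manifest["stages"]["input"]["focal_records"]
        == sf["removed_focal"]
        + sf["cross_dropped_focal"]
        + (sf["focal_kept"] - tri["focal_kept"])
        + tri["focal_kept"]
        and manifest["stages"]["input"]["outgroup_records"]
        == sf["removed_outgroup"]
        + sf["cross_dropped_outgroup"]
        + (sf["outgroup_kept"] - tri["outgroup_kept"])
        + tri["outgroup_kept"]
    )
    return PipelineResult(
        tables=tables,
        kept_genes=kept_genes,
        excluded_genes=excluded,
        removals=removals,
        site_classes=site_classes,
        effects=effects,
        manifest=manifest,
    )
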