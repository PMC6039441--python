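"""Site- and gene-level quality filters applied before effect annotation.

Site filters run in a fixed order — hard filters, depth, missingness,
homology mask — so each removal carries one deterministic reason code.
Defaults for the hard filters follow the GATK germline hard-filter
recommendations (QD < 2, FS > 60, MQ < 40, MQRankSum < -12.5,
ReadPosRankSum < -8); every threshold is configurable and an absent metric
passes. The gene-level rule removes a gene when more than 10% of its coding
sequence has depth below the lower limit.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Optional, Sequence

from .io_formats import GeneModel, VariantRecord

__all__ = ["FilterConfig", "apply_site_filters", "gene_coverage_filter", "Removal"]

# (metric, comparator, threshold): fail when metric <comparator> threshold
DEFAULT_HARD_FILTERS: tuple[tuple[str, str, float], ...] = (
    ("QD", "<", 2.0),
    ("FS", ">", 60.0),
    ("MQ", "<", 40.0),
    ("MQRankSum", "<", -12.5),
    ("ReadPosRankSum", "<", -8.0),
)


@dataclasses.dataclass
class FilterConfig:
    hard_filters: tuple[tuple[str, str, float], ...] = DEFAULT_HARD_FILTERS
    depth_lower: float = 8.0
    depth_upper: float = 100.0
    max_missing_fraction: float = 0.2
    mask_intervals: tuple[tuple[str, int, int], ...] = ()
    gene_low_coverage_max_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.depth_lower > self.depth_upper:
            raise ValueError("depth_lower exceeds depth_upper")
        if not 0.0 <= self.max_missing_fraction <= 1.0:
            raise ValueError("max_missing_fraction outside [0, 1]")
        if not 0.0 <= self.gene_low_coverage_max_fraction <= 1.0:
            raise ValueError("gene_low_coverage_max_fraction outside [0, 1]")


@dataclasses.dataclass
class Removal:
    chrom: str
    pos: int
    reason: str


_COMPARATORS = {"<": lambda a, b: a < b, ">": lambda a, b: a > b,
                "<=": lambda a, b: a <= b, ">=": lambda a, b: a >= b}


def _hard_filter_reason(rec: VariantRecord, cfg: FilterConfig) -> Optional[str]:
    for metric, op, threshold in cfg.hard_filters:
        value = rec.site_annotations.get(metric)
        if value is None:
            continue  # absent metric passes
        if _COMPARATORS[op](value, threshold):
            return f"hard_{metric}"
    return None


def _in_mask(rec: VariantRecord, mask: Iterable[tuple[str, int, int]]) -> bool:
    return any(c == rec.chrom and s <= rec.pos <= e for c, s, e in mask)


def apply_site_filters(
    records: Sequence[VariantRecord], config: FilterConfig
) -> tuple[list[VariantRecord], list[Removal]]:
    """Partition records into kept and removed, with one reason per removal.

    A record is removed iff it fails a hard-filter metric, its per-site mean
    depth falls outside [depth_lower, depth_upper], its missing-genotype
    fraction exceeds max_missing_fraction, or it intersects a mask interval;
    the recorded reason is the first failing rule in that order. Records are
    never mutated: kept + removed partition the input.
    """
    kept: list[VariantRecord] = []
    removed: list[Removal] = []
    for rec in records:
        reason = _hard_filter_reason(rec, config)
        if reason is None:
            depth = rec.mean_depth()
            if depth < config.depth_lower:
                reason = "depth_low"
            elif depth > config.depth_upper:
                reason = "depth_high"
            elif rec.missing_fraction() > config.max_missing_fraction:
                reason = "missingness"
            elif _in_mask(rec, config.mask_intervals):
                reason = "mask"
        if reason is None:
            kept.append(rec)
        else:
            removed.append(Removal(rec.chrom, rec.pos, reason))
    return kept, removed


def gene_coverage_filter(
    gene_models: Sequence[GeneModel],
    per_base_depth: Mapping[tuple[str, int], float],
    config: FilterConfig,
) -> set[str]:
    """Gene ids whose CDS has low coverage over more than the allowed fraction.

    A CDS base is low-coverage when its (sample-averaged) depth is below
    ``depth_lower``; a base absent from the depth map counts as depth 0. The
    comparison is strictly greater: a gene at exactly the threshold is kept.
    """
    excluded: set[str] = set()
    for gene in gene_models:
        length = gene.cds_length
        if length == 0:
            raise ValueError(f"gene {gene.gene_id}: zero CDS length")
        n_low = sum(
            1
            for s, e in gene.cds_intervals
            for p in range(s, e + 1)
            if per_base_depth.get((gene.chrom, p), 0.0) < config.depth_lower
        )
        if n_low / length > config.gene_low_coverage_max_fraction:
            excluded.add(gene.gene_id)
    return excluded
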