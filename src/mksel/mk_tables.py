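"""Site classification and per-gene McDonald-Kreitman count tables.

A surviving biallelic CDS site is a polymorphism if either species segregates
for it, a fixed difference if both species are monomorphic for different
alleles, and is removed if both species are fixed for the same allele (no
information about either polymorphism or divergence). Triallelic sites were
removed upstream but are re-checked here defensively.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = ["MKTable", "SiteClass", "classify_site", "build_mk_table", "tables_to_frame"]


class UncallableSiteError(ValueError):
    """A species has zero called genotype copies at a site that reached
    classification; such sites must be removed by the missingness filter."""


@dataclasses.dataclass
class MKTable:
    """Per-gene counts of non-synonymous/synonymous polymorphisms (PN, PS)
    and fixed differences (DN, DS)."""

    gene_id: str
    PN: int = 0
    PS: int = 0
    DN: int = 0
    DS: int = 0
    n_removed_triallelic: int = 0
    n_removed_same_fixed: int = 0

    def __post_init__(self) -> None:
        for name in ("PN", "PS", "DN", "DS"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.gene_id}: negative count {name}")

    @property
    def total(self) -> int:
        return self.PN + self.PS + self.DN + self.DS

    @property
    def all_zero(self) -> bool:
        return self.total == 0


# classification outcomes
POLYMORPHISM = "polymorphism"
DIVERGENCE = "divergence"
REMOVE_SAME_FIXED = "remove_same_fixed"
REMOVE_TRIALLELIC = "remove_triallelic"
INVARIANT = "invariant"

SiteClass = str


def classify_site(
    focal_alleles: Sequence[str],
    outgroup_alleles: Sequence[str],
    ref: Optional[str] = None,
) -> SiteClass:
    """Classify one site from the called allele copies of each species.

    Precedence: triallelic removal first; then segregation in either species
    makes the site a polymorphism (even if the outgroup is fixed for one of
    the two alleles); both-fixed-different is a divergence. Both species fixed
    for the same allele is removed when that allele differs from the
    reference (``remove_same_fixed``) and invariant when it is the reference.
    """
    if len(focal_alleles) == 0 or len(outgroup_alleles) == 0:
        raise UncallableSiteError("species with zero called copies at classified site")
    focal = set(focal_alleles)
    outgroup = set(outgroup_alleles)
    union = focal | outgroup
    if len(union) > 2:
        return REMOVE_TRIALLELIC
    if len(focal) > 1 or len(outgroup) > 1:
        return POLYMORPHISM
    # both monomorphic
    if focal == outgroup:
        allele = next(iter(focal))
        if ref is not None and allele == ref:
            return INVARIANT
        return REMOVE_SAME_FIXED
    return DIVERGENCE


def build_mk_table(
    gene_id: str,
    classified: Iterable[tuple[SiteClass, str]],
) -> MKTable:
    """Cross-tabulate classified sites into an MK table.

    ``classified`` yields (site class, effect) pairs where effect is
    "synonymous" or "nonsynonymous" for polymorphism/divergence sites (it is
    ignored for removed/invariant sites). Genes with zero surviving sites
    yield an all-zero table that downstream estimators flag rather than drop.
    """
    counts: Counter = Counter()
    for site_class, effect in classified:
        if site_class in (POLYMORPHISM, DIVERGENCE):
            if effect not in ("synonymous", "nonsynonymous"):
                raise ValueError(
                    f"{gene_id}: site class {site_class} needs a syn/nonsyn effect, "
                    f"got {effect!r}"
                )
            counts[(site_class, effect)] += 1
        elif site_class in (REMOVE_SAME_FIXED, REMOVE_TRIALLELIC, INVARIANT):
            counts[(site_class, None)] += 1
        else:
            raise ValueError(f"{gene_id}: unknown site class {site_class!r}")
    return MKTable(
        gene_id=gene_id,
        PN=counts[(POLYMORPHISM, "nonsynonymous")],
        PS=counts[(POLYMORPHISM, "synonymous")],
        DN=counts[(DIVERGENCE, "nonsynonymous")],
        DS=counts[(DIVERGENCE, "synonymous")],
        n_removed_triallelic=counts[(REMOVE_TRIALLELIC, None)],
        n_removed_same_fixed=counts[(REMOVE_SAME_FIXED, None)],
    )


def tables_to_frame(tables: Sequence[MKTable]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [t.gene_id for t in tables],
            "PN": [t.PN for t in tables],
            "PS": [t.PS for t in tables],
            "DN": [t.DN for t in tables],
            "DS": [t.DS for t in tables],
            "n_removed_triallelic": [t.n_removed_triallelic for t in tables],
            "n_removed_same_fixed": [t.n_removed_same_fixed for t in tables],
        }
    )
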