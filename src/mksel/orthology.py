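"""Reciprocal-best-hit orthology from pairwise protein-similarity tables.

Hits above the E-value threshold (default 1e-10, inclusive) are discarded;
per query, every subject attaining the maximum bitscore is kept as a best
hit, so tied scores yield one-to-many candidates and reciprocity decides
which survive. Three-way ortholog sets require cycle consistency across the
three pairwise maps.
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict
from typing import Iterable, Mapping, Sequence

from .io_formats import HitRow

__all__ = ["OrthologMap", "best_hits", "reciprocal_best", "threeway_orthologs"]

DEFAULT_EVALUE_THRESHOLD = 1e-10


@dataclasses.dataclass
class OrthologMap:
    species_pair: tuple[str, str]
    pairs: set[tuple[str, str]]
    threshold_evalue: float = DEFAULT_EVALUE_THRESHOLD

    def genes_a(self) -> set[str]:
        return {a for a, _ in self.pairs}

    def genes_b(self) -> set[str]:
        return {b for _, b in self.pairs}

    def ambiguous_genes(self) -> set[str]:
        """Genes participating in more than one reciprocal pair (tied hits)."""
        count_a: dict[str, int] = defaultdict(int)
        count_b: dict[str, int] = defaultdict(int)
        for a, b in self.pairs:
            count_a[a] += 1
            count_b[b] += 1
        return {a for a, c in count_a.items() if c > 1} | {
            b for b, c in count_b.items() if c > 1
        }

    def transposed(self) -> "OrthologMap":
        return OrthologMap(
            species_pair=(self.species_pair[1], self.species_pair[0]),
            pairs={(b, a) for a, b in self.pairs},
            threshold_evalue=self.threshold_evalue,
        )


def best_hits(
    hits: Iterable[HitRow], threshold: float = DEFAULT_EVALUE_THRESHOLD
) -> dict[str, set[str]]:
    """Per-query best-subject sets after E-value thresholding.

    Duplicate (query, subject) rows keep the maximum bitscore; all subjects
    tied at the per-query maximum are retained.
    """
    dedup: dict[tuple[str, str], HitRow] = {}
    for h in hits:
        if h.evalue > threshold:
            continue
        key = (h.query_id, h.subject_id)
        if key not in dedup or h.bitscore > dedup[key].bitscore:
            dedup[key] = h
    by_query: dict[str, list[HitRow]] = defaultdict(list)
    for h in dedup.values():
        by_query[h.query_id].append(h)
    out: dict[str, set[str]] = {}
    for query, rows in by_query.items():
        top = max(r.bitscore for r in rows)
        out[query] = {r.subject_id for r in rows if r.bitscore == top}
    return out


def reciprocal_best(
    best_ab: Mapping[str, set[str]],
    best_ba: Mapping[str, set[str]],
    species_pair: tuple[str, str] = ("A", "B"),
    threshold: float = DEFAULT_EVALUE_THRESHOLD,
) -> OrthologMap:
    """Pairs (a, b) with b in A's best set and a in B's best set."""
    pairs = {
        (a, b)
        for a, subjects in best_ab.items()
        for b in subjects
        if a in best_ba.get(b, set())
    }
    return OrthologMap(species_pair=species_pair, pairs=pairs, threshold_evalue=threshold)


def threeway_orthologs(
    map_ab: OrthologMap, map_bc: OrthologMap, map_ac: OrthologMap
) -> tuple[set[tuple[str, str, str]], set[tuple[str, str, str]]]:
    """Cycle-consistent triples (a, b, c) across the three pairwise maps.

    Returns (triples, ambiguous): a triple is ambiguous when any of its
    members appears in more than one retained triple (tied best hits
    propagated through reciprocity).
    """
    bc = defaultdict(set)
    for b, c in map_bc.pairs:
        bc[b].add(c)
    ac_pairs = map_ac.pairs
    triples = {
        (a, b, c)
        for a, b in map_ab.pairs
        for c in bc.get(b, set())
        if (a, c) in ac_pairs
    }
    seen: dict[tuple[int, str], int] = defaultdict(int)
    for t in triples:
        for i, g in enumerate(t):
            seen[(i, g)] += 1
    ambiguous = {
        t for t in triples if any(seen[(i, g)] > 1 for i, g in enumerate(t))
    }
    return triples, ambiguous
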