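"""Cross-species and caste-bias statistics.

Covers the downstream battery run on per-gene selection estimates: caste-bias
classification from a differential-expression table, pairwise and three-way
overlap enrichment of positively selected gene sets over an ortholog-defined
universe, two-proportion contrasts, and gamma-by-class ANOVA with
Tukey-Kramer multiple comparisons.
"""

from __future__ import annotations

import dataclasses
import decimal
from typing import Mapping, Optional, Sequence

import numpy as np
import scipy.stats

from .io_formats import ExpressionRow

__all__ = [
    "CasteLabel",
    "EnrichmentResult",
    "classify_caste_bias",
    "overlap_fisher",
    "compare_two_proportions",
    "threeway_overlap_test",
    "gamma_by_class",
    "positive_fraction",
    "tukey_kramer",
]

LABELS = ("queen_biased", "worker_biased", "non_deg")


@dataclasses.dataclass
class CasteLabel:
    gene_id: str
    label: str


@dataclasses.dataclass
class EnrichmentResult:
    contingency_table: list[list[int]]
    odds_ratio: Optional[float]
    p_value: float
    test_name: str
    tail: str


def classify_caste_bias(
    rows: Sequence[ExpressionRow], fdr_threshold: float = 0.05, fpkm_threshold: float = 1.0
) -> list[CasteLabel]:
    """Label genes queen-biased / worker-biased / non-DEG.

    Merge-conflict loci are dropped first (they cannot be identified after
    transcript merging). A gene is queen-biased iff FDR < 0.05, queen FPKM
    > 1 and queen FPKM exceeds worker FPKM; worker-biased symmetrically;
    everything else is non-DEG.
    """
    out: list[CasteLabel] = []
    for r in rows:
        if r.merge_conflict:
            continue
        if r.fdr < fdr_threshold and r.fpkm_queen > fpkm_threshold and r.fpkm_queen > r.fpkm_worker:
            label = "queen_biased"
        elif r.fdr < fdr_threshold and r.fpkm_worker > fpkm_threshold and r.fpkm_worker > r.fpkm_queen:
            label = "worker_biased"
        else:
            label = "non_deg"
        out.append(CasteLabel(gene_id=r.gene_id, label=label))
    return out


def overlap_fisher(
    set_a: set[str], set_b: set[str], universe: set[str]
) -> EnrichmentResult:
    """One-tailed (enrichment) Fisher exact test of two gene sets' overlap.

    The 2x2 table cross-classifies the universe by membership in A and B;
    the p-value is the upper-tail hypergeometric sum P(X >= overlap).
    """
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("sets must be subsets of the universe")
    n = len(universe)
    a_and_b = len(set_a & set_b)
    a_only = len(set_a) - a_and_b
    b_only = len(set_b) - a_and_b
    neither = n - a_and_b - a_only - b_only
    table = [[a_and_b, a_only], [b_only, neither]]
    if not set_a or not set_b:
        return EnrichmentResult(table, None, 1.0, "fisher_exact", "one")
    odds, p = scipy.stats.fisher_exact(table, alternative="greater")
    odds_val = float(odds) if np.isfinite(odds) else None
    return EnrichmentResult(table, odds_val, float(p), "fisher_exact", "one")


def compare_two_proportions(
    k1: int, n1: int, k2: int, n2: int, method: str = "chisq"
) -> tuple[float, float]:
    """Compare k1/n1 vs k2/n2 on a 2x2 table.

    methods: "chisq" (Pearson, no continuity correction — the default),
    "chisq_yates" (continuity-corrected), "fisher" (two-sided exact; the
    first return value is then the odds ratio).
    """
    if k1 > n1 or k2 > n2:
        raise ValueError("successes exceed trials")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if method == "fisher":
        odds, p = scipy.stats.fisher_exact(table, alternative="two-sided")
        return float(odds), float(p)
    if method not in {"chisq", "chisq_yates"}:
        raise ValueError(f"unknown method {method!r}")
    if table.sum() == 0 or (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 0.0, 1.0
    stat, p, _, _ = scipy.stats.chi2_contingency(
        table, correction=(method == "chisq_yates")
    )
    return float(stat), float(p)


def threeway_overlap_test(
    set_a: set[str], set_b: set[str], set_c: set[str], universe: set[str]
) -> tuple[int, float, float, float]:
    """Chi-square test of mutual independence of three set memberships.

    The universe is cross-classified into the 8 cells of (in A) x (in B) x
    (in C); expected counts come from the product of marginal membership
    frequencies; df = 4 (8 cells - 1 - 3 estimated marginals). Returns
    (observed triple overlap, expected triple overlap, chi2, p).
    """
    for s in (set_a, set_b, set_c):
        if not s <= universe:
            raise ValueError("sets must be subsets of the universe")
    n = len(universe)
    if n == 0:
        raise ValueError("empty universe")
    obs = np.zeros((2, 2, 2))
    for g in universe:
        obs[int(g in set_a), int(g in set_b), int(g in set_c)] += 1
    pa, pb, pc = len(set_a) / n, len(set_b) / n, len(set_c) / n
    marg = [
        np.array([1 - pa, pa]),
        np.array([1 - pb, pb]),
        np.array([1 - pc, pc]),
    ]
    expected = n * np.einsum("i,j,k->ijk", *marg)
    if np.all(expected == obs):
        return int(obs[1, 1, 1]), float(expected[1, 1, 1]), 0.0, 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        cells = (obs - expected) ** 2 / expected
    chi2 = float(np.nansum(np.where(expected > 0, cells, 0.0)))
    p = float(scipy.stats.chi2.sf(chi2, df=4))
    return int(obs[1, 1, 1]), float(expected[1, 1, 1]), chi2, p


def tukey_kramer(
    groups: Sequence[np.ndarray],
) -> list[tuple[int, int, float, float]]:
    """Tukey-Kramer HSD pairwise comparisons for unequal group sizes.

    Returns (i, j, mean difference, adjusted p) per pair, using the
    studentized-range distribution with the pooled within-group variance;
    reduces to classic Tukey HSD when sizes are equal.
    """
    k = len(groups)
    ns = np.array([len(g) for g in groups])
    means = np.array([np.mean(g) for g in groups])
    df_within = int(ns.sum() - k)
    ss_within = sum(float(((g - m) ** 2).sum()) for g, m in zip(groups, means))
    ms_within = ss_within / df_within
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = means[i] - means[j]
            se = np.sqrt(ms_within / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            if se == 0.0:
                p = 1.0 if diff == 0.0 else 0.0
            else:
                q = abs(diff) / se
                p = float(scipy.stats.studentized_range.sf(q, k, df_within))
            out.append((i, j, float(diff), min(1.0, p)))
    return out


def gamma_by_class(
    gamma: Mapping[str, float], labels: Sequence[CasteLabel]
) -> dict:
    """One-way ANOVA of gamma across caste classes with Tukey-Kramer HSD.

    Genes without a gamma estimate are dropped. Returns group means with
    standard errors, the fixed-effects F statistic and p-value, and adjusted
    pairwise p-values keyed by class-name pairs.
    """
    by_class: dict[str, list[float]] = {lab: [] for lab in LABELS}
    for cl in labels:
        g = gamma.get(cl.gene_id)
        if g is not None and np.isfinite(g):
            by_class[cl.label].append(g)
    present = [lab for lab in LABELS if len(by_class[lab]) >= 2]
    if len(present) < 2:
        raise ValueError("need >= 2 groups with >= 2 members")
    arrays = [np.asarray(by_class[lab], dtype=float) for lab in present]
    if np.ptp(np.concatenate(arrays)) == 0:
        f_stat, p = 0.0, 1.0
    else:
        f_stat, p = scipy.stats.f_oneway(*arrays)
    groups = {
        lab: {
            "n": len(arr),
            "mean": float(arr.mean()),
            "sem": float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else float("nan"),
        }
        for lab, arr in zip(present, arrays)
    }
    tukey = {
        (present[i], present[j]): p_adj
        for i, j, _, p_adj in tukey_kramer(arrays)
    }
    return {
        "groups": groups,
        "anova_F": float(f_stat) if np.isfinite(f_stat) else 0.0,
        "anova_p": float(p) if np.isfinite(p) else 1.0,
        "df_between": len(present) - 1,
        "df_within": int(sum(len(a) for a in arrays) - len(present)),
        "tukey_p": tukey,
    }


def positive_fraction(
    labels: Sequence[CasteLabel], positive_set: set[str]
) -> dict[str, tuple[int, int, float]]:
    """Per-class (k, n, percent) of genes in the positively selected set.

    Percent is 100*k/n rounded half-up to one decimal, the display convention
    used for reported proportions.
    """
    out: dict[str, tuple[int, int, float]] = {}
    for lab in LABELS:
        members = [cl.gene_id for cl in labels if cl.label == lab]
        n = len(members)
        k = sum(1 for g in members if g in positive_set)
        if n == 0:
            out[lab] = (0, 0, 0.0)
            continue
        pct = float(
            decimal.Decimal(100.0 * k / n).quantize(
                decimal.Decimal("0.1"), rounding=decimal.ROUND_HALF_UP
            )
        )
        out[lab] = (k, n, pct)
    return out
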