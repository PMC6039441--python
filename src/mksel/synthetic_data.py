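"""Synthetic inputs with known ground truth for every pipeline stage.

Four generators cover the pipeline's inputs:

* PRF count tables — per-gene (PN, PS, DN, DS) drawn from the same Poisson
  random field parameterisation the hierarchical model inverts, so parameter
  recovery is well-posed;
* a two-species toy genome/VCF fixture that plants known MK counts and one
  instance of every filtering and exclusion rule, with a manifest recording
  what was planted where;
* a caste-biased differential-expression table with planted labels;
* protein-similarity hit tables with planted reciprocal-best structure and
  decoys (one-directional bests, above-threshold E-values, tied bitscores).

Defaults mirror the study design: ten diploid focal samples and two diploid
outgroup samples (n_focal = 20, n_outgroup = 4 haploid), a non-synonymous/
synonymous mutational opportunity ratio z = 2.5, and a gamma mixture tuned
so roughly a tenth of genes exceed gamma = 1.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .io_formats import ExpressionRow, GeneModel, HitRow
from .mk_tables import MKTable
from .selection_inference import prf_H, prf_Qratio

__all__ = [
    "SimulationTruth",
    "simulate_gamma_mixture",
    "gamma_mixture_exceedance",
    "simulate_mk_counts",
    "simulate_expression",
    "simulate_hit_tables",
    "simulate_two_species_vcf",
    "FixtureManifest",
]


@dataclasses.dataclass
class SimulationTruth:
    """Ground-truth parameters of the PRF count generator.

    theta_s is the per-gene synonymous polymorphism intensity, d the
    divergence intensity multiplier, z the non-synonymous/synonymous
    mutational opportunity ratio; n_focal and n_outgroup are haploid sample
    sizes.
    """

    gamma: np.ndarray
    theta_s: np.ndarray
    d: np.ndarray
    z: np.ndarray
    n_focal: int = 20
    n_outgroup: int = 4

    def __post_init__(self) -> None:
        n = len(self.gamma)
        for name in ("theta_s", "d", "z"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim == 0:
                arr = np.full(n, float(arr))
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != n_genes {n}")
            if not np.all(arr > 0):
                raise ValueError(f"{name} must be positive")
            setattr(self, name, arr)
        if self.n_focal < 2 or self.n_outgroup < 2:
            raise ValueError("haploid sample sizes must be >= 2")

    @classmethod
    def from_gamma(
        cls,
        gamma: np.ndarray,
        theta_s: float = 15.0,
        d: float = 1.0,
        z: float = 2.5,
        n_focal: int = 20,
        n_outgroup: int = 4,
    ) -> "SimulationTruth":
        g = np.asarray(gamma, dtype=float)
        return cls(
            gamma=g,
            theta_s=np.full(len(g), theta_s),
            d=np.full(len(g), d),
            z=np.full(len(g), z),
            n_focal=n_focal,
            n_outgroup=n_outgroup,
        )

    @classmethod
    def default(
        cls,
        n_genes: int,
        frac_positive: float = 0.12,
        seed: int = 0,
        theta_median: float = 15.0,
        theta_sdlog: float = 1.2,
        d: float = 1.0,
        z: float = 2.5,
        n_focal: int = 20,
        n_outgroup: int = 4,
    ) -> "SimulationTruth":
        """Study-condition truth: gamma from the positive/deleterious mixture
        and per-gene theta from a lognormal, reflecting the order-of-magnitude
        spread in mutational target size (gene length) that the model's
        gene-level random intercept exists to absorb."""
        gamma = simulate_gamma_mixture(n_genes, frac_positive, seed=seed)
        rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
        theta = np.exp(rng.normal(np.log(theta_median), theta_sdlog, size=n_genes))
        return cls(
            gamma=gamma,
            theta_s=theta,
            d=np.full(n_genes, d),
            z=np.full(n_genes, z),
            n_focal=n_focal,
            n_outgroup=n_outgroup,
        )


def simulate_gamma_mixture(
    n_genes: int,
    frac_positive: float = 0.12,
    seed: int = 0,
    neg_mean: float = -2.0,
    neg_sd: float = 1.5,
    pos_mean: float = 3.0,
    pos_shift: float = 0.0,
) -> np.ndarray:
    """Draw per-gene gamma from a deleterious/neutral + positive mixture.

    The deleterious/neutral component is Normal(neg_mean, neg_sd); the
    positive component is pos_shift + Exponential(mean pos_mean), strictly
    positive for pos_shift >= 0.
    """
    if not 0.0 <= frac_positive <= 1.0:
        raise ValueError("frac_positive outside [0, 1]")
    rng = np.random.default_rng(seed)
    positive = rng.random(n_genes) < frac_positive
    gamma = rng.normal(neg_mean, neg_sd, size=n_genes)
    n_pos = int(positive.sum())
    gamma[positive] = pos_shift + rng.exponential(pos_mean, size=n_pos)
    return gamma


def gamma_mixture_exceedance(
    frac_positive: float,
    threshold: float = 1.0,
    neg_mean: float = -2.0,
    neg_sd: float = 1.5,
    pos_mean: float = 3.0,
    pos_shift: float = 0.0,
) -> float:
    """Analytic P(gamma > threshold) of the mixture in simulate_gamma_mixture."""
    p_neg = scipy.stats.norm.sf(threshold, loc=neg_mean, scale=neg_sd)
    if threshold <= pos_shift:
        p_pos = 1.0
    else:
        p_pos = float(np.exp(-(threshold - pos_shift) / pos_mean))
    return frac_positive * p_pos + (1.0 - frac_positive) * float(p_neg)


def simulate_mk_counts(
    truth: SimulationTruth, seed: int = 0
) -> tuple[list[MKTable], pd.DataFrame]:
    """Draw per-gene MK tables from the PRF product-Poisson model.

    PS ~ Poisson(theta), PN ~ Poisson(theta * z * Qratio(gamma, n)),
    DS ~ Poisson(theta * d), DN ~ Poisson(theta * d * z * H(gamma)).
    """
    rng = np.random.default_rng(seed)
    n = truth.n_focal
    qr = np.array([prf_Qratio(g, n) for g in truth.gamma])
    h = np.array([prf_H(g) for g in truth.gamma])
    rates = np.column_stack(
        [
            truth.theta_s,
            truth.theta_s * truth.z * qr,
            truth.theta_s * truth.d,
            truth.theta_s * truth.d * truth.z * h,
        ]
    )
    if not np.all(np.isfinite(rates)):
        bad = int(np.argwhere(~np.isfinite(rates))[0][0])
        raise ValueError(f"non-finite Poisson rate for gene index {bad}")
    counts = rng.poisson(rates)
    tables = [
        MKTable(gene_id=f"g{i:05d}", PS=int(c[0]), PN=int(c[1]), DS=int(c[2]), DN=int(c[3]))
        for i, c in enumerate(counts)
    ]
    truth_df = pd.DataFrame(
        {
            "gene_id": [t.gene_id for t in tables],
            "gamma_true": truth.gamma,
            "theta_s": truth.theta_s,
            "d": truth.d,
            "z": truth.z,
        }
    )
    return tables, truth_df


# ---------------------------------------------------------------------------
# Expression table


def simulate_expression(
    n_genes: int = 7612,
    n_queen_biased: int = 114,
    n_worker_biased: int = 287,
    seed: int = 0,
    n_merge_conflict: int = 0,
) -> tuple[list[ExpressionRow], dict[str, str]]:
    """Expression rows with planted caste-bias labels.

    Biased genes get FDR < 0.05 and FPKM > 1 in the biased direction;
    non-DEG genes get either FDR >= 0.05 or FPKM <= 1. Returns the rows and
    the {gene_id: label} truth map (merge-conflict rows carry no label).
    """
    if n_queen_biased + n_worker_biased + n_merge_conflict > n_genes:
        raise ValueError("label counts exceed n_genes")
    rng = np.random.default_rng(seed)
    rows: list[ExpressionRow] = []
    labels: dict[str, str] = {}
    kinds = (
        ["queen_biased"] * n_queen_biased
        + ["worker_biased"] * n_worker_biased
        + ["merge_conflict"] * n_merge_conflict
        + ["non_deg"] * (n_genes - n_queen_biased - n_worker_biased - n_merge_conflict)
    )
    rng.shuffle(kinds)
    for i, kind in enumerate(kinds):
        gid = f"g{i:05d}"
        if kind == "queen_biased":
            hi = 1.0 + rng.exponential(20.0)
            lo = rng.uniform(0.0, hi * 0.5)
            row = ExpressionRow(gid, rng.uniform(0, 0.05 - 1e-9), hi, lo)
        elif kind == "worker_biased":
            hi = 1.0 + rng.exponential(20.0)
            lo = rng.uniform(0.0, hi * 0.5)
            row = ExpressionRow(gid, rng.uniform(0, 0.05 - 1e-9), lo, hi)
        elif kind == "merge_conflict":
            row = ExpressionRow(gid, rng.uniform(0, 1), rng.exponential(5), rng.exponential(5), True)
        else:
            if rng.random() < 0.8:
                row = ExpressionRow(gid, rng.uniform(0.05, 1.0), rng.exponential(5), rng.exponential(5))
            else:  # significant q-value but sub-threshold expression
                row = ExpressionRow(gid, rng.uniform(0, 0.05 - 1e-9), rng.uniform(0, 1.0), rng.uniform(0, 1.0))
        rows.append(row)
        if kind != "merge_conflict":
            labels[gid] = kind if kind in ("queen_biased", "worker_biased") else "non_deg"
    return rows, labels


# ---------------------------------------------------------------------------
# Hit tables


def simulate_hit_tables(
    n_shared: int = 50,
    n_a_only: int = 10,
    n_b_only: int = 10,
    seed: int = 0,
    n_above_threshold: int = 5,
    n_tied: int = 3,
) -> tuple[list[HitRow], list[HitRow], set[tuple[str, str]]]:
    """Hit tables with planted mutual best hits and decoys.

    True pairs (Ai, Bi) are mutual best hits below the E-value threshold.
    Decoys: A-only/B-only genes whose best hit is not reciprocated; pairs
    whose only hits sit above 1e-10; and tied-bitscore second subjects that
    survive the best-hit stage but fail reciprocity.
    """
    rng = np.random.default_rng(seed)
    ab: list[HitRow] = []
    ba: list[HitRow] = []
    true_pairs: set[tuple[str, str]] = set()
    for i in range(n_shared):
        a, b = f"A{i:04d}", f"B{i:04d}"
        score = float(200.0 + rng.integers(0, 300))
        ab.append(HitRow(a, b, 10.0 ** -rng.uniform(20, 80), score))
        ba.append(HitRow(b, a, 10.0 ** -rng.uniform(20, 80), score))
        true_pairs.add((a, b))
        # weaker secondary hit keeps the best-set non-trivial
        if i + 1 < n_shared:
            ab.append(HitRow(a, f"B{i + 1:04d}", 1e-15, score - 50.0))
    for i in range(n_a_only):
        # best hit of the A-only gene lands on a shared B gene whose own
        # best points back to its true partner: one-directional best
        target = f"B{int(rng.integers(0, max(n_shared, 1))):04d}" if n_shared else "Bx"
        ab.append(HitRow(f"Aonly{i:03d}", target, 1e-30, 150.0))
    for i in range(n_b_only):
        target = f"A{int(rng.integers(0, max(n_shared, 1))):04d}" if n_shared else "Ax"
        ba.append(HitRow(f"Bonly{i:03d}", target, 1e-30, 150.0))
    for i in range(n_above_threshold):
        a, b = f"Aweak{i:03d}", f"Bweak{i:03d}"
        ab.append(HitRow(a, b, 1e-5, 40.0))
        ba.append(HitRow(b, a, 1e-5, 40.0))
    for i in range(min(n_tied, n_shared - 1)):
        # tie the best bitscore of Ai with a second subject Bj (j = i+1);
        # both enter Ai's best set, reciprocity keeps only (Ai, Bi)
        a = f"A{i:04d}"
        own = [h for h in ab if h.query_id == a and h.subject_id == f"B{i:04d}"][0]
        ab.append(HitRow(a, f"B{i + 1:04d}", own.evalue, own.bitscore))
    return ab, ba, true_pairs


# ---------------------------------------------------------------------------
# Two-species VCF fixture

_SAFE_BODY_CODON = "CTT"  # no single-base change creates a stop codon
_COMP = str.maketrans("ACGT", "TGCA")


@dataclasses.dataclass
class _Plant:
    """One planted variant site."""

    gene_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    kind: str  # PN/PS/DN/DS/violation name
    species: str  # focal/outgroup/both


@dataclasses.dataclass
class FixtureManifest:
    expected_mk: dict[str, MKTable]
    violations: list[dict]
    excluded_genes: dict[str, str]  # gene_id -> expected reason
    low_coverage_gene: str
    n_focal_samples: int
    n_outgroup_samples: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "expected_mk": {
                g: dataclasses.asdict(t) for g, t in self.expected_mk.items()
            },
            "violations": self.violations,
            "excluded_genes": self.excluded_genes,
            "low_coverage_gene": self.low_coverage_gene,
            "n_focal_samples": self.n_focal_samples,
            "n_outgroup_samples": self.n_outgroup_samples,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _vcf_row(chrom, pos, ref, alts, info, gts, dps):
    info_str = ";".join(f"{k}={v}" for k, v in info.items()) if info else "."
    cols = [chrom, str(pos), ".", ref, ",".join(alts), ".", ".", info_str, "GT:DP"]
    for gt, dp in zip(gts, dps):
        cols.append(f"{gt}:{dp if dp is not None else '.'}")
    return "\t".join(cols)


def _write_vcf(path, chrom, chrom_len, samples, rows):
    header = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={chrom},length={chrom_len}>",
        '##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">',
        '##INFO=<ID=FS,Number=1,Type=Float,Description="Strand bias phred">',
        '##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">',
        '##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="MQ rank sum">',
        '##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Read pos rank sum">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    rows = sorted(rows, key=lambda r: int(r.split("\t")[1]))
    Path(path).write_text("\n".join(header + rows) + "\n")


class _FixtureBuilder:
    """Assembles the toy genome, gene models, planted variants and manifest."""

    def __init__(self, seed: int, n_clean_genes: int = 7, body_codons: int = 60):
        self.rng = np.random.default_rng(seed)
        self.chrom = "chr1"
        self.spacer = 100
        self.body_codons = body_codons
        self.n_clean = n_clean_genes
        self.genome_parts: list[str] = []
        self.cursor = 1  # next free 1-based position
        self.genes: list[GeneModel] = []
        self.focal_rows: list[str] = []
        self.out_rows: list[str] = []
        self.plants: list[_Plant] = []
        self.violations: list[dict] = []
        self.excluded: dict[str, str] = {}
        self.expected: dict[str, MKTable] = {}
        self.mask: list[tuple[str, int, int]] = []
        self.depth_override: dict[int, float] = {}
        self.n_focal = 10
        self.n_out = 2
        self.focal_samples = [f"f{i}" for i in range(1, 11)]
        self.out_samples = ["o1", "o2"]

    # -- genome construction ------------------------------------------------

    def _spacer_seq(self) -> str:
        return "".join(self.rng.choice(list("ACGT"), size=self.spacer))

    def add_gene(
        self, gene_id: str, cds: str, strand: str = "+", two_exons: bool = False
    ) -> GeneModel:
        self.genome_parts.append(self._spacer_seq())
        self.cursor += self.spacer
        genomic = cds if strand == "+" else _rc(cds)
        start = self.cursor
        if two_exons and len(genomic) >= 30:
            cut = (len(genomic) // 2) // 3 * 3 or 3
            intron = self._spacer_seq()[:30]
            self.genome_parts.append(genomic[:cut] + intron + genomic[cut:])
            iv = [
                (start, start + cut - 1),
                (start + cut + 30, start + len(genomic) + 29),
            ]
            self.cursor += len(genomic) + 30
        else:
            self.genome_parts.append(genomic)
            iv = [(start, start + len(genomic) - 1)]
            self.cursor += len(genomic)
        gene = GeneModel(gene_id=gene_id, chrom=self.chrom, strand=strand, cds_intervals=iv)
        self.genes.append(gene)
        return gene

    def genome(self) -> dict[str, str]:
        return {self.chrom: "".join(self.genome_parts)}

    # -- variant planting ---------------------------------------------------

    def _site(self, gene: GeneModel, codon_idx: int, within: int) -> tuple[int, str]:
        """Genomic position and genomic-strand ref base of a CDS coordinate."""
        offset = codon_idx * 3 + within
        pos = gene.cds_positions()[offset]
        ref = self.genome()[self.chrom][pos - 1]
        return pos, ref

    def _genomic_alt(self, gene: GeneModel, cds_alt: str) -> str:
        return cds_alt if gene.strand == "+" else cds_alt.translate(_COMP)

    def plant_site(
        self,
        gene: GeneModel,
        codon_idx: int,
        within: int,
        cds_alt: str,
        kind: str,
        focal_gts: Optional[list[str]] = None,
        out_gts: Optional[list[str]] = None,
        info: Optional[dict] = None,
        dp: int = 30,
        focal_dps: Optional[list] = None,
        out_dps: Optional[list] = None,
        alt_override: Optional[str] = None,
    ) -> _Plant:
        pos, ref = self._site(gene, codon_idx, within)
        alt = alt_override or self._genomic_alt(gene, cds_alt)
        assert alt != ref, f"planted alt equals ref at {pos}"
        plant = _Plant(gene.gene_id, self.chrom, pos, ref, alt, kind, "both")
        if focal_gts is not None:
            dps = focal_dps or [dp] * self.n_focal
            self.focal_rows.append(
                _vcf_row(self.chrom, pos, ref, [alt], info or {}, focal_gts, dps)
            )
        if out_gts is not None:
            dps = out_dps or [dp] * self.n_out
            self.out_rows.append(
                _vcf_row(self.chrom, pos, ref, [alt], info or {}, out_gts, dps)
            )
        self.plants.append(plant)
        return plant

    # convenience genotype vectors
    def f_seg(self, n_het: int = 3) -> list[str]:
        return ["0/1"] * n_het + ["0/0"] * (self.n_focal - n_het)

    def f_fixed(self, allele: str = "0") -> list[str]:
        return [f"{allele}/{allele}"] * self.n_focal

    def o_fixed(self, allele: str = "0") -> list[str]:
        return [f"{allele}/{allele}"] * self.n_out

    def o_seg(self) -> list[str]:
        return ["0/1", "0/0"]


def simulate_two_species_vcf(
    seed: int = 0,
    out_dir: Optional[str | Path] = None,
    n_clean_genes: int = 7,
    body_codons: int = 60,
    mk_rate: float = 3.0,
):
    """Build the end-to-end two-species fixture.

    Returns (genome, gene_models, focal_vcf_rows_path-or-records, ...) —
    when ``out_dir`` is given, writes genome.fasta, genes.gff3, focal.vcf,
    outgroup.vcf, mask.bed, depth.tsv and manifest.json there and returns
    the manifest; file-free use returns in-memory objects plus the manifest.

    Planted content: per clean gene, Poisson(mk_rate) many sites of each of
    PN/PS/DN/DS (recorded exactly); one planted instance of every site
    filter violation (hard filter, low/high depth, missingness, mask,
    indel), triallelic and same-allele-fixed sites, one low-coverage gene,
    one gene per disqualifying variant effect, one gene per model warning.
    """
    b = _FixtureBuilder(seed, n_clean_genes=n_clean_genes, body_codons=body_codons)
    rng = b.rng
    m = body_codons

    def clean_cds() -> str:
        return "ATG" + _SAFE_BODY_CODON * m + "TAA"

    # --- clean genes with planted MK counts
    used: dict[str, set[int]] = {}
    for i in range(n_clean_genes):
        gid = f"clean{i:02d}"
        strand = "+" if i % 2 == 0 else "-"
        gene = b.add_gene(gid, clean_cds(), strand=strand, two_exons=(i % 3 == 0))
        counts = {k: int(rng.poisson(mk_rate)) for k in ("PN", "PS", "DN", "DS")}
        # body codons 1..m are available; reserve distinct codons per site
        codons = rng.permutation(np.arange(1, m + 1))
        ci = 0
        for kind, n_sites in counts.items():
            for _ in range(n_sites):
                codon = int(codons[ci])
                ci += 1
                if kind in ("PS", "DS"):
                    within, cds_alt = 2, "C"  # CTT -> CTC, synonymous
                else:
                    within, cds_alt = 0, "A"  # CTT -> ATT, nonsynonymous
                if kind in ("PN", "PS"):
                    b.plant_site(
                        gene, codon, within, cds_alt, kind,
                        focal_gts=b.f_seg(int(rng.integers(1, b.n_focal))),
                        out_gts=b.o_fixed("0"),
                    )
                else:
                    b.plant_site(
                        gene, codon, within, cds_alt, kind,
                        focal_gts=b.f_fixed("0"),
                        out_gts=b.o_fixed("1"),
                    )
        b.expected[gid] = MKTable(gene_id=gid, **counts)

    host = b.genes[0]  # clean00 hosts the site-level violations
    free = [c for c in range(1, m + 1)]
    planted_codons = {
        (p.gene_id, (host.cds_positions().index(p.pos)) // 3)
        for p in b.plants
        if p.gene_id == host.gene_id
    }
    free = [c for c in free if (host.gene_id, c) not in planted_codons]
    it = iter(free)

    def next_codon() -> int:
        return next(it)

    def add_violation(kind: str, **kwargs):
        codon = next_codon()
        plant = b.plant_site(host, codon, 0, "A", kind, **kwargs)
        b.violations.append(
            {"chrom": plant.chrom, "pos": plant.pos, "reason": kind, "gene_id": host.gene_id}
        )
        return plant

    add_violation("hard_QD", focal_gts=b.f_seg(), out_gts=None, info={"QD": 1.0})
    add_violation("hard_FS", focal_gts=b.f_seg(), info={"FS": 75.0})
    add_violation("hard_MQ", focal_gts=b.f_seg(), info={"MQ": 25.0})
    add_violation("depth_low", focal_gts=b.f_seg(), dp=3)
    add_violation("depth_high", focal_gts=b.f_seg(), dp=500)
    add_violation(
        "missingness",
        focal_gts=["./."] * 3 + ["0/1"] * 2 + ["0/0"] * 5,
    )
    mask_plant = add_violation("mask", focal_gts=b.f_seg())
    b.mask.append((b.chrom, mask_plant.pos, mask_plant.pos))

    # indel record (ingested, excluded before annotation)
    indel_codon = next_codon()
    pos, ref = b._site(host, indel_codon, 0)
    two = b.genome()[b.chrom][pos - 1 : pos + 1]
    b.focal_rows.append(
        _vcf_row(b.chrom, pos, two, [two[0]], {}, b.f_seg(), [30] * b.n_focal)
    )
    b.violations.append(
        {"chrom": b.chrom, "pos": pos, "reason": "indel", "gene_id": host.gene_id}
    )

    # triallelic: focal segregates C/A, outgroup fixed for a third allele G
    tri_codon = next_codon()
    b.plant_site(host, tri_codon, 0, "A", "triallelic", focal_gts=b.f_seg())
    tri_pos, tri_ref = b._site(host, tri_codon, 0)
    tri_alt2 = b._genomic_alt(host, "G")
    b.out_rows.append(
        _vcf_row(b.chrom, tri_pos, tri_ref, [tri_alt2], {}, b.o_fixed("1"), [30] * b.n_out)
    )
    b.violations.append(
        {"chrom": b.chrom, "pos": tri_pos, "reason": "triallelic", "gene_id": host.gene_id}
    )

    # both species fixed for the same non-reference allele
    sf_plant = b.plant_site(
        host, next_codon(), 0, "A", "same_fixed",
        focal_gts=b.f_fixed("1"), out_gts=b.o_fixed("1"),
    )
    b.violations.append(
        {"chrom": sf_plant.chrom, "pos": sf_plant.pos, "reason": "same_fixed", "gene_id": host.gene_id}
    )

    # --- low-coverage gene: >10% of CDS bases below the depth limit
    lowcov = b.add_gene("lowcov", clean_cds())
    n_low = int(0.15 * lowcov.cds_length)
    for s, e in lowcov.cds_intervals:
        for p in range(s, min(s + n_low, e) + 1):
            b.depth_override[p] = 2.0
    b.excluded["lowcov"] = "low_coverage"

    # --- genes with disqualifying variant effects
    # a Trp codon in the body can mutate to a stop: TGG -> TGA
    gstop_cds = "ATG" + _SAFE_BODY_CODON * 10 + "TGG" + _SAFE_BODY_CODON * 10 + "TAA"
    gstop = b.add_gene("stopgain", gstop_cds)
    b.plant_site(gstop, 11, 2, "A", "stop_gained", focal_gts=b.f_seg())  # TGG->TGA
    b.excluded["stopgain"] = "stop_gained"

    gsl = b.add_gene("stoploss", clean_cds())
    b.plant_site(gsl, m + 1, 0, "C", "stop_lost", focal_gts=b.f_seg())  # TAA->CAA
    b.excluded["stoploss"] = "stop_lost"

    gstart = b.add_gene("startloss", clean_cds())
    b.plant_site(gstart, 0, 0, "G", "start_lost", focal_gts=b.f_seg())  # ATG->GTG
    b.excluded["startloss"] = "start_lost"

    # non-ATG annotated start: carries the no_start_codon warning, and its
    # codon-0 variant is a nonsyn_start effect
    gns = b.add_gene("nonsynstart", "GTG" + _SAFE_BODY_CODON * m + "TAA")
    b.plant_site(gns, 0, 2, "C", "nonsyn_start", focal_gts=b.f_seg())  # GTG->GTC
    b.excluded["nonsynstart"] = "no_start_codon"

    # --- one gene model per warning type
    b.add_gene("incomplete", "ATG" + _SAFE_BODY_CODON * 5 + "CT")  # length % 3 != 0
    b.excluded["incomplete"] = "incomplete_transcript"
    b.add_gene("multistop", "ATG" + _SAFE_BODY_CODON * 3 + "TAA" + _SAFE_BODY_CODON * 3 + "TAA")
    b.excluded["multistop"] = "multiple_stop_codons"
    b.add_gene("nostart", "CTT" + _SAFE_BODY_CODON * 5 + "TAA")
    b.excluded["nostart"] = "no_start_codon"

    b.genome_parts.append(b._spacer_seq())
    genome = b.genome()

    # per-base depth: 30 everywhere on CDS except overridden positions
    depth: dict[tuple[str, int], float] = {}
    for gene in b.genes:
        for s, e in gene.cds_intervals:
            for p in range(s, e + 1):
                depth[(b.chrom, p)] = b.depth_override.get(p, 30.0)

    manifest = FixtureManifest(
        expected_mk=b.expected,
        violations=b.violations,
        excluded_genes=b.excluded,
        low_coverage_gene="lowcov",
        n_focal_samples=b.n_focal,
        n_outgroup_samples=b.n_out,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        chrom_len = len(genome[b.chrom])
        with open(out / "genome.fasta", "w") as fh:
            fh.write(f">{b.chrom}\n")
            seq = genome[b.chrom]
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
        with open(out / "genes.gff3", "w") as fh:
            fh.write("##gff-version 3\n")
            for gene in b.genes:
                gs = min(s for s, _ in gene.cds_intervals)
                ge = max(e for _, e in gene.cds_intervals)
                fh.write(
                    f"{gene.chrom}\t.\tgene\t{gs}\t{ge}\t.\t{gene.strand}\t.\tID={gene.gene_id}\n"
                )
                for s, e in gene.cds_intervals:
                    fh.write(
                        f"{gene.chrom}\t.\tCDS\t{s}\t{e}\t.\t{gene.strand}\t0\t"
                        f"ID={gene.gene_id}.cds;Parent={gene.gene_id}\n"
                    )
        _write_vcf(out / "focal.vcf", b.chrom, chrom_len, b.focal_samples, b.focal_rows)
        _write_vcf(out / "outgroup.vcf", b.chrom, chrom_len, b.out_samples, b.out_rows)
        with open(out / "mask.bed", "w") as fh:
            for chrom, s, e in b.mask:
                fh.write(f"{chrom}\t{s - 1}\t{e}\n")
        with open(out / "depth.tsv", "w") as fh:
            fh.write("chrom\tpos\tdepth\n")
            for (chrom, p), dvalue in sorted(depth.items()):
                fh.write(f"{chrom}\t{p}\t{dvalue}\n")
        manifest.to_json(out / "manifest.json")

    return {
        "genome": genome,
        "genes": b.genes,
        "mask": b.mask,
        "depth": depth,
        "focal_vcf_rows": b.focal_rows,
        "outgroup_vcf_rows": b.out_rows,
        "focal_samples": b.focal_samples,
        "outgroup_samples": b.out_samples,
        "chrom": b.chrom,
        "manifest": manifest,
    }
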