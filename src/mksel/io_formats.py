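"""Readers/writers and in-memory types for the formats the pipeline touches.

All coordinates are 1-based inclusive after ingest (the VCF/GFF convention);
BED's 0-based half-open intervals are converted at the I/O boundary and never
leak into downstream modules.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import gffutils
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "GeneModel",
    "VariantRecord",
    "ExpressionRow",
    "HitRow",
    "FormatError",
    "read_fasta",
    "read_vcf",
    "read_gff",
    "read_bed",
    "read_table",
    "write_table",
    "attach_warnings",
]

#: SnpEff-style gene warnings that disqualify a gene from selection inference.
GENE_WARNINGS = ("incomplete_transcript", "multiple_stop_codons", "no_start_codon")


class FormatError(ValueError):
    """Malformed or inconsistent input file."""


@dataclasses.dataclass
class GeneModel:
    """A single-transcript protein-coding gene model.

    ``cds_intervals`` are (start, end) pairs in 1-based inclusive genomic
    coordinates, sorted in genome order and non-overlapping. The coding
    sequence is read left-to-right across intervals for ``+`` strand genes
    and right-to-left, reverse-complemented, for ``-`` strand genes.
    """

    gene_id: str
    chrom: str
    strand: str
    cds_intervals: list[tuple[int, int]]
    warnings: set[str] = dataclasses.field(default_factory=set)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise FormatError(f"gene {self.gene_id}: unknown strand {self.strand!r}")
        ivs = sorted(self.cds_intervals)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 <= e1:
                raise FormatError(f"gene {self.gene_id}: overlapping CDS intervals")
        for s, e in ivs:
            if e < s:
                raise FormatError(f"gene {self.gene_id}: interval end {e} < start {s}")
        self.cds_intervals = ivs
        if self.cds_length == 0:
            raise FormatError(f"gene {self.gene_id}: zero-length CDS")

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_intervals)

    def cds_positions(self) -> list[int]:
        """Genomic positions of CDS bases in 5'->3' (coding) order."""
        pos = [p for s, e in self.cds_intervals for p in range(s, e + 1)]
        return pos if self.strand == "+" else pos[::-1]

    def cds_sequence(self, genome: Mapping[str, str]) -> str:
        """Coding-strand CDS sequence spliced from the attached genome."""
        chrom_seq = genome[self.chrom]
        parts = [chrom_seq[s - 1 : e] for s, e in self.cds_intervals]
        seq = "".join(parts)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq


@dataclasses.dataclass
class VariantRecord:
    """One VCF site: alleles, per-sample diploid genotypes and depths.

    Genotype calls are pairs of allele indices (0 = REF) with ``None`` for a
    missing allele. ``site_annotations`` carries the INFO metrics the hard
    filters consume (QD, FS, MQ, rank sums); an absent metric means the site
    passes that metric.
    """

    chrom: str
    pos: int
    ref: str
    alts: list[str]
    genotypes: list[tuple[Optional[int], Optional[int]]]
    depths: list[Optional[int]]
    site_annotations: dict[str, float] = dataclasses.field(default_factory=dict)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and all(len(a) == 1 for a in self.alts)

    def called_allele_indices(self) -> list[int]:
        """Allele indices with at least one called copy."""
        seen = sorted({a for gt in self.genotypes for a in gt if a is not None})
        return seen

    def observed_alleles(self) -> set[str]:
        """Allele strings (REF/ALT) backed by >= 1 called genotype copy."""
        alleles = [self.ref] + list(self.alts)
        return {alleles[i] for i in self.called_allele_indices()}

    def missing_fraction(self) -> float:
        miss = sum(1 for gt in self.genotypes if gt[0] is None and gt[1] is None)
        return miss / len(self.genotypes) if self.genotypes else 1.0

    def mean_depth(self) -> float:
        depths = [d for d in self.depths if d is not None]
        return sum(depths) / len(depths) if depths else 0.0


@dataclasses.dataclass
class ExpressionRow:
    gene_id: str
    fdr: float
    fpkm_queen: float
    fpkm_worker: float
    merge_conflict: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.fdr <= 1.0:
            raise FormatError(f"gene {self.gene_id}: FDR {self.fdr} outside [0, 1]")


@dataclasses.dataclass
class HitRow:
    query_id: str
    subject_id: str
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise FormatError(f"hit {self.query_id}->{self.subject_id}: negative E-value")
        if self.bitscore <= 0:
            raise FormatError(f"hit {self.query_id}->{self.subject_id}: non-positive bitscore")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: uppercase sequence} map."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"empty sequence for {rec.id!r} in {path}")
        out[rec.id] = seq
    return out


def _parse_gt(sample) -> tuple[Optional[int], Optional[int]]:
    alleles = sample.get("GT", (None, None))
    if alleles is None:
        alleles = (None, None)
    a = list(alleles) + [None] * (2 - len(alleles))
    return (a[0], a[1])


def read_vcf(path: str | Path) -> list[VariantRecord]:
    """Read a (plain-text or bgzipped) VCF into VariantRecords.

    Multi-allelic ALTs are retained as lists so the triallelic filter can see
    them; missing genotypes become (None, None), never an error.
    """
    records: list[VariantRecord] = []
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    with vcf:
        n_samples = len(vcf.header.samples)
        for i, rec in enumerate(vcf.fetch() if vcf.index else vcf):
            if rec.ref is None or rec.pos is None:
                raise FormatError(f"{path}: malformed record at data line {i + 1}")
            if len(rec.samples) != n_samples:
                raise FormatError(f"{path}: sample count mismatch at data line {i + 1}")
            annotations = {
                k: float(v)
                for k, v in rec.info.items()
                if isinstance(v, (int, float))
            }
            gts, dps = [], []
            for name in rec.samples:
                sample = rec.samples[name]
                gts.append(_parse_gt(sample))
                dp = sample.get("DP")
                dps.append(int(dp) if dp is not None else None)
            records.append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref.upper(),
                    alts=[a.upper() for a in (rec.alts or [])],
                    genotypes=gts,
                    depths=dps,
                    site_annotations=annotations,
                )
            )
    return records


def read_gff(path: str | Path) -> list[GeneModel]:
    """Read gene models (gene + CDS features) from GFF3.

    The first/only mRNA per gene is used; CDS intervals come back 1-based
    inclusive, sorted in genome order. Warnings are attached later, from
    sequence, by :func:`attach_warnings`.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        cds = list(db.children(gene, featuretype="CDS", order_by="start"))
        if not cds:
            continue
        strand = gene.strand
        if strand not in {"+", "-"}:
            raise FormatError(f"gene {gene.id}: unknown strand {strand!r}")
        intervals = [(c.start, c.end) for c in cds]
        models.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=strand,
                cds_intervals=intervals,
            )
        )
    return models


def attach_warnings(gene: GeneModel, genome: Mapping[str, str]) -> GeneModel:
    """Derive SnpEff-style gene warnings from the attached sequence.

    incomplete_transcript: CDS length not divisible by 3;
    no_start_codon: first codon is not ATG;
    multiple_stop_codons: more than one stop in the translated CDS.
    """
    gene.warnings.clear()
    if gene.cds_length % 3 != 0:
        gene.warnings.add("incomplete_transcript")
        return gene
    seq = gene.cds_sequence(genome)
    if not seq.startswith("ATG"):
        gene.warnings.add("no_start_codon")
    protein = str(Seq(seq).translate())
    if protein.count("*") > 1:
        gene.warnings.add("multiple_stop_codons")
    return gene


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read BED intervals, converting 0-based half-open to 1-based inclusive."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{ln}: BED line has < 3 fields")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if end < start:
                raise FormatError(f"{path}:{ln}: end {end} < start {start}")
            out.append((chrom, start + 1, end))
    return out


def write_bed(intervals: Iterable[tuple[str, int, int]], path: str | Path) -> None:
    """Write 1-based inclusive intervals as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start - 1}\t{end}\n")


# TSV schemas keyed by name: (columns, dtypes applied on read).
TABLE_SCHEMAS: dict[str, dict[str, type]] = {
    "expression": {
        "gene_id": str,
        "fdr": float,
        "fpkm_queen": float,
        "fpkm_worker": float,
        "merge_conflict": bool,
    },
    "hits": {"query_id": str, "subject_id": str, "evalue": float, "bitscore": float},
    "mk": {"gene_id": str, "PN": int, "PS": int, "DN": int, "DS": int},
    "gamma": {"gene_id": str, "gamma": float},
}


def read_table(path: str | Path, schema: str | Mapping[str, type]) -> pd.DataFrame:
    """Read a headered TSV and coerce it to a named (or explicit) schema."""
    spec = TABLE_SCHEMAS[schema] if isinstance(schema, str) else dict(schema)
    df = pd.read_csv(path, sep="\t")
    missing = set(spec) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return df[list(spec)].astype(spec)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def expression_rows(df: pd.DataFrame) -> list[ExpressionRow]:
    return [
        ExpressionRow(
            gene_id=r.gene_id,
            fdr=float(r.fdr),
            fpkm_queen=float(r.fpkm_queen),
            fpkm_worker=float(r.fpkm_worker),
            merge_conflict=bool(r.merge_conflict),
        )
        for r in df.itertuples()
    ]


def hit_rows(df: pd.DataFrame) -> list[HitRow]:
    return [
        HitRow(
            query_id=r.query_id,
            subject_id=r.subject_id,
            evalue=float(r.evalue),
            bitscore=float(r.bitscore),
        )
        for r in df.itertuples()
    ]
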