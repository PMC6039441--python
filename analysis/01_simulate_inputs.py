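"""Generate every synthetic input the downstream analyses consume.

Writes the two-species variant fixture (genome, gene models, focal/outgroup
VCFs, homology mask, per-base depth, truth manifest), the PRF count
simulation with its gamma truth, the caste-biased expression table, and the
reciprocal-best-hit tables, all under results/synthetic/.
"""

import argparse
import dataclasses
import json
from pathlib import Path

import pandas as pd

from mksel import io_formats as io
from mksel.mk_tables import tables_to_frame
from mksel.synthetic_data import (
    SimulationTruth,
    simulate_expression,
    simulate_hit_tables,
    simulate_mk_counts,
    simulate_two_species_vcf,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-genes", type=int, default=500)
    ap.add_argument("--out-dir", type=Path, default=Path("results/synthetic"))
    args = ap.parse_args()
    out = args.out_dir
    out.mkdir(parents=True, exist_ok=True)

    fx = simulate_two_species_vcf(seed=args.seed, out_dir=out)
    man = fx["manifest"]
    print(f"variant fixture: {len(fx['genes'])} genes, "
          f"{len(fx['focal_vcf_rows'])} focal / {len(fx['outgroup_vcf_rows'])} outgroup records, "
          f"{len(man.violations)} planted violations, "
          f"{len(man.excluded_genes)} genes planted for exclusion")

    truth = SimulationTruth.default(args.n_genes, frac_positive=0.12, seed=args.seed)
    tables, truth_df = simulate_mk_counts(truth, seed=args.seed)
    io.write_table(tables_to_frame(tables), out / "mk_counts.tsv")
    io.write_table(truth_df, out / "gamma_truth.tsv")
    n_pos = int((truth.gamma > 1).sum())
    print(f"PRF counts: {args.n_genes} genes, {n_pos} with true gamma > 1 "
          f"({100 * n_pos / args.n_genes:.1f}%)")

    rows, labels = simulate_expression(
        n_genes=7612, n_queen_biased=114, n_worker_biased=287, seed=args.seed
    )
    io.write_table(pd.DataFrame([dataclasses.asdict(r) for r in rows]),
                   out / "expression.tsv")
    json.dump(labels, open(out / "expression_labels.json", "w"))
    print(f"expression: {len(rows)} genes (114 queen-biased, 287 worker-biased planted)")

    ab, ba, pairs = simulate_hit_tables(n_shared=50, n_a_only=10, n_b_only=10,
                                        seed=args.seed)
    io.write_table(pd.DataFrame([dataclasses.asdict(h) for h in ab]), out / "hits_ab.tsv")
    io.write_table(pd.DataFrame([dataclasses.asdict(h) for h in ba]), out / "hits_ba.tsv")
    io.write_table(pd.DataFrame(sorted(pairs), columns=["gene_a", "gene_b"]),
                   out / "true_pairs.tsv")
    print(f"hit tables: {len(ab)} + {len(ba)} rows, {len(pairs)} true reciprocal pairs")


if __name__ == "__main__":
    main()
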