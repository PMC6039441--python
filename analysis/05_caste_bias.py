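"""Selection on caste-biased genes: classification, ANOVA, proportions.

Classifies the simulated expression table into queen-biased, worker-biased
and non-DEG genes, joins the gamma estimates from 03_fit_selection.py, and
runs the gamma-by-class battery (one-way ANOVA with Tukey-Kramer HSD;
positive-fraction chi-square contrast). Also recomputes, from their printed
integer inputs, the study-style worked examples for the two-proportion
contrast in both wasp and bumblebee configurations.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from mksel import io_formats as io
from mksel.comparative_stats import (
    classify_caste_bias,
    compare_two_proportions,
    gamma_by_class,
    positive_fraction,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--in-dir", type=Path, default=Path("results/synthetic"))
    ap.add_argument("--est-dir", type=Path, default=Path("results/selection"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/caste"))
    args = ap.parse_args()
    out = args.out_dir
    out.mkdir(parents=True, exist_ok=True)

    rows = io.expression_rows(io.read_table(args.in_dir / "expression.tsv", "expression"))
    labels = classify_caste_bias(rows)
    counts = pd.Series([c.label for c in labels]).value_counts()
    print(f"caste classes: {counts.to_dict()}")

    est = pd.read_csv(args.est_dir / "estimates_mcmc.tsv", sep="\t")
    # the expression simulation indexes genes the same way as the count
    # simulation, so the join is by shared synthetic gene ids
    gamma = dict(zip(est.gene_id, est.gamma))
    positive = set(est.gene_id[est.gamma > 1])
    shared = [c for c in labels if c.gene_id in gamma]
    frac = positive_fraction(shared, positive)
    print("positive fraction per class (k, n, %):", {k: v for k, v in frac.items()})
    res = gamma_by_class(gamma, shared)
    print(f"ANOVA: F_{res['df_between']},{res['df_within']} = {res['anova_F']:.3f}, "
          f"p = {res['anova_p']:.3f}")
    for (a, b), p in res["tukey_p"].items():
        print(f"  Tukey {a} vs {b}: p = {p:.3f}")

    # worked examples from printed integer inputs (k positive, n in class)
    worked = {}
    for species, (kq, nq, kw, nw) in {
        "wasp": (22, 114, 32, 287),
        "bumblebee": (58, 185, 34, 192),
    }.items():
        entry = {"queen_pct": round(100 * kq / nq, 1),
                 "worker_pct": round(100 * kw / nw, 1)}
        for method in ("chisq", "chisq_yates", "fisher"):
            stat, p = compare_two_proportions(kq, nq, kw, nw, method=method)
            entry[method] = {"stat": round(stat, 3), "p": round(p, 4)}
        worked[species] = entry
        print(f"{species}: queen {entry['queen_pct']}% vs worker {entry['worker_pct']}%; "
              f"chi2 = {entry['chisq']['stat']} (p {entry['chisq']['p']}), "
              f"Yates {entry['chisq_yates']['stat']} (p {entry['chisq_yates']['p']})")

    report = {
        "class_counts": counts.to_dict(),
        "positive_fraction": {k: list(v) for k, v in frac.items()},
        "anova": {"F": res["anova_F"], "p": res["anova_p"],
                  "groups": res["groups"]},
        "tukey_p": {f"{a}|{b}": p for (a, b), p in res["tukey_p"].items()},
        "worked_examples": worked,
    }
    (out / "caste_report.json").write_text(json.dumps(report, indent=1))
    print(f"wrote {out / 'caste_report.json'}")


if __name__ == "__main__":
    main()
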