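#!/usr/bin/env python
"""Transcriptome-weighted amino-acid demand prediction.

Merges the simulated expression table with representative-protein residue
counts on gene stable ID, predicts the per-residue demand change between
the two conditions, and compares the proline fractions of the top-500
induced vs suppressed genes (unpaired two-tailed Student's t-test).
"""

import argparse
import dataclasses
import json
from pathlib import Path

from prodemand import (
    compare_topgene_composition,
    demand_change,
    merge_expression_composition,
    read_expression_table,
    read_proteome_fasta,
    top_n_by_change,
)
from prodemand.io_formats import write_matrix_tsv


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--results-dir", type=Path, default=Path("results"))
    parser.add_argument("--top-n", type=int, default=500)
    args = parser.parse_args()

    sim = args.results_dir / "simdata"
    proteome = read_proteome_fasta(sim / "proteome.fa")
    expr = read_expression_table(sim / "expr.tsv")
    c_from, c_to = expr.condition_labels

    merged, merge_report = merge_expression_composition(expr, proteome)
    print(
        f"merged {merge_report.n_merged} genes "
        f"({merge_report.n_unmatched_proteins} proteome genes without "
        f"expression, {merge_report.n_unmatched_genes} expression genes "
        f"without protein)"
    )
    report = demand_change(merged, c_from, c_to, merge_report)
    write_matrix_tsv(report.table, args.results_dir / "demand_pct_change.tsv")
    pro = report.pct_change["P"]
    other = report.pct_change.drop("P").median()
    print(f"predicted %dAA: Pro {pro:+.2f}% vs median other residue {other:+.2f}%")

    induced = top_n_by_change(expr, c_from, c_to, args.top_n, "induced")
    suppressed = top_n_by_change(expr, c_from, c_to, args.top_n, "suppressed")
    comparison, fractions = compare_topgene_composition(induced, suppressed, proteome)
    (args.results_dir / "top_gene_comparison.json").write_text(
        json.dumps(
            {"comparison": dataclasses.asdict(comparison), "fractions": fractions},
            indent=2,
        )
        + "\n"
    )
    print(
        f"top-{args.top_n} Pro fraction: induced mean "
        f"{comparison.means[0]:.4f} vs suppressed {comparison.means[1]:.4f} "
        f"(t = {comparison.t_stat:.2f}, p = {comparison.p_value:.3g})"
    )


if __name__ == "__main__":
    main()
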