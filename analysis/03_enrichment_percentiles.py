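#!/usr/bin/env python
"""Set-level residue enrichment and percentile standing.

For each gene set, computes the mean-of-proteins composition, its fold
enrichment and percent increase relative to the whole-proteome background,
and the share of members above the background's 75th percentile of proline
fraction (the percentile-rank analysis).
"""

import argparse
import dataclasses
import json
from pathlib import Path

from prodemand import (
    GeneSet,
    fold_enrichment,
    percent_increase,
    percentile_analysis,
    read_gene_sets,
    read_proteome_fasta,
    set_composition,
)
from prodemand.io_formats import write_matrix_tsv


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--results-dir", type=Path, default=Path("results"))
    parser.add_argument("--residue", default="P")
    args = parser.parse_args()

    sim = args.results_dir / "simdata"
    proteome = read_proteome_fasta(sim / "proteome.fa")
    gene_sets = read_gene_sets(sim / "sets.gmt")

    background = set_composition(
        GeneSet("ALL", "all proteins", frozenset(proteome.gene_index)), proteome
    ).composition
    comps = {gs.set_id: set_composition(gs, proteome).composition for gs in gene_sets}

    fold = fold_enrichment(comps, background)
    pct = percent_increase(comps, background)
    write_matrix_tsv(fold.values, args.results_dir / "set_fold_enrichment.tsv")
    write_matrix_tsv(pct.values, args.results_dir / "set_percent_increase.tsv")

    report = {}
    for gs in gene_sets:
        summary = percentile_analysis(gs, proteome, residue=args.residue)
        report[gs.set_id] = dataclasses.asdict(summary)
        print(
            f"{gs.set_id}: {args.residue} fold {fold.values.loc[gs.set_id, args.residue]:.3f}, "
            f"{pct.values.loc[gs.set_id, args.residue]:+.1f}% vs background, "
            f"{100 * summary.fraction_above:.1f}% of members above the "
            f"75th percentile"
        )
    (args.results_dir / "percentile_summary.json").write_text(
        json.dumps(report, indent=2) + "\n"
    )


if __name__ == "__main__":
    main()
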