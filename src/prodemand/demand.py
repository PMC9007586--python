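"""Transcriptome-weighted amino-acid demand-change prediction.

The model assumes changes in mRNA abundance are proportional to changes in
protein translation, so the demand change for residue ``a`` contributed by a
gene is ``dR * N_a`` where ``N_a`` is the residue count of the gene's
representative protein.  Summed over genes and expressed relative to the
starting state:

    %dAA(a) = 100 * sum_g[(R_to(g) - R_from(g)) * N_a(g)]
                   / sum_g[R_from(g) * N_a(g)]

computed per residue, with explicit bookkeeping of genes and proteins that
fail the gene-ID merge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .composition import (
    CANONICAL_RESIDUES,
    RepresentativePolicy,
    composition,
    select_representatives,
)
from .errors import ValidationError
from .io_formats import ExpressionTable, Proteome
from .set_stats import GroupComparison, group_compare


@dataclass
class MergedGeneRecord:
    """One gene after the expression/composition merge."""

    gene_id: str
    abundances: dict[str, float]  # condition label -> abundance
    counts: dict[str, int]  # residue -> N_aa of the representative protein

    def abundance(self, condition: str) -> float:
        if condition not in self.abundances:
            raise ValidationError(
                f"gene {self.gene_id!r} has no abundance for condition {condition!r}"
            )
        return self.abundances[condition]


@dataclass
class MergeReport:
    n_merged: int
    n_unmatched_proteins: int  # genes with protein but no expression row
    n_unmatched_genes: int  # expression rows with no protein
    unmatched_protein_genes: list[str] = field(default_factory=list)
    unmatched_expression_genes: list[str] = field(default_factory=list)


def merge_expression_composition(
    expr: ExpressionTable,
    proteome: Proteome,
    policy: RepresentativePolicy | None = None,
) -> tuple[list[MergedGeneRecord], MergeReport]:
    """Inner join of the expression table with representative-protein residue
    counts on (version-stripped) gene stable ID; order follows the table."""
    reps = select_representatives(proteome, policy)
    merged: list[MergedGeneRecord] = []
    unmatched_expr: list[str] = []
    for gene_id in expr.gene_ids:
        if gene_id not in reps:
            unmatched_expr.append(gene_id)
            continue
        counts = composition(reps[gene_id].sequence).counts
        merged.append(
            MergedGeneRecord(
                gene_id=gene_id,
                abundances={c: float(expr.data.at[gene_id, c]) for c in expr.condition_labels},
                counts=counts,
            )
        )
    matched_ids = {m.gene_id for m in merged}
    unmatched_prot = [g for g in reps if g not in matched_ids]
    if not merged:
        raise ValidationError("no gene is shared between expression table and proteome")
    report = MergeReport(
        n_merged=len(merged),
        n_unmatched_proteins=len(unmatched_prot),
        n_unmatched_genes=len(unmatched_expr),
        unmatched_protein_genes=unmatched_prot,
        unmatched_expression_genes=unmatched_expr,
    )
    return merged, report


@dataclass
class DemandReport:
    """Per-residue demand change with numerator/denominator bookkeeping."""

    table: pd.DataFrame  # index residues; columns numerator, denominator, pct_change
    n_genes_used: int
    n_unmatched_proteins: int = 0
    n_unmatched_genes: int = 0

    @property
    def pct_change(self) -> pd.Series:
        return self.table["pct_change"]

    @property
    def undefined_residues(self) -> list[str]:
        return list(self.table.index[self.table["pct_change"].isna()])


def demand_change(
    merged: list[MergedGeneRecord],
    cond_from: str,
    cond_to: str,
    merge_report: MergeReport | None = None,
) -> DemandReport:
    """Predicted per-residue demand change between two conditions.

    Residues whose denominator ``sum(R_from * N_aa)`` is zero get a NaN
    ``pct_change`` and are flagged via ``undefined_residues`` rather than
    silently reported as 0.
    """
    if not merged:
        raise ValidationError("merged gene list is empty")
    r_from = np.array([m.abundance(cond_from) for m in merged])
    r_to = np.array([m.abundance(cond_to) for m in merged])
    if not (np.isfinite(r_from).all() and np.isfinite(r_to).all()):
        raise ValidationError("non-finite abundance in merged records")
    counts = np.array(
        [[m.counts[a] for a in CANONICAL_RESIDUES] for m in merged], dtype=float
    )
    numerator = (r_to - r_from) @ counts
    denominator = r_from @ counts
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * numerator / denominator
    undefined = denominator == 0.0
    if undefined.any():
        bad = [a for a, u in zip(CANONICAL_RESIDUES, undefined) if u]
        warnings.warn(f"zero demand denominator for residue(s) {bad}; reported as NaN")
        pct = np.where(undefined, np.nan, pct)
    table = pd.DataFrame(
        {"numerator": numerator, "denominator": denominator, "pct_change": pct},
        index=list(CANONICAL_RESIDUES),
    )
    return DemandReport(
        table=table,
        n_genes_used=len(merged),
        n_unmatched_proteins=merge_report.n_unmatched_proteins if merge_report else 0,
        n_unmatched_genes=merge_report.n_unmatched_genes if merge_report else 0,
    )


@dataclass
class TopGenes:
    """Genes ranked by expression change between two conditions."""

    direction: str  # "induced" | "suppressed"
    n_requested: int
    gene_ids: list[str]
    ranking_stat: dict[str, float]


def _change_stat(r_from: pd.Series, r_to: pd.Series, stat: str) -> pd.Series:
    if stat == "log2fc_pseudo":
        return np.log2((r_to + 1.0) / (r_from + 1.0))
    if stat == "abs_diff":
        return r_to - r_from
    raise ValidationError(f"unknown ranking stat {stat!r}")


def top_n_by_change(
    expr: ExpressionTable,
    cond_from: str,
    cond_to: str,
    n: int,
    direction: str,
    stat: str = "log2fc_pseudo",
) -> TopGenes:
    """Top-n induced (largest change) or suppressed (smallest change) genes.

    Default statistic is the pseudocounted log2 fold change
    ``log2((R_to + 1) / (R_from + 1))``; ties break on gene ID.
    """
    if direction not in ("induced", "suppressed"):
        raise ValidationError(f"unknown direction {direction!r}")
    if n < 1:
        raise ValidationError("n must be >= 1")
    values = _change_stat(expr.column(cond_from), expr.column(cond_to), stat)
    if n > len(values):
        warnings.warn(
            f"requested top {n} but only {len(values)} genes eligible; returning all"
        )
        n = len(values)
    ascending = direction == "suppressed"
    ranked = values.sort_index().sort_values(ascending=ascending, kind="stable")
    chosen = ranked.iloc[:n]
    return TopGenes(
        direction=direction,
        n_requested=n,
        gene_ids=list(chosen.index),
        ranking_stat=chosen.to_dict(),
    )


def compare_topgene_composition(
    top_induced: TopGenes,
    top_suppressed: TopGenes,
    proteome: Proteome,
    policy: RepresentativePolicy | None = None,
    residue: str = "P",
    variant: str = "pooled",
) -> tuple[GroupComparison, dict[str, list[float]]]:
    """Compare a residue's fraction between induced and suppressed gene lists.

    Returns the two-group comparison plus both per-gene fraction lists (in
    gene-list rank order); genes without a representative protein are dropped
    from the comparison.
    """
    reps = select_representatives(proteome, policy)

    def fractions(genes: list[str]) -> list[float]:
        return [
            composition(reps[g].sequence).fractions[residue] for g in genes if g in reps
        ]

    vals_ind = fractions(top_induced.gene_ids)
    vals_sup = fractions(top_suppressed.gene_ids)
    if len(vals_ind) < 2 or len(vals_sup) < 2:
        raise ValidationError("each gene list must resolve at least 2 proteins")
    comparison = group_compare(
        vals_ind, vals_sup, variant=variant, labels=("induced", "suppressed")
    )
    return comparison, {"induced": vals_ind, "suppressed": vals_sup}
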