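"""Gene-set composition summaries, enrichment matrices, percentile ranks,
and the two-group residue-proportion comparison.

Fold enrichment of a protein or set is its residue fraction divided by the
whole-proteome background fraction; percent increase is ``100 * (fold - 1)``.
Percentile ranks use the mid-rank convention (ties count half), and the
background quantile is the linearly interpolated order statistic, so tie
behaviour is deterministic and documented.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .composition import (
    CANONICAL_RESIDUES,
    CompositionVector,
    RepresentativePolicy,
    composition,
    select_representatives,
)
from .errors import ValidationError
from .io_formats import GeneSet, Proteome


@dataclass
class SetCompositionResult:
    """Aggregate composition of a gene set plus member-resolution accounting."""

    composition: CompositionVector
    n_resolved: int
    unresolved_gene_ids: list[str] = field(default_factory=list)


def set_composition(
    gene_set: GeneSet,
    proteome: Proteome,
    policy: RepresentativePolicy | None = None,
    aggregation: str = "mean_of_proteins",
) -> SetCompositionResult:
    """Aggregate composition of a gene set's representative proteins.

    ``mean_of_proteins`` (default) is the unweighted mean of member fraction
    vectors; ``pooled_residues`` is the composition of the concatenation of
    member sequences.  Members with no protein in the proteome are reported,
    not silently dropped.
    """
    if aggregation not in ("mean_of_proteins", "pooled_residues"):
        raise ValidationError(f"unknown aggregation {aggregation!r}")
    reps = select_representatives(proteome, policy)
    members = sorted(gene_set.gene_ids)
    resolved = [g for g in members if g in reps]
    unresolved = [g for g in members if g not in reps]
    if not resolved:
        raise ValidationError(
            f"gene set {gene_set.set_id!r}: no member resolves to a protein"
        )
    if aggregation == "pooled_residues":
        pooled = "".join(reps[g].sequence for g in resolved)
        comp = composition(pooled)
    else:
        vectors = np.array(
            [composition(reps[g].sequence).fraction_series().to_numpy() for g in resolved]
        )
        mean = vectors.mean(axis=0)
        mean = mean / mean.sum()  # guard against unit-sum drift
        comp = CompositionVector(fractions=dict(zip(CANONICAL_RESIDUES, mean)))
    return SetCompositionResult(
        composition=comp, n_resolved=len(resolved), unresolved_gene_ids=unresolved
    )


@dataclass
class EnrichmentMatrix:
    """Entities x residues matrix of fold ratios or percent increases."""

    values: pd.DataFrame
    mode: str  # "fold" | "percent_increase"

    def __post_init__(self) -> None:
        if self.mode not in ("fold", "percent_increase"):
            raise ValidationError(f"unknown enrichment mode {self.mode!r}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValidationError("enrichment matrix has non-finite values")

    def below_background_mask(self) -> pd.DataFrame:
        """True where enrichment is below the background average."""
        cutoff = 1.0 if self.mode == "fold" else 0.0
        return self.values < cutoff


def _as_fraction_frame(
    entity_comps: dict[str, CompositionVector] | list[tuple[str, CompositionVector]],
) -> pd.DataFrame:
    items = entity_comps.items() if isinstance(entity_comps, dict) else entity_comps
    labels, rows = zip(*[(label, cv.fraction_series()) for label, cv in items])
    return pd.DataFrame(list(rows), index=list(labels))


def fold_enrichment(
    entity_comps, background: CompositionVector
) -> EnrichmentMatrix:
    """Residue fractions of each entity divided by the background fractions."""
    bg = background.fraction_series()
    zero = bg[bg <= 0]
    if len(zero):
        raise ValidationError(
            f"background fraction is zero for residue(s) {list(zero.index)}"
        )
    frame = _as_fraction_frame(entity_comps)
    return EnrichmentMatrix(values=frame / bg, mode="fold")


def percent_increase(
    entity_comps, background: CompositionVector
) -> EnrichmentMatrix:
    """100 x (entity fraction - background) / background, per residue."""
    fold = fold_enrichment(entity_comps, background)
    return EnrichmentMatrix(values=100.0 * (fold.values - 1.0), mode="percent_increase")


@dataclass
class PercentileSummary:
    """Where set members sit within the proteome-wide residue-fraction
    distribution, and what fraction clears a background quantile."""

    residue: str
    per_protein_percentile: dict[str, float]
    threshold_q: float
    threshold_value: float
    fraction_above: float
    n_background: int
    unresolved_gene_ids: list[str] = field(default_factory=list)


def midrank_percentiles(background: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Mid-rank percentile of each value within background:
    100 * (#strictly below + 0.5 * #ties) / N."""
    bg = np.sort(np.asarray(background, dtype=float))
    vals = np.asarray(values, dtype=float)
    below = np.searchsorted(bg, vals, side="left")
    weak = np.searchsorted(bg, vals, side="right")
    return 100.0 * (below + 0.5 * (weak - below)) / bg.size


def percentile_analysis(
    gene_set: GeneSet,
    proteome: Proteome,
    policy: RepresentativePolicy | None = None,
    residue: str = "P",
    threshold_q: float = 0.75,
) -> PercentileSummary:
    """Rank set members' residue fractions against all representative proteins.

    The background is every representative protein in the proteome (set
    members included).  ``fraction_above`` is the share of resolved members
    strictly exceeding the background's linearly interpolated ``threshold_q``
    quantile.
    """
    if residue not in CANONICAL_RESIDUES:
        raise ValidationError(f"unknown residue {residue!r}")
    if not 0.0 < threshold_q < 1.0:
        raise ValidationError("threshold_q must be in (0, 1)")
    reps = select_representatives(proteome, policy)
    if len(reps) < 4:
        raise ValidationError("background must contain at least 4 proteins")
    bg_fractions = {
        gene: composition(rec.sequence).fractions[residue] for gene, rec in reps.items()
    }
    background = np.array(list(bg_fractions.values()))
    members = sorted(gene_set.gene_ids)
    resolved = [g for g in members if g in bg_fractions]
    unresolved = [g for g in members if g not in bg_fractions]
    if not resolved:
        raise ValidationError(
            f"gene set {gene_set.set_id!r}: no member resolves to a protein"
        )
    member_vals = np.array([bg_fractions[g] for g in resolved])
    percentiles = midrank_percentiles(background, member_vals)
    threshold_value = float(np.quantile(background, threshold_q))  # linear interp
    fraction_above = float(np.mean(member_vals > threshold_value))
    return PercentileSummary(
        residue=residue,
        per_protein_percentile=dict(zip(resolved, percentiles.tolist())),
        threshold_q=threshold_q,
        threshold_value=threshold_value,
        fraction_above=fraction_above,
        n_background=background.size,
        unresolved_gene_ids=unresolved,
    )


@dataclass
class GroupComparison:
    """Two-sample location comparison with distribution summaries."""

    group_labels: tuple[str, str]
    n1: int
    n2: int
    means: tuple[float, float]
    medians: tuple[float, float]
    quartiles: tuple[tuple[float, float], tuple[float, float]]  # (q1, q3) per group
    t_stat: float
    df: float
    p_value: float
    variant: str


def group_compare(
    values_a,
    values_b,
    variant: str = "pooled",
    labels: tuple[str, str] = ("group_a", "group_b"),
) -> GroupComparison:
    """Unpaired two-tailed two-sample t-test with violin-style summaries.

    ``pooled`` (default) is the classical Student test with n1 + n2 - 2
    degrees of freedom; ``welch`` drops the equal-variance assumption.
    """
    if variant not in ("pooled", "welch"):
        raise ValidationError(f"unknown t-test variant {variant!r}")
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs at least 2 observations")
    var_a, var_b = a.var(ddof=1), b.var(ddof=1)
    if var_a == 0.0 and var_b == 0.0:
        if a.mean() == b.mean():
            raise ValidationError("both groups constant and equal: t undefined")
        warnings.warn("both groups have zero variance; reporting p = 0")
        t_stat, df, p = np.inf if a.mean() > b.mean() else -np.inf, a.size + b.size - 2, 0.0
    else:
        res = stats.ttest_ind(a, b, equal_var=(variant == "pooled"))
        t_stat, p = float(res.statistic), float(res.pvalue)
        df = float(res.df)
    q1a, meda, q3a = np.percentile(a, [25, 50, 75])
    q1b, medb, q3b = np.percentile(b, [25, 50, 75])
    return GroupComparison(
        group_labels=tuple(labels),
        n1=int(a.size),
        n2=int(b.size),
        means=(float(a.mean()), float(b.mean())),
        medians=(float(meda), float(medb)),
        quartiles=((float(q1a), float(q3a)), (float(q1b), float(q3b))),
        t_stat=float(t_stat),
        df=float(df),
        p_value=float(p),
        variant=variant,
    )
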