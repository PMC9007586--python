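"""Synthetic proteomes, gene sets, expression tables and protein panels
with known ground truth.

The generator emulates the statistical structure the analysis consumes: each
gene gets a target residue composition drawn around a proteome-wide
background (a Dirichlet prior), designated gene sets get a proline-fraction
shift, expression is log-normal with designated induced/suppressed sets of a
stated log2 effect size, and panels follow a log-linear dose-response in
proline fraction.  Everything downstream of a seed is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .composition import CANONICAL_RESIDUES, composition
from .demand import MergedGeneRecord, demand_change
from .errors import ValidationError
from .io_formats import ExpressionTable, GeneSet, ProteinRecord, Proteome
from .association import PanelMeasurement

#: Whole-proteome average amino-acid composition of the mouse (GRCm38)
#: proteome, used as the default background for synthetic compositions
#: (Pro sits at 6.12%).  Renormalized to sum exactly to 1.
MOUSE_BACKGROUND_COMPOSITION: dict[str, float] = {
    "A": 0.0681, "C": 0.0227, "D": 0.0479, "E": 0.0694, "F": 0.0375,
    "G": 0.0629, "H": 0.0262, "I": 0.0445, "K": 0.0571, "L": 0.1004,
    "M": 0.0228, "N": 0.0360, "P": 0.0612, "Q": 0.0478, "R": 0.0559,
    "S": 0.0853, "T": 0.0543, "V": 0.0610, "W": 0.0119, "Y": 0.0270,
}

PRO_INDEX = CANONICAL_RESIDUES.index("P")


def _background_vector() -> np.ndarray:
    v = np.array([MOUSE_BACKGROUND_COMPOSITION[a] for a in CANONICAL_RESIDUES])
    return v / v.sum()


@dataclass(frozen=True)
class SetSpec:
    """A synthetic gene set: membership size and proline-fraction shift."""

    set_id: str
    label: str
    n_members: int
    pro_shift: float = 0.0


@dataclass(frozen=True)
class ExprSpec:
    """Two-condition expression design.

    Members of ``induced_set`` are multiplied by ``2**log2_effect`` in the
    second condition, members of ``suppressed_set`` divided; the second
    condition additionally carries multiplicative log-normal noise of
    log2-scale standard deviation ``noise_sd``.
    """

    induced_set: str | None = "induced"
    suppressed_set: str | None = "suppressed"
    log2_effect: float = 1.0
    noise_sd: float = 0.25
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 2.0
    condition_labels: tuple[str, str] = ("undifferentiated", "differentiated")


@dataclass(frozen=True)
class PanelSpec:
    """Log-linear protein panel: ratio = 2**(alpha + beta * pro + noise)."""

    n: int = 17
    alpha: float = 0.4
    beta: float = -10.0
    noise_sd: float = 0.3
    pro_range: tuple[float, float] = (0.04, 0.20)


@dataclass
class SimulationConfig:
    """Study-condition defaults: 2,000 genes with a mouse-proteome background
    composition, a 500-gene induced set shifted +0.03 in proline and a
    500-gene unshifted suppressed set, and a twofold expression effect."""

    seed: int = 0
    n_genes: int = 2000
    length_range: tuple[int, int] = (100, 600)
    base_composition: np.ndarray | None = None
    concentration: float = 50.0
    set_spec: list[SetSpec] = field(
        default_factory=lambda: [
            SetSpec("induced", "induced during differentiation", 500, 0.03),
            SetSpec("suppressed", "suppressed during differentiation", 500, 0.0),
        ]
    )
    expr_spec: ExprSpec = field(default_factory=ExprSpec)
    panel_spec: PanelSpec = field(default_factory=PanelSpec)
    max_isoforms_per_gene: int = 1

    def resolved_base(self) -> np.ndarray:
        base = (
            _background_vector()
            if self.base_composition is None
            else np.asarray(self.base_composition, dtype=float)
        )
        if base.shape != (20,) or (base <= 0).any():
            raise ValidationError("base_composition must be 20 positive values")
        if abs(base.sum() - 1.0) > 1e-6:
            raise ValidationError("base_composition must sum to 1")
        return base / base.sum()

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise ValidationError("invalid length_range")
        if self.concentration <= 0:
            raise ValidationError("concentration must be positive")
        if self.max_isoforms_per_gene < 1:
            raise ValidationError("max_isoforms_per_gene must be >= 1")
        if sum(s.n_members for s in self.set_spec) > self.n_genes:
            raise ValidationError("set memberships exceed n_genes")
        base = self.resolved_base()
        for s in self.set_spec:
            shifted = base[PRO_INDEX] + s.pro_shift
            if not 0.0 < shifted < 1.0:
                raise ValidationError(
                    f"set {s.set_id!r}: pro_shift {s.pro_shift} leaves Pro "
                    f"fraction {shifted} outside (0, 1)"
                )


@dataclass
class SyntheticTruth:
    """Ground truth recorded during generation.

    ``expected_abundances`` are the noise-free abundances (baseline times the
    designed fold effects); ``expected_demand()`` recomputes the analytic
    expected per-residue demand change from those abundances and the realized
    representative residue counts via the demand formula itself.
    """

    target_composition: dict[str, np.ndarray]
    memberships: dict[str, list[str]]
    induced: list[str]
    suppressed: list[str]
    representative_counts: dict[str, dict[str, int]]
    expected_abundances: pd.DataFrame | None = None
    condition_labels: tuple[str, str] = ("undifferentiated", "differentiated")

    def gene_sets(self, labels: dict[str, str] | None = None) -> list[GeneSet]:
        labels = labels or {}
        return [
            GeneSet(set_id=sid, label=labels.get(sid, sid), gene_ids=frozenset(genes))
            for sid, genes in self.memberships.items()
        ]

    def expected_demand(self):
        if self.expected_abundances is None:
            raise ValidationError("expected abundances not yet generated")
        c_from, c_to = self.condition_labels
        merged = [
            MergedGeneRecord(
                gene_id=g,
                abundances={
                    c_from: float(self.expected_abundances.at[g, c_from]),
                    c_to: float(self.expected_abundances.at[g, c_to]),
                },
                counts=self.representative_counts[g],
            )
            for g in self.expected_abundances.index
        ]
        return demand_change(merged, c_from, c_to)


def _shifted_target(base: np.ndarray, pro_shift: float) -> np.ndarray:
    """Add pro_shift to the Pro entry and rescale the others to keep unit sum."""
    target = base.copy()
    p_old = target[PRO_INDEX]
    p_new = p_old + pro_shift
    scale = (1.0 - p_new) / (1.0 - p_old)
    target *= scale
    target[PRO_INDEX] = p_new
    return target


_LETTERS = np.array(list(CANONICAL_RESIDUES))


def _sample_sequence(rng: np.random.Generator, comp: np.ndarray, length: int) -> str:
    # i.i.d. residue sampling realized as multinomial counts + permutation
    counts = rng.multinomial(length, comp)
    return "".join(rng.permutation(np.repeat(_LETTERS, counts)))


def gen_proteome(config: SimulationConfig) -> tuple[Proteome, SyntheticTruth]:
    """Generate a synthetic proteome with Ensembl-style synthetic stable IDs."""
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    base = config.resolved_base()
    lo, hi = config.length_range

    gene_targets: list[np.ndarray] = []
    memberships: dict[str, list[str]] = {s.set_id: [] for s in config.set_spec}
    gene_ids = [f"SIMG{i:06d}" for i in range(1, config.n_genes + 1)]
    cursor = 0
    set_of_gene: dict[str, str] = {}
    for s in config.set_spec:
        block = gene_ids[cursor : cursor + s.n_members]
        memberships[s.set_id] = list(block)
        for g in block:
            set_of_gene[g] = s.set_id
        cursor += s.n_members
    shift_by_set = {s.set_id: s.pro_shift for s in config.set_spec}

    records: list[ProteinRecord] = []
    rep_counts: dict[str, dict[str, int]] = {}
    target_by_gene: dict[str, np.ndarray] = {}
    protein_serial = 0
    for gi, gene in enumerate(gene_ids):
        shift = shift_by_set.get(set_of_gene.get(gene), 0.0)
        target = _shifted_target(base, shift) if shift else base
        target_by_gene[gene] = target
        drawn = rng.dirichlet(config.concentration * target)
        n_iso = (
            int(rng.integers(1, config.max_isoforms_per_gene + 1))
            if config.max_isoforms_per_gene > 1
            else 1
        )
        gene_records: list[ProteinRecord] = []
        for _ in range(n_iso):
            protein_serial += 1
            length = int(rng.integers(lo, hi + 1))
            seq = _sample_sequence(rng, drawn, length)
            gene_records.append(
                ProteinRecord(
                    protein_id=f"SIMP{protein_serial:06d}",
                    sequence=seq,
                    transcript_id=f"SIMT{protein_serial:06d}",
                    gene_id=gene,
                    gene_symbol=f"Sim{gi + 1}",
                )
            )
        records.extend(gene_records)
        # representative = longest isoform, ties by transcript_id (default policy)
        longest = max(len(r.sequence) for r in gene_records)
        tied = [r for r in gene_records if len(r.sequence) == longest]
        rep = min(tied, key=lambda r: r.transcript_id)
        rep_counts[gene] = composition(rep.sequence).counts

    truth = SyntheticTruth(
        target_composition=target_by_gene,
        memberships=memberships,
        induced=list(memberships.get(config.expr_spec.induced_set or "", [])),
        suppressed=list(memberships.get(config.expr_spec.suppressed_set or "", [])),
        representative_counts=rep_counts,
        condition_labels=config.expr_spec.condition_labels,
    )
    return Proteome(records), truth


def gen_expression(
    config: SimulationConfig, truth: SyntheticTruth
) -> ExpressionTable:
    """Generate the two-condition expression table implied by the truth.

    Baselines are log2-normal; induced genes are multiplied and suppressed
    genes divided by ``2**log2_effect`` in the second condition, which also
    carries multiplicative log-normal noise.  Fills
    ``truth.expected_abundances`` with the noise-free values.
    """
    spec = config.expr_spec
    rng = np.random.default_rng([config.seed, 1])
    genes = list(truth.target_composition)
    n = len(genes)
    baseline = 2.0 ** rng.normal(spec.baseline_log2_mean, spec.baseline_log2_sd, n)
    effect = np.zeros(n)
    induced = set(truth.induced)
    suppressed = set(truth.suppressed)
    for i, g in enumerate(genes):
        if g in induced:
            effect[i] = spec.log2_effect
        elif g in suppressed:
            effect[i] = -spec.log2_effect
    expected_cond2 = baseline * 2.0**effect
    noise = (
        2.0 ** rng.normal(0.0, spec.noise_sd, n) if spec.noise_sd > 0 else np.ones(n)
    )
    cond2 = expected_cond2 * noise
    c1, c2 = spec.condition_labels
    table = ExpressionTable(
        pd.DataFrame({c1: baseline, c2: cond2}, index=pd.Index(genes))
    )
    truth.expected_abundances = pd.DataFrame(
        {c1: baseline, c2: expected_cond2}, index=pd.Index(genes)
    )
    truth.condition_labels = spec.condition_labels
    return table


def gen_panel(
    config: SimulationConfig,
) -> tuple[list[PanelMeasurement], float]:
    """Generate a protein panel with a known log-linear proline effect.

    Returns the panel and the true log2-scale slope ``beta``.
    """
    spec = config.panel_spec
    if spec.n < 3:
        raise ValidationError("panel needs at least 3 proteins")
    rng = np.random.default_rng([config.seed, 2])
    lo, hi = spec.pro_range
    pro = np.linspace(lo, hi, spec.n)
    noise = rng.normal(0.0, spec.noise_sd, spec.n) if spec.noise_sd > 0 else np.zeros(spec.n)
    ratios = 2.0 ** (spec.alpha + spec.beta * pro + noise)
    panel = [
        PanelMeasurement(
            protein_label=f"SIMPANEL{i + 1:02d}",
            pro_fraction=float(pro[i]),
            expression_ratio=float(ratios[i]),
        )
        for i in range(spec.n)
    ]
    return panel, spec.beta
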