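"""Per-protein amino-acid composition and representative-isoform selection.

The composition of a peptide is its residue count vector ``N_aa`` over the 20
canonical amino acids and the corresponding fractions ``N_aa / effective
length``.  Non-canonical codes occasionally present in Ensembl peptide files
(X, U, B, Z, O) are excluded from both numerator and denominator and tallied
separately, so fractions stay comparable across proteins.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .errors import ValidationError
from .io_formats import ProteinRecord, Proteome

#: The 20 canonical residues, in one-letter alphabetical order.
CANONICAL_RESIDUES: str = "ACDEFGHIKLMNPQRSTVWY"

#: Codes tolerated in input sequences but excluded from compositions.
TOLERATED_EXTRAS: str = "XUBZO*"

_CANONICAL_SET = frozenset(CANONICAL_RESIDUES)
_TOLERATED_SET = frozenset(TOLERATED_EXTRAS)

#: Three-letter names, for table formatting.
RESIDUE_NAMES = {
    "A": "Ala", "C": "Cys", "D": "Asp", "E": "Glu", "F": "Phe",
    "G": "Gly", "H": "His", "I": "Ile", "K": "Lys", "L": "Leu",
    "M": "Met", "N": "Asn", "P": "Pro", "Q": "Gln", "R": "Arg",
    "S": "Ser", "T": "Thr", "V": "Val", "W": "Trp", "Y": "Tyr",
}


@dataclass
class CompositionVector:
    """Residue counts and fractions for one protein (or a pooled set).

    ``counts`` and ``effective_length`` are None for aggregates that are
    means of fractions rather than counts of actual residues.
    """

    fractions: dict[str, float]
    counts: dict[str, int] | None = None
    effective_length: int | None = None
    n_skipped: int = 0

    def __post_init__(self) -> None:
        if set(self.fractions) != _CANONICAL_SET:
            raise ValidationError("fractions must cover exactly the 20 canonical residues")
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"fractions sum to {total}, expected 1")
        if self.counts is not None:
            if sum(self.counts.values()) != self.effective_length:
                raise ValidationError("counts do not sum to effective_length")

    def fraction_series(self) -> pd.Series:
        return pd.Series(
            [self.fractions[a] for a in CANONICAL_RESIDUES],
            index=list(CANONICAL_RESIDUES),
            dtype=float,
        )


def composition(sequence: str) -> CompositionVector:
    """Compute the CompositionVector of one peptide sequence.

    Trailing stop codons (``*``) are stripped; other tolerated non-canonical
    codes are excluded from counts and length, tallied in ``n_skipped``.
    Unknown characters raise.
    """
    seq = sequence.upper().rstrip("*")
    if not seq:
        raise ValidationError("empty sequence after stop stripping")
    tally = Counter(seq)
    unknown = set(tally) - _CANONICAL_SET - _TOLERATED_SET
    if unknown:
        raise ValidationError(f"unexpected residue codes: {sorted(unknown)}")
    counts = {a: tally.get(a, 0) for a in CANONICAL_RESIDUES}
    effective_length = sum(counts.values())
    if effective_length == 0:
        raise ValidationError("sequence contains no canonical residues")
    n_skipped = len(seq) - effective_length
    fractions = {a: counts[a] / effective_length for a in CANONICAL_RESIDUES}
    return CompositionVector(
        fractions=fractions,
        counts=counts,
        effective_length=effective_length,
        n_skipped=n_skipped,
    )


@dataclass
class RepresentativePolicy:
    """How to choose the protein(s) standing for each gene.

    ``longest_isoform`` (default) takes the maximum effective-length isoform,
    ties broken by lexicographically smallest transcript_id (protein_id when
    transcripts are absent); ``canonical_list`` uses an explicit gene_id ->
    protein_id map; ``all_isoforms`` keeps everything.
    """

    mode: str = "longest_isoform"
    canonical_map: dict[str, str] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.mode not in ("longest_isoform", "canonical_list", "all_isoforms"):
            raise ValidationError(f"unknown representative mode {self.mode!r}")
        if self.mode == "canonical_list" and self.canonical_map is None:
            raise ValidationError("canonical_list mode requires canonical_map")


def _effective_length(record: ProteinRecord) -> int:
    seq = record.sequence.upper().rstrip("*")
    return sum(1 for c in seq if c in _CANONICAL_SET)


def select_representatives(
    proteome: Proteome, policy: RepresentativePolicy | None = None
) -> dict[str, ProteinRecord] | dict[str, list[ProteinRecord]]:
    """Map each gene to its representative ProteinRecord (or isoform list)."""
    policy = policy or RepresentativePolicy()
    if policy.mode == "all_isoforms":
        return {
            gene: [proteome.get(pid) for pid in pids]
            for gene, pids in proteome.gene_index.items()
        }
    if policy.mode == "canonical_list":
        out: dict[str, ProteinRecord] = {}
        known = {rec.protein_id for rec in proteome.records}
        for gene, pid in policy.canonical_map.items():
            if pid not in known:
                raise ValidationError(
                    f"canonical_map names absent protein {pid!r} for gene {gene!r}"
                )
            out[gene] = proteome.get(pid)
        return out
    reps: dict[str, ProteinRecord] = {}
    for gene, pids in proteome.gene_index.items():
        candidates = [proteome.get(pid) for pid in pids]
        best_len = max(_effective_length(r) for r in candidates)
        tied = [r for r in candidates if _effective_length(r) == best_len]
        reps[gene] = min(tied, key=lambda r: r.transcript_id or r.protein_id)
    return reps


def composition_table(
    proteome: Proteome, policy: RepresentativePolicy | None = None
) -> pd.DataFrame:
    """Fractions matrix: one row per representative (gene ID when annotated,
    protein ID otherwise), 20 residue columns, rows in input order."""
    if len(proteome) == 0:
        raise ValidationError("empty proteome")
    rows: list[tuple[str, CompositionVector]] = []
    if proteome.gene_index:
        reps = select_representatives(proteome, policy)
        covered: set[str] = set()
        for rec in proteome.records:  # preserve input order
            if rec.gene_id is not None and rec.gene_id not in covered:
                covered.add(rec.gene_id)
                chosen = reps[rec.gene_id]
                if isinstance(chosen, list):
                    for iso in chosen:
                        rows.append((iso.protein_id, composition(iso.sequence)))
                else:
                    rows.append((rec.gene_id, composition(chosen.sequence)))
            elif rec.gene_id is None:
                rows.append((rec.protein_id, composition(rec.sequence)))
    else:
        rows = [(rec.protein_id, composition(rec.sequence)) for rec in proteome.records]
    return pd.DataFrame(
        [cv.fraction_series() for _, cv in rows],
        index=[label for label, _ in rows],
    )
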