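"""Readers and writers for the external formats the pipeline touches.

Supported inputs are Ensembl-dialect peptide FASTA (headers carry
whitespace-separated ``key:value`` tokens such as ``gene:ENSMUSG...``),
plain FASTA, GMT and two-column TSV gene sets, and tab-separated
gene-by-condition expression tables.  Outputs are TSV matrices and JSON
reports; both round-trip losslessly.
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import FormatError, ValidationError

_VERSION_SUFFIX = re.compile(r"\.\d+$")


def strip_version(stable_id: str) -> str:
    """Remove a trailing ``.N`` version suffix from a stable ID (idempotent)."""
    return _VERSION_SUFFIX.sub("", stable_id)


@dataclass(frozen=True)
class ProteinRecord:
    """One peptide sequence with its protein/transcript/gene stable IDs."""

    protein_id: str
    sequence: str
    transcript_id: str | None = None
    gene_id: str | None = None
    gene_symbol: str | None = None

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValidationError("protein_id must be non-empty")
        if not self.sequence:
            raise ValidationError(
                f"protein {self.protein_id!r}: empty sequence after stop stripping"
            )


@dataclass
class Proteome:
    """A collection of ProteinRecords with a gene_id -> protein_ids index."""

    records: list[ProteinRecord]
    gene_index: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.protein_id in seen:
                raise FormatError(f"duplicate protein_id {rec.protein_id!r}")
            seen.add(rec.protein_id)
        if not self.gene_index:
            self.gene_index = {}
            for rec in self.records:
                if rec.gene_id is not None:
                    self.gene_index.setdefault(rec.gene_id, []).append(rec.protein_id)

    def __len__(self) -> int:
        return len(self.records)

    def get(self, protein_id: str) -> ProteinRecord:
        return self._by_protein_id[protein_id]

    @property
    def _by_protein_id(self) -> dict[str, ProteinRecord]:
        cached = getattr(self, "_pid_cache", None)
        if cached is None or len(cached) != len(self.records):
            cached = {rec.protein_id: rec for rec in self.records}
            object.__setattr__(self, "_pid_cache", cached)
        return cached


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene stable IDs (GO-term style)."""

    set_id: str
    label: str
    gene_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise FormatError(f"gene set {self.set_id!r} has no members")

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class ExpressionTable:
    """Gene-by-condition matrix of non-negative FPKM-like abundances."""

    data: pd.DataFrame  # index = gene stable IDs, columns = condition labels

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene IDs in expression table: {dups}")
        if self.data.isna().any().any():
            raise ValidationError("expression table contains NA values")
        if (self.data.to_numpy() < 0).any():
            rows, cols = np.nonzero(self.data.to_numpy() < 0)
            raise ValidationError(
                "negative abundance at row "
                f"{self.data.index[rows[0]]!r}, column {self.data.columns[cols[0]]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def condition_labels(self) -> list[str]:
        return list(self.data.columns)

    def column(self, label: str) -> pd.Series:
        if label not in self.data.columns:
            raise ValidationError(
                f"condition {label!r} not in table (has {list(self.data.columns)})"
            )
        return self.data[label]


# ---------------------------------------------------------------------------
# FASTA

_HEADER_TOKEN = re.compile(r"^(\w+):(\S+)$")


def _parse_header_tokens(description: str) -> dict[str, str]:
    tokens: dict[str, str] = {}
    for tok in description.split()[1:]:  # first token is the ID itself
        m = _HEADER_TOKEN.match(tok)
        if m:
            tokens[m.group(1)] = m.group(2)
    return tokens


def read_proteome_fasta(
    path: str | Path,
    id_policy: str = "strip_version",
    gene_map: Mapping[str, str] | str | Path | None = None,
) -> Proteome:
    """Read a peptide FASTA (Ensembl pep dialect or plain) into a Proteome.

    Parameters
    ----------
    path:
        FASTA file.  Ensembl-style headers (``gene:``, ``transcript:``,
        ``gene_symbol:`` tokens) populate the corresponding record fields;
        plain headers yield records with those fields absent.
    id_policy:
        ``"strip_version"`` (default) removes ``.N`` suffixes from all stable
        IDs so downstream Gene.stable.ID merges never fail on version
        mismatch; ``"keep"`` leaves IDs untouched.
    gene_map:
        Optional protein_id -> gene_id mapping (dict, or path to a two-column
        TSV) for plain FASTA files that carry no gene tokens.
    """
    if id_policy not in ("strip_version", "keep"):
        raise ValidationError(f"unknown id_policy {id_policy!r}")
    path = Path(path)
    if not path.exists():
        raise IOError(f"FASTA file not found: {path}")
    if isinstance(gene_map, (str, Path)):
        gene_map = read_gene_map_tsv(gene_map)

    fix = strip_version if id_policy == "strip_version" else (lambda s: s)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        protein_id = fix(rec.id)
        if protein_id in seen:
            raise FormatError(f"duplicate protein_id {protein_id!r} in {path}")
        seen.add(protein_id)
        tokens = _parse_header_tokens(rec.description)
        sequence = str(rec.seq).rstrip("*")
        gene_id = tokens.get("gene")
        transcript_id = tokens.get("transcript")
        if gene_map is not None and gene_id is None:
            gene_id = gene_map.get(protein_id)
        records.append(
            ProteinRecord(
                protein_id=protein_id,
                sequence=sequence,
                transcript_id=fix(transcript_id) if transcript_id else None,
                gene_id=fix(gene_id) if gene_id else None,
                gene_symbol=tokens.get("gene_symbol"),
            )
        )
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return Proteome(records)


def write_proteome_fasta(proteome: Proteome, path: str | Path) -> None:
    """Write a Proteome with Ensembl-style headers; deterministic record order."""
    with open(path, "w") as fh:
        for rec in proteome.records:
            tokens = [rec.protein_id, "pep"]
            if rec.gene_id:
                tokens.append(f"gene:{rec.gene_id}")
            if rec.transcript_id:
                tokens.append(f"transcript:{rec.transcript_id}")
            if rec.gene_symbol:
                tokens.append(f"gene_symbol:{rec.gene_symbol}")
            fh.write(">" + " ".join(tokens) + "\n")
            seq = rec.sequence
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def read_gene_map_tsv(path: str | Path) -> dict[str, str]:
    """Two-column TSV (protein_id, gene_id) -> dict; versions stripped."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            mapping[strip_version(fields[0])] = strip_version(fields[1])
    return mapping


# ---------------------------------------------------------------------------
# Gene sets


def read_gene_sets(path: str | Path, format: str | None = None) -> list[GeneSet]:
    """Read gene sets from GMT (one set per line) or two-column TSV.

    The format is inferred from the extension when not given.  Duplicate
    memberships are deduplicated; sets come back in file order.
    """
    path = Path(path)
    if format is None:
        format = "gmt" if path.suffix.lower() == ".gmt" else "tsv"
    if format not in ("gmt", "tsv"):
        raise ValidationError(f"unknown gene-set format {format!r}")

    order: list[str] = []
    labels: dict[str, str] = {}
    members: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected >=2 tab-separated fields")
            if format == "gmt":
                set_id, label, *genes = fields
                if not genes:
                    raise FormatError(f"{path}:{lineno}: gene set {set_id!r} empty")
                if set_id not in members:
                    order.append(set_id)
                    labels[set_id] = label
                    members[set_id] = []
                members[set_id].extend(genes)
            else:
                set_id, gene = fields[0], fields[1]
                if set_id not in members:
                    order.append(set_id)
                    labels[set_id] = set_id
                    members[set_id] = []
                members[set_id].append(gene)
    if not order:
        raise FormatError(f"no gene sets in {path}")
    return [
        GeneSet(set_id=sid, label=labels[sid], gene_ids=frozenset(members[sid]))
        for sid in order
    ]


def write_gene_sets_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.set_id, gs.label, *sorted(gs.gene_ids)]) + "\n")


# ---------------------------------------------------------------------------
# Expression tables


def read_expression_table(path: str | Path) -> ExpressionTable:
    """TSV with header row; first column gene IDs, remaining columns numeric.

    Gene IDs are version-stripped.  NA, non-numeric or negative cells are
    rejected with the offending row/column named.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[1] == 0:
        raise FormatError(f"{path}: expected at least one condition column")
    df.index = df.index.map(lambda s: strip_version(str(s)))
    numeric = pd.DataFrame(index=df.index)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValidationError(
                f"{path}: non-numeric abundance at row {row!r}, column {col!r}"
            )
        if converted.isna().any():
            row = df.index[converted.isna().to_numpy().nonzero()[0][0]]
            raise ValidationError(f"{path}: NA abundance at row {row!r}, column {col!r}")
        numeric[col] = converted.astype(float)
    return ExpressionTable(numeric)


def write_expression_table(table: ExpressionTable, path: str | Path) -> None:
    out = table.data.copy()
    out.insert(0, "gene_id", out.index)
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Generic matrix / report output


def write_matrix_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a labeled real matrix as TSV, lossless and in input order."""
    values = matrix.to_numpy(dtype=float)
    if values.size and not np.isfinite(values).all():
        raise ValidationError("matrix contains non-finite values")
    matrix.to_csv(path, sep="\t", index=True, index_label="", float_format="%.17g")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    return df


def _json_default(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if isinstance(obj, pd.DataFrame):
        return {"index": list(obj.index), "columns": list(obj.columns),
                "values": obj.to_numpy().tolist()}
    raise TypeError(f"cannot serialize {type(obj).__name__}")


def write_report_json(report, path: str | Path) -> None:
    """Serialize a pipeline report (dataclass or mapping) to JSON.

    Non-finite floats are rejected so the file always round-trips.
    """
    try:
        text = json.dumps(report, default=_json_default, indent=2, allow_nan=False)
    except ValueError as exc:
        raise ValidationError(f"report contains non-finite values: {exc}") from exc
    with open(path, "w") as fh:
        fh.write(text + "\n")


def read_report_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
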