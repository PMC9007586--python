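"""Correlation of protein-expression change against proline composition.

A protein panel pairs each protein's proline fraction with a measured
expression fold change (e.g. densitometry after proline withdrawal or
transporter knockout).  The association is summarized by the Pearson
correlation of the (by default log2-transformed) fold change with the
proline fraction, with the two-tailed p-value from
``t = r * sqrt(n - 2) / sqrt(1 - r^2)`` on n - 2 degrees of freedom, plus
the least-squares slope and intercept of the same regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FormatError, ValidationError


@dataclass(frozen=True)
class PanelMeasurement:
    """One protein on a western-blot style panel."""

    protein_label: str
    pro_fraction: float
    expression_ratio: float
    replicate_sd: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.pro_fraction <= 1.0:
            raise ValidationError(
                f"{self.protein_label}: pro_fraction {self.pro_fraction} outside [0, 1]"
            )
        if self.expression_ratio <= 0.0:
            raise ValidationError(
                f"{self.protein_label}: expression_ratio must be positive"
            )
        if self.replicate_sd is not None and self.replicate_sd < 0.0:
            raise ValidationError(f"{self.protein_label}: negative replicate_sd")


@dataclass
class CorrelationResult:
    n: int
    r: float
    p_value: float
    slope: float
    intercept: float
    transform: str


def correlate_panel(
    panel: list[PanelMeasurement], transform: str = "log2"
) -> CorrelationResult:
    """Pearson correlation of (transformed) expression ratio vs proline fraction.

    Fold changes are ratio-scaled, so the default transform is log2; pass
    ``transform="identity"`` to correlate the raw ratios.
    """
    if transform not in ("log2", "identity"):
        raise ValidationError(f"unknown transform {transform!r}")
    if len(panel) < 3:
        raise ValidationError("panel needs at least 3 proteins")
    x = np.array([m.pro_fraction for m in panel])
    ratios = np.array([m.expression_ratio for m in panel])
    y = np.log2(ratios) if transform == "log2" else ratios
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValidationError("zero variance in pro_fraction or expression values")
    r, p = stats.pearsonr(x, y)
    fit = stats.linregress(x, y)
    if abs(r) >= 1.0 - 1e-15:
        warnings.warn("panel is exactly collinear; p reported as 0")
        p = 0.0
    return CorrelationResult(
        n=len(panel),
        r=float(r),
        p_value=float(p),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        transform=transform,
    )


def read_panel_tsv(path: str | Path) -> list[PanelMeasurement]:
    """Read a panel table (columns: protein_label, pro_fraction,
    expression_ratio[, sd]).  Proline composition given as printed
    percentages (values > 1) is converted to fractions."""
    df = pd.read_csv(path, sep="\t")
    required = {"protein_label", "pro_fraction", "expression_ratio"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    panel = []
    for _, row in df.iterrows():
        pro = float(row["pro_fraction"])
        if pro > 1.0:  # printed as percent
            pro = pro / 100.0
        sd = float(row["sd"]) if "sd" in df.columns and pd.notna(row.get("sd")) else None
        panel.append(
            PanelMeasurement(
                protein_label=str(row["protein_label"]),
                pro_fraction=pro,
                expression_ratio=float(row["expression_ratio"]),
                replicate_sd=sd,
            )
        )
    return panel


def write_panel_tsv(panel: list[PanelMeasurement], path: str | Path) -> None:
    rows = [
        {
            "protein_label": m.protein_label,
            "pro_fraction": m.pro_fraction,
            "expression_ratio": m.expression_ratio,
            "sd": "" if m.replicate_sd is None else m.replicate_sd,
        }
        for m in panel
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.17g")
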