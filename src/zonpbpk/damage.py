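"""Functional vs tissue damage and the loss-of-clearance classification.

Functional damage is the relative reduction of hepatic enzyme/transporter
abundance needed to explain the intoxicated PK:

    F = 1 - e_d / e_h

Tissue damage is the relative loss of enzyme-expressing lobule area implied
by the dead-cell fraction d, given the healthy expressed fraction p_e:

    T = 1 - (p_e - d) / p_e        (clamped into [0, 1]; the clamp binds
                                    exactly when d >= p_e, i.e. the necrotic
                                    area covers the whole expressing area)

Comparing the two classifies the loss of clearance capacity: functional
damage below tissue damage implies compensation by the surviving tissue,
equality (within tolerance) an uncompensated loss, and an excess an
aggravated loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fitting import PKDataset
from .simulator import SITES, SimulationResult, compute_auc, sample_site

__all__ = [
    "DamageReport",
    "compute_functional_damage",
    "compute_tissue_damage",
    "classify_loss",
    "auc_change_table",
]

CLASSIFICATIONS = ("compensated", "uncompensated", "aggravated", "indeterminate")


def compute_functional_damage(e_h: float, e_d: float) -> float:
    """F = 1 - e_d/e_h for healthy and intoxicated enzyme amounts."""
    if e_h <= 0:
        raise ValueError("healthy enzyme amount e_h must be > 0")
    if e_d < 0:
        raise ValueError("intoxicated enzyme amount e_d must be >= 0")
    if e_d > e_h:
        raise ValueError(
            "e_d > e_h would imply negative damage; enzyme induction is out of scope"
        )
    return 1.0 - e_d / e_h


def compute_tissue_damage(p_e: float, d: float) -> float:
    """T = 1 - (p_e - d)/p_e, clamped into [0, 1]."""
    if not 0 < p_e <= 1:
        raise ValueError("expressed fraction p_e must lie in (0, 1]")
    if not 0 <= d <= 1:
        raise ValueError("dead fraction d must lie in [0, 1]")
    return float(min(1.0, max(0.0, 1.0 - (p_e - d) / p_e)))


def classify_loss(functional: float, tissue: float, tolerance: float = 0.05) -> str:
    """Compensated / uncompensated / aggravated call at the given tolerance."""
    for name, v in (("functional", functional), ("tissue", tissue)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} damage must lie in [0, 1]")
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    if functional > tissue + tolerance:
        return "aggravated"
    if functional < tissue - tolerance:
        return "compensated"
    return "uncompensated"


@dataclass
class DamageReport:
    """Per-drug summary mirroring the enzyme/damage table of the analysis."""

    drug: str
    enzyme: str
    functional_damage: float
    tissue_damage: float
    p_e: float
    d: float
    classification: str
    tolerance: float = 0.05
    auc_changes: pd.DataFrame | None = None
    scan_boundary: bool = False

    def __post_init__(self) -> None:
        for name in ("functional_damage", "tissue_damage", "p_e", "d"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        expected = classify_loss(self.functional_damage, self.tissue_damage, self.tolerance)
        if self.classification != expected:
            raise ValueError(
                f"classification {self.classification!r} inconsistent with damages "
                f"(expected {expected!r} at tolerance {self.tolerance})"
            )


def _auc_cells(data: SimulationResult | PKDataset) -> pd.Series:
    """Trapezoidal AUC per (compound, site) over the observed window."""
    out = {}
    if isinstance(data, SimulationResult):
        for compound in data.species:
            for site in SITES:
                conc = sample_site(data, site, compound)
                out[(compound, site)] = compute_auc(data.times, conc)
    else:
        means = data.cell_means()
        for (compound, site), cell in means.groupby(level=["compound", "site"]):
            times = cell.index.get_level_values("time_min").to_numpy(float)
            order = np.argsort(times)
            if len(times) >= 2:
                out[(compound, site)] = compute_auc(times[order], cell.to_numpy(float)[order])
    s = pd.Series(out, dtype=float)
    s.index = pd.MultiIndex.from_tuples(s.index, names=["compound", "site"])
    return s


def auc_change_table(
    healthy: SimulationResult | PKDataset, tox: SimulationResult | PKDataset
) -> pd.DataFrame:
    """AUC_tox / AUC_healthy and percent change per compound and site.

    Cells present on only one side are reported with missing values, never
    as zero.  For observed datasets the AUC is the trapezoid over the
    replicate means at the design times (the common observed window).
    """
    h = _auc_cells(healthy)
    t = _auc_cells(tox)
    table = pd.DataFrame({"auc_healthy": h, "auc_tox": t})
    table["ratio"] = table["auc_tox"] / table["auc_healthy"]
    table["percent_change"] = 100.0 * (table["ratio"] - 1.0)
    return table.sort_index()
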