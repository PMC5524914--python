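"""Organ-plasma partition coefficients from tissue composition.

Implements the tissue-composition method of Poulin & Theil (J Pharm Sci 91,
2002): a drug distributes between the aqueous and lipid phases of each tissue
according to its octanol-water partition coefficient, with phospholipids
treated as a 30:70 lipid:water mixture.  The tissue:plasma coefficient is

    Kp = [P*(f_nl + 0.3*f_ph) + (f_w + 0.7*f_ph)]_tissue
         ---------------------------------------------  *  fu_p / fu_t
         [P*(f_nl + 0.3*f_ph) + (f_w + 0.7*f_ph)]_plasma

with P = 10**logP and the tissue unbound fraction estimated from plasma
binding as fu_t = 1 / (1 + 0.5*(1 - fu_p)/fu_p).  The same (non-adipose) form
is applied uniformly to every perfused tissue; blood pools have Kp = 1 by
definition.  Per-compound, per-organ overrides are honoured verbatim.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import TYPE_CHECKING, Mapping

import yaml

if TYPE_CHECKING:  # pragma: no cover
    from .compounds import CompoundModel
    from .physiology import MousePhysiology

__all__ = ["load_tissue_composition", "partition_coefficient", "compute_partition_coefficients"]

_BLOOD_POOLS = ("venous_blood", "arterial_blood")


def load_tissue_composition(path: str | Path | None = None) -> dict[str, dict[str, float]]:
    """Load the water / neutral-lipid / phospholipid fraction table."""
    if path is None:
        text = resources.files("zonpbpk.data").joinpath("tissue_composition.yaml").read_text()
    else:
        text = Path(path).read_text()
    return yaml.safe_load(text)


def _solubility(p: float, comp: Mapping[str, float]) -> float:
    return p * (comp["neutral_lipid"] + 0.3 * comp["phospholipid"]) + (
        comp["water"] + 0.7 * comp["phospholipid"]
    )


def partition_coefficient(
    log_lipophilicity: float,
    fraction_unbound: float,
    tissue: Mapping[str, float],
    plasma: Mapping[str, float],
) -> float:
    """Tissue:plasma partition coefficient for one tissue composition."""
    if not 0 < fraction_unbound <= 1:
        raise ValueError("fraction_unbound must lie in (0, 1]")
    p = 10.0 ** log_lipophilicity
    fu_p = fraction_unbound
    fu_t = 1.0 / (1.0 + 0.5 * (1.0 - fu_p) / fu_p)
    kp = _solubility(p, tissue) / _solubility(p, plasma) * fu_p / fu_t
    if kp <= 0:  # pragma: no cover - impossible for positive compositions
        raise ValueError("partition coefficient must be positive")
    return kp


def compute_partition_coefficients(
    compound: "CompoundModel",
    physiology: "MousePhysiology",
    overrides: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """One Kp per organ of ``physiology`` for ``compound``.

    Raises a descriptive error if the compound is missing the physicochemical
    fields the method needs.  ``overrides`` (organ -> Kp) win over the
    computed values, allowing fitted or literature coefficients to be pinned.
    """
    for field_name in ("log_lipophilicity", "fraction_unbound"):
        if getattr(compound, field_name, None) is None:
            raise ValueError(
                f"cannot compute partition coefficients for {compound.name}: "
                f"missing field {field_name!r}"
            )
    table = load_tissue_composition()
    plasma = table["plasma"]
    kps: dict[str, float] = {}
    for organ in physiology.organs:
        if organ.name in _BLOOD_POOLS:
            kps[organ.name] = 1.0
            continue
        comp = table.get(organ.name)
        if comp is None:
            raise KeyError(f"no tissue composition for organ {organ.name!r}")
        kps[organ.name] = partition_coefficient(
            compound.log_lipophilicity, compound.fraction_unbound, comp, plasma
        )
    if overrides:
        for organ_name, value in overrides.items():
            if value <= 0:
                raise ValueError(f"override Kp for {organ_name!r} must be > 0")
            kps[organ_name] = float(value)
    return kps
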