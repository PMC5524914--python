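"""Whole-body mouse compartment scaffold and the two-zone liver.

The physiology is loaded from a versioned YAML table (organ volumes, regional
blood-flow fractions, sub-compartment fractions) and scaled linearly to the
requested body weight.  Every organ is decomposed into plasma, red blood
cells, interstitium and cellular space; within an organ the sub-compartments
are assumed to be in instantaneous (well-stirred) equilibrium.

The liver can be split into a periportal and a pericentral zone.  The zones
are arranged strictly in series along the sinusoidal flow direction: the
periportal zone receives the mixed portal-venous (80%) and hepatic-arterial
(20%) inflow, the pericentral zone drains into the hepatic vein.  Zone
volumes are set from the pericentral enzyme-expression fraction measured on
stained sections, each sub-compartment being split by the same fraction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "OrganSpec",
    "MousePhysiology",
    "ZonedLiverSpec",
    "build_default_physiology",
    "load_physiology",
    "split_liver",
]

_REL_TOL = 1e-9

SUBCOMPARTMENTS = ("plasma", "red_blood_cells", "interstitial", "cellular")


class PhysiologyError(ValueError):
    """Raised when a physiology table violates one of its invariants."""


@dataclass(frozen=True)
class OrganSpec:
    """A single perfused organ.

    ``blood_flow`` is the organ's perfusion in L/min.  For the liver this is
    the *total* inflow (portal vein + hepatic artery); its arterial share is
    carried separately by :class:`MousePhysiology`.
    """

    name: str
    total_volume: float  # L
    sub_volumes: Mapping[str, float]  # L, keys = SUBCOMPARTMENTS
    blood_flow: float  # L/min

    def __post_init__(self) -> None:
        if self.total_volume <= 0:
            raise PhysiologyError(f"{self.name}: total_volume must be > 0")
        if self.blood_flow < 0:
            raise PhysiologyError(f"{self.name}: blood_flow must be >= 0")
        missing = set(SUBCOMPARTMENTS) - set(self.sub_volumes)
        if missing:
            raise PhysiologyError(f"{self.name}: missing sub-volumes {sorted(missing)}")
        if any(v < 0 for v in self.sub_volumes.values()):
            raise PhysiologyError(f"{self.name}: sub-volumes must be >= 0")
        total = sum(self.sub_volumes.values())
        if not math.isclose(total, self.total_volume, rel_tol=_REL_TOL):
            raise PhysiologyError(
                f"{self.name}: sub-volumes sum to {total!r}, expected {self.total_volume!r}"
            )

    @property
    def vascular_volume(self) -> float:
        return self.sub_volumes["plasma"] + self.sub_volumes["red_blood_cells"]

    def scaled(self, factor: float) -> "OrganSpec":
        return OrganSpec(
            name=self.name,
            total_volume=self.total_volume * factor,
            sub_volumes={k: v * factor for k, v in self.sub_volumes.items()},
            blood_flow=self.blood_flow,
        )


@dataclass(frozen=True)
class MousePhysiology:
    """Complete whole-body scaffold shared by every simulation."""

    body_weight: float  # kg
    organs: tuple[OrganSpec, ...]
    hematocrit: float
    cardiac_output: float  # L/min
    portal_fraction_of_liver_inflow: float = 0.80

    def __post_init__(self) -> None:
        if not 0 < self.hematocrit < 1:
            raise PhysiologyError("hematocrit must lie in (0, 1)")
        if self.body_weight <= 0:
            raise PhysiologyError("body_weight must be > 0")
        names = [o.name for o in self.organs]
        if len(names) != len(set(names)):
            raise PhysiologyError("duplicate organ names")
        # conservation: arterial-fed flows sum to cardiac output
        arterial = sum(o.blood_flow for o in self.organs if o.name not in ("lung", "venous_blood", "arterial_blood", "liver"))
        arterial += self.hepatic_artery_flow
        if not math.isclose(arterial, self.cardiac_output, rel_tol=1e-9):
            raise PhysiologyError(
                f"arterial flows sum to {arterial!r} L/min, expected cardiac output "
                f"{self.cardiac_output!r} L/min"
            )
        liver = self.organ("liver")
        if not math.isclose(
            liver.blood_flow,
            self.portal_vein_flow + self.hepatic_artery_flow,
            rel_tol=1e-9,
        ):
            raise PhysiologyError("liver inflow must equal portal + hepatic-artery flow")

    def organ(self, name: str) -> OrganSpec:
        for o in self.organs:
            if o.name == name:
                return o
        raise KeyError(name)

    @property
    def portal_vein_flow(self) -> float:
        """Portal-venous flow: the pooled gut and spleen outflows (L/min)."""
        return self.organ("gut").blood_flow + self.organ("spleen").blood_flow

    @property
    def hepatic_artery_flow(self) -> float:
        liver = self.organ("liver")
        return liver.blood_flow - self.portal_vein_flow


@dataclass(frozen=True)
class ZonedLiverSpec:
    """The liver split into an upstream periportal and a downstream pericentral zone.

    ``pericentral_fraction`` is the stained (enzyme-expressing) fraction p_e of
    the lobule; the zone volumes follow it exactly, each sub-compartment being
    split by the same fraction.  Blood passes periportal -> pericentral in
    series, both zones carrying the full liver inflow.
    """

    pericentral_fraction: float
    periportal: OrganSpec
    pericentral: OrganSpec

    def __post_init__(self) -> None:
        if not 0 < self.pericentral_fraction < 1:
            raise PhysiologyError("pericentral_fraction must lie strictly in (0, 1)")
        total = self.periportal.total_volume + self.pericentral.total_volume
        if not math.isclose(
            self.pericentral.total_volume / total, self.pericentral_fraction, rel_tol=1e-9
        ):
            raise PhysiologyError("pericentral volume share must equal pericentral_fraction")

    @property
    def total_volume(self) -> float:
        return self.periportal.total_volume + self.pericentral.total_volume


def _organ_from_entry(name: str, entry: Mapping, hematocrit: float, scale: float,
                      cardiac_output: float) -> OrganSpec:
    volume = float(entry["volume_L"]) * scale
    vasc = float(entry.get("vascular_fraction", 0.0))
    inter = float(entry.get("interstitial_fraction", 0.0))
    if vasc + inter > 1 + 1e-12:
        raise PhysiologyError(f"{name}: vascular + interstitial fractions exceed 1")
    cellular = max(0.0, 1.0 - vasc - inter)
    sub = {
        "plasma": volume * vasc * (1 - hematocrit),
        "red_blood_cells": volume * vasc * hematocrit,
        "interstitial": volume * inter,
        "cellular": volume * cellular,
    }
    # exact closure against float round-off
    sub["cellular"] = max(0.0, volume - sub["plasma"] - sub["red_blood_cells"] - sub["interstitial"])
    flow = float(entry.get("flow_fraction_of_cardiac_output", 0.0)) * cardiac_output
    return OrganSpec(name=name, total_volume=volume, sub_volumes=sub, blood_flow=flow)


def load_physiology(path: str | Path | None = None, body_weight: float = 0.025) -> MousePhysiology:
    """Load a physiology table and scale organ volumes linearly to body weight.

    Parameters
    ----------
    path:
        YAML physiology file; defaults to the bundled mouse table.
    body_weight:
        Target body weight in kg.  Volumes scale linearly; flows scale with
        body weight as well (constant cardiac output per kg).
    """
    if body_weight <= 0:
        raise PhysiologyError("body_weight must be > 0 kg")
    if path is None:
        text = resources.files("zonpbpk.data").joinpath("mouse_physiology.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    ref_bw = float(raw["reference_body_weight_kg"])
    scale = body_weight / ref_bw
    hct = float(raw["hematocrit"])
    co = float(raw["cardiac_output_L_per_min"]) * scale
    organs = []
    for name, entry in raw["organs"].items():
        if name == "liver":
            continue  # handled below (flow fraction is arterial share only)
        organs.append(_organ_from_entry(name, entry, hct, scale, co))
    liver_entry = raw["organs"]["liver"]
    liver = _organ_from_entry("liver", liver_entry, hct, scale, co)
    portal = sum(o.blood_flow for o in organs if o.name in ("gut", "spleen"))
    liver = replace(liver, blood_flow=portal + liver.blood_flow)
    organs.append(liver)
    phys = MousePhysiology(
        body_weight=body_weight,
        organs=tuple(organs),
        hematocrit=hct,
        cardiac_output=co,
        portal_fraction_of_liver_inflow=float(raw.get("portal_fraction_of_liver_inflow", 0.80)),
    )
    return phys


def build_default_physiology(body_weight: float = 0.025) -> MousePhysiology:
    """Return the bundled mouse physiology scaled to ``body_weight`` (kg).

    The default of 0.025 kg matches young adult C57BL/6 males (20-25 g).  A
    warning is emitted outside the 0.015-0.040 kg range where linear scaling
    of a 25 g reference animal becomes questionable.
    """
    if body_weight <= 0:
        raise PhysiologyError("body_weight must be > 0 kg")
    if not 0.015 <= body_weight <= 0.040:
        warnings.warn(
            f"body_weight {body_weight} kg outside the 0.015-0.040 kg range; "
            "linear scaling of the reference mouse may be inaccurate",
            stacklevel=2,
        )
    return load_physiology(None, body_weight)


def split_liver(physiology: MousePhysiology, pericentral_fraction: float) -> ZonedLiverSpec:
    """Split the liver into series periportal/pericentral zones.

    Each sub-compartment (plasma, RBC, interstitial, cellular) is divided by
    the same fraction, so zone proportions are identical to the whole organ.
    Both zones carry the full liver inflow (series arrangement).
    """
    if not 0 < pericentral_fraction < 1:
        raise PhysiologyError("pericentral_fraction must lie strictly in (0, 1)")
    liver = physiology.organ("liver")
    f = pericentral_fraction
    pericentral = OrganSpec(
        name="liver_pericentral",
        total_volume=liver.total_volume * f,
        sub_volumes={k: v * f for k, v in liver.sub_volumes.items()},
        blood_flow=liver.blood_flow,
    )
    periportal = OrganSpec(
        name="liver_periportal",
        total_volume=liver.total_volume - pericentral.total_volume,
        sub_volumes={
            k: liver.sub_volumes[k] - pericentral.sub_volumes[k] for k in liver.sub_volumes
        },
        blood_flow=liver.blood_flow,
    )
    return ZonedLiverSpec(
        pericentral_fraction=f, periportal=periportal, pericentral=pericentral
    )
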