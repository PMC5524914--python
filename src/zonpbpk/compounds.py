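"""Compound models for the six-drug cocktail and its tracked metabolites.

Each :class:`CompoundModel` carries the physicochemistry (dose, fraction
unbound, lipophilicity, molecular weight) and the clearance topology (linear
hepatic / renal / biliary processes, Michaelis-Menten branches, and
parent-to-metabolite links) of one drug.

Clearance convention
--------------------
A linear "specific clearance" of ``r`` 1/min denotes the first-order rate
constant acting on the *unbound* concentration in the cellular space of the
named organ, scaled by the whole organ's cellular volume::

    turnover [umol/min] = abundance * r * fu * C_plasma,out * V_cell(organ)

A clearance sited in ``liver_pericentral`` keeps its whole-liver referencing
but physically takes place in (and sees the substrate concentration of) the
pericentral zone of a zonated liver.  Michaelis-Menten processes use a
reference enzyme concentration of 1 umol/L of cellular water, so that
``abundance`` (healthy value 1.0) is the only scale factor available to a
hepatic-damage analysis; functional damage multiplies ``abundance`` by
``(1 - f)`` for every hepatic process.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .partition import compute_partition_coefficients  # re-exported  # noqa: F401
from .physiology import MousePhysiology, build_default_physiology

__all__ = [
    "ClearanceSpec",
    "MetaboliteLink",
    "CompoundModel",
    "builtin_cocktail",
    "load_compounds",
    "serialize_compounds",
    "dose_in_amount",
    "effective_plasma_clearances",
    "calibrate_excretion",
    "compute_partition_coefficients",
    "EXCRETION_TARGETS",
]

LINEAR_KINDS = ("linear_hepatic", "linear_renal", "linear_biliary")
HEPATIC_SITES = ("liver", "liver_pericentral", "liver_to_bile")

#: Observed unchanged-urine fractions targeted by the renal calibration
#: (fraction of eliminated dose recovered unchanged in urine); pravastatin
#: additionally targets 23% unchanged in feces vs 30% metabolized.
EXCRETION_TARGETS: dict[str, float] = {
    "caffeine": 0.051,
    "torsemide": 0.20,
    "codeine": 0.069,
    "talinolol": 0.55,
    "pravastatin": 0.41,
}
_PRAVASTATIN_SHARES = {"metabolic": 0.30, "biliary": 0.23, "renal": 0.41}


@dataclass(frozen=True)
class ClearanceSpec:
    """One active clearance process."""

    label: str
    kind: str  # linear_hepatic | linear_renal | linear_biliary | michaelis_menten_hepatic
    site: str  # liver | liver_pericentral | kidney | liver_to_bile
    rate: float | None = None  # 1/min, linear kinds
    k_cat: float | None = None  # 1/min, MM
    k_m: float | None = None  # umol/L, MM
    abundance: float = 1.0  # relative enzyme/transporter expression

    def __post_init__(self) -> None:
        if self.kind in LINEAR_KINDS:
            if self.rate is None or self.rate < 0:
                raise ValueError(f"{self.label}: linear clearance needs rate >= 0")
        elif self.kind == "michaelis_menten_hepatic":
            if self.k_cat is None or self.k_cat < 0:
                raise ValueError(f"{self.label}: MM clearance needs k_cat >= 0")
            if self.k_m is None or self.k_m <= 0:
                raise ValueError(f"{self.label}: MM clearance needs K_m > 0")
        else:
            raise ValueError(f"{self.label}: unknown clearance kind {self.kind!r}")
        if self.abundance < 0:
            raise ValueError(f"{self.label}: abundance must be >= 0")

    @property
    def hepatic(self) -> bool:
        return self.site in HEPATIC_SITES


@dataclass(frozen=True)
class MetaboliteLink:
    """Routes a share of a parent clearance process into a metabolite."""

    parent: str
    metabolite: str
    fraction_of_clearance: float
    tracked: bool = True
    via: str | None = None  # label of the parent clearance carrying the flux

    def __post_init__(self) -> None:
        if not 0 <= self.fraction_of_clearance <= 1:
            raise ValueError("fraction_of_clearance must lie in [0, 1]")


@dataclass(frozen=True)
class CompoundModel:
    name: str
    fraction_unbound: float
    log_lipophilicity: float
    molecular_weight: float  # g/mol
    clearances: tuple[ClearanceSpec, ...]
    dose_per_kg: float | None = None  # mg/kg; None for metabolites
    metabolite_links: tuple[MetaboliteLink, ...] = ()
    zonated: bool = False
    pericentral_fraction: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.fraction_unbound <= 1:
            raise ValueError(f"{self.name}: fraction_unbound must lie in (0, 1]")
        if self.molecular_weight <= 0:
            raise ValueError(f"{self.name}: molecular_weight must be > 0")
        if self.dose_per_kg is not None and self.dose_per_kg < 0:
            raise ValueError(f"{self.name}: dose must be >= 0")
        if self.zonated and not (self.pericentral_fraction and 0 < self.pericentral_fraction < 1):
            raise ValueError(f"{self.name}: zonated model needs pericentral_fraction in (0,1)")
        by_via: dict[str | None, float] = {}
        for link in self.metabolite_links:
            by_via[link.via] = by_via.get(link.via, 0.0) + link.fraction_of_clearance
        for via, total in by_via.items():
            if total > 1 + 1e-12:
                raise ValueError(
                    f"{self.name}: metabolite fractions via {via!r} sum to {total} > 1"
                )

    @property
    def is_metabolite(self) -> bool:
        return self.dose_per_kg is None

    def clearance(self, label: str) -> ClearanceSpec:
        for c in self.clearances:
            if c.label == label:
                return c
        raise KeyError(f"{self.name}: no clearance labelled {label!r}")

    def with_liver_damage(self, damage: float) -> "CompoundModel":
        """Scale the abundance of every hepatic process by ``(1 - damage)``.

        Renal processes are untouched: the toxin acts on the liver lobule.
        """
        if not 0 <= damage <= 1:
            raise ValueError("damage must lie in [0, 1]")
        scaled = tuple(
            replace(c, abundance=c.abundance * (1.0 - damage)) if c.hepatic else c
            for c in self.clearances
        )
        return replace(self, clearances=scaled)


def dose_in_amount(compound: CompoundModel, body_weight: float) -> float:
    """Molar iv-bolus dose in umol for a mouse of ``body_weight`` kg."""
    if body_weight <= 0:
        raise ValueError("body_weight must be > 0 kg")
    if compound.dose_per_kg is None:
        raise ValueError(f"{compound.name} is a metabolite and carries no dose")
    # mg / (g/mol) = mmol -> umol
    return compound.dose_per_kg * body_weight / compound.molecular_weight * 1000.0


# ---------------------------------------------------------------------------
# Serialization


def _clearance_to_dict(c: ClearanceSpec) -> dict:
    d: dict = {"label": c.label, "kind": c.kind, "site": c.site}
    if c.kind in LINEAR_KINDS:
        d["rate_per_min"] = c.rate
    else:
        d["k_cat_per_min"] = c.k_cat
        d["k_m_umol_per_L"] = c.k_m
    if c.abundance != 1.0:
        d["abundance"] = c.abundance
    return d


def serialize_compounds(compounds: Sequence[CompoundModel]) -> str:
    """Render compound models to the YAML compound-file dialect."""
    out: dict[str, dict] = {}
    for m in compounds:
        entry: dict = {
            "fraction_unbound": m.fraction_unbound,
            "log_lipophilicity": m.log_lipophilicity,
            "molecular_weight_g_per_mol": m.molecular_weight,
            "zonated": m.zonated,
            "clearances": [_clearance_to_dict(c) for c in m.clearances],
        }
        if m.dose_per_kg is not None:
            entry["dose_mg_per_kg"] = m.dose_per_kg
        if m.pericentral_fraction is not None:
            entry["pericentral_fraction"] = m.pericentral_fraction
        if m.metabolite_links:
            entry["metabolite_links"] = [
                {
                    "metabolite": l.metabolite,
                    "via": l.via,
                    "fraction_of_clearance": l.fraction_of_clearance,
                    "tracked": l.tracked,
                }
                for l in m.metabolite_links
            ]
        out[m.name] = entry
    return yaml.safe_dump(out, sort_keys=False)


def _parse_compound(name: str, entry: Mapping) -> CompoundModel:
    clearances = []
    for c in entry.get("clearances", []):
        clearances.append(
            ClearanceSpec(
                label=c["label"],
                kind=c["kind"],
                site=c["site"],
                rate=c.get("rate_per_min"),
                k_cat=c.get("k_cat_per_min"),
                k_m=c.get("k_m_umol_per_L"),
                abundance=float(c.get("abundance", 1.0)),
            )
        )
    links = tuple(
        MetaboliteLink(
            parent=name,
            metabolite=l["metabolite"],
            fraction_of_clearance=float(l["fraction_of_clearance"]),
            tracked=bool(l.get("tracked", True)),
            via=l.get("via"),
        )
        for l in entry.get("metabolite_links", [])
    )
    return CompoundModel(
        name=name,
        dose_per_kg=entry.get("dose_mg_per_kg"),
        fraction_unbound=float(entry["fraction_unbound"]),
        log_lipophilicity=float(entry["log_lipophilicity"]),
        molecular_weight=float(entry["molecular_weight_g_per_mol"]),
        clearances=tuple(clearances),
        metabolite_links=links,
        zonated=bool(entry.get("zonated", False)),
        pericentral_fraction=entry.get("pericentral_fraction"),
    )


def load_compounds(source: str | Path | None = None) -> list[CompoundModel]:
    """Read compound models from a compound file (YAML text or path)."""
    if source is None:
        text = resources.files("zonpbpk.data").joinpath("cocktail_compounds.yaml").read_text()
    elif isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and Path(source).exists()):
        text = Path(source).read_text()
    else:
        text = source
    raw = yaml.safe_load(text)
    return [_parse_compound(name, entry) for name, entry in raw.items()]


# ---------------------------------------------------------------------------
# Effective (plasma-referenced) clearances and excretion calibration


def _liver_cell_volume(physiology: MousePhysiology) -> float:
    return physiology.organ("liver").sub_volumes["cellular"]


def _well_stirred_cl(q: float, clu: float) -> float:
    """Plasma clearance of a well-stirred organ: Q * E with E = CLu/(Q+CLu)."""
    return q * clu / (q + clu)


def effective_plasma_clearances(
    compound: CompoundModel, physiology: MousePhysiology
) -> dict[str, float]:
    """First-order plasma clearances (L/min) of each elimination route.

    Michaelis-Menten branches are linearized at their first-order limit
    (Vmax/Km), which is the regime relevant for clearance bookkeeping.
    Hepatic routes are combined through the series two-zone (or single
    well-stirred) extraction and the total is split across hepatic processes
    in proportion to their intrinsic clearances.
    """
    fu = compound.fraction_unbound
    v_cell_liver = _liver_cell_volume(physiology)
    q_liver = physiology.organ("liver").blood_flow
    kidney = physiology.organ("kidney")

    hepatic_int: dict[str, tuple[str, float]] = {}  # label -> (zone, CLint_u)
    renal_int: dict[str, float] = {}
    for c in compound.clearances:
        if c.kind == "michaelis_menten_hepatic":
            clint = c.abundance * c.k_cat / c.k_m * v_cell_liver  # Vmax/Km, Eref=1 umol/L
            hepatic_int[c.label] = ("pericentral" if c.site == "liver_pericentral" else "whole", clint * fu)
        elif c.kind in ("linear_hepatic", "linear_biliary"):
            clint = c.abundance * c.rate * v_cell_liver
            hepatic_int[c.label] = ("pericentral" if c.site == "liver_pericentral" else "whole", clint * fu)
        elif c.kind == "linear_renal":
            renal_int[c.label] = c.abundance * c.rate * kidney.sub_volumes["cellular"] * fu

    out: dict[str, float] = {}
    total_hep_int = sum(v for _, v in hepatic_int.values())
    if total_hep_int > 0:
        if compound.zonated:
            f_pc = compound.pericentral_fraction
            clu_pp = sum(v * (1 - f_pc) for zone, v in hepatic_int.values() if zone == "whole")
            clu_pc = sum(
                v if zone == "pericentral" else v * f_pc for zone, v in hepatic_int.values()
            )
            e_pp = clu_pp / (q_liver + clu_pp)
            e_pc = clu_pc / (q_liver + clu_pc)
            cl_hep = q_liver * (1 - (1 - e_pp) * (1 - e_pc))
        else:
            cl_hep = _well_stirred_cl(q_liver, total_hep_int)
        for label, (_, clint) in hepatic_int.items():
            out[label] = cl_hep * clint / total_hep_int
    for label, clint in renal_int.items():
        out[label] = _well_stirred_cl(kidney.blood_flow, clint)
    return out


def _renal_rate_for_share(
    compound: CompoundModel, physiology: MousePhysiology, urinary_share: float
) -> float:
    """Specific renal clearance giving ``urinary_share`` of total elimination."""
    eff = effective_plasma_clearances(compound, physiology)
    cl_nonrenal = sum(
        v for k, v in eff.items() if compound.clearance(k).kind != "linear_renal"
    )
    cl_renal_target = urinary_share / (1.0 - urinary_share) * cl_nonrenal
    kidney = physiology.organ("kidney")
    q = kidney.blood_flow
    if cl_renal_target >= q:
        raise ValueError(
            f"{compound.name}: requested renal clearance {cl_renal_target:.2e} L/min "
            f"exceeds renal plasma flow {q:.2e} L/min"
        )
    clu = q * cl_renal_target / (q - cl_renal_target)
    return clu / (compound.fraction_unbound * kidney.sub_volumes["cellular"])


def calibrate_excretion(
    compounds: Sequence[CompoundModel],
    physiology: MousePhysiology | None = None,
    targets: Mapping[str, float] = EXCRETION_TARGETS,
) -> list[CompoundModel]:
    """Re-derive renal specific clearances so urinary shares hit their targets.

    Hepatic (Table-value) clearances are kept fixed.  For pravastatin the
    biliary intrinsic clearance is additionally set so the metabolic, fecal
    and urinary routes split 30:23:41, since the raw literature renal rate is
    far above the renal plasma-flow limit and therefore unidentifiable.
    Because organ volumes and flows scale together with body weight, the
    calibrated shares are body-weight invariant.
    """
    physiology = physiology or build_default_physiology()
    out = []
    for m in compounds:
        if m.name not in targets:
            out.append(m)
            continue
        if m.name == "pravastatin":
            met = m.clearance("hepatic_metabolic")
            bil_rate = met.rate * _PRAVASTATIN_SHARES["biliary"] / _PRAVASTATIN_SHARES["metabolic"]
            clearances = tuple(
                replace(c, rate=bil_rate) if c.kind == "linear_biliary" else c
                for c in m.clearances
            )
            m = replace(m, clearances=clearances)
        rate = _renal_rate_for_share(
            replace(
                m,
                clearances=tuple(c for c in m.clearances if c.kind != "linear_renal"),
            ),
            physiology,
            targets[m.name],
        )
        clearances = tuple(
            replace(c, rate=rate) if c.kind == "linear_renal" else c for c in m.clearances
        )
        out.append(replace(m, clearances=clearances))
    return out


def builtin_cocktail(
    physiology: MousePhysiology | None = None, calibrate: bool = True
) -> list[CompoundModel]:
    """The 9 built-in models: 6 parent drugs + 3 tracked metabolites.

    With ``calibrate=True`` (default) the renal clearances are adjusted so
    the unchanged-urine fractions match the observed values; hepatic
    clearances always carry the published rates verbatim.
    """
    models = load_compounds(None)
    if calibrate:
        models = calibrate_excretion(models, physiology)
    return models
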