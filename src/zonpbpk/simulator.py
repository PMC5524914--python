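"""Whole-body ODE assembly and integration.

The body is a closed flow network: venous pool -> lung -> arterial pool ->
organs -> venous pool, with the gut and spleen draining through the portal
vein into the liver, which also receives a hepatic-artery share and drains
into the hepatic vein.  Every organ is perfusion-limited and well-stirred:
its outflow plasma concentration is ``amount / V_eff`` where the effective
volume ``V_eff = V_vascular + (V_interstitial + V_cellular) * Kp`` lumps the
instantaneously equilibrated sub-compartments (blood:plasma ratio 1 by
default).

Parents and tracked metabolites are solved simultaneously; metabolites are
formed in the liver cellular space of the producing zone.  Cumulative urine,
bile and untracked-metabolite sinks close the mass balance exactly.

Linear families are integrated exactly with a matrix-exponential propagator;
Michaelis-Menten families fall back to a stiff-capable ODE solver
(LSODA, rtol 1e-8 / atol 1e-10 umol).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .compounds import CompoundModel, compute_partition_coefficients
from .physiology import MousePhysiology, split_liver

__all__ = [
    "DoseEvent",
    "SimulationResult",
    "SimulationError",
    "simulate",
    "sample_site",
    "compute_auc",
]

SITES = ("right_heart", "portal_vein", "hepatic_vein")

_DIRECT_ORGANS = ("heart", "brain", "muscle", "adipose", "skin", "bone", "kidney")
_SINKS = ("urine", "bile", "untracked")


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class DoseEvent:
    compound: str
    time: float  # min
    amount: float  # umol
    route: str = "iv_bolus"

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise ValueError("dose amount must be >= 0")
        if self.route != "iv_bolus":
            raise ValueError(f"unsupported route {self.route!r}; only iv_bolus is modelled")
        if self.time < 0:
            raise ValueError("dose time must be >= 0")


@dataclass
class _Species:
    model: CompoundModel
    comps: list[str]
    offset: int
    veff: np.ndarray

    def idx(self, comp: str) -> int:
        return self.offset + self.comps.index(comp)


@dataclass
class SimulationResult:
    """Time-resolved amounts per compartment and compound, plus sinks."""

    times: np.ndarray  # min
    species: tuple[str, ...]
    compartments: dict[str, tuple[str, ...]]
    amounts: dict[str, np.ndarray]  # species -> (n_comp, n_times) umol
    effective_volumes: dict[str, dict[str, float]]  # species -> comp -> L
    physiology: MousePhysiology
    models: dict[str, CompoundModel]
    doses: tuple[DoseEvent, ...]

    def amount(self, species: str, compartment: str) -> np.ndarray:
        comp_list = self.compartments[species]
        return self.amounts[species][comp_list.index(compartment)]

    def concentration(self, species: str, compartment: str) -> np.ndarray:
        """Outflow plasma concentration (umol/L) of one compartment."""
        return self.amount(species, compartment) / self.effective_volumes[species][compartment]

    def families(self) -> list[set[str]]:
        """Connected parent+tracked-metabolite groups among the simulated species."""
        groups = {name: {name} for name in self.species}
        for name, model in self.models.items():
            for link in model.metabolite_links:
                if link.tracked and link.metabolite in groups:
                    merged = groups[name] | groups[link.metabolite]
                    for member in merged:
                        groups[member] = merged
        seen, out = set(), []
        for g in groups.values():
            key = frozenset(g)
            if key not in seen:
                seen.add(key)
                out.append(set(g))
        return out

    def mass_balance_error(self) -> float:
        """Max relative deviation of (body + sinks) from the dosed amount."""
        worst = 0.0
        for family in self.families():
            family_doses = [d for d in self.doses if d.compound in family]
            dosed_total = sum(d.amount for d in family_doses)
            if dosed_total <= 0:
                continue
            expected = np.zeros_like(self.times)
            for d in family_doses:
                expected[self.times >= d.time - 1e-12] += d.amount
            total = np.zeros_like(self.times)
            for name in family:
                total = total + self.amounts[name].sum(axis=0)
            worst = max(worst, float(np.max(np.abs(total - expected)) / dosed_total))
        return worst

    def to_tidy(self) -> pd.DataFrame:
        rows = []
        for name in self.species:
            for j, comp in enumerate(self.compartments[name]):
                conc = (
                    self.amounts[name][j] / self.effective_volumes[name][comp]
                    if comp not in _SINKS
                    else np.full_like(self.times, np.nan)
                )
                rows.append(
                    pd.DataFrame(
                        {
                            "time_min": self.times,
                            "compound": name,
                            "site_or_compartment": comp,
                            "concentration_umol_per_L": conc,
                            "amount_umol": self.amounts[name][j],
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)


def _species_layout(physiology: MousePhysiology, models: Sequence[CompoundModel]) -> list[_Species]:
    layouts: list[_Species] = []
    offset = 0
    for m in models:
        comps = ["venous_blood", "lung", "arterial_blood", *_DIRECT_ORGANS, "gut", "spleen"]
        comps += ["liver_periportal", "liver_pericentral"] if m.zonated else ["liver"]
        comps += list(_SINKS)
        kps = compute_partition_coefficients(m, physiology)
        veff = np.ones(len(comps))
        for j, comp in enumerate(comps):
            if comp in _SINKS:
                veff[j] = 1.0  # sinks store amounts; volume unused
                continue
            if comp in ("liver_periportal", "liver_pericentral"):
                zoned = split_liver(physiology, m.pericentral_fraction)
                organ = zoned.periportal if comp == "liver_periportal" else zoned.pericentral
                kp = kps["liver"]
            else:
                organ = physiology.organ(comp)
                kp = kps[comp]
            veff[j] = organ.vascular_volume + (
                organ.sub_volumes["interstitial"] + organ.sub_volumes["cellular"]
            ) * kp
        layouts.append(_Species(model=m, comps=comps, offset=offset, veff=veff))
        offset += len(comps)
    return layouts


def _liver_zone_split(sp: _Species, physiology: MousePhysiology, site: str) -> list[tuple[str, float]]:
    """(zone compartment, share of whole-liver cellular volume) for a hepatic process."""
    if not sp.model.zonated:
        return [("liver", 1.0)]
    f_pc = sp.model.pericentral_fraction
    if site == "liver_pericentral":
        return [("liver_pericentral", 1.0)]
    # homogeneous process distributed across both zones by cellular volume
    return [("liver_periportal", 1.0 - f_pc), ("liver_pericentral", f_pc)]


def _build_system(physiology: MousePhysiology, models: Sequence[CompoundModel]):
    layouts = _species_layout(physiology, models)
    by_name = {sp.model.name: sp for sp in layouts}
    n = sum(len(sp.comps) for sp in layouts)
    M = np.zeros((n, n))
    co = physiology.cardiac_output
    q_liver = physiology.organ("liver").blood_flow
    q_ha = physiology.hepatic_artery_flow
    v_cell_liver = physiology.organ("liver").sub_volumes["cellular"]
    v_cell_kidney = physiology.organ("kidney").sub_volumes["cellular"]
    mm_terms = []  # nonlinear Michaelis-Menten fluxes

    def k_out(sp: _Species, comp: str) -> float:
        return 1.0 / sp.veff[sp.comps.index(comp)]

    for sp in layouts:
        m = sp.model
        i = sp.idx
        # --- distribution network -------------------------------------------------
        M[i("lung"), i("venous_blood")] += co * k_out(sp, "venous_blood")
        M[i("venous_blood"), i("venous_blood")] -= co * k_out(sp, "venous_blood")
        M[i("arterial_blood"), i("lung")] += co * k_out(sp, "lung")
        M[i("lung"), i("lung")] -= co * k_out(sp, "lung")
        art = i("arterial_blood")
        for organ_name in _DIRECT_ORGANS:
            q = physiology.organ(organ_name).blood_flow
            M[i(organ_name), art] += q * k_out(sp, "arterial_blood")
            M[art, art] -= q * k_out(sp, "arterial_blood")
            M[i("venous_blood"), i(organ_name)] += q * k_out(sp, organ_name)
            M[i(organ_name), i(organ_name)] -= q * k_out(sp, organ_name)
        liver_in = i("liver_periportal") if m.zonated else i("liver")
        for organ_name in ("gut", "spleen"):
            q = physiology.organ(organ_name).blood_flow
            M[i(organ_name), art] += q * k_out(sp, "arterial_blood")
            M[art, art] -= q * k_out(sp, "arterial_blood")
            M[liver_in, i(organ_name)] += q * k_out(sp, organ_name)
            M[i(organ_name), i(organ_name)] -= q * k_out(sp, organ_name)
        M[liver_in, art] += q_ha * k_out(sp, "arterial_blood")
        M[art, art] -= q_ha * k_out(sp, "arterial_blood")
        if m.zonated:
            pp, pc = i("liver_periportal"), i("liver_pericentral")
            M[pc, pp] += q_liver * k_out(sp, "liver_periportal")
            M[pp, pp] -= q_liver * k_out(sp, "liver_periportal")
            M[i("venous_blood"), pc] += q_liver * k_out(sp, "liver_pericentral")
            M[pc, pc] -= q_liver * k_out(sp, "liver_pericentral")
        else:
            M[i("venous_blood"), i("liver")] += q_liver * k_out(sp, "liver")
            M[i("liver"), i("liver")] -= q_liver * k_out(sp, "liver")

        # --- elimination and metabolite formation --------------------------------
        links = [l for l in m.metabolite_links if l.tracked and l.metabolite in by_name]

        def destinations(label: str, sink: str) -> list[tuple[str | None, str, float]]:
            """[(metabolite species or None for sink, dst comp or sink, fraction)]"""
            out: list[tuple[str | None, str, float]] = []
            routed = 0.0
            for l in links:
                if l.via is not None and l.via != label:
                    continue
                out.append((l.metabolite, "", l.fraction_of_clearance))
                routed += l.fraction_of_clearance
            out.append((None, sink, max(0.0, 1.0 - routed)))
            return out

        for c in m.clearances:
            if c.kind == "linear_renal":
                clint_u = c.abundance * c.rate * v_cell_kidney * m.fraction_unbound
                k = clint_u * k_out(sp, "kidney")
                M[i("kidney"), i("kidney")] -= k
                M[i("urine"), i("kidney")] += k
                continue
            sink = "bile" if c.kind == "linear_biliary" else "untracked"
            zone_shares = _liver_zone_split(sp, physiology, c.site)
            for zone_comp, share in zone_shares:
                src = i(zone_comp)
                if c.kind == "michaelis_menten_hepatic":
                    vmax = c.abundance * c.k_cat * 1.0 * v_cell_liver * share  # Eref = 1 umol/L
                    dsts = []
                    for met, sink_name, frac in destinations(c.label, sink):
                        if met is None:
                            dsts.append((i(sink_name), frac))
                        else:
                            msp = by_name[met]
                            dst_comp = zone_comp if zone_comp in msp.comps else "liver"
                            dsts.append((msp.idx(dst_comp), frac))
                    mm_terms.append(
                        {
                            "src": src,
                            "k_conc": m.fraction_unbound * k_out(sp, zone_comp),
                            "vmax": vmax,
                            "km": c.k_m,
                            "dsts": dsts,
                        }
                    )
                    continue
                clint_u = c.abundance * c.rate * v_cell_liver * share * m.fraction_unbound
                k = clint_u * k_out(sp, zone_comp)
                M[src, src] -= k
                for met, sink_name, frac in destinations(c.label, sink):
                    if met is None:
                        M[i(sink_name), src] += frac * k
                    else:
                        msp = by_name[met]
                        dst_comp = zone_comp if zone_comp in msp.comps else "liver"
                        M[msp.idx(dst_comp), src] += frac * k
    return layouts, M, mm_terms


def _rhs_factory(M: np.ndarray, mm_terms: list[dict]):
    if not mm_terms:
        return lambda t, y: M @ y

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        dy = M @ y
        for term in mm_terms:
            cu = term["k_conc"] * max(y[term["src"]], 0.0)
            rate = term["vmax"] * cu / (term["km"] + cu)
            dy[term["src"]] -= rate
            for dst, frac in term["dsts"]:
                dy[dst] += frac * rate
        return dy

    return rhs


def simulate(
    physiology: MousePhysiology,
    compounds: Sequence[CompoundModel],
    doses: Sequence[DoseEvent],
    horizon: float = 120.0,
    grid: float = 0.5,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> SimulationResult:
    """Integrate the whole-body system and return amounts on a fixed grid.

    ``horizon`` and ``grid`` are in minutes.  Intravenous boluses are applied
    as instantaneous additions to the venous blood pool at their dose times.
    """
    names = [m.name for m in compounds]
    if len(names) != len(set(names)):
        raise ValueError("duplicate compound names")
    for d in doses:
        if d.compound not in names:
            raise ValueError(f"dose for unknown compound {d.compound!r}")
        if d.time > horizon:
            raise ValueError("horizon must cover every dose time")
    layouts, M, mm_terms = _build_system(physiology, compounds)
    n = M.shape[0]
    t_out = np.arange(0.0, horizon + grid * 1e-9, grid)
    if t_out[-1] < horizon:
        t_out = np.append(t_out, horizon)
    y = np.zeros(n)
    by_name = {sp.model.name: sp for sp in layouts}
    sol = np.zeros((n, len(t_out)))

    event_times = sorted({d.time for d in doses})
    rhs = _rhs_factory(M, mm_terms)
    linear = not mm_terms
    prop_cache: dict[float, np.ndarray] = {}

    def propagate(y0: np.ndarray, t0: float, t1: float) -> np.ndarray:
        if t1 == t0:
            return y0
        dt = t1 - t0
        key = round(dt, 12)
        if key not in prop_cache:
            prop_cache[key] = expm(M * dt)
        return prop_cache[key] @ y0

    def apply_doses(t: float) -> None:
        for d in doses:
            if d.time == t:
                y[by_name[d.compound].idx("venous_blood")] += d.amount

    # integrate segment-wise between bolus events
    apply_doses(0.0)
    segment_bounds = sorted({0.0, horizon, *event_times})
    out_pos = 0
    if t_out[0] == 0.0:
        sol[:, 0] = y
        out_pos = 1
    for seg_start, seg_end in zip(segment_bounds[:-1], segment_bounds[1:]):
        mask = (t_out > seg_start + 1e-12) & (t_out <= seg_end + 1e-12)
        seg_targets = t_out[mask]
        if linear:
            state_t = seg_start
            cols = np.empty((n, len(seg_targets)))
            for j, t_next in enumerate(seg_targets):
                y = propagate(y, state_t, t_next)
                state_t = t_next
                cols[:, j] = y
            if seg_targets.size == 0 or seg_targets[-1] < seg_end - 1e-12:
                y = propagate(y, state_t, seg_end)
        else:
            eval_times = seg_targets if seg_targets.size else np.asarray([seg_end])
            res = solve_ivp(
                rhs,
                (seg_start, seg_end),
                y,
                method="LSODA",
                t_eval=np.unique(np.append(eval_times, seg_end)),
                rtol=rtol,
                atol=atol,
            )
            if not res.success:
                raise SimulationError(
                    f"solver failed for compounds {names} near t={seg_start:.3f} min: {res.message}"
                )
            cols = res.y[:, : len(seg_targets)]
            y = res.y[:, -1]
        if cols.size and cols.min() < -1e-6 or y.min() < -1e-6:
            raise SimulationError(
                f"negative amount beyond tolerance in segment ending t={seg_end:.3f} min"
            )
        y = np.maximum(y, 0.0)
        sol[:, out_pos : out_pos + len(seg_targets)] = np.maximum(cols, 0.0)
        out_pos += len(seg_targets)
        if seg_end in event_times:
            apply_doses(seg_end)
            # the grid value at a dose time reports the post-bolus state
            if seg_targets.size and abs(seg_targets[-1] - seg_end) < 1e-12:
                sol[:, out_pos - 1] = y

    amounts = {}
    compartments = {}
    veffs = {}
    for sp in layouts:
        block = sol[sp.offset : sp.offset + len(sp.comps), :]
        amounts[sp.model.name] = block
        compartments[sp.model.name] = tuple(sp.comps)
        veffs[sp.model.name] = dict(zip(sp.comps, sp.veff))
    return SimulationResult(
        times=t_out,
        species=tuple(names),
        compartments=compartments,
        amounts=amounts,
        effective_volumes=veffs,
        physiology=physiology,
        models={m.name: m for m in compounds},
        doses=tuple(doses),
    )


def sample_site(result: SimulationResult, site: str, compound: str) -> np.ndarray:
    """Plasma concentration time series (umol/L) at one experimental site.

    ``right_heart`` maps to the venous blood pool, ``portal_vein`` to the
    flow-weighted gut/spleen outflow entering the liver, and ``hepatic_vein``
    to the liver outflow downstream of the pericentral zone.
    """
    if site not in SITES:
        raise ValueError(f"unknown site {site!r}; valid sites: {SITES}")
    if compound not in result.species:
        raise KeyError(f"compound {compound!r} not simulated")
    if site == "right_heart":
        return result.concentration(compound, "venous_blood")
    if site == "portal_vein":
        q_gut = result.physiology.organ("gut").blood_flow
        q_spl = result.physiology.organ("spleen").blood_flow
        c = (
            q_gut * result.concentration(compound, "gut")
            + q_spl * result.concentration(compound, "spleen")
        ) / (q_gut + q_spl)
        return c
    out_comp = (
        "liver_pericentral" if result.models[compound].zonated else "liver"
    )
    return result.concentration(compound, out_comp)


def compute_auc(times: Sequence[float], concentrations: Sequence[float]) -> float:
    """Linear trapezoidal area under the curve (umol*min/L)."""
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if t.shape != c.shape or t.ndim != 1:
        raise ValueError("times and concentrations must be 1-D and equally long")
    if len(t) < 2:
        raise ValueError("need at least two points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(c < 0):
        raise ValueError("concentrations must be >= 0")
    return float(np.trapezoid(c, t))
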