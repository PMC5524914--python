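"""Build the cocktail compound models and tabulate their parameters.

Writes the calibrated compound table (doses, binding, clearance processes)
and the organ-plasma partition coefficients every simulation uses.
"""

from pathlib import Path

import pandas as pd

from zonpbpk.compounds import builtin_cocktail, compute_partition_coefficients, dose_in_amount
from zonpbpk.physiology import build_default_physiology

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

phys = build_default_physiology()
models = builtin_cocktail(phys)

rows = []
for m in models:
    for c in m.clearances:
        rows.append(
            {
                "compound": m.name,
                "dose_mg_per_kg": m.dose_per_kg,
                "dose_umol_25g": dose_in_amount(m, 0.025) if m.dose_per_kg else None,
                "fraction_unbound": m.fraction_unbound,
                "logP": m.log_lipophilicity,
                "MW_g_per_mol": m.molecular_weight,
                "zonated": m.zonated,
                "pericentral_fraction": m.pericentral_fraction,
                "process": c.label,
                "kind": c.kind,
                "site": c.site,
                "rate_per_min": c.rate,
                "k_cat_per_min": c.k_cat,
                "K_m_umol_per_L": c.k_m,
            }
        )
table = pd.DataFrame(rows)
table.to_csv(OUT / "compound_models.csv", index=False)

kp_rows = []
for m in models:
    kps = compute_partition_coefficients(m, phys)
    for organ, kp in kps.items():
        kp_rows.append({"compound": m.name, "organ": organ, "Kp": kp})
pd.DataFrame(kp_rows).to_csv(OUT / "partition_coefficients.csv", index=False)

print(f"{len(models)} compound models ({sum(m.dose_per_kg is not None for m in models)} "
      f"parents, {sum(m.dose_per_kg is None for m in models)} tracked metabolites)")
print(table[["compound", "process", "kind", "rate_per_min"]].to_string(index=False))
print(f"\nwrote {OUT/'compound_models.csv'} and {OUT/'partition_coefficients.csv'}")
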