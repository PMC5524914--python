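"""Compare functional and tissue damage and classify the clearance loss.

Combines the recovered functional damages (04) with the quantified
expression fractions and dead-area fraction (05) into the per-enzyme damage
table, classifying each drug's loss of hepatic clearance capacity as
compensated, uncompensated or aggravated.
"""

from pathlib import Path

import pandas as pd

from zonpbpk.damage import classify_loss, compute_tissue_damage

OUT = Path(__file__).resolve().parents[1] / "results"

ENZYME_OF = {"caffeine": "CYP1A", "midazolam": "CYP3A", "torsemide": "CYP2C"}
TOLERANCE = 0.05

functional = pd.read_csv(OUT / "functional_damage.csv").set_index("drug")
expression = pd.read_csv(OUT / "expression_quant.csv").set_index("enzyme")
d = float(pd.read_csv(OUT / "dead_area.csv")["dead_fraction"].iloc[0])

rows = []
for drug, enzyme in ENZYME_OF.items():
    p_e = float(expression.loc[enzyme, "p_e"])
    f_damage = float(functional.loc[drug, "recovered_functional_damage"])
    t_damage = compute_tissue_damage(p_e, d)
    rows.append(
        {
            "drug": drug,
            "enzyme": enzyme,
            "pericentral_expression": round(p_e, 3),
            "dead_fraction": round(d, 3),
            "functional_damage": round(f_damage, 3),
            "tissue_damage": round(t_damage, 3),
            "classification": classify_loss(f_damage, t_damage, TOLERANCE),
        }
    )
# CYP2D row: the lesion exceeds the expressing area, tissue damage clamps to 1;
# no functional value is attached to it (codeine's CYP2D-metabolized share is unknown)
p_e_2d = float(expression.loc["CYP2D", "p_e"])
rows.append(
    {
        "drug": "codeine",
        "enzyme": "CYP2D",
        "pericentral_expression": round(p_e_2d, 3),
        "dead_fraction": round(d, 3),
        "functional_damage": None,
        "tissue_damage": round(compute_tissue_damage(p_e_2d, d), 3),
        "classification": "indeterminate",
    }
)

report = pd.DataFrame(rows)
report.to_csv(OUT / "damage_report.csv", index=False)
print(report.to_string(index=False))
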