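"""Identify the healthy hepatic clearance from synthetic three-site PK.

Generates a healthy caffeine/paraxanthine dataset at the study design
(3 sites x 5 times x 3 animals, 20% CV), fits the CYP1A specific clearance
by log-scale least squares with multi-starts, and reports the estimate and
the per-site Pearson / concordance diagnostics of the fitted model.
"""

from pathlib import Path

import pandas as pd

from zonpbpk.compounds import builtin_cocktail
from zonpbpk.fitting import FitParameter, FitProblem, fit
from zonpbpk.physiology import build_default_physiology
from zonpbpk.synthetic import PKGeneratorSpec, generate_pk_dataset

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)
SEED = 1

phys = build_default_physiology()
by = {m.name: m for m in builtin_cocktail(phys)}
family = [by["caffeine"], by["paraxanthine"]]
true_rate = by["caffeine"].clearance("CYP1A").rate

dataset = generate_pk_dataset(
    PKGeneratorSpec(models=family, physiology=phys, cv=0.2, seed=SEED)
)
dataset.to_csv(OUT / "pk_healthy_caffeine.csv")

problem = FitProblem(
    parameters=[
        FitParameter(name="CL_CYP1A", lower=0.01, upper=5.0, initial=0.2,
                     target=("caffeine", "CYP1A", "rate"))
    ],
    dataset=dataset,
    models=family,
)
result = fit(problem, phys, n_starts=4, seed=SEED)

estimate = result.estimates["CL_CYP1A"]
print(f"true CYP1A specific clearance : {true_rate:.4f} 1/min")
print(f"fitted                        : {estimate:.4f} 1/min "
      f"({100 * (estimate / true_rate - 1):+.1f}%)")
print(f"objective (log-SSE)           : {result.objective:.4f}")
print("\nper-site diagnostics of the fitted model:")
print(result.diagnostics.round(3).to_string())
result.diagnostics.to_csv(OUT / "fit_diagnostics.csv")
pd.Series(result.estimates).to_csv(OUT / "fit_estimates.csv", header=["value"])
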