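# zonpbpk

Whole-body mouse PBPK modelling with a zonated liver, built to ask a precise
question about toxic liver damage: **when a hepatotoxin kills part of the
liver lobule, is the loss of drug-clearance capacity explained by the dead
tissue alone, or does the surviving tissue lose function too?**

Carbon tetrachloride destroys the *pericentral* zone of the lobule — exactly
where the cytochrome P450 enzymes live. The package quantifies both sides of
the comparison:

* **Functional damage** `F = 1 − e_d/e_h`: the relative reduction in hepatic
  enzyme/transporter abundance required to make a whole-body PBPK model
  reproduce the plasma pharmacokinetics of intoxicated animals.
* **Tissue damage** `T = 1 − (p_e − d)/p_e` (clamped to [0, 1]): the loss of
  enzyme-expressing lobule area implied by the dead-cell fraction `d` from
  H&E sections, given the healthy expressed-area fraction `p_e` from
  immunostaining.

`F < T` means the surviving tissue compensates, `F ≈ T` an uncompensated
loss, and `F > T` an **aggravated** loss — damage beyond the dead area.

## What is in the box

| module | role |
| --- | --- |
| `zonpbpk.physiology` | mouse organ volumes/flows from a versioned table; the liver split into series periportal → pericentral zones by the stained fraction |
| `zonpbpk.compounds` | the six-drug phenotyping cocktail (caffeine, midazolam, torsemide, codeine, talinolol, pravastatin) plus three tracked metabolites, with published clearances and Michaelis–Menten branches |
| `zonpbpk.partition` | organ–plasma partition coefficients from tissue composition (Poulin–Theil) |
| `zonpbpk.simulator` | the whole-body ODE system; exact matrix-exponential propagation for linear families, stiff LSODA otherwise; concentrations at the right heart, portal vein and hepatic vein; trapezoidal AUCs |
| `zonpbpk.fitting` | log-scale least-squares objective `E = Σ log(s(tᵢ)/x̄ᵢ)²`, bounded multi-start fits, the functional-damage scan, Lin's concordance |
| `zonpbpk.image_quant` | three-class threshold labelling of lobule sections and the expressed/dead area statistics |
| `zonpbpk.damage` | the damage formulas, AUC change tables and the compensated/uncompensated/aggravated call |
| `zonpbpk.synthetic` | generators for the full study design: three-site PK with log-normal noise and destructive sampling, and lobule images with exact ground truth |
| `zonpbpk.pipeline` | one-call reproducible pipeline with config hashing and provenance |

The numbered scripts under `analysis/` run the study end to end
(model building → healthy simulation → fit → damage scan → image
quantification → damage report) and write their tables to `results/`.

## Worked example

```python
import numpy as np
from zonpbpk import (
    build_default_physiology, builtin_cocktail,
    PKGeneratorSpec, generate_pk_dataset, scan_functional_damage,
    StainGeneratorSpec, generate_stain_images,
    classify_pixels, quantify_expression, quantify_dead_area,
    compute_tissue_damage, classify_loss,
)

phys = build_default_physiology()          # 25 g mouse
by = {m.name: m for m in builtin_cocktail(phys)}
family = [by["torsemide"], by["hydroxytorsemide"]]

# intoxicated three-site dataset with a known 92% CYP2C reduction
tox = generate_pk_dataset(
    PKGeneratorSpec(models=family, physiology=phys, cv=0.2, seed=42), damage=0.92
)
scan = scan_functional_damage(phys, family, tox, grid=np.arange(0, 1.0001, 0.02))

imgs, _ = generate_stain_images(StainGeneratorSpec(0.48, seed=43), 3)
p_e = quantify_expression([classify_pixels(i) for i in imgs], "CYP2C").p_e
he, _ = generate_stain_images(StainGeneratorSpec(0.36, mode="he", seed=44), 10)
d = quantify_dead_area([classify_pixels(i) for i in he])

F, T = scan.fd_star, compute_tissue_damage(p_e, d)
print(f"functional damage {F:.2f}, tissue damage {T:.2f}:",
      classify_loss(F, T, tolerance=0.05))
```

prints

```
functional damage 0.92, tissue damage 0.75: aggravated
```

i.e. the 92% loss of CYP2C activity recovered from the plasma curves far
exceeds the 75% loss of CYP2C-expressing area implied by a 36% pericentral
lesion over a 48% expressing fraction — an aggravated loss of clearance
capacity. Running the full `analysis/` chain produces the same call for all
three zonated drug families and the per-enzyme damage table in
`results/damage_report.csv`.

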