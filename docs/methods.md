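# Methods

## Whole-body model

The mouse is represented by a closed flow network of perfusion-limited,
well-stirred organs: venous pool → lung → arterial pool → {heart, brain,
muscle, adipose, skin, bone, kidney, gut, spleen, liver} → venous pool. Gut
and spleen drain through the portal vein into the liver, which also receives
a hepatic-artery share of arterial blood; the inflow split is 80% portal /
20% arterial. The liver drains into the hepatic vein. The three experimental
sampling sites map onto this topology exactly: *right heart* = venous pool
plasma, *portal vein* = flow-weighted gut/spleen outflow, *hepatic vein* =
liver outflow.

Organ volumes, regional flow fractions and sub-compartment (plasma / red
blood cell / interstitial / cellular) fractions live in a versioned YAML
table (`zonpbpk/data/mouse_physiology.yaml`), compiled from the rodent
physiology compilations of Brown et al. (1997) and Davies & Morris (1993)
and balanced so that the conservation invariants (flows sum to cardiac
output, sub-volumes sum to organ volume) hold exactly. The reference animal
weighs 25 g (the study population is 20–25 g); volumes and cardiac output
scale linearly with body weight, which makes all clearance *ratios* (and
hence excretion fractions) body-weight invariant. Every number is
config-overridable; nothing is hard-coded in the solver.

Within an organ the sub-compartments equilibrate instantaneously
(well-stirred assumption). Each compartment therefore carries a single state
— its drug amount — and exposes the outflow plasma concentration
`C = A / V_eff` with `V_eff = V_vascular + (V_interstitial + V_cellular)·Kp`.
The blood:plasma ratio defaults to 1 (no partitioning data is available for
these compounds), so vascular space sits at plasma concentration.

### Partition coefficients

Organ:plasma coefficients come from the tissue-composition method of Poulin
& Theil (2002): drug distributes between tissue water and lipids according
to `P = 10^logP`, phospholipids counting as a 30:70 lipid:water mixture, with
the tissue unbound fraction estimated from plasma binding as
`fu_t = 1/(1 + 0.5(1−fu_p)/fu_p)`. The non-adipose form is applied uniformly
to all perfused tissues — adipose-specific refinements matter little for
this cocktail and uniformity keeps the method auditable. Fitted or
literature coefficients can be pinned per compound and organ via overrides.

### Liver zonation

For caffeine, midazolam and torsemide the liver is split into a periportal
and a pericentral zone **in series** along the sinusoidal flow direction;
codeine, talinolol and pravastatin use the standard unzoned liver. Zone
volumes follow the measured pericentral expressed-area fraction (CYP1A 56%,
CYP3A 47%, CYP2C 48%), every sub-compartment being split by the same
fraction — the data do not resolve zone-specific compositional differences,
so zone proportions are assumed identical to the whole organ.

Two well-stirred tanks in series are *not* algebraically identical to one:
for a linear, zone-proportional clearance the extraction ratios differ by
~E²/4 and the transient dispersion differs at early times. The equivalence
holds in the well-stirred limit (weak extraction, past the initial mixing
transient), which is what the collapse test verifies: a probe with hepatic
extraction ≲1% agrees between zoned and unzoned models to better than 0.1%
at all three sites from 10 min onward. At caffeine-like extraction (~13%)
the structural difference is a few percent — one reason zonated and unzoned
fits of the same data can return slightly different clearances.

### Clearance convention

A linear specific clearance of `r` 1/min (the published parameter form) is
interpreted as a first-order rate constant acting on the **unbound**
concentration in the cellular space of the named organ, scaled by the whole
organ's cellular volume:

    turnover [µmol/min] = abundance · r · fu · C_out · V_cell(organ)

A configuration switch allows referencing total instead of unbound
concentration, since the publication of the rates does not state the
convention. A process sited in the pericentral zone keeps its whole-liver
referencing (so the printed rate keeps its whole-organ meaning) but sees the
pericentral substrate concentration and forms its metabolites there.

Michaelis–Menten branches (midazolam → 1′-OH, k_cat 80.82 1/min, K_m 0.95
µmol/L; → 4′-OH, 28.73 1/min, 8.43 µmol/L) need an enzyme concentration to
turn k_cat into a Vmax; only the product is identifiable. We fix a reference
enzyme concentration of 1 µmol/L of cellular water and expose a
dimensionless `abundance` (healthy value 1.0). Hepatic damage multiplies
`abundance` — of every hepatic process of a family, metabolite clearances
included — by `(1 − f)`; renal processes are untouched.

### Metabolite topology

Caffeine's hepatic clearance (0.59 1/min total) is split 87:13 between a
pericentral CYP1A route and a homogeneous non-CYP1A route; 27% of the CYP1A
turnover yields tracked paraxanthine, the rest flows to an untracked sink.
Torsemide's CYP2C turnover yields hydroxytorsemide entirely; midazolam's
1′-OH branch yields the tracked metabolite while the 4′-OH branch is an
untracked sink. 1′-hydroxymidazolam glucuronidation is a homogeneous hepatic
linear clearance (no zone-specific data exist in mice). Codeine's metabolite
network is collapsed to one lumped hepatic step. Tracked metabolites appear
in the liver cellular space of the producing zone and are solved
simultaneously with their parents; all sinks (urine, bile, untracked) are
explicit states, so the mass balance closes identically.

### Excretion calibration

Renal specific clearances are re-derived at build time so the model's
unchanged-urine shares match the observed fractions (caffeine 5.1%,
torsemide 20%, codeine 6.9%, talinolol 55%), holding the published hepatic
rates fixed. The inversion uses the well-stirred organ clearance
`CL = Q·CLu/(Q + CLu)` (series-zone form for the zonated liver) and refuses
targets beyond the renal plasma-flow limit. For pravastatin the published
renal rate (500 1/min) lies far above that limit and is therefore
unidentifiable in a flow-limited kidney; instead the renal and biliary
intrinsic clearances are set so the metabolic : fecal : urinary routes split
30 : 23 : 41, the observed disposition pattern. A 48-h simulation recovers
every target within 3 percentage points as the urinary share of eliminated
drug; for torsemide (fu = 0.01, hence a multi-day terminal phase under the
unbound-referencing convention) the share-of-eliminated reading is the
identifiable quantity, as share-of-dose has not converged by 48 h.

## Integration

Linear families form an LTI system and are propagated **exactly** with a
cached matrix exponential on the output grid (0.5 min by default) — no
truncation error, exact mass conservation. Families with Michaelis–Menten
kinetics use LSODA with rtol 1e-8 and atol 1e-10 µmol, integrating
segment-wise between bolus events. The iv bolus is an instantaneous addition
to the venous pool; the grid value at a dose time reports the post-bolus
state. Negative states beyond 1e-6 µmol abort with an error; smaller
round-off negatives are clipped.

AUCs are linear trapezoids. Because a bolus into a finite venous pool
creates an unphysical concentration spike at t = 0+, quadrature including
t = 0 is step-size sensitive; exposure comparisons therefore use the
observed window (2–120 min, the design's sampling span), over which halving
the grid moves the AUC by < 0.1%.

## Fitting and the damage scan

The objective is `E = Σ_i log(s(t_i)/x̄_i)²` over every (compound, site,
time) cell, with `x̄_i` the replicate mean — natural log (the base only
rescales E), joint over parent and metabolite per family. Cell means below
the assay LLOQ are excluded and reported, never substituted; simulated zeros
are floored at 1e-12 µmol/L. The objective is invariant to concentration
units by construction.

`fit` wraps bounded trust-region least squares on the log residuals with
seeded multi-starts (default 8) replacing manual restart heuristics, and
reports per-site Pearson and Lin concordance coefficients
(`ρ_c = 2·cov/(var_x + var_y + (Δmean)²)`, population moments) of the
fitted model.

`scan_functional_damage` freezes the healthy family and profiles E over the
enzyme-reduction factor f on a grid (default 0–1, step 0.005), then polishes
the argmin with a bounded scalar minimization between the neighbouring grid
points. The scan is capped at f = 1 and flags boundary attainment (full
removal of hepatic activity still insufficient) rather than extrapolating.

## Synthetic data

The PK generator reproduces the study design: sites {right heart, portal
vein, hepatic vein}, times {2, 15, 30, 60, 120} min, three animals per time
point, destructive sampling (no within-animal correlation). Noise is
multiplicative log-normal with CV 20% by default — concentrations are
positive and assay errors CV-like; the study reports SDs but no error
model, so the level is a documented choice. The noise factor `exp(σZ)` with
`σ² = ln(1+CV²)` is median-unbiased.

The image generator draws idealized lobule sections: a bright central-vein
lumen, a dark stained (IHC) or dead (H&E) region growing concentrically
around the vein — the pericentral geometry of both CYP expression and the
CCl₄ lesion — and mid-grey tissue elsewhere. The stained set is the
`k = round(target · n_tissue)` tissue pixels nearest the vein, so any target
in [0, 1] is feasible to a single pixel; a small per-image jitter (SD 0.005)
emulates section-to-section variability. Grey levels are drawn within class
bands kept separable by the default thresholds, so the fixtures exercise the
classifier without colour-space ambiguity. What the synthetic images do
**not** emulate: chromogen gradients, partial-volume pixels, multiple
lobules per field, staining artefacts — passing tests demonstrate correct
area accounting, not robustness to real histology.

## Damage report

Tissue damage `T = 1 − (p_e − d)/p_e` is clamped into [0, 1]; the clamp
binds exactly when the lesion covers the whole expressing area (the CYP2D
case: d = 36% > p_e = 10% → 100%). Area fractions are identified with
volume fractions, as in the underlying image analysis. The
compensated/uncompensated/aggravated call uses a default tolerance of 5
percentage points — no numeric criterion is published, and 5 points is the
order of the replicate scatter in both F and T. Codeine's
total-hepatic-clearance damage is never reported as a CYP2D value, since
its CYP2D-metabolized share is unknown.

## Problem sizes and defaults used in the shipped analyses

Scans in the analysis scripts use the full 0.005 grid; Monte-Carlo recovery
experiments use a 0.05 grid plus local refinement, 20 seeds per condition,
which bounds the recovery error estimate at the grid scale while keeping
the experiments compact. Image sets use 10 sections of 128×128 px (the study
quantified ten fields per animal). The 48-h excretion check integrates on a
5-min grid.

## Known limitations

* Absolute plasma levels depend on the bundled physiology table; the
  source study's software-internal mouse physiology is not published, so
  curve levels are comparable only in shape and ratio terms, not bit-exact.
* Enterohepatic recirculation is not modelled (pravastatin's portal
  concentrations in vivo suggest it), nor are oral absorption, drug–drug
  interactions, transporter saturation or protein-binding kinetics.
* The two-zone series liver is a coarse average over the true expression
  gradient; only enzyme placement, not permeability, distinguishes zones.
* The classification tolerance is a reporting convention, not an inferential
  test; no uncertainty is propagated into the compensated/aggravated call
  beyond the scan grid and image scatter.
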