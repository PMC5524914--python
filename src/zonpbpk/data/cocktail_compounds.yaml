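# The six-drug phenotyping cocktail and its three tracked metabolites.
#
# Doses are the intravenous bolus doses administered to the mice; metabolites
# are formed, never dosed.  Clearance rates are first-order specific
# clearances (1/min) referenced to the unbound concentration in the hepatic
# (or renal) cellular space and scaled by the whole-organ cellular volume;
# Michaelis-Menten processes are parametrized by k_cat (1/min, at a reference
# enzyme concentration of 1 umol/L in cellular water) and K_m (umol/L).
#
# A clearance with site `liver_pericentral` is physically confined to the
# pericentral zone of a zonated liver (it sees pericentral substrate and
# forms its metabolites there) while keeping its whole-liver referencing, so
# the printed rate retains its whole-organ meaning.
#
# Caffeine's hepatic clearance (0.59 1/min total) is split 87:13 between the
# pericentral CYP1A route (0.5133 1/min) and a homogeneous non-CYP1A hepatic
# route (0.0767 1/min); 27% of the CYP1A turnover yields paraxanthine.
#
# Renal (and for pravastatin also biliary) rates listed here are the raw
# literature values; `builtin_cocktail` recalibrates them so the model's
# urinary-excretion shares match the observed unchanged-urine fractions
# (caffeine 5.1%, torsemide 20%, codeine 6.9%, talinolol 55%, pravastatin
# 41% urine / 23% feces).
caffeine:
  dose_mg_per_kg: 5.0
  fraction_unbound: 0.85
  log_lipophilicity: -0.07
  molecular_weight_g_per_mol: 194.19
  zonated: true
  pericentral_fraction: 0.56
  clearances:
    - {label: CYP1A, kind: linear_hepatic, site: liver_pericentral, rate_per_min: 0.5133}
    - {label: other_hepatic, kind: linear_hepatic, site: liver, rate_per_min: 0.0767}
    - {label: renal, kind: linear_renal, site: kidney, rate_per_min: 0.0324}
  metabolite_links:
    - {metabolite: paraxanthine, via: CYP1A, fraction_of_clearance: 0.27, tracked: true}

paraxanthine:
  fraction_unbound: 0.85
  log_lipophilicity: -0.63
  molecular_weight_g_per_mol: 180.16
  zonated: true
  pericentral_fraction: 0.56
  clearances:
    - {label: CYP1A, kind: linear_hepatic, site: liver_pericentral, rate_per_min: 3.5e-7}
    - {label: renal, kind: linear_renal, site: kidney, rate_per_min: 0.00926}

midazolam:
  dose_mg_per_kg: 2.0
  fraction_unbound: 0.046
  log_lipophilicity: 3.33
  molecular_weight_g_per_mol: 325.77
  zonated: true
  pericentral_fraction: 0.47
  clearances:
    - {label: CYP3A_1OH, kind: michaelis_menten_hepatic, site: liver_pericentral,
       k_cat_per_min: 80.82, k_m_umol_per_L: 0.95}
    - {label: CYP3A_4OH, kind: michaelis_menten_hepatic, site: liver_pericentral,
       k_cat_per_min: 28.73, k_m_umol_per_L: 8.43}
  metabolite_links:
    - {metabolite: 1-hydroxymidazolam, via: CYP3A_1OH, fraction_of_clearance: 1.0, tracked: true}

1-hydroxymidazolam:
  fraction_unbound: 0.0125
  log_lipophilicity: 3.09
  molecular_weight_g_per_mol: 341.77
  zonated: true
  pericentral_fraction: 0.47
  clearances:
    # glucuronidation; no zone-specific data, hence homogeneous
    - {label: UGT, kind: linear_hepatic, site: liver, rate_per_min: 15.6}

torsemide:
  dose_mg_per_kg: 2.0
  fraction_unbound: 0.01
  log_lipophilicity: 2.3
  molecular_weight_g_per_mol: 348.42
  zonated: true
  pericentral_fraction: 0.48
  clearances:
    - {label: CYP2C, kind: linear_hepatic, site: liver_pericentral, rate_per_min: 1.93}
    - {label: renal, kind: linear_renal, site: kidney, rate_per_min: 0.64}
  metabolite_links:
    - {metabolite: hydroxytorsemide, via: CYP2C, fraction_of_clearance: 1.0, tracked: true}

hydroxytorsemide:
  fraction_unbound: 0.01
  log_lipophilicity: 0.75
  molecular_weight_g_per_mol: 364.41
  zonated: true
  pericentral_fraction: 0.48
  clearances:
    - {label: hepatic, kind: linear_hepatic, site: liver, rate_per_min: 15.3}
    - {label: renal, kind: linear_renal, site: kidney, rate_per_min: 79.6}

codeine:
  dose_mg_per_kg: 2.0
  fraction_unbound: 0.7
  log_lipophilicity: 1.54
  molecular_weight_g_per_mol: 299.36
  zonated: false
  clearances:
    # single lumped metabolic step; the full metabolite network is collapsed
    - {label: hepatic_total, kind: linear_hepatic, site: liver, rate_per_min: 1.60}
    - {label: renal, kind: linear_renal, site: kidney, rate_per_min: 0.21}

talinolol:
  dose_mg_per_kg: 1.0
  fraction_unbound: 0.39
  log_lipophilicity: 2.3
  molecular_weight_g_per_mol: 363.49
  zonated: false
  clearances:
    - {label: hepatic_total, kind: linear_hepatic, site: liver, rate_per_min: 2.95}
    - {label: renal, kind: linear_renal, site: kidney, rate_per_min: 39.76}

pravastatin:
  dose_mg_per_kg: 20.0
  fraction_unbound: 0.5
  log_lipophilicity: 1.65
  molecular_weight_g_per_mol: 424.53
  zonated: false
  clearances:
    - {label: hepatic_metabolic, kind: linear_hepatic, site: liver, rate_per_min: 2.52}
    - {label: biliary, kind: linear_biliary, site: liver_to_bile, rate_per_min: 4.57e-6}
    - {label: renal, kind: linear_renal, site: kidney, rate_per_min: 500.0}
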