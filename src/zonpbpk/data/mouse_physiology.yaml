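# Reference whole-body physiology for an adult C57BL/6 mouse.
#
# Organ volumes are expressed for the reference body weight and are scaled
# linearly with body weight by the loader.  Regional blood flows are expressed
# as fractions of cardiac output and must sum to exactly 1 over all
# arterial-fed territories (the liver receives its arterial share through the
# hepatic artery; the portal vein collects the gut and spleen outflows).
#
# Sources: organ weights and regional flow fractions compiled from the rodent
# physiology tables of Brown et al., Toxicol Ind Health 13:407-484 (1997) and
# Davies & Morris, Pharm Res 10:1093-1095 (1993), rounded and balanced so that
# the stated conservation invariants hold exactly.  All values are
# config-overridable.
reference_body_weight_kg: 0.025
hematocrit: 0.45
cardiac_output_L_per_min: 0.0114
# liver inflow split portal : hepatic-artery
portal_fraction_of_liver_inflow: 0.80

organs:
  venous_blood:
    volume_L: 0.85e-3
    vascular_fraction: 1.0
    interstitial_fraction: 0.0
  arterial_blood:
    volume_L: 0.425e-3
    vascular_fraction: 1.0
    interstitial_fraction: 0.0
  lung:
    volume_L: 0.175e-3
    # pulmonary flow equals cardiac output; listed for completeness
    flow_fraction_of_cardiac_output: 1.0
    vascular_fraction: 0.26
    interstitial_fraction: 0.19
  heart:
    volume_L: 0.125e-3
    flow_fraction_of_cardiac_output: 0.065
    vascular_fraction: 0.06
    interstitial_fraction: 0.16
  brain:
    volume_L: 0.4125e-3
    flow_fraction_of_cardiac_output: 0.033
    vascular_fraction: 0.03
    interstitial_fraction: 0.18
  muscle:
    volume_L: 9.6e-3
    flow_fraction_of_cardiac_output: 0.22
    vascular_fraction: 0.02
    interstitial_fraction: 0.12
  adipose:
    volume_L: 1.75e-3
    flow_fraction_of_cardiac_output: 0.07
    vascular_fraction: 0.01
    interstitial_fraction: 0.14
  skin:
    volume_L: 4.125e-3
    flow_fraction_of_cardiac_output: 0.08
    vascular_fraction: 0.02
    interstitial_fraction: 0.30
  bone:
    volume_L: 2.675e-3
    flow_fraction_of_cardiac_output: 0.12
    vascular_fraction: 0.04
    interstitial_fraction: 0.10
  kidney:
    volume_L: 0.425e-3
    flow_fraction_of_cardiac_output: 0.137
    vascular_fraction: 0.10
    interstitial_fraction: 0.20
  gut:
    volume_L: 1.05e-3
    flow_fraction_of_cardiac_output: 0.20
    vascular_fraction: 0.03
    interstitial_fraction: 0.20
  spleen:
    volume_L: 0.0875e-3
    flow_fraction_of_cardiac_output: 0.02
    vascular_fraction: 0.22
    interstitial_fraction: 0.15
  liver:
    volume_L: 1.375e-3
    # arterial share only; total liver perfusion = hepatic artery + portal vein
    flow_fraction_of_cardiac_output: 0.055
    vascular_fraction: 0.15
    interstitial_fraction: 0.16
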