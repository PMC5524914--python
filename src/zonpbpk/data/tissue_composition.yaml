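# Fractional tissue composition (water, neutral lipid, phospholipid) used by
# the tissue-composition partition-coefficient method.  Values are the
# standard rodent/human homogenate fractions tabulated by Poulin & Theil,
# J Pharm Sci 91:129-156 (2002).
plasma:  {water: 0.945, neutral_lipid: 0.0023, phospholipid: 0.0013}
adipose: {water: 0.120, neutral_lipid: 0.8530, phospholipid: 0.0016}
bone:    {water: 0.446, neutral_lipid: 0.0273, phospholipid: 0.0027}
brain:   {water: 0.788, neutral_lipid: 0.0392, phospholipid: 0.0533}
gut:     {water: 0.749, neutral_lipid: 0.0292, phospholipid: 0.0138}
heart:   {water: 0.779, neutral_lipid: 0.0140, phospholipid: 0.0118}
kidney:  {water: 0.771, neutral_lipid: 0.0123, phospholipid: 0.0284}
liver:   {water: 0.705, neutral_lipid: 0.0138, phospholipid: 0.0303}
lung:    {water: 0.811, neutral_lipid: 0.0219, phospholipid: 0.0140}
muscle:  {water: 0.756, neutral_lipid: 0.0100, phospholipid: 0.0072}
skin:    {water: 0.651, neutral_lipid: 0.0239, phospholipid: 0.0111}
spleen:  {water: 0.771, neutral_lipid: 0.0077, phospholipid: 0.0136}
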