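{
  "membrane": {
    "description": "Thin-film composite aquaporin-vesicle forward-osmosis flat sheet",
    "thickness_um": 112,
    "area_cm2": 0.785,
    "water_flux_L_m2_h": 9.71
  },
  "compounds": [
    {
      "name": "AGKT",
      "class": "peptide",
      "molar_mass_g_mol": 375,
      "permeability_m2_s": 3.8e-13,
      "permeability_ci95_m2_s": 1.14e-12,
      "radius_of_gyration_A": 4.4,
      "rg_sd_A": 0.1,
      "reported_flux_ug_m2_h": 12,
      "reported_rejection_pct": 99.9
    },
    {
      "name": "GGG SGA GKT",
      "class": "peptide",
      "molar_mass_g_mol": 692,
      "permeability_m2_s": 1.39e-12,
      "permeability_ci95_m2_s": 9e-13,
      "radius_of_gyration_A": 5.9,
      "rg_sd_A": 0.4,
      "reported_flux_ug_m2_h": 45,
      "reported_rejection_pct": 99.5
    },
    {
      "name": "DEIA",
      "class": "pesticide",
      "molar_mass_g_mol": 146,
      "permeability_m2_s": 5.36e-12,
      "radius_of_gyration_A": 1.24,
      "reported_flux_ug_m2_h": 172,
      "reported_rejection_pct": 98.2
    },
    {
      "name": "BAM",
      "class": "pesticide",
      "molar_mass_g_mol": 190,
      "permeability_m2_s": 3.9e-12,
      "radius_of_gyration_A": 1.3,
      "reported_flux_ug_m2_h": 125,
      "reported_rejection_pct": 98.7
    },
    {
      "name": "Atrazine",
      "class": "pesticide",
      "molar_mass_g_mol": 216,
      "permeability_m2_s": 4.31e-12,
      "radius_of_gyration_A": 1.73,
      "reported_flux_ug_m2_h": 139,
      "reported_rejection_pct": 98.6
    }
  ]
}
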