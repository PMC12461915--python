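{
 "_comment": "SYNTHETIC stand-in for the ECCions81 parameter set. Charges are the published scaled charges (s=0.81; monovalent ions +/-0.81 e, divalent cations +1.62 e) applied to formal charges. The Lennard-Jones sigma/epsilon values below are representative placeholders chosen at typical aqueous-ion magnitudes, NOT the published table; anion-oxygen pairs carry explicit overrides as in the published model. Units: nm, kJ/mol, e.",
 "scaling_factor": 0.81,
 "species": [
  {"name": "Li", "formal_charge": 1, "sigma": 0.162, "epsilon": 0.7},
  {"name": "Na", "formal_charge": 1, "sigma": 0.24, "epsilon": 0.8},
  {"name": "K", "formal_charge": 1, "sigma": 0.302, "epsilon": 1.0},
  {"name": "Mg", "formal_charge": 2, "sigma": 0.155, "epsilon": 3.0},
  {"name": "Ca", "formal_charge": 2, "sigma": 0.28, "epsilon": 2.0},
  {"name": "Cl", "formal_charge": -1, "sigma": 0.4, "epsilon": 0.55},
  {"name": "Br", "formal_charge": -1, "sigma": 0.425, "epsilon": 0.6},
  {"name": "I", "formal_charge": -1, "sigma": 0.46, "epsilon": 0.65},
  {"name": "OW", "formal_charge": 0, "sigma": 0.3165, "epsilon": 0.8}
 ],
 "overrides": [
  {"species_a": "Cl", "species_b": "OW", "sigma_ab": 0.345, "epsilon_ab": 0.75},
  {"species_a": "Br", "species_b": "OW", "sigma_ab": 0.36, "epsilon_ab": 0.78},
  {"species_a": "I", "species_b": "OW", "sigma_ab": 0.385, "epsilon_ab": 0.8}
 ]
}
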