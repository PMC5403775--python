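# Canonical study configuration: i.p. Bi-213-MX35 in the ovarian-cancer
# mouse model, two activity-concentration scenarios.
nuclide:
  name: Bi-213
  half_life_min: 45.59
  emissions:
    - energy_mev: 8.376   # Po-213 daughter alpha, scored at the Bi-213 site
      branch: 0.9786
    - energy_mev: 5.87    # direct Bi-213 alpha branch
      branch: 0.0214
  delta_j: 1.33e-12       # conventional per-transformation alpha energy

biokinetics:
  k_transfer_per_s: 3.7439221312551156e-05   # calibrated: 1.3 Gy blood dose at 3 MBq/mL
  k_clear_per_s: 1.0e-05
  k_on_per_m_s: 1.0e+05
  k_off_per_s: 1.0e-05
  fluid_volume_ml: 1.0
  blood_volume_ml: 1.5
  antibody_molar_mass_g_per_mol: 150000.0

microdosimetry:
  geometry: half-space
  histories: 1000000
  seed: 20170424
  retention: 1.0
  cell_radius_um: 4.5
  antigens_per_cell: 700000
  radii_um: [9.0, 30.0, 50.0]

scenarios:
  - label: "3 MBq/mL"
    conc_mbq_per_ml: 3.0
    antibody_mass_ug: 10.0
    injected_volume_ml: 1.0
    specific_activity_gbq_per_umol: 45.6
    immunoreactive_fraction: 0.91
    target_blood_dose_gy: 1.3
  - label: "9 MBq/mL"
    conc_mbq_per_ml: 9.0
    antibody_mass_ug: 30.0
    injected_volume_ml: 1.0
    specific_activity_gbq_per_umol: 45.6
    immunoreactive_fraction: 0.91
    target_blood_dose_gy: 3.9

seed: 20170424
marrow_to_blood: 0.58
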