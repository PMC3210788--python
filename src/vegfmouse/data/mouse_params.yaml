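# Default parameterisation of the two-compartment mouse VEGF model.
# Units follow the dataclass docstrings in vegfmouse.parameters /
# vegfmouse.geometry. Keys mirror the published parameter-table row labels.

whole_body:
  body_mass: 25.0           # g
  blood_volume: 1.75        # mL
  plasma_volume: 0.855      # mL (3.42 mL per 100 g body weight)
  blood_density: 1.002      # g/cm^3
  muscle_density: 1.06      # g/cm^3

muscle:
  capillary_density: 650.0          # #/mm^2
  capillary_fiber_ratio: 1.95
  fiber_cross_section: 2500.0       # um^2
  luminal_capillary_diameter: 5.25  # um
  capillary_wall_thickness: 0.5     # um
  perimeter_correction_capillary: 1.23
  surface_correction_capillary: 1.1
  perimeter_correction_fiber: 1.21
  myonuclear_domain_volume: 21400.0  # um^3
  ec_surface_per_side: 1000.0        # um^2
  interstitial_fraction: 0.1526      # cm^3/cm^3 tissue
  fiber_perimeter_printed: 214.10    # um (canonical published value)

matrix:
  ebm_thickness: 154.0      # nm
  pbm_thickness: 154.0      # nm
  bm_pore_size: 7.0         # nm
  ecm_pore_size: 66.0       # nm
  collagen_body_fraction: 0.025
  collagen_density: 1.41    # g/cm^3
  bm_collagen_to_total_ratio: 0.0083
  partition_coefficient_bm: 0.35
  partition_coefficient_ecm: 0.90
  ebm_volume_fraction: 0.002014   # cm^3/cm^3 tissue
  pbm_volume_fraction: 0.009123   # cm^3/cm^3 tissue

receptors:
  vegfr1_per_ec: 1050.0
  vegfr2_per_ec: 700.0
  nrp1_per_ec: 35000.0
  nrp1_per_myocyte: 35000.0
  luminal_fraction: 0.5
  ecm_sites_molar: 0.75e-6   # M
  ebm_sites_molar: 13.0e-6   # M
  pbm_sites_molar: 13.0e-6   # M

kinetics:
  kon_r1: 3.00e7        # M^-1 s^-1
  koff_r1: 1.00e-3      # s^-1
  kon_r2: 1.00e7
  koff_r2: 1.00e-3
  kon_n1: 3.13e6
  koff_n1: 1.00e-3
  kon_gag: 4.20e5
  koff_gag: 1.00e-2
  kc_v164r2_n1: 3.10e13   # (mol/cm^2)^-1 s^-1
  koff_v164r2_n1: 1.00e-3
  kc_v164n1_r2: 1.00e14
  koff_v164n1_r2: 1.00e-3
  kc_r1_n1: 1.00e14
  kdissoc_r1n1: 1.00e-2
  kint: 2.80e-4
  kon_trap: 1.13e8
  koff_trap: 4.23e-5

transport:
  q_v164: 0.0626          # molecules/cell/s (optimised)
  v164_secretion_share: 0.92
  k_lymph: 7.00e-6        # cm^3/s (optimised)
  kp_vegf: 4.00e-8        # cm/s
  kp_trap: 3.00e-8        # cm/s
  c_vegf: 0.23            # min^-1
  c_trap: 8.86e-4         # min^-1 (optimised)
  c_complex: 2.79e-4      # min^-1 (optimised)
  k_deg: 0.0              # min^-1
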