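# Default parameter set for fimsim.
#
# Calibration anchors: the coiling kinetics give an equilibrium uncoiling
# force of 32.2 pN; the shipped cell geometry gives a 0.2 pN drag force at
# 0.01 Pa wall shear stress; the catch-bond constants give bond lifetimes
# that peak between 30 and 70 pN and fall to seconds above 90 pN; the
# fully uncoiled S-curve ends near 150 pN.

fimbria:                 # mechanics of one fimbrial shaft
  n_subunits: 1430       # subunits (~1 um native rod)
  rise_A: 0.7            # nm helical rise per coiled subunit
  k_coil: 2000.0         # pN/nm per-subunit stiffness; A-segment = k_coil/n_A
  x0_B: 5.0              # nm contour length per uncoiled subunit
  x0_C: 6.6              # nm contour length per stretched subunit
  l_pB: 3.0              # nm persistence length of segment B
  l_pC: 8.0              # nm persistence length of segment C
  x_AB: 0.30             # nm Bell distance, uncoiling (A->B)
  x_BA: 1.20             # nm Bell distance, recoiling (B->A)
  k0_AB: 0.2             # 1/s zero-force uncoiling rate
  k0_BA: 26135.5         # 1/s zero-force recoiling rate
  k_eq: 1.0e-3           # B<->C equilibrium constant at zero force
  x_eq: 0.40             # nm stretch-transition distance
  kBT: 4.1               # pN*nm thermal energy
  mode: yielding         # yielding | linear | strain_hardening
  buckling_force: 10.0   # pN compressive clamp

bond:                    # two-state allosteric FimH catch bond
  k0_10: 0.5             # 1/s rupture from low-affinity state at F=0
  x_10: 0.30             # nm
  k0_20: 1.0e-7          # 1/s rupture from activated state at F=0
  x_20: 0.70             # nm
  k0_12: 0.1             # 1/s low->high activation at F=0
  x_12: 1.0              # nm
  k0_21: 2.0             # 1/s high->low deactivation at F=0
  x_21: 0.80             # nm
  k_on: 10.0             # 1/s association while tip within capture radius
  capture_radius: 3.0    # nm
  kBT: 4.1               # pN*nm

cell:                    # near-wall sphere hydrodynamics
  radius_um: 0.7940      # calibrated: 0.2 pN drag at 0.01 Pa at rest
  gap_um: 0.05           # resting surface-to-wall separation
  viscosity_Pa_s: 1.0e-3 # water

simulation:
  dt_s: 1.0e-4           # base step; the engine sub-divides for fast rates
  output_dt_s: 0.01      # snapshot interval
  grace_window_s: 0.1    # zero bonds for this long => detached
  k_wall_pN_nm: 50.0     # short-range wall repulsion stiffness
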