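# Default eleven-state Ramachandran region table.
#
# Each entry is an axis-aligned rectangle in degrees with half-open intervals
# [lo, hi) on both axes; the psi axis is treated as wrapped (periodic with
# period 360), so a region may be listed as several rectangles (the extended
# region "eps" below).  Names may be given in ASCII aliases; they map onto the
# canonical eleven-state taxonomy:
#   1 eps_prime  2 eps  3 alpha_R  4 gamma  5 delta_R  6 delta_L
#   7 zeta  8 gamma_prime  9 alpha_L  10 beta_s  11 beta_p
# Edit freely to match any published boundary set; the classifier only
# requires the rectangles to be pairwise disjoint on the torus.
regions:
  - {name: alpha_R,     phi_lo: -160, phi_hi: -20,  psi_lo: -70,  psi_hi: -10}
  - {name: delta_R,     phi_lo: -160, phi_hi: -20,  psi_lo: -10,  psi_hi: 60}
  - {name: gamma_prime, phi_lo: -110, phi_hi: -40,  psi_lo: 60,   psi_hi: 100}
  - {name: zeta,        phi_lo: -180, phi_hi: -110, psi_lo: 60,   psi_hi: 100}
  - {name: beta_s,      phi_lo: -180, phi_hi: -110, psi_lo: 100,  psi_hi: 180}
  - {name: beta_p,      phi_lo: -110, phi_hi: -40,  psi_lo: 100,  psi_hi: 180}
  - {name: eps_prime,   phi_lo: -180, phi_hi: -20,  psi_lo: -180, psi_hi: -140}
  - {name: eps,         phi_lo: 20,   phi_hi: 180,  psi_lo: 140,  psi_hi: 180}
  - {name: eps,         phi_lo: 20,   phi_hi: 180,  psi_lo: -180, psi_hi: -140}
  - {name: alpha_L,     phi_lo: 20,   phi_hi: 160,  psi_lo: 10,   psi_hi: 70}
  - {name: delta_L,     phi_lo: 20,   phi_hi: 160,  psi_lo: -60,  psi_hi: 10}
  - {name: gamma,       phi_lo: 40,   phi_hi: 110,  psi_lo: -100, psi_hi: -60}
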