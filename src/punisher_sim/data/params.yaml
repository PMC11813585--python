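# Packaged parameter registry.
#
# One fixed unit system repo-wide: concentrations nM, time h, protein length
# amino acids (see punisher_sim.units).  Host-cell values describe an E. coli
# cell growing at ~1-2 doublings/h; circuit values define the default
# ("reference design point") Punisher, chosen with the package's own
# switching-threshold toolkit so that the bifurcation threshold lies between
# the pre- and post-mutation burden of the packaged scenarios.
schema_version: 1

host:
  # metabolic (a) lumped gene
  c_a: 1.0          # nM
  alpha_a: 11500.0
  n_a: 300.0        # aa
  beta_a: 6.0       # 1/h (~7 min mRNA half-life)
  k_a: 500.0        # nM
  # ribosomal (r) lumped gene
  c_r: 1.0
  alpha_r: 12000.0
  n_r: 7459.0       # aa per ribosome
  beta_r: 6.0
  k_r: 500.0
  # global
  phi_q: 0.55       # housekeeping proteome mass fraction
  M: 1.19e+9        # aa, total cell protein mass
  K_D: 1300.0       # nM, chloramphenicol-ribosome dissociation constant
  sigma: 0.5        # nutrient quality
  # rate kernel
  eps_max: 7.2e+4   # aa/h (20 aa/s)
  K_eps: 5.8e+4     # nM charged tRNA
  nu_max: 4000.0    # 1/h per metabolic protein
  K_nu: 1.0e+5      # nM uncharged tRNA
  psi_max: 3.5e+5   # nM (steady-state total tRNA pool scale)
  tau_ppgpp: 1.0

punisher:
  I: 0.8            # inducer-bound switch fraction (reference design point)
  eta_s: 2.0        # switch self-activation cooperativity
  K_s: 8.6e+3       # nM
  F_sb: 0.05        # baseline switch promoter activity
  K_bI: 2.4e+4      # nM, integrase tetramer-DNA dissociation constant
  k_sx_plus: 3.6    # 1/h forward strand exchange
  k_sx_minus: 0.36  # 1/h backward strand exchange
  k_conf: 1.8       # 1/h conformation change (commitment)
  K_C: 60.0         # nM, CAT-chloramphenicol affinity
  kappa: 10.0       # 1/h membrane diffusion
  h_ext: 4000.0     # nM external chloramphenicol

genes:
  # Punisher block
  s:    {c: 10.0, alpha: 120.0, n: 300.0, beta: 6.0, k: 500.0, delta: 2.0e-4}
  i:    {c: 10.0, alpha: 120.0, n: 450.0, beta: 6.0, k: 500.0, delta: 2.0e-4}
  prot: {c: 10.0, alpha: 25.0,  n: 300.0, beta: 6.0, k: 500.0, delta: 0.0}
  cat:  {c: 10.0, alpha: 60.0,  n: 220.0, beta: 6.0, k: 500.0, delta: 0.0}
  # single constitutive burdensome gene
  b:    {c: 10.0, alpha: 800.0, n: 300.0, beta: 6.0, k: 500.0, delta: 0.0}
  # two toggle switches (t1x repress each other; t2x likewise)
  t11:  {c: 10.0, alpha: 700.0, n: 300.0, beta: 6.0, k: 500.0, delta: 0.0}
  t12:  {c: 10.0, alpha: 700.0, n: 300.0, beta: 6.0, k: 500.0, delta: 0.0}
  t21:  {c: 10.0, alpha: 700.0, n: 300.0, beta: 6.0, k: 500.0, delta: 0.0}
  t22:  {c: 10.0, alpha: 700.0, n: 300.0, beta: 6.0, k: 500.0, delta: 0.0}

toggle_regulation:
  F_b: 0.02         # residual activity at full repression
  eta: 2.0
  K: 6.0e+4         # nM repressor-DNA dissociation constant
  I_toggles: 0.87   # punisher inducer fraction used with the two-toggle circuit

coexpression:
  # CAT cistrons co-transcribed with each toggle gene; the CAT RBS strength
  # is given as an mRNA-ribosome association rate k_cat_plus (1/(nM h)) and
  # converted to a dissociation constant via k = (k_off + eps_ref/n_cat)/k_cat_plus
  k_cat_plus: 2.0
  k_off: 1.0e+5     # 1/h effective RBS clearance (unbinding + initiation)
  eps_ref: 3.6e+4   # aa/h reference elongation rate for the conversion
  scan_min: 0.24    # 1/(nM h)
  scan_max: 60.0

stochastic:
  volume_factor: 0.6022   # molecules per nM (~1 fL cell)
  tau: 0.01               # h, leap interval
  horizon: 15.0           # h
  n_trajectories: 20

population:
  mu: 1.0e-12       # per-gene mutation probability per division
  t_cult: 500.0     # h
  n_cells: 1.0e+9   # turbidostat population size
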