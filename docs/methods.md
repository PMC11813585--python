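# Methods

This note documents the models implemented in `punisher_sim`, the
assumptions behind them, the packaged parameter values, the numerical
choices, and the limits of what the test suite demonstrates.

## 1. The problem

Synthetic genes compete with a host cell's native genes for ribosomes.
This expression burden slows growth, so mutants that lose synthetic gene
expression grow faster and take over engineered populations ("mutation
spread").  The package models a burden-sensing safeguard circuit — here
called the Punisher — consisting of

* a self-activating **switch** transcription factor, active only when
  bound by a chemical inducer (bound fraction `I`), destabilized by a
  dedicated synthetic **protease**;
* a serine **integrase** co-expressed from the switch's operon;
* an excisable chloramphenicol-resistance gene (**CAT**) flanked by the
  integrase's attachment sites.

While burden is high, the switch cannot reach its high-expression
equilibrium.  A burden-alleviating mutation frees ribosomes, the switch
self-activates, the integrase rises and irreversibly excises CAT, and in
chloramphenicol-containing medium the mutant is permanently
growth-crippled.

## 2. Single-cell model

### 2.1 Host cell

The host is the coarse-grained resource-aware cell: two lumped native
gene classes — metabolic (`a`, aminoacylates tRNA at a rate scaled by
nutrient quality `sigma`) and ribosomal (`r`) — plus charged/uncharged
tRNA pools `t_c`, `t_u`.  mRNA and protein mass balances have the form

    dm_j/dt = F_j c_j alpha_j lambda − (beta_j + lambda) m_j
    dp_j/dt = (eps/n_j) (m_j/k_j)/D · R − (delta_j p_prot + lambda) p_j

with transcription growth-coupled (gene dosage and RNAP availability
scale with growth) and all species diluted at the growth rate.  All mRNAs
compete for ribosomes through one dimensionless denominator

    D = (K_D+h)/K_D · (1 + Σ_j m_j/k_j − T),

whose prefactor models ribosome sequestration by intracellular
chloramphenicol `h` (dissociation constant `K_D`) and whose correction
term `T ∝ phi_q·Delta/(eps R)` keeps the housekeeping proteome fraction
`phi_q` constant when the protease degrades synthetic protein at mass
flux `Delta = p_prot Σ n_x delta_x p_x`; `T` vanishes when `Delta` does.

Growth-law closures (isolated in one "rate kernel" so the mass balances
are testable independently):

| closure | form | interpretation |
|---|---|---|
| elongation | `eps = eps_max t_c/(t_c+K_eps)` | runs on charged tRNA |
| growth | `lambda = (eps·B − Delta)/((1−phi_q)·M)` | net accumulation of the non-housekeeping proteome |
| translating ribosomes | `B = R·Σ(m_j/k_j)/D` | occupancy of the explicit transcripts |
| ribosomal regulation | `F_r = t_c/(t_c + tau_ppgpp·t_u)` | charged:uncharged balance, a coarse ppGpp proxy |
| tRNA synthesis | `psi = psi_max·F_r` (flux `psi·lambda`) | co-regulated with rRNA, growth-proportional |
| aminoacylation | `nu = nu_max·sigma·t_u/(t_u+K_nu)` | nutrient-quality limited |

These forms were cross-validated against the steady-state reduction of
§3: the closed-form required-regulation curve (below) is exact under this
kernel in the many-transcript limit, which fixes the relation
`eps·R ≈ lambda·M(1−phi_q)·(K_D+h)/K_D` used by the correction factor
`chi`.

### 2.2 Circuit blocks

* Switch self-activation: `F_s = F_sb + (1−F_sb)(I·p_s)^eta_s/((I·p_s)^eta_s + K_s^eta_s)`.
* Integrase co-expression: the integrase shares the switch transcript;
  rather than a separate mRNA state we use the identity
  `m_i = m_s·n_i/n_s` (one fewer stiff variable).
* Excision: reversible strand exchange with Hill-4 integrase dependence
  (tetramer, hard-coded) followed by an irreversible conformation change;
  `d(c_cat+c_LRi)/dt = −(k_conf+lambda)·c_LRi` identically.  The printed
  back-flux `k_sx−` exists, but irreversibility emerges because `k_conf`
  drains the intermediate.
* Chloramphenicol: `dh/dt = kappa(h_ext−h) − h·p_cat/K_C − lambda·h`.
* Toggle switches: mutual Hill repression
  `F = F_b + (1−F_b)/(1+((1−occ)·p_rep/K)^eta)`; an inducer pulse sets the
  repressor's neutralized fraction `occ` to a rectangular profile.
* Mutation: an instantaneous event sets the gene's DNA concentration to
  zero (for CAT, the remaining functional copies); existing mRNA and
  protein decay naturally.

### 2.3 Parameter registry

No external datasets exist; every value lives in
`src/punisher_sim/data/params.yaml`.  Host values were chosen once for
E. coli realism: `M = 1.19e9 aa`, `phi_q = 0.55`, `eps_max = 7.2e4 aa/h`
(20 aa/s), steady state near `lambda ≈ 2/h`, ribosome pool ≈ 26 µM, total
mRNA ≈ 4–5 µM, total tRNA ≈ 2.5e5 nM, `K_D = 1300 nM`, external
chloramphenicol 4 µM.  Circuit values define the packaged *reference
design point*; they were selected with the package's own
threshold toolkit plus full-ODE validation — position the switching
threshold inside the pre/post-mutation burden window, then verify on the
full model that (i) the switch stays low for ≥25 h before mutation,
(ii) it fires after mutation, (iii) it does not fire at weak induction
(I = 0.6), (iv) toggle flip pulses are rejected, and (v) single-toggle-gene
mutants do not trigger.  This mirrors the intended use of the toolkit:
the inducer level is the free tuning knob (`I = 0.8` for the single-gene
application, `I = 0.87` for the two-toggle application).

The CAT RBS scan of the co-expression comparison takes an association
rate `k+` (nM⁻¹h⁻¹) and converts it to the competition constant via
`k = (k_off + eps_ref/n_cat)/k+` with `k_off = 1e5 /h` (~28 s⁻¹ effective
RBS clearance), chosen so the scanned range 0.24–60 nM⁻¹h⁻¹ spans the
under- to over-protected regimes rather than collapsing growth.

## 3. Steady-state switching analysis

At steady state the burden of gene `j` is its competition share

    xi_j = F̄_j alpha_j c_j / kbar_j,      kbar_j = k_j (beta_j+lambda)/lambda,

an identity of the mRNA balance (`xi_j = m̄_j/k_j`).  The total sensed
burden `Xi` sums all genes except switch and integrase.  Solving the
model for the `F_s` needed to hold a given `p_s` gives

    Fs_req = p_s(1+chi) · Xi/(xs+xi) · ( M(1−phi_q)/n_s · xs/(xs+xi) − p_s(1+chi) )⁻¹,

with `xs`, `xi` the maximal switch/integrase burdens and
`chi = (K_D+h̄)/K_D · delta_s M(1−phi_q) n_r xi_prot/(eps̄ n_prot xi_r)`
the protease-to-dilution removal ratio of the switch protein.  `Xi`
enters as a single multiplicative factor (the `1+Xi ≈ Xi` reduction is
kept as printed; it costs ~10 % against the full ODE, which the tests
treat as the reduction's tolerance).  Intersections with the real Hill
curve are the fixed points; stability follows the one-dimensional
graphical criterion (`p_s` grows where real > required), an approximation
we use instead of the full Jacobian.

Numerics: roots by sign change on a 2000-point log grid over
(1e-3, unreachable boundary) refined with Brent's method (rtol 1e-10);
the saddle-node threshold `Xi_hat` by bisection on existence of the
low branch (rtol 1e-6); a dense-grid brute-force search serves as the
independent oracle in tests.  The integrase fold-change bound is the
ratio of Hill-4 excision propensities between the high fixed point just
below `Xi_hat` and the vanishing low fixed point just above it — the
least-separated triggering scenario — with
`p_i = p_s (k_s/k_i)(delta_s p_prot+lambda)/(delta_i p_prot+lambda)` from
co-expression.  `eps̄`, `h̄`, `lambdā` are taken from the genetic
background's own steady state, once per scan (quasi-static assumption).

## 4. Stochastic simulation

Hybrid tau-leaping: species named in the config (default the switch
transcript/protein, integrase and the DNA states — the low-copy pool)
jump by Poisson draws over birth/death channels mirrored term-by-term
from the deterministic right-hand side; everything else advances by a
stiff sub-integration over each leap with the discrete values frozen.
Counts convert at 0.6022 molecules/nM (~1 fL cell).  A leap driving any
count negative is retried with a halved step, never clamped.  Defaults:
`tau = 0.01 h` (coarser leaps measurably inflate near-threshold noise),
horizon 15 h, 20 trajectories.

Transition rates for the population model are first-passage summaries:
the event is the switch concentration crossing the unstable fixed point
with a ±10 % hysteresis band; the exponential-rate MLE
`events/total time` carries exact Poisson confidence bounds, and zero
events yield rate 0 with a one-sided upper bound, flagged.  Ensembles
start from the relevant converged steady state — starting from an empty
cell transits a protease-free window that inflates false positives.
A two-state telegraph process with known rates calibrates the estimator
(recovery within 20 % at ~10³ events).

## 5. Population model

Cells are classified by functionality of B (burdensome gene), S
(switch+integrase, one mutable unit because co-expressed), P (protease)
and C (CAT) — 16 genetic states — each with Punisher state H, L or 0
(no switch/integrase protein), 48 states total, ordered B-major with
(0, L, H) innermost.  Dynamics:

    dx/dt = (D + A + T − L(x,d)) x,      L = (x·d)/sum(x)

* `D`: division at per-state rate `d_j` with independent per-gene
  mutation probability `mu` per daughter;
  `D_kj = d_j(2 P_mut(j→k) − δ_kj)`, columns summing to `d_j` (division
  flux conserved; simultaneous multi-gene mutation enters at `mu²` via
  the combinatorial expansion).
* `A`: CAT excision at `k_sx+·Hill4(p̄_i)·k_conf/(k_conf+k_sx−)` from the
  state's library integrase level.
* `T`: Punisher-state transitions.  Deterministically driven entries
  (an equilibrium that does not exist for the genetic background) use
  1/first-passage-time from pinned single-cell simulations; S-mutated
  states decay L,H → 0 at the switch protein's removal rate; S-functional
  states refill 0 → L.  Spontaneous flips between coexisting equilibria
  default to zero and can be refreshed with stochastic estimates (the
  measured false-positive rate at the reference design point is 0 in
  6×8 h of ensemble time, upper 95 % bound ≈ 0.06/h).

Per-state division rates, burdensome-protein contents `p_b` and
integrase levels come from a 48-entry library of deterministic
steady states with excision frozen (excision is the A matrix's job) and
the Punisher state pinned by initial condition.  A state whose requested
equilibrium does not exist inherits all properties of its closest
unmutated progenitor, restoring genes in the fixed order B, S, P, C until
the equilibrium exists; `p_b` is forced to zero whenever B is mutated.
The library is computed once per registry and reused.

The turbidostat keeps `sum(x)` constant; the closed form
`x(t) = N·y(t)/sum(y(t))` with `y' = (D+A+T)y` is used as an independent
integrator oracle in tests.  Productivity: `Theta = Σ x_j d_j p_b(j)/Σ x_j`;
yield `Y = ∫ Theta dt` over `t_cult = 500 h`; function duration `tau` =
time until `Theta` first falls below half its maximum (the productivity
signal is the tracked quantity).  Defaults: `mu = 1e-12`, 1e9 cells, the
Punisher population starting in BSPC:L and the control — hosting only the
burdensome and CAT genes — in BS′P′C:0.

## 6. Numerical choices

* ODE integration: LSODA, rtol 1e-8, atol 1e-6 (nM scale); mutation and
  pulse edges are exact segment boundaries; solver outputs are clipped at
  zero for reporting only.
* Steady state: integrate 50 h (the standard horizon for all steady-state
  growth comparisons) and check max scaled derivative < 1e-6.
* The scenario right-hand side has an allocation-free compiled path; a
  readable reference implementation is kept and the two are asserted
  equal in tests.
* Population ODE: LSODA, rtol 1e-8, atol 1e-10 (counts span 1e9 to 1e-3).
* Problem sizes in tests and the acceptance script — ensembles of 4–8
  stochastic trajectories, 14–18-point RBS scans with 3 bisection
  refinements, 500-sample population grids — were chosen as the smallest
  sizes at which the reported quantities are stable to well within their
  stated tolerances.

## 7. What the synthetic conditions do and do not show

All inputs are model-generated; there is no measured data.  The packaged
conditions emulate a well-characterized E. coli host with one of two
application circuits, mutations as instantaneous whole-gene expression
loss, and a perfectly mixed turbidostat.  Passing tests therefore
demonstrate internal consistency of the framework — the circuit logic,
the analytic reduction against the full ODE, the estimator against known
rates, the population integrator against closed forms — not quantitative
agreement with any real strain.  Real-data features deliberately out of
scope: partial or graded expression loss, cell-cycle and division noise
beyond birth/death stochasticity, native-gene beneficial mutations and
clonal interference, chloramphenicol-resistance point mutants, plasmid
copy-number dynamics, and recombination directionality factors.

## 8. Known limitations

* The `1+Xi → Xi` reduction biases the analytic threshold by ~10 %
  relative to the full ODE; design decisions should be validated on the
  full model (the packaged design point was).
* Fallback states inherit their progenitor's division rate, so a
  freshly mutated cell's transient growth advantage before its Punisher
  state updates is understated; the L→H transition rate carries that
  information instead.
* Under the packaged parametrization the essential-gene co-expression
  comparison has no CAT RBS strength at which *no* mutant combination
  outgrows the original: the freed-resource boost of the remaining CAT
  cistrons caps the dosage-loss penalty (~1.2×) below the whole-toggle
  burden relief (~1.35×).  The scan machinery reports the window when it
  exists and otherwise quantifies how far the method is from acceptable —
  itself an illustration of the strategy's fragility that motivates
  burden sensing.
* The stochastic false-positive rate is sensitive to the leap size near
  the switching threshold; estimates should use `tau ≤ 0.01 h`.
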