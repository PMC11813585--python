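# punisher-sim

A resource-aware modelling toolkit for **burden-sensing genetic-stability
circuits** in engineered bacteria.

Synthetic genes compete with a host cell's native genes for ribosomes.
The resulting expression burden slows growth, so mutants that lose
synthetic gene expression outgrow their engineered siblings and take over
the population — "mutation spread", a central failure mode of
biotechnology.  This package models a countermeasure circuit (the
*Punisher*): a protease-destabilized, inducer-dependent self-activating
switch co-expressed with a serine integrase.  When a mutation frees
ribosomes, the switch jumps to its high-expression equilibrium, the
integrase irreversibly excises the cell's chloramphenicol-resistance gene
(CAT), and in antibiotic-containing medium the mutant is permanently
growth-crippled — whatever synthetic gene it was that mutated.

The toolkit links circuit design parameters to population outcomes in
three tiers:

1. **Single cell** (`host_cell`, `circuits`) — a coarse-grained E. coli
   model with explicit ribosome competition.  Every transcript claims the
   share `(m_j/k_j)/D` of the ribosome pool, with the competition
   denominator `D = (K_D+h)/K_D · (1 + Σ m_j/k_j − T)` inflated by
   intracellular chloramphenicol `h`; growth is `λ = εB/((1−φ_q)M)`.
   Circuit topologies (single burdensome gene, two toggle switches, CAT
   co-expression, with/without the Punisher), mutation events and inducer
   pulses compose into stiff ODE systems.
2. **Design analysis** (`threshold_analysis`) — at steady state each gene's
   burden is `ξ_j = F̄_j α_j c_j/k̄_j`, and the switch's fixed points are
   the intersections of its Hill curve with the *required* activation
   `F̄s_req(p_s, Ξ) ∝ p_s(1+χ)·Ξ`.  The saddle-node burden `Ξ̂` at which
   the low state vanishes is the circuit's switching threshold: a design
   functions iff `Ξ_post < Ξ̂ < Ξ_pre`.  Design-space scans over copy
   number, inducer fraction `I`, cooperativity and baseline activity map
   the acceptable region and the integrase activity fold-change bound.
3. **Population** (`stochastic`, `population`) — Punisher state-transition
   rates estimated from hybrid tau-leaping single-cell trajectories feed a
   48-state turbidostat model `ẋ = (D + A + T − L(x,d))x` (16 genetic
   states × {high, low, zero} Punisher states) that predicts mutant
   takeover, per-cell productivity `Θ`, yield `Y` and function duration
   `τ` (time Θ stays above half its maximum).

## Worked example

```python
from punisher_sim import circuits as cir, scenarios_io as sio

reg = sio.load_registry()
sc = sio.build_scenario(
    "single_burdensome_gene_with_punisher", None, reg,
    mutations=[cir.MutationEvent(time=25.0, genes=("b",))])
traj = cir.simulate(sc, (0.0, 60.0))
t = traj.table
pre  = t[t.time.between(23, 24.9)].iloc[-1]
post = t[t.time > 25.0]
print(f"growth before mutation : {pre.lam:.3f} /h")
print(f"transient peak after   : {post.lam.max():.3f} /h")
print(f"punished final growth  : {t.lam.iloc[-1]:.3f} /h")
print(f"CAT copies left        : {t.c_cat.iloc[-1]:.4f} of {t.c_cat.iloc[0]:.0f} nM")
```

prints

```
growth before mutation : 1.314 /h
transient peak after   : 1.774 /h
punished final growth  : 0.925 /h
CAT copies left        : 0.0146 of 10 nM
```

Losing the burdensome gene transiently accelerates the mutant
(1.31 → 1.77 /h); the freed resources flip the switch, the integrase
excises CAT within the hour, chloramphenicol floods the cell and growth
collapses to 0.93 /h — below the unmutated cell, permanently.  The same
design rejects 1-hour toggle-flip transients (CAT retained > 99.7 %) and
at the population level roughly doubles the time an engineered population
keeps producing (function duration 90 h vs 45 h for the no-Punisher
control at a mutation probability of 1e-12 per gene per division).

A thin CLI wraps the same workflows:

```bash
punisher-sim run config.yaml           # simulate a scenario file
punisher-sim scan-threshold ...        # design-space scan
punisher-sim estimate-rates ...        # stochastic transition rates
punisher-sim population [--control]    # 48-state turbidostat run
punisher-sim sweep-mu ...              # function duration vs mutation rate
```

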