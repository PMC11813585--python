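"""Structured population model of mutation spread in a turbidostat.

Cells are classified by which synthetic genes remain functional — the
burdensome gene B, the switch+integrase unit S (one mutable unit, being
co-expressed), the protease P and the CAT gene C — giving 2^4 = 16 genetic
states, each subdivided by the Punisher's expression state: high (H), low
(L) or zero (0, no switch/integrase protein present).  The 16 x 3 = 48
cell counts evolve as

    dx/dt = (D + A + T - L(x, d)) x

where ``D`` carries division with per-gene mutation probability ``mu`` per
division, ``A`` carries CAT excision by integrase action, ``T`` carries
Punisher-state transitions, and the turbidostat dilution
``L = (x . d) / sum(x)`` keeps the total abundance constant.

Per-state division rates, burdensome-protein contents and integrase
activities come from a library of deterministic single-cell steady states;
states whose requested Punisher equilibrium does not exist inherit the
properties of their closest unmutated progenitor.  Punisher-state
transition rates are supplied by first-passage analysis (deterministic
where the transition is driven by loss of an equilibrium, stochastic
estimates for rare spontaneous flips).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .circuits import Scenario, simulate
from .scenarios_io import build_scenario, load_registry

__all__ = [
    "GENES", "PUNISHER_STATES", "StateIndex", "enumerate_states",
    "parse_label", "CellProperties", "build_cell_library",
    "PopulationModel", "build_matrices", "dilution", "simulate_population",
    "productivity_metrics", "punisher_population_model",
    "control_population_model",
]

GENES = ("B", "S", "P", "C")
PUNISHER_STATES = ("0", "L", "H")
PRIME = "′"


@dataclass(frozen=True, order=True)
class StateIndex:
    """One of the 48 population states.

    ``genetic`` is a 4-tuple of booleans — is each of (B, S, P, C) still
    functional? — and ``punisher`` is one of '0', 'L', 'H'.  The canonical
    linear order runs through genetic states in binary order (B the most
    significant bit, functional = 0) with the three Punisher substates
    (0, L, H) nested innermost, so BSPC:0 is index 0 and B'S'P'C':H is 47.
    """

    genetic: tuple[bool, bool, bool, bool]
    punisher: str

    def __post_init__(self) -> None:
        if len(self.genetic) != 4:
            raise ValueError("genetic state must have 4 entries")
        if self.punisher not in PUNISHER_STATES:
            raise ValueError(f"unknown punisher state {self.punisher!r}")

    @property
    def genetic_index(self) -> int:
        return sum((0 if f else 1) << (3 - i) for i, f in enumerate(self.genetic))

    @property
    def linear(self) -> int:
        return 3 * self.genetic_index + PUNISHER_STATES.index(self.punisher)

    @property
    def label(self) -> str:
        g = "".join(f"{name}{'' if f else PRIME}" for name, f in zip(GENES, self.genetic))
        return f"{g}:{self.punisher}"

    def functional(self, gene: str) -> bool:
        return self.genetic[GENES.index(gene)]

    def mutate(self, gene: str) -> "StateIndex":
        i = GENES.index(gene)
        g = list(self.genetic)
        g[i] = False
        return StateIndex(tuple(g), self.punisher)

    def with_punisher(self, q: str) -> "StateIndex":
        return StateIndex(self.genetic, q)


def enumerate_states() -> list[StateIndex]:
    """The 48 states in canonical order (round-trips with ``linear``)."""
    out = []
    for bits in itertools.product([True, False], repeat=4):
        for q in PUNISHER_STATES:
            out.append(StateIndex(tuple(bits), q))
    out.sort(key=lambda s: s.linear)
    return out


def parse_label(label: str) -> StateIndex:
    """Parse a state label like ``B'SPC:H`` (ASCII or typographic prime)."""
    try:
        g_part, q = label.split(":")
    except ValueError as e:
        raise ValueError(f"malformed state label {label!r}") from e
    g_part = g_part.replace("'", PRIME)
    flags = []
    i = 0
    for name in GENES:
        if i >= len(g_part) or g_part[i] != name:
            raise ValueError(f"malformed state label {label!r}")
        i += 1
        if i < len(g_part) and g_part[i] == PRIME:
            flags.append(False)
            i += 1
        else:
            flags.append(True)
    if i != len(g_part):
        raise ValueError(f"malformed state label {label!r}")
    return StateIndex(tuple(flags), q)


# ---------------------------------------------------------------------------
# single-cell property library
# ---------------------------------------------------------------------------

@dataclass
class CellProperties:
    """Steady-state single-cell properties backing one population state."""

    d: float              # division rate, 1/h
    p_b: float            # burdensome protein content, nM
    p_s: float            # switch protein, nM
    p_i: float            # integrase protein, nM
    p_prot: float         # protease protein, nM
    excision_rate: float  # effective CAT excision rate, 1/h
    source: str           # label of the state actually simulated (fallbacks)
    equilibrium_exists: bool


_MUT_GENES = {"B": ("b",), "S": ("s",), "P": ("prot",), "C": ("cat",)}


def _pinned_scenario(registry: dict, state: StateIndex) -> Scenario:
    """Single-cell scenario for one population state: mutated genes zeroed,
    excision frozen (handled by the A matrix at population level)."""
    sc = build_scenario("single_burdensome_gene_with_punisher", None, registry,
                        overrides={"k_sx_plus": 0.0})
    muts: list[str] = []
    for gene, present in zip(GENES, state.genetic):
        if not present:
            muts.extend(_MUT_GENES[gene])
    if state.punisher == "0":
        # no switch/integrase proteins present and none being made
        muts.extend(g for g in ("s",) if g not in muts)
    return sc.with_genes_mutated(sorted(set(muts)))


def _classify(p_s: float, I: float, K_s: float) -> str:
    """Low/high classification of a converged switch level: the high branch
    has the inducer-bound switch concentration above its DNA-binding
    constant, the low branch far below."""
    return "H" if I * p_s > K_s else "L"


def _simulate_pinned(sc: Scenario, registry: dict, q: str, horizon: float = 50.0):
    from .circuits import initial_state, steady_state

    y0 = initial_state(sc)
    if q == "H":
        K_s = registry["punisher"]["K_s"]
        I = sc.punisher.I if sc.punisher else 1.0
        lay = sc.layout
        if "p_s" in lay:
            y0[lay["p_s"]] = 10.0 * K_s / max(I, 1e-6)
            y0[lay["p_i"]] = 10.0 * K_s / max(I, 1e-6)
    return steady_state(sc, y0=y0, horizon=horizon)


def _excision_rate(p_i: float, registry: dict) -> float:
    pp = registry["punisher"]
    hill = p_i ** 4 / (pp["K_bI"] ** 4 + p_i ** 4) if p_i > 0 else 0.0
    commit = pp["k_conf"] / (pp["k_conf"] + pp["k_sx_minus"])
    return pp["k_sx_plus"] * hill * commit


def build_cell_library(registry: dict | None = None, horizon: float = 50.0,
                       progress: bool = False) -> dict[int, CellProperties]:
    """Deterministic single-cell steady states for all 48 population states.

    For each genetic state the '0', 'L' and 'H' Punisher states are pinned
    by initial condition (zero vs high switch/integrase protein) with
    excision frozen.  If the converged state does not match the requested
    equilibrium (it does not exist for that genetic background), the state
    inherits every property of its closest unmutated progenitor: mutated
    genes are restored in the fixed order B, S, P, C until the equilibrium
    exists.  The burdensome protein content is forced to zero whenever B is
    mutated, whatever the fallback said.
    """
    reg = registry or load_registry()
    K_s = reg["punisher"]["K_s"]
    lib: dict[int, CellProperties] = {}
    raw: dict[tuple[tuple[bool, ...], str], CellProperties | None] = {}

    def compute(state: StateIndex) -> CellProperties | None:
        sc = _pinned_scenario(reg, state)
        ss, rates, _ = _simulate_pinned(sc, reg, state.punisher, horizon)
        lay = sc.layout
        p_s = ss[lay.get("p_s", 0)] if "p_s" in lay else 0.0
        p_i = ss[lay.get("p_i", 0)] if "p_i" in lay else 0.0
        I = sc.punisher.I if sc.punisher else 1.0
        if state.punisher in ("L", "H") and state.functional("S"):
            got = _classify(p_s, I, K_s)
            if got != state.punisher:
                return None  # requested equilibrium does not exist
        if state.punisher in ("L", "H") and not state.functional("S"):
            return None  # no switch protein can be made: L/H never self-supporting
        return CellProperties(
            d=rates.lam,
            p_b=ss[lay["p_b"]] if "p_b" in lay else 0.0,
            p_s=p_s, p_i=p_i,
            p_prot=ss[lay.get("p_prot", 0)] if "p_prot" in lay else 0.0,
            excision_rate=_excision_rate(p_i, reg),
            source=state.label,
            equilibrium_exists=True,
        )

    states = enumerate_states()
    for st in states:
        key = (st.genetic, st.punisher)
        if key not in raw:
            raw[key] = compute(st)

    for st in states:
        props = raw[(st.genetic, st.punisher)]
        fallback = st
        while props is None:
            fallback = _restore_one(fallback)
            key = (fallback.genetic, fallback.punisher)
            if key not in raw:
                raw[key] = compute(fallback)
            props = raw[key]
        props = replace(props)
        if not st.functional("B"):
            props.p_b = 0.0
        if props.source != st.label:
            props = replace(props, equilibrium_exists=False)
        lib[st.linear] = props
        if progress:
            print(f"{st.label:12s} <- {props.source:12s} d={props.d:.3f}")
    return lib


def _restore_one(state: StateIndex) -> StateIndex:
    """Restore the first mutated gene in the order B, S, P, C."""
    for i, f in enumerate(state.genetic):
        if not f:
            g = list(state.genetic)
            g[i] = True
            return StateIndex(tuple(g), state.punisher)
    raise RuntimeError(f"no progenitor available for {state.label}")


# ---------------------------------------------------------------------------
# transition-rate library (Punisher state changes)
# ---------------------------------------------------------------------------

def deterministic_transition_rates(
    registry: dict | None = None,
    library: dict[int, CellProperties] | None = None,
    horizon: float = 30.0,
) -> dict[tuple[int, str, str], float]:
    """First-passage-based Punisher-state transition rates per genetic state.

    Deterministically driven transitions (an equilibrium that does not
    exist for the genetic background) get rate 1/t*, with t* the time for
    the pinned single-cell model to reach the destination basin from the
    origin state's (possibly inherited) starting point.  Structural rules:
    S-mutated states decay L->0 and H->0 at the switch protein's removal
    rate; S-functional states refill 0->L (or 0->H when L does not exist).
    Spontaneous (noise-driven) flips between coexisting equilibria are not
    covered here — they are the stochastic module's task and default to 0.

    Returns a mapping (genetic_index, from, to) -> rate (1/h).
    """
    reg = registry or load_registry()
    lib = library or build_cell_library(reg)
    rates: dict[tuple[int, str, str], float] = {}
    genetic_states = [s for s in enumerate_states() if s.punisher == "L"]

    for st in genetic_states:
        g = st.genetic_index
        if not st.functional("S"):
            # punisher proteins only decay; timescale = dilution + protease
            for q in ("L", "H"):
                src = lib[st.with_punisher(q).linear]
                delta_s = reg["genes"]["s"]["delta"]
                rates[(g, q, "0")] = src.d + delta_s * src.p_prot
            continue
        lo = lib[st.with_punisher("L").linear]
        hi = lib[st.with_punisher("H").linear]
        if not lo.equilibrium_exists:
            # low branch gone: true-positive switching L -> H
            t_fp = _first_passage_time(reg, st, start="L", horizon=horizon)
            rates[(g, "L", "H")] = 1.0 / max(t_fp, 1e-3)
            rates[(g, "0", "H")] = 1.0 / max(t_fp, 1e-3)
        else:
            # refill from zero into the low basin
            rates[(g, "0", "L")] = lo.d + reg["genes"]["s"]["delta"] * lo.p_prot
        if not hi.equilibrium_exists and lo.equilibrium_exists:
            # high branch gone: relaxation H -> L
            t_fp = _first_passage_time(reg, st, start="H", horizon=horizon)
            rates[(g, "H", "L")] = 1.0 / max(t_fp, 1e-3)
    return rates


def _first_passage_time(reg: dict, st: StateIndex, start: str, horizon: float) -> float:
    """Time for the pinned single-cell model to cross into the destination
    basin, measured from the moment the genetic state applies."""
    sc = _pinned_scenario(reg, st.with_punisher(start))
    from .circuits import initial_state

    K_s = reg["punisher"]["K_s"]
    I = sc.punisher.I if sc.punisher else 1.0
    y0 = initial_state(sc)
    lay = sc.layout
    if start == "H" and "p_s" in lay:
        y0[lay["p_s"]] = 10.0 * K_s / max(I, 1e-6)
        y0[lay["p_i"]] = 10.0 * K_s / max(I, 1e-6)
    else:
        # L start: seed with the unmutated progenitor's low steady state scale
        pass
    tr = simulate(sc, (0.0, horizon), y0=y0, n_samples=600)
    ps = tr["p_s"]
    t = tr["time"]
    if start == "L":
        crossed = np.nonzero(I * ps > K_s)[0]
    else:
        crossed = np.nonzero(I * ps < K_s)[0]
    if len(crossed) == 0:
        return horizon
    return max(float(t[crossed[0]]), 1e-3)


# ---------------------------------------------------------------------------
# population matrices and dynamics
# ---------------------------------------------------------------------------

@dataclass
class PopulationModel:
    """Assembled 48-state model ready for integration."""

    d: np.ndarray                      # (48,) division rates
    D: np.ndarray                      # (48,48) division + mutation
    A: np.ndarray                      # (48,48) integrase action (C -> C')
    T: np.ndarray                      # (48,48) punisher-state transitions
    p_b: np.ndarray                    # (48,) burdensome protein content
    mu: float
    t_cult: float = 500.0
    labels: list[str] = field(default_factory=lambda: [s.label for s in enumerate_states()])


def build_matrices(
    library: dict[int, CellProperties],
    transition_rates: dict[tuple[int, str, str], float],
    mu: float,
    t_cult: float = 500.0,
) -> PopulationModel:
    """Assemble the division/mutation, excision and transition matrices.

    ``D``: a state-j cell divides at rate d_j; the two daughters mutate
    each still-functional gene independently with probability ``mu``, so
    D_{kj} = d_j (2 P_mut(j->k) - delta_{kj}) and every column sums to d_j
    (division flux is conserved; mutation only redistributes daughters).
    ``A`` moves C-functional states to their C-mutated partner at the
    library's integrase-activity excision rate.  ``T`` applies the supplied
    Punisher-state rates within each genetic state.
    """
    if mu < 0 or mu > 1:
        raise ValueError("mu must be a probability")
    states = enumerate_states()
    n = len(states)
    d = np.array([library[s.linear].d for s in states])
    p_b = np.array([library[s.linear].p_b for s in states])
    if np.any(d < 0):
        raise ValueError("negative division rate in library")

    D = np.zeros((n, n))
    for j, sj in enumerate(states):
        # daughter genetic-state distribution
        probs: dict[int, float] = {}
        func = [i for i, f in enumerate(sj.genetic) if f]
        for pattern in itertools.product([0, 1], repeat=len(func)):
            p = 1.0
            g = list(sj.genetic)
            for bit, gi in zip(pattern, func):
                if bit:
                    p *= mu
                    g[gi] = False
                else:
                    p *= 1.0 - mu
            k = StateIndex(tuple(g), sj.punisher).linear
            probs[k] = probs.get(k, 0.0) + p
        for k, p in probs.items():
            D[k, j] += 2.0 * d[j] * p
        D[j, j] -= d[j]

    A = np.zeros((n, n))
    for j, sj in enumerate(states):
        if sj.functional("C"):
            rate = library[sj.linear].excision_rate
            k = sj.mutate("C").linear
            A[k, j] += rate
            A[j, j] -= rate

    T = np.zeros((n, n))
    for (g, q_from, q_to), rate in transition_rates.items():
        sj = StateIndex(_genetic_from_index(g), q_from)
        sk = sj.with_punisher(q_to)
        T[sk.linear, sj.linear] += rate
        T[sj.linear, sj.linear] -= rate

    return PopulationModel(d=d, D=D, A=A, T=T, p_b=p_b, mu=mu, t_cult=t_cult)


def _genetic_from_index(g: int) -> tuple[bool, bool, bool, bool]:
    return tuple(not ((g >> (3 - i)) & 1) for i in range(4))


def dilution(x: np.ndarray, d: np.ndarray) -> float:
    """Turbidostat dilution rate ``L = (x . d)/sum(x)``."""
    total = float(np.sum(x))
    if total <= 0:
        raise ValueError("empty reactor")
    return float(np.dot(x, d)) / total


def simulate_population(
    model: PopulationModel,
    x0: np.ndarray,
    t_cult: float | None = None,
    n_samples: int = 500,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> pd.DataFrame:
    """Integrate ``dx/dt = (D + A + T - L(x,d)) x`` from ``x0``.

    Returns a table with time, the 48 state counts (columns are state
    labels) and the per-cell productivity ``Theta``.
    """
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (48,) or np.any(x0 < 0):
        raise ValueError("x0 must be a non-negative 48-vector")
    M = model.D + model.A + model.T
    d = model.d

    def rhs(t, x):
        xc = np.maximum(x, 0.0)
        L = np.dot(xc, d) / max(np.sum(xc), 1e-300)
        return M @ xc - L * xc

    horizon = model.t_cult if t_cult is None else t_cult
    sol = solve_ivp(rhs, (0.0, horizon), x0, method="LSODA",
                    t_eval=np.linspace(0.0, horizon, n_samples),
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"population integration failed: {sol.message}")
    x = np.clip(sol.y.T, 0.0, None)
    table = pd.DataFrame(x, columns=model.labels)
    table.insert(0, "time", sol.t)
    with np.errstate(invalid="ignore"):
        theta = (x * (d * model.p_b)).sum(axis=1) / np.maximum(x.sum(axis=1), 1e-300)
    table["Theta"] = theta
    return table


def productivity_metrics(trajectory: pd.DataFrame, model: PopulationModel
                         ) -> tuple[np.ndarray, float, float]:
    """Per-cell productivity ``Theta(t)``, total yield ``Y`` and function
    duration ``tau``.

    ``Theta = sum_j x_j d_j p_b(j) / sum_j x_j`` (burdensome protein
    synthesis rate per cell); ``Y`` integrates Theta over the culture;
    ``tau`` is the time for which Theta remains above 50% of its maximum
    (measured as the first downward crossing; the full horizon if it never
    drops).
    """
    t = trajectory["time"].to_numpy()
    theta = trajectory["Theta"].to_numpy()
    Y = float(np.trapezoid(theta, t))
    peak = float(theta.max()) if len(theta) else 0.0
    if peak <= 0:
        return theta, 0.0, 0.0
    below = np.nonzero(theta < 0.5 * peak)[0]
    i_peak = int(np.argmax(theta))
    below = below[below > i_peak]
    if len(below) == 0:
        tau = float(t[-1])
    else:
        i = below[0]
        # linear interpolation of the crossing time
        t0, t1 = t[i - 1], t[i]
        th0, th1 = theta[i - 1], theta[i]
        frac = (0.5 * peak - th0) / (th1 - th0) if th1 != th0 else 0.0
        tau = float(t0 + frac * (t1 - t0))
    return theta, Y, tau


# ---------------------------------------------------------------------------
# packaged experiment wrappers
# ---------------------------------------------------------------------------

def punisher_population_model(
    registry: dict | None = None,
    mu: float | None = None,
    library: dict[int, CellProperties] | None = None,
    transition_rates: dict[tuple[int, str, str], float] | None = None,
) -> tuple[PopulationModel, np.ndarray]:
    """Model plus initial condition for the Punisher-bearing population:
    every cell starts unmutated with the Punisher at its low state."""
    reg = registry or load_registry()
    lib = library or build_cell_library(reg)
    tr = transition_rates if transition_rates is not None \
        else deterministic_transition_rates(reg, lib)
    m = mu if mu is not None else reg["population"]["mu"]
    model = build_matrices(lib, tr, m, t_cult=reg["population"]["t_cult"])
    x0 = np.zeros(48)
    x0[parse_label("BSPC:L").linear] = reg["population"]["n_cells"]
    return model, x0


def control_population_model(
    registry: dict | None = None,
    mu: float | None = None,
    library: dict[int, CellProperties] | None = None,
    transition_rates: dict[tuple[int, str, str], float] | None = None,
) -> tuple[PopulationModel, np.ndarray]:
    """No-Punisher control: cells host only the burdensome and CAT genes
    (switch/integrase and protease absent), starting in BS'P'C:0."""
    reg = registry or load_registry()
    lib = library or build_cell_library(reg)
    tr = transition_rates if transition_rates is not None \
        else deterministic_transition_rates(reg, lib)
    m = mu if mu is not None else reg["population"]["mu"]
    model = build_matrices(lib, tr, m, t_cult=reg["population"]["t_cult"])
    x0 = np.zeros(48)
    x0[parse_label("BS'P'C:0").linear] = reg["population"]["n_cells"]
    return model, x0
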