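"""Synthetic gene circuits layered on the resource-aware host cell.

A circuit is a set of :class:`GeneSpec` objects (generic mRNA/protein mass
balances competing for ribosomes) plus, optionally, the burden-sensing
"Punisher" block: a protease-destabilized self-activating switch gene
co-expressed with a serine integrase that irreversibly excises the
chloramphenicol-resistance gene CAT once the switch reaches its
high-expression equilibrium.  Loss of CAT in chloramphenicol-containing
medium cripples translation, so a mutant whose burden drop activated the
switch is permanently growth-penalized.

:func:`assemble_scenario` builds the named circuit topologies studied with
this framework (single burdensome gene, two toggle switches, CAT
co-expression, and their no-Punisher controls) into a :class:`Scenario`
whose composed right-hand side can be integrated with
:func:`simulate` / :func:`steady_state`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .host_cell import (
    HostParams,
    HostState,
    RateBundle,
    compute_rate_kernel,
    host_rhs,
)

__all__ = [
    "Regulation", "Constitutive", "SelfActivatingHill", "RepressionHill",
    "GeneSpec", "PunisherParams", "DnaState", "MutationEvent", "InducerPulse",
    "Scenario", "Trajectory",
    "switch_regulation", "synthetic_gene_rhs", "excision_rhs",
    "chloramphenicol_rhs", "assemble_scenario", "simulate", "steady_state",
    "initial_state", "TOPOLOGIES",
]

#: Hill exponent of integrase-mediated strand exchange (integrase tetramer).
INTEGRASE_HILL = 4


# ---------------------------------------------------------------------------
# regulation descriptors
# ---------------------------------------------------------------------------

class Regulation:
    """Base class for transcription regulation descriptors, F_x in [0, 1]."""


@dataclass(frozen=True)
class Constitutive(Regulation):
    def __call__(self) -> float:
        return 1.0


@dataclass(frozen=True)
class SelfActivatingHill(Regulation):
    """Self-activation by the inducer-bound fraction of the gene's own protein."""

    F_b: float    # baseline promoter activity, in (0, 1]
    eta: float    # Hill cooperativity
    K: float      # protein-DNA dissociation constant, nM


@dataclass(frozen=True)
class RepressionHill(Regulation):
    """Repression by another gene's protein (toggle-switch half)."""

    repressor: str  # name of the repressing gene
    F_b: float      # residual activity at full repression
    eta: float
    K: float        # repressor-DNA dissociation constant, nM


@dataclass
class GeneSpec:
    """Per-gene expression parameters (units as in :mod:`punisher_sim.units`).

    ``transcript_of`` marks a co-expressed cistron: the gene has no mRNA
    state of its own and is translated from the named carrier gene's
    transcript, with the effective mRNA ``m_x = m_carrier * n_x/n_carrier``.
    ``uses_dna_state`` marks the excisable CAT gene, whose DNA concentration
    is the dynamic ``c_cat`` variable rather than the fixed ``c``.
    """

    name: str
    c: float          # DNA concentration, nM
    alpha: float      # promoter strength
    n: float          # protein length, aa
    beta: float       # mRNA degradation rate, 1/h
    k: float          # mRNA-ribosome dissociation constant, nM
    delta: float = 0.0          # protease degradation rate constant, 1/(nM h)
    regulation: Regulation = field(default_factory=Constitutive)
    transcript_of: str | None = None
    uses_dna_state: bool = False

    def __post_init__(self) -> None:
        for attr in ("c", "alpha", "n", "beta", "k", "delta"):
            if getattr(self, attr) < 0:
                raise ValueError(f"GeneSpec.{attr} must be >= 0 for gene {self.name!r}")


@dataclass
class PunisherParams:
    """Design parameters of the Punisher circuit."""

    I: float            # inducer-bound switch fraction, in [0, 1]
    eta_s: float        # switch self-activation cooperativity (>= 1)
    K_s: float          # switch protein-DNA dissociation constant, nM
    F_sb: float         # baseline switch promoter activity, in (0, 1]
    K_bI: float         # integrase-DNA dissociation constant, nM
    k_sx_plus: float    # forward strand-exchange rate, 1/h
    k_sx_minus: float   # backward strand-exchange rate, 1/h
    k_conf: float       # conformation-change (commitment) rate, 1/h
    K_C: float          # CAT-chloramphenicol affinity constant, nM
    kappa: float        # chloramphenicol membrane diffusion rate, 1/h
    h_ext: float        # external chloramphenicol, nM

    def __post_init__(self) -> None:
        if not 0.0 <= self.I <= 1.0:
            raise ValueError("I must lie in [0, 1]")
        if not 0.0 < self.F_sb <= 1.0:
            raise ValueError("F_sb must lie in (0, 1]")
        if self.eta_s < 1.0:
            raise ValueError("eta_s must be >= 1")
        for attr in ("K_s", "K_bI", "k_sx_plus", "k_sx_minus", "k_conf", "K_C", "kappa", "h_ext"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be >= 0")


@dataclass
class DnaState:
    """Excisable-gene DNA bookkeeping: functional copies and the
    post-strand-exchange intermediate (both nM)."""

    c_cat: float
    c_LRi: float = 0.0

    def __post_init__(self) -> None:
        if self.c_cat < 0 or self.c_LRi < 0:
            raise ValueError("DnaState concentrations must be >= 0")


@dataclass(frozen=True)
class MutationEvent:
    """Instantaneous expression loss of one or more genes at ``time``."""

    time: float
    genes: tuple[str, ...]


@dataclass(frozen=True)
class InducerPulse:
    """Rectangular pulse neutralizing a repressor protein.

    During [start, start+duration) the fraction ``level`` of the ``target``
    gene's protein is inducer-bound and unable to repress.
    """

    start: float
    duration: float
    target: str
    level: float = 1.0


# ---------------------------------------------------------------------------
# elementary operations (printed equation blocks)
# ---------------------------------------------------------------------------

def switch_regulation(p_s: float, pp: PunisherParams) -> float:
    """Self-activation Hill function of the switch promoter.

    ``F_s = F_sb + (1-F_sb) * (I*p_s)^eta / ((I*p_s)^eta + K_s^eta)``.
    The degenerate 0/0 case (``K_s = 0`` with ``I*p_s = 0``) is defined as
    the baseline ``F_sb``.
    """
    if p_s < 0:
        raise ValueError("p_s must be >= 0")
    x = pp.I * p_s
    if pp.K_s == 0.0 and x == 0.0:
        return pp.F_sb
    num = x ** pp.eta_s
    return pp.F_sb + (1.0 - pp.F_sb) * num / (num + pp.K_s ** pp.eta_s)


def synthetic_gene_rhs(
    gene: GeneSpec,
    m_x: float,
    p_x: float,
    F_x: float,
    rates: RateBundle,
    p_prot: float,
) -> tuple[float, float]:
    """Generic synthetic-gene mass balances.

    ``dm/dt = F_x c_x alpha_x lambda - (beta_x + lambda) m_x``
    ``dp/dt = eps/n_x (m_x/k_x)/D R - (delta_x p_prot + lambda) p_x``
    """
    if m_x < 0 or p_x < 0 or p_prot < 0 or not 0.0 <= F_x <= 1.0 + 1e-12:
        raise ValueError("synthetic_gene_rhs: invalid input")
    dm = F_x * gene.c * gene.alpha * rates.lam - (gene.beta + rates.lam) * m_x
    dp = (rates.eps / gene.n * (m_x / gene.k) / rates.D * rates.R
          - (gene.delta * p_prot + rates.lam) * p_x)
    return dm, dp


def excision_rhs(dna: DnaState, p_i: float, pp: PunisherParams, lam: float) -> tuple[float, float]:
    """Integrase-mediated CAT excision kinetics.

    Reversible strand exchange (Hill-4 in integrase, tetramer assembly on
    the two attachment sites) followed by an irreversible conformation
    change; the intermediate is additionally lost to dilution::

        dc_cat/dt = -k_sx+ * p_i^4/(K_bI^4 + p_i^4) * c_cat + k_sx- * c_LRi
        dc_LRi/dt = +k_sx+ * p_i^4/(K_bI^4 + p_i^4) * c_cat
                    - k_sx- * c_LRi - (k_conf + lambda) * c_LRi
    """
    if p_i < 0 or lam < 0:
        raise ValueError("excision_rhs: negative input")
    hill = p_i ** INTEGRASE_HILL / (pp.K_bI ** INTEGRASE_HILL + p_i ** INTEGRASE_HILL) if p_i > 0 else 0.0
    fwd = pp.k_sx_plus * hill * dna.c_cat
    dc_cat = -fwd + pp.k_sx_minus * dna.c_LRi
    dc_LRi = fwd - pp.k_sx_minus * dna.c_LRi - (pp.k_conf + lam) * dna.c_LRi
    return dc_cat, dc_LRi


def chloramphenicol_rhs(h: float, p_cat: float, pp: PunisherParams, lam: float) -> float:
    """Intracellular chloramphenicol balance.

    ``dh/dt = kappa*(h_ext - h) - h*p_cat/K_C - lambda*h``: membrane
    diffusion, CAT-mediated degradation and growth dilution.
    """
    if h < 0 or p_cat < 0 or lam < 0:
        raise ValueError("chloramphenicol_rhs: negative input")
    return pp.kappa * (pp.h_ext - h) - h * p_cat / pp.K_C - lam * h


# ---------------------------------------------------------------------------
# scenario assembly
# ---------------------------------------------------------------------------

HOST_VARS = ("m_a", "m_r", "p_a", "R", "t_c", "t_u")


@dataclass
class Scenario:
    """A composed host + circuit ODE system.

    State vector layout: the six host variables, then intracellular
    chloramphenicol ``h``, then ``c_cat`` and ``c_LRi``, then one mRNA per
    gene owning a transcript, then one protein per gene.
    """

    name: str
    host: HostParams
    genes: list[GeneSpec]
    punisher: PunisherParams | None = None
    mutations: list[MutationEvent] = field(default_factory=list)
    pulses: list[InducerPulse] = field(default_factory=list)
    initial_proteins: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [g.name for g in self.genes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate gene names in scenario")
        self._gene_by_name = {g.name: g for g in self.genes}
        for g in self.genes:
            if g.transcript_of is not None and g.transcript_of not in self._gene_by_name:
                raise ValueError(f"gene {g.name!r}: unknown carrier {g.transcript_of!r}")
        self._mrna_genes = [g.name for g in self.genes if g.transcript_of is None]
        self._layout = {}
        i = 0
        for v in HOST_VARS:
            self._layout[v] = i
            i += 1
        self._layout["h"] = i; i += 1
        self._layout["c_cat"] = i; i += 1
        self._layout["c_LRi"] = i; i += 1
        for nm in self._mrna_genes:
            self._layout[f"m_{nm}"] = i; i += 1
        for g in self.genes:
            self._layout[f"p_{g.name}"] = i; i += 1
        self.n_states = i
        self.mutations = sorted(self.mutations, key=lambda e: e.time)

    # -- helpers -----------------------------------------------------------

    @property
    def layout(self) -> dict[str, int]:
        return dict(self._layout)

    def gene(self, name: str) -> GeneSpec:
        return self._gene_by_name[name]

    def var_names(self) -> list[str]:
        return [v for v, _ in sorted(self._layout.items(), key=lambda kv: kv[1])]

    def with_genes_mutated(self, names: Sequence[str]) -> "Scenario":
        """Return a copy of the scenario with the named genes' transcription
        permanently disabled (c_x -> 0)."""
        genes = []
        for g in self.genes:
            if g.name in names:
                genes.append(replace(g, c=0.0))
            else:
                genes.append(replace(g))
        sc = Scenario(name=self.name, host=self.host, genes=genes,
                      punisher=self.punisher, mutations=[], pulses=list(self.pulses),
                      initial_proteins=dict(self.initial_proteins))
        return sc

    def _inducer_occupancy(self, t: float) -> dict[str, float]:
        occ: dict[str, float] = {}
        for p in self.pulses:
            if p.start <= t < p.start + p.duration:
                occ[p.target] = max(occ.get(p.target, 0.0), p.level)
        return occ

    def regulation_value(self, gene: GeneSpec, proteins: dict[str, float], t: float) -> float:
        reg = gene.regulation
        if isinstance(reg, Constitutive):
            return 1.0
        if isinstance(reg, SelfActivatingHill):
            pp = self.punisher
            if pp is None:
                raise ValueError("self-activating switch requires PunisherParams")
            return switch_regulation(proteins[gene.name], pp)
        if isinstance(reg, RepressionHill):
            occ = self._inducer_occupancy(t).get(reg.repressor, 0.0)
            p_rep = proteins[reg.repressor] * (1.0 - occ)
            x = (p_rep / reg.K) ** reg.eta if reg.K > 0 else math.inf
            return reg.F_b + (1.0 - reg.F_b) / (1.0 + x)
        raise TypeError(f"unknown regulation descriptor {reg!r}")

    # -- right-hand side ---------------------------------------------------

    def effective_mrnas(self, y: np.ndarray) -> dict[str, float]:
        """Per-gene effective transcript concentration (nM), resolving
        co-expressed cistrons through the Eq-style length scaling
        ``m_x = m_carrier * n_x / n_carrier``."""
        m = {}
        for g in self.genes:
            if g.transcript_of is None:
                m[g.name] = y[self._layout[f"m_{g.name}"]]
        for g in self.genes:
            if g.transcript_of is not None:
                carrier = self._gene_by_name[g.transcript_of]
                m[g.name] = m[g.transcript_of] * g.n / carrier.n
        return m

    def rates_at(self, y: np.ndarray) -> RateBundle:
        """Rate kernel evaluated at a packed state vector."""
        host_state = HostState(*(max(v, 0.0) for v in y[:6]), h=max(y[self._layout["h"]], 0.0))
        mrnas = self.effective_mrnas(np.maximum(y, 0.0))
        proteins = {g.name: max(y[self._layout[f"p_{g.name}"]], 0.0) for g in self.genes}
        p_prot = proteins.get("prot", 0.0)
        delta_mass = p_prot * sum(g.n * g.delta * proteins[g.name] for g in self.genes)
        ratios = [mrnas[g.name] / g.k for g in self.genes]
        return compute_rate_kernel(host_state, self.host, ratios, delta_mass)

    # -- compiled fast path ------------------------------------------------

    def _compile(self) -> None:
        """Precompute index arrays for the allocation-free RHS evaluation."""
        genes = self.genes
        lay = self._layout
        n = len(genes)
        self._gc = np.array([g.c for g in genes])
        self._galpha = np.array([g.alpha for g in genes])
        self._gn = np.array([g.n for g in genes])
        self._gbeta = np.array([g.beta for g in genes])
        self._gk = np.array([g.k for g in genes])
        self._gdelta = np.array([g.delta for g in genes])
        self._p_idx = np.array([lay[f"p_{g.name}"] for g in genes], dtype=int)
        self._own = np.array([g.transcript_of is None for g in genes], dtype=bool)
        self._m_idx = np.array([lay[f"m_{g.name}"] if g.transcript_of is None else -1
                                for g in genes], dtype=int)
        name_pos = {g.name: i for i, g in enumerate(genes)}
        self._carrier_pos = np.array([name_pos[g.transcript_of] if g.transcript_of else -1
                                      for g in genes], dtype=int)
        self._carrier_nratio = np.array(
            [g.n / self._gene_by_name[g.transcript_of].n if g.transcript_of else 1.0
             for g in genes])
        self._uses_dna = np.array([g.uses_dna_state for g in genes], dtype=bool)
        self._prot_pos = name_pos.get("prot", -1)
        self._i_pos = name_pos.get("i", -1)
        self._cat_positions = np.array(
            [i for i, g in enumerate(genes)
             if g.name == "cat" or g.name.startswith("cat_")], dtype=int)
        self._excision_active = (
            self.punisher is not None and "cat" in name_pos and "i" in name_pos
            and self._gene_by_name["cat"].uses_dna_state)
        self._h_active = self.punisher is not None and self.punisher.kappa > 0
        # regulation dispatch: 0 constitutive, 1 self-activating, 2 repression
        self._reg_kind = np.zeros(n, dtype=int)
        self._reg_par = [None] * n
        for i, g in enumerate(genes):
            r = g.regulation
            if isinstance(r, SelfActivatingHill):
                self._reg_kind[i] = 1
            elif isinstance(r, RepressionHill):
                self._reg_kind[i] = 2
                self._reg_par[i] = (name_pos[r.repressor], r.F_b, r.eta, r.K)

    def _regulation_vector(self, p: np.ndarray, t: float) -> np.ndarray:
        F = np.ones(len(self.genes))
        pp = self.punisher
        occ = self._inducer_occupancy(t) if self.pulses else {}
        for i, kind in enumerate(self._reg_kind):
            if kind == 1:
                F[i] = switch_regulation(p[i], pp)
            elif kind == 2:
                rp, F_b, eta, K = self._reg_par[i]
                o = occ.get(self.genes[rp].name, 0.0)
                x = ((1.0 - o) * p[rp] / K) ** eta if K > 0 else math.inf
                F[i] = F_b + (1.0 - F_b) / (1.0 + x)
        return F

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        """Composed right-hand side (allocation-light fast path; agrees with
        :meth:`rhs_reference` to rounding error)."""
        if not hasattr(self, "_gc"):
            self._compile()
        hp = self.host
        yc = np.maximum(y, 0.0)
        m_a, m_r, p_a, R, t_c, t_u = yc[:6]
        lay = self._layout
        h = yc[lay["h"]]
        c_cat = yc[lay["c_cat"]]
        c_LRi = yc[lay["c_LRi"]]
        p = yc[self._p_idx]
        m = np.empty(len(self.genes))
        m[self._own] = yc[self._m_idx[self._own]]
        shared = ~self._own
        if shared.any():
            m[shared] = m[self._carrier_pos[shared]] * self._carrier_nratio[shared]
        p_prot = p[self._prot_pos] if self._prot_pos >= 0 else 0.0
        delta_mass = p_prot * float(np.dot(self._gn * self._gdelta, p))
        u_synth = m / self._gk
        u = m_a / hp.k_a + m_r / hp.k_r + float(u_synth.sum())

        eps = hp.eps_max * t_c / (t_c + hp.K_eps) if t_c > 0 else 0.0
        A = (hp.K_D + h) / hp.K_D
        T = 0.0
        if delta_mass > 0.0 and eps > 0.0 and R > 0.0:
            w = delta_mass / (eps * R)
            T = (A * hp.phi_q * w) / (1.0 - hp.phi_q) * (1.0 - A * w)
        D = A * (1.0 + u - T)
        B = R * u / D
        lam = max(eps * B - delta_mass, 0.0) / ((1.0 - hp.phi_q) * hp.M)
        denom = t_c + hp.tau_ppgpp * t_u
        F_r = t_c / denom if denom > 0 else 0.0
        psi = hp.psi_max * F_r
        nu = hp.nu_max * hp.sigma * t_u / (t_u + hp.K_nu) if t_u > 0 else 0.0

        dy = np.zeros_like(y)
        dy[0] = hp.c_a * hp.alpha_a * lam - (hp.beta_a + lam) * m_a
        dy[1] = F_r * hp.c_r * hp.alpha_r * lam - (hp.beta_r + lam) * m_r
        dy[2] = eps / hp.n_a * (m_a / hp.k_a) / D * R - lam * p_a
        dy[3] = eps / hp.n_r * (m_r / hp.k_r) / D * R - lam * R
        dy[4] = nu * p_a - eps * B - lam * t_c
        dy[5] = psi * lam - nu * p_a + eps * B - lam * t_u

        F = self._regulation_vector(p, t)
        c_eff = np.where(self._uses_dna, c_cat, self._gc)
        dm = F * c_eff * self._galpha * lam - (self._gbeta + lam) * m
        dp = eps / self._gn * u_synth / D * R - (self._gdelta * p_prot + lam) * p
        own = self._own
        dy[self._m_idx[own]] = dm[own]
        dy[self._p_idx] = dp

        if self._excision_active:
            pp = self.punisher
            p_i = p[self._i_pos]
            hill = p_i ** 4 / (pp.K_bI ** 4 + p_i ** 4) if p_i > 0 else 0.0
            fwd = pp.k_sx_plus * hill * c_cat
            dy[lay["c_cat"]] = -fwd + pp.k_sx_minus * c_LRi
            dy[lay["c_LRi"]] = fwd - pp.k_sx_minus * c_LRi - (pp.k_conf + lam) * c_LRi
        if self._h_active:
            pp = self.punisher
            p_cat = float(p[self._cat_positions].sum()) if len(self._cat_positions) else 0.0
            dy[lay["h"]] = pp.kappa * (pp.h_ext - h) - h * p_cat / pp.K_C - lam * h
        return dy

    def rhs_reference(self, t: float, y: np.ndarray) -> np.ndarray:
        yc = np.maximum(y, 0.0)
        host_state = HostState(*yc[:6], h=yc[self._layout["h"]])
        mrnas = self.effective_mrnas(yc)
        proteins = {g.name: yc[self._layout[f"p_{g.name}"]] for g in self.genes}
        p_prot = proteins.get("prot", 0.0)
        delta_mass = p_prot * sum(g.n * g.delta * proteins[g.name] for g in self.genes)
        ratios = [mrnas[g.name] / g.k for g in self.genes]
        rates = compute_rate_kernel(host_state, self.host, ratios, delta_mass)

        dy = np.zeros_like(y)
        dy[:6] = host_rhs(host_state, self.host, rates)

        lam, eps, D, R = rates.lam, rates.eps, rates.D, host_state.R
        c_cat = yc[self._layout["c_cat"]]
        for g in self.genes:
            F_x = self.regulation_value(g, proteins, t)
            c_x = c_cat if g.uses_dna_state else g.c
            if g.transcript_of is None:
                dy[self._layout[f"m_{g.name}"]] = (
                    F_x * c_x * g.alpha * lam - (g.beta + lam) * mrnas[g.name]
                )
            dy[self._layout[f"p_{g.name}"]] = (
                eps / g.n * (mrnas[g.name] / g.k) / D * R
                - (g.delta * p_prot + lam) * proteins[g.name]
            )

        if self.punisher is not None and "cat" in self._gene_by_name \
                and self._gene_by_name["cat"].uses_dna_state and "i" in self._gene_by_name:
            dna = DnaState(c_cat, yc[self._layout["c_LRi"]])
            dc_cat, dc_LRi = excision_rhs(dna, proteins["i"], self.punisher, lam)
            dy[self._layout["c_cat"]] = dc_cat
            dy[self._layout["c_LRi"]] = dc_LRi

        if self.punisher is not None and self.punisher.kappa > 0:
            p_cat = sum(v for k, v in proteins.items()
                        if k == "cat" or k.startswith("cat_"))
            dy[self._layout["h"]] = chloramphenicol_rhs(
                yc[self._layout["h"]], p_cat, self.punisher, lam
            )
        return dy


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Tidy simulation output: one row per sample time."""

    scenario: Scenario
    table: pd.DataFrame  # columns: time, every state variable, lam, eps, D

    def final_state(self) -> np.ndarray:
        cols = self.scenario.var_names()
        return self.table.iloc[-1][cols].to_numpy(dtype=float)

    def __getitem__(self, col: str) -> np.ndarray:
        return self.table[col].to_numpy()


def initial_state(scenario: Scenario) -> np.ndarray:
    """Packaged initial condition: a physiologically plausible host state,
    zero synthetic expression, the full CAT copy number, no intracellular
    chloramphenicol."""
    y0 = np.zeros(scenario.n_states)
    lay = scenario.layout
    y0[lay["m_a"]] = 1000.0
    y0[lay["m_r"]] = 400.0
    y0[lay["p_a"]] = 1.0e6
    y0[lay["R"]] = 2.0e4
    y0[lay["t_c"]] = 8.0e4
    y0[lay["t_u"]] = 6.0e4
    if "cat" in {g.name for g in scenario.genes}:
        cat = scenario.gene("cat")
        y0[lay["c_cat"]] = cat.c
    for nm, v in scenario.initial_proteins.items():
        if f"p_{nm}" in lay:
            y0[lay[f"p_{nm}"]] = v
    return y0


def _segment_boundaries(scenario: Scenario, t0: float, t1: float) -> list[float]:
    pts = {t0, t1}
    for ev in scenario.mutations:
        if t0 < ev.time < t1:
            pts.add(ev.time)
    for p in scenario.pulses:
        for edge in (p.start, p.start + p.duration):
            if t0 < edge < t1:
                pts.add(edge)
    return sorted(pts)


def simulate(
    scenario: Scenario,
    t_span: tuple[float, float] = (0.0, 50.0),
    y0: np.ndarray | None = None,
    n_samples: int = 400,
    rtol: float = 1e-8,
    atol: float = 1e-6,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the scenario ODEs, applying mutation events and inducer
    pulse edges as exact segment boundaries.

    Mutation events zero the affected genes' transcription (``c_x -> 0``;
    for the excisable CAT gene also the remaining functional copies) while
    existing mRNA and protein decay naturally.  Solver: stiff-capable
    ``LSODA`` with tight relative tolerance — the system mixes fast tRNA
    and mRNA timescales with slow protein accumulation.
    """
    if y0 is None:
        y0 = initial_state(scenario)
    t0, t1 = t_span
    bounds = _segment_boundaries(scenario, t0, t1)
    t_eval_all = np.linspace(t0, t1, n_samples)
    rows_t: list[np.ndarray] = []
    rows_y: list[np.ndarray] = []

    work = Scenario(scenario.name, scenario.host, [replace(g) for g in scenario.genes],
                    scenario.punisher, [], list(scenario.pulses),
                    dict(scenario.initial_proteins))
    y = np.asarray(y0, dtype=float).copy()
    mut_by_time: dict[float, list[str]] = {}
    for ev in scenario.mutations:
        mut_by_time.setdefault(ev.time, []).extend(ev.genes)
    if t0 in mut_by_time:
        y = _apply_mutation(work, y, mut_by_time[t0])

    for a, b in zip(bounds[:-1], bounds[1:]):
        seg_eval = t_eval_all[(t_eval_all >= a) & (t_eval_all <= b)]
        if len(seg_eval) == 0 or seg_eval[0] > a:
            seg_eval = np.concatenate([[a], seg_eval])
        if seg_eval[-1] < b:
            seg_eval = np.concatenate([seg_eval, [b]])
        sol = solve_ivp(work.rhs, (a, b), y, method=method,
                        t_eval=seg_eval, rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(f"integration failed on [{a}, {b}]: {sol.message}")
        rows_t.append(sol.t)
        rows_y.append(sol.y.T)
        y = sol.y[:, -1].copy()
        if b in mut_by_time:
            y = _apply_mutation(work, y, mut_by_time[b])

    t_all = np.concatenate(rows_t)
    y_all = np.vstack(rows_y)
    keep = np.concatenate([[True], np.diff(t_all) > 0])
    t_all, y_all = t_all[keep], np.clip(y_all[keep], 0.0, None)

    extra = np.array([_diag_row(work, yy) for yy in y_all])
    table = pd.DataFrame(y_all, columns=scenario.var_names())
    table.insert(0, "time", t_all)
    table["lam"] = extra[:, 0]
    table["eps"] = extra[:, 1]
    table["D"] = extra[:, 2]
    return Trajectory(scenario=work, table=table)


def _apply_mutation(scenario: Scenario, y: np.ndarray, genes: Sequence[str]) -> np.ndarray:
    y = y.copy()
    for nm in genes:
        g = scenario.gene(nm)
        g.c = 0.0
        if g.uses_dna_state:
            y[scenario.layout["c_cat"]] = 0.0
            y[scenario.layout["c_LRi"]] = 0.0
    if hasattr(scenario, "_gc"):
        del scenario._gc  # invalidate the compiled RHS cache
    return y


def _diag_row(scenario: Scenario, y: np.ndarray) -> tuple[float, float, float]:
    r = scenario.rates_at(y)
    return r.lam, r.eps, r.D


def steady_state(
    scenario: Scenario,
    y0: np.ndarray | None = None,
    horizon: float = 50.0,
    tol: float = 1e-6,
    rtol: float = 1e-8,
) -> tuple[np.ndarray, RateBundle, bool]:
    """Integrate to (approximate) steady state over ``horizon`` hours.

    Returns ``(state, rates, converged)`` where ``converged`` reports
    whether the max-norm of scale-normalized derivatives fell below
    ``tol``.  The fixed 50 h default horizon is also used when reporting
    "steady-state" growth rates for mutant-vs-original comparisons.
    """
    traj = simulate(scenario, (0.0, horizon), y0=y0, n_samples=60, rtol=rtol)
    y = traj.final_state()
    dy = traj.scenario.rhs(horizon, y)
    scale = np.maximum(np.abs(y), 1.0)
    converged = bool(np.max(np.abs(dy) / scale) < tol)
    return y, traj.scenario.rates_at(y), converged


# ---------------------------------------------------------------------------
# topology library (parameter values are filled in by the registry)
# ---------------------------------------------------------------------------

TOPOLOGIES = (
    "host_only",
    "single_burdensome_gene_with_punisher",
    "burdensome_gene_no_punisher",
    "two_toggles_with_punisher",
    "two_toggles_no_punisher",
    "two_toggles_cat_coexpression",
)


def assemble_scenario(
    topology_name: str,
    host: HostParams,
    registry: dict,
    overrides: dict[str, float] | None = None,
    mutations: Sequence[MutationEvent] = (),
    pulses: Sequence[InducerPulse] = (),
) -> Scenario:
    """Build one of the named circuit topologies from registry parameters.

    ``registry`` is the loaded parameter registry (see
    :mod:`punisher_sim.scenarios_io`); ``overrides`` remaps individual
    symbols such as ``I`` or ``alpha_b`` before assembly.
    """
    from .scenarios_io import build_scenario  # thin indirection, avoids cycle

    return build_scenario(topology_name, host, registry, overrides=overrides,
                          mutations=mutations, pulses=pulses)
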