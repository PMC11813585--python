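"""Coarse-grained resource-aware host-cell model.

The host cell is reduced to two lumped native gene classes — metabolic
(``a``) and ribosomal (``r``) — plus charged/uncharged tRNA pools that close
the loop between nutrient quality, translation and growth:

* metabolic proteins ``p_a`` aminoacylate tRNA at a nutrient-dependent rate
  ``nu(t_u, sigma)``;
* ribosomes ``R`` consume charged tRNA ``t_c`` while elongating at rate
  ``eps(t_c)``;
* the growth rate ``lambda`` is proportional to the total translation flux;
* ribosomal transcription is regulated by the charged/uncharged tRNA balance
  through ``F_r(t_u, t_c)`` (a coarse ppGpp proxy).

All mRNAs — native and synthetic — compete for ribosomes through a single
dimensionless "ribosomal competition denominator" ``D``: the translation
flux directed to gene ``j`` is ``eps * R * (m_j/k_j) / D`` (in aa/h), where
``k_j`` is the mRNA-ribosome dissociation constant of gene ``j``'s RBS.
``D`` is inflated by intracellular chloramphenicol ``h`` (which inactivates
ribosomes with dissociation constant ``K_D``) and carries a correction for
synthetic-protein turnover by the circuit's protease, so that the
housekeeping proteome fraction ``phi_q`` stays constant.

Host mass balances live in :func:`host_rhs`; every growth-law closure
(``lambda``, ``eps``, ``F_r``, ``psi``, ``nu``) is isolated in
:func:`compute_rate_kernel` so the mass balances can be tested
independently of the kernel's functional forms.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "HostParams",
    "HostState",
    "RateBundle",
    "competition_denominator",
    "translation_activity",
    "compute_rate_kernel",
    "host_rhs",
]


@dataclass
class HostParams:
    """Parameters of the native cell: lumped gene classes and rate kernel.

    Concentrations are nM, times are hours, lengths are amino acids
    (see :mod:`punisher_sim.units`).
    """

    # metabolic (a) gene class
    c_a: float          # gene DNA concentration, nM
    alpha_a: float      # promoter strength, dimensionless
    n_a: float          # protein length, aa
    beta_a: float       # mRNA degradation rate, 1/h
    k_a: float          # mRNA-ribosome dissociation constant, nM
    # ribosomal (r) gene class
    c_r: float
    alpha_r: float
    n_r: float
    beta_r: float
    k_r: float
    # global cell parameters
    phi_q: float        # housekeeping proteome mass fraction, in (0, 1)
    M: float            # total cell protein mass, aa
    K_D: float          # chloramphenicol-ribosome dissociation constant, nM
    sigma: float        # nutrient quality factor, dimensionless
    # rate-kernel parameters
    eps_max: float      # maximal translation elongation rate, aa/h
    K_eps: float        # charged-tRNA half-saturation of elongation, nM
    nu_max: float       # maximal aminoacylation rate per metabolic protein, 1/h
    K_nu: float         # uncharged-tRNA half-saturation of aminoacylation, nM
    psi_max: float      # tRNA synthesis scale (steady-state total tRNA pool), nM
    tau_ppgpp: float    # charged/uncharged balance constant in F_r, dimensionless

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"HostParams.{f.name} must be finite and >= 0, got {v}")
        if not 0.0 < self.phi_q < 1.0:
            raise ValueError(f"phi_q must lie in (0, 1), got {self.phi_q}")
        if self.K_D <= 0:
            raise ValueError("K_D must be positive")


@dataclass
class HostState:
    """Native-cell state variables (all nM; all non-negative)."""

    m_a: float   # metabolic mRNA
    m_r: float   # ribosomal mRNA
    p_a: float   # metabolic protein
    R: float     # ribosomes (total)
    t_c: float   # charged (aminoacyl-) tRNA
    t_u: float   # uncharged tRNA
    h: float = 0.0   # intracellular chloramphenicol

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"HostState.{f.name} must be finite and >= 0, got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([self.m_a, self.m_r, self.p_a, self.R, self.t_c, self.t_u])


@dataclass
class RateBundle:
    """Instantaneous rates and resource bookkeeping for one cell state."""

    lam: float    # growth rate, 1/h
    eps: float    # translation elongation rate, aa/h
    F_r: float    # ribosomal transcription regulation, in [0, 1]
    psi: float    # tRNA synthesis scale, nM (synthesis flux is psi*lam)
    nu: float     # aminoacylation rate per metabolic protein, 1/h
    B: float      # translating ribosome concentration, nM
    D: float      # ribosomal competition denominator, dimensionless
    R: float = 0.0  # total ribosome pool the bundle was computed at, nM


def competition_denominator(
    h: float,
    mrna_over_k: Iterable[float],
    *,
    K_D: float,
    phi_q: float,
    delta: float = 0.0,
    eps: float | None = None,
    R: float | None = None,
) -> float:
    """Ribosomal competition denominator ``D``.

    ``D = (K_D+h)/K_D * (1 + sum_j m_j/k_j - T)`` where the correction

    ``T = [(K_D+h)/K_D * phi_q * Delta/(eps R)] / (1-phi_q)
          * (1 - (K_D+h)/K_D * Delta/(eps R))``

    accounts for protease turnover of synthetic proteins
    (``Delta = p_prot * sum_x n_x delta_x p_x``, an aa/h mass flux) under the
    constant-housekeeping-fraction assumption; ``T`` vanishes when ``Delta``
    does. The prefactor ``(K_D+h)/K_D`` models sequestration of ribosomes by
    intracellular chloramphenicol.

    Parameters
    ----------
    h : intracellular chloramphenicol, nM.
    mrna_over_k : iterable of ``m_j/k_j`` for every native and synthetic mRNA.
    delta : protease degradation mass flux ``Delta`` (aa/h); requires ``eps``
        and ``R`` when positive.
    """
    ratios = np.asarray(list(mrna_over_k), dtype=float)
    if h < 0 or np.any(ratios < 0) or delta < 0:
        raise ValueError("competition_denominator: negative input")
    if not 0.0 <= phi_q < 1.0:
        raise ValueError(f"phi_q bracket denominator (1-phi_q) must be positive, got phi_q={phi_q}")
    A = (K_D + h) / K_D
    u = float(ratios.sum())
    T = 0.0
    if delta > 0.0:
        if eps is None or R is None or eps <= 0.0 or R <= 0.0:
            raise ValueError("competition_denominator: delta > 0 requires eps > 0 and R > 0")
        w = delta / (eps * R)
        T = (A * phi_q * w) / (1.0 - phi_q) * (1.0 - A * w)
    return A * (1.0 + u - T)


def translation_activity(R: float, D: float, mrna_over_k: Iterable[float]) -> float:
    """Translating ribosome concentration ``B = R * sum_j(m_j/k_j) / D`` (nM).

    ``(m_j/k_j)/D`` is the fraction of the ribosome pool engaged on mRNA
    ``j``, so ``B`` sums the ribosomes actively elongating on the explicitly
    modelled (metabolic, ribosomal and synthetic) transcripts.
    """
    u = float(np.sum(np.fromiter(mrna_over_k, dtype=float)))
    if R < 0 or D <= 0 or u < 0:
        raise ValueError("translation_activity: invalid input")
    return R * u / D


def compute_rate_kernel(
    state: HostState,
    params: HostParams,
    synth_mrna_over_k: Sequence[float] = (),
    delta: float = 0.0,
) -> RateBundle:
    """Evaluate the growth-law closures at the given cell state.

    Functional forms (all saturating/first-order):

    * ``eps(t_c) = eps_max * t_c / (t_c + K_eps)`` — elongation runs on
      charged tRNA;
    * ``F_r(t_u, t_c) = t_c / (t_c + tau_ppgpp * t_u)`` — ribosomal
      transcription tracks the charged:uncharged balance;
    * ``psi(t_u, t_c) = psi_max * F_r`` — tRNA is co-regulated with rRNA and
      synthesized proportionally to growth (flux ``psi * lambda``);
    * ``nu(t_u, sigma) = nu_max * sigma * t_u / (t_u + K_nu)`` — nutrient
      quality scales aminoacylation;
    * ``lambda = (eps*B - Delta) / ((1 - phi_q) * M)`` — growth is the net
      accumulation of the non-housekeeping proteome, whose mass is
      ``(1-phi_q)*M``; the protease flux ``Delta`` makes and immediately
      unmakes protein, so it is subtracted.

    ``D`` and ``B`` are computed from the full mRNA pool (native mRNAs from
    ``state`` plus ``synth_mrna_over_k``).
    """
    arr = state.as_array()
    if np.any(arr < 0) or state.h < 0:
        raise ValueError("compute_rate_kernel: negative state")
    eps = params.eps_max * state.t_c / (state.t_c + params.K_eps) if state.t_c > 0 else 0.0
    if delta > 0.0 and eps == 0.0:
        raise ValueError("compute_rate_kernel: delta > 0 with eps = 0 (division by zero)")
    ratios = [state.m_a / params.k_a, state.m_r / params.k_r, *synth_mrna_over_k]
    D = competition_denominator(
        state.h, ratios, K_D=params.K_D, phi_q=params.phi_q,
        delta=delta, eps=eps if eps > 0 else None, R=state.R if state.R > 0 else None,
    )
    B = translation_activity(state.R, D, ratios)
    lam = max((eps * B - delta), 0.0) / ((1.0 - params.phi_q) * params.M)
    denom = state.t_c + params.tau_ppgpp * state.t_u
    F_r = state.t_c / denom if denom > 0 else 0.0
    psi = params.psi_max * F_r
    nu = params.nu_max * params.sigma * state.t_u / (state.t_u + params.K_nu) if state.t_u > 0 else 0.0
    return RateBundle(lam=lam, eps=eps, F_r=F_r, psi=psi, nu=nu, B=B, D=D, R=state.R)


def host_rhs(state: HostState, params: HostParams, rates: RateBundle) -> np.ndarray:
    """Mass-balance derivatives of the six native state variables.

    Returns ``d/dt [m_a, m_r, p_a, R, t_c, t_u]``; the chloramphenicol
    balance is circuit-dependent and lives in :mod:`punisher_sim.circuits`.
    Transcription scales with the growth rate (gene dosage and RNAP
    availability are growth-coupled), translation of gene ``j`` draws
    ``eps*R*(m_j/k_j)/D / n_j`` protein per hour, and every species is
    diluted by growth.
    """
    lam, eps, D, R = rates.lam, rates.eps, rates.D, state.R
    dm_a = params.c_a * params.alpha_a * lam - (params.beta_a + lam) * state.m_a
    dm_r = rates.F_r * params.c_r * params.alpha_r * lam - (params.beta_r + lam) * state.m_r
    dp_a = eps / params.n_a * (state.m_a / params.k_a) / D * R - lam * state.p_a
    dR = eps / params.n_r * (state.m_r / params.k_r) / D * R - lam * R
    dt_c = rates.nu * state.p_a - eps * rates.B - lam * state.t_c
    dt_u = rates.psi * lam - rates.nu * state.p_a + eps * rates.B - lam * state.t_u
    return np.array([dm_a, dm_r, dp_a, dR, dt_c, dt_u])
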