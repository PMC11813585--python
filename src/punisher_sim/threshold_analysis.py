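"""Analytical steady-state machinery of the burden-sensing switch.

The expression burden of gene ``j`` is the steady-state share of the
ribosome pool its transcript claims,

    xi_j = F_j * alpha_j * c_j / kbar_j,          kbar_j = k_j (beta_j + lam) / lam,

which equals the gene's contribution ``m_j/k_j`` to the ribosomal
competition denominator.  The total burden sensed by the switch,
``Xi = sum xi_j`` over every gene except the switch and integrase
themselves, sets the slope of the *required* regulation curve

    Fs_req(p_s, Xi) = p_s (1+chi) * Xi / (xs + xi)
                      / ( M(1-phi_q)/n_s * xs/(xs+xi) - p_s (1+chi) ),

(``xs``, ``xi`` the maximal switch/integrase burdens at full activation,
``chi`` the protease-to-dilution removal ratio of the switch protein),
while the *real* regulation is the self-activation Hill curve.  Their
intersections are the switch's fixed points; as Xi falls, the low- and
middle-intersection annihilate in a saddle-node bifurcation at the
switching threshold ``Xi_hat``.  A circuit design "functions correctly"
when ``Xi_hat`` lies strictly between the post- and pre-mutation burden of
the application circuit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .circuits import PunisherParams, Scenario, steady_state, switch_regulation

__all__ = [
    "BurdenSummary", "ThresholdReport", "UnreachableError", "NoSwitchingError",
    "gene_burden", "total_burden", "burden_summary", "required_regulation",
    "find_fixed_points", "find_threshold", "fold_change_bound",
    "design_space_scan",
]


class UnreachableError(ValueError):
    """Requested steady-state switch concentration exceeds the physically
    attainable protein mass."""


class NoSwitchingError(RuntimeError):
    """The design admits no saddle-node at any burden (no switching)."""


def gene_burden(F_bar: float, alpha: float, c: float, kbar: float) -> float:
    """Steady-state burden ``xi_j = F_j alpha_j c_j / kbar_j`` of one gene."""
    if min(F_bar, alpha, c) < 0:
        raise ValueError("gene_burden: negative input")
    if kbar <= 0:
        raise ValueError("gene_burden: kbar must be positive")
    return F_bar * alpha * c / kbar


def total_burden(xi_per_gene: dict[str, float], exclude: tuple[str, ...] = ("s", "i")) -> float:
    """Total sensed burden: the sum of per-gene burdens excluding the
    switch and integrase genes themselves."""
    return float(sum(v for k, v in xi_per_gene.items() if k not in exclude))


@dataclass
class BurdenSummary:
    """Burden decomposition plus the reference steady-state context needed
    by the analytic reduction (computed once per genetic background)."""

    xi_per_gene: dict[str, float]   # includes native 'a' and 'r'
    Xi: float                       # total sensed burden (excl. s, i)
    xi_s_max: float                 # switch burden at F_s = 1
    xi_i_max: float                 # integrase burden at F_s = 1
    chi: float                      # protease/dilution removal ratio of p_s
    # reference steady state
    lam_bar: float
    eps_bar: float
    h_bar: float
    R_bar: float
    p_prot_bar: float
    pi_over_ps: float               # steady-state integrase:switch protein ratio
    n_s: float
    M_eff: float                    # M * (1 - phi_q), available proteome mass (aa)

    @property
    def ps_unreachable(self) -> float:
        """Switch concentration beyond which no finite F_s suffices."""
        return self.M_eff / self.n_s * self.xi_s_max / (self.xi_s_max + self.xi_i_max) \
            / (1.0 + self.chi)


def kbar(k: float, beta: float, lam: float) -> float:
    """Effective RBS constant folding mRNA turnover into the burden formula."""
    if lam <= 0:
        raise ValueError("kbar: lam must be positive")
    return k * (beta + lam) / lam


def burden_summary(scenario: Scenario, ss: np.ndarray | None = None,
                   horizon: float = 50.0) -> BurdenSummary:
    """Compute the burden decomposition at a scenario's steady state.

    The reference quantities (``lam``, ``eps``, ``h``, ``R``, ``p_prot``)
    are read from the converged full-model state; per-gene burdens are then
    evaluated through the closed-form ``xi_j = F_j alpha_j c_j / kbar_j``
    so that the analytic reduction can be cross-checked against the raw
    ``m_j/k_j`` resource shares.
    """
    pp = scenario.punisher
    if pp is None:
        raise ValueError("burden_summary requires a Punisher-bearing scenario")
    if ss is None:
        ss, rates, _ = steady_state(scenario, horizon=horizon)
    else:
        rates = scenario.rates_at(ss)
    lay = scenario.layout
    lam, eps, h = rates.lam, rates.eps, max(ss[lay["h"]], 0.0)
    host = scenario.host
    proteins = {g.name: ss[lay[f"p_{g.name}"]] for g in scenario.genes}
    p_prot = proteins.get("prot", 0.0)

    xi: dict[str, float] = {
        "a": gene_burden(1.0, host.alpha_a, host.c_a, kbar(host.k_a, host.beta_a, lam)),
        "r": gene_burden(rates.F_r, host.alpha_r, host.c_r, kbar(host.k_r, host.beta_r, lam)),
    }
    for g in scenario.genes:
        if g.transcript_of is not None:
            # co-expressed cistron: burden via the carrier transcript
            carrier = scenario.gene(g.transcript_of)
            F_c = scenario.regulation_value(carrier, proteins, horizon)
            c_eff = ss[lay["c_cat"]] if carrier.uses_dna_state else carrier.c
            m_carrier = F_c * c_eff * carrier.alpha * lam / (carrier.beta + lam)
            xi[g.name] = (m_carrier * g.n / carrier.n) / g.k
            continue
        F_x = scenario.regulation_value(g, proteins, horizon)
        c_eff = ss[lay["c_cat"]] if g.uses_dna_state else g.c
        xi[g.name] = gene_burden(F_x, g.alpha, c_eff, kbar(g.k, g.beta, lam))

    s = scenario.gene("s") if "s" in {g.name for g in scenario.genes} else None
    if s is None:
        raise ValueError("scenario has no switch gene 's'")
    ig = scenario.gene("i")
    kbar_s = kbar(s.k, s.beta, lam)
    xi_s_max = gene_burden(1.0, s.alpha, s.c, kbar_s)
    xi_i_max = xi_s_max * (s.k / ig.k) * (ig.n / s.n)

    xi_prot = xi.get("prot", 0.0)
    xi_r = xi["r"]
    A = (host.K_D + h) / host.K_D
    chi = A * s.delta * host.M * (1.0 - host.phi_q) * host.n_r * xi_prot \
        / (eps * scenario.gene("prot").n * xi_r) if xi_prot > 0 else 0.0

    gamma_s = s.delta * p_prot + lam
    gamma_i = ig.delta * p_prot + lam
    pi_over_ps = (s.k / ig.k) * (gamma_s / gamma_i)

    return BurdenSummary(
        xi_per_gene=xi, Xi=total_burden(xi), xi_s_max=xi_s_max, xi_i_max=xi_i_max,
        chi=chi, lam_bar=lam, eps_bar=eps, h_bar=h, R_bar=ss[lay["R"]],
        p_prot_bar=p_prot, pi_over_ps=pi_over_ps, n_s=s.n,
        M_eff=host.M * (1.0 - host.phi_q),
    )


def required_regulation(p_s: float, Xi: float, bs: BurdenSummary) -> float:
    """Fs value required to hold the switch at concentration ``p_s`` under
    total burden ``Xi`` (the analytic "required" curve).

    Raises :class:`UnreachableError` when ``p_s`` exceeds the attainable
    concentration (bracket term non-positive).
    """
    if p_s < 0 or Xi < 0:
        raise ValueError("required_regulation: negative input")
    if p_s == 0.0:
        return 0.0
    xs, xi_ = bs.xi_s_max, bs.xi_i_max
    pe = p_s * (1.0 + bs.chi)
    bracket = bs.M_eff / bs.n_s * xs / (xs + xi_) - pe
    if bracket <= 0.0:
        raise UnreachableError(
            f"p_s = {p_s:g} nM exceeds the attainable switch concentration "
            f"({bs.ps_unreachable:g} nM)")
    return pe * Xi / (xs + xi_) / bracket


def real_regulation(p_s: float, pp: PunisherParams) -> float:
    """The switch promoter's actual activity (self-activation Hill curve)."""
    return switch_regulation(p_s, pp)


@dataclass
class ThresholdReport:
    """Fixed-point structure and design diagnostics for one parameter set."""

    fixed_points: list[tuple[float, str]]   # (p_s*, 'stable'|'unstable'), ascending
    Xi_hat: float | None
    fold_change_bound: float | None
    triggers: bool | None
    error: str | None = None


def _g(p_s: float, Xi: float, pp: PunisherParams, bs: BurdenSummary) -> float:
    """Sign function of fixed points: real minus required regulation."""
    return real_regulation(p_s, pp) - required_regulation(p_s, Xi, bs)


def find_fixed_points(Xi: float, pp: PunisherParams, bs: BurdenSummary,
                      n_grid: int = 2000) -> list[tuple[float, str]]:
    """All steady-state switch concentrations at burden ``Xi``.

    Roots of ``Fs_real(p_s) = Fs_req(p_s, Xi)`` located by sign changes on
    a log-spaced grid over (1e-3, ps_unreachable), refined by Brent
    bisection.  Stability follows the one-dimensional graphical criterion:
    ``p_s`` grows where the real curve lies above the required one, so a
    root with the sign function decreasing through zero is stable.
    """
    hi = bs.ps_unreachable * (1.0 - 1e-9)
    grid = np.geomspace(1e-3, hi, n_grid)
    vals = np.array([_g(p, Xi, pp, bs) for p in grid])
    roots: list[tuple[float, str]] = []
    for a, b, fa, fb in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
        if fa == 0.0:
            continue
        if fa * fb < 0:
            r = brentq(lambda p: _g(p, Xi, pp, bs), a, b, xtol=1e-12, rtol=1e-10)
            stability = "stable" if fa > 0 else "unstable"
            roots.append((r, stability))
    # g(0+) = F_sb - 0 > 0, so the leftmost root is always stable and
    # stabilities alternate; keep them sorted ascending.
    roots.sort(key=lambda t: t[0])
    return roots


def _mid_activity(pp: PunisherParams) -> float:
    return pp.F_sb + 0.5 * (1.0 - pp.F_sb)


def _has_low_branch(Xi: float, pp: PunisherParams, bs: BurdenSummary) -> bool:
    fps = find_fixed_points(Xi, pp, bs)
    stable = [(p, s) for p, s in fps if s == "stable"]
    if not stable:
        return False
    mid = _mid_activity(pp)
    return any(real_regulation(p, pp) < mid for p, _ in stable)


def find_threshold(pp: PunisherParams, bs: BurdenSummary,
                   Xi_lo: float = 1e-3, Xi_hi: float | None = None,
                   rel_tol: float = 1e-6) -> float:
    """Saddle-node burden ``Xi_hat``: the infimum of burdens at which the
    low-expression branch exists, located by bisection on the fixed-point
    structure.

    Raises :class:`NoSwitchingError` when the low branch exists at every
    scanned burden (no bifurcation: e.g. ``F_sb -> 1``, no dynamic range)
    or at none of them.
    """
    if Xi_hi is None:
        Xi_hi = max(10.0 * bs.Xi, 50.0)
    lo_has = _has_low_branch(Xi_lo, pp, bs)
    hi_has = _has_low_branch(Xi_hi, pp, bs)
    if lo_has or not hi_has:
        raise NoSwitchingError(
            f"no saddle-node in burden range [{Xi_lo:g}, {Xi_hi:g}]")
    a, b = Xi_lo, Xi_hi
    while (b - a) > rel_tol * b:
        m = 0.5 * (a + b)
        if _has_low_branch(m, pp, bs):
            b = m
        else:
            a = m
    return 0.5 * (a + b)


def _integrase_activity(p_s: float, pp: PunisherParams, bs: BurdenSummary) -> float:
    """Hill-4 DNA-cutting propensity at the integrase level tied to p_s."""
    p_i = p_s * bs.pi_over_ps
    return p_i ** 4 / (pp.K_bI ** 4 + p_i ** 4)


def fold_change_bound(pp: PunisherParams, bs: BurdenSummary,
                      Xi_hat: float | None = None) -> float:
    """Lower bound on the integrase DNA-cutting activity fold-change upon
    switching.

    Evaluated at the bifurcation itself — the least-separated triggering
    scenario: the ratio of Hill-4 excision propensities between the high
    fixed point just below ``Xi_hat`` and the disappearing low fixed point
    just above it.  Any actual trigger (burden dropping further below the
    threshold) separates the two states more.
    """
    if Xi_hat is None:
        Xi_hat = find_threshold(pp, bs)
    eps_rel = 1e-4
    below = find_fixed_points(Xi_hat * (1.0 - eps_rel), pp, bs)
    above = find_fixed_points(Xi_hat * (1.0 + eps_rel), pp, bs)
    stable_below = [p for p, s in below if s == "stable"]
    stable_above = [p for p, s in above if s == "stable"]
    if not stable_below or not stable_above:
        raise NoSwitchingError("could not bracket the saddle-node fixed points")
    p_high = max(stable_below)
    p_low = min(stable_above)
    return _integrase_activity(p_high, pp, bs) / _integrase_activity(p_low, pp, bs)


def threshold_report(pp: PunisherParams, bs: BurdenSummary,
                     Xi_pre: float | None = None,
                     Xi_post: float | None = None) -> ThresholdReport:
    """Fixed points at the summary's own burden plus threshold diagnostics."""
    fps = find_fixed_points(bs.Xi, pp, bs)
    try:
        Xi_hat = find_threshold(pp, bs)
        fc = fold_change_bound(pp, bs, Xi_hat)
    except NoSwitchingError as e:
        return ThresholdReport(fixed_points=fps, Xi_hat=None,
                               fold_change_bound=None, triggers=None, error=str(e))
    trig = None
    if Xi_pre is not None and Xi_post is not None:
        trig = bool(Xi_post < Xi_hat < Xi_pre)
    return ThresholdReport(fixed_points=fps, Xi_hat=Xi_hat,
                           fold_change_bound=fc, triggers=trig)


# ---------------------------------------------------------------------------
# design-space scans
# ---------------------------------------------------------------------------

_SCANNABLE = ("c_si", "I", "eta_s", "inv_F_sb")


def _apply_design_param(pp: PunisherParams, bs: BurdenSummary,
                        param: str, value: float) -> tuple[PunisherParams, BurdenSummary]:
    """Re-map a scan parameter onto the analytic inputs (quasi-static: the
    reference steady state is held fixed across the scan)."""
    if param == "I":
        return replace(pp, I=value), bs
    if param == "eta_s":
        return replace(pp, eta_s=value), bs
    if param == "inv_F_sb":
        return replace(pp, F_sb=1.0 / value), bs
    if param == "c_si":
        scale = value / _reference_c_si(bs)
        bs2 = replace(bs, xi_s_max=bs.xi_s_max * scale, xi_i_max=bs.xi_i_max * scale)
        bs2._c_si = value  # type: ignore[attr-defined]
        return pp, bs2
    raise ValueError(f"unsupported scan parameter {param!r}; allowed: {_SCANNABLE}")


def _reference_c_si(bs: BurdenSummary) -> float:
    return getattr(bs, "_c_si", 10.0)


def design_space_scan(
    axis1: tuple[str, np.ndarray],
    axis2: tuple[str, np.ndarray],
    pp: PunisherParams,
    bs: BurdenSummary,
    Xi_pre: float,
    Xi_post: float,
) -> pd.DataFrame:
    """Grid scan of the switching threshold over two design parameters.

    Returns a long-format table with one row per grid point: axis values,
    ``Xi_hat``, the fold-change bound, acceptable-region membership
    (``Xi_post < Xi_hat < Xi_pre``) and an error code ('' or
    'no_switching').  Per-point failures are recorded, never raised.
    """
    name1, vals1 = axis1
    name2, vals2 = axis2
    rows = []
    for v1 in vals1:
        for v2 in vals2:
            pp2, bs2 = _apply_design_param(pp, bs, name1, float(v1))
            pp2, bs2 = _apply_design_param(pp2, bs2, name2, float(v2))
            row = {name1: float(v1), name2: float(v2), "Xi_hat": np.nan,
                   "fold_change_bound": np.nan, "acceptable": False, "error": ""}
            try:
                Xi_hat = find_threshold(pp2, bs2)
                row["Xi_hat"] = Xi_hat
                row["fold_change_bound"] = fold_change_bound(pp2, bs2, Xi_hat)
                row["acceptable"] = bool(Xi_post < Xi_hat < Xi_pre)
            except (NoSwitchingError, UnreachableError) as e:
                row["error"] = "no_switching"
            rows.append(row)
    return pd.DataFrame(rows)
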