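"""Hybrid tau-leaping stochastic single-cell simulation.

Gene expression noise matters for the Punisher twice over: rare
"false-positive" switch activations in unmutated cells, and the
first-passage timing of "true-positive" activations after a mutation.
Both are captured by a hybrid scheme: low-copy species (the switch/
integrase transcripts and proteins, and the excisable DNA states) advance
by Poisson tau-leaps over their birth/death channels, while the remaining
high-copy host species follow the deterministic right-hand side, frozen
discrete values feeding each leap's continuous sub-integration.

Transition-rate estimation summarizes ensembles of first-passage times
into exponential rates with exact Poisson confidence intervals, the form
consumed by the population model's T matrix.  A two-state telegraph
process with known rates serves as the estimator's calibration benchmark.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.stats import chi2

from .circuits import Scenario, initial_state
from .units import MOLECULES_PER_NM

__all__ = [
    "StochasticConfig", "TransitionRateEstimate", "simulate_hybrid",
    "first_passage_times", "estimate_rate", "estimate_transition_rates",
    "telegraph_simulate", "telegraph_estimate",
]

#: default species treated discretely (low copy number)
DEFAULT_DISCRETE = ("m_s", "p_s", "p_i", "c_cat", "c_LRi")


@dataclass
class StochasticConfig:
    """Settings of the hybrid simulator."""

    seed: int = 0
    n_trajectories: int = 20
    tau: float = 0.01                    # h, leap interval
    horizon: float = 15.0                # h
    discrete_species: tuple[str, ...] = DEFAULT_DISCRETE
    volume_factor: float = MOLECULES_PER_NM   # molecules per nM
    max_halvings: int = 12               # negative-count retry budget
    record_every: int = 10               # store every k-th leap

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.n_trajectories < 1:
            raise ValueError("n_trajectories must be >= 1")
        if self.volume_factor <= 0:
            raise ValueError("volume_factor must be positive")


@dataclass
class TransitionRateEstimate:
    """Exponential-rate estimate for one Punisher-state transition."""

    from_state: str
    to_state: str
    rate: float
    ci_low: float
    ci_high: float
    n_events: int
    total_time: float
    flagged: bool = False   # True when no events were observed

    def __post_init__(self) -> None:
        if self.rate < 0 or not self.ci_low <= max(self.rate, self.ci_low) <= self.ci_high:
            raise ValueError("inconsistent rate estimate")


# ---------------------------------------------------------------------------
# birth/death channel decomposition
# ---------------------------------------------------------------------------

def _channels(scenario: Scenario, t: float, y: np.ndarray):
    """Decompose the discrete species' dynamics into non-negative birth and
    death channel rates (nM/h), mirroring the deterministic RHS term by
    term so the hybrid scheme degenerates to the ODE in the large-copy
    limit."""
    lay = scenario.layout
    yc = np.maximum(y, 0.0)
    rates = scenario.rates_at(yc)
    lam, eps, D, R = rates.lam, rates.eps, rates.D, yc[lay["R"]]
    mrnas = scenario.effective_mrnas(yc)
    proteins = {g.name: yc[lay[f"p_{g.name}"]] for g in scenario.genes}
    p_prot = proteins.get("prot", 0.0)
    out = []  # (state index, +1/-1, rate nM/h)
    names = {g.name for g in scenario.genes}
    c_cat = yc[lay["c_cat"]]
    for g in scenario.genes:
        F_x = scenario.regulation_value(g, proteins, t)
        c_x = c_cat if g.uses_dna_state else g.c
        if g.transcript_of is None and f"m_{g.name}" in lay:
            out.append((lay[f"m_{g.name}"], +1, F_x * c_x * g.alpha * lam))
            out.append((lay[f"m_{g.name}"], -1, (g.beta + lam) * mrnas[g.name]))
        out.append((lay[f"p_{g.name}"], +1, eps / g.n * (mrnas[g.name] / g.k) / D * R))
        out.append((lay[f"p_{g.name}"], -1, (g.delta * p_prot + lam) * proteins[g.name]))
    if scenario.punisher is not None and "cat" in names and "i" in names \
            and scenario.gene("cat").uses_dna_state:
        pp = scenario.punisher
        p_i = proteins["i"]
        hill = p_i ** 4 / (pp.K_bI ** 4 + p_i ** 4) if p_i > 0 else 0.0
        fwd = pp.k_sx_plus * hill * c_cat
        back = pp.k_sx_minus * yc[lay["c_LRi"]]
        conf = (pp.k_conf + lam) * yc[lay["c_LRi"]]
        out.append((lay["c_cat"], -1, fwd))
        out.append((lay["c_cat"], +1, back))
        out.append((lay["c_LRi"], +1, fwd))
        out.append((lay["c_LRi"], -1, back + conf))
    return out


def simulate_hybrid(
    scenario: Scenario,
    config: StochasticConfig,
    y0: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """One hybrid tau-leaping trajectory.

    Discrete species listed in ``config.discrete_species`` jump by Poisson
    draws over their birth/death channels; the remaining (continuous)
    species are advanced by a stiff ODE sub-integration over each leap with
    the discrete values held fixed.  A leap that would drive any discrete
    count negative is retried with a halved step (up to
    ``config.max_halvings`` times) rather than silently clamped.  With an
    empty discrete partition the scheme reduces to the plain ODE solution.
    Trajectories are reproducible: the same seed gives the same path.
    """
    rng = rng or np.random.default_rng(config.seed)
    lay = scenario.layout
    disc_idx = np.array([lay[s] for s in config.discrete_species if s in lay], dtype=int)
    disc_set = set(disc_idx.tolist())
    cont_idx = np.array([i for i in range(scenario.n_states) if i not in disc_set], dtype=int)
    y = (initial_state(scenario) if y0 is None else np.asarray(y0, dtype=float)).copy()
    om = config.volume_factor
    # round discrete species onto the count grid
    y[disc_idx] = np.round(y[disc_idx] * om) / om

    def cont_rhs(t, yc_part, y_full_template):
        y_full = y_full_template.copy()
        y_full[cont_idx] = yc_part
        dy = scenario.rhs(t, y_full)
        return dy[cont_idx]

    records = [(0.0, y.copy())]
    t = 0.0
    step = 0
    n_steps = int(np.ceil(config.horizon / config.tau))
    for step in range(1, n_steps + 1):
        t_next = min(t + config.tau, config.horizon)
        # 1) continuous sub-integration with discrete frozen
        if len(cont_idx):
            sol = solve_ivp(cont_rhs, (t, t_next), y[cont_idx], method="LSODA",
                            rtol=1e-6, atol=1e-6, args=(y,))
            if not sol.success:
                raise RuntimeError(f"hybrid continuous step failed at t={t:.3f}")
            y_cont_end = sol.y[:, -1]
        else:
            y_cont_end = y[cont_idx]
        # 2) discrete tau-leap over [t, t_next], halving on negativity
        if len(disc_idx):
            chans = [(i, s, r) for (i, s, r) in _channels(scenario, t, y) if i in disc_set]
            remaining = t_next - t
            counts = np.round(y[disc_idx] * om).astype(np.int64)
            pos = {int(i): k for k, i in enumerate(disc_idx)}
            frac = 1.0
            for _ in range(config.max_halvings + 1):
                dt = remaining * frac
                delta = np.zeros_like(counts)
                for i, sgn, rate in chans:
                    if rate <= 0:
                        continue
                    n_jump = rng.poisson(rate * om * dt)
                    delta[pos[i]] += sgn * n_jump
                if np.all(counts + delta >= 0):
                    counts = counts + delta
                    remaining -= dt
                    if remaining <= 1e-12:
                        break
                    frac = 1.0
                else:
                    frac *= 0.5
            else:
                raise RuntimeError("tau-leap could not avoid negative counts")
            y[disc_idx] = counts / om
        y[cont_idx] = np.maximum(y_cont_end, 0.0)
        t = t_next
        if step % config.record_every == 0 or step == n_steps:
            records.append((t, y.copy()))

    times = np.array([r[0] for r in records])
    ys = np.vstack([r[1] for r in records])
    table = pd.DataFrame(ys, columns=scenario.var_names())
    table.insert(0, "time", times)
    return table


# ---------------------------------------------------------------------------
# first-passage rate estimation
# ---------------------------------------------------------------------------

def first_passage_times(
    scenario: Scenario,
    config: StochasticConfig,
    threshold: float,
    direction: str = "up",
    observable: str = "p_s",
    hysteresis: float = 0.1,
    y0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """First-passage times of an ensemble of hybrid trajectories.

    The event is the observable crossing ``threshold`` (the unstable fixed
    point separating the switch's basins) with a +/-10% hysteresis band:
    an upward passage requires exceeding ``threshold*(1+hysteresis)``.
    Returns (event_times, censored_times); censored entries ran to the
    horizon without crossing.
    """
    ss = np.random.SeedSequence(config.seed)
    events, censored = [], []
    eff = threshold * (1.0 + hysteresis) if direction == "up" \
        else threshold * (1.0 - hysteresis)
    for child in ss.spawn(config.n_trajectories):
        rng = np.random.default_rng(child)
        tab = simulate_hybrid(scenario, config, y0=y0, rng=rng)
        x = tab[observable].to_numpy()
        hit = np.nonzero(x > eff if direction == "up" else x < eff)[0]
        if len(hit):
            events.append(float(tab["time"].iloc[hit[0]]))
        else:
            censored.append(float(tab["time"].iloc[-1]))
    return np.array(events), np.array(censored)


def estimate_rate(events: np.ndarray, censored: np.ndarray,
                  from_state: str, to_state: str,
                  conf: float = 0.95) -> TransitionRateEstimate:
    """Exponential-rate MLE with exact Poisson confidence bounds.

    ``rate = n_events / total_observed_time``; with zero events the point
    estimate is 0 and only the one-sided upper bound is reported (flagged).
    """
    n = len(events)
    total = float(np.sum(events) + np.sum(censored))
    if total <= 0:
        raise ValueError("no observation time")
    alpha = 1.0 - conf
    if n == 0:
        upper = chi2.ppf(1.0 - alpha, 2) / (2.0 * total)
        return TransitionRateEstimate(from_state, to_state, 0.0, 0.0,
                                      float(upper), 0, total, flagged=True)
    rate = n / total
    lo = chi2.ppf(alpha / 2.0, 2 * n) / (2.0 * total)
    hi = chi2.ppf(1.0 - alpha / 2.0, 2 * n + 2) / (2.0 * total)
    return TransitionRateEstimate(from_state, to_state, float(rate),
                                  float(lo), float(hi), n, total)


def estimate_transition_rates(
    scenario: Scenario,
    config: StochasticConfig,
    threshold: float,
    start_low: bool = True,
    y0: np.ndarray | None = None,
) -> list[TransitionRateEstimate]:
    """Punisher transition-rate estimates for one genetic state.

    Runs the ensemble from the low (or high) state and summarizes the
    observed first-passage times into L->H (or H->L) exponential rates.
    """
    if start_low:
        ev, cen = first_passage_times(scenario, config, threshold, "up", y0=y0)
        return [estimate_rate(ev, cen, "L", "H")]
    ev, cen = first_passage_times(scenario, config, threshold, "down", y0=y0)
    return [estimate_rate(ev, cen, "H", "L")]


# ---------------------------------------------------------------------------
# telegraph benchmark (synthetic two-state generator)
# ---------------------------------------------------------------------------

def telegraph_simulate(k_on: float, k_off: float, horizon: float,
                       seed: int = 0) -> pd.DataFrame:
    """Exact simulation of a two-state telegraph process (synthetic
    benchmark with known ground-truth rates).

    State flips 0 -> 1 at ``k_on`` and 1 -> 0 at ``k_off``; returns the
    jump times and the state entered at each jump.
    """
    if k_on <= 0 or k_off <= 0 or horizon <= 0:
        raise ValueError("rates and horizon must be positive")
    rng = np.random.default_rng(seed)
    t, state = 0.0, 0
    times, states = [0.0], [0]
    while True:
        rate = k_on if state == 0 else k_off
        t += rng.exponential(1.0 / rate)
        if t >= horizon:
            break
        state = 1 - state
        times.append(t)
        states.append(state)
    return pd.DataFrame({"time": times, "state": states})


def telegraph_estimate(traj: pd.DataFrame, horizon: float) -> tuple[float, float]:
    """Recover (k_on, k_off) from a telegraph trajectory via dwell-time
    totals: each rate is (number of exits)/(total time spent in the state)."""
    times = traj["time"].to_numpy()
    states = traj["state"].to_numpy()
    bounds = np.concatenate([times, [horizon]])
    dwell = np.diff(bounds)
    time0 = float(dwell[states == 0].sum())
    time1 = float(dwell[states == 1].sum())
    exits0 = int(np.sum(states[:-1] == 0)) if len(states) > 1 else 0
    exits1 = int(np.sum(states[:-1] == 1)) if len(states) > 1 else 0
    if time0 <= 0 or time1 <= 0:
        raise ValueError("trajectory never visited both states")
    return exits0 / time0, exits1 / time1
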