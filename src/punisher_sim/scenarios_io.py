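"""Parameter registry, scenario configuration and fixture generators.

The packaged registry (``data/params.yaml``) holds every model parameter
keyed by its conventional symbol name.  Scenario configuration files are
small YAML documents naming a circuit topology plus optional symbol
overrides, mutation events, inducer pulses and simulation controls;
:func:`load_config` validates them against the registry (unknown symbols
are rejected by name).
"""

from __future__ import annotations

import copy
import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import yaml

from .circuits import (
    GeneSpec,
    InducerPulse,
    MutationEvent,
    PunisherParams,
    RepressionHill,
    Scenario,
    SelfActivatingHill,
    TOPOLOGIES,
)
from .host_cell import HostParams

__all__ = [
    "load_registry", "host_params", "punisher_params", "gene_spec",
    "build_scenario", "ScenarioConfig", "load_config", "dump_config",
    "make_fixture", "FIXTURES", "cat_k_from_association_rate",
]


def load_registry(path: str | Path | None = None) -> dict:
    """Load the parameter registry (packaged default or a user file)."""
    if path is None:
        text = importlib.resources.files("punisher_sim").joinpath("data/params.yaml").read_text()
    else:
        text = Path(path).read_text()
    reg = yaml.safe_load(text)
    for section in ("host", "punisher", "genes"):
        if section not in reg:
            raise ValueError(f"registry missing section {section!r}")
    return reg


def host_params(registry: dict, overrides: dict[str, float] | None = None) -> HostParams:
    vals = dict(registry["host"])
    for key, v in (overrides or {}).items():
        if key in vals:
            vals[key] = v
    return HostParams(**vals)


def punisher_params(registry: dict, overrides: dict[str, float] | None = None) -> PunisherParams:
    vals = dict(registry["punisher"])
    for key, v in (overrides or {}).items():
        if key in vals:
            vals[key] = v
    return PunisherParams(**vals)


def gene_spec(registry: dict, name: str, **extra: Any) -> GeneSpec:
    vals = dict(registry["genes"][name])
    vals.update(extra)
    return GeneSpec(name=name, **vals)


def cat_k_from_association_rate(registry: dict, k_plus: float) -> float:
    """Convert a CAT RBS association rate (1/(nM h)) into the effective
    mRNA-ribosome dissociation constant used by the competition model.

    The RBS site is cleared either by unbinding (``k_off``) or by the
    initiated ribosome moving away (at roughly ``eps_ref/n_cat``), so
    ``k = (k_off + eps_ref/n_cat) / k_plus``.
    """
    co = registry["coexpression"]
    n_cat = registry["genes"]["cat"]["n"]
    if k_plus <= 0:
        raise ValueError("k_cat_plus must be positive")
    return (co["k_off"] + co["eps_ref"] / n_cat) / k_plus


# ---------------------------------------------------------------------------
# symbol-addressed overrides
# ---------------------------------------------------------------------------

_HOST_KEYS = ("c_a", "alpha_a", "n_a", "beta_a", "k_a", "c_r", "alpha_r", "n_r",
              "beta_r", "k_r", "phi_q", "M", "K_D", "sigma", "eps_max", "K_eps",
              "nu_max", "K_nu", "psi_max", "tau_ppgpp")
_PUNISHER_KEYS = ("I", "eta_s", "K_s", "F_sb", "K_bI", "k_sx_plus", "k_sx_minus",
                  "k_conf", "K_C", "kappa", "h_ext")
_GENE_FIELDS = ("c", "alpha", "n", "beta", "k", "delta")


def apply_overrides(registry: dict, overrides: dict[str, float]) -> dict:
    """Return a deep-copied registry with symbol-named overrides applied.

    Recognized symbols: host parameters (``alpha_a`` ...), Punisher
    parameters (``I``, ``K_s`` ...), per-gene parameters ``<field>_<gene>``
    (e.g. ``alpha_b``, ``c_s``), the linked pair ``c_si`` (sets the switch
    and integrase DNA concentration together), ``k_cat_plus`` and
    ``mu``/``t_cult``/``sigma``-style section scalars.  Unknown symbols
    raise ``KeyError`` naming the offending symbol.
    """
    reg = copy.deepcopy(registry)
    for sym, val in overrides.items():
        if sym in _HOST_KEYS:
            reg["host"][sym] = val
        elif sym in _PUNISHER_KEYS:
            reg["punisher"][sym] = val
        elif sym == "c_si":
            reg["genes"]["s"]["c"] = val
            reg["genes"]["i"]["c"] = val
        elif sym == "k_cat_plus":
            reg["coexpression"]["k_cat_plus"] = val
        elif sym in ("mu", "t_cult", "n_cells"):
            reg["population"][sym] = val
        elif sym in ("F_b_toggle", "eta_toggle", "K_toggle", "I_toggles"):
            key = {"F_b_toggle": "F_b", "eta_toggle": "eta",
                   "K_toggle": "K", "I_toggles": "I_toggles"}[sym]
            reg["toggle_regulation"][key] = val
        elif "_" in sym:
            fld, _, gene = sym.partition("_")
            if fld in _GENE_FIELDS and gene in reg["genes"]:
                reg["genes"][gene][fld] = val
            else:
                raise KeyError(f"unknown parameter symbol {sym!r}")
        else:
            raise KeyError(f"unknown parameter symbol {sym!r}")
    return reg


# ---------------------------------------------------------------------------
# topology assembly
# ---------------------------------------------------------------------------

def _punisher_genes(reg: dict) -> list[GeneSpec]:
    pp = reg["punisher"]
    s = gene_spec(reg, "s", regulation=SelfActivatingHill(
        F_b=pp["F_sb"], eta=pp["eta_s"], K=pp["K_s"]))
    i = gene_spec(reg, "i", transcript_of="s")
    prot = gene_spec(reg, "prot")
    cat = gene_spec(reg, "cat", uses_dna_state=True)
    return [s, i, prot, cat]


def _toggle_genes(reg: dict) -> list[GeneSpec]:
    tr = reg["toggle_regulation"]
    pairs = [("t11", "t12"), ("t21", "t22")]
    out = []
    for g1, g2 in pairs:
        out.append(gene_spec(reg, g1, regulation=RepressionHill(
            repressor=g2, F_b=tr["F_b"], eta=tr["eta"], K=tr["K"])))
        out.append(gene_spec(reg, g2, regulation=RepressionHill(
            repressor=g1, F_b=tr["F_b"], eta=tr["eta"], K=tr["K"])))
    return out


def build_scenario(
    topology_name: str,
    host: HostParams | None,
    registry: dict,
    overrides: dict[str, float] | None = None,
    mutations: Sequence[MutationEvent] = (),
    pulses: Sequence[InducerPulse] = (),
) -> Scenario:
    """Assemble a named circuit topology into a ready-to-integrate Scenario."""
    if topology_name not in TOPOLOGIES:
        raise ValueError(f"unknown topology {topology_name!r}; known: {TOPOLOGIES}")
    reg = apply_overrides(registry, overrides or {})
    if host is None:
        host = host_params(reg)
    pp = punisher_params(reg)

    genes: list[GeneSpec] = []
    punisher: PunisherParams | None = None

    if topology_name == "host_only":
        punisher = None
    elif topology_name == "single_burdensome_gene_with_punisher":
        genes = [gene_spec(reg, "b")] + _punisher_genes(reg)
        punisher = pp
    elif topology_name == "burdensome_gene_no_punisher":
        # control: burdensome and CAT genes only, chloramphenicol still present
        genes = [gene_spec(reg, "b"), gene_spec(reg, "cat", uses_dna_state=True)]
        punisher = pp
    elif topology_name == "two_toggles_with_punisher":
        reg2 = apply_overrides(reg, {"I": reg["toggle_regulation"]["I_toggles"]})
        pp = punisher_params(reg2)
        genes = _toggle_genes(reg2) + _punisher_genes(reg2)
        punisher = pp
    elif topology_name == "two_toggles_no_punisher":
        genes = _toggle_genes(reg) + [gene_spec(reg, "cat", uses_dna_state=True)]
        punisher = pp
    elif topology_name == "two_toggles_cat_coexpression":
        genes = list(_toggle_genes(reg))
        k_cat = cat_k_from_association_rate(reg, reg["coexpression"]["k_cat_plus"])
        for carrier in ("t11", "t12", "t21", "t22"):
            genes.append(_renamed_cat(reg, carrier, k_cat))
        punisher = pp

    seeds: dict[str, float] = {}
    if topology_name.startswith("two_toggles"):
        # break each toggle's symmetry: first gene of each pair starts ON
        seeds = {"t11": 5.0e4, "t21": 5.0e4}
    sc = Scenario(
        name=topology_name, host=host, genes=genes, punisher=punisher,
        mutations=list(mutations), pulses=list(pulses), initial_proteins=seeds,
    )
    return sc


def _renamed_cat(reg: dict, carrier: str, k_cat: float) -> GeneSpec:
    vals = dict(reg["genes"]["cat"])
    vals["k"] = k_cat
    return GeneSpec(name=f"cat_{carrier}", transcript_of=carrier, **vals)


def toggle_on_state_seed(scenario: Scenario, on_genes: Sequence[str] = ("t11", "t21"),
                         level: float = 5.0e4) -> dict[str, float]:
    """Initial protein seeds that place each toggle in a definite state."""
    return {g: level for g in on_genes if g in {x.name for x in scenario.genes}}


# ---------------------------------------------------------------------------
# essential-gene co-expression comparison (CAT RBS-strength scan)
# ---------------------------------------------------------------------------

#: symmetry-reduced set of mutant combinations of the four toggle genes
COEXPRESSION_MUTANT_COMBOS = (
    ("t11",),                       # one gene of one toggle
    ("t11", "t12"),                 # a whole toggle
    ("t11", "t21"),                 # one gene of each toggle
    ("t11", "t12", "t21"),          # a toggle plus one further gene
    ("t11", "t12", "t21", "t22"),   # all synthetic circuitry
)


def coexpression_relative_growth(registry: dict, k_plus: float,
                                 combos=COEXPRESSION_MUTANT_COMBOS,
                                 horizon: float = 50.0) -> dict:
    """Steady-state growth of every mutant combination relative to the
    unmutated cell, for one CAT RBS association rate ``k_plus``.

    In the co-expression strategy each toggle gene's transcript carries a
    CAT cistron, so losing toggle genes also removes CAT dosage; whether a
    mutant outgrows the original depends on the balance between freed
    translational resources and lost chloramphenicol protection.
    """
    from .circuits import steady_state

    sc = build_scenario("two_toggles_cat_coexpression", None, registry,
                        overrides={"k_cat_plus": k_plus})
    _, rates0, _ = steady_state(sc, horizon=horizon)
    out = {"k_plus": k_plus, "lam_unmutated": rates0.lam}
    rel = {}
    for combo in combos:
        mut = sc.with_genes_mutated(combo)
        _, rates, _ = steady_state(mut, horizon=horizon)
        rel["+".join(combo)] = rates.lam / rates0.lam
    out["relative_growth"] = rel
    out["max_relative_growth"] = max(rel.values())
    out["acceptable"] = out["max_relative_growth"] <= 1.0
    return out


def coexpression_window(registry: dict, k_min: float = 0.24, k_max: float = 60.0,
                        n_grid: int = 20, refine: int = 4,
                        horizon: float = 50.0) -> dict:
    """Locate the CAT RBS-strength window in which no mutant combination
    outgrows the unmutated cell.

    A ~``n_grid``-point log scan brackets the acceptable region's
    boundaries, which are then sharpened by ``refine`` bisection steps in
    log space.  Returns the scan rows plus ``(k_low, k_high)`` (NaN if the
    region is empty or open at the scan edge).
    """
    import numpy as np

    grid = np.geomspace(k_min, k_max, n_grid)
    rows = [coexpression_relative_growth(registry, k, horizon=horizon)
            for k in grid]
    acc = np.array([r["acceptable"] for r in rows])
    result = {"rows": rows, "k_low": float("nan"), "k_high": float("nan")}
    if not acc.any():
        return result

    def bisect(k_bad, k_good):
        for _ in range(refine):
            mid = float(np.sqrt(k_bad * k_good))
            if coexpression_relative_growth(registry, mid, horizon=horizon)["acceptable"]:
                k_good = mid
            else:
                k_bad = mid
        return float(np.sqrt(k_bad * k_good))

    first = int(np.argmax(acc))
    last = int(len(acc) - 1 - np.argmax(acc[::-1]))
    if first > 0:
        result["k_low"] = bisect(grid[first - 1], grid[first])
    elif acc[0]:
        result["k_low"] = float(grid[0])
    if last < len(acc) - 1:
        result["k_high"] = bisect(grid[last + 1], grid[last])
    elif acc[-1]:
        result["k_high"] = float(grid[-1])
    return result


# ---------------------------------------------------------------------------
# scenario configuration files
# ---------------------------------------------------------------------------

@dataclass
class ScenarioConfig:
    """Validated scenario configuration."""

    topology: str
    overrides: dict[str, float] = field(default_factory=dict)
    mutations: list[MutationEvent] = field(default_factory=list)
    pulses: list[InducerPulse] = field(default_factory=list)
    horizon: float = 50.0
    rtol: float = 1e-8
    seed: int = 0
    n_samples: int = 400
    output_dir: str = "runs"
    schema_version: int = 1

    def normalized(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "topology": self.topology,
            "overrides": dict(self.overrides),
            "mutations": [{"time": m.time, "genes": list(m.genes)} for m in self.mutations],
            "pulses": [{"start": p.start, "duration": p.duration,
                        "target": p.target, "level": p.level} for p in self.pulses],
            "simulation": {"horizon": self.horizon, "rtol": self.rtol,
                           "seed": self.seed, "n_samples": self.n_samples},
            "output_dir": self.output_dir,
        }


_TOP_KEYS = {"schema_version", "topology", "overrides", "mutations", "pulses",
             "simulation", "output_dir"}
_SIM_KEYS = {"horizon", "rtol", "seed", "n_samples"}


def load_config(path: str | Path, registry: dict | None = None) -> ScenarioConfig:
    """Parse and validate a scenario YAML file.

    Unknown top-level keys, unknown topology names and unknown override
    symbols each raise ``ValueError`` naming the offending field.
    """
    raw = yaml.safe_load(Path(path).read_text())
    return parse_config(raw, registry=registry)


def parse_config(raw: dict, registry: dict | None = None) -> ScenarioConfig:
    if registry is None:
        registry = load_registry()
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    topology = raw.get("topology")
    if topology not in TOPOLOGIES:
        raise ValueError(f"unknown or missing topology {topology!r}")
    overrides = dict(raw.get("overrides") or {})
    # validation pass: apply_overrides raises KeyError naming bad symbols
    try:
        apply_overrides(registry, overrides)
    except KeyError as e:
        raise ValueError(f"invalid override: {e.args[0]}") from e
    mutations = [MutationEvent(time=float(m["time"]), genes=tuple(m["genes"]))
                 for m in (raw.get("mutations") or [])]
    if any(m.time < 0 for m in mutations):
        raise ValueError("mutation times must be >= 0")
    if [m.time for m in mutations] != sorted(m.time for m in mutations):
        raise ValueError("mutation events must be time-ordered")
    pulses = [InducerPulse(start=float(p["start"]), duration=float(p["duration"]),
                           target=str(p["target"]), level=float(p.get("level", 1.0)))
              for p in (raw.get("pulses") or [])]
    sim = dict(raw.get("simulation") or {})
    unknown_sim = set(sim) - _SIM_KEYS
    if unknown_sim:
        raise ValueError(f"unknown simulation keys: {sorted(unknown_sim)}")
    return ScenarioConfig(
        topology=topology, overrides=overrides, mutations=mutations, pulses=pulses,
        horizon=float(sim.get("horizon", 50.0)), rtol=float(sim.get("rtol", 1e-8)),
        seed=int(sim.get("seed", 0)), n_samples=int(sim.get("n_samples", 400)),
        output_dir=str(raw.get("output_dir", "runs")),
        schema_version=int(raw.get("schema_version", 1)),
    )


def dump_config(cfg: ScenarioConfig, path: str | Path | None = None) -> str:
    text = yaml.safe_dump(cfg.normalized(), sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# fixtures: the named experiments
# ---------------------------------------------------------------------------

FIXTURES = (
    "fig1_single_gene",
    "fig3_two_toggles",
    "fig3_flip_pulse",
    "fig4_coexpression",
    "fig5_population",
    "telegraph_benchmark",
)


def make_fixture(name: str, registry: dict | None = None) -> dict:
    """Return a self-contained named experiment: a ScenarioConfig (or plain
    parameter bundle for non-ODE fixtures) plus the qualitative assertions
    its test exercises."""
    reg = registry or load_registry()
    if name == "fig1_single_gene":
        cfg = ScenarioConfig(
            topology="single_burdensome_gene_with_punisher",
            mutations=[MutationEvent(time=25.0, genes=("b",))],
            horizon=50.0,
        )
        return {"config": cfg, "expect": {
            "lam_rises_after_mutation": True,
            "lam_collapses_below_premutation": True,
            "no_recovery": True,
        }}
    if name == "fig3_two_toggles":
        cfg = ScenarioConfig(
            topology="two_toggles_with_punisher",
            mutations=[MutationEvent(time=30.0, genes=("t11", "t12"))],
            horizon=60.0,
        )
        return {"config": cfg, "expect": {"punisher_triggers": True}}
    if name == "fig3_flip_pulse":
        cfg = ScenarioConfig(
            topology="two_toggles_with_punisher",
            pulses=[InducerPulse(start=30.0, duration=1.0, target="t11", level=1.0),
                    InducerPulse(start=30.0, duration=1.0, target="t21", level=1.0)],
            horizon=60.0,
        )
        return {"config": cfg, "expect": {"cat_retained_within_1pct": True}}
    if name == "fig4_coexpression":
        co = reg["coexpression"]
        return {"scan_range": (co["scan_min"], co["scan_max"]),
                "topology": "two_toggles_cat_coexpression",
                "expect": {"some_mutant_outgrows_original_somewhere": True,
                           "punisher_never_rewards_mutation": True}}
    if name == "fig5_population":
        pop = reg["population"]
        return {"mu": pop["mu"], "t_cult": pop["t_cult"], "n_cells": pop["n_cells"],
                "expect": {"tau_ratio_above_1": True}}
    if name == "telegraph_benchmark":
        return {"k_on": 0.5, "k_off": 2.0, "horizon": 1500.0, "seed": 42,
                "expect": {"recovery_within_20pct": True}}
    raise ValueError(f"unknown fixture {name!r}; known: {FIXTURES}")
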