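"""Named model variants and the suite runner.

Every variant the analysis explores — dispersal removal, single-mechanism
runs, halved/doubled rate constants, scaled carrier sources, relaxed
recruitment rules — is expressed as a :class:`Scenario`: a named bundle of
parameter overrides (absolute or multiplicative) and configuration-flag
overrides applied to a baseline.  The registry covers the built-in variants;
arbitrary sweeps are expressible with the same override mechanism.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

from .config import ModelConfig, ParameterSet
from .distributions import (AggregateDistribution, BreakdownTable,
                            ExponentialFit, fit_exponential, mechanism_shares,
                            percentage_breakdown, size_distribution)
from .network import CELL, DISPERSED
from .simulate import SolverError, Trajectory, integrate


@dataclass(frozen=True)
class Override:
    """``set`` replaces a field; ``scale`` multiplies it."""

    op: str
    value: float

    def apply(self, current: float) -> float:
        if self.op == "set":
            return self.value
        if self.op == "scale":
            return current * self.value
        raise ValueError(f"unknown override op {self.op!r}")


@dataclass(frozen=True)
class Scenario:
    name: str
    param_overrides: dict[str, Override] = field(default_factory=dict)
    config_overrides: dict[str, object] = field(default_factory=dict)


_RATE_FIELD = {"multimerisation": "k_mult", "hspg": "k_hspg", "lipoprotein": "k_lipo"}
_SOURCE_FIELD = {"hspg": "r_H", "lipoprotein": "r_L"}


def rate_scale(mechanism: str, factor: float) -> Scenario:
    """Scale one mechanism's rate constant (the sensitivity sweeps)."""
    fld = _RATE_FIELD[mechanism]
    tag = {0.5: "half", 2.0: "double"}.get(factor, f"x{factor:g}")
    return Scenario(f"rate_{tag}_{mechanism}", {fld: Override("scale", factor)})


def source_scale(carrier: str, factor: float) -> Scenario:
    """Scale a carrier:monomer source ratio."""
    return Scenario(f"source_x{factor:g}_{carrier}",
                    {_SOURCE_FIELD[carrier]: Override("scale", factor)})


def builtin_scenarios() -> dict[str, Scenario]:
    """Registry of the named variants used throughout the analysis."""
    zero_disp = {f: Override("set", 0.0)
                 for f in ("d_monomer", "d_multimer", "d_hspg", "d_lipo")}
    reg = {
        "baseline": Scenario("baseline"),
        "no_dispersal": Scenario("no_dispersal", dict(zero_disp)),
        "no_monomer_dispersal": Scenario("no_monomer_dispersal",
                                         {"d_monomer": Override("set", 0.0)}),
        # single-mechanism runs; "only" refers to the carrier mechanisms, so
        # hspg_only keeps multimerisation (HSPGs can only recruit multimers)
        "multimer_only": Scenario(
            "multimer_only",
            {"r_H": Override("set", 0.0), "r_L": Override("set", 0.0)},
            {"mechanisms_enabled": frozenset({"multimerisation"})}),
        "hspg_only": Scenario(
            "hspg_only", {"r_L": Override("set", 0.0)},
            {"mechanisms_enabled": frozenset({"multimerisation", "hspg"})}),
        "lipo_only": Scenario(
            "lipo_only", {"r_H": Override("set", 0.0)},
            {"mechanisms_enabled": frozenset({"lipoprotein"})}),
        # relaxed recruitment rules
        "lipo_recruits_multimers": Scenario("lipo_recruits_multimers", {},
                                            {"lipo_recruit_max": 5}),
        "hspg_recruits_monomers": Scenario("hspg_recruits_monomers", {},
                                           {"hspg_recruits_monomers": True}),
    }
    for mech in _RATE_FIELD:
        for factor in (0.5, 2.0):
            sc = rate_scale(mech, factor)
            reg[sc.name] = sc
    return reg


def get_scenario(name: str) -> Scenario:
    reg = builtin_scenarios()
    if name not in reg:
        raise KeyError(f"unknown scenario {name!r}; known: {sorted(reg)}")
    return reg[name]


def apply_scenario(base_config: ModelConfig, base_params: ParameterSet,
                   scenario: Scenario) -> tuple[ModelConfig, ParameterSet]:
    """Return transformed copies of the baseline; the baseline is untouched."""
    param_fields = {f.name for f in dataclasses.fields(ParameterSet)}
    config_fields = {f.name for f in dataclasses.fields(ModelConfig)}
    changes: dict[str, float] = {}
    for fld, ov in scenario.param_overrides.items():
        if fld not in param_fields:
            raise KeyError(f"scenario {scenario.name!r}: unknown parameter field {fld!r}")
        changes[fld] = ov.apply(getattr(base_params, fld))
    params = dataclasses.replace(base_params, **changes)
    for fld in scenario.config_overrides:
        if fld not in config_fields:
            raise KeyError(f"scenario {scenario.name!r}: unknown config field {fld!r}")
    config = dataclasses.replace(base_config, **scenario.config_overrides)
    return config, params


@dataclass
class ScenarioReport:
    """Results of one scenario run at the reporting time."""

    scenario: Scenario
    trajectory: Trajectory | None
    cell_distribution: AggregateDistribution | None
    cell_breakdown: BreakdownTable | None
    dispersed_breakdown: BreakdownTable | None
    fit: ExponentialFit | None
    shares: dict[str, float] | None
    error: str | None = None


def run_scenario(config: ModelConfig, params: ParameterSet, scenario: Scenario,
                 t_end: float = 24 * 60.0, **integrate_kw) -> ScenarioReport:
    cfg, par = apply_scenario(config, params, scenario)
    traj = integrate(cfg, par, t_end, **integrate_kw)
    state = traj.snapshot(t_end)
    cell = size_distribution(state, traj.index, CELL, time=t_end)
    dispersed = size_distribution(state, traj.index, DISPERSED, time=t_end)
    fit = fit_exponential(cell)
    # a dispersal-free variant legitimately leaves the dispersed pool empty
    disp_table = (percentage_breakdown(dispersed)
                  if dispersed.total_entities() > 0 else None)
    return ScenarioReport(scenario, traj, cell, percentage_breakdown(cell),
                          disp_table, fit, mechanism_shares(cell))


def run_scenario_suite(config: ModelConfig, params: ParameterSet,
                       scenarios: list[Scenario], t_end: float = 24 * 60.0,
                       **integrate_kw) -> dict[str, ScenarioReport]:
    """Run scenarios in the given order; solver failures do not abort the suite."""
    reports: dict[str, ScenarioReport] = {}
    for sc in scenarios:
        if sc.name in reports:
            raise ValueError(f"duplicate scenario name {sc.name!r}")
        try:
            reports[sc.name] = run_scenario(config, params, sc, t_end, **integrate_kw)
        except (SolverError, ValueError) as exc:
            reports[sc.name] = ScenarioReport(sc, None, None, None, None, None,
                                              None, error=str(exc))
    return reports
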