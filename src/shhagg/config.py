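"""Model structure and parameter containers.

The model tracks sonic hedgehog (Shh) aggregates forming on the surface of a
single producing cell through three mechanisms — pairwise multimerisation,
recruitment of small multimers by heparan sulfate proteoglycans (HSPGs), and
one-at-a-time monomer recruitment by lipoproteins — together with first-order
dispersal of every cell-associated species into an inert "dispersed" pool.

:class:`ModelConfig` describes the structure of the reaction network (size
caps, recruitment windows, mechanism/variant switches); :class:`ParameterSet`
holds the kinetic constants.  Both serialise to/from a flat key-value mapping
(YAML or JSON) whose keys are exactly the dataclass field names.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

#: The three aggregate-forming mechanisms.
MECHANISMS = frozenset({"multimerisation", "hspg", "lipoprotein"})

#: Species classes used for dispersal switches.  "monomer" is free Shh (size
#: 1), "multimer" is a free aggregate of size >= 2, "hspg"/"lipo" are
#: carrier-bound aggregates including empty carriers.
SPECIES_CLASSES = ("monomer", "multimer", "hspg", "lipo")


def _default_dispersal() -> dict[str, bool]:
    return {c: True for c in SPECIES_CLASSES}


@dataclass(frozen=True)
class ModelConfig:
    """Structural description of the aggregation reaction network.

    Parameters
    ----------
    max_size:
        Largest number of Shh monomers an aggregate may contain.  Sizes above
        ``max_size`` cannot form: reactions that would exceed the cap are
        omitted, so the boundary size is absorbing.
    report_size:
        Largest size reported individually in distributions; larger aggregates
        are pooled into a single ``>report_size`` overflow bucket.
    hspg_recruit_min, hspg_recruit_max:
        Window of free-multimer sizes an HSPG may recruit.  The default
        window 2..10 encodes that HSPGs bind small multimers but not
        monomers.
    lipo_recruit_max:
        Largest free multimer a lipoprotein may recruit (1 = monomers only;
        the relaxed variant uses 5).
    hspg_recruits_monomers:
        Variant switch allowing HSPGs to recruit free monomers (lowers the
        effective recruitment window minimum to 1).
    hspg_capacity:
        Optional cap on the total Shh bound to one HSPG (``None`` =
        unbounded up to ``max_size``).
    mechanisms_enabled:
        Subset of :data:`MECHANISMS` that is active.
    dispersal_enabled:
        Per-species-class switches for first-order dispersal
        (keys :data:`SPECIES_CLASSES`).
    free_carriers_disperse:
        Whether empty HSPGs / lipoproteins also disperse.
    """

    max_size: int = 200
    report_size: int = 40
    hspg_recruit_min: int = 2
    hspg_recruit_max: int = 10
    lipo_recruit_max: int = 1
    hspg_recruits_monomers: bool = False
    hspg_capacity: int | None = None
    mechanisms_enabled: frozenset[str] = MECHANISMS
    dispersal_enabled: Mapping[str, bool] = field(default_factory=_default_dispersal)
    free_carriers_disperse: bool = True

    def __post_init__(self) -> None:
        if self.max_size < 2:
            raise ValueError(f"max_size must be >= 2, got {self.max_size}")
        if not 1 <= self.report_size <= self.max_size:
            raise ValueError("report_size must lie in [1, max_size]")
        # the recruitment window is implicitly capped by the largest aggregate
        if self.hspg_recruit_max > self.max_size:
            object.__setattr__(self, "hspg_recruit_max", self.max_size)
        if self.lipo_recruit_max > self.max_size:
            object.__setattr__(self, "lipo_recruit_max", self.max_size)
        lo = self.effective_hspg_min
        if not lo <= self.hspg_recruit_max <= self.max_size:
            raise ValueError(
                "require hspg_recruit_min <= hspg_recruit_max <= max_size"
            )
        if lo < 1 or (not self.hspg_recruits_monomers and self.hspg_recruit_min < 2):
            raise ValueError("hspg_recruit_min must be >= 2 unless monomer recruitment is on")
        if not 1 <= self.lipo_recruit_max <= self.max_size:
            raise ValueError("lipo_recruit_max must lie in [1, max_size]")
        if self.hspg_capacity is not None and self.hspg_capacity < lo:
            raise ValueError("hspg_capacity below the recruitment window minimum")
        unknown = set(self.mechanisms_enabled) - MECHANISMS
        if unknown:
            raise ValueError(f"unknown mechanisms: {sorted(unknown)}")
        object.__setattr__(self, "mechanisms_enabled", frozenset(self.mechanisms_enabled))
        disp = dict(_default_dispersal(), **dict(self.dispersal_enabled))
        if set(disp) != set(SPECIES_CLASSES):
            raise ValueError(f"dispersal_enabled keys must be {SPECIES_CLASSES}")
        object.__setattr__(self, "dispersal_enabled", disp)

    @property
    def effective_hspg_min(self) -> int:
        """Smallest multimer an HSPG may recruit (1 in the monomer variant)."""
        return 1 if self.hspg_recruits_monomers else self.hspg_recruit_min

    @property
    def hspg_size_cap(self) -> int:
        """Largest total Shh load of a single HSPG."""
        if self.hspg_capacity is None:
            return self.max_size
        return min(self.hspg_capacity, self.max_size)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["mechanisms_enabled"] = sorted(self.mechanisms_enabled)
        return d

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "ModelConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs = {k: v for k, v in data.items() if k in known}
        if "mechanisms_enabled" in kwargs:
            kwargs["mechanisms_enabled"] = frozenset(kwargs["mechanisms_enabled"])
        return cls(**kwargs)


@dataclass(frozen=True)
class ParameterSet:
    """Kinetic parameters, on molecule counts per cell and minutes.

    The model is deterministic and counts molecules per cell, so
    second-order rate constants carry units count^-1 min^-1 and dispersal
    rates min^-1.  Within each mechanism the rate constant is the same for
    every aggregate size.

    ``s_M`` (800 Shh per cell per minute) is literature-informed.  ``r_H``
    and ``r_L`` are the carrier:monomer source ratios (the carrier sources
    are ``s_H = r_H * s_M`` and ``s_L = r_L * s_M``).  Their defaults encode
    one HSPG per 25 monomers and one lipoprotein per 19.2 monomers: a Shh
    mass budget shows the carriers must be the scarcer species — 800 Shh/min
    shared over >15,000 carriers/min could never load lipoproteins to the
    several-Shh mean loads the distributions display.  The rate constants
    and dispersal rates default to the values obtained by this package's
    calibration procedure (see docs/methods.md) and can be overridden
    freely.
    """

    s_M: float = 800.0          # monomer production, count/min
    r_H: float = 1.0 / 25.0     # HSPG : monomer source ratio (1 per 25 Shh)
    r_L: float = 1.0 / 19.2     # lipoprotein : monomer source ratio
    k_mult: float = 3.54e-6     # multimerisation, count^-1 min^-1
    k_hspg: float = 5.77e-7     # HSPG recruitment, count^-1 min^-1
    k_lipo: float = 1.52e-6     # lipoprotein recruitment, count^-1 min^-1
    d_monomer: float = 2.0e-3   # dispersal rates, min^-1
    d_multimer: float = 2.0e-3
    d_hspg: float = 2.0e-3
    d_lipo: float = 2.0e-3

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be >= 0")

    @property
    def s_H(self) -> float:
        """HSPG particle source, count/min."""
        return self.r_H * self.s_M

    @property
    def s_L(self) -> float:
        """Lipoprotein particle source, count/min."""
        return self.r_L * self.s_M

    def dispersal_rate(self, species_class: str) -> float:
        return {
            "monomer": self.d_monomer,
            "multimer": self.d_multimer,
            "hspg": self.d_hspg,
            "lipo": self.d_lipo,
        }[species_class]

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "ParameterSet":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: float(v) for k, v in data.items() if k in known})


def load_config_file(path: str | Path) -> tuple[ModelConfig, ParameterSet, dict[str, Any]]:
    """Read a flat YAML/JSON mapping into (ModelConfig, ParameterSet, extras).

    Keys matching :class:`ModelConfig` / :class:`ParameterSet` field names are
    consumed; any remaining keys (run-control options such as ``t_end`` or
    ``scenarios``) are returned untouched in ``extras``.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a flat key-value mapping")
    cfg_keys = {f.name for f in dataclasses.fields(ModelConfig)}
    par_keys = {f.name for f in dataclasses.fields(ParameterSet)}
    config = ModelConfig.from_dict({k: v for k, v in data.items() if k in cfg_keys})
    params = ParameterSet.from_dict({k: v for k, v in data.items() if k in par_keys})
    extras = {k: v for k, v in data.items() if k not in cfg_keys | par_keys}
    return config, params, extras


def save_config_file(config: ModelConfig, params: ParameterSet, path: str | Path,
                     extras: Mapping[str, Any] | None = None) -> None:
    """Write the flat key-value form of a configuration to YAML or JSON."""
    data: dict[str, Any] = {**config.to_dict(), **params.to_dict(), **(extras or {})}
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))
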