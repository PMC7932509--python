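"""Species enumeration and mass-action reaction network.

The state of the model is a vector of molecule counts over all species.  A
species is identified by its mechanism class (free multimer, HSPG-bound or
lipoprotein-bound aggregate), its total Shh load, and the pool it sits in
(cell surface or dispersed).  Dispersed species are inert: they take part in
no reaction, so the dispersed pool simply accumulates.

The right-hand side of the ODE system is compiled from the explicit reaction
inventory into sparse-matrix form, with an analytic Jacobian for use with
stiff implicit integrators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
from scipy import sparse

from .config import ModelConfig, ParameterSet

CELL = "cell"
DISPERSED = "dispersed"

FREE_MULTIMER = "free_multimer"
HSPG_BOUND = "hspg_bound"
LIPO_BOUND = "lipo_bound"


class Species(NamedTuple):
    """One chemical species: class, Shh load, and pool."""

    mechanism_class: str   # free_multimer | hspg_bound | lipo_bound
    shh_count: int         # total Shh monomers in the aggregate (0 = empty carrier)
    pool: str              # cell | dispersed

    def label(self) -> str:
        prefix = {FREE_MULTIMER: "M", HSPG_BOUND: "H", LIPO_BOUND: "L"}[self.mechanism_class]
        tag = "" if self.pool == CELL else "*"
        return f"{prefix}{self.shh_count}{tag}"

    @property
    def species_class(self) -> str:
        """Dispersal class: monomer, multimer, hspg or lipo."""
        if self.mechanism_class == FREE_MULTIMER:
            return "monomer" if self.shh_count == 1 else "multimer"
        return "hspg" if self.mechanism_class == HSPG_BOUND else "lipo"


@dataclass
class SpeciesIndex:
    """Ordered species list with a bidirectional species <-> position map."""

    config: ModelConfig
    species: list[Species]
    position: dict[Species, int] = field(init=False)
    shh_counts: np.ndarray = field(init=False)
    cell_mask: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.position = {s: i for i, s in enumerate(self.species)}
        if len(self.position) != len(self.species):
            raise ValueError("duplicate species in index")
        self.shh_counts = np.array([s.shh_count for s in self.species], dtype=float)
        self.cell_mask = np.array([s.pool == CELL for s in self.species])

    def __len__(self) -> int:
        return len(self.species)

    def idx(self, mechanism_class: str, shh_count: int, pool: str = CELL) -> int:
        return self.position[Species(mechanism_class, shh_count, pool)]

    def counts(self, state: np.ndarray, mechanism_class: str, pool: str) -> dict[int, float]:
        """Map Shh load -> count for one class/pool, from a state vector."""
        return {
            s.shh_count: float(state[i])
            for i, s in enumerate(self.species)
            if s.mechanism_class == mechanism_class and s.pool == pool
        }


def _hspg_sizes(config: ModelConfig) -> list[int]:
    return [0] + list(range(config.effective_hspg_min, config.hspg_size_cap + 1))


def enumerate_species(config: ModelConfig) -> SpeciesIndex:
    """Enumerate every species implied by a model configuration.

    Free multimers of sizes ``1..max_size`` always exist.  HSPG-bound species
    (the empty carrier plus loads from the recruitment-window minimum up to
    the capacity) exist iff the hspg mechanism is enabled; lipoprotein-bound
    species with loads ``0..max_size`` iff the lipoprotein mechanism is
    enabled.  Each cell species is mirrored in the dispersed pool, except
    that empty carriers are mirrored only when ``free_carriers_disperse``.
    """
    cell: list[Species] = [Species(FREE_MULTIMER, n, CELL) for n in range(1, config.max_size + 1)]
    if "hspg" in config.mechanisms_enabled:
        cell += [Species(HSPG_BOUND, j, CELL) for j in _hspg_sizes(config)]
    if "lipoprotein" in config.mechanisms_enabled:
        cell += [Species(LIPO_BOUND, k, CELL) for k in range(0, config.max_size + 1)]
    dispersed = [
        Species(s.mechanism_class, s.shh_count, DISPERSED)
        for s in cell
        if s.shh_count > 0 or config.free_carriers_disperse
    ]
    return SpeciesIndex(config, cell + dispersed)


@dataclass(frozen=True)
class Reaction:
    """One elementary reaction under the law of mass action.

    ``symmetry_factor`` is 1/2 for coagulation of identical partners (the
    standard Smoluchowski convention), 1 otherwise; the mass-action flux is
    ``rate_constant * symmetry_factor * product of reactant counts``.
    """

    reactants: tuple[Species, ...]
    products: tuple[Species, ...]
    rate_constant: float
    symmetry_factor: float = 1.0
    kind: str = ""

    @property
    def units(self) -> str:
        return {0: "count·min⁻¹", 1: "min⁻¹", 2: "count⁻¹·min⁻¹"}[len(self.reactants)]

    def format(self) -> str:
        lhs = " + ".join(s.label() for s in self.reactants) or "∅"
        rhs = " + ".join(s.label() for s in self.products)
        sym = "  ×1/2" if self.symmetry_factor == 0.5 else ""
        return f"{lhs} -> {rhs}   k={self.rate_constant:.6g} {self.units}{sym}  [{self.kind}]"


def reaction_inventory(config: ModelConfig, params: ParameterSet) -> list[Reaction]:
    """Build the complete reaction list for a configuration.

    Contains constant sources (monomers and, where enabled, free carriers),
    pairwise coagulation of free multimers, carrier recruitment of free
    multimers within each mechanism's size window, and first-order dispersal
    of cell species.  Bound aggregates never react with each other, dispersed
    species never react, and no reaction produces a load above ``max_size``
    (or the HSPG capacity), making the boundary sizes absorbing.
    """
    N = config.max_size
    rxns: list[Reaction] = []
    M = lambda n: Species(FREE_MULTIMER, n, CELL)  # noqa: E731
    H = lambda j: Species(HSPG_BOUND, j, CELL)     # noqa: E731
    L = lambda k: Species(LIPO_BOUND, k, CELL)     # noqa: E731

    # (i) constant sources
    rxns.append(Reaction((), (M(1),), params.s_M, kind="source"))
    if "hspg" in config.mechanisms_enabled:
        rxns.append(Reaction((), (H(0),), params.s_H, kind="source"))
    if "lipoprotein" in config.mechanisms_enabled:
        rxns.append(Reaction((), (L(0),), params.s_L, kind="source"))

    # (ii) pairwise coagulation of free multimers
    if "multimerisation" in config.mechanisms_enabled:
        for i in range(1, N // 2 + 1):
            for j in range(i, N - i + 1):
                rxns.append(Reaction(
                    (M(i), M(j)), (M(i + j),), params.k_mult,
                    symmetry_factor=0.5 if i == j else 1.0, kind="coagulation",
                ))

    # (iii) HSPG recruitment of free multimers within the size window
    if "hspg" in config.mechanisms_enabled:
        cap = config.hspg_size_cap
        window = range(config.effective_hspg_min, config.hspg_recruit_max + 1)
        hspg_sizes = set(_hspg_sizes(config))
        for j in sorted(hspg_sizes):
            for m in window:
                if j + m <= cap and (j + m) in hspg_sizes:
                    rxns.append(Reaction((H(j), M(m)), (H(j + m),), params.k_hspg,
                                         kind="hspg_recruit"))

    # (iv) lipoprotein recruitment of free multimers up to lipo_recruit_max
    if "lipoprotein" in config.mechanisms_enabled:
        for k in range(0, N):
            for m in range(1, config.lipo_recruit_max + 1):
                if k + m <= N:
                    rxns.append(Reaction((L(k), M(m)), (L(k + m),), params.k_lipo,
                                         kind="lipo_recruit"))

    # (v) first-order dispersal, cell -> dispersed, species unchanged
    index = enumerate_species(config)
    for s in index.species:
        if s.pool != CELL:
            continue
        if s.shh_count == 0 and not config.free_carriers_disperse:
            continue
        cls = s.species_class
        if not config.dispersal_enabled[cls]:
            continue
        rate = params.dispersal_rate(cls)
        if rate > 0:
            rxns.append(Reaction((s,), (Species(s.mechanism_class, s.shh_count, DISPERSED),),
                                 rate, kind="dispersal"))
    return rxns


def format_inventory(reactions: Iterable[Reaction]) -> str:
    """Human-readable audit listing, one reaction per line."""
    return "\n".join(r.format() for r in reactions)


class MassActionRHS:
    """Compiled derivative evaluator for a reaction inventory.

    Callable as ``rhs(t, y) -> dy/dt``; ``rhs.jac(t, y)`` returns the sparse
    analytic Jacobian.  Both are deterministic and side-effect-free.  The
    constant-source reactions give a fixed inflow vector, unimolecular
    reactions a constant sparse linear operator, and bimolecular reactions a
    stoichiometry matrix applied to the vector of mass-action fluxes.
    """

    def __init__(self, index: SpeciesIndex, reactions: list[Reaction]):
        self.index = index
        self.reactions = reactions
        n = len(index)
        self.n = n
        self.source = np.zeros(n)
        lin_rows: list[int] = []
        lin_cols: list[int] = []
        lin_vals: list[float] = []
        bi_a: list[int] = []
        bi_b: list[int] = []
        bi_k: list[float] = []
        st_rows: list[int] = []
        st_cols: list[int] = []
        st_vals: list[float] = []

        for rx in reactions:
            try:
                r_idx = [index.position[s] for s in rx.reactants]
                p_idx = [index.position[s] for s in rx.products]
            except KeyError as exc:  # pragma: no cover - config/index mismatch
                raise ValueError(f"reaction references unknown species: {exc}") from exc
            if len(r_idx) == 0:
                for p in p_idx:
                    self.source[p] += rx.rate_constant * rx.symmetry_factor
            elif len(r_idx) == 1:
                k = rx.rate_constant * rx.symmetry_factor
                a = r_idx[0]
                lin_rows.append(a); lin_cols.append(a); lin_vals.append(-k)
                for p in p_idx:
                    lin_rows.append(p); lin_cols.append(a); lin_vals.append(k)
            elif len(r_idx) == 2:
                r = len(bi_a)
                bi_a.append(r_idx[0])
                bi_b.append(r_idx[1])
                bi_k.append(rx.rate_constant * rx.symmetry_factor)
                for a in r_idx:
                    st_rows.append(a); st_cols.append(r); st_vals.append(-1.0)
                for p in p_idx:
                    st_rows.append(p); st_cols.append(r); st_vals.append(1.0)
            else:  # pragma: no cover
                raise ValueError("reactions with >2 reactants are not supported")

        self.linear = sparse.coo_matrix(
            (lin_vals, (lin_rows, lin_cols)), shape=(n, n)
        ).tocsr()
        self.n_bi = len(bi_a)
        self.bi_a = np.asarray(bi_a, dtype=np.intp)
        self.bi_b = np.asarray(bi_b, dtype=np.intp)
        self.bi_k = np.asarray(bi_k, dtype=float)
        self.stoich_bi = sparse.coo_matrix(
            (st_vals, (st_rows, st_cols)), shape=(n, self.n_bi)
        ).tocsr()

    def __call__(self, t: float, y: np.ndarray) -> np.ndarray:
        if y.shape[-1] != self.n:
            raise ValueError(f"state length {y.shape[-1]} != index size {self.n}")
        dy = self.source + self.linear @ y
        if self.n_bi:
            flux = self.bi_k * y[self.bi_a] * y[self.bi_b]
            dy = dy + self.stoich_bi @ flux
        return dy

    def jac(self, t: float, y: np.ndarray) -> sparse.csr_matrix:
        if self.n_bi == 0:
            return self.linear.copy()
        m = self.n_bi
        rows = np.concatenate([np.arange(m), np.arange(m)])
        cols = np.concatenate([self.bi_a, self.bi_b])
        data = np.concatenate([self.bi_k * y[self.bi_b], self.bi_k * y[self.bi_a]])
        dflux = sparse.coo_matrix((data, (rows, cols)), shape=(m, self.n)).tocsr()
        return self.linear + self.stoich_bi @ dflux


def build_rhs(config: ModelConfig, params: ParameterSet,
              index: SpeciesIndex | None = None) -> MassActionRHS:
    """Compile the mass-action derivative evaluator for a configuration."""
    if index is None:
        index = enumerate_species(config)
    return MassActionRHS(index, reaction_inventory(config, params))


def total_shh(state: np.ndarray, index: SpeciesIndex) -> float:
    """Total Shh monomer-equivalents over both pools."""
    return float(np.dot(np.asarray(state, dtype=float), index.shh_counts))


def total_carriers(state: np.ndarray, index: SpeciesIndex, mechanism_class: str) -> float:
    """Total carrier particles (free + bound, both pools) of one class."""
    mask = np.array([s.mechanism_class == mechanism_class for s in index.species])
    return float(np.asarray(state, dtype=float)[mask].sum())
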