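"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's compiled/vectorised code
paths: the naive RHS sums mass-action fluxes reaction by reaction in pure
Python, the naive binner walks species one by one, and the Gillespie
simulator samples exact stochastic trajectories of the same reaction
network.
"""

from __future__ import annotations

import numpy as np
import pytest

import shhagg as sa


def naive_rhs(index: sa.SpeciesIndex, reactions, state: np.ndarray) -> np.ndarray:
    """Per-reaction mass-action flux summation, straight from the definition."""
    dy = np.zeros(len(index))
    for rx in reactions:
        flux = rx.rate_constant * rx.symmetry_factor
        for sp in rx.reactants:
            flux *= state[index.position[sp]]
        for sp in rx.reactants:
            dy[index.position[sp]] -= flux
        for sp in rx.products:
            dy[index.position[sp]] += flux
    return dy


def naive_bin(index: sa.SpeciesIndex, state: np.ndarray, pool: str,
              report_size: int) -> np.ndarray:
    """Hand-rolled mechanism-by-size entity binning (4 x report_size+1)."""
    out = np.zeros((4, report_size + 1))
    for sp, x in zip(index.species, state):
        if sp.pool != pool or sp.shh_count == 0:
            continue
        if sp.mechanism_class == sa.network.FREE_MULTIMER:
            row = 0 if sp.shh_count == 1 else 1
        elif sp.mechanism_class == sa.network.HSPG_BOUND:
            row = 2
        else:
            row = 3
        col = min(sp.shh_count - 1, report_size)
        out[row, col] += x
    return out


class GillespieModel:
    """Exact stochastic simulator for a compiled reaction inventory."""

    def __init__(self, index: sa.SpeciesIndex, reactions):
        n = len(index)
        self.n = n
        kinds, a_idx, b_idx, k_eff = [], [], [], []
        deltas = []
        for rx in reactions:
            ridx = [index.position[s] for s in rx.reactants]
            pidx = [index.position[s] for s in rx.products]
            delta = np.zeros(n, dtype=np.int64)
            for i in ridx:
                delta[i] -= 1
            for i in pidx:
                delta[i] += 1
            deltas.append(delta)
            k_eff.append(rx.rate_constant * rx.symmetry_factor)
            if len(ridx) == 0:
                kinds.append(0); a_idx.append(0); b_idx.append(0)
            elif len(ridx) == 1:
                kinds.append(1); a_idx.append(ridx[0]); b_idx.append(0)
            elif ridx[0] == ridx[1]:
                kinds.append(3); a_idx.append(ridx[0]); b_idx.append(ridx[0])
            else:
                kinds.append(2); a_idx.append(ridx[0]); b_idx.append(ridx[1])
        self.kinds = np.array(kinds)
        self.a = np.array(a_idx)
        self.b = np.array(b_idx)
        self.k = np.array(k_eff)
        self.deltas = np.array(deltas)

    def propensities(self, y: np.ndarray) -> np.ndarray:
        p = np.empty(self.k.size)
        src = self.kinds == 0
        uni = self.kinds == 1
        bi = self.kinds == 2
        same = self.kinds == 3
        p[src] = self.k[src]
        p[uni] = self.k[uni] * y[self.a[uni]]
        p[bi] = self.k[bi] * y[self.a[bi]] * y[self.b[bi]]
        p[same] = self.k[same] * y[self.a[same]] * (y[self.a[same]] - 1)
        return p

    def run(self, t_end: float, rng: np.random.Generator) -> np.ndarray:
        y = np.zeros(self.n, dtype=np.int64)
        t = 0.0
        while True:
            props = self.propensities(y)
            total = props.sum()
            if total <= 0:
                break
            t += rng.exponential(1.0 / total)
            if t > t_end:
                break
            ch = np.searchsorted(np.cumsum(props), rng.random() * total)
            y += self.deltas[ch]
        return y


@pytest.fixture(scope="session")
def default_params() -> sa.ParameterSet:
    return sa.ParameterSet()


@pytest.fixture(scope="session")
def small_config() -> sa.ModelConfig:
    """A fully featured but small network for fast integration tests."""
    return sa.ModelConfig(max_size=30, report_size=20)
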