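"""Mechanism-resolved size distributions, percentage breakdowns and fits.

Distributions count *entities*: one free monomer, one free multimer or one
loaded carrier each count as a single entity regardless of Shh load.  This
is the convention under which the percentage breakdown of a pool sums to
100 across all mechanisms and sizes.  Empty carriers are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .network import (CELL, DISPERSED, FREE_MULTIMER, HSPG_BOUND, LIPO_BOUND,
                      SpeciesIndex)
from .simulate import Trajectory

#: Row order of every distribution/table.
MECHANISM_ROWS = ("monomers", "multimers", "hspg", "lipoproteins")


@dataclass
class AggregateDistribution:
    """Entity counts per mechanism row and Shh size for one pool.

    ``counts`` has shape ``(4, report_size + 1)``: columns are sizes
    ``1..report_size`` followed by a single ``>report_size`` overflow bucket.
    """

    pool: str
    counts: np.ndarray
    report_size: int
    time: float | None = None

    def row(self, name: str) -> np.ndarray:
        return self.counts[MECHANISM_ROWS.index(name)]

    def total_entities(self) -> float:
        return float(self.counts.sum())

    def size_totals(self, include_overflow: bool = False) -> np.ndarray:
        """Entity totals across mechanisms, indexed by size 1..report_size."""
        tot = self.counts.sum(axis=0)
        return tot if include_overflow else tot[:-1]

    def to_frame(self) -> pd.DataFrame:
        cols = [str(n) for n in range(1, self.report_size + 1)] + [f">{self.report_size}"]
        return pd.DataFrame(self.counts, index=list(MECHANISM_ROWS), columns=cols)


class BreakdownTable(AggregateDistribution):
    """Same layout as :class:`AggregateDistribution`, entries in percent."""


def size_distribution(state: np.ndarray, index: SpeciesIndex, pool: str,
                      report_size: int | None = None,
                      time: float | None = None) -> AggregateDistribution:
    """Bin a state vector into the mechanism-by-size entity distribution.

    Free monomers go to the ``monomers`` row, free multimers (size >= 2) to
    ``multimers``, HSPG-bound aggregates to ``hspg`` by total Shh load, and
    loaded lipoproteins to ``lipoproteins``.  Empty carriers do not appear.
    Sizes above ``report_size`` are pooled in the overflow bucket.
    """
    if pool not in (CELL, DISPERSED):
        raise ValueError(f"unknown pool {pool!r}")
    if report_size is None:
        report_size = index.config.report_size
    counts = np.zeros((len(MECHANISM_ROWS), report_size + 1))
    state = np.asarray(state, dtype=float)
    for i, sp in enumerate(index.species):
        if sp.pool != pool or sp.shh_count == 0:
            continue
        if sp.mechanism_class == FREE_MULTIMER:
            row = 0 if sp.shh_count == 1 else 1
        elif sp.mechanism_class == HSPG_BOUND:
            row = 2
        elif sp.mechanism_class == LIPO_BOUND:
            row = 3
        else:  # pragma: no cover
            raise ValueError(f"unknown mechanism class {sp.mechanism_class}")
        col = sp.shh_count - 1 if sp.shh_count <= report_size else report_size
        counts[row, col] += state[i]
    return AggregateDistribution(pool, counts, report_size, time)


def percentage_breakdown(dist: AggregateDistribution) -> BreakdownTable:
    """Express a distribution as percentages of the total entity count.

    Rounding to two decimals happens only at serialisation, never here.
    """
    total = dist.total_entities()
    if total <= 0:
        raise ValueError("empty distribution: total entity count is zero")
    return BreakdownTable(dist.pool, 100.0 * dist.counts / total,
                          dist.report_size, dist.time)


def mechanism_shares(dist: AggregateDistribution) -> dict[str, float]:
    """Per-mechanism share (percent of all entities) of a distribution."""
    total = dist.total_entities()
    if total <= 0:
        raise ValueError("empty distribution")
    return {name: 100.0 * float(dist.row(name).sum()) / total for name in MECHANISM_ROWS}


@dataclass
class ExponentialFit:
    """Fit of entity counts vs size to A * exp(-lambda * n)."""

    amplitude: float
    decay_rate: float
    r_squared: float


def _counts_and_sizes(dist, size_range):
    if isinstance(dist, AggregateDistribution):
        totals = dist.size_totals()
        sizes = np.arange(1, dist.report_size + 1)
    else:  # raw counts indexed by size 1..n
        totals = np.asarray(getattr(dist, "counts", dist), dtype=float)
        sizes = np.arange(1, totals.size + 1)
    if size_range is not None:
        lo, hi = size_range
        keep = (sizes >= lo) & (sizes <= hi)
        sizes, totals = sizes[keep], totals[keep]
    return sizes, totals


def fit_exponential(dist, size_range: tuple[int, int] | None = None,
                    method: str = "loglinear") -> ExponentialFit:
    """Fit the size-wise entity totals to a decaying exponential.

    The default estimator is ordinary least squares on log counts over the
    sizes with positive counts (deterministic, no starting guess); the
    ``"nonlinear"`` method refines it with Levenberg–Marquardt on the raw
    counts.  R^2 is always reported on the log-linear scale.  ``dist`` may
    be an :class:`AggregateDistribution`, a reference distribution, or a
    plain count array indexed by size 1..n; the overflow bucket is excluded.
    """
    sizes, totals = _counts_and_sizes(dist, size_range)
    pos = totals > 0
    if pos.sum() < 3:
        raise ValueError("need at least 3 sizes with positive counts to fit")
    x = sizes[pos].astype(float)
    logy = np.log(totals[pos])
    slope, intercept = np.polyfit(x, logy, 1)
    resid = logy - (slope * x + intercept)
    ss_tot = float(np.sum((logy - logy.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    A, lam = float(np.exp(intercept)), float(-slope)
    if method == "nonlinear":
        popt, _ = curve_fit(lambda n, a, l: a * np.exp(-l * n), x, totals[pos],
                            p0=(A, lam), maxfev=10000)
        A, lam = float(popt[0]), float(popt[1])
    elif method != "loglinear":
        raise ValueError(f"unknown fit method {method!r}")
    return ExponentialFit(A, lam, max(0.0, min(1.0, r2)))


def aggregate_monomer_ratio(trajectory: Trajectory, window: tuple[float, float]) -> float:
    """Dispersed aggregate : dispersed monomer entity ratio over a window.

    Dispersed species are inert, so their counts are cumulative; the
    accumulation over ``[t0, t1]`` is the difference of the dispersed
    distributions at the window edges.  Aggregates are all dispersed
    entities except free monomers.
    """
    t0, t1 = window
    if not (trajectory.times[0] - 1e-9 <= t0 < t1 <= trajectory.times[-1] + 1e-9):
        raise ValueError(f"window {window} outside trajectory span")
    d0 = size_distribution(trajectory.snapshot(t0), trajectory.index, DISPERSED)
    d1 = size_distribution(trajectory.snapshot(t1), trajectory.index, DISPERSED)
    monomers = float(d1.row("monomers").sum() - d0.row("monomers").sum())
    aggregates = (d1.total_entities() - d0.total_entities()) - monomers
    if monomers <= 0:
        raise ValueError("no dispersed monomer accumulation over the window")
    return aggregates / monomers


def fraction_leq_size(dist: AggregateDistribution, cutoff: int) -> float:
    """Fraction of aggregate entities (monomer row excluded) of size <= cutoff.

    The overflow bucket counts as larger than any cutoff up to
    ``report_size``.
    """
    if not 1 <= cutoff <= dist.report_size:
        raise ValueError("cutoff must lie in [1, report_size]")
    agg = dist.counts[1:]  # multimers, hspg, lipoproteins
    total = float(agg.sum())
    if total <= 0:
        raise ValueError("distribution contains no aggregates")
    return float(agg[:, :cutoff].sum()) / total
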