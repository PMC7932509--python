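"""Parameter-informing tools: synthetic references and dominance bounds.

The study's external comparison data (microscopy cluster volume-frequency
counts that decay exponentially with size) is not deposited, so this module
generates synthetic stand-ins: exact exponential size-frequency curves,
optionally with multiplicative lognormal noise.  It also implements the
procedure used to bracket the carrier source ratios: the acceptable range of
a carrier source runs from the value where the mechanism first contributes
appreciably (share above ``threshold_low``) to the value where it dominates
the distribution (share above ``threshold_high``).

The tooling supports reproducing the manual calibration; it does not try to
re-derive a canonical rate-constant set automatically.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np

from .config import ModelConfig, ParameterSet
from .distributions import AggregateDistribution, mechanism_shares, size_distribution
from .network import CELL
from .simulate import integrate

_SOURCE_FIELD = {"hspg": "r_H", "lipoprotein": "r_L"}
_SHARE_ROW = {"hspg": "hspg", "lipoprotein": "lipoproteins"}


@dataclass
class ReferenceDistribution:
    """Synthetic exponential size-frequency reference.

    ``counts[n-1]`` is the (noisy) frequency of size ``n``; with ``sigma=0``
    the counts are exactly ``A * exp(-decay_rate * n)``.
    """

    sizes: np.ndarray
    counts: np.ndarray
    amplitude: float
    decay_rate: float
    sigma: float
    seed: int | None


def generate_reference(amplitude: float, decay_rate: float, n_max: int,
                       sigma: float = 0.0, seed: int | None = None) -> ReferenceDistribution:
    """Generate an exponential reference, reproducible for a given seed.

    Multiplicative noise is lognormal: each count is scaled by
    ``exp(sigma * z)`` with standard-normal ``z``.
    """
    if amplitude <= 0 or decay_rate <= 0:
        raise ValueError("amplitude and decay_rate must be positive")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    sizes = np.arange(1, n_max + 1)
    counts = amplitude * np.exp(-decay_rate * sizes.astype(float))
    if sigma > 0:
        rng = np.random.default_rng(seed)
        counts = counts * np.exp(sigma * rng.standard_normal(n_max))
    return ReferenceDistribution(sizes, counts, amplitude, decay_rate, sigma, seed)


def fit_discrepancy(model_dist: AggregateDistribution,
                    reference: ReferenceDistribution) -> float:
    """RMS difference of size-wise entity shares between model and reference.

    Both size profiles are restricted to the overlapping size support and
    normalised to sum to one before comparison; lower is better, zero means
    identical shapes.
    """
    model_counts = model_dist.size_totals()
    n = min(model_counts.size, reference.counts.size)
    if n == 0:
        raise ValueError("no overlapping size support")
    a, b = model_counts[:n], reference.counts[:n]
    if a.sum() <= 0 or b.sum() <= 0:
        raise ValueError("cannot normalise an all-zero profile")
    diff = a / a.sum() - b / b.sum()
    return float(np.sqrt(np.mean(diff**2)))


class NonMonotoneShareError(RuntimeError):
    """The mechanism share was not monotone in the source over the bracket."""


@dataclass
class DominanceBounds:
    """Carrier-source values bracketing 'present but not dominant'."""

    mechanism: str
    lower: float
    upper: float
    threshold_low: float
    threshold_high: float


def _mechanism_share(config: ModelConfig, params: ParameterSet, mechanism: str,
                     source: float, t_eval: float, **integrate_kw) -> float:
    """Percent of aggregate entities (free monomers excluded) formed by one
    mechanism, cell pool at ``t_eval``.

    Monomers are excluded from the denominator because the bounds are defined
    on the number of *aggregates*: free monomers cannot be recruited away by
    HSPGs, so including them would cap every carrier share below 100%.
    """
    params = dataclasses.replace(params, **{_SOURCE_FIELD[mechanism]: source})
    traj = integrate(config, params, t_eval, grid_dt=None, **integrate_kw)
    dist = size_distribution(traj.snapshot(t_eval), traj.index, CELL)
    shares = mechanism_shares(dist)
    aggregate_total = 100.0 - shares["monomers"]
    if aggregate_total <= 0:
        return 0.0
    return 100.0 * shares[_SHARE_ROW[mechanism]] / aggregate_total


def _bisect_crossing(share, lo: float, hi: float, threshold: float,
                     rel_tol: float) -> float:
    # share(lo) < threshold <= share(hi); shrink to 1% relative width
    while (hi - lo) / (0.5 * (hi + lo)) > rel_tol:
        mid = math.sqrt(lo * hi)
        if share(mid) < threshold:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


class ThresholdNotBracketedError(ValueError):
    """The share never crosses the threshold inside the scanned bracket.

    Carries ``saturation_share``, the largest share seen over the scan: a
    mechanism whose competitors cannot be recruited away saturates below
    100%, so a high dominance threshold may simply not exist.
    """

    def __init__(self, message: str, saturation_share: float):
        super().__init__(message)
        self.saturation_share = saturation_share


def source_for_share(config: ModelConfig, params: ParameterSet, mechanism: str,
                     threshold: float, t_eval: float = 24 * 60.0,
                     bracket: tuple[float, float] = (1e-3, 1e4),
                     points_per_decade: int = 2, rel_tol: float = 0.01,
                     **integrate_kw) -> float:
    """Source ratio at which a mechanism's aggregate share crosses a threshold.

    A log-spaced scan over ``bracket`` locates the crossing of the
    mechanism's share of aggregate entities (percent, free monomers
    excluded, cell pool at ``t_eval``); the crossing is then refined by
    bisection in log space to ``rel_tol`` relative width.  A share profile
    that is not monotone non-decreasing over the scan raises
    :class:`NonMonotoneShareError`; a threshold above the saturation share
    raises :class:`ThresholdNotBracketedError`.
    """
    if mechanism not in _SOURCE_FIELD:
        raise ValueError("mechanism must be 'hspg' or 'lipoprotein'")
    if not 0 < threshold < 100:
        raise ValueError("threshold must lie in (0, 100)")

    cache: dict[float, float] = {}

    def share(src: float) -> float:
        if src not in cache:
            cache[src] = _mechanism_share(config, params, mechanism, src,
                                          t_eval, **integrate_kw)
        return cache[src]

    lo, hi = bracket
    n_pts = max(2, int(round(points_per_decade * math.log10(hi / lo))) + 1)
    grid = np.geomspace(lo, hi, n_pts)
    shares = np.array([share(float(g)) for g in grid])
    if np.any(np.diff(shares) < -0.5):  # tolerate solver-level jitter only
        raise NonMonotoneShareError(
            f"{mechanism} share not monotone over bracket: {shares.round(2).tolist()}")
    above = np.nonzero(shares >= threshold)[0]
    if above.size == 0 or above[0] == 0:
        raise ThresholdNotBracketedError(
            f"{mechanism}: threshold {threshold}% not bracketed by sources in "
            f"{bracket} (shares {shares.round(2).tolist()})",
            saturation_share=float(shares.max()))
    i = int(above[0])
    return _bisect_crossing(share, float(grid[i - 1]), float(grid[i]),
                            threshold, rel_tol)


def find_dominance_bounds(config: ModelConfig, params: ParameterSet, mechanism: str,
                          thresholds: tuple[float, float] = (10.0, 90.0),
                          t_eval: float = 24 * 60.0,
                          bracket: tuple[float, float] = (1e-3, 1e4),
                          points_per_decade: int = 2, rel_tol: float = 0.01,
                          **integrate_kw) -> DominanceBounds:
    """Bracket the source ratio of one carrier mechanism by its 24 h share.

    ``lower`` is the source at which the mechanism's aggregate share rises
    through ``threshold_low`` (the mechanism becomes appreciably present),
    ``upper`` the source at which it exceeds ``threshold_high`` (it
    dominates the aggregate distribution).
    """
    thr_lo, thr_hi = thresholds
    if not 0 < thr_lo < thr_hi < 100:
        raise ValueError("thresholds must satisfy 0 < low < high < 100")
    kw = dict(t_eval=t_eval, bracket=bracket,
              points_per_decade=points_per_decade, rel_tol=rel_tol,
              **integrate_kw)
    lower = source_for_share(config, params, mechanism, thr_lo, **kw)
    upper = source_for_share(config, params, mechanism, thr_hi, **kw)
    return DominanceBounds(mechanism, lower, upper, thr_lo, thr_hi)
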