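"""Entropy and mutual-information measures over synapse-count distributions.

Two mutual informations organize the analyses: MI(S(0); S(t)) — how much the
current synapse count still tells about the initial one — and MI(S(t); I) —
how much it tells about which stimulation condition I was applied.  Both are
computed from conditional distribution trajectories by total probability, so
the same simulated (or exactly propagated) conditionals can be re-weighted
under any initial law or condition mix without re-running anything.

The time-scale extractors live here too: ``tau_fraction`` finds threshold
crossings of an MI curve (95%-of-plateau decay, 50%-of-max rise, ...) with
log-linear interpolation between the exponential grid points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.special import xlogy

from .model_core import DistributionTrajectory

__all__ = [
    "MICurve",
    "ConditionMix",
    "entropy",
    "mi_between_time_points",
    "mi_condition",
    "tau_fraction",
    "BEYOND_HORIZON",
]

#: Sentinel returned by :func:`tau_fraction` when the threshold is never crossed.
BEYOND_HORIZON = math.inf

_LN2 = math.log(2.0)


@dataclass(frozen=True)
class MICurve:
    """Mutual information (bits) on an increasing time grid."""

    times: np.ndarray
    mi: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times)
        m = np.asarray(self.mi, dtype=float)
        if t.ndim != 1 or t.shape != m.shape:
            raise ValueError("times and mi must be aligned vectors")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "mi", m)


@dataclass(frozen=True)
class ConditionMix:
    """Probabilities P(I) over stimulation conditions."""

    probs: dict

    def __post_init__(self) -> None:
        vals = np.array(list(self.probs.values()), dtype=float)
        if (vals < 0).any() or abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError("condition mix must be non-negative and sum to 1")

    def entropy(self) -> float:
        vals = np.array(list(self.probs.values()), dtype=float)
        return float(-xlogy(vals, vals).sum() / _LN2)


def entropy(p: np.ndarray) -> float:
    """Shannon entropy in bits, with 0*log(0) := 0.

    Raises for vectors that are not normalized to within 1e-8.
    """
    p = np.asarray(p, dtype=float)
    if abs(p.sum() - 1.0) > 1e-8 or (p < 0).any():
        raise ValueError("entropy requires a normalized probability vector")
    return float(-xlogy(p, p).sum() / _LN2)


def _as_stack(conditionals: Mapping, keys) -> tuple[np.ndarray, np.ndarray]:
    """Stack per-key trajectories into (times, array of shape (K, T, nstates))."""
    times = None
    mats = []
    for k in keys:
        c = conditionals[k]
        if isinstance(c, DistributionTrajectory):
            t, dist = np.asarray(c.times), c.dists
        else:
            t, dist = c
            t, dist = np.asarray(t), np.asarray(dist, dtype=float)
        if times is None:
            times = t
        elif t.shape != times.shape or not np.array_equal(t, times):
            raise ValueError("conditional trajectories must share one time grid")
        mats.append(dist)
    stack = np.stack(mats)
    if stack.ndim != 3:
        raise ValueError("each conditional must be (times, states)")
    return times, stack


def _mi_of_mixture(weights: np.ndarray, stack: np.ndarray) -> np.ndarray:
    """MI(t) = H(marginal) - sum_k w_k H(conditional_k), vectorized over t."""
    marg = np.einsum("k,ktn->tn", weights, stack)
    h_marg = -xlogy(marg, marg).sum(axis=1) / _LN2
    h_cond = -xlogy(stack, stack).sum(axis=2) / _LN2  # (K, T)
    mi = h_marg - weights @ h_cond
    return np.clip(mi, 0.0, None)  # clip float residue ~1e-16


def mi_between_time_points(
    p_init: Mapping[int, float] | np.ndarray,
    conditionals: Mapping[int, DistributionTrajectory],
) -> MICurve:
    """MI(S(0); S(t)) from per-initial-state conditional trajectories.

    ``p_init`` assigns probability to each simulated initial count S0 (as a
    mapping, or a vector indexed by S0 whose support must be covered by
    ``conditionals``).  The marginal p[S(t)] is assembled by total
    probability, so new initial laws reuse the same conditionals.
    """
    if isinstance(p_init, Mapping):
        items = [(int(k), float(v)) for k, v in p_init.items() if v > 0]
    else:
        arr = np.asarray(p_init, dtype=float)
        items = [(int(i), float(v)) for i, v in enumerate(arr) if v > 0]
    keys = [k for k, _ in items]
    w = np.array([v for _, v in items])
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("p_init must be normalized over the simulated S0 values")
    missing = [k for k in keys if k not in conditionals]
    if missing:
        raise KeyError(f"no conditional trajectory for initial count(s) {missing}")
    times, stack = _as_stack(conditionals, keys)
    return MICurve(times, _mi_of_mixture(w, stack))


def mi_condition(
    mix: ConditionMix | Mapping[str, float],
    conditionals: Mapping[str, DistributionTrajectory],
) -> MICurve:
    """MI(S(t); I) for a stimulation-condition mix P(I).

    Bounded above by the mix entropy H(P); equals it when the conditional
    distributions have disjoint supports (perfect discriminability).
    """
    probs = mix.probs if isinstance(mix, ConditionMix) else dict(mix)
    keys = [k for k, v in probs.items() if v > 0]
    w = np.array([probs[k] for k in keys], dtype=float)
    if abs(w.sum() - 1.0) > 1e-9 or (w < 0).any():
        raise ValueError("condition mix must be non-negative and sum to 1")
    times, stack = _as_stack(conditionals, keys)
    return MICurve(times, _mi_of_mixture(w, stack))


def tau_fraction(
    curve: MICurve,
    mode: str,
    fraction: float,
    reference: str = "initial",
    reference_value: float | None = None,
) -> float:
    """First grid time at which the curve crosses ``fraction * reference``.

    ``mode="decay_to"`` looks for the first downward crossing,
    ``mode="rise_to"`` for the first upward crossing.  The reference level is
    the curve's initial value, its maximum, or an externally supplied
    plateau height (``reference="plateau"`` with ``reference_value``, e.g.
    the t=0 mutual information of the matched two-state model).  Crossings
    between grid points are located by linear interpolation in log-time.
    Returns :data:`BEYOND_HORIZON` when the threshold is never crossed.
    """
    if curve.times.size == 0:
        raise ValueError("empty curve")
    if mode not in ("decay_to", "rise_to"):
        raise ValueError(f"mode must be 'decay_to' or 'rise_to', got {mode!r}")
    if reference == "initial":
        ref = float(curve.mi[0])
    elif reference == "max":
        ref = float(curve.mi.max())
    elif reference == "plateau":
        if reference_value is None:
            raise ValueError("reference='plateau' needs reference_value")
        ref = float(reference_value)
    else:
        raise ValueError(f"unknown reference {reference!r}")
    thr = fraction * ref
    y = curve.mi
    t = np.asarray(curve.times, dtype=float)
    below = y < thr if mode == "decay_to" else y > thr
    if mode == "decay_to" and below[0]:
        return float(t[0])
    if mode == "rise_to" and below[0]:
        return float(t[0])
    idx = np.nonzero(below)[0]
    if idx.size == 0:
        return BEYOND_HORIZON
    i = int(idx[0])
    y0, y1 = y[i - 1], y[i]
    if y1 == y0:
        return float(t[i])
    lt0 = math.log(max(t[i - 1], 1e-300))
    lt1 = math.log(t[i])
    frac = (thr - y0) / (y1 - y0)
    return float(math.exp(lt0 + frac * (lt1 - lt0)))
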