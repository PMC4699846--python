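"""Matching model time steps to experimental days.

In vivo, roughly 5% of dendritic spines present on a given day are new
relative to the day before.  The model analog is the expected fraction of
newly formed *and still persistent* synapses over a window of T steps under
working-point conditions.  Under the approximation that a connection forms
at most one synapse during the window, the probability that a connection
with post-formation count S forms it at some step and keeps it to the end of
the window has a closed geometric-series form; the number of steps per day
is the T at which the resulting population fraction matches the 5% of the
experiments (T ~ 2.3e7 at the default working point).

The fraction is non-monotone in T: it rises on the fast lower-peak turnover
scale, overshoots, and then settles as the single-formation window
saturates.  The calibrated T is the settling (descending) crossing of the
target; an "onset" branch returning the first ascending crossing is also
available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model_core import DeletionProfile, ModelParams, StationaryDistribution

__all__ = [
    "CalibrationResult",
    "CalibrationError",
    "new_persistent_prob",
    "new_fraction",
    "solve_steps_per_day",
]


class CalibrationError(RuntimeError):
    """Raised when the target fraction is unreachable; carries the scanned curve."""

    def __init__(self, msg: str, curve: tuple[np.ndarray, np.ndarray] | None = None):
        super().__init__(msg)
        self.curve = curve


@dataclass(frozen=True)
class CalibrationResult:
    steps_per_day: int
    achieved_fraction: float

    def __post_init__(self) -> None:
        if self.steps_per_day < 1:
            raise ValueError("steps_per_day must be >= 1")
        if not (0.0 <= self.achieved_fraction <= 1.0):
            raise ValueError("achieved_fraction must lie in [0, 1]")


def _powT(x: float, T: float) -> float:
    # (1-x)^T without loss of precision for x ~ 1e-8, T ~ 1e7
    return math.exp(T * math.log1p(-x)) if x < 1.0 else 0.0


def new_persistent_prob(
    S: int, params: ModelParams, d: DeletionProfile, T: int | float
) -> float:
    """P(new & persistent | S): a synapse forms in a T-step window and survives it.

    ``S`` is the connection's synapse count *after* the formation (so the
    formation happened from S-1, at rate (N-S+1) b), and survival is the
    probability that no deletion occurs among the S synapses for the rest of
    the window.  Closed geometric-series form; the degenerate case
    (N-S+1) b = S d[S] is evaluated by its analytic limit.
    """
    N, b = params.N, params.b
    if not (1 <= S <= N):
        raise ValueError(f"S must lie in 1..{N}, got {S!r}")
    if T < 0:
        raise ValueError(f"T must be >= 0, got {T!r}")
    if b == 0.0:
        return 0.0
    form = (N - S + 1) * b
    dele = S * d.d[S]
    T = float(T)
    if T == 0.0:
        return 0.0
    cT = _powT(dele, T)  # (1 - S d[S])^T
    aT = _powT(form, T)  # (1 - (N-S+1) b)^T
    tail = (1.0 - dele) * form / (1.0 - form)
    if math.isclose(form, dele, rel_tol=1e-12, abs_tol=0.0):
        series = T * _powT(dele, T - 1.0)  # removable singularity
    else:
        series = (cT - aT) / (form - dele)
    p = series * tail
    return min(max(p, 0.0), 1.0)


def new_fraction(
    p_wp: StationaryDistribution,
    params: ModelParams,
    d: DeletionProfile,
    T: int | float,
    measure: str = "conditional",
) -> float:
    """Expected daily fraction of new persistent synapses at window length T.

    The expectation measure over the pre-formation count S-1 is open to
    interpretation; three readings are exposed:

    - ``"conditional"`` (default): numerator averages P(new&persistent|S)
      over S-1 ~ p_wp restricted to formable states {0..N-1}, renormalized;
      denominator is E[S] over the full p_wp (mean pre-existing count).
      This is the reading that reproduces the published calibration.
    - ``"restricted"``: both numerator and denominator use the restricted,
      renormalized law of S-1.
    - ``"full"``: unnormalized numerator over the full p_wp; denominator
      E[S] over the full p_wp.
    """
    N = params.N
    if p_wp.N != N or d.N != N:
        raise ValueError("p_wp, d and params must share N")
    p = p_wp.p
    probs = np.array(
        [new_persistent_prob(s1 + 1, params, d, T) for s1 in range(N)]
    )
    mean_S = float(np.arange(N + 1) @ p)
    if measure == "conditional":
        w = p[:N] / p[:N].sum()
        num, den = float(w @ probs), mean_S
    elif measure == "restricted":
        w = p[:N] / p[:N].sum()
        num, den = float(w @ probs), float(np.arange(N) @ w)
    elif measure == "full":
        num, den = float(p[:N] @ probs), mean_S
    else:
        raise ValueError(f"unknown measure {measure!r}")
    if den <= 0:
        raise CalibrationError("expected pre-existing synapse count is not positive")
    return num / den


def solve_steps_per_day(
    p_wp: StationaryDistribution,
    params: ModelParams,
    d: DeletionProfile,
    target_fraction: float = 0.05,
    measure: str = "conditional",
    branch: str = "settling",
    horizon: float = 1e12,
) -> CalibrationResult:
    """Steps per experimental day: window length T whose daily new-synapse
    fraction equals the target.

    The fraction-vs-T curve rises, overshoots and settles; ``branch``
    selects which crossing of the target defines T:

    - ``"settling"`` (default): the descending crossing beyond the curve's
      maximum — the calibration point for matching steady-state turnover.
    - ``"onset"``: the first ascending crossing (smallest T reaching the
      target).

    Bisection on the monotone segment, then integer refinement to the
    smallest integer T on the target side of the crossing.
    """
    if not (0.0 < target_fraction < 1.0):
        raise CalibrationError(f"target must lie in (0, 1), got {target_fraction!r}")
    if branch not in ("settling", "onset"):
        raise ValueError(f"branch must be 'settling' or 'onset', got {branch!r}")

    def f(T: float) -> float:
        return new_fraction(p_wp, params, d, T, measure=measure)

    grid = np.unique(np.round(np.logspace(0, math.log10(horizon), 400)))
    vals = np.array([f(T) for T in grid])
    k_max = int(np.argmax(vals))
    if vals[k_max] < target_fraction:
        raise CalibrationError(
            f"fraction never reaches {target_fraction} (max {vals[k_max]:.4g} "
            f"at T = {grid[k_max]:.4g})",
            curve=(grid, vals),
        )
    if branch == "onset":
        k = int(np.argmax(vals >= target_fraction))
        lo = grid[k - 1] if k > 0 else 1.0
        hi = grid[k]
        rising = True
    else:
        after = vals[k_max:]
        rel = np.nonzero(after < target_fraction)[0]
        if rel.size == 0:
            raise CalibrationError(
                "fraction does not settle below the target within the horizon; "
                "increase the horizon",
                curve=(grid, vals),
            )
        k = k_max + int(rel[0])
        lo, hi = grid[k - 1], grid[k]
        rising = False
    while hi - lo > 1.0:
        mid = math.floor((lo + hi) / 2.0)
        if (f(mid) >= target_fraction) == rising:
            hi = mid
        else:
            lo = mid
    # report the integer T still meeting the target
    T = int(hi if rising else lo)
    T = max(T, 1)
    return CalibrationResult(steps_per_day=T, achieved_fraction=f(T))
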