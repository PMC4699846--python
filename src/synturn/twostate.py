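"""Reduced two-state (peak-level) model of the bimodal working-point chain.

On long time scales the bimodal chain behaves like a metastable switch: each
connection sits in the lower peak (around zero synapses) or the upper peak
(around mu) and only rarely crosses the probability barrier between them.
Lumping the peaks into two states with stationary masses (1-C, C) gives a
2x2 chain whose free transition rate R is matched to the full system by
equating the stationary probability flow through the barrier state S~ (the
interpeak minimum):

    R = (N - S~) * b * p_wp[S~].

The closed-form time evolution and mutual information of the lumped chain
reproduce the second (late) decay of the full model's information curves,
and expose what controls storage time: only the barrier probability
p_wp[S~] enters R, so narrower or more separated peaks store longer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model_core import ModelParams, StationaryDistribution, interpeak_minimum

__all__ = [
    "TwoStateParams",
    "two_state_matrix",
    "two_state_p1",
    "two_state_mi",
    "matched_rate",
    "matched_two_state",
    "upper_peak_mass",
    "slowdown_factor",
]


@dataclass(frozen=True)
class TwoStateParams:
    """Lumped model: stationary upper mass C, rate R, initial upper mass p_init."""

    C: float
    R: float
    p_init: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.C < 1.0):
            raise ValueError(f"C must lie in (0, 1), got {self.C!r}")
        if self.R <= 0:
            raise ValueError(f"R must be > 0, got {self.R!r}")
        if self.R / self.C > 1.0 or self.R / (1.0 - self.C) > 1.0:
            raise ValueError("R/C and R/(1-C) must be valid probabilities (<= 1)")
        if not (0.0 <= self.p_init <= 1.0):
            raise ValueError(f"p_init must lie in [0, 1], got {self.p_init!r}")

    @property
    def relaxation_rate(self) -> float:
        """Spectral gap R / (C (1 - C)); its inverse is the e-fold time."""
        return self.R / (self.C * (1.0 - self.C))


def two_state_matrix(C: float, R: float) -> np.ndarray:
    """2x2 transition matrix with stationary (1-C, C) and eigenvalues
    {1, 1 - R/(C(1-C))}."""
    TwoStateParams(C=C, R=R)  # validate
    return np.array(
        [
            [1.0 - R / (1.0 - C), R / (1.0 - C)],
            [R / C, 1.0 - R / C],
        ]
    )


def two_state_p1(t: float, params: TwoStateParams) -> float:
    """Upper-state probability p1(t) = C + (p_init - C) exp(-t R/(C(1-C))).

    Continuous-time envelope of the discrete chain; exact to O(R^2 t) at the
    per-step rates of interest (R ~ 1e-10).
    """
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t!r}")
    return params.C + (params.p_init - params.C) * math.exp(
        -float(t) * params.relaxation_rate
    )


def _h2(p: float) -> float:
    if p <= 0.0 or p >= 1.0:
        return 0.0
    return -p * math.log2(p) - (1.0 - p) * math.log2(1.0 - p)


def two_state_mi(t: float, C: float, R: float, q: float) -> float:
    """MI (bits) between a Bernoulli(q) initial peak identity and the state at t.

    MI = H2(p1(t, q)) - (1-q) H2(p1(t, 0)) - q H2(p1(t, 1)); at t=0 this is
    H2(q), and it decays to 0 as all branches converge to the stationary C.
    """
    if not (0.0 <= q <= 1.0):
        raise ValueError(f"q must lie in [0, 1], got {q!r}")
    mix = two_state_p1(t, TwoStateParams(C=C, R=R, p_init=q))
    lo = two_state_p1(t, TwoStateParams(C=C, R=R, p_init=0.0))
    hi = two_state_p1(t, TwoStateParams(C=C, R=R, p_init=1.0))
    return max(_h2(mix) - (1.0 - q) * _h2(lo) - q * _h2(hi), 0.0)


def upper_peak_mass(p_wp: StationaryDistribution | np.ndarray) -> float:
    """Stationary mass of the upper peak, sum_{S > S~} p_wp[S]."""
    p = p_wp.p if isinstance(p_wp, StationaryDistribution) else np.asarray(p_wp, float)
    s_tilde = interpeak_minimum(p)
    return float(p[s_tilde + 1 :].sum())


def matched_rate(p_wp: StationaryDistribution, params: ModelParams) -> float:
    """Barrier-flow-matched rate R = (N - S~) b p_wp[S~] of the lumped model."""
    s_tilde = interpeak_minimum(p_wp)
    return float((params.N - s_tilde) * params.b * p_wp.p[s_tilde])


def matched_two_state(
    p_wp: StationaryDistribution, params: ModelParams, q: float = 0.0
) -> TwoStateParams:
    """Lumped model matched to a bimodal working point.

    The stationary upper mass is taken as the upper-peak mass of ``p_wp``
    (not the mixture weight parameter; for sharp peaks the two agree to
    ~1e-3), the rate from :func:`matched_rate`, and ``q`` is the initial
    upper-peak probability.
    """
    return TwoStateParams(C=upper_peak_mass(p_wp), R=matched_rate(p_wp, params), p_init=q)


def slowdown_factor(p_wp: StationaryDistribution, params: ModelParams) -> float:
    """How much slower the multi-synaptic system forgets than a mono-synaptic one.

    factor = ( (N - S~) p_wp[S~] / sum_{S <= S~} p_wp[S] )^(-1): the ratio of
    the lower peak's total mass to its barrier exit flux per unit b.  The
    formation rate b cancels, so the factor is a pure shape property of the
    stationary distribution; deeper interpeak minima give larger factors.
    """
    s_tilde = interpeak_minimum(p_wp)
    lower_mass = float(p_wp.p[: s_tilde + 1].sum())
    return lower_mass / ((params.N - s_tilde) * p_wp.p[s_tilde])
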