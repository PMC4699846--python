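"""Birth-death Markov chain over the synapse count of a compound-connection.

A *compound-connection* between two neurons consists of ``N`` potential
synaptic sites of which ``S`` host a realized synapse.  Vacant sites form a
synapse with a constant per-step probability ``b``; realized synapses are
removed with a count-dependent probability ``d[S]`` that encodes the current
stimulation condition.  Restricting the dynamics to one change at a time
yields a tridiagonal (birth-death) transition matrix whose stationary
distribution can be *prescribed*: given any strictly positive target
distribution ``p`` over ``S = 0..N``, detailed balance

    p[S] * S * d[S] = p[S-1] * (N - S + 1) * b

is inverted for the deletion rates, so the chain has ``p`` as its exact
stationary law.  Three target shapes are used throughout: a Poisson-shaped
lower peak (*low* stimulation), a Gaussian-shaped upper peak (*high*
stimulation), and their mixture, the bimodal *working-point* (*wp*)
distribution observed for cortical connections at resting activity.

Everything in this module is exact linear algebra on ``(N+1) x (N+1)``
matrices; it serves as the ground-truth oracle for the event-driven
simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

__all__ = [
    "ModelParams",
    "PeakParams",
    "StationaryDistribution",
    "DeletionProfile",
    "TransitionMatrix",
    "DistributionTrajectory",
    "gaussian_peak",
    "poisson_peak",
    "wp_mixture",
    "deletion_rates",
    "transition_matrix",
    "stationary_of",
    "propagate",
    "interpeak_minimum",
    "total_variation",
]

_NORM_TOL = 1e-12


def total_variation(p: np.ndarray, q: np.ndarray) -> float:
    """Total-variation distance between two probability vectors."""
    return 0.5 * float(np.abs(np.asarray(p, float) - np.asarray(q, float)).sum())


@dataclass(frozen=True)
class ModelParams:
    """Structural parameters of a compound-connection.

    Parameters
    ----------
    N
        Number of potential synaptic sites (>= 1).
    b
        Synapse-formation probability per vacant site per time step
        (0 < b < 1; the paper regime is b << 1, default 1e-8).
    """

    N: int
    b: float = 1e-8

    def __post_init__(self) -> None:
        if int(self.N) != self.N or self.N < 1:
            raise ValueError(f"N must be an integer >= 1, got {self.N!r}")
        if not (0.0 < self.b < 1.0):
            raise ValueError(f"b must lie in (0, 1), got {self.b!r}")
        object.__setattr__(self, "N", int(self.N))


@dataclass(frozen=True)
class PeakParams:
    """Shape parameters of the condition-specific stationary distributions.

    ``mu``/``sigma`` place the Gaussian upper peak (*high* condition),
    ``lam`` is the Poisson parameter of the lower peak (*low* condition)
    and ``C`` the upper-peak weight in the *wp* mixture.  Defaults are the
    working-point used for the decay and learning experiments.
    """

    mu: float = 5.0
    sigma: float = 1.2
    lam: float = 0.05
    C: float = 0.1

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma!r}")
        if self.lam <= 0:
            raise ValueError(f"lam must be > 0, got {self.lam!r}")
        if not (0.0 <= self.C <= 1.0):
            raise ValueError(f"C must lie in [0, 1], got {self.C!r}")


@dataclass(frozen=True)
class StationaryDistribution:
    """A strictly positive probability vector over synapse counts 0..N."""

    p: np.ndarray
    condition: str = "custom"

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.ndim != 1 or p.size < 1:
            raise ValueError("p must be a one-dimensional probability vector")
        if abs(p.sum() - 1.0) > _NORM_TOL:
            raise ValueError(f"p must be normalized within {_NORM_TOL}")
        if not np.all(p > 0.0):
            raise ValueError("stationary distribution must be strictly positive")
        object.__setattr__(self, "p", p)

    @property
    def N(self) -> int:
        return self.p.size - 1

    def mean(self) -> float:
        return float(np.arange(self.p.size) @ self.p)


@dataclass(frozen=True)
class DeletionProfile:
    """Per-count deletion probabilities ``d[S]`` for S = 1..N.

    Stored as a vector of length N+1 with ``d[0] = 0`` (no synapse to
    delete); all entries for S >= 1 are strictly positive for a profile
    produced by :func:`deletion_rates`.
    """

    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.ndim != 1 or d.size < 2:
            raise ValueError("d must be a vector over S = 0..N with N >= 1")
        object.__setattr__(self, "d", d)

    @property
    def N(self) -> int:
        return self.d.size - 1


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic tridiagonal one-step transition matrix over S = 0..N."""

    M: np.ndarray

    def __post_init__(self) -> None:
        M = np.asarray(self.M, dtype=float)
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise ValueError("M must be square")
        if np.abs(M.sum(axis=1) - 1.0).max() > _NORM_TOL:
            raise ValueError("rows of a transition matrix must sum to 1")
        if (M < -_NORM_TOL).any() or (M > 1 + _NORM_TOL).any():
            raise ValueError("transition probabilities must lie in [0, 1]")
        band = np.triu(M, 2) + np.tril(M, -2)
        if np.abs(band).max() > 0:
            raise ValueError("transition matrix must be tridiagonal")
        object.__setattr__(self, "M", M)

    @property
    def N(self) -> int:
        return self.M.shape[0] - 1


@dataclass
class DistributionTrajectory:
    """Distributions over S sampled on a strictly increasing time grid."""

    times: np.ndarray
    dists: np.ndarray  # shape (len(times), N+1)
    condition_schedule: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times)
        self.dists = np.asarray(self.dists, dtype=float)
        if self.times.ndim != 1 or self.dists.shape[0] != self.times.size:
            raise ValueError("times and dists must align")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        err = np.abs(self.dists.sum(axis=1) - 1.0).max() if self.times.size else 0.0
        if err > 1e-10:
            raise ValueError("each distribution must be normalized within 1e-10")

    @property
    def N(self) -> int:
        return self.dists.shape[1] - 1


def gaussian_peak(mu: float, sigma: float, N: int) -> StationaryDistribution:
    """Gaussian-shaped *high*-condition target, p[S] ∝ exp(-(S-mu)^2 / sigma^2).

    Note the exponent uses ``sigma**2``, not ``2 sigma**2``; ``sigma`` is the
    peak width in synapse counts, defined by this convention.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma!r}")
    if N < 0:
        raise ValueError(f"N must be >= 0, got {N!r}")
    S = np.arange(N + 1, dtype=float)
    logu = -((S - mu) ** 2) / sigma**2
    u = np.exp(logu - logu.max())  # overflow-safe; normalizer cancels
    return StationaryDistribution(u / u.sum(), condition="high")


def poisson_peak(lam: float, N: int) -> StationaryDistribution:
    """Truncated-Poisson *low*-condition target, p[S] ∝ lam^S / S!."""
    if lam <= 0:
        raise ValueError(f"lam must be > 0, got {lam!r}")
    S = np.arange(N + 1, dtype=float)
    logu = S * np.log(lam) - gammaln(S + 1)
    u = np.exp(logu - logu.max())
    return StationaryDistribution(u / u.sum(), condition="low")


def wp_mixture(
    p_low: StationaryDistribution, p_high: StationaryDistribution, C: float
) -> StationaryDistribution:
    """Working-point mixture p_wp = (1-C) * p_low + C * p_high."""
    if p_low.N != p_high.N:
        raise ValueError(
            f"mixture components must share N (got {p_low.N} and {p_high.N})"
        )
    if not (0.0 <= C <= 1.0):
        raise ValueError(f"C must lie in [0, 1], got {C!r}")
    p = (1.0 - C) * p_low.p + C * p_high.p
    return StationaryDistribution(p / p.sum(), condition="wp")


def condition_distribution(
    condition: str, peaks: PeakParams, N: int
) -> StationaryDistribution:
    """Build the stationary target for one stimulation condition label."""
    if condition == "low":
        return poisson_peak(peaks.lam, N)
    if condition == "high":
        return gaussian_peak(peaks.mu, peaks.sigma, N)
    if condition == "wp":
        return wp_mixture(
            poisson_peak(peaks.lam, N), gaussian_peak(peaks.mu, peaks.sigma, N), peaks.C
        )
    raise ValueError(f"unknown stimulation condition {condition!r}")


def deletion_rates(
    p: StationaryDistribution, params: ModelParams
) -> DeletionProfile:
    """Invert a target stationary distribution into deletion rates.

    Detailed balance between adjacent counts gives

        d[S] = ((N - S + 1) / S) * (p[S-1] / p[S]) * b,   S = 1..N.

    Raises if the resulting rates violate the validity bound
    ``S*d[S] + (N-S)*b <= 1`` (a diagonal entry of the transition matrix
    would turn negative).
    """
    N, b = params.N, params.b
    if p.N != N:
        raise ValueError(f"distribution is over 0..{p.N} but params.N = {N}")
    S = np.arange(1, N + 1, dtype=float)
    d = np.zeros(N + 1)
    d[1:] = (N - S + 1.0) / S * (p.p[:-1] / p.p[1:]) * b
    stay_deficit = np.arange(N + 1) * d + (N - np.arange(N + 1)) * b
    bad = np.nonzero(stay_deficit > 1.0)[0]
    if bad.size:
        raise ValueError(
            f"validity bound S*d[S] + (N-S)*b <= 1 violated at S = {bad[0]}: "
            f"{stay_deficit[bad[0]]:.6g} > 1 (reduce b or flatten the target)"
        )
    return DeletionProfile(d)


def transition_matrix(params: ModelParams, d: DeletionProfile) -> TransitionMatrix:
    """One-change-at-a-time transition matrix for (b, d).

    Row ``S`` has up-probability ``(N-S)*b``, down-probability ``S*d[S]``
    and stay-probability ``1 - (N-S)*b - S*d[S]``.
    """
    N, b = params.N, params.b
    if d.N != N:
        raise ValueError(f"profile is over 0..{d.N} but params.N = {N}")
    S = np.arange(N + 1, dtype=float)
    up = (N - S) * b
    down = S * d.d
    stay = 1.0 - up - down
    if (stay < 0).any():
        bad = int(np.nonzero(stay < 0)[0][0])
        raise ValueError(
            f"validity bound violated at S = {bad}: stay-probability {stay[bad]:.6g} < 0"
        )
    M = np.diag(stay) + np.diag(up[:-1], 1) + np.diag(down[1:], -1)
    return TransitionMatrix(M)


def stationary_of(M: TransitionMatrix) -> StationaryDistribution:
    """Unique left fixed vector of an irreducible, aperiodic chain.

    Serves as the independent oracle for :func:`deletion_rates`: the
    round-trip ``stationary_of(transition_matrix(deletion_rates(p)))``
    recovers ``p`` to 1e-10.  Computed from the null space of ``M.T - I``,
    which is well conditioned even when all rates are ~1e-8 and the
    eigenvalues of ``M`` cluster at 1.
    """
    A = M.M
    sub = np.diag(A, -1)
    sup = np.diag(A, 1)
    if (sub <= 0).any() or (sup <= 0).any():
        raise ValueError(
            "chain is reducible: a zero off-diagonal rate disconnects the state space"
        )
    # irreducible + aperiodic => the null space of the generator (M - I) is
    # one-dimensional.  The generator is rebuilt from the off-diagonal rates
    # (stored exactly) rather than as M - I, whose diagonal would lose ~8
    # digits to cancellation at rates of order 1e-8.  One (redundant) balance
    # equation is replaced by the normalization row; the bordered solve is
    # scale-invariant in the rates and residual-accurate even for steep
    # targets where an SVD null vector drifts.
    Q = _generator(A)
    B = Q.T / np.abs(Q).max()
    B[-1, :] = 1.0
    rhs = np.zeros(A.shape[0])
    rhs[-1] = 1.0
    pi = np.linalg.solve(B, rhs)
    pi = np.abs(pi)
    return StationaryDistribution(pi / pi.sum())


def _generator(M: np.ndarray) -> np.ndarray:
    """Discrete-time generator M - I with the diagonal rebuilt exactly.

    Off-diagonal transition probabilities are stored exactly in M; the
    diagonal 1 - sum(rates) is not (absolute float rounding ~1e-16 becomes
    ~1e-8 *relative* error on rates of order 1e-8 once 1 is subtracted).
    Rows of the generator sum to zero by construction.
    """
    Q = M - np.diag(np.diag(M))
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _reversible_measure(M: np.ndarray) -> np.ndarray:
    """Detailed-balance measure of a positive tridiagonal chain (unnormalized).

    For a birth-death chain pi[S]/pi[S-1] = M[S-1,S]/M[S,S-1] always holds.
    """
    up = np.diag(M, 1)
    down = np.diag(M, -1)
    logpi = np.concatenate([[0.0], np.cumsum(np.log(up) - np.log(down))])
    pi = np.exp(logpi - logpi.max())
    return pi / pi.sum()


def propagate(
    p0: np.ndarray, M: TransitionMatrix, t: int | float
) -> np.ndarray:
    """Exact master-equation propagation ``p0 @ M**t``.

    Uses the spectral decomposition of the chain symmetrized by its
    detailed-balance measure, so astronomically large ``t`` (1e10 and
    beyond) cost the same as ``t = 1``.  Falls back to square-and-multiply
    matrix powers when the chain has a vanishing off-diagonal rate (where
    the symmetrization is undefined).
    """
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t!r}")
    p0 = np.asarray(p0, dtype=float)
    A = M.M
    if p0.shape != (A.shape[0],):
        raise ValueError("p0 must be a vector over S = 0..N")
    if abs(p0.sum() - 1.0) > 1e-9:
        raise ValueError("p0 must be normalized")
    if t == 0:
        return p0.copy()
    up = np.diag(A, 1)
    down = np.diag(A, -1)
    if (up <= 0).any() or (down <= 0).any():
        ti = int(t)
        if ti != t:
            raise ValueError("non-integer t requires a fully connected chain")
        pt = p0 @ np.linalg.matrix_power(A, ti)
    else:
        # Work with the generator Q = M - I, symmetrized by the chain's
        # detailed-balance measure: eigenvalues of Q carry absolute error
        # ~eps*||Q|| (~1e-24 at b=1e-8), so eigenvectors stay accurate even
        # though the eigenvalues of M itself cluster within 1e-8 of 1.
        Q = _generator(A)
        pi = _reversible_measure(A)
        s = np.sqrt(pi)
        sym = (s[:, None] * Q) / s[None, :]
        q, V = np.linalg.eigh((sym + sym.T) / 2.0)
        w = 1.0 + q  # eigenvalues of M
        tf = float(t)
        wt = np.zeros_like(w)
        pos = w > 0
        wt[pos] = np.exp(tf * np.log1p(q[pos]))
        neg = ~pos & (np.abs(w) > 0)
        if neg.any():
            # negative eigenvalues need an integer power; magnitudes < 1 decay fast
            sign = 1.0 if int(tf) % 2 == 0 else -1.0
            wt[neg] = sign * np.exp(tf * np.log(np.abs(w[neg])))
        y = (p0 / s) @ V
        pt = ((y * wt) @ V.T) * s
    pt = np.clip(pt, 0.0, None)
    return pt / pt.sum()


def interpeak_minimum(p_wp: StationaryDistribution | np.ndarray) -> int:
    """Index of the probability minimum between the two modes of a bimodal p.

    The returned count ``S~`` is the barrier state governing peak-to-peak
    transitions.  Ties resolve to the smallest S.  Raises a ValueError for
    distributions without exactly two local maxima.
    """
    p = p_wp.p if isinstance(p_wp, StationaryDistribution) else np.asarray(p_wp, float)
    n = p.size
    maxima = [
        i
        for i in range(n)
        if (i == 0 or p[i] > p[i - 1]) and (i == n - 1 or p[i] > p[i + 1])
    ]
    if len(maxima) != 2:
        raise ValueError(
            f"no interpeak minimum: distribution has {len(maxima)} local maxima, need 2"
        )
    lo, hi = maxima
    interior = p[lo + 1 : hi]
    if interior.size == 0:
        raise ValueError("no interpeak minimum: modes are adjacent")
    return lo + 1 + int(np.argmin(interior))
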