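"""Event-driven stochastic simulation of individual compound-connections.

The exact chain is discrete-time: per step, each vacant site forms with
probability ``b`` and each realized synapse is deleted with probability
``d[S]`` for the *current* total count ``S``.  Instead of stepping, each
site carries a geometric waiting time (the discrete-time analog of the
exponential law, drawn by inverse CDF); after every realized event — and at
every stimulation-condition switch — all pending intervals are redrawn,
because the deletion rate depends on ``S``.  Geometric waits are memoryless,
so the redraw is statistically neutral and the sampled trajectory is an
exact draw from the chain.  Runtime scales with the number of events, not
with the simulated duration, which is what makes 1e10-step horizons cheap.

Unlike master-equation propagation (:mod:`synturn.model_core`), the
simulator tracks *which* sites are occupied, enabling turnover accounting:
created / removed / persistent synapses between two observation times are
read off the overlap of occupied locations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .model_core import DeletionProfile, DistributionTrajectory, ModelParams

__all__ = [
    "ConnectionState",
    "TurnoverReport",
    "PopulationResult",
    "simulate_connection",
    "simulate_population",
    "turnover_counts",
]

_NO_EVENT = np.iinfo(np.int64).max


@dataclass(frozen=True)
class ConnectionState:
    """Occupancy of the N potential sites of one connection at one time."""

    occupancy: np.ndarray  # boolean, length N

    def __post_init__(self) -> None:
        object.__setattr__(self, "occupancy", np.asarray(self.occupancy, dtype=bool))

    @property
    def N(self) -> int:
        return self.occupancy.size

    @property
    def S(self) -> int:
        return int(self.occupancy.sum())


@dataclass(frozen=True)
class TurnoverReport:
    """Synapse turnover between two snapshots of the same connection."""

    created: int
    removed: int
    persistent: int


@dataclass
class PopulationResult:
    """Ensemble outcome: empirical distributions plus per-connection snapshots."""

    trajectory: DistributionTrajectory
    snapshots: np.ndarray  # boolean, shape (n, len(times), N)


def turnover_counts(state_t1: ConnectionState, state_t2: ConnectionState) -> TurnoverReport:
    """Created / removed / persistent synapses from site-wise overlap."""
    if state_t1.N != state_t2.N:
        raise ValueError(f"states differ in N: {state_t1.N} vs {state_t2.N}")
    a, b = state_t1.occupancy, state_t2.occupancy
    return TurnoverReport(
        created=int((~a & b).sum()),
        removed=int((a & ~b).sum()),
        persistent=int((a & b).sum()),
    )


def _draw_waits(
    occ: np.ndarray, b: float, d: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Geometric waiting times (>= 1 step) per site; _NO_EVENT for rate 0."""
    N = occ.size
    S = int(occ.sum())
    rates = np.where(occ, d[S], b)
    waits = np.full(N, _NO_EVENT, dtype=np.int64)
    active = rates > 0
    if active.any():
        waits[active] = rng.geometric(rates[active])
    return waits


def simulate_connection(
    params: ModelParams,
    profiles: Mapping[str, DeletionProfile],
    schedule: Sequence[tuple[str, int]],
    record_times: Sequence[int],
    seed: int | np.random.Generator,
    initial: ConnectionState | int = 0,
) -> list[ConnectionState]:
    """Simulate one connection through a phase schedule; snapshot at record times.

    Parameters
    ----------
    schedule
        Ordered phases ``(condition label, duration in steps)``.
    record_times
        Absolute step times (within the schedule's total duration) at which
        the occupancy is recorded; a snapshot at ``t`` reflects all events up
        to and including step ``t``.
    initial
        Starting occupancy, or an integer count ``S0`` (the first ``S0``
        sites are occupied; site identity is exchangeable).
    """
    N, b = params.N, params.b
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if isinstance(initial, ConnectionState):
        occ = initial.occupancy.copy()
        if occ.size != N:
            raise ValueError(f"initial state has N = {occ.size}, params.N = {N}")
    else:
        if not (0 <= initial <= N):
            raise ValueError(f"initial count must lie in [0, {N}], got {initial!r}")
        occ = np.zeros(N, dtype=bool)
        occ[: int(initial)] = True

    record_times = np.asarray(sorted(int(t) for t in record_times), dtype=np.int64)
    total = sum(int(dur) for _, dur in schedule)
    if record_times.size and record_times[-1] > total:
        raise ValueError(
            f"record time {record_times[-1]} exceeds schedule duration {total}"
        )
    for cond, _ in schedule:
        if cond not in profiles:
            raise KeyError(f"unknown condition label {cond!r} in schedule")

    out: list[ConnectionState] = []
    ri = 0
    t = 0  # absolute current time (steps completed)
    for cond, dur in schedule:
        d = profiles[cond].d
        phase_end = t + int(dur)
        waits = _draw_waits(occ, b, d, rng)  # condition switch: redraw everything
        while True:
            wmin = waits.min()
            t_event = t + int(wmin) if wmin != _NO_EVENT else _NO_EVENT
            t_next = min(t_event, phase_end)
            while ri < record_times.size and record_times[ri] < t_next:
                out.append(ConnectionState(occ.copy()))
                ri += 1
            if t_event > phase_end:
                t = phase_end
                break
            t = t_event
            candidates = np.nonzero(waits == wmin)[0]
            site = int(candidates[0] if candidates.size == 1 else rng.choice(candidates))
            occ[site] = ~occ[site]
            while ri < record_times.size and record_times[ri] <= t:
                out.append(ConnectionState(occ.copy()))
                ri += 1
            if t == phase_end:
                break
            waits = _draw_waits(occ, b, d, rng)
    while ri < record_times.size:
        out.append(ConnectionState(occ.copy()))
        ri += 1
    return out


def simulate_population(
    n: int,
    params: ModelParams,
    profiles: Mapping[str, DeletionProfile],
    schedule: Sequence[tuple[str, int]],
    record_times: Sequence[int],
    seed: int,
    initial: int | np.ndarray = 0,
) -> PopulationResult:
    """Simulate ``n`` independent connections with derived seeds ``seed + i``.

    ``initial`` is either one count for every connection or a probability
    vector over S(0) from which each connection draws its starting count
    (with its own derived stream, so runs are bit-reproducible).
    """
    if n < 1:
        raise ValueError(f"population size must be >= 1, got {n!r}")
    record_times = sorted(int(t) for t in record_times)
    times = np.asarray(record_times, dtype=np.int64)
    N = params.N
    snaps = np.zeros((n, times.size, N), dtype=bool)
    init_dist = None
    if not np.isscalar(initial):
        init_dist = np.asarray(initial, dtype=float)
        if init_dist.shape != (N + 1,) or abs(init_dist.sum() - 1.0) > 1e-9:
            raise ValueError("initial must be a count or a distribution over 0..N")
    for i in range(n):
        rng = np.random.default_rng(int(seed) + i)
        if init_dist is None:
            s0 = int(initial)
            occ0: ConnectionState | int = s0
        else:
            s0 = int(rng.choice(N + 1, p=init_dist))
            occ = np.zeros(N, dtype=bool)
            occ[rng.choice(N, size=s0, replace=False)] = True
            occ0 = ConnectionState(occ)
        states = simulate_connection(
            params, profiles, schedule, record_times, rng, initial=occ0
        )
        for k, st in enumerate(states):
            snaps[i, k] = st.occupancy
    counts = snaps.sum(axis=2)  # (n, T)
    freqs = np.stack(
        [np.bincount(counts[:, k], minlength=N + 1) / n for k in range(times.size)]
    )
    cond_at = []
    bounds: list[tuple[int, str]] = []
    acc = 0
    for cond, dur in schedule:
        acc += int(dur)
        bounds.append((acc, cond))
    for t in times:
        cond_at.append(next(c for end, c in bounds if t <= end))
    traj = DistributionTrajectory(times, freqs, condition_schedule=cond_at)
    return PopulationResult(trajectory=traj, snapshots=snaps)
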