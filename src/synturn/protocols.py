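"""The three experimental paradigms as reproducible pipelines.

* decay: fix one stimulation condition, start from a chosen initial law of
  S(0), and follow MI(S(0); S(t)) on an exponential time grid (the
  information-decay experiments, including the long-lived plateau under the
  bimodal working point).
* learning/retention: equilibrate to the working point, switch each branch
  to its condition (learning), then revert all branches to the working point
  (retention); MI(S(t); condition) in both phases and the time-scale ratio
  delta_T = tau50(retention) / tau50(learning).
* retraining: the in-vivo motor-learning timeline (30 d rest, 16 d early
  training, 74 d rest, 8 d late training, against control and late-only
  paradigms) with per-day created/removed synapse counts from site-level
  turnover accounting.

Exact master-equation propagation is the default everywhere it applies;
population mode runs the event-driven simulator instead and is subject to
sampling error only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import twostate
from .calibration import CalibrationResult
from .information import (
    BEYOND_HORIZON,
    ConditionMix,
    MICurve,
    mi_between_time_points,
    mi_condition,
    tau_fraction,
)
from .model_core import (
    DeletionProfile,
    DistributionTrajectory,
    ModelParams,
    PeakParams,
    StationaryDistribution,
    TransitionMatrix,
    condition_distribution,
    deletion_rates,
    propagate,
    total_variation,
    transition_matrix,
)
from .simulate import simulate_population, turnover_counts, ConnectionState

__all__ = [
    "CONDITIONS",
    "ConditionSystem",
    "Protocol",
    "build_system",
    "exponential_grid",
    "make_initial",
    "decay_experiment",
    "learning_experiment",
    "retraining_experiment",
    "sweep",
    "DecayResult",
    "LearningResult",
    "RetrainingResult",
    "SweepResult",
]

CONDITIONS = ("low", "wp", "high")


@dataclass(frozen=True)
class ConditionSystem:
    """Stationary target, deletion profile and transition matrix per condition."""

    params: ModelParams
    peaks: PeakParams
    stationary: dict[str, StationaryDistribution]
    profiles: dict[str, DeletionProfile]
    matrices: dict[str, TransitionMatrix]


def build_system(params: ModelParams, peaks: PeakParams) -> ConditionSystem:
    stat = {c: condition_distribution(c, peaks, params.N) for c in CONDITIONS}
    prof = {c: deletion_rates(stat[c], params) for c in CONDITIONS}
    mats = {c: transition_matrix(params, prof[c]) for c in CONDITIONS}
    return ConditionSystem(params, peaks, stat, prof, mats)


@dataclass(frozen=True)
class Protocol:
    """Ordered stimulation phases plus initial condition and mix."""

    phases: tuple[tuple[str, int], ...]
    initial_spec: str = "wp_draw"
    mix: ConditionMix | None = None
    n_connections: int = 500
    base_seed: int = 0

    def __post_init__(self) -> None:
        for cond, dur in self.phases:
            if dur < 1:
                raise ValueError(f"phase duration must be >= 1, got {dur!r}")

    @property
    def duration(self) -> int:
        return sum(d for _, d in self.phases)


def exponential_grid(horizon: int | float, growth: float = 1.2) -> np.ndarray:
    """Deduplicated integer grid t_k = round(growth**k), 1 <= t_k <= horizon."""
    if horizon < 1:
        raise ValueError(f"horizon must be >= 1, got {horizon!r}")
    kmax = int(math.ceil(math.log(float(horizon)) / math.log(growth))) + 1
    t = np.unique(np.round(growth ** np.arange(kmax + 1)).astype(np.int64))
    return t[(t >= 1) & (t <= int(horizon))]


def make_initial(
    spec: str,
    N: int,
    *,
    S0: int | None = None,
    C: float | None = None,
    p_wp: StationaryDistribution | None = None,
    lower_states: Sequence[int] = (0, 1, 2),
    upper_from: int = 4,
) -> np.ndarray:
    """Initial distribution over S(0) for a named specification.

    ``wp_draw`` uses the working-point law itself; ``delta`` a point mass at
    S0; ``two_delta`` masses 1-C at S=0 and C at S=N; ``piecewise_uniform``
    spreads 1-C uniformly over ``lower_states`` and C uniformly over
    ``{upper_from..N}`` (the count between the peaks is excluded by default
    and assignable via these knobs).
    """
    p = np.zeros(N + 1)
    if spec == "wp_draw":
        if p_wp is None:
            raise ValueError("wp_draw requires p_wp")
        return p_wp.p.copy()
    if spec == "delta":
        if S0 is None or not (0 <= S0 <= N):
            raise ValueError(f"delta requires S0 in 0..{N}, got {S0!r}")
        p[int(S0)] = 1.0
        return p
    if C is None or not (0.0 <= C <= 1.0):
        raise ValueError(f"{spec} requires C in [0, 1], got {C!r}")
    if spec == "two_delta":
        p[0] = 1.0 - C
        p[N] = C
        return p
    if spec == "piecewise_uniform":
        lower = [s for s in lower_states if 0 <= s <= N]
        upper = list(range(int(upper_from), N + 1))
        if not lower or not upper:
            raise ValueError("piecewise_uniform peaks are empty for this N")
        p[lower] = (1.0 - C) / len(lower)
        p[upper] = C / len(upper)
        return p
    raise ValueError(f"unknown initial specification {spec!r}")


def _exact_conditionals(
    M: TransitionMatrix, support: Sequence[int], times: np.ndarray
) -> dict[int, DistributionTrajectory]:
    n = M.N + 1
    out = {}
    for s0 in support:
        e = np.zeros(n)
        e[s0] = 1.0
        dists = np.stack([propagate(e, M, int(t)) for t in times])
        out[s0] = DistributionTrajectory(times, dists)
    return out


@dataclass
class DecayResult:
    condition: str
    initial: np.ndarray
    mi: MICurve
    trajectory: DistributionTrajectory  # marginal p[S(t)]
    conditionals: dict[int, DistributionTrajectory]


def decay_experiment(
    system: ConditionSystem,
    initial: np.ndarray,
    condition: str,
    horizon: int | float,
    mode: str = "exact",
    n: int = 500,
    seed: int = 0,
    growth: float = 1.2,
) -> DecayResult:
    """Information decay under a fixed stimulation condition.

    Each initial count in the support of ``initial`` is propagated (exactly,
    or as a simulated population of ``n`` connections per initial count) and
    MI(S(0); S(t)) is assembled by total probability on an exponential grid.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}, got {condition!r}")
    if horizon < 1:
        raise ValueError(f"horizon must be >= 1, got {horizon!r}")
    initial = np.asarray(initial, dtype=float)
    times = exponential_grid(horizon, growth)
    support = [int(s) for s in np.nonzero(initial > 0)[0]]
    if mode == "exact":
        conds = _exact_conditionals(system.matrices[condition], support, times)
    elif mode == "population":
        conds = {}
        for j, s0 in enumerate(support):
            pop = simulate_population(
                n,
                system.params,
                system.profiles,
                [(condition, int(times[-1]))],
                times,
                seed + 1_000_003 * j,
                initial=s0,
            )
            conds[s0] = pop.trajectory
    else:
        raise ValueError(f"mode must be 'exact' or 'population', got {mode!r}")
    curve = mi_between_time_points({s: initial[s] for s in support}, conds)
    marg = np.einsum(
        "k,ktn->tn",
        np.array([initial[s] for s in support]),
        np.stack([conds[s].dists for s in support]),
    )
    traj = DistributionTrajectory(times, marg, condition_schedule=[condition] * times.size)
    return DecayResult(condition, initial, curve, traj, conds)


@dataclass
class LearningResult:
    learning: MICurve
    retention: MICurve
    tau50_learning: float
    tau50_retention: float
    delta_T: float
    warnings: list[str] = field(default_factory=list)


def learning_experiment(
    system: ConditionSystem,
    mix: ConditionMix | Mapping[str, float] | None = None,
    learn_horizon: int | float = 1e10,
    retain_horizon: int | float = 1e13,
    mode: str = "exact",
    n: int = 1500,
    seed: int = 0,
    growth: float = 1.2,
    convergence_tv: float = 1e-6,
) -> LearningResult:
    """Learning (condition switch away from wp) then retention (switch back).

    MI(S(t); condition) is tracked per phase; tau50 is the 50%-of-max
    crossing in each phase, and delta_T their retention/learning ratio.
    Phases shorter than their own convergence (total variation to the phase
    stationary above ``convergence_tv`` at the horizon) are recorded as
    warnings, matching the requirement that each phase runs to equilibrium.
    """
    if mix is None:
        mix = ConditionMix({c: 1.0 / 3.0 for c in CONDITIONS})
    elif not isinstance(mix, ConditionMix):
        mix = ConditionMix(dict(mix))
    warnings: list[str] = []
    p_wp = system.stationary["wp"].p
    t_learn = exponential_grid(learn_horizon, growth)
    t_ret = exponential_grid(retain_horizon, growth)

    if mode == "exact":
        learn_branches: dict[str, DistributionTrajectory] = {}
        end_state: dict[str, np.ndarray] = {}
        for c in CONDITIONS:
            M = system.matrices[c]
            dists = np.stack([propagate(p_wp, M, int(t)) for t in t_learn])
            learn_branches[c] = DistributionTrajectory(t_learn, dists)
            end_state[c] = dists[-1]
            tv = total_variation(dists[-1], system.stationary[c].p)
            if tv > convergence_tv:
                warnings.append(
                    f"learning phase not converged for condition {c!r}: TV = {tv:.2e}"
                )
        Mwp = system.matrices["wp"]
        ret_branches = {
            c: DistributionTrajectory(
                t_ret, np.stack([propagate(end_state[c], Mwp, int(t)) for t in t_ret])
            )
            for c in CONDITIONS
        }
        for c in CONDITIONS:
            tv = total_variation(ret_branches[c].dists[-1], p_wp)
            if tv > convergence_tv:
                warnings.append(
                    f"retention phase not converged for condition {c!r}: TV = {tv:.2e}"
                )
    elif mode == "population":
        rng = np.random.default_rng(seed)
        draws = rng.choice(CONDITIONS, size=n, p=[mix.probs[c] for c in CONDITIONS])
        learn_branches = {}
        ret_branches = {}
        for j, c in enumerate(CONDITIONS):
            nc = max(int((draws == c).sum()), 1)
            sched = [(c, int(t_learn[-1])), ("wp", int(t_ret[-1]))]
            rts = np.concatenate([t_learn, t_learn[-1] + t_ret])
            pop = simulate_population(
                nc,
                system.params,
                system.profiles,
                sched,
                rts,
                seed + 7_777_777 * (j + 1),
                initial=p_wp,
            )
            dists = pop.trajectory.dists
            learn_branches[c] = DistributionTrajectory(t_learn, dists[: t_learn.size])
            ret_branches[c] = DistributionTrajectory(t_ret, dists[t_learn.size :])
    else:
        raise ValueError(f"mode must be 'exact' or 'population', got {mode!r}")

    mi_learn = mi_condition(mix, learn_branches)
    mi_ret = mi_condition(mix, ret_branches)
    tau_l = tau_fraction(mi_learn, "rise_to", 0.5, reference="max")
    tau_r = tau_fraction(mi_ret, "decay_to", 0.5, reference="max")
    if math.isinf(tau_l) or math.isinf(tau_r) or tau_l == 0:
        delta = BEYOND_HORIZON
    else:
        delta = tau_r / tau_l
    return LearningResult(mi_learn, mi_ret, tau_l, tau_r, delta, warnings)


# --- retraining (dendritic-spine) paradigm ------------------------------------

PARADIGMS = ("control", "retraining", "late_only")


@dataclass
class RetrainingResult:
    paradigm: str
    days: np.ndarray  # day index 1..D for per-day turnover
    created: np.ndarray  # (replicates, D) population totals per day
    removed: np.ndarray
    synapse_count: np.ndarray  # (replicates, D+1) totals at day boundaries
    n_connections: int
    groups: dict[str, int]

    def mean_sem(self, which: str) -> tuple[np.ndarray, np.ndarray]:
        x = {"created": self.created, "removed": self.removed}[which]
        m = x.mean(axis=0)
        sem = x.std(axis=0, ddof=1) / math.sqrt(x.shape[0]) if x.shape[0] > 1 else 0 * m
        return m, sem


def _retraining_schedule(paradigm: str, group: str) -> list[tuple[str, int]]:
    """Phase list in days for one connection group under one paradigm."""
    if paradigm == "control" or group == "wp":
        return [("wp", 128)]
    if paradigm == "retraining":
        return [("wp", 30), (group, 16), ("wp", 74), (group, 8)]
    if paradigm == "late_only":
        return [("wp", 120), (group, 8)]
    raise ValueError(f"unknown paradigm {paradigm!r}")


def retraining_experiment(
    paradigm: str,
    params: ModelParams | None = None,
    peaks: PeakParams | None = None,
    steps_per_day: int = 23_000_000,
    frac_low: float = 0.0435,
    frac_high: float = 0.0065,
    target_synapses: int = 160,
    replicates: int = 8,
    seed: int = 0,
) -> RetrainingResult:
    """Per-day synapse creation/removal under the in-vivo stimulation scheme.

    A population sized so its expected initial synapse count matches the
    observed spine count is split into a small low-stimulated and an even
    smaller high-stimulated subgroup; the remainder stays at the working
    point.  Occupancy snapshots at day boundaries give per-day created and
    removed counts via site overlap, repeated over seeded replicates
    ("animals").  Defaults follow the published protocol: N = 5, sigma = 1.0,
    4.35% low / 0.65% high, ~160 synapses, 8 replicates.
    """
    if paradigm not in PARADIGMS:
        raise ValueError(f"paradigm must be one of {PARADIGMS}, got {paradigm!r}")
    params = params or ModelParams(N=5, b=1e-8)
    peaks = peaks or PeakParams(sigma=1.0)
    system = build_system(params, peaks)
    p_wp = system.stationary["wp"]
    n = max(int(round(target_synapses / p_wp.mean())), 1)
    n_low = int(round(frac_low * n))
    n_high = int(round(frac_high * n))
    groups = {"low": n_low, "high": n_high, "wp": n - n_low - n_high}

    total_days = 128
    day_bounds = np.arange(total_days + 1, dtype=np.int64) * int(steps_per_day)
    created = np.zeros((replicates, total_days), dtype=int)
    removed = np.zeros((replicates, total_days), dtype=int)
    counts = np.zeros((replicates, total_days + 1), dtype=int)
    for r in range(replicates):
        base = seed + 104_729 * (r + 1)
        offset = 0
        for group, ng in groups.items():
            if ng == 0:
                continue
            sched = [
                (cond, days * int(steps_per_day))
                for cond, days in _retraining_schedule(paradigm, group)
            ]
            pop = simulate_population(
                ng,
                params,
                system.profiles,
                sched,
                day_bounds,
                base + offset,
                initial=p_wp.p,
            )
            snaps = pop.snapshots  # (ng, D+1, N)
            prev = snaps[:, :-1, :]
            nxt = snaps[:, 1:, :]
            created[r] += (~prev & nxt).sum(axis=(0, 2))
            removed[r] += (prev & ~nxt).sum(axis=(0, 2))
            counts[r] += snaps.sum(axis=(0, 2))
            offset += ng
    return RetrainingResult(
        paradigm=paradigm,
        days=np.arange(1, total_days + 1),
        created=created,
        removed=removed,
        synapse_count=counts,
        n_connections=n,
        groups=groups,
    )


# --- parameter sweeps ----------------------------------------------------------


@dataclass
class SweepResult:
    cells: list[dict]  # peak params + metric value + status per cell

    def values(self, key: str = "value") -> list:
        return [c[key] for c in self.cells]


def _tau95(system: ConditionSystem, horizon: float, growth: float) -> float:
    """Plateau decay time: wp-condition MI from the two-delta initial falling
    below 95% of the matched two-state plateau H2(C_upper)."""
    peaks = system.peaks
    initial = make_initial("two_delta", system.params.N, C=peaks.C)
    res = decay_experiment(system, initial, "wp", horizon, growth=growth)
    ts = twostate.matched_two_state(
        system.stationary["wp"], system.params, q=float(initial[system.params.N :].sum())
    )
    plateau = twostate.two_state_mi(0.0, ts.C, ts.R, ts.p_init)
    return tau_fraction(res.mi, "decay_to", 0.95, reference="plateau", reference_value=plateau)


def sweep(
    params: ModelParams,
    base_peaks: PeakParams,
    vary: Mapping[str, Sequence[float]],
    metric: str = "tau95",
    horizon: float = 1e12,
    growth: float = 1.3,
) -> SweepResult:
    """Metric over a one-factor-at-a-time grid of peak parameters.

    ``vary`` maps parameter names (mu, sigma, lam, C) to value lists; the
    full cartesian product is evaluated.  Cells whose working point is not
    bimodal (or whose rates violate the validity bound) are marked invalid
    rather than failing the sweep.
    """
    if metric not in ("tau95", "deltaT"):
        raise ValueError(f"metric must be 'tau95' or 'deltaT', got {metric!r}")
    names = list(vary)
    grids = [list(vary[k]) for k in names]
    cells: list[dict] = []
    idx = np.indices([len(g) for g in grids]).reshape(len(names), -1).T if names else []
    for combo in idx:
        kw = {k: grids[j][combo[j]] for j, k in enumerate(names)}
        peaks = PeakParams(**{**base_peaks.__dict__, **kw})
        cell = {**peaks.__dict__}
        try:
            system = build_system(params, peaks)
            if metric == "tau95":
                cell["value"] = _tau95(system, horizon, growth)
            else:
                res = learning_experiment(
                    system, learn_horizon=min(horizon, 1e10), retain_horizon=horizon,
                    growth=growth,
                )
                cell["value"] = res.delta_T
            cell["status"] = "ok" if math.isfinite(cell["value"]) else "beyond horizon"
        except ValueError as exc:
            cell["value"] = math.nan
            cell["status"] = f"invalid: {exc}"
        cells.append(cell)
    return SweepResult(cells)
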