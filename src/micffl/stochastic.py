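"""Exact stochastic simulation (Gillespie's direct method) and moment
estimation for the titrative circuits.

The jump process is defined by the reaction list of
:func:`micffl.circuits.build_reaction_system`; propensities use the full
nonlinear Hill activation (no linearization is needed at this level, which
is what makes the simulation the oracle for the linear noise approximation).

Two recording modes are provided: a uniform sampling grid (sample-and-hold,
used for stationary moments) and full event-wise recording (used e.g. to
assert miRNA conservation when the recycling probability is 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .circuits import (
    CircuitTopology,
    KineticParameters,
    ReactionSystem,
    build_reaction_system,
    get_topology,
    with_interaction_strength,
)
from .errors import ConfigurationError

__all__ = [
    "Trajectory",
    "MomentSummary",
    "gillespie",
    "stationary_moments",
    "correlation_scan",
]


@njit(cache=True)
def _propensities(x, kind, rate, ii, jj, hn, hh, a):
    atot = 0.0
    for r in range(kind.size):
        k = kind[r]
        if k == 0:
            v = rate[r]
        elif k == 1:
            v = rate[r] * x[ii[r]]
        elif k == 2:
            v = rate[r] * x[ii[r]] * x[jj[r]]
        else:
            p = float(x[ii[r]])
            if p <= 0.0:
                v = 0.0
            else:
                num = p ** hn[r]
                v = rate[r] * num / (num + hh[r] ** hn[r])
        a[r] = v
        atot += v
    return atot


@njit(cache=True)
def _ssa_grid(x0, stoich, kind, rate, ii, jj, hn, hh, times, seed):
    """Direct-method SSA sampled on a fixed time grid (state held between
    events).  Returns the sampled states and whether an absorbing state was
    reached before the horizon."""
    np.random.seed(seed)
    n_rec = times.size
    n_s = x0.size
    out = np.zeros((n_rec, n_s), dtype=np.int64)
    a = np.zeros(kind.size, dtype=np.float64)
    x = x0.copy()
    t = 0.0
    rec = 0
    absorbed = False
    t_end = times[n_rec - 1]
    while True:
        atot = _propensities(x, kind, rate, ii, jj, hn, hh, a)
        if atot <= 0.0:
            absorbed = True
            break
        t_next = t + (-math.log(np.random.random())) / atot
        while rec < n_rec and times[rec] < t_next:
            for s in range(n_s):
                out[rec, s] = x[s]
            rec += 1
        if t_next > t_end:
            t = t_end
            break
        u = np.random.random() * atot
        acc = 0.0
        r_sel = kind.size - 1
        for r in range(kind.size):
            acc += a[r]
            if u < acc:
                r_sel = r
                break
        for s in range(n_s):
            x[s] += stoich[r_sel, s]
        t = t_next
    while rec < n_rec:
        for s in range(n_s):
            out[rec, s] = x[s]
        rec += 1
    return out, absorbed


@njit(cache=True)
def _ssa_events(x0, stoich, kind, rate, ii, jj, hn, hh, t_end, max_events, seed):
    """Direct-method SSA recording every event (initial state included)."""
    np.random.seed(seed)
    n_s = x0.size
    t_out = np.zeros(max_events + 1, dtype=np.float64)
    x_out = np.zeros((max_events + 1, n_s), dtype=np.int64)
    a = np.zeros(kind.size, dtype=np.float64)
    x = x0.copy()
    for s in range(n_s):
        x_out[0, s] = x[s]
    t = 0.0
    n = 0
    absorbed = False
    while n < max_events:
        atot = _propensities(x, kind, rate, ii, jj, hn, hh, a)
        if atot <= 0.0:
            absorbed = True
            break
        dt = (-math.log(np.random.random())) / atot
        if t + dt > t_end:
            break
        t += dt
        u = np.random.random() * atot
        acc = 0.0
        r_sel = kind.size - 1
        for r in range(kind.size):
            acc += a[r]
            if u < acc:
                r_sel = r
                break
        for s in range(n_s):
            x[s] += stoich[r_sel, s]
        n += 1
        t_out[n] = t
        for s in range(n_s):
            x_out[n, s] = x[s]
    return t_out[: n + 1], x_out[: n + 1], absorbed


@dataclass(frozen=True)
class Trajectory:
    """Sampled stochastic path (integer copy numbers)."""

    t: np.ndarray
    states: np.ndarray
    species: tuple[str, ...]
    seed: int
    absorbed: bool = False
    mode: str = "grid"

    def __getitem__(self, species: str) -> np.ndarray:
        return self.states[:, self.species.index(species)]


def _initial_state(system: ReactionSystem, state0) -> np.ndarray:
    if state0 is None:
        # deterministic driven fixed point, rounded: fast equilibration
        from .deterministic import steady_state_given_transcription

        ss = steady_state_given_transcription(system.params, system.topology)
        x0 = np.rint(ss.state_vector(system)).astype(np.int64)
    elif isinstance(state0, dict):
        x0 = np.array(
            [int(round(state0.get(s, 0))) for s in system.species], dtype=np.int64
        )
    else:
        x0 = np.asarray(state0).astype(np.int64)
    if x0.shape != (system.n_species,) or np.any(x0 < 0):
        raise ValueError("state0 must be non-negative integers, one per species")
    return x0


def gillespie(
    system: ReactionSystem,
    state0=None,
    t_end: float = 100.0,
    seed: int = 0,
    *,
    record: str = "grid",
    n_samples: int = 2000,
    max_events: int = 1_000_000,
) -> Trajectory:
    """Statistically exact sample of the jump process.

    ``record="grid"`` samples the held state on ``n_samples`` uniform times
    in [0, t_end]; ``record="events"`` stores every event up to
    ``max_events``.  Identical (seed, inputs) give identical paths."""
    x0 = _initial_state(system, state0)
    kind, rate, ii, jj, hn, hh = system.kernel_arrays()
    stoich = system.stoichiometry
    seed = int(seed) % (2**32)
    if record == "grid":
        times = np.linspace(0.0, float(t_end), int(n_samples))
        states, absorbed = _ssa_grid(
            x0, stoich, kind, rate, ii, jj, hn, hh, times, seed
        )
        return Trajectory(times, states, system.species, seed, absorbed, "grid")
    if record == "events":
        t, states, absorbed = _ssa_events(
            x0, stoich, kind, rate, ii, jj, hn, hh, float(t_end), int(max_events),
            seed,
        )
        return Trajectory(t, states, system.species, seed, absorbed, "events")
    raise ValueError(f"unknown record mode {record!r}")


@dataclass(frozen=True)
class MomentSummary:
    """First two stationary moments with batch-means standard errors."""

    species: tuple[str, ...]
    mean: np.ndarray
    variance: np.ndarray
    se_mean: np.ndarray
    covariance: float            # cov(pair)
    correlation: float | None    # Pearson rho(pair); None when degenerate
    correlation_se: float | None
    pair: tuple[str, str]
    n_samples: int
    ess: np.ndarray
    flags: tuple[str, ...] = field(default=())

    def mean_of(self, species: str) -> float:
        return float(self.mean[self.species.index(species)])

    def var_of(self, species: str) -> float:
        return float(self.variance[self.species.index(species)])


def stationary_moments(
    traj: Trajectory,
    burn_in: float,
    *,
    n_batches: int = 20,
    pair: tuple[str, str] = ("pTF", "pT"),
) -> MomentSummary:
    """Moments over [burn_in, t_end] of a grid-sampled trajectory.

    Standard errors come from ``n_batches`` batch means; the effective
    sample size is the ratio of the naive to the batch-means variance of
    the mean.  A constant trajectory is flagged and its correlation left
    undefined."""
    if traj.mode != "grid":
        raise ValueError("stationary moments require a grid-sampled trajectory")
    if burn_in >= traj.t[-1]:
        raise ValueError(f"burn_in {burn_in} >= trajectory end {traj.t[-1]}")
    keep = traj.t >= burn_in
    x = traj.states[keep].astype(float)
    n = x.shape[0]
    if n < 2 * n_batches:
        raise ValueError(f"only {n} samples after burn-in; need >= {2 * n_batches}")
    mean = x.mean(axis=0)
    var = x.var(axis=0)

    usable = (n // n_batches) * n_batches
    batches = x[:usable].reshape(n_batches, usable // n_batches, -1)
    bmeans = batches.mean(axis=1)
    se_mean = bmeans.std(axis=0, ddof=1) / np.sqrt(n_batches)
    with np.errstate(divide="ignore", invalid="ignore"):
        ess = np.where(se_mean > 0, var / se_mean**2, np.float64(n))

    ia, ib = traj.species.index(pair[0]), traj.species.index(pair[1])
    cov = float(np.mean((x[:, ia] - mean[ia]) * (x[:, ib] - mean[ib])))
    flags: list[str] = []
    if traj.absorbed:
        flags.append("absorbed")
    if var[ia] <= 0 or var[ib] <= 0:
        flags.append("degenerate")
        rho, rho_se = None, None
    else:
        rho = cov / math.sqrt(var[ia] * var[ib])
        # batch-means SE of the correlation
        brho = np.empty(n_batches)
        for b in range(n_batches):
            xa, xb = batches[b, :, ia], batches[b, :, ib]
            sa, sb = xa.std(), xb.std()
            brho[b] = (
                np.mean((xa - xa.mean()) * (xb - xb.mean())) / (sa * sb)
                if sa > 0 and sb > 0
                else 0.0
            )
        rho_se = float(brho.std(ddof=1) / np.sqrt(n_batches))
    return MomentSummary(
        traj.species, mean, var, se_mean, cov, rho, rho_se, pair, n,
        np.asarray(ess), tuple(flags),
    )


def default_burn_in(params: KineticParameters, topology: CircuitTopology) -> float:
    """Ten times the slowest deterministic relaxation time at the driven
    fixed point."""
    from .deterministic import relaxation_time

    return 10.0 * relaxation_time(params, topology)


def correlation_scan(
    params: KineticParameters,
    topology: CircuitTopology | str,
    k_mi_grid,
    strength_grid,
    *,
    n_seeds: int = 10,
    seed: int = 0,
    t_sample: float = 200.0,
    burn_in: float | None = None,
    n_samples: int = 4000,
    pair: tuple[str, str] = ("pTF", "pT"),
):
    """Pearson correlation of (pTF, pT) over a (miRNA transcription rate,
    interaction strength F) grid, estimated from ``n_seeds`` independent
    SSA runs per cell.

    Returns a dict with ``rho`` (mean over seeds), ``rho_se`` (standard
    error over seeds) and the per-seed array, each shaped
    (len(k_mi_grid), len(strength_grid))."""
    if isinstance(topology, str):
        topology = get_topology(topology)
    k_mi_grid = np.asarray(k_mi_grid, dtype=float)
    strength_grid = np.asarray(strength_grid, dtype=float)
    if k_mi_grid.size == 0 or strength_grid.size == 0:
        raise ConfigurationError("scan grids must be non-empty")
    rng = np.random.default_rng(seed)
    cell_seeds = rng.integers(0, 2**31 - 1, size=(k_mi_grid.size,
                                                  strength_grid.size, n_seeds))
    rho = np.full((k_mi_grid.size, strength_grid.size, n_seeds), np.nan)
    for a, k_mi in enumerate(k_mi_grid):
        for b, f in enumerate(strength_grid):
            p = with_interaction_strength(params.replace(k_mi=float(k_mi)), float(f))
            system = build_reaction_system(p, topology)
            bi = default_burn_in(p, topology) if burn_in is None else burn_in
            t_end = bi + t_sample
            for s in range(n_seeds):
                traj = gillespie(
                    system, None, t_end, int(cell_seeds[a, b, s]),
                    n_samples=n_samples,
                )
                m = stationary_moments(traj, bi, pair=pair)
                if m.correlation is not None:
                    rho[a, b, s] = m.correlation
    rho_mean = np.nanmean(rho, axis=2)
    rho_se = np.nanstd(rho, axis=2, ddof=1) / np.sqrt(n_seeds)
    return {
        "k_mi": k_mi_grid,
        "strength": strength_grid,
        "rho": rho_mean,
        "rho_se": rho_se,
        "rho_per_seed": rho,
    }
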