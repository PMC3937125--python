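"""Linear noise approximation (LNA) around the deterministic fixed point.

Fluctuations of the copy numbers are Gaussian to leading order in the
system-size expansion; their stationary covariance C solves the continuous
Lyapunov equation

    A C + C A^T + B = 0

where A is the drift Jacobian at the fixed point (the Hill activation enters
through its first-order Taylor expansion around pTF*) and
B = sum_r nu_r nu_r^T a_r(x*) is the diffusion matrix assembled from the
reaction stoichiometries and steady-state propensities.  The Pearson
correlation of (pTF, pT) derived from C is the fast analogue of the SSA
correlation scan, and the threshold analysis quantifies the titration-driven
hypersensitivity of the target to the miRNA transcription rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_continuous_lyapunov

from .circuits import (
    CircuitTopology,
    K_BIMOL,
    K_HILL,
    K_LINEAR,
    KineticParameters,
    ReactionSystem,
    build_reaction_system,
    get_topology,
    hill_activation,
    hill_slope,
    with_interaction_strength,
)
from .deterministic import SteadyState, steady_state_given_transcription
from .errors import AnalysisError, ConfigurationError, NumericalError

__all__ = [
    "LNAResult",
    "ThresholdResult",
    "drift_jacobian",
    "linearize_hill",
    "lna_covariance",
    "correlation_heatmap",
    "noise_profile",
    "threshold_analysis",
    "equimolar_flux",
]


def drift_jacobian(system: ReactionSystem, state: np.ndarray) -> np.ndarray:
    """Jacobian of the macroscopic drift S^T a(x) at ``state`` (count units)."""
    n_r, n_s = system.n_reactions, system.n_species
    grad = np.zeros((n_r, n_s))
    for r, rxn in enumerate(system.reactions):
        if rxn.kind == K_LINEAR:
            grad[r, rxn.i] = rxn.rate
        elif rxn.kind == K_BIMOL:
            grad[r, rxn.i] = rxn.rate * state[rxn.j]
            grad[r, rxn.j] = rxn.rate * state[rxn.i]
        elif rxn.kind == K_HILL:
            grad[r, rxn.i] = hill_slope(
                float(state[rxn.i]), rxn.hill_n, rxn.hill_h, rxn.rate
            )
    return system.stoichiometry.T @ grad


def linearize_hill(
    params: KineticParameters, steady: SteadyState
) -> tuple[float, float]:
    """First-order expansion of the target transcription rate around pTF*.

    Returns (intercept, slope) such that the rate is approximately
    intercept + slope * pTF near the fixed point; slope is
    k_mT n h^n pTF*^{n-1} / (pTF*^n + h^n)^2."""
    ptf = steady["pTF"]
    if ptf < 0:
        raise ValueError("pTF* must be >= 0")
    p = params
    slope = hill_slope(ptf, p.hill_n, p.hill_h, p.k_mt)
    value = hill_activation(ptf, p.hill_n, p.hill_h, p.k_mt)
    return value - slope * ptf, slope


@dataclass(frozen=True)
class LNAResult:
    """Stationary Gaussian fluctuation structure at one fixed point."""

    species: tuple[str, ...]
    steady: SteadyState
    a: np.ndarray          # drift Jacobian
    b: np.ndarray          # diffusion matrix
    covariance: np.ndarray

    def index(self, species: str) -> int:
        return self.species.index(species)

    def corr(self, sa: str, sb: str) -> float:
        ia, ib = self.index(sa), self.index(sb)
        va, vb = self.covariance[ia, ia], self.covariance[ib, ib]
        if va <= 0 or vb <= 0:
            raise AnalysisError(f"degenerate variance for ({sa}, {sb})")
        return float(self.covariance[ia, ib] / np.sqrt(va * vb))

    @property
    def rho(self) -> float:
        """Pearson correlation of (pTF, pT)."""
        return self.corr("pTF", "pT")

    def cv(self, species: str, omega: float = 1.0) -> float:
        """Coefficient of variation sqrt(C_ss)/<x_s> of one species
        (``omega`` converts the steady concentration to counts)."""
        i = self.index(species)
        mean = self.steady[species] * omega
        if mean <= 0:
            raise AnalysisError(f"zero mean for {species}")
        return float(np.sqrt(max(self.covariance[i, i], 0.0)) / mean)

    def residual(self) -> float:
        """Relative Lyapunov residual ||A C + C A^T + B|| / ||B||."""
        num = np.linalg.norm(self.a @ self.covariance
                             + self.covariance @ self.a.T + self.b)
        return float(num / np.linalg.norm(self.b))


def lna_covariance(
    params: KineticParameters,
    topology: CircuitTopology | str,
    *,
    steady: SteadyState | None = None,
) -> LNAResult:
    """Solve the Lyapunov equation at the driven fixed point.

    The miRNA is driven by ``params.k_mi``/``params.g_mi``; copy-number
    scale is ``params.omega``.  Raises :class:`AnalysisError` if the fixed
    point is not linearly stable (A not Hurwitz)."""
    if isinstance(topology, str):
        topology = get_topology(topology)
    system = build_reaction_system(params, topology)
    if steady is None:
        steady = steady_state_given_transcription(params, topology)
    x = steady.state_vector(system)
    a = drift_jacobian(system, x)
    eig = np.linalg.eigvals(a)
    if np.any(np.real(eig) >= -1e-12):
        raise AnalysisError(
            f"fixed point not stable: max Re(eig) = {np.real(eig).max():.3g}"
        )
    props = system.propensities(x)
    s = system.stoichiometry.astype(float)
    b = s.T @ (s * props[:, None])
    try:
        c = solve_continuous_lyapunov(a, -b)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise NumericalError(f"Lyapunov solve failed: {exc}") from exc
    c = 0.5 * (c + c.T)
    nb = np.linalg.norm(b)
    if nb == 0.0:
        raise AnalysisError("zero diffusion matrix: no reaction fires at the "
                            "fixed point")
    res = np.linalg.norm(a @ c + c @ a.T + b) / nb
    if not np.isfinite(res) or res > 1e-6:
        raise NumericalError(f"Lyapunov residual too large: {res:.3g}")
    return LNAResult(system.species, steady, a, b, c)


def correlation_heatmap(
    params: KineticParameters,
    topology: CircuitTopology | str,
    k_mi_grid,
    strength_grid,
):
    """LNA correlation rho(pTF, pT) over a (miRNA transcription, F) grid.

    Cells whose analysis fails (unstable or degenerate fixed point) are
    reported as NaN in ``rho`` and flagged in ``failed``."""
    k_mi_grid = np.asarray(k_mi_grid, dtype=float)
    strength_grid = np.asarray(strength_grid, dtype=float)
    if k_mi_grid.size == 0 or strength_grid.size == 0:
        raise ConfigurationError("heatmap grids must be non-empty")
    rho = np.full((k_mi_grid.size, strength_grid.size), np.nan)
    failed = np.zeros_like(rho, dtype=bool)
    for a, k_mi in enumerate(k_mi_grid):
        for b, f in enumerate(strength_grid):
            p = with_interaction_strength(params.replace(k_mi=float(k_mi)), float(f))
            try:
                rho[a, b] = lna_covariance(p, topology).rho
            except (AnalysisError, NumericalError):
                failed[a, b] = True
    return {"k_mi": k_mi_grid, "strength": strength_grid, "rho": rho,
            "failed": failed}


def noise_profile(
    params: KineticParameters,
    topology: CircuitTopology | str,
    k_mi_grid,
    species: str = "pT",
):
    """LNA coefficient of variation of one species along a miRNA
    transcription grid (fluctuation-size profile)."""
    k_mi_grid = np.asarray(k_mi_grid, dtype=float)
    cv = np.full(k_mi_grid.size, np.nan)
    for k, k_mi in enumerate(k_mi_grid):
        p = params.replace(k_mi=float(k_mi))
        try:
            res = lna_covariance(p, topology)
        except (AnalysisError, NumericalError):
            continue
        i = res.index(species)
        mean = res.steady[species] * p.omega
        if mean > 0 and res.covariance[i, i] > 0:
            cv[k] = np.sqrt(res.covariance[i, i]) / mean
    return {"k_mi": k_mi_grid, "cv": cv}


def equimolar_flux(params: KineticParameters, topology: CircuitTopology | str) -> float:
    """Near-equimolarity reference: the miRNA transcription rate at which
    miRNA production balances the summed transcription of its target mRNAs
    (at their miRNA-free levels), discounted by the recycling probability."""
    if isinstance(topology, str):
        topology = get_topology(topology)
    p = params
    flux = 0.0
    if topology.mirna_targets_tf:
        flux += p.k_mtf
    if topology.mirna_targets_t:
        if topology.tf_regulates_t:
            ptf0 = p.k_ptf * p.k_mtf / (p.g_ptf * p.g_mtf)
            flux += hill_activation(ptf0, p.hill_n, p.hill_h, p.k_mt)
        else:
            flux += p.basal * p.k_mt
    return (1.0 - p.alpha) * flux


@dataclass(frozen=True)
class ThresholdResult:
    """Hypersensitivity of the target to the miRNA transcription rate."""

    k_mi: np.ndarray
    pt: np.ndarray                  # pT* along the grid
    pt0: float                      # miRNA-free reference
    sensitivity: np.ndarray         # |d log pT* / d log k_mi|
    crossover: float | None         # sensitivity-peak location (the threshold)
    half_repression: float | None   # where pT* = pT0 / 2
    equimolar: float                # flux-balance reference point
    flags: tuple[str, ...] = ()


def threshold_analysis(
    params: KineticParameters,
    topology: CircuitTopology | str,
    k_mi_grid,
) -> ThresholdResult:
    """Locate the titration threshold along a miRNA transcription grid.

    The threshold (``crossover``) is the point of maximal logarithmic
    sensitivity |d log pT*/d log k_mi|, refined by quadratic interpolation
    around the grid maximum; in the strong-interaction limit it sits at the
    near-equimolarity flux balance.  The half-repression point (pT* fallen
    to half its miRNA-free value) is reported alongside.  Both are None
    (and flagged) when the grid does not reach them."""
    if isinstance(topology, str):
        topology = get_topology(topology)
    grid = np.asarray(k_mi_grid, dtype=float)
    if grid.ndim != 1 or grid.size < 5 or np.any(np.diff(grid) <= 0):
        raise ValueError("k_mi grid must be 1-D, increasing, with >= 5 points")
    if np.any(grid <= 0):
        raise ValueError("k_mi grid must be strictly positive (log sensitivity)")
    pt = np.array([
        steady_state_given_transcription(params.replace(k_mi=float(k)), topology)["pT"]
        for k in grid
    ])
    pt0 = steady_state_given_free_mirna_pt0(params, topology)

    flags: list[str] = []
    log_k, log_p = np.log(grid), np.log(np.maximum(pt, 1e-300))
    sens = np.abs(np.gradient(log_p, log_k))
    i = int(np.argmax(sens))
    if i == 0 or i == sens.size - 1:
        crossover = float(grid[i])
        flags.append("sensitivity_peak_at_grid_edge")
    else:
        # quadratic refinement in log k
        y0, y1, y2 = sens[i - 1], sens[i], sens[i + 1]
        denom = y0 - 2 * y1 + y2
        delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        delta = float(np.clip(delta, -1.0, 1.0))
        crossover = float(np.exp(log_k[i] + delta * (log_k[min(i + 1, len(log_k) - 1)]
                                                     - log_k[i])))

    half = None
    below = np.nonzero(pt <= pt0 / 2.0)[0]
    if below.size and below[0] > 0:
        j = below[0]
        # log-linear interpolation of the half-crossing
        f = (np.log(pt0 / 2.0) - log_p[j - 1]) / (log_p[j] - log_p[j - 1])
        half = float(np.exp(log_k[j - 1] + f * (log_k[j] - log_k[j - 1])))
    elif below.size:
        half = float(grid[0])
        flags.append("half_repression_before_grid")
    else:
        flags.append("no_crossover_in_grid")

    return ThresholdResult(
        grid, pt, pt0, sens, crossover, half,
        equimolar_flux(params, topology), tuple(flags),
    )


def steady_state_given_free_mirna_pt0(
    params: KineticParameters, topology: CircuitTopology
) -> float:
    """miRNA-free target protein reference used by the threshold analysis."""
    from .deterministic import steady_state_given_free_mirna

    return steady_state_given_free_mirna(0.0, params, topology).pt0
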