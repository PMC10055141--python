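"""Finite-horizon optimal control energy between activation states.

The brain is modelled as a linear time-invariant system
``x' = A x + B u`` over the normalized connectome ``A`` with diagonal
input matrix ``B``. The optimal control input steering the system
from a source state ``x0`` to a target state ``xT`` in time ``T``
minimizes

    J(u) = int_0^T (xT - x(t))'(xT - x(t)) + rho * u(t)'u(t) dt,

jointly penalizing trajectory distance to the target and input
energy. The Hamiltonian's stationarity condition gives
``u*(t) = -B' lambda(t) / (2 rho)``, and the joint state/costate
dynamics are linear:

    d/dt [x; lam] = [[A, -B B'/(2 rho)], [-2 I, -A']] [x; lam] + [0; 2 xT].

The two-point boundary-value problem is solved in closed form via the
exponential of the 2N x 2N block matrix; the initial costate comes
from the linear system enforcing x(T) = xT. Control energy is
``E = sum_k int_0^T u_k(t)^2 dt`` (trapezoidal quadrature on the time
grid; the grid only affects the quadrature, not the state evolution,
which is exact at grid times).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm, lu_factor, lu_solve

from .graph import Connectome, NormalizedSystem, normalize_adjacency

__all__ = [
    "ControlProblem",
    "ControlTrajectory",
    "TransitionEnergyMatrix",
    "solve_optimal_control",
    "transition_energy_matrix",
    "transition_asymmetry",
    "source_target_variability",
    "indirect_transition_fraction",
    "euclidean_state_distance",
]

#: condition number of the boundary solve above which a warning is logged
COND_WARN = 1e10


@dataclass
class ControlProblem:
    """One source-to-target steering problem on a normalized system.

    ``b_diag`` holds the per-node control-input gains (the diagonal of
    B); all ones means whole-brain uniform control.
    """

    system: NormalizedSystem
    x0: np.ndarray
    xT: np.ndarray
    T: float = 1.0
    rho: float = 1.0
    b_diag: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = self.system.n_nodes
        self.x0 = np.asarray(self.x0, dtype=float).reshape(n)
        self.xT = np.asarray(self.xT, dtype=float).reshape(n)
        if self.T <= 0:
            raise ValueError("horizon T must be positive")
        if self.rho <= 0:
            raise ValueError("rho must be positive")
        if self.b_diag is None:
            self.b_diag = np.ones(n)
        else:
            self.b_diag = np.asarray(self.b_diag, dtype=float).reshape(n)
            if np.any(self.b_diag < 0) or not np.any(self.b_diag > 0):
                raise ValueError(
                    "b_diag must be nonnegative with at least one positive entry"
                )


@dataclass
class ControlTrajectory:
    """Optimal trajectory, input, costate and energy of one transition."""

    times: np.ndarray
    states: np.ndarray  # (n_steps+1, N)
    inputs: np.ndarray  # (n_steps+1, N)
    costates: np.ndarray  # (n_steps+1, N)
    energy_per_node: np.ndarray
    total_energy: float
    boundary_condition_number: float = np.nan


@dataclass
class TransitionEnergyMatrix:
    """All-pairs optimal transition energies (rows: source, cols: target)."""

    energies: np.ndarray
    term_labels: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        if e.ndim != 2 or e.shape[0] != e.shape[1]:
            raise ValueError("energies must be square")
        if not np.all(np.isfinite(e)):
            raise ValueError("energies must be finite")
        self.energies = e
        if self.term_labels is None:
            self.term_labels = [f"state{i:03d}" for i in range(e.shape[0])]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.energies, index=self.term_labels, columns=self.term_labels
        )


def _hamiltonian_block(system: NormalizedSystem, b_diag: np.ndarray, rho: float):
    """2N x 2N state/costate block matrix of the optimality system."""
    a = system.a_norm
    n = a.shape[0]
    bbt = np.diag(b_diag.astype(float) ** 2) / (2.0 * rho)
    top = np.hstack([a, -bbt])
    bot = np.hstack([-2.0 * np.eye(n), -a.T])
    return np.vstack([top, bot])


def _exp_with_integral(m: np.ndarray, t: float):
    """(expm(M t), int_0^t expm(M s) ds) via one augmented exponential."""
    k = m.shape[0]
    aug = np.zeros((2 * k, 2 * k))
    aug[:k, :k] = m
    aug[:k, k:] = np.eye(k)
    e = expm(aug * t)
    return e[:k, :k], e[:k, k:]


class _TransitionSolver:
    """Per-connectome precomputation shared by all source/target pairs.

    Holds expm(M T), its integral, and the step operators for the
    quadrature grid; solving one pair then reduces to a linear solve
    for the initial costate plus matrix-vector propagation.
    """

    def __init__(
        self,
        system: NormalizedSystem,
        T: float = 1.0,
        rho: float = 1.0,
        b_diag: np.ndarray | None = None,
        n_steps: int = 1000,
    ) -> None:
        if n_steps < 100:
            raise ValueError("n_steps must be at least 100")
        n = system.n_nodes
        if b_diag is None:
            b_diag = np.ones(n)
        b_diag = np.asarray(b_diag, dtype=float).reshape(n)
        self.system = system
        self.T = float(T)
        self.rho = float(rho)
        self.b_diag = b_diag
        self.n_steps = int(n_steps)
        self.n = n
        m = _hamiltonian_block(system, b_diag, rho)
        self.e_T, self.f_T = _exp_with_integral(m, self.T)
        dt = self.T / self.n_steps
        self.dt = dt
        self.e_dt, self.f_dt = _exp_with_integral(m, dt)
        # boundary operator: x(T) = E11 x0 + E12 lam0 + [F(T) b]_x
        self.e12 = self.e_T[:n, n:]
        self.e11 = self.e_T[:n, :n]
        self.cond = float(np.linalg.cond(self.e12))
        try:
            self.lu = lu_factor(self.e12)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
            raise np.linalg.LinAlgError(
                f"singular boundary solve (condition number {self.cond:.3e}); "
                "the configuration is uncontrollable"
            ) from exc

    def costate0(self, x0: np.ndarray, xT: np.ndarray) -> np.ndarray:
        """Initial costate(s) enforcing x(T) = xT; accepts column-stacked batches."""
        n = self.n
        # constant forcing b = [0; 2 xT]  ->  F(T) b restricted to the x rows
        fx = self.f_T[:n, n:] @ (2.0 * xT)
        rhs = xT - self.e11 @ x0 - fx
        if not np.all(np.isfinite(rhs)):
            raise FloatingPointError("non-finite boundary data")
        lam0 = lu_solve(self.lu, rhs)
        if self.cond > COND_WARN:
            import warnings

            warnings.warn(
                f"boundary solve condition number {self.cond:.3e} exceeds "
                f"{COND_WARN:.0e}; energies may be inaccurate",
                RuntimeWarning,
                stacklevel=2,
            )
        return lam0

    def propagate(self, x0: np.ndarray, xT: np.ndarray):
        """Trajectory of [x; lam] over the grid for batched columns.

        Returns (times, Z) with Z of shape (n_steps+1, 2N, P).
        """
        n = self.n
        x0 = np.asarray(x0, dtype=float).reshape(n, -1)
        xT = np.asarray(xT, dtype=float).reshape(n, -1)
        lam0 = self.costate0(x0, xT)
        z = np.vstack([x0, lam0])
        forcing = np.vstack([np.zeros_like(xT), 2.0 * xT])
        g = self.f_dt @ forcing  # constant per-step contribution
        traj = np.empty((self.n_steps + 1,) + z.shape)
        traj[0] = z
        for k in range(self.n_steps):
            z = self.e_dt @ z + g
            traj[k + 1] = z
        times = np.linspace(0.0, self.T, self.n_steps + 1)
        return times, traj

    def energies(self, x0: np.ndarray, xT: np.ndarray, reach_tol: float = 1e-6):
        """Total energy per column pair without storing full trajectories."""
        n = self.n
        x0 = x0.reshape(n, -1)
        xT = xT.reshape(n, -1)
        lam0 = self.costate0(x0, xT)
        z = np.vstack([x0, lam0])
        forcing = np.vstack([np.zeros_like(xT), 2.0 * xT])
        g = self.f_dt @ forcing
        scale = (self.b_diag / (2.0 * self.rho))[:, None]
        acc = 0.5 * ((scale * z[n:]) ** 2).sum(axis=0)
        for k in range(self.n_steps):
            z = self.e_dt @ z + g
            w = 0.5 if k == self.n_steps - 1 else 1.0
            acc += w * ((scale * z[n:]) ** 2).sum(axis=0)
        total = acc * self.dt
        xend = z[:n]
        denom = np.maximum(np.linalg.norm(xT, axis=0), 1.0)
        miss = np.linalg.norm(xend - xT, axis=0) / denom
        if np.any(miss > reach_tol):
            bad = int(np.argmax(miss))
            raise RuntimeError(
                f"terminal state missed target by relative {miss[bad]:.3e} "
                f"(pair column {bad}); increase n_steps or check conditioning "
                f"(boundary condition number {self.cond:.3e})"
            )
        return total


def solve_optimal_control(
    problem: ControlProblem, n_steps: int = 1000, reach_tol: float = 1e-6
) -> ControlTrajectory:
    """Solve one optimal state-transition problem.

    Parameters
    ----------
    problem
        System, boundary states, horizon, input-energy weight and
        control gains.
    n_steps
        Number of quadrature intervals on [0, T] (>= 100). The state
        evolution is exact at grid points; n_steps only controls the
        energy quadrature and the returned trajectory resolution.
    reach_tol
        Maximum allowed relative terminal miss ||x(T) - xT|| / max(1, ||xT||).
    """
    solver = _TransitionSolver(
        problem.system, problem.T, problem.rho, problem.b_diag, n_steps
    )
    n = solver.n
    times, traj = solver.propagate(problem.x0[:, None], problem.xT[:, None])
    states = traj[:, :n, 0]
    costates = traj[:, n:, 0]
    inputs = -(problem.b_diag[None, :] * costates) / (2.0 * problem.rho)
    denom = max(1.0, float(np.linalg.norm(problem.xT)))
    miss = float(np.linalg.norm(states[-1] - problem.xT)) / denom
    if miss > reach_tol:
        raise RuntimeError(
            f"terminal state missed target by relative {miss:.3e}; increase "
            f"n_steps or check conditioning (condition number {solver.cond:.3e})"
        )
    energy_per_node = np.trapezoid(inputs**2, times, axis=0)
    return ControlTrajectory(
        times=times,
        states=states,
        inputs=inputs,
        costates=costates,
        energy_per_node=energy_per_node,
        total_energy=float(energy_per_node.sum()),
        boundary_condition_number=solver.cond,
    )


def transition_energy_matrix(
    connectome: Connectome,
    states: pd.DataFrame,
    T: float = 1.0,
    rho: float = 1.0,
    c: float = 0.0,
    b_diag: np.ndarray | None = None,
    n_steps: int = 1000,
    normalize_states: bool = False,
    system: NormalizedSystem | None = None,
) -> TransitionEnergyMatrix:
    """Optimal control energy for every ordered pair of states.

    ``states`` is a regions x terms table sharing the connectome's node
    order. Entry [i, j] of the result is the energy to steer the system
    from state i to state j; the diagonal (self-transitions) is
    included. ``normalize_states`` rescales each map to unit Euclidean
    norm first.
    """
    x = states.to_numpy(dtype=float)
    if x.shape[0] != connectome.n_nodes:
        raise ValueError(
            f"states have {x.shape[0]} regions but connectome has "
            f"{connectome.n_nodes} nodes"
        )
    if normalize_states:
        norms = np.linalg.norm(x, axis=0)
        if np.any(norms == 0):
            raise ValueError("cannot normalize an all-zero state map")
        x = x / norms
    labels = list(states.columns)
    k = x.shape[1]
    if system is None:
        system = normalize_adjacency(connectome, c=c)
    solver = _TransitionSolver(system, T=T, rho=rho, b_diag=b_diag, n_steps=n_steps)
    # batch all K^2 ordered pairs: column p = i * K + j
    src = np.repeat(np.arange(k), k)
    tgt = np.tile(np.arange(k), k)
    try:
        total = solver.energies(x[:, src], x[:, tgt])
    except (RuntimeError, FloatingPointError) as exc:
        raise RuntimeError(f"transition energy computation failed: {exc}") from exc
    energies = total.reshape(k, k)
    if not np.all(np.isfinite(energies)):
        bad = np.argwhere(~np.isfinite(energies))[0]
        raise RuntimeError(
            f"non-finite energy for transition {labels[bad[0]]} -> {labels[bad[1]]}"
        )
    # quadrature noise can leave tiny negative values on self-transitions
    energies = np.maximum(energies, 0.0)
    return TransitionEnergyMatrix(energies=energies, term_labels=labels)


def transition_asymmetry(tem: TransitionEnergyMatrix):
    """Directional cost difference and per-target net reach-vs-leave score.

    asym[i, j] = E(i -> j) - E(j -> i); the net score of target j is the
    mean of asym[i, j] over sources i != j. Positive net scores mark
    states harder to reach than to leave.
    """
    e = tem.energies
    k = e.shape[0]
    asym = e - e.T
    if k < 2:
        raise ValueError("need at least 2 states")
    # column mean of asym excluding the (zero) diagonal
    net = asym.sum(axis=0) / (k - 1)
    return asym, pd.Series(net, index=tem.term_labels, name="net_asymmetry")


def source_target_variability(tem: TransitionEnergyMatrix) -> dict:
    """Compare energy variability across target vs across source states.

    ``sd_across_targets`` holds, for each source state (row), the SD of
    its energies over the K-1 off-diagonal targets — how much cost
    varies when the *destination* changes. ``sd_across_sources`` is the
    column-wise analogue (varying the origin). The two SD samples are
    compared with a pooled two-sample t-test (df = 2K - 2) and Cohen's
    d; a positive t means the destination of a transition shapes its
    cost more than the origin does.
    """
    e = tem.energies
    k = e.shape[0]
    if k < 3:
        raise ValueError("need at least 3 states for SD comparison")
    mask = ~np.eye(k, dtype=bool)
    across_targets = np.array([e[i, :][mask[i, :]].std(ddof=1) for i in range(k)])
    across_sources = np.array([e[:, j][mask[:, j]].std(ddof=1) for j in range(k)])
    diff = across_targets.mean() - across_sources.mean()
    sp2 = (across_targets.var(ddof=1) + across_sources.var(ddof=1)) / 2.0
    report = {
        "sd_across_targets": pd.Series(across_targets, index=tem.term_labels),
        "sd_across_sources": pd.Series(across_sources, index=tem.term_labels),
        "mean_sd_across_targets": float(across_targets.mean()),
        "mean_sd_across_sources": float(across_sources.mean()),
        "df": 2 * k - 2,
        "degenerate": False,
    }
    if sp2 == 0.0:
        report.update(t=np.nan, cohens_d=np.nan, degenerate=True)
        return report
    se = np.sqrt(sp2 * 2.0 / k)
    report["t"] = float(diff / se)
    report["cohens_d"] = float(diff / np.sqrt(sp2))
    return report


def indirect_transition_fraction(tem: TransitionEnergyMatrix):
    """Fraction of ordered pairs with a cheaper two-step route.

    For each (i, j), i != j, checks whether some intermediate k (k not
    in {i, j}) gives E(i -> k) + E(k -> j) < E(i -> j). Returns the
    overall fraction and a table of best intermediates.
    """
    e = tem.energies
    k = e.shape[0]
    if k < 3:
        raise ValueError("need at least 3 states")
    if np.any(e < 0):
        raise ValueError("energies must be nonnegative")
    # two_step[i, j, m] = E(i -> m) + E(m -> j)
    two_step = e[:, None, :] + e.T[None, :, :]
    # exclude m == i and m == j
    idx = np.arange(k)
    two_step[idx, :, idx] = np.inf
    two_step[:, idx, idx] = np.inf
    best_val = two_step.min(axis=2)
    best_k = two_step.argmin(axis=2)
    cheaper = (best_val < e) & ~np.eye(k, dtype=bool)
    frac = float(cheaper.sum()) / (k * (k - 1))
    rows = []
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            rows.append(
                {
                    "source": tem.term_labels[i],
                    "target": tem.term_labels[j],
                    "direct": e[i, j],
                    "best_two_step": best_val[i, j],
                    "best_intermediate": tem.term_labels[int(best_k[i, j])],
                    "cheaper_indirect": bool(cheaper[i, j]),
                }
            )
    return frac, pd.DataFrame(rows)


def euclidean_state_distance(states: pd.DataFrame) -> pd.DataFrame:
    """Pairwise L2 distances between state vectors (terms as columns)."""
    from scipy.spatial.distance import squareform, pdist

    x = states.to_numpy(dtype=float).T
    d = squareform(pdist(x)) if x.shape[0] > 1 else np.zeros((1, 1))
    return pd.DataFrame(d, index=states.columns, columns=states.columns)
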