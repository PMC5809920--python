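"""Independent numerical references for the analytic diffusion solution.

Two deliberately different routes to the same governing equation:

* a finite-difference solver (implicit backward-Euler or explicit FTCS)
  marching ``dphi/dtau = d2phi/deta2`` with the Dirichlet source at eta = 0
  and a ghost-point zero-flux closure at eta = 1, and
* a stochastic lattice random walk with the source cell held at fixed
  occupancy, whose mean occupancy converges to the continuum profile.

Together with the eigenfunction series this gives a three-way consistency
check, and the walker additionally quantifies how noisy the profile is at
the single-digit molecule numbers where the continuum description frays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import diags
from scipy.sparse.linalg import splu

from .diffusion import DimensionlessProfile
from .errors import InvalidParameterError

#: Default number of interior spatial nodes.
DEFAULT_N_SPACE: int = 200

#: Default implicit time step; automatically reduced for small tau targets
#: (backward Euler is first order in time and the solution is steep at
#: early times).
DEFAULT_D_TAU: float = 1e-4

#: Default RNG seed of the particle walker.
DEFAULT_SEED: int = 20180212


@dataclass(frozen=True)
class FDGrid:
    """Discretization of the finite-difference oracle.

    ``n_space`` interior nodes (uniform, spacing 1/n_space), time step
    ``d_tau`` (``None`` selects ``min(1e-4, tau_target/250)``), and scheme
    ``"implicit"`` (backward Euler, unconditionally stable) or
    ``"explicit"`` (FTCS, requires d_tau/deta^2 <= 0.5).
    """

    n_space: int = DEFAULT_N_SPACE
    d_tau: float | None = None
    scheme: str = "implicit"

    def __post_init__(self) -> None:
        if self.n_space < 10:
            raise InvalidParameterError(f"n_space must be >= 10, got {self.n_space}")
        if self.d_tau is not None and self.d_tau <= 0:
            raise InvalidParameterError(f"d_tau must be > 0, got {self.d_tau}")
        if self.scheme not in ("implicit", "explicit"):
            raise InvalidParameterError(
                f"scheme must be 'implicit' or 'explicit', got {self.scheme!r}"
            )

    @property
    def d_eta(self) -> float:
        return 1.0 / self.n_space

    def step_for(self, tau_target: float) -> float:
        """Concrete time step for a target time (adaptive default)."""
        if self.d_tau is not None:
            return self.d_tau
        if self.scheme == "explicit":
            return 0.4 * self.d_eta**2
        return min(DEFAULT_D_TAU, max(tau_target, 1e-12) / 250.0)


def solve_fd(
    tau_target: float, grid: FDGrid = FDGrid(), return_residual: bool = False
):
    """March the discretized diffusion equation to ``tau_target``.

    The state vector holds nodes eta_1 .. eta_M (M = n_space); the source
    node eta_0 is pinned at phi = 1 and the zero-flux face uses the ghost
    substitution phi_{M+1} = phi_{M-1}.

    Parameters
    ----------
    tau_target
        Dimensionless time to integrate to (>= 0; 0 returns the initial
        condition).
    grid
        Discretization; the explicit scheme raises if its stability ratio
        d_tau/d_eta^2 exceeds 1/2.
    return_residual
        Also return the maximum per-step flux-balance residual
        |dS/dtau - influx| * d_eta, where S is the trapezoid mass of the
        moving nodes.  For the implicit scheme this residual is an exact
        algebraic identity and sits at rounding level.

    Returns
    -------
    DimensionlessProfile, or (DimensionlessProfile, float) with the residual.
    """
    if tau_target < 0:
        raise InvalidParameterError(f"tau_target must be >= 0, got {tau_target}")
    M = grid.n_space
    h = grid.d_eta
    eta = np.linspace(0.0, 1.0, M + 1)
    if tau_target == 0:
        vals = np.zeros(M + 1)
        vals[0] = 1.0
        prof = DimensionlessProfile(tau=0.0, eta_grid=eta, phi=vals)
        return (prof, 0.0) if return_residual else prof

    dtau = grid.step_for(tau_target)
    n_steps = max(1, int(round(tau_target / dtau)))
    dtau = tau_target / n_steps
    r = dtau / h**2
    if grid.scheme == "explicit" and r > 0.5:
        raise InvalidParameterError(
            f"explicit scheme unstable: d_tau/d_eta^2 = {r:.3g} > 0.5"
        )

    phi = np.zeros(M)  # nodes 1..M; node 0 is the Dirichlet source
    source = np.zeros(M)
    source[0] = r  # contribution of phi_0 = 1
    max_res = 0.0

    if grid.scheme == "implicit":
        main = np.full(M, 1.0 + 2.0 * r)
        lower = np.full(M - 1, -r)
        upper = np.full(M - 1, -r)
        lower[-1] = -2.0 * r  # ghost closure at the no-flux node
        lu = splu(diags([lower, main, upper], [-1, 0, 1], format="csc"))
        for _ in range(n_steps):
            s_old = phi[:-1].sum() + 0.5 * phi[-1]
            phi = lu.solve(phi + source)
            s_new = phi[:-1].sum() + 0.5 * phi[-1]
            res = abs((s_new - s_old) / dtau - (1.0 - phi[0]) / h**2) * h
            max_res = max(max_res, res)
    else:
        for _ in range(n_steps):
            s_old = phi[:-1].sum() + 0.5 * phi[-1]
            influx = (1.0 - phi[0]) / h**2  # evaluated at the old level
            new = np.empty_like(phi)
            new[0] = phi[0] + r * (1.0 - 2.0 * phi[0] + phi[1])
            new[1:-1] = phi[1:-1] + r * (phi[:-2] - 2.0 * phi[1:-1] + phi[2:])
            new[-1] = phi[-1] + 2.0 * r * (phi[-2] - phi[-1])
            phi = new
            s_new = phi[:-1].sum() + 0.5 * phi[-1]
            res = abs((s_new - s_old) / dtau - influx) * h
            max_res = max(max_res, res)

    vals = np.concatenate([[1.0], np.clip(phi, 0.0, 1.0)])
    prof = DimensionlessProfile(tau=tau_target, eta_grid=eta, phi=vals)
    return (prof, max_res) if return_residual else prof


@dataclass(frozen=True)
class ParticleWalkResult:
    """Replicate-averaged lattice-walk occupancy.

    ``mean_counts[i]`` estimates ``n_source * phi(tau, eta[i])``;
    ``sem_counts`` is the Monte-Carlo standard error over replicates.
    """

    tau: float
    eta: np.ndarray
    mean_counts: np.ndarray
    sem_counts: np.ndarray
    n_source: int
    replicates: int

    @property
    def phi_hat(self) -> np.ndarray:
        """Occupancy normalized by the source occupancy."""
        return self.mean_counts / self.n_source


def particle_walk(
    tau_target: float,
    n_particles: int,
    seed: int = DEFAULT_SEED,
    n_cells: int = 51,
    replicates: int = 20,
) -> ParticleWalkResult:
    """Stochastic lattice realization of the source-driven diffusion.

    Particles hop +/- one cell per step on ``n_cells`` lattice cells over
    [0, 1] (step variance matched to unit diffusivity: d_tau = h^2/2).
    The far face reflects; the source cell at eta = 0 is replenished to a
    fixed occupancy of ``n_particles`` after every step (particles hopping
    left out of the domain are reabsorbed).  The expected occupancy of cell
    i is ``n_particles * phi(tau, eta_i)`` up to O(h) lattice bias.

    Deterministic for a fixed ``seed``: the same seed yields bit-identical
    counts.
    """
    if tau_target < 0:
        raise InvalidParameterError(f"tau_target must be >= 0, got {tau_target}")
    if n_particles < 1:
        raise InvalidParameterError(f"n_particles must be >= 1, got {n_particles}")
    if n_cells < 2 or replicates < 1:
        raise InvalidParameterError("n_cells must be >= 2 and replicates >= 1")

    rng = np.random.default_rng(seed)
    h = 1.0 / (n_cells - 1)
    d_tau = h * h / 2.0
    n_steps = int(np.ceil(tau_target / d_tau))
    last = n_cells - 1

    counts = np.zeros((replicates, n_cells))
    for rep in range(replicates):
        pos = np.zeros(n_particles, dtype=np.int64)  # source full, bulk empty
        for _ in range(n_steps):
            pos = pos + (rng.integers(0, 2, pos.size) * 2 - 1)
            pos[pos > last] = last  # reflect at the accumulating face
            pos = pos[pos >= 0]  # reabsorbed into the source reservoir
            c0 = int(np.count_nonzero(pos == 0))
            if c0 < n_particles:
                pos = np.concatenate(
                    [pos, np.zeros(n_particles - c0, dtype=np.int64)]
                )
            elif c0 > n_particles:
                at0 = np.flatnonzero(pos == 0)
                pos = np.delete(pos, at0[: c0 - n_particles])
        counts[rep] = np.bincount(pos, minlength=n_cells)

    mean = counts.mean(axis=0)
    if replicates > 1:
        sem = counts.std(axis=0, ddof=1) / np.sqrt(replicates)
    else:
        sem = np.zeros(n_cells)
    return ParticleWalkResult(
        tau=tau_target,
        eta=np.linspace(0.0, 1.0, n_cells),
        mean_counts=mean,
        sem_counts=sem,
        n_source=n_particles,
        replicates=replicates,
    )
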