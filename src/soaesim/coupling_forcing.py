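"""Chain-level force terms: viscous coupling, elastic coupling, stimulus, noise.

Two nearest-neighbor couplings are supported.  Elastic coupling adds a term
proportional to the discrete laplacian of *position* to dx/dt; it acts like
springs linking adjacent hair bundles (tectorial membrane or salletal strand)
and enters the right-hand side explicitly.  Viscous coupling is drag against
the *velocity* difference between neighbors; because the drag depends on the
unknown velocities themselves, the equations of motion are implicit and must
be rearranged into a linear tridiagonal system B xdot = g before integration.
For any beta > 0 every entry of B^-1 is nonzero, so the strictly local drag
mediates an effective global coupling along the whole chain.

Both couplings clamp virtual neighbors beyond the chain ends at zero
(x_0 = x_{N+1} = 0 for the elastic case, xdot_0 = xdot_{N+1} = 0 for the
viscous case), so every diagonal entry of B is 1 + 2 beta.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.linalg import solve_banded

from .model_core import NoiseSpec


def elastic_term(x: np.ndarray, gamma: float) -> np.ndarray:
    """gamma * (x_{n+1} - 2 x_n + x_{n-1}) with clamped virtual ends."""
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    x = np.asarray(x, dtype=float)
    lap = -2.0 * x
    lap[:-1] += x[1:]
    lap[1:] += x[:-1]
    return gamma * lap


@dataclass
class ViscousSystem:
    """Tridiagonal system B xdot = g arising from implicit viscous coupling.

    B is symmetric with 1 + 2 beta on the diagonal and -beta off it; strictly
    diagonally dominant (hence invertible) for beta > 0.  ``solve`` uses O(N)
    banded elimination.
    """

    N: int
    beta: float

    def __post_init__(self):
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.N < 1:
            raise ValueError("N must be >= 1")
        # banded storage for scipy.linalg.solve_banded ((1, 1) form)
        ab = np.zeros((3, self.N))
        ab[0, 1:] = -self.beta
        ab[1, :] = 1.0 + 2.0 * self.beta
        ab[2, :-1] = -self.beta
        self._ab = ab

    def solve(self, g: np.ndarray) -> np.ndarray:
        """Effective velocities xdot solving B xdot = g."""
        g = np.asarray(g, dtype=float)
        if g.shape[-1] != self.N:
            raise ValueError(f"g has length {g.shape[-1]}, expected {self.N}")
        if self.beta == 0.0:
            return g.copy()
        return solve_banded((1, 1), self._ab, g)

    def dense_matrix(self) -> np.ndarray:
        """B as a dense array (for inspection and cross-checking; the solver
        itself never forms it)."""
        B = np.diag(np.full(self.N, 1.0 + 2.0 * self.beta))
        idx = np.arange(self.N - 1)
        B[idx, idx + 1] = -self.beta
        B[idx + 1, idx] = -self.beta
        return B


def build_viscous_system(N: int, beta: float) -> ViscousSystem:
    return ViscousSystem(N=N, beta=beta)


@dataclass
class StimulusSpec:
    """Global sinusoidal stimulus: every unit receives delta * sin(2 pi F t + phase)."""

    delta: float
    F: float  # kHz
    phase: float = 0.0

    def __post_init__(self):
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.delta > 0 and self.F <= 0:
            raise ValueError("F must be > 0")


def forcing_term(t: float, N: int, stim: StimulusSpec) -> np.ndarray:
    """Stimulus contribution to dx/dt at time t, identical for all N units.

    The acoustic stimulus drives the whole papilla; it is not tonotopically
    weighted.
    """
    if stim.delta == 0.0:
        return np.zeros(N)
    return np.full(N, stim.delta * np.sin(2.0 * np.pi * stim.F * t + stim.phase))


class PiecewiseConstantNoise:
    """Piecewise-constant random forcing: N(0, sd^2) per unit per hold interval.

    Draws are generated once from the seed, so the process is reproducible and
    identical across integrator step sizes (provided the step divides the hold
    interval).  ``__call__`` returns the N-vector in force at time t.
    """

    def __init__(self, spec: NoiseSpec, t_end: float, N: int):
        if spec.update_interval <= 0:
            raise ValueError("update_interval must be > 0")
        self.spec = spec
        self.N = N
        self.n_intervals = int(np.ceil(t_end / spec.update_interval)) + 1
        rng = np.random.default_rng(spec.seed)
        if spec.sd == 0.0:
            self.draws = np.zeros((self.n_intervals, N))
        else:
            self.draws = rng.normal(0.0, spec.sd, size=(self.n_intervals, N))

    def __call__(self, t: float) -> np.ndarray:
        k = int(t / self.spec.update_interval)
        k = min(max(k, 0), self.n_intervals - 1)
        return self.draws[k]


def noise_process(spec: NoiseSpec, t_grid: np.ndarray, N: int = 1,
                  integration_step: Optional[float] = None) -> PiecewiseConstantNoise:
    """Build the noise process covering ``t_grid``.

    If ``integration_step`` is given it must divide the hold interval exactly,
    so the forcing is constant within every integrator step.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if integration_step is not None:
        ratio = spec.update_interval / integration_step
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            raise ValueError(
                f"integration step {integration_step} must divide the noise "
                f"hold interval {spec.update_interval} exactly")
    return PiecewiseConstantNoise(spec, float(t_grid[-1]), N)
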