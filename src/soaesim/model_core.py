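"""Tonotopic chain of van der Pol oscillators: configuration and intrinsic dynamics.

The model represents the apical, high-frequency region of a lizard basilar
papilla as a one-dimensional array of ``N`` self-sustained oscillators.  Each
unit stands for one transverse row of hair cells and is a van der Pol
oscillator in Liénard form,

    dx_n/dt = mu_n (alpha_n x_n - x_n^3 / 3) - omega_n y_n
    dy_n/dt = omega_n x_n

where ``x`` is hair-bundle displacement and ``y`` an internal variable with no
direct physical reading.  ``alpha_n`` (distance squared) sets the limit-cycle
amplitude (~ 2 sqrt(alpha)), ``omega_n = 2 pi f_n`` (rad/ms) the natural
frequency, and ``mu_n`` the nonlinearity.  Natural frequencies climb
geometrically along the chain — roughly 1% per unit — spanning 1 to 2.97 kHz
for the standard 110-unit chain.  The ratio ``omega_n / mu_n`` is held at 5
everywhere, so every unit is an equally weakly nonlinear (nearly sinusoidal)
oscillator differing from its neighbors only in timescale.

Units: time in ms, cyclic frequency in kHz, angular frequency in rad/ms.

The model is nondimensional at heart: its natural time unit is the one in
which the angular frequency of unit n is numerically 3^((n-1)/110), i.e.
runs from 1 to 3 along the standard chain.  Presenting frequencies in kHz
(f_n = 3^((n-1)/110) kHz, so that the chain reads 1–2.97 kHz) rescales time
by 2 pi, which multiplies every inverse-time coefficient by 2 pi.  The
angular frequencies and nonlinearities already carry this factor through
omega = 2 pi f; the coupling, stimulus, and noise magnitudes (gamma, delta,
noise sd) are quoted in natural units in configs — matching the conventional
parameter tables for this model — and are converted by the engine via the
``*_eff`` properties below.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import yaml

# Fixed ratio of angular frequency to nonlinearity parameter; renders the
# unperturbed oscillations nearly sinusoidal.
DEFAULT_MU_RATIO = 5.0

# Exponent denominator of the geometric frequency ladder.  Held at 110 even
# for longer chains, so a 210-unit chain spans 1 to 3^(209/110) ~ 8.06 kHz.
DEFAULT_FREQ_DENOMINATOR = 110

PROFILE_KINDS = ("uniform", "taper18", "parabolic", "disordered")


def frequency_ladder(N: int, denominator: int = DEFAULT_FREQ_DENOMINATOR) -> np.ndarray:
    """Geometric ladder of natural frequencies, f_n = 3^((n-1)/denominator) kHz.

    Successive units differ by the constant factor 3^(1/denominator), about 1%
    for the default denominator of 110.
    """
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N}")
    if denominator < 1:
        raise ValueError(f"denominator must be >= 1, got {denominator}")
    n = np.arange(1, N + 1)
    return 3.0 ** ((n - 1) / denominator)


def angular_frequencies(N: int, denominator: int = DEFAULT_FREQ_DENOMINATOR) -> np.ndarray:
    """omega_n = 2 pi f_n in rad/ms."""
    return 2.0 * np.pi * frequency_ladder(N, denominator)


def amplitude_profile(
    kind: str,
    N: int,
    rng_seed: Optional[int] = None,
    disorder_sd: float = 0.03,
) -> np.ndarray:
    """Profile of oscillation-amplitude parameters alpha_n along the chain.

    ``uniform``    — alpha_n = 1 everywhere.
    ``taper18``    — linear taper to zero over the outermost 18 units at each
                     end (n/18 for n <= 18, 1 for 19 <= n <= 92, (111-n)/18
                     for n >= 93); defined for N = 110.
    ``parabolic``  — alpha_n = n (111 - n) / 3025, a smooth arch peaking at 1
                     mid-chain and vanishing at both virtual ends; N = 110.
    ``disordered`` — taper18 with the 74 central values replaced by draws from
                     a normal distribution (mean 1, sd ``disorder_sd``),
                     clipped below at 0 since alpha is a squared distance.
    """
    if kind not in PROFILE_KINDS:
        raise ValueError(f"unknown profile kind {kind!r}; expected one of {PROFILE_KINDS}")
    if kind in ("taper18", "parabolic", "disordered") and N != 110:
        raise ValueError(f"profile {kind!r} is defined for N=110 chains, got N={N}")
    n = np.arange(1, N + 1, dtype=float)
    if kind == "uniform":
        return np.ones(N)
    if kind == "parabolic":
        return n * (111.0 - n) / 3025.0
    # taper18 base
    alpha = np.ones(N)
    alpha[:18] = n[:18] / 18.0
    alpha[92:] = (111.0 - n[92:]) / 18.0
    if kind == "disordered":
        rng = np.random.default_rng(rng_seed)
        alpha[18:92] = np.clip(rng.normal(1.0, disorder_sd, size=74), 0.0, None)
    return alpha


@dataclass
class NoiseSpec:
    """Piecewise-constant random forcing added to dx/dt.

    Independent draws N(0, sd^2) per oscillator, held constant within each
    ``update_interval`` (default 16 µs), emulating broadband mechanical noise.
    The hold interval and sd parameterize the forcing itself; there is no
    1/sqrt(dt) diffusion rescaling.
    """

    sd: float = 0.1
    update_interval: float = 0.016  # ms
    seed: Optional[int] = None

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.update_interval <= 0:
            raise ValueError("noise update_interval must be > 0")


@dataclass
class AlphaProfileSpec:
    """Descriptor for the amplitude profile (kind plus disorder parameters)."""

    kind: str = "uniform"
    disorder_sd: float = 0.03
    disorder_seed: Optional[int] = None

    def build(self, N: int) -> np.ndarray:
        return amplitude_profile(self.kind, N, rng_seed=self.disorder_seed,
                                 disorder_sd=self.disorder_sd)


@dataclass
class ChainConfig:
    """Full parameterization of one chain simulation.

    beta  — dimensionless viscous (velocity-laplacian) coupling strength
    gamma — elastic (position-laplacian) coupling, 1/ms
    delta — amplitude (velocity) of the global sinusoidal stimulus
    F     — stimulus frequency, kHz
    """

    N: int = 110
    freq_exponent_denominator: int = DEFAULT_FREQ_DENOMINATOR
    mu_ratio: float = DEFAULT_MU_RATIO
    alpha_profile: AlphaProfileSpec = field(default_factory=AlphaProfileSpec)
    beta: float = 0.0
    gamma: float = 0.0
    delta: float = 0.0
    F: float = 0.0
    stimulus_phase: float = 0.0
    noise: Optional[NoiseSpec] = None
    seed: int = 0
    t_total: float = 3360.0       # ms
    t_equilibrate: float = 160.0  # ms
    sample_interval: float = 0.016  # ms

    def __post_init__(self):
        if isinstance(self.alpha_profile, str):
            self.alpha_profile = AlphaProfileSpec(kind=self.alpha_profile)
        if isinstance(self.alpha_profile, dict):
            self.alpha_profile = AlphaProfileSpec(**self.alpha_profile)
        if isinstance(self.noise, dict):
            self.noise = NoiseSpec(**self.noise)
        if self.N < 2:
            raise ValueError("chain needs N >= 2 oscillators")
        if min(self.beta, self.gamma, self.delta) < 0:
            raise ValueError("beta, gamma, delta must all be >= 0")
        if not (self.t_total > self.t_equilibrate >= 0):
            raise ValueError("require t_total > t_equilibrate >= 0")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be > 0")
        if self.delta > 0 and self.F <= 0:
            raise ValueError("stimulus requires F > 0 when delta > 0")

    # --- derived arrays -------------------------------------------------
    @property
    def freqs_khz(self) -> np.ndarray:
        return frequency_ladder(self.N, self.freq_exponent_denominator)

    @property
    def omegas(self) -> np.ndarray:
        return 2.0 * np.pi * self.freqs_khz

    @property
    def mus(self) -> np.ndarray:
        return self.omegas / self.mu_ratio

    def alphas(self) -> np.ndarray:
        return self.alpha_profile.build(self.N)

    # gamma, delta, and the noise sd are quoted in the model's natural time
    # unit (angular frequency of unit 1 = 1); the kHz/ms presentation
    # rescales time by 2 pi, hence these conversions for the integrator.
    @property
    def gamma_eff(self) -> float:
        """Elastic coupling in 1/ms (display units)."""
        return 2.0 * np.pi * self.gamma

    @property
    def delta_eff(self) -> float:
        """Stimulus velocity amplitude in display units."""
        return 2.0 * np.pi * self.delta

    @property
    def noise_sd_eff(self) -> float:
        """Noise forcing sd in display units."""
        return 0.0 if self.noise is None else 2.0 * np.pi * self.noise.sd

    @property
    def record_ms(self) -> float:
        """Length of the analyzed record after discarding equilibration."""
        return self.t_total - self.t_equilibrate

    # --- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ChainConfig":
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ChainConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class ChainState:
    """Instantaneous state of the chain: displacements x, internal variables y."""

    x: np.ndarray
    y: np.ndarray
    t: float = 0.0

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of identical length")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("state contains non-finite entries")

    @property
    def N(self) -> int:
        return self.x.size


def intrinsic_rhs(state: ChainState, config: ChainConfig):
    """Uncoupled right-hand sides g_n of the van der Pol units.

    Returns (dx/dt, dy/dt) with no coupling, forcing, or noise.
    """
    if state.N != config.N:
        raise ValueError(f"state has {state.N} units but config expects {config.N}")
    omega = config.omegas
    mu = config.mus
    alpha = config.alphas()
    dx = mu * (alpha * state.x - state.x**3 / 3.0) - omega * state.y
    dy = omega * state.x
    return dx, dy
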