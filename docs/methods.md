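# Methods

## The model

`soaesim` simulates the high-frequency (apical) region of a lizard basilar
papilla as a chain of `N` self-sustained oscillators. Each unit stands for one
transverse row of hair cells — in the tokay gecko, a sallet-coupled row — and
is written as a van der Pol oscillator in Liénard (two-variable) form:

    dx_n/dt = mu_n (alpha_n x_n − x_n^3/3) − omega_n y_n + C_n(x, dx/dt) + delta_eff sin(2 pi F t) + eta_n(t)
    dy_n/dt = omega_n x_n

with `x_n` the hair-bundle displacement and `y_n` an internal variable
summarizing adaptation and other slow bundle dynamics. The parameters:

* `alpha_n` (distance²) sets the limit-cycle amplitude: an isolated unit
  settles on a nearly circular cycle of radius `2 sqrt(alpha_n)`.
* `omega_n = 2 pi f_n` with `f_n = 3^((n−1)/110)` kHz — a geometric tonotopic
  ladder rising ≈1% per unit, spanning 1–2.97 kHz at `N = 110` (and 1–8.06 kHz
  at `N = 210`, keeping the same exponent denominator).
* `mu_n = omega_n / 5` (the ratio is fixed) makes every unit an equally and
  weakly nonlinear oscillator: the cycles are nearly sinusoidal (third
  harmonic ≳20 dB below the fundamental), and units differ only in timescale.

The system is treated as overdamped — no inertia — which the hydrodynamics
justifies: a 50-µm sallet moving ±50 nm at 1–7 kHz has peak velocities of
0.3–2.2 mm/s and Reynolds numbers of 0.015–0.11 in water
(`emission_metrics.reynolds_number`), so viscous forces dominate inertial ones.

### Units and the 2π convention

The model is nondimensional at heart: its natural time unit is the one in
which the *angular* frequency of unit `n` is numerically `3^((n−1)/110)`, i.e.
runs from 1 to 3 along the standard chain. The package presents time in ms and
frequency in kHz, a pure rescaling of time by `2π` chosen so the chain reads
1–2.97 kHz. Configuration files quote the conventional natural-unit values of
the coupling, stimulus, and noise magnitudes (`gamma = 1`, `delta = 0.2`,
noise sd 0.1); the integrator multiplies every inverse-time coefficient by
`2π` (`ChainConfig.gamma_eff`, `.delta_eff`, `.noise_sd_eff`). The
dimensionless viscous coupling `beta` needs no conversion. This convention is
load-bearing: the coupling-to-frequency ratio `gamma_eff/omega_1 = gamma`
controls how many units one group entrains, hence the number of emission
peaks; treating `gamma = 1` as 1/ms directly would weaken the coupling
2π-fold and fragment the spectrum.

## Coupling

Two nearest-neighbor couplings, selected by which of `beta`, `gamma` is
nonzero (both at once is permitted but carries no validated claims):

* **Elastic** (`gamma`, 1/natural-time): adds
  `gamma_eff (x_{n+1} − 2 x_n + x_{n−1})` to `dx_n/dt` — springs along the
  tectorial membrane or the inter-sallet strand. Virtual neighbors beyond the
  ends are clamped (`x_0 = x_{N+1} = 0`), so the outermost units feel an
  asymmetric pull and oscillate less.
* **Viscous** (`beta`, dimensionless): drag against the velocity difference
  of neighbors. Because the drag involves the unknown velocities, the
  equations are implicit; they are rearranged into `B ẋ = g` with `B`
  symmetric tridiagonal (diagonal `1 + 2β`, off-diagonal `−β`). `B` is
  strictly diagonally dominant for `β > 0`, and every entry of `B⁻¹` is
  nonzero — strictly local drag mediates an effective global coupling. The
  production path solves the system with O(N) banded elimination; a dense
  inverse exists only as a test oracle. The boundary uses virtual stationary
  neighbors (`ẋ_0 = ẋ_{N+1} = 0`), mirroring the elastic clamped ends; the
  choice only affects the two end units.

**Stimulus**: a global sinusoidal drive `delta_eff sin(2 pi F t)` (zero
initial phase; spectra are phase-invariant) applied identically to every
unit — an acoustic tone moves the whole papilla.

**Noise**: a piecewise-constant random force added to `dx/dt`, drawn
independently per unit and per 16-µs hold interval from `N(0, sd²)`. The hold
interval and sd parameterize the forcing itself; there is deliberately no
`1/sqrt(dt)` diffusion rescaling, because the process is specified as a held
forcing, not a Wiener increment.

## Integration

* Deterministic runs: adaptive explicit Runge–Kutta (scipy RK45) with
  `rtol = 1e-6`, `atol = 1e-9`. A robustness test halves the tolerances and
  checks that every summed-spectrum peak moves by < 0.5 dB.
* Noisy runs: fixed-step classical RK4 with step 4 µs, an exact divisor of the
  16-µs noise hold, so the forcing is constant within each step and the
  trajectory is independent of how steps tile holds. The stepper is
  numba-compiled; a 3.4-s, 110-unit noisy run takes seconds.

Initialization assigns each unit a uniformly random phase on its unperturbed
cycle: `x_n = 2 sqrt(alpha_n) cos φ_n`, `y_n = 2 sqrt(alpha_n) sin φ_n`
(silent units with `alpha_n = 0` start at the origin). Three independent seed
streams (initial phases, quenched disorder, noise) derive from the master
seed, so sweeps can pin the disorder pattern while re-randomizing dynamics.

Defaults chosen where unstated: equilibration 160 ms (group structure forms
well within this horizon in pilot runs; it is a config field), output sampling
16 µs (matches the noise hold; 8000 samples per 128-ms window, 7.8125-Hz
bins — fine enough to resolve a 30-Hz suppression band).

## Spectral pipeline

The emission proxy is the displacement summed across the chain. Spectra are
segment-averaged Hann periodograms: mean removal per segment, Hann taper,
one-sided density with window-power compensation (via `scipy.signal.welch`),
averaged over segments. Hop is window/4 (75% overlap) everywhere — the only
hop that makes a 1.6-s record yield exactly 47 segments of 128 ms; the same
convention is applied to 3.2-s runs (97 segments) and to the recorded-data
path (80-ms windows). Overlap fraction and detrending are config-exposed.

Simulated spectra are reported in dB relative to the peak spectral density of
a single free-running unit (`alpha = 1`) at its natural frequency — 1 kHz,
the chain's first rung, which sits exactly on the 7.8125-Hz bin grid — run
and windowed identically. Peak detection is offset-invariant and suppression
is a dB difference, so this reference choice cancels in every claimed number.

The recorded-emission path accepts WAV or two-column text, and optionally
subtracts a control (postmortem/background) spectrum in power before dB
conversion. The difference is floored at 10% of the per-bin control density:
below the background's own fluctuation scale a difference spectrum carries no
information, and an absolute floor would instead fabricate deeply prominent
notches between noise residuals. No A-weighting or absolute calibration is
applied (relative dB only).

## Metrics

* **Peaks**: local maxima of the dB spectrum with topographic prominence
  ≥ 6 dB and mutual separation ≥ 30 Hz, inside an analysis band that defaults
  to the spectrum's span minus 5% at each edge. The figure-level workflows
  count *central* peaks inside the chain's tonotopic span `[f_1, f_N]`:
  synchronized groups oscillate near the median natural frequency of their
  members, so group peaks live in that band, while the weak (−25 dB and
  below) combination tones outside it are not emission peaks. All thresholds
  are config-exposed; the reported counts are not knife-edge against them.
* **Suppression**: mean of `baseline dB − stimulated dB` over the 30-Hz bands
  flanking the stimulus. A guard interval of 2.5 bins (~19.5 Hz) around the
  stimulus frequency is excluded first: the tone's own Hann main lobe spans
  ±2 bins (plus off-grid spread) and would otherwise mask the suppression
  trough with its leakage. Both flanking bands are averaged by default
  ("immediately adjacent" does not say one- or two-sided; two-sided is
  symmetric and lower-variance), with a one-sided mode selectable.
* **Repulsion tracking**: per sweep point, detected peaks plus the signed
  offsets from the stimulus frequency of the nearest group on each side,
  excluding the entrained peak pinned at the stimulus (same guard).
* **Group counting**: the number of synchronized groups is counted as
  plateaus of each oscillator's dominant spectral frequency along the chain
  (changes > 2 bins start a new group; taper-silenced ends skipped). This
  measures groups directly and stays monotone in the coupling sweep where
  summed-spectrum peak counts are noisy, because weakly coupled, drifting
  groups smear their summed-spectrum peaks below the detection criterion
  while still being distinct groups.
* **Wave direction**: the circular-mean analytic-signal phase step between
  adjacent units. Positive means the high-frequency neighbor leads
  (synchronization waves run from the high-frequency end toward the
  low-frequency end, the elastic-chain signature); values near ±π mark
  antiphase pairs (a viscous-chain feature).

## Synthetic data and what the tests show

All test inputs are generated in-process: chain simulations from the presets,
synthetic sinusoid/noise fixtures for the spectral estimator, and a synthetic
"recorded emission" (a 12-tone comb, 240-Hz spacing, over Gaussian noise,
with an independent noise control) for the recorded-data path. The generator
reproduces the study conditions — chain sizes 110/210, amplitude profiles
(uniform, 18-unit linear taper, parabolic arch, 3%-sd central disorder),
coupling 0–2, stimulus amplitude 0–1 at 0.6–3.6 kHz, noise sd 0.1 held 16 µs,
1.6/3.2-s records. It does not emulate microphone/meatus acoustics,
calibration, A-weighting electronics, physiological drift, or temperature
sensitivity, so passing tests validate the model's emergent dynamics and the
pipeline's statistics, not absolute sound-pressure levels of real ears.

Problem sizes in the test suite: the full-length (3.2-s, N=110) runs are used
where a claim is quantitative (peak count, suppression, sweeps); structural
and qualitative unit tests use shortened records (0.32–1-s) and small chains,
sizes the results do not depend on.

## Known limitations

* Claims about combined viscoelastic coupling (β and γ both nonzero) are not
  validated; the engine merely permits it.
* The viscous chain's spectrum, while lacking the elastic chain's strong
  group peaks (its maxima sit ~14 dB lower, near the single-unit reference
  level), still contains maxima that a pure prominence criterion counts;
  "no well-defined peaks" is asserted via power concentration and relative
  height, not an empty PeakSet.
* Peak counts at weak elastic coupling (γ ≲ 0.5) vary by several across
  seeds; only the γ = 1 count and the group-count monotonicity are treated
  as stable observables.
* The recorded-data path is exercised on synthetic fixtures only; no animal
  recordings ship with the package.
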