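"""Preset- and sweep-level workflows tying simulation, spectra, and metrics.

Presets name the parameter sets of the standard simulation conditions
(chain size, amplitude profile, coupling, stimulus, noise, record length) and
are shipped as YAML files; each run is fully reproducible from its preset and
a seed.  Sweeps vary one parameter (gamma, delta, or F) over an ordered grid,
keeping the quenched disorder pattern fixed across the sweep while dynamical
randomness (initial phases, noise) varies per point.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model_core import ChainConfig
from .sim_engine import Trace, simulate
from .spectral_analysis import (Spectrum, LayeredSpectra, summed_spectrum,
                                layered_spectra)
from .emission_metrics import PeakSet, detect_peaks, repulsion_track

logger = logging.getLogger("soaesim")

PRESET_NAMES = ("fig2", "fig3ab", "fig3cd", "fig3e", "fig4a", "fig4b",
                "fig5a", "fig5b", "fig5c", "fig6ab", "fig6c", "fig6d")

#: sweep definitions: parameter and default grid (exact grids for the gamma
#: and F sweeps are not prescribed; these spans match the stated ranges)
SWEEP_GRIDS = {
    "fig3e": ("gamma", [0.25, 0.5, 1.0, 1.5, 2.0]),
    "fig6c": ("delta", [0.0, 0.2, 0.4, 0.6, 0.8, 1.0]),
    "fig6d": ("F", [round(f, 2) for f in np.arange(0.6, 3.61, 0.3)]),
}


def load_preset(name: str) -> ChainConfig:
    """Load a named preset shipped with the package."""
    if name not in PRESET_NAMES:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}")
    ref = resources.files("soaesim").joinpath(f"presets/{name}.yaml")
    import yaml
    with ref.open() as fh:
        return ChainConfig.from_dict(yaml.safe_load(fh))


def emission_band_khz(config: ChainConfig) -> tuple:
    """Display band for the chain's emission spectrum: zero up to 35% above
    the highest natural frequency."""
    return (0.0, 1.35 * float(config.freqs_khz[-1]))


def central_band_khz(config: ChainConfig) -> tuple:
    """The chain's tonotopic span [f_1, f_N].  Synchronized groups oscillate
    near the median natural frequency of their members, so the central
    emission peaks live in this band; spectral structure outside it consists
    of boundary-group skirts and weak combination tones."""
    f = config.freqs_khz
    return (float(f[0]), float(f[-1]))


@dataclass
class RunResult:
    """Artifact bundle of one preset run."""

    name: str
    config: ChainConfig
    trace: Trace
    spectrum: Spectrum            # cropped to the emission band
    peaks: PeakSet
    layered: Optional[LayeredSpectra] = None


@dataclass
class SweepSpec:
    """One-parameter sweep over a base preset."""

    parameter: str                # gamma | delta | F
    values: Sequence[float]
    base_preset: str
    seed_policy: str = "per-point"  # or "fixed"

    def __post_init__(self):
        if self.parameter not in ("gamma", "delta", "F"):
            raise ValueError("parameter must be one of gamma, delta, F")
        if len(self.values) == 0 or not np.all(np.isfinite(self.values)):
            raise ValueError("sweep values must be nonempty and finite")
        if self.seed_policy not in ("fixed", "per-point"):
            raise ValueError("seed_policy must be 'fixed' or 'per-point'")


@dataclass
class SweepResult:
    spec: SweepSpec
    spectra: dict                 # sweep value -> Spectrum (emission band)
    peaks: dict                   # sweep value -> PeakSet
    peaks_table: pd.DataFrame
    flanking_table: pd.DataFrame


def run_preset(name: str, seed: int, out_dir=None, layered: bool = False,
               config_override: Optional[dict] = None) -> RunResult:
    """Simulate a preset, compute its normalized emission spectrum and peaks,
    and (optionally) write the artifact bundle."""
    config = load_preset(name)
    fields = {"seed": seed}
    if config_override:
        fields.update(config_override)
    config = dataclasses.replace(config, **fields)
    trace = simulate(config)
    spec = summed_spectrum(trace).band(*emission_band_khz(config))
    peaks = detect_peaks(spec, band_khz=central_band_khz(config))
    lay = None
    if layered:
        lay = layered_spectra(trace)
    result = RunResult(name=name, config=config, trace=trace, spectrum=spec,
                       peaks=peaks, layered=lay)
    if out_dir is not None:
        _write_bundle(result, Path(out_dir))
    return result


def _write_bundle(result: RunResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = out_dir / result.name
    result.config.to_yaml(f"{stem}.config.yaml")
    result.trace.save(f"{stem}.trace.npz")
    result.spectrum.export_text(f"{stem}.spectrum.tsv")
    result.peaks.export_text(f"{stem}.peaks.tsv")
    if result.layered is not None:
        result.layered.export_text(f"{stem}.layered.tsv")
    summary = {
        "preset": result.name, "seed": result.config.seed,
        "n_peaks": result.peaks.count,
        "spacing_mean_hz": result.peaks.spacing_mean_hz,
        "spacing_sd_hz": result.peaks.spacing_sd_hz,
    }
    with open(f"{stem}.summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    logger.info("wrote bundle for %s to %s", result.name, out_dir)


def run_sweep(spec_or_name, seed: int, out_dir=None) -> SweepResult:
    """Run a sweep (by SweepSpec or by named grid: fig3e, fig6c, fig6d).

    The quenched disorder pattern, if any, is pinned to one seed across the
    whole sweep; initial phases and noise reseed per point unless the policy
    is 'fixed'.
    """
    if isinstance(spec_or_name, str):
        if spec_or_name not in SWEEP_GRIDS:
            raise KeyError(f"unknown sweep {spec_or_name!r}; "
                           f"available: {', '.join(SWEEP_GRIDS)}")
        parameter, values = SWEEP_GRIDS[spec_or_name]
        spec = SweepSpec(parameter=parameter, values=values,
                         base_preset=spec_or_name)
    else:
        spec = spec_or_name

    base = load_preset(spec.base_preset)
    state = np.random.SeedSequence(seed).generate_state(len(spec.values) + 1)
    disorder_seed = int(state[0] % 2**31)
    point_seeds = [int(s % 2**31) for s in state[1:]]

    spectra, peaks = {}, {}
    for i, value in enumerate(spec.values):
        cfg = dataclasses.replace(base, **{spec.parameter: float(value)})
        if cfg.alpha_profile.kind == "disordered":
            cfg.alpha_profile = dataclasses.replace(
                cfg.alpha_profile, disorder_seed=disorder_seed)
        cfg = dataclasses.replace(
            cfg, seed=seed if spec.seed_policy == "fixed" else point_seeds[i])
        trace = simulate(cfg)
        sp = summed_spectrum(trace).band(*emission_band_khz(cfg))
        spectra[float(value)] = sp
        peaks[float(value)] = detect_peaks(sp, band_khz=central_band_khz(cfg))

    if spec.parameter == "F":
        # flanking offsets are measured against each point's own stimulus
        frames_p, frames_f = [], []
        for value, sp in spectra.items():
            pt, ft = repulsion_track({value: sp}, F_khz=value,
                                     band_khz=central_band_khz(base))
            frames_p.append(pt)
            frames_f.append(ft)
        peaks_table = pd.concat(frames_p, ignore_index=True)
        flanking = pd.concat(frames_f, ignore_index=True)
    else:
        F_ref = base.F if base.F > 0 else float(np.median(base.freqs_khz))
        peaks_table, flanking = repulsion_track(spectra, F_khz=F_ref,
                                                band_khz=central_band_khz(base))

    result = SweepResult(spec=spec, spectra=spectra, peaks=peaks,
                         peaks_table=peaks_table, flanking_table=flanking)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        tag = f"{spec.base_preset}_{spec.parameter}"
        peaks_table.to_csv(out_dir / f"{tag}.peaks.tsv", sep="\t", index=False)
        flanking.to_csv(out_dir / f"{tag}.flanking.tsv", sep="\t", index=False)
        stack = pd.concat(
            {v: pd.DataFrame({"freq_khz": s.freqs_khz, "power_db": s.power_db})
             for v, s in spectra.items()},
            names=["sweep_value"]).reset_index(level=0)
        stack.to_csv(out_dir / f"{tag}.spectra.tsv", sep="\t", index=False)
    return result
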