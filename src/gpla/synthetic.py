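"""Synthetic spike/LFP benchmarks: oscillation mixtures and phase-locked spikes.

Every simulation follows the same recipe: a small set of narrow-band
oscillatory components is mixed linearly onto the LFP channels (plus white
Gaussian noise), and each spiking unit is an inhomogeneous Poisson process
whose rate is modulated by the instantaneous phase of the component it is
assigned to,

    lambda(t) = lambda0 * (1 + kappa * envelope(t) * cos(phi(t) - phi0)),

clipped at zero.  The coupling strength ``kappa`` runs from 0 (no coupling)
to 1 (maximal sinusoidal modulation); for a constant-envelope oscillation the
ground-truth phase-locking value of such a unit is ``(kappa/2) e^{i phi0}``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal.windows import tukey

from .coupling import SpikeTrainSet
from .preprocess import RawLFP

__all__ = [
    "OscillationSpec",
    "CouplingSpec",
    "oscillation_components",
    "gen_lfp",
    "gen_locked_spikes",
    "gen_scenario",
    "gen_multipop",
    "snr_of_estimate",
    "true_plv",
    "SNR_CAP",
]


@dataclass
class OscillationSpec:
    """One oscillatory LFP component."""

    freq: float
    amplitude: float = 1.0
    phase: float = 0.0
    envelope: tuple[float, float] | None = None  # (start_s, stop_s) Tukey window
    noise_sigma: float = 0.0
    random_trial_phase: bool = True


@dataclass
class CouplingSpec:
    """Assignment of units to oscillations and their modulation parameters."""

    strength: float  # kappa in [0, 1]
    base_rate: float  # lambda0, Hz
    locking_phase: float = 0.0
    component: int | None = 0  # None = uncoupled

    def __post_init__(self) -> None:
        if not (0 <= self.strength <= 1):
            raise ValueError("coupling strength must lie in [0, 1]")
        if self.base_rate < 0:
            raise ValueError("base rate must be non-negative")


def oscillation_components(
    specs: list[OscillationSpec],
    fs: float,
    duration: float,
    n_trials: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Oscillation time courses, their phases, and envelopes.

    Returns ``(components, phases, envelopes)`` with shapes
    ``(n_trials, n_comp, T)``; ``components`` is the real signal
    ``amplitude * envelope * cos(phase) + noise``.
    """
    T = int(round(duration * fs))
    t = np.arange(T) / fs
    comps = np.zeros((n_trials, len(specs), T))
    phases = np.zeros_like(comps)
    envs = np.ones_like(comps)
    for j, spec in enumerate(specs):
        if spec.freq >= fs / 2:
            raise ValueError(f"component frequency {spec.freq} >= Nyquist")
        for k in range(n_trials):
            phi0 = rng.uniform(0, 2 * np.pi) if spec.random_trial_phase else 0.0
            phase = 2 * np.pi * spec.freq * t + spec.phase + phi0
            env = np.ones(T)
            if spec.envelope is not None:
                start, stop = spec.envelope
                i0, i1 = int(round(start * fs)), int(round(stop * fs))
                env = np.zeros(T)
                env[i0:i1] = tukey(i1 - i0, alpha=0.5)
            sig = spec.amplitude * env * np.cos(phase)
            if spec.noise_sigma > 0:
                sig = sig + rng.normal(0, spec.noise_sigma, T)
            comps[k, j] = sig
            phases[k, j] = phase
            envs[k, j] = env
    return comps, phases, envs


def gen_lfp(
    specs: list[OscillationSpec],
    mixing: np.ndarray,
    fs: float,
    duration: float,
    n_trials: int,
    rng: np.random.Generator,
    noise_sigma: float = 0.0,
    components: np.ndarray | None = None,
) -> RawLFP:
    """Mix oscillatory components onto channels with additive Gaussian noise.

    ``mixing`` is ``(n_channels, n_components)``; pass ``components`` (from
    :func:`oscillation_components`) to reuse the exact time courses that also
    drive spike generation.
    """
    mixing = np.atleast_2d(np.asarray(mixing, dtype=float))
    if components is None:
        components, _, _ = oscillation_components(specs, fs, duration, n_trials, rng)
    if mixing.shape[1] != components.shape[1]:
        raise ValueError(
            f"mixing has {mixing.shape[1]} columns, {components.shape[1]} components"
        )
    trials = []
    for k in range(n_trials):
        sig = mixing @ components[k]
        if noise_sigma > 0:
            sig = sig + rng.normal(0, noise_sigma, sig.shape)
        trials.append(sig)
    return RawLFP(trials=trials, fs=fs)


def gen_locked_spikes(
    phase: np.ndarray,
    specs: list[CouplingSpec],
    fs: float,
    rng: np.random.Generator,
    envelope: np.ndarray | None = None,
) -> SpikeTrainSet:
    """Inhomogeneous Poisson spikes locked to per-component phase signals.

    ``phase`` has shape ``(n_trials, n_comp, T)``; each unit ``m`` draws
    per-sample Poisson counts from ``lambda0 (1 + kappa * env * cos(phi -
    phi0)) / fs`` of its assigned component (homogeneous Poisson when
    unassigned).
    """
    n_trials, _, T = phase.shape
    trains = []
    for spec in specs:
        per_trial = []
        for k in range(n_trials):
            if spec.component is None or spec.strength == 0:
                rate = np.full(T, spec.base_rate)
            else:
                mod = np.cos(phase[k, spec.component] - spec.locking_phase)
                if envelope is not None:
                    mod = mod * envelope[k, spec.component]
                rate = spec.base_rate * (1 + spec.strength * mod)
            rate = np.clip(rate, 0, None)
            counts = rng.poisson(rate / fs)
            idx = np.repeat(np.nonzero(counts)[0], counts[counts > 0])
            per_trial.append(idx.astype(np.int64))
        trains.append(per_trial)
    return SpikeTrainSet(trains=trains, trial_length=T, fs=fs)


# ---------------------------------------------------------------------------
# scenario presets
# ---------------------------------------------------------------------------

_SCENARIOS = ("global_sync", "wave", "three_clusters", "uncoupled")


def gen_scenario(
    kind: str,
    n_units: int = 18,
    rng: np.random.Generator | None = None,
    *,
    freq: float = 5.0,
    fs: float = 250.0,
    duration: float = 6.0,
    n_trials: int = 25,
    base_rate: float = 12.0,
    kappa: float = 0.8,
    noise_sigma: float = 0.05,
) -> tuple[RawLFP, SpikeTrainSet, dict]:
    """Single-channel transient-oscillation scenarios.

    * ``global_sync`` — all units locked at the oscillation trough.
    * ``wave``        — locking phases spread evenly over 180 degrees.
    * ``three_clusters`` — three groups at phases 120 degrees apart.
    * ``uncoupled``   — homogeneous Poisson spike trains.
    """
    if kind not in _SCENARIOS:
        raise ValueError(f"kind must be one of {_SCENARIOS}")
    if rng is None:
        rng = np.random.default_rng()
    env = (duration * 0.25, duration * 0.75)
    spec = OscillationSpec(freq=freq, envelope=env, noise_sigma=0.0)
    comps, phases, envs = oscillation_components([spec], fs, duration, n_trials, rng)

    if kind == "global_sync":
        phis = np.full(n_units, np.pi)
        strength = kappa
    elif kind == "wave":
        phis = np.linspace(0, np.pi, n_units, endpoint=False)
        strength = kappa
    elif kind == "three_clusters":
        centers = np.array([0.0, 2 * np.pi / 3, 4 * np.pi / 3])
        phis = centers[np.arange(n_units) % 3]
        strength = kappa
    else:
        phis = np.zeros(n_units)
        strength = 0.0

    cspecs = [
        CouplingSpec(
            strength=strength,
            base_rate=base_rate,
            locking_phase=float(phis[m]),
            component=0 if strength > 0 else None,
        )
        for m in range(n_units)
    ]
    spikes = gen_locked_spikes(phases, cspecs, fs, rng, envelope=envs)
    lfp = gen_lfp(
        [spec], np.ones((1, 1)), fs, duration, n_trials, rng,
        noise_sigma=noise_sigma, components=comps,
    )
    truth = {"kind": kind, "locking_phases": phis, "kappa": strength, "freq": freq}
    return lfp, spikes, truth


def gen_multipop(
    n_pops: int,
    n_units: int = 100,
    n_channels: int = 100,
    freq_range: tuple[float, float] = (11.0, 15.5),
    strength: float = 0.5,
    rng: np.random.Generator | None = None,
    *,
    coupled_fraction: float = 0.4,
    fs: float = 200.0,
    trial_duration: float = 120.0,
    n_trials: int = 1,
    base_rate: float = 20.0,
    noise_sigma: float = 1.0,
) -> tuple[RawLFP, SpikeTrainSet, dict]:
    """Multiple non-overlapping cell assemblies locked to distinct rhythms.

    ``coupled_fraction`` of the units are partitioned into ``n_pops``
    assemblies; assembly ``p`` is phase-locked (strength ``kappa``) to its own
    oscillatory component, the component frequencies being spread within
    ``freq_range``.  The LFP mixes all components onto every channel with
    random Gaussian weights plus white noise.  The noiseless coupling matrix
    has rank ``n_pops`` (rank 0 at strength 0); ground truth records the
    assignment.
    """
    if not 1 <= n_pops <= n_units:
        raise ValueError("n_pops must be between 1 and n_units")
    if rng is None:
        rng = np.random.default_rng()
    f_lo, f_hi = freq_range
    freqs = f_lo + (f_hi - f_lo) * (np.arange(n_pops) + 0.5) / n_pops
    specs = [OscillationSpec(freq=float(f)) for f in freqs]
    comps, phases, _ = oscillation_components(specs, fs, trial_duration, n_trials, rng)
    mixing = rng.normal(0, 1, (n_channels, n_pops))
    lfp = gen_lfp(
        specs, mixing, fs, trial_duration, n_trials, rng,
        noise_sigma=noise_sigma, components=comps,
    )

    n_coupled = int(round(coupled_fraction * n_units))
    assignment = np.full(n_units, -1)
    if strength > 0 and n_coupled > 0:
        assignment[:n_coupled] = np.arange(n_coupled) % n_pops
    locking = rng.uniform(0, 2 * np.pi, n_units)
    cspecs = [
        CouplingSpec(
            strength=strength if assignment[m] >= 0 else 0.0,
            base_rate=base_rate,
            locking_phase=float(locking[m]),
            component=int(assignment[m]) if assignment[m] >= 0 else None,
        )
        for m in range(n_units)
    ]
    spikes = gen_locked_spikes(phases, cspecs, fs, rng)
    truth = {
        "assignment": assignment,
        "rank": int(n_pops if strength > 0 and n_coupled else 0),
        "freqs": freqs,
        "strength": strength,
        "band": (f_lo - 1.0, f_hi + 1.0),
    }
    return lfp, spikes, truth


SNR_CAP = 1e12


def true_plv(kappa: float, phi0: float) -> complex:
    """Ground-truth PLV of a cosine-modulated unit on a constant-envelope tone."""
    return (kappa / 2) * np.exp(1j * phi0)


def snr_of_estimate(estimated: complex, truth: complex) -> float:
    """|truth| / |estimated - truth|, capped at ``SNR_CAP`` for exact matches."""
    err = abs(estimated - truth)
    if err == 0:
        return SNR_CAP
    return min(abs(truth) / err, SNR_CAP)
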