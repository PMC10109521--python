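"""Pairwise spike-field coupling statistics and the coupling matrix.

Two normalizations of the same flat sum over spikes are supported:

* ``plv`` — the phase-locking value, the mean over spikes of the LFP phasor
  ``exp(i phi)`` at spike times, normalized by the total spike count ``N``;
  its modulus is bounded by 1.
* ``c`` — the amplitude-weighted statistic, the sum of analytic-signal values
  at spike times scaled by ``1/sqrt(N)``.  With whitened LFPs its null
  variance is 1, which is what the random-matrix significance test requires.

Stacking the statistic for every (channel, unit) pair gives the complex
``n_channels x n_units`` coupling matrix that the singular-value
decomposition summarizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .preprocess import AnalyticLFP

__all__ = [
    "SpikeTrainSet",
    "CouplingMatrix",
    "pairwise_plv",
    "pairwise_c",
    "build_coupling_matrix",
]

Mode = Literal["plv", "c"]


@dataclass
class SpikeTrainSet:
    """Spike sample indices per unit per trial.

    ``trains[m][k]`` is the sorted integer array of spike times (sample
    indices into the LFP) of unit ``m`` in trial ``k``.  Continuous spike
    times must be converted to indices before construction (see
    :func:`from_times`).
    """

    trains: list[list[np.ndarray]]
    trial_length: int | Sequence[int]
    fs: float
    units: list[str] | None = None

    def __post_init__(self) -> None:
        if not self.trains:
            raise ValueError("SpikeTrainSet needs at least one unit")
        n_trials = len(self.trains[0])
        lengths = self.trial_lengths
        for m, per_trial in enumerate(self.trains):
            if len(per_trial) != n_trials:
                raise ValueError(f"unit {m} has {len(per_trial)} trials, expected {n_trials}")
            self.trains[m] = [np.asarray(t, dtype=np.int64) for t in per_trial]
            for k, t in enumerate(self.trains[m]):
                if t.size and (t.min() < 0 or t.max() >= lengths[k]):
                    raise ValueError(
                        f"unit {m} trial {k}: spike index outside [0, {lengths[k]})"
                    )
        if self.units is None:
            self.units = [f"unit{m}" for m in range(len(self.trains))]

    @property
    def n_units(self) -> int:
        return len(self.trains)

    @property
    def n_trials(self) -> int:
        return len(self.trains[0])

    @property
    def trial_lengths(self) -> list[int]:
        if np.isscalar(self.trial_length):
            return [int(self.trial_length)] * len(self.trains[0])
        return [int(x) for x in self.trial_length]

    def counts(self) -> np.ndarray:
        """Total spike count per unit, summed over trials."""
        return np.array([sum(t.size for t in per_trial) for per_trial in self.trains])

    @classmethod
    def from_times(
        cls,
        times_s: list[list[np.ndarray]],
        trial_length: int | Sequence[int],
        fs: float,
        units: list[str] | None = None,
    ) -> "SpikeTrainSet":
        """Build from continuous spike times in seconds.

        Times are rounded to the nearest sample, ties toward the earlier
        sample; spikes rounding past the trial end are clipped to the last
        sample.
        """
        lengths = (
            [int(trial_length)] * len(times_s[0])
            if np.isscalar(trial_length)
            else [int(x) for x in trial_length]
        )
        trains = []
        for per_trial in times_s:
            rounded = []
            for k, t in enumerate(per_trial):
                idx = np.ceil(np.asarray(t, dtype=float) * fs - 0.5).astype(np.int64)
                idx = np.clip(idx, 0, lengths[k] - 1)
                rounded.append(np.sort(idx))
            trains.append(rounded)
        return cls(trains=trains, trial_length=trial_length, fs=fs, units=units)


@dataclass
class CouplingMatrix:
    """Complex channels x units coupling matrix plus normalization metadata."""

    values: np.ndarray
    mode: Mode
    whitened: bool
    band: tuple[float, float]
    unit_counts: np.ndarray
    units: list[str] = field(default_factory=list)
    n_trials: int = 1

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_units(self) -> int:
        return self.values.shape[1]


def _spike_sum(trains: list[np.ndarray], lfp: AnalyticLFP, channel: int | None = None):
    """Sum of analytic-signal values at spike times over trials; returns (sum, N)."""
    total = None
    n = 0
    for k, idx in enumerate(trains):
        tr = lfp.trials[k]
        sig = tr if channel is None else tr[channel : channel + 1]
        if idx.size:
            s = sig[:, idx].sum(axis=1)
            total = s if total is None else total + s
            n += idx.size
    if total is None:
        total = np.zeros(
            lfp.n_channels if channel is None else 1, dtype=complex
        )
    return total, n


def pairwise_plv(trains: list[np.ndarray], lfp: AnalyticLFP, channel: int = 0) -> complex:
    """Phase-locking value of one unit to one channel: mean spike phasor.

    Returns ``nan`` (flagged missing) when the unit fired no spikes — zero
    would wrongly mean "no locking".
    """
    total = 0.0 + 0.0j
    n = 0
    for k, idx in enumerate(trains):
        if idx.size:
            z = lfp.trials[k][channel, idx]
            mod = np.abs(z)
            mod[mod == 0] = 1.0
            total += np.sum(z / mod)
            n += idx.size
    if n == 0:
        return complex(np.nan, np.nan)
    return complex(total / n)


def pairwise_c(trains: list[np.ndarray], lfp: AnalyticLFP, channel: int = 0) -> complex:
    """Amplitude-weighted coupling of one unit to one channel, scaled 1/sqrt(N)."""
    total, n = _spike_sum(trains, lfp, channel)
    if n == 0:
        return complex(np.nan, np.nan)
    return complex(total[0] / np.sqrt(n))


def build_coupling_matrix(
    spikes: SpikeTrainSet,
    lfp: AnalyticLFP,
    mode: Mode = "plv",
    *,
    whitened: bool = False,
    min_spikes: int = 0,
    edge_margin: int = 0,
) -> CouplingMatrix:
    """Assemble the coupling matrix over all channels and retained units.

    Units with fewer than ``min_spikes`` total spikes are excluded (their
    estimates would be too noisy); ``edge_margin`` samples at each trial end
    are ignored to avoid filter/Hilbert edge artifacts.
    """
    if spikes.n_trials != lfp.n_trials:
        raise ValueError(
            f"spikes have {spikes.n_trials} trials, LFP has {lfp.n_trials}"
        )
    lengths = spikes.trial_lengths
    for k, tr in enumerate(lfp.trials):
        if tr.shape[1] != lengths[k]:
            raise ValueError(
                f"trial {k}: LFP length {tr.shape[1]} != spike trial length {lengths[k]}"
            )

    if edge_margin > 0:
        kept_trains = [
            [
                t[(t >= edge_margin) & (t < lengths[k] - edge_margin)]
                for k, t in enumerate(per_trial)
            ]
            for per_trial in spikes.trains
        ]
    else:
        kept_trains = spikes.trains

    counts = np.array([sum(t.size for t in per_trial) for per_trial in kept_trains])
    retained = [m for m in range(spikes.n_units) if counts[m] >= max(min_spikes, 1)]
    if not retained:
        excluded = {spikes.units[m]: int(counts[m]) for m in range(spikes.n_units)}
        raise ValueError(f"no units meet the minimum spike count; counts: {excluded}")

    if mode == "plv":
        phasor_trials = []
        for tr in lfp.trials:
            mod = np.abs(tr)
            mod[mod == 0] = 1.0
            phasor_trials.append(tr / mod)
        src = AnalyticLFP(trials=phasor_trials, band=lfp.band, fs=lfp.fs)
    elif mode == "c":
        src = lfp
    else:
        raise ValueError(f"unknown mode {mode!r}")

    cols = []
    for m in retained:
        total, n = _spike_sum(kept_trains[m], src)
        scale = n if mode == "plv" else np.sqrt(n)
        cols.append(total / scale)
    values = np.stack(cols, axis=1)
    return CouplingMatrix(
        values=values,
        mode=mode,
        whitened=whitened,
        band=lfp.band,
        unit_counts=counts[retained],
        units=[spikes.units[m] for m in retained],
        n_trials=spikes.n_trials,
    )
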