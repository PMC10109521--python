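"""Band-limited analytic-signal extraction and reduced-rank whitening of LFPs.

The local field potential (LFP) enters the analysis as a real multi-trial,
multi-channel time series.  Coupling statistics are defined on the complex
analytic signal of a narrow frequency band, obtained by zero-phase band-pass
filtering followed by the Hilbert transform.  For the analytical
(random-matrix) significance test the channels must additionally be
decorrelated; this module implements the reduced-rank whitening used for that
purpose: the eigendecomposition of the all-trial covariance fixes the retained
rank, and each trial is whitened with its own truncated eigendecomposition so
that trial-specific covariance structure is removed exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal

__all__ = [
    "RawLFP",
    "AnalyticLFP",
    "WhiteningModel",
    "bandpass_analytic",
    "fit_whitening",
    "apply_whitening",
    "fit_unwhitening",
    "edge_margin_samples",
]


@dataclass
class RawLFP:
    """Real multi-trial LFP: one ``(n_channels, n_samples)`` matrix per trial."""

    trials: list[np.ndarray]
    fs: float
    channel_ids: list[str] | None = None
    channel_coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.trials:
            raise ValueError("RawLFP needs at least one trial")
        self.trials = [np.asarray(t, dtype=float) for t in self.trials]
        n_c = self.trials[0].shape[0]
        for k, t in enumerate(self.trials):
            if t.ndim != 2 or t.shape[0] != n_c:
                raise ValueError(f"trial {k} has shape {t.shape}, expected ({n_c}, T)")
            if t.shape[1] < 2:
                raise ValueError(f"trial {k} has fewer than 2 samples")
            if not np.all(np.isfinite(t)):
                raise ValueError(f"trial {k} contains non-finite values")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.channel_ids is None:
            self.channel_ids = [f"ch{i}" for i in range(n_c)]

    @property
    def n_channels(self) -> int:
        return self.trials[0].shape[0]

    @property
    def n_trials(self) -> int:
        return len(self.trials)


@dataclass
class AnalyticLFP:
    """Complex analytic band-limited LFP, same layout as :class:`RawLFP`."""

    trials: list[np.ndarray]
    band: tuple[float, float]
    fs: float

    def __post_init__(self) -> None:
        f_lo, f_hi = self.band
        if not (0 < f_lo < f_hi < self.fs / 2):
            raise ValueError(f"band {self.band} invalid for fs={self.fs}")
        self.trials = [np.asarray(t, dtype=complex) for t in self.trials]

    @property
    def n_channels(self) -> int:
        return self.trials[0].shape[0]

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def center_frequency(self) -> float:
        return 0.5 * (self.band[0] + self.band[1])


@dataclass
class WhiteningModel:
    """Per-trial reduced-rank whitening operators and their regression inverse.

    ``per_trial_ops[k]`` holds ``(eigvals, eigvecs)`` of trial ``k``'s
    covariance, truncated at the all-trial rank ``n_c_eff``.  ``unwhitening``
    is the least-squares map from whitened back to original channel space and
    is filled in by :func:`fit_unwhitening`.
    """

    n_c_eff: int
    variance_threshold: float
    per_trial_ops: list[tuple[np.ndarray, np.ndarray]]
    global_eigvals: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    unwhitening: np.ndarray | None = None


def _sorted_eigh(cov: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hermitian eigendecomposition sorted by descending eigenvalue.

    Ties are broken by original channel index (stable sort), and each
    eigenvector's global phase is fixed by making its largest-modulus entry
    real positive.
    """
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(-vals, kind="stable")
    vals, vecs = vals[order], vecs[:, order]
    for j in range(vecs.shape[1]):
        i = int(np.argmax(np.abs(vecs[:, j])))
        pivot = vecs[i, j]
        if np.abs(pivot) > 0:
            vecs[:, j] *= np.conj(pivot) / np.abs(pivot)
    return vals, vecs


def bandpass_analytic(
    raw: RawLFP,
    band: tuple[float, float],
    *,
    order: int = 4,
) -> AnalyticLFP:
    """Zero-phase band-pass filter each channel and take its analytic signal.

    A forward-backward Butterworth filter (``filtfilt``) avoids phase
    distortion; the Hilbert transform then yields the complex analytic signal
    whose argument is the instantaneous phase in ``band``.
    """
    f_lo, f_hi = band
    nyq = raw.fs / 2
    if not (0 < f_lo < f_hi < nyq):
        raise ValueError(f"band {band} outside (0, {nyq}) for fs={raw.fs}")
    sos = signal.butter(order, [f_lo, f_hi], btype="bandpass", fs=raw.fs, output="sos")
    # filtfilt needs trials comfortably longer than the filter's edge padding
    padlen = 3 * (2 * order + 1)
    out = []
    for k, tr in enumerate(raw.trials):
        if tr.shape[1] <= padlen:
            raise ValueError(
                f"trial {k} length {tr.shape[1]} too short for order-{order} "
                f"zero-phase filter (needs > {padlen} samples)"
            )
        filt = signal.sosfiltfilt(sos, tr, axis=1)
        out.append(signal.hilbert(filt, axis=1))
    return AnalyticLFP(trials=out, band=(f_lo, f_hi), fs=raw.fs)


def edge_margin_samples(lfp: AnalyticLFP, cycles: float = 3.0) -> int:
    """Samples to discard at each trial end (Hilbert/filter edge artifacts).

    Default is three cycles of the band's lower edge.
    """
    return int(round(cycles * lfp.fs / lfp.band[0]))


def fit_whitening(lfp: AnalyticLFP, variance_threshold: float = 0.99) -> WhiteningModel:
    """Fit the reduced-rank whitening operator.

    The retained rank ``n_c_eff`` is the smallest number of eigenvalues of the
    all-trial concatenated covariance ``(1/T) L L^H`` explaining at least
    ``variance_threshold`` of total variance.  Each trial then gets its own
    truncated eigendecomposition so that the whitened trial covariance is the
    identity on the retained components.
    """
    if not (0 < variance_threshold <= 1):
        raise ValueError("variance_threshold must be in (0, 1]")
    L = np.concatenate(lfp.trials, axis=1)
    total_T = L.shape[1]
    cov = (L @ L.conj().T) / total_T
    vals, _ = _sorted_eigh(cov)
    total = vals.sum().real
    if total <= 0:
        raise ValueError("degenerate LFP: total variance is zero")
    frac = np.cumsum(vals.real) / total
    n_c_eff = int(np.searchsorted(frac, variance_threshold - 1e-12) + 1)
    n_c_eff = min(n_c_eff, lfp.n_channels)

    per_trial = []
    for k, tr in enumerate(lfp.trials):
        cov_k = (tr @ tr.conj().T) / tr.shape[1]
        vals_k, vecs_k = _sorted_eigh(cov_k)
        lam = vals_k[:n_c_eff].real
        if lam[-1] <= 0:
            raise ValueError(
                f"trial {k} covariance is rank-deficient below n_c_eff={n_c_eff}"
            )
        per_trial.append((lam, vecs_k[:, :n_c_eff]))
    return WhiteningModel(
        n_c_eff=n_c_eff,
        variance_threshold=variance_threshold,
        per_trial_ops=per_trial,
        global_eigvals=vals.real,
    )


def apply_whitening(lfp: AnalyticLFP, model: WhiteningModel) -> AnalyticLFP:
    """Whiten each trial: ``L_w = Lambda^{-1/2} X^H L``."""
    if len(model.per_trial_ops) != lfp.n_trials:
        raise ValueError(
            f"model fitted on {len(model.per_trial_ops)} trials, got {lfp.n_trials}"
        )
    out = []
    for (lam, X), tr in zip(model.per_trial_ops, lfp.trials):
        if X.shape[0] != tr.shape[0]:
            raise ValueError("channel-count mismatch between model and data")
        out.append((X.conj().T @ tr) / np.sqrt(lam)[:, None])
    return AnalyticLFP(trials=out, band=lfp.band, fs=lfp.fs)


def fit_unwhitening(whitened: AnalyticLFP, original: AnalyticLFP) -> np.ndarray:
    """Least-squares operator mapping whitened signals back to channel space.

    Solves ``min_W || L - W L_w ||`` over the concatenated trials; the result
    is the ``n_c x n_c_eff`` unwhitening matrix applied to the LFP vector
    after the singular-value decomposition.
    """
    Lw = np.concatenate(whitened.trials, axis=1)
    L = np.concatenate(original.trials, axis=1)
    if Lw.shape[1] != L.shape[1]:
        raise ValueError("whitened and original LFP have different total lengths")
    W_inv, *_ = np.linalg.lstsq(Lw.conj().T, L.conj().T, rcond=None)
    return W_inv.conj().T
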