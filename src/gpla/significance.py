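"""Significance tests for the gPLV: jitter surrogates and the analytic MP test.

Two complementary routes are provided.  Surrogate tests destroy spike-LFP
locking by jittering spikes within windows matched to the analysis band while
preserving per-window counts (and, in the group-preserved variant, the
relative timing between units); the observed gPLV is compared against the
resulting empirical null.  The analytic test avoids surrogates entirely: with
whitened LFPs and the 1/sqrt(N)-normalized coupling statistic, the null
coupling matrix has asymptotically iid standard complex Gaussian entries, so
the squared singular values of C follow the Marchenko-Pastur law and the
largest one can be compared with the deterministic edge (1 + sqrt(alpha))^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coupling import CouplingMatrix, SpikeTrainSet, build_coupling_matrix
from .core import decompose
from .preprocess import AnalyticLFP

__all__ = [
    "MPLaw",
    "SignificanceReport",
    "interval_jitter",
    "group_preserved_jitter",
    "surrogate_test",
    "mp_threshold",
    "mp_density",
    "analytic_test",
    "count_significant",
]


@dataclass
class MPLaw:
    """Marchenko-Pastur law with aspect ratio ``alpha = n_c_eff / n_u``."""

    alpha: float

    @property
    def support(self) -> tuple[float, float]:
        sq = np.sqrt(self.alpha)
        return ((1 - sq) ** 2, (1 + sq) ** 2)

    @property
    def threshold(self) -> float:
        """Detection threshold theta_DET: the upper support edge."""
        return self.support[1]


@dataclass
class SignificanceReport:
    method: str
    significant: bool
    threshold: float | None = None
    p_value: float | None = None
    n_surrogates: int | None = None
    jitter_window_s: float | None = None
    seed: int | None = None
    statistic: float | None = None
    eigenvalues: np.ndarray | None = None
    per_component: np.ndarray | None = None
    n_significant: int | None = None


def _window_edges(length: int, window: int) -> np.ndarray:
    """Window boundaries anchored at 0; last partial window kept."""
    edges = np.arange(0, length, window)
    return np.append(edges, length)


def interval_jitter(
    spikes: SpikeTrainSet, window_s: float, rng: np.random.Generator
) -> SpikeTrainSet:
    """Redraw each spike uniformly within its window.

    The trial is partitioned into contiguous windows of ``window_s`` seconds
    (typically one period of the analysis band's center frequency); the
    per-window, per-unit spike counts are preserved exactly, so rate
    modulations slower than the window survive while locking within the band
    is destroyed.
    """
    if window_s <= 0:
        raise ValueError("jitter window must be positive")
    window = max(1, int(round(window_s * spikes.fs)))
    lengths = spikes.trial_lengths
    new_trains = []
    for per_trial in spikes.trains:
        out_trial = []
        for k, t in enumerate(per_trial):
            if t.size == 0 or window == 1:
                out_trial.append(t.copy())
                continue
            w_start = (t // window) * window
            w_end = np.minimum(w_start + window, lengths[k])
            jittered = w_start + (rng.random(t.size) * (w_end - w_start)).astype(np.int64)
            out_trial.append(np.sort(jittered))
        new_trains.append(out_trial)
    return SpikeTrainSet(
        trains=new_trains, trial_length=spikes.trial_length, fs=spikes.fs,
        units=list(spikes.units),
    )


def group_preserved_jitter(
    spikes: SpikeTrainSet, window_s: float, rng: np.random.Generator
) -> SpikeTrainSet:
    """Circularly shift all units' spikes together within each window.

    One uniform shift is drawn per (trial, window) and shared by every unit,
    so the relative spike timing across units — ensemble structure that may
    exist independently of the LFP — is preserved modulo the window, while
    the alignment to the LFP is destroyed.
    """
    if window_s <= 0:
        raise ValueError("jitter window must be positive")
    window = max(1, int(round(window_s * spikes.fs)))
    lengths = spikes.trial_lengths
    n_trials = spikes.n_trials
    shifts: list[dict[int, int]] = []
    for k in range(n_trials):
        edges = _window_edges(lengths[k], window)
        shifts.append(
            {
                int(edges[i]): int(rng.integers(0, edges[i + 1] - edges[i]))
                for i in range(len(edges) - 1)
            }
        )
    new_trains = []
    for per_trial in spikes.trains:
        out_trial = []
        for k, t in enumerate(per_trial):
            if t.size == 0:
                out_trial.append(t.copy())
                continue
            w_start = (t // window) * window
            w_len = np.minimum(w_start + window, lengths[k]) - w_start
            shift = np.array([shifts[k][int(s)] for s in w_start])
            out_trial.append(np.sort(w_start + (t - w_start + shift) % w_len))
        new_trains.append(out_trial)
    return SpikeTrainSet(
        trains=new_trains, trial_length=spikes.trial_length, fs=spikes.fs,
        units=list(spikes.units),
    )


def surrogate_test(
    spikes: SpikeTrainSet,
    lfp: AnalyticLFP,
    *,
    n_surrogates: int = 99,
    jitter_kind: str = "interval",
    window_s: float | None = None,
    mode: str = "plv",
    min_spikes: int = 0,
    edge_margin: int = 0,
    alpha_level: float = 0.05,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> SignificanceReport:
    """Empirical gPLV null from jittered spikes; add-one p-value.

    ``window_s`` defaults to one period of the band's center frequency.
    """
    if n_surrogates < 19:
        raise ValueError("need at least 19 surrogates for a 5% level test")
    if rng is None:
        rng = np.random.default_rng(seed)
    if window_s is None:
        window_s = 1.0 / lfp.center_frequency
    jitter = interval_jitter if jitter_kind == "interval" else group_preserved_jitter

    obs = decompose(
        build_coupling_matrix(
            spikes, lfp, mode=mode, min_spikes=min_spikes, edge_margin=edge_margin
        )
    ).gplv
    exceed = 0
    for _ in range(n_surrogates):
        surr = jitter(spikes, window_s, rng)
        g = decompose(
            build_coupling_matrix(
                surr, lfp, mode=mode, min_spikes=min_spikes, edge_margin=edge_margin
            )
        ).gplv
        if g >= obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_surrogates)
    return SignificanceReport(
        method=f"surrogate_{jitter_kind}",
        significant=p <= alpha_level,
        p_value=p,
        n_surrogates=n_surrogates,
        jitter_window_s=window_s,
        seed=seed,
        statistic=obs,
    )


def mp_threshold(n_c_eff: int, n_u: int) -> MPLaw:
    """MP law with the effective aspect ratio alpha_eff = n_c_eff / n_u."""
    if n_c_eff < 1 or n_u < 1:
        raise ValueError("dimensions must be >= 1")
    return MPLaw(alpha=n_c_eff / n_u)


def mp_density(x: np.ndarray, alpha: float) -> np.ndarray:
    """Marchenko-Pastur density on [a, b], zero outside."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    x = np.asarray(x, dtype=float)
    a = (1 - np.sqrt(alpha)) ** 2
    b = (1 + np.sqrt(alpha)) ** 2
    out = np.zeros_like(x)
    inside = (x > a) & (x < b) & (x > 0)
    xi = x[inside]
    out[inside] = np.sqrt((b - xi) * (xi - a)) / (2 * np.pi * alpha * xi)
    return out


def analytic_test(C: CouplingMatrix) -> SignificanceReport:
    """Random-matrix test of the gPLV against the MP upper edge.

    Requires ``mode='c'`` on whitened LFPs (the conditions under which the
    null coupling matrix is asymptotically iid standard complex Gaussian).
    The statistic for each squared singular value is ``d_k^2 / n_u``, compared
    with ``theta_DET = (1 + sqrt(alpha_eff))^2``; the number of components
    above threshold estimates the number of independently coupled
    populations.
    """
    if C.mode != "c" or not C.whitened:
        raise ValueError(
            "analytic test requires mode='c' on whitened LFPs; got "
            f"mode={C.mode!r}, whitened={C.whitened}"
        )
    result = decompose(C)
    n_u = C.n_units
    law = mp_threshold(C.n_channels, n_u)
    ell = result.spectrum**2 / n_u
    per_component = ell > law.threshold
    # count contiguously from the top: stop at the first non-significant value
    n_sig = 0
    for flag in per_component:
        if not flag:
            break
        n_sig += 1
    return SignificanceReport(
        method="analytic",
        significant=bool(per_component[0]),
        threshold=law.threshold,
        statistic=float(ell[0]),
        eigenvalues=ell,
        per_component=per_component,
        n_significant=n_sig,
    )


def count_significant(C: CouplingMatrix) -> int:
    """Number of singular values above the MP threshold (coupled populations)."""
    return int(analytic_test(C).n_significant)
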