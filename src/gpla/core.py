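"""Singular-value decomposition of the coupling matrix and phase conventions.

The generalized phase-locking value (gPLV) is the largest singular value of
the coupling matrix; the associated left/right singular vectors are the LFP
and spike vectors.  Because the SVD is only defined up to a common rotation
of both vectors in the complex plane, the convention adopted here sets the
phase of the mean of the LFP vector to zero; the residual mean phase of the
spike vector then measures the overall spike-LFP phase shift Phi_d.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .coupling import CouplingMatrix

__all__ = [
    "GPLAResult",
    "decompose",
    "apply_conventions",
    "normalize_gplv",
    "phase_modulus_regression",
    "fit_phase_distribution",
    "PhaseModulusFit",
    "VonMisesFit",
]


@dataclass
class GPLAResult:
    """Outcome of GPLA for one frequency band."""

    gplv: float
    lfp_vector: np.ndarray
    spike_vector: np.ndarray
    spectrum: np.ndarray
    mode: str
    whitened: bool
    band: tuple[float, float]
    unit_counts: np.ndarray | None = None
    phi_d: float | None = None
    rotated: bool = False
    rotation_skipped: bool = False
    unwhitened: bool = False
    rescaled: bool = False
    n_significant: int | None = None

    @property
    def complex_gplv(self) -> complex:
        """gPLV carrying the overall spike-LFP phase shift, gPLV * e^{-i Phi_d}."""
        if self.phi_d is None:
            raise ValueError("apply_conventions must run before complex_gplv")
        return self.gplv * np.exp(-1j * self.phi_d)

    @property
    def gplv_normalized(self) -> float:
        return normalize_gplv(self)


def decompose(C: CouplingMatrix) -> GPLAResult:
    """Full SVD of the coupling matrix; gPLV is the leading singular value."""
    if not np.all(np.isfinite(C.values)):
        raise ValueError(
            "coupling matrix has non-finite entries; exclude zero-spike units upstream"
        )
    U, d, Vh = np.linalg.svd(C.values, full_matrices=False)
    return GPLAResult(
        gplv=float(d[0]),
        lfp_vector=U[:, 0],
        spike_vector=Vh[0].conj(),
        spectrum=d,
        mode=C.mode,
        whitened=C.whitened,
        band=C.band,
        unit_counts=C.unit_counts.copy(),
    )


def apply_conventions(
    result: GPLAResult,
    unwhitening: np.ndarray | None = None,
    counts: np.ndarray | None = None,
) -> GPLAResult:
    """Rotate, optionally unwhiten and rescale the singular vectors.

    Both vectors are rotated by ``e^{-i phase(mean(lfp_vector))}`` so the mean
    LFP-vector phase is zero; ``phi_d`` records the resulting mean phase
    difference between LFP and spike vectors.  If ``unwhitening`` is given the
    LFP vector is mapped back to channel space; if ``counts`` is given the
    spike vector is divided entrywise by ``sqrt(counts)`` and renormalized,
    undoing the per-unit ``1/sqrt(N)`` weighting of the ``c`` statistic.
    """
    u = result.lfp_vector.copy()
    v = result.spike_vector.copy()

    mean_u = u.mean()
    skipped = False
    if np.abs(mean_u) < 1e-15 * max(1.0, np.abs(u).max()):
        # mean phase undefined; leave vectors unrotated but still record phi_d = NaN-free 0
        phi_lfp = 0.0
        skipped = True
    else:
        phi_lfp = float(np.angle(mean_u))
        u = u * np.exp(-1j * phi_lfp)
        v = v * np.exp(-1j * phi_lfp)

    mean_v = v.mean()
    phi_spike_rot = float(np.angle(mean_v)) if np.abs(mean_v) > 0 else 0.0
    # Phi_d = mean LFP phase - mean spike phase, computed on the rotated vectors
    # (where the mean LFP phase is zero by construction)
    phi_d = -phi_spike_rot

    if unwhitening is not None:
        if unwhitening.shape[1] != u.shape[0]:
            raise ValueError(
                f"unwhitening maps {unwhitening.shape[1]} components, "
                f"LFP vector has {u.shape[0]}"
            )
        u = unwhitening @ u
        unwhitened = True
    else:
        unwhitened = False

    if counts is not None:
        counts = np.asarray(counts, dtype=float)
        if counts.shape[0] != v.shape[0]:
            raise ValueError("counts length does not match spike vector")
        if np.any(counts <= 0):
            raise ValueError("counts must be positive")
        v = v / np.sqrt(counts)
        v = v / np.linalg.norm(v)
        rescaled = True
    else:
        rescaled = False

    return replace(
        result,
        lfp_vector=u,
        spike_vector=v,
        phi_d=phi_d,
        rotated=not skipped,
        rotation_skipped=skipped,
        unwhitened=unwhitened,
        rescaled=rescaled,
    )


def normalize_gplv(result: GPLAResult) -> float:
    """gPLV scaled to [0, 1] by its maximum sqrt(n_c * n_s); plv mode only.

    In ``c`` mode individual entries are unbounded so the bound does not hold.
    """
    if result.mode != "plv":
        raise ValueError("normalized gPLV is defined only for plv-mode matrices")
    n_c = result.lfp_vector.shape[0]
    n_s = result.spike_vector.shape[0]
    return float(result.gplv / np.sqrt(n_c * n_s))


@dataclass
class PhaseModulusFit:
    slope: float
    intercept: float
    p_value: float
    n: int
    degenerate: bool = False


def phase_modulus_regression(vector: np.ndarray) -> PhaseModulusFit:
    """OLS of coefficient phase on modulus with an F-test of zero slope.

    Phases are taken relative to their circular mean (mapped to (-pi, pi]) so
    the regression does not straddle a wrap-around point.  A spatially
    organized coupling (e.g. recurrent inhibition pulling phase back toward
    the input focus) shows up as a significant negative slope.
    """
    vector = np.asarray(vector)
    if vector.shape[0] < 3:
        raise ValueError("need at least 3 coefficients")
    moduli = np.abs(vector)
    if np.ptp(moduli) < 1e-12 * max(1.0, moduli.max()):
        return PhaseModulusFit(np.nan, np.nan, np.nan, vector.shape[0], degenerate=True)
    circ_mean = np.angle(vector.sum())
    phases = np.angle(vector * np.exp(-1j * circ_mean))
    res = stats.linregress(moduli, phases)
    # linregress's two-sided t-test on the slope is equivalent to the F-test
    # with (1, n-2) degrees of freedom
    return PhaseModulusFit(
        slope=float(res.slope),
        intercept=float(res.intercept + circ_mean),
        p_value=float(res.pvalue),
        n=vector.shape[0],
    )


@dataclass
class VonMisesFit:
    mu: float
    kappa: float
    n: int
    uniform_flag: bool = False


_KAPPA_CAP = 1e6


def fit_phase_distribution(phases: np.ndarray) -> VonMisesFit:
    """Maximum-likelihood von Mises fit to a sample of phases (radians)."""
    phases = np.asarray(phases, dtype=float)
    if phases.shape[0] < 2:
        raise ValueError("need at least 2 phases")
    z = np.exp(1j * phases).mean()
    r = np.abs(z)
    mu = float(np.angle(z))
    if r < 1e-9:
        return VonMisesFit(mu=mu, kappa=0.0, n=phases.shape[0], uniform_flag=True)
    if r > 1 - 1e-12:
        return VonMisesFit(mu=mu, kappa=_KAPPA_CAP, n=phases.shape[0])
    kappa, loc, _ = stats.vonmises.fit(phases, fscale=1)
    kappa = float(min(kappa, _KAPPA_CAP))
    return VonMisesFit(mu=float(loc), kappa=kappa, n=phases.shape[0])
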