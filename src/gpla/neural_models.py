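"""Linearized two-population neural mass and neural field models.

These models provide the biophysical reading of GPLA outputs.  A pair of
excitatory (E) and inhibitory (I) rate populations with first-order membrane
dynamics interact through synaptic strengths ``nu[P<-Q]``; each connection may
carry an alpha-synapse kernel and/or a pure delay.  Linearizing the sigmoidal
rate functions at the input-free equilibrium yields transfer functions from
the exogenous input to the population rates and to a chosen LFP proxy (which
synaptic current dominates the electrode signal), from which phase-lag curves
across frequency follow in closed form.

The spatial extension adds exponentially decaying horizontal E-E connectivity
with scale ``r0``; its linear response to a localized input is a spatial
convolution with the complex kernel ``k(x) = exp(-|x| a(f))`` whose imaginary
part sets the sign of the phase gradient across the array (outward
propagation when ``Im[a] > 0``, inward when recurrent inhibition dominates
and ``Im[a] < 0``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .coupling import SpikeTrainSet
from .preprocess import RawLFP

__all__ = [
    "MassParams",
    "FieldParams",
    "TransferModel",
    "mass2d",
    "mass_alpha",
    "field_preset",
    "FIELD_PRESETS",
    "mass_transfer",
    "mass_phase_curves",
    "field_kernel_coeff",
    "spatial_kernel",
    "simulate_field_2d",
    "model_rank1_prediction",
]

_CONNS = ("ee", "ei", "ie", "ii")  # "ei" = E <- I etc.


@dataclass
class MassParams:
    """Two-population mass model; ``nu_ei`` is the strength of the I -> E synapse."""

    tau_e: float = 0.02
    tau_i: float = 0.02
    nu_ee: float = 0.0
    nu_ei: float = 1.0
    nu_ie: float = 1.0
    nu_ii: float = 0.0
    chi_e: float = 1.0
    chi_i: float = 1.0
    # per-connection alpha-synapse time constants (s); None = instantaneous
    tau_s: dict[str, float] = field(default_factory=dict)
    # per-connection pure delays (s)
    delay: dict[str, float] = field(default_factory=dict)
    lfp_proxy: str = "exogenous"  # EPSP | IPSP | exogenous
    ffi_gain: float = 0.0  # feedforward-inhibition share of the exogenous drive


def mass2d(ffi_gain: float = 0.0, lfp_proxy: str = "exogenous") -> MassParams:
    """Membrane dynamics only (PING-capable, no synaptic kinetics)."""
    return MassParams(ffi_gain=ffi_gain, lfp_proxy=lfp_proxy)


def mass_alpha(lfp_proxy: str = "IPSP") -> MassParams:
    """Adds delayed alpha-synapse I-I coupling, the ING ingredient."""
    return MassParams(
        nu_ii=3.0,
        tau_s={"ii": 0.006},
        delay={"ii": 0.003},
        lfp_proxy=lfp_proxy,
    )


def _kernel(p: MassParams, conn: str, omega: np.ndarray) -> np.ndarray:
    h = np.ones_like(omega, dtype=complex)
    ts = p.tau_s.get(conn)
    if ts is not None:
        h = h / (1 + 1j * omega * ts) ** 2
    d = p.delay.get(conn)
    if d is not None:
        h = h * np.exp(-1j * omega * d)
    return h


@dataclass
class TransferModel:
    """Frequency response of the linearized model (optionally over space)."""

    freqs: np.ndarray
    H_lambda_e: np.ndarray
    H_lambda_i: np.ndarray
    H_lfp: np.ndarray
    psi_e: np.ndarray | None = None
    psi_i: np.ndarray | None = None
    psi_l: np.ndarray | None = None


def mass_transfer(params: MassParams, freqs: np.ndarray) -> TransferModel:
    """Closed-form response of the linearized mass model to its exogenous drive.

    Solves the 2x2 frequency-domain system for the rate responses
    ``lambda_E, lambda_I`` per unit exogenous input and forms the LFP proxy.
    Raises if the chosen parameters put the resonance at or past instability
    (vanishing determinant near the real frequency axis).
    """
    freqs = np.asarray(freqs, dtype=float)
    omega = 2 * np.pi * freqs
    p = params
    g_ee = p.nu_ee * _kernel(p, "ee", omega)
    g_ei = p.nu_ei * _kernel(p, "ei", omega)
    g_ie = p.nu_ie * _kernel(p, "ie", omega)
    g_ii = p.nu_ii * _kernel(p, "ii", omega)

    # rows scaled so unknowns are the rates:  A @ [lam_e, lam_i] = [eta_e, eta_i]
    a11 = (1 + 1j * omega * p.tau_e) / p.chi_e - g_ee
    a12 = g_ei
    a21 = -g_ie
    a22 = (1 + 1j * omega * p.tau_i) / p.chi_i + g_ii
    det = a11 * a22 - a12 * a21
    scale = np.abs(a11 * a22) + np.abs(a12 * a21) + 1e-30
    if np.min(np.abs(det) / scale) < 1e-6:
        raise ValueError(
            "linearization unstable: transfer-function determinant vanishes "
            "within the requested frequency range"
        )
    eta_e = np.ones_like(det)
    eta_i = np.full_like(det, p.ffi_gain)
    lam_e = (a22 * eta_e - a12 * eta_i) / det
    lam_i = (a11 * eta_i - a21 * eta_e) / det

    if p.lfp_proxy == "EPSP":
        lfp = g_ee * lam_e + eta_e
    elif p.lfp_proxy == "IPSP":
        lfp = -g_ei * lam_i
    elif p.lfp_proxy == "exogenous":
        lfp = eta_e
    else:
        raise ValueError(f"unknown lfp_proxy {p.lfp_proxy!r}")
    return TransferModel(freqs=freqs, H_lambda_e=lam_e, H_lambda_i=lam_i, H_lfp=lfp)


def mass_phase_curves(params: MassParams, freqs: np.ndarray) -> dict[str, np.ndarray]:
    """Phase of E and I rates relative to the LFP proxy, and their difference.

    Phases are unwrapped along the frequency grid; at ``f -> 0`` all gains are
    real so phases start at 0 or pi.
    """
    tm = mass_transfer(params, freqs)
    phi_e = np.unwrap(np.angle(tm.H_lambda_e / tm.H_lfp))
    phi_i = np.unwrap(np.angle(tm.H_lambda_i / tm.H_lfp))
    if np.abs(tm.H_lambda_i).max() == 0:
        phi_ei = np.zeros_like(phi_e)  # I population silent: difference undefined
    else:
        phi_ei = np.unwrap(np.angle(tm.H_lambda_e / tm.H_lambda_i))
    return {"phi_e": phi_e, "phi_i": phi_i, "phi_ei": phi_ei, "freqs": tm.freqs}


# ---------------------------------------------------------------------------
# spatial (neural field) model
# ---------------------------------------------------------------------------


@dataclass
class FieldParams:
    """Two-population neural field on a square electrode grid.

    Synaptic strengths are the sigmoid-independent constants; the effective
    (linearized) strengths are these times the sigmoid slopes at the
    equilibrium.  Lengths are in micrometres.
    """

    tau_e: float = 0.02
    tau_i: float = 0.02
    nu_ee: float = 0.2
    nu_ei: float = 1.0  # I -> E
    nu_ie: float = 0.2  # E -> I
    nu_ii: float = 0.0
    chi_e: float = 1.0
    chi_i: float = 1.0
    v_th_e: float = 0.0
    v_th_i: float = 0.0
    q_e: float = 20.0
    q_i: float = 20.0
    r0: float = 440.0
    dx: float = 800.0
    extent: float = 12000.0
    input_sigma: float = 1400.0
    # inhibitory synaptic kinetics: alpha-kernel time constant and conduction
    # delay on the I -> E connection (GABA_A-like); the lag they add to the
    # feedback loop is what lets strong recurrent inhibition pull the phase
    # of the response back toward the input focus
    tau_s_inh: float = 0.015
    delay_inh: float = 0.008
    lfp_proxy: str = "EPSP"
    name: str = ""

    @property
    def n_side(self) -> int:
        return int(round(self.extent / self.dx)) + 1


# Excitability / threshold combinations spanning weak to strong recurrent
# inhibition; all other parameters shared.
FIELD_PRESETS = {
    "weak": dict(chi_i=0.1, v_th_i=0.0),
    "lower_med": dict(chi_i=0.33, v_th_i=1.0),
    "upper_med": dict(chi_i=1.0, v_th_i=5.0),
    "strong": dict(chi_i=3.33, v_th_i=5.0),
}


def field_preset(name: str) -> FieldParams:
    if name not in FIELD_PRESETS:
        raise ValueError(f"preset must be one of {sorted(FIELD_PRESETS)}")
    return FieldParams(name=name, **FIELD_PRESETS[name])


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _rate(v: np.ndarray, chi: float, v_th: float, q: float) -> np.ndarray:
    return q * _sigmoid(4 * chi * (v - v_th) / q)


def _rate_gain(v: float, chi: float, v_th: float, q: float) -> float:
    s = _sigmoid(4 * chi * (v - v_th) / q)
    return 4 * chi * s * (1 - s)


def field_equilibrium(p: FieldParams) -> dict[str, float]:
    """Input-free fixed point and the linearized gains there.

    The spatially uniform equilibrium solves ``V_E = nu_ee lam_E - nu_ei
    lam_I`` and ``V_I = nu_ie lam_E - nu_ii lam_I`` (the normalized horizontal
    kernel sums to one, so uniform states see its full weight).
    """
    v_e, v_i = 0.0, 0.0
    for _ in range(2000):
        lam_e = _rate(v_e, p.chi_e, p.v_th_e, p.q_e)
        lam_i = _rate(v_i, p.chi_i, p.v_th_i, p.q_i)
        v_e_new = p.nu_ee * lam_e - p.nu_ei * lam_i
        v_i_new = p.nu_ie * lam_e - p.nu_ii * lam_i
        # damped iteration for robustness
        v_e += 0.2 * (v_e_new - v_e)
        v_i += 0.2 * (v_i_new - v_i)
    g_e = _rate_gain(v_e, p.chi_e, p.v_th_e, p.q_e)
    g_i = _rate_gain(v_i, p.chi_i, p.v_th_i, p.q_i)
    return {
        "v_e": v_e,
        "v_i": v_i,
        "lam_e": _rate(v_e, p.chi_e, p.v_th_e, p.q_e),
        "lam_i": _rate(v_i, p.chi_i, p.v_th_i, p.q_i),
        "g_e": g_e,
        "g_i": g_i,
    }


def effective_couplings(p: FieldParams) -> dict[str, float]:
    """Linearized synaptic strengths nu * gain at the input-free equilibrium."""
    eq = field_equilibrium(p)
    return {
        "ee": p.nu_ee * eq["g_e"],
        "ei_loop": p.nu_ei * p.nu_ie * eq["g_e"] * eq["g_i"],
        "g_e": eq["g_e"],
        "g_i": eq["g_i"],
    }


def kernel_coeff_from_couplings(
    loop: float, ee: float, tau: float, r0: float, f: float | np.ndarray
) -> np.ndarray:
    """Low-frequency spatial decay coefficient from effective couplings.

    ``a^2 = (1/r0^2) [1 + loop - ee - i 2 pi tau f (2 loop - ee)]`` where
    ``loop = nu_EI nu_IE`` and ``ee = nu_EE`` are the gain-scaled couplings;
    the principal square root with ``Re[a] > 0`` gives a kernel decaying with
    distance.
    """
    re0 = 1 + loop - ee
    if re0 <= 0:
        raise ValueError(
            f"field linearization unstable: 1 + nu_EI*nu_IE - nu_EE = {re0:.3f} <= 0"
        )
    f = np.asarray(f, dtype=float)
    a2 = (re0 - 1j * 2 * np.pi * tau * f * (2 * loop - ee)) / r0**2
    a = np.sqrt(a2 + 0j)
    a = np.where(a.real < 0, -a, a)
    return a if a.ndim else a[()]


def field_kernel_coeff(p: FieldParams, f: float | np.ndarray) -> np.ndarray:
    """Complex spatial decay coefficient a(f) of the horizontal response kernel.

    Evaluates :func:`kernel_coeff_from_couplings` at the input-free
    equilibrium's linearized couplings; the sign of ``Im[a]`` separates
    outward propagation (weak inhibition) from waves converging back onto the
    input focus (strong inhibition).
    """
    eff = effective_couplings(p)
    return kernel_coeff_from_couplings(eff["ei_loop"], eff["ee"], p.tau_e, p.r0, f)


def spatial_kernel(a: complex, x_grid: np.ndarray) -> np.ndarray:
    """k(x) = exp(-|x| a): decay with distance plus a phase gradient of
    sign ``-sign(Im[a])``."""
    return np.exp(-np.abs(np.asarray(x_grid, dtype=float)) * a)


def _grid_coords(p: FieldParams) -> np.ndarray:
    n = p.n_side
    axis = (np.arange(n) - (n - 1) / 2) * p.dx
    xx, yy = np.meshgrid(axis, axis, indexing="ij")
    return np.stack([xx.ravel(), yy.ravel()], axis=1)


def _horizontal_kernel(p: FieldParams) -> np.ndarray:
    coords = _grid_coords(p)
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    K = np.exp(-d / p.r0)
    return K / K.sum(axis=1, keepdims=True)


def input_profile(p: FieldParams) -> np.ndarray:
    """Isotropic Gaussian input amplitude n(x) centred on the array."""
    coords = _grid_coords(p)
    r2 = (coords**2).sum(axis=1)
    return np.exp(-r2 / (2 * p.input_sigma**2))


def simulate_field_2d(
    p: FieldParams,
    duration: float,
    rng: np.random.Generator,
    *,
    dt: float = 1e-3,
    input_mean: float = 0.0,
    input_std: float = 60.0,
    input_lowpass_hz: float | None = 30.0,
    fs_out: float = 250.0,
    warmup: float = 0.5,
) -> tuple[RawLFP, SpikeTrainSet, dict]:
    """Integrate the field equations and emit LFP proxies plus Poisson spikes.

    The exogenous drive is spatially the Gaussian ``n(x)`` and temporally a
    synchronous broadband Gaussian noise (std ``input_std``), so any phase
    gradient in the response is produced by the circuit, not the input.  One
    excitatory unit per grid node fires as an inhomogeneous Poisson process
    with rate ``lambda_E(x, t)``; the LFP proxy is the horizontal-EE EPSP sum
    (default) or the IPSP.
    """
    if dt > p.tau_e / 20 or dt > p.tau_i / 20:
        raise ValueError(f"dt={dt} too coarse: need dt <= tau/20")
    decim = int(round(1 / (dt * fs_out)))
    if decim < 1 or abs(1 / (dt * decim) - fs_out) > 1e-9:
        raise ValueError("fs_out must divide 1/dt")
    K = _horizontal_kernel(p)
    n_x = input_profile(p)
    eq = field_equilibrium(p)
    n_nodes = K.shape[0]

    n_steps = int(round((duration + warmup) * dt**-1))
    n_warm = int(round(warmup / dt))
    v_e = np.full(n_nodes, eq["v_e"])
    v_i = np.full(n_nodes, eq["v_i"])
    eps = rng.normal(0, 1.0, n_steps)
    if input_lowpass_hz is not None:
        # band-limit the drive so its power lies in the analysis range
        sos = signal.butter(2, input_lowpass_hz, btype="low", fs=1 / dt, output="sos")
        eps = signal.sosfilt(sos, eps)
        eps /= eps.std()
    # excitatory drive: positive mean plus band-limited fluctuations,
    # rectified at zero
    eps = np.clip(input_mean + input_std * eps, 0, None)

    keep = n_steps - n_warm
    lam_e_out = np.empty((n_nodes, keep))
    lfp_out = np.empty((n_nodes, keep))
    # alpha-kernel I -> E synapse (two first-order stages) fed with a delay
    lam_i_eq = eq["lam_i"]
    syn_u = np.full(n_nodes, lam_i_eq)
    syn_s = np.full(n_nodes, lam_i_eq)
    n_delay = max(1, int(round(p.delay_inh / dt)))
    buf = np.full((n_delay, n_nodes), lam_i_eq)
    for s in range(n_steps):
        lam_e = _rate(v_e, p.chi_e, p.v_th_e, p.q_e)
        lam_i = _rate(v_i, p.chi_i, p.v_th_i, p.q_i)
        lam_i_del = buf[s % n_delay].copy()
        buf[s % n_delay] = lam_i
        syn_u += dt / p.tau_s_inh * (lam_i_del - syn_u)
        syn_s += dt / p.tau_s_inh * (syn_u - syn_s)
        epsp = p.nu_ee * (K @ lam_e)
        s_e = epsp - p.nu_ei * syn_s + n_x * eps[s]
        s_i = p.nu_ie * lam_e - p.nu_ii * lam_i
        v_e += dt / p.tau_e * (-v_e + s_e)
        v_i += dt / p.tau_i * (-v_i + s_i)
        if s >= n_warm:
            j = s - n_warm
            lam_e_out[:, j] = lam_e
            lfp_out[:, j] = epsp if p.lfp_proxy == "EPSP" else -p.nu_ei * syn_s

    # average consecutive blocks down to fs_out (box filter removes most
    # energy above the output Nyquist; membrane dynamics remove the rest)
    T_out = keep // decim
    lam_ds = lam_e_out[:, : T_out * decim].reshape(n_nodes, T_out, decim).mean(axis=2)
    lfp_ds = lfp_out[:, : T_out * decim].reshape(n_nodes, T_out, decim).mean(axis=2)

    counts = rng.poisson(np.clip(lam_ds, 0, None) / fs_out)
    trains = []
    for m in range(n_nodes):
        idx = np.repeat(np.nonzero(counts[m])[0], counts[m][counts[m] > 0])
        trains.append([idx.astype(np.int64)])
    spikes = SpikeTrainSet(trains=trains, trial_length=T_out, fs=fs_out)
    lfp = RawLFP(trials=[lfp_ds], fs=fs_out)
    truth = {
        "equilibrium": eq,
        "n_x": n_x,
        "coords": _grid_coords(p),
        "preset": p.name,
        "rates": lam_ds,
    }
    return lfp, spikes, truth


def model_rank1_prediction(p: FieldParams, f: float) -> dict[str, np.ndarray]:
    """Separable linear-response prediction of the spike/LFP vectors at ``f``.

    Solves the linearized field equations on the grid for a unit-amplitude
    oscillatory input with spatial profile ``n(x)``; the predicted coupling
    matrix ``psi_L psi_E^H`` has exact rank one.
    """
    eq = field_equilibrium(p)
    g_e, g_i = eq["g_e"], eq["g_i"]
    omega = 2 * np.pi * f
    K = _horizontal_kernel(p)
    n_x = input_profile(p)
    n_nodes = K.shape[0]
    h_inh = np.exp(-1j * omega * p.delay_inh) / (1 + 1j * omega * p.tau_s_inh) ** 2
    beta = (p.nu_ei * g_i * p.nu_ie * g_e * h_inh) / (
        1 + 1j * omega * p.tau_i + p.nu_ii * g_i
    )
    A = (1 + 1j * omega * p.tau_e + beta) * np.eye(n_nodes) - p.nu_ee * g_e * K
    v_e = np.linalg.solve(A, n_x.astype(complex))
    psi_e = g_e * v_e
    lam_i = (g_i * p.nu_ie * psi_e) / (1 + 1j * omega * p.tau_i + p.nu_ii * g_i)
    psi_l = (
        p.nu_ee * (K @ psi_e) if p.lfp_proxy == "EPSP" else -p.nu_ei * h_inh * lam_i
    )
    return {
        "psi_e": psi_e,
        "psi_i": lam_i,
        "psi_l": psi_l,
        "coupling": np.outer(psi_l, psi_e.conj()),
    }
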