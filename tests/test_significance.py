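"""Jitter surrogates and the Marchenko-Pastur analytic test."""

import numpy as np
import pytest

from gpla.coupling import CouplingMatrix, SpikeTrainSet, build_coupling_matrix
from gpla.significance import (
    analytic_test,
    group_preserved_jitter,
    interval_jitter,
    mp_density,
    mp_threshold,
    surrogate_test,
)

from conftest import make_analytic_tone, spikes_at

FS = 400.0
FREQ = 20.0


def locked_spikes(n_spikes=300, cycle=20, T=8000):
    """Spikes perfectly locked to the tone (every cycle, same phase)."""
    idx = np.arange(n_spikes) * cycle + 5
    return spikes_at(idx[idx < T], T, FS)


class TestJitter:
    def test_interval_jitter_preserves_window_counts(self, rng):
        spikes = locked_spikes()
        window_s = 0.1  # 40 samples
        surr = interval_jitter(spikes, window_s, rng)
        w = int(round(window_s * FS))
        before = np.bincount(spikes.trains[0][0] // w, minlength=200)
        after = np.bincount(surr.trains[0][0] // w, minlength=200)
        assert np.array_equal(before, after)
        assert surr.counts()[0] == spikes.counts()[0]

    def test_one_sample_window_is_identity(self, rng):
        spikes = locked_spikes()
        surr = interval_jitter(spikes, 1 / FS, rng)
        assert np.array_equal(surr.trains[0][0], spikes.trains[0][0])

    def test_group_jitter_preserves_relative_timing(self, rng):
        T = 4000
        a = np.sort(rng.integers(0, T, 150))
        b = np.sort(rng.integers(0, T, 120))
        spikes = SpikeTrainSet(trains=[[a], [b]], trial_length=T, fs=FS)
        window_s = 0.2
        w = int(round(window_s * FS))
        surr = group_preserved_jitter(spikes, window_s, rng)
        # within each full window, the pairwise spike-time differences between
        # units are unchanged modulo the window length
        for start in range(0, T - w, w):
            sel_a = a[(a >= start) & (a < start + w)]
            sel_b = b[(b >= start) & (b < start + w)]
            sa = surr.trains[0][0]
            sb = surr.trains[1][0]
            new_a = sa[(sa >= start) & (sa < start + w)]
            new_b = sb[(sb >= start) & (sb < start + w)]
            if sel_a.size == 0 or sel_b.size == 0:
                continue
            old_diffs = np.sort((sel_a[:, None] - sel_b[None, :]).ravel() % w)
            new_diffs = np.sort((new_a[:, None] - new_b[None, :]).ravel() % w)
            assert np.array_equal(old_diffs, new_diffs)

    @pytest.mark.parametrize("jitter", [interval_jitter, group_preserved_jitter])
    def test_jitter_preserves_total_counts(self, rng, jitter):
        T = 4000
        trains = [[np.sort(rng.integers(0, T, n))] for n in (40, 90, 3)]
        spikes = SpikeTrainSet(trains=trains, trial_length=T, fs=FS)
        surr = jitter(spikes, 0.13, rng)
        assert np.array_equal(surr.counts(), spikes.counts())
        for per_trial in surr.trains:
            t = per_trial[0]
            assert t.min() >= 0 and t.max() < T

    @pytest.mark.parametrize("jitter", [interval_jitter, group_preserved_jitter])
    def test_jitter_collapses_locking(self, rng, jitter):
        """A perfectly locked train jittered at one oscillation period loses
        its phase locking down to the sampling-noise floor."""
        lfp = make_analytic_tone(freq=FREQ, fs=FS, duration=20.0)
        spikes = locked_spikes()
        n = spikes.counts()[0]
        C_obs = build_coupling_matrix(spikes, lfp, mode="plv")
        assert abs(C_obs.values[0, 0]) > 0.99
        mods = []
        for _ in range(200):
            surr = jitter(spikes, 1 / FREQ, rng)
            mods.append(abs(build_coupling_matrix(surr, lfp, mode="plv").values[0, 0]))
        assert np.median(mods) < 2 / np.sqrt(n)


class TestSurrogateTest:
    def test_p_value_formula_when_observed_tops_all(self, rng):
        lfp = make_analytic_tone(freq=FREQ, fs=FS, duration=20.0)
        spikes = locked_spikes()
        rep = surrogate_test(spikes, lfp, n_surrogates=99, seed=3)
        assert rep.p_value == pytest.approx(0.01)
        assert rep.significant

    def test_deterministic_under_seed(self, rng):
        lfp = make_analytic_tone(freq=FREQ, fs=FS, duration=10.0)
        T = lfp.trials[0].shape[1]
        spikes = spikes_at(np.sort(rng.integers(0, T, 200)), T, FS)
        r1 = surrogate_test(spikes, lfp, n_surrogates=29, seed=7)
        r2 = surrogate_test(spikes, lfp, n_surrogates=29, seed=7)
        assert r1.p_value == r2.p_value

    def test_requires_enough_surrogates(self, rng):
        lfp = make_analytic_tone(freq=FREQ, fs=FS)
        spikes = locked_spikes(T=lfp.trials[0].shape[1])
        with pytest.raises(ValueError):
            surrogate_test(spikes, lfp, n_surrogates=10)

    def test_false_positive_rate_calibrated(self, rng):
        """Homogeneous Poisson spikes vs an oscillation: ~5% rejections."""
        lfp = make_analytic_tone(freq=FREQ, fs=FS, duration=10.0)
        T = lfp.trials[0].shape[1]
        hits = 0
        runs = 100
        for _ in range(runs):
            spikes = spikes_at(np.sort(rng.integers(0, T, 150)), T, FS)
            rep = surrogate_test(
                spikes, lfp, n_surrogates=19,
                rng=np.random.default_rng(rng.integers(2**31)),
            )
            hits += rep.significant
        assert hits / runs <= 0.12


class TestMPLaw:
    def test_threshold_values(self):
        assert mp_threshold(100, 100).threshold == pytest.approx(4.0)
        assert mp_threshold(25, 100).threshold == pytest.approx(2.25)
        assert mp_threshold(25, 100).alpha == pytest.approx(0.25)

    def test_density_is_normalized(self):
        from scipy import integrate

        for alpha in (0.25, 0.5, 1.0):
            a = (1 - np.sqrt(alpha)) ** 2
            b = (1 + np.sqrt(alpha)) ** 2
            total, _ = integrate.quad(
                lambda x: float(mp_density(np.array([x]), alpha)[0]), a, b, limit=200
            )
            assert total == pytest.approx(1.0, abs=1e-6)

    def test_density_vanishes_at_edges_and_outside(self):
        alpha = 0.5
        a = (1 - np.sqrt(alpha)) ** 2
        b = (1 + np.sqrt(alpha)) ** 2
        assert mp_density(np.array([a, b]), alpha).max() == 0.0
        assert mp_density(np.array([a - 0.01, b + 0.01]), alpha).max() == 0.0

    def test_support_brackets_iid_matrix_spectrum(self, rng):
        n_c, n_u = 120, 300
        X = (rng.normal(size=(n_c, n_u)) + 1j * rng.normal(size=(n_c, n_u))) / np.sqrt(2)
        ell = np.linalg.svd(X, compute_uv=False) ** 2 / n_u
        a, b = mp_threshold(n_c, n_u).support
        outside = np.mean((ell < a - 0.05) | (ell > b + 0.05))
        assert outside < 0.01


def iid_coupling(rng, n_c, n_u):
    X = (rng.normal(size=(n_c, n_u)) + 1j * rng.normal(size=(n_c, n_u))) / np.sqrt(2)
    return CouplingMatrix(
        values=X, mode="c", whitened=True, band=(10.0, 20.0),
        unit_counts=np.full(n_u, 500),
    )


class TestAnalyticTest:
    def test_refuses_wrong_normalization(self, rng):
        C = iid_coupling(rng, 10, 10)
        C.mode = "plv"
        with pytest.raises(ValueError, match="mode='c'"):
            analytic_test(C)
        C.mode, C.whitened = "c", False
        with pytest.raises(ValueError, match="whitened"):
            analytic_test(C)

    def test_null_matrices_rarely_exceed_edge(self, rng):
        hits = sum(
            analytic_test(iid_coupling(rng, 100, 100)).significant for _ in range(40)
        )
        assert hits / 40 <= 0.05 + 0.05  # >= 95% of draws below threshold

    def test_planted_signal_always_detected(self, rng):
        n_c = n_u = 80
        for _ in range(10):
            C = iid_coupling(rng, n_c, n_u)
            u = rng.normal(size=n_c) + 1j * rng.normal(size=n_c)
            v = rng.normal(size=n_u) + 1j * rng.normal(size=n_u)
            u /= np.linalg.norm(u)
            v /= np.linalg.norm(v)
            # planted strength well above sqrt(n_u * theta_DET)
            C.values = C.values + 3 * np.sqrt(n_u * 4.0) * np.outer(u, v.conj())
            rep = analytic_test(C)
            assert rep.significant
            assert rep.n_significant == 1

    def test_single_unit_reduces_to_univariate_threshold(self, rng):
        C = iid_coupling(rng, 4, 1)
        rep = analytic_test(C)
        stat = np.linalg.norm(C.values[:, 0]) ** 2 / 1
        assert rep.statistic == pytest.approx(stat)
        assert rep.threshold == pytest.approx((1 + np.sqrt(4 / 1)) ** 2)

    def test_counts_contiguously_from_top(self, rng):
        C = iid_coupling(rng, 60, 60)
        u = np.eye(60)[:, :3]
        # plant components 1 and 2 strongly, leave the rest null
        C.values = C.values + 80 * u[:, :1] @ u[:, :1].T + 60 * u[:, 1:2] @ u[:, 1:2].T
        rep = analytic_test(C)
        assert rep.n_significant == 2
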