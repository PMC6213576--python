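"""Ikeda-Carpenter emission model, broadening convolution, Pade tables."""

import numpy as np
import pytest
from scipy.integrate import quad

from tofprofile.moderator import (
    BroadeningParams,
    EnergyRangeError,
    ICParams,
    ModeratorTable,
    PadeSeries,
    default_table,
    fit_pade,
    ic_convolved,
    ic_profile,
    initial_guess,
)


def random_ic_params(rng):
    alpha = rng.uniform(0.1, 3.0)
    beta = alpha * rng.uniform(0.01, 0.5)
    return ICParams(alpha=alpha, beta=beta, R=rng.uniform(0.0, 1.0),
                    t0=rng.uniform(0.0, 5.0))


class TestICProfile:
    def test_zero_before_onset(self):
        p = ICParams(alpha=1.0, beta=0.05, R=0.3, t0=2.0)
        t = np.array([-5.0, 0.0, 1.0, 2.0])
        assert np.all(ic_profile(t, p) == 0.0)

    def test_r_zero_mode_at_two_over_alpha(self):
        p = ICParams(alpha=1.3, beta=0.05, R=0.0, t0=0.0)
        t = np.linspace(0, 20, 200001)
        assert abs(t[np.argmax(ic_profile(t, p))] - 2.0 / 1.3) < 1e-3

    def test_normalization_quadrature(self):
        p = ICParams(alpha=1.0, beta=0.05, R=0.3, t0=0.0)
        val, err = quad(lambda t: ic_profile(t, p), 0.0, 50.0 / 0.05, limit=300)
        assert abs(val - 1.0) < 1e-6

    def test_normalization_random_params(self, rng):
        for _ in range(20):
            p = random_ic_params(rng)
            hi = p.t0 + 10.0 / p.alpha + 40.0 / p.beta
            val, _ = quad(lambda t: ic_profile(t, p), p.t0, hi, limit=500)
            assert abs(val - 1.0) < 1e-5

    def test_positive_skew(self, rng):
        # emission always has a long high-TOF tail
        for _ in range(20):
            p = random_ic_params(rng)
            t = np.linspace(p.t0, p.t0 + 10 / p.alpha + 60 / p.beta, 40001)
            y = ic_profile(t, p)
            w = y / y.sum()
            mu = (w * t).sum()
            m2 = (w * (t - mu) ** 2).sum()
            m3 = (w * (t - mu) ** 3).sum()
            assert m3 / m2**1.5 > 0.0

    def test_alpha_beta_order_enforced(self):
        with pytest.raises(ValueError):
            ICParams(alpha=0.05, beta=1.0, R=0.3)
        with pytest.raises(ValueError):
            ICParams(alpha=1.0, beta=1.0, R=0.3)


class TestConvolution:
    def test_delta_kernels_are_identity(self):
        p = ICParams(alpha=1.0, beta=0.05, R=0.3, t0=0.0)
        t = np.arange(0.25, 400, 0.5)
        b = BroadeningParams(scale=7.0, background=0.5)
        assert np.array_equal(ic_convolved(t, p, b),
                              7.0 * ic_profile(t, p) * 0.5 + 0.5)

    def test_mean_preserved_by_symmetric_broadening(self):
        # profile well away from t=0 so no mass is pushed off the grid
        p = ICParams(alpha=1.0, beta=0.05, R=0.3, t0=200.0)
        t = np.arange(0.25, 1500, 0.5)
        plain = ic_convolved(t, p, BroadeningParams(scale=1e4))
        broad = ic_convolved(t, p, BroadeningParams(sigma_g=4.0, pulse_width=6.0, scale=1e4))
        mu0 = (plain * t).sum() / plain.sum()
        mu1 = (broad * t).sum() / broad.sum()
        assert abs(mu1 - mu0) < 0.15  # within discretization

    def test_counts_conserved_when_resolved(self):
        p = ICParams(alpha=1.0, beta=0.05, R=0.3, t0=200.0)
        t = np.arange(0.25, 2500, 0.5)
        y = ic_convolved(t, p, BroadeningParams(sigma_g=5.0, pulse_width=8.0, scale=1000.0))
        assert abs(y.sum() - 1000.0) < 1.0  # +-0.1%

    def test_matches_direct_dense_convolution(self):
        # independent O(N^2) discrete convolution on the same fine grid
        p = ICParams(alpha=1.0, beta=0.05, R=0.3, t0=30.0)
        t = np.arange(0.5, 600, 1.0)
        b = BroadeningParams(sigma_g=2.0, scale=1.0)
        mine = ic_convolved(t, p, b)

        from tofprofile.moderator import _convolved_fine, _fine_grid

        tf, width = _fine_grid(t, p, b)
        step = tf[1] - tf[0]
        y = ic_profile(tf, p)
        half = int(np.ceil(6.0 * b.sigma_g / step))
        lags = np.arange(-half, half + 1) * step
        kern = np.exp(-0.5 * (lags / b.sigma_g) ** 2)
        kern /= kern.sum()
        direct = np.zeros_like(y)
        for w_k, lag in zip(kern, range(-half, half + 1)):
            shifted = np.roll(y, lag)
            if lag > 0:
                shifted[:lag] = 0.0
            elif lag < 0:
                shifted[lag:] = 0.0
            direct += w_k * shifted
        edges = np.concatenate([t - width / 2, [t[-1] + width / 2]])
        idx = np.digitize(tf, edges) - 1
        ok = (idx >= 0) & (idx < t.size)
        sums = np.bincount(idx[ok], weights=direct[ok], minlength=t.size)
        cnt = np.bincount(idx[ok], minlength=t.size)
        oracle = np.where(cnt > 0, sums / np.maximum(cnt, 1), 0.0) * width
        assert np.abs(mine - oracle).max() < 1e-8

    def test_nonuniform_grid_rejected(self):
        p = ICParams(alpha=1.0, beta=0.05, R=0.3)
        t = np.array([0.0, 1.0, 3.0, 6.0])
        with pytest.raises(ValueError):
            ic_convolved(t, p, BroadeningParams(sigma_g=1.0))


class TestPade:
    def test_constant_series(self):
        s = PadeSeries(a=(2.5, 0, 0, 0, 0), b=(0, 0, 0, 0))
        assert np.allclose(s(np.linspace(-5, 2, 17)), 2.5)

    def test_fit_then_evaluate_round_trip(self):
        # a smooth synthetic parameter curve sampled at 141 log-spaced energies
        energies = np.logspace(-5, 2, 141)
        x = np.log10(energies)
        y = 0.4 + 0.1 * np.tanh(x + 1.5) + 0.01 * x
        series = fit_pade(x, y)
        assert np.abs(series(x) / y - 1.0).max() < 0.01

    def test_out_of_range_error_names_range(self, table):
        with pytest.raises(EnergyRangeError, match="1e-05"):
            table.evaluate(200.0)

    def test_corrupt_table_rejected(self):
        bad = ModeratorTable(
            alpha=PadeSeries(a=(0.01, 0, 0, 0, 0), b=(0, 0, 0, 0)),  # alpha < beta
            beta=PadeSeries(a=(0.5, 0, 0, 0, 0), b=(0, 0, 0, 0)),
            R=PadeSeries(a=(0.3, 0, 0, 0, 0), b=(0, 0, 0, 0)),
            t0=PadeSeries(a=(1.0, 0, 0, 0, 0), b=(0, 0, 0, 0)),
            e_min=1e-5, e_max=100.0,
        )
        with pytest.raises(ValueError, match="corrupt"):
            bad.evaluate(0.01)

    def test_default_table_valid_over_range(self, table):
        for e in np.logspace(-5, 2, 141):
            p = table.evaluate(e)
            assert p.alpha > p.beta > 0
            assert 0 <= p.R <= 1

    def test_json_round_trip(self, table, tmp_path):
        path = tmp_path / "mod.json"
        table.to_json(path)
        again = ModeratorTable.from_json(path)
        for e in (1e-4, 0.01, 1.0, 50.0):
            assert again.evaluate(e) == table.evaluate(e)


class TestInitialGuess:
    def test_same_energy_same_seed(self, table):
        # different positions, same de Broglie energy -> identical IC seeds
        p1, _ = initial_guess(1.5, 1.0, 30.9, table)
        lam = 4 * np.pi * np.sin(0.5) / 1.5
        # pick (q_r, two_theta) reproducing the same wavelength
        tth2 = 1.4
        qr2 = 4 * np.pi * np.sin(tth2 / 2) / lam
        p2, _ = initial_guess(qr2, tth2, 30.9, table)
        assert np.isclose(p1.alpha, p2.alpha) and np.isclose(p1.R, p2.R)

    def test_energy_matches_de_broglie_oracle(self, table):
        qr, tth, L = 1.8, 1.1, 30.9
        lam = 2.0 * (2 * np.pi / qr) * np.sin(tth / 2)
        e_oracle = 6.62607015e-34**2 / (
            2 * 1.67492749804e-27 * (lam * 1e-10) ** 2) / 1.602176634e-19
        from tofprofile.geometry import energy_from_q
        assert np.isclose(energy_from_q(qr, tth), e_oracle, rtol=1e-6)

    def test_scale_seeded_from_counts(self, table):
        counts = np.zeros(31)
        counts[10:20] = 50.0
        _, broad = initial_guess(1.5, 1.0, 30.9, table, tof_counts=counts)
        assert broad.scale == pytest.approx(500.0, rel=0.01)
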