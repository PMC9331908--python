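"""Bootstrap: degenerate cases, percentile oracles, reproducibility,
and agreement of the batched refitter with scipy's reference optimizer."""

import numpy as np
import pytest

import craspetherm as ct
from craspetherm.bootstrap import _refit, _refit_batch
from craspetherm.errors import InvalidInputError
from craspetherm.models import _boatman_topt_theta


@pytest.fixture(scope="module")
def noisy_setup():
    temps = np.linspace(2, 36, 28)
    ds = ct.generate_dataset("boatman_2017", ct.CANONICAL_PARAMS, temps, noise_sd=5, seed=21)
    fit = ct.fit_model(ds, "boatman_2017", n_starts=8, seed=2)
    return ds, fit


def test_residual_bootstrap_noiseless_is_degenerate(fixture_dataset, canonical_fit):
    """All residuals are zero, so every replicate equals the point fit."""
    boot = ct.bootstrap_fit(
        fixture_dataset, "boatman_2017", canonical_fit,
        n_boot=25, method="residual", seed=0,
    )
    assert boot.n_failed == 0
    lo, hi = boot.trait_cis["t_opt"]
    assert hi - lo == pytest.approx(0.0, abs=1e-6)
    lo, hi = boot.trait_cis["r_max_hat"]
    assert hi - lo == pytest.approx(0.0, abs=1e-6)


def test_trait_interval_is_sorted_replicate_percentile(noisy_setup):
    """CI endpoints equal quantiles of the replicate trait draws (oracle)."""
    ds, fit = noisy_setup
    boot = ct.bootstrap_fit(ds, "boatman_2017", fit, n_boot=199, level=0.95, seed=5)
    draws = boot.trait_draws["t_opt"]
    lo, hi = boot.trait_cis["t_opt"]
    assert lo == pytest.approx(np.quantile(draws, 0.025))
    assert hi == pytest.approx(np.quantile(draws, 0.975))
    assert lo <= fit.t_opt <= hi


def test_same_seed_reproduces_replicates(noisy_setup):
    ds, fit = noisy_setup
    a = ct.bootstrap_fit(ds, "boatman_2017", fit, n_boot=50, seed=9)
    b = ct.bootstrap_fit(ds, "boatman_2017", fit, n_boot=50, seed=9)
    np.testing.assert_array_equal(a.replicates, b.replicates)


def test_wider_level_never_narrows(noisy_setup):
    ds, fit = noisy_setup
    a = ct.bootstrap_fit(ds, "boatman_2017", fit, n_boot=199, level=0.80, seed=3)
    b = ct.bootstrap_fit(ds, "boatman_2017", fit, n_boot=199, level=0.95, seed=3)
    for trait in ("t_opt", "r_max_hat"):
        assert b.trait_cis[trait][0] <= a.trait_cis[trait][0] + 1e-12
        assert b.trait_cis[trait][1] >= a.trait_cis[trait][1] - 1e-12


def test_invalid_inputs(noisy_setup):
    ds, fit = noisy_setup
    with pytest.raises(InvalidInputError):
        ct.bootstrap_fit(ds, "boatman_2017", fit, level=1.2)
    with pytest.raises(InvalidInputError):
        ct.bootstrap_fit(ds, "boatman_2017", fit, n_boot=0)
    with pytest.raises(InvalidInputError):
        ct.bootstrap_fit(ds, "boatman_2017", fit, method="jackknife")
    with pytest.raises(InvalidInputError):
        ct.bootstrap_fit(ds, "gaussian", fit)  # fit/model mismatch


class TestPredictionBand:
    def test_identical_replicates_collapse_to_curve(self, fixture_dataset, canonical_fit):
        boot = ct.bootstrap_fit(
            fixture_dataset, "boatman_2017", canonical_fit,
            n_boot=10, method="residual", seed=0,
        )
        grid = np.linspace(0, 40, 41)
        lo, hi = ct.prediction_band(boot, grid)
        np.testing.assert_allclose(lo, hi, atol=1e-9)
        np.testing.assert_allclose(lo, canonical_fit.predict(grid), atol=1e-6)

    def test_zero_beyond_all_tmax(self, noisy_setup):
        ds, fit = noisy_setup
        boot = ct.bootstrap_fit(ds, "boatman_2017", fit, n_boot=99, seed=1)
        lo, hi = ct.prediction_band(boot, [75.0])
        assert lo[0] == 0.0 and hi[0] == 0.0

    def test_band_equals_columnwise_quantiles(self, noisy_setup):
        ds, fit = noisy_setup
        boot = ct.bootstrap_fit(ds, "boatman_2017", fit, n_boot=99, seed=1)
        grid = np.linspace(0, 40, 17)
        lo, hi = ct.prediction_band(boot, grid)
        curves = np.vstack([boot.model.evaluate(th, grid) for th in boot.replicates])
        np.testing.assert_allclose(lo, np.quantile(curves, 0.025, axis=0))
        np.testing.assert_allclose(hi, np.quantile(curves, 0.975, axis=0))
        assert np.all(lo >= 0)

    def test_empty_grid_rejected(self, noisy_setup):
        ds, fit = noisy_setup
        boot = ct.bootstrap_fit(ds, "boatman_2017", fit, n_boot=20, seed=1)
        with pytest.raises(InvalidInputError):
            ct.prediction_band(boot, [])


def test_batched_refitter_matches_scipy_reference(noisy_setup):
    """The vectorized Levenberg-Marquardt path lands on the same minima as
    scipy's bounded trust-region solver on identical resamples."""
    ds, fit = noisy_setup
    m = fit.model
    lo, hi = map(np.array, zip(*m.bounds(ds.temperatures, ds.rates)))
    rng = np.random.default_rng(12)
    B = 60
    idx = rng.integers(0, ds.n, size=(B, ds.n))
    T, R = ds.temperatures[idx], ds.rates[idx]
    th_batch, ok = _refit_batch(m, fit.theta_hat, lo, hi, T, R)
    assert ok.mean() > 0.7
    th_scipy = np.array([_refit(m, fit.theta_hat, lo, hi, T[i], R[i]) for i in range(B)])

    def rss(th, i):
        return float(np.sum((m.evaluate(th, T[i]) - R[i]) ** 2))

    rb = np.array([rss(th_batch[i], i) for i in range(B)])
    rs = np.array([rss(th_scipy[i], i) for i in range(B)])
    rel = (rb - rs) / np.maximum(rs, 1e-12)
    # same cost within numerical slack for the vast majority of replicates
    assert np.median(np.abs(rel)) < 1e-4
    assert np.mean(rel < 0.02) > 0.9
    tb = np.array([_boatman_topt_theta(t) for t in th_batch[ok]])
    ts = np.array([_boatman_topt_theta(t) for t in th_scipy])
    assert abs(np.median(tb) - np.median(ts)) < 0.25


def test_non_batched_model_uses_scipy_path(fixture_dataset):
    """Models without an analytic Jacobian bootstrap through scipy refits."""
    fit = ct.fit_model(fixture_dataset, "gaussian", n_starts=6, seed=0)
    boot = ct.bootstrap_fit(fixture_dataset, "gaussian", fit, n_boot=25, seed=4)
    assert boot.replicates.shape[0] + boot.n_failed == 25
    lo, hi = boot.trait_cis["t_opt"]
    assert lo <= hi
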