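"""TCSPC decay-curve, simulation, and tau8-fit tests.

Expected curves are checked against independent quadrature oracles
(direct numerical integration of the exp⊗Gauss convolution density),
and fits are checked by parameter recovery on simulated photons.
"""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import erfc

from flimphot.tcspc import (
    DecayModel,
    IllConditionedDecayWarning,
    IRFModel,
    LifetimeFitResult,
    TCSPCHistogram,
    amplitude_weighted_lifetime,
    expected_decay_curve,
    fit_lifetime,
    simulate_histogram,
    tau8_from_fit,
)

PERIOD = 12.5
EDGES = np.linspace(0.0, PERIOD, 257)


def _oracle_density(t, t0, sigma, tau, n_wrap=80):
    """Quadrature oracle: exp⊗Gauss single-pulse density summed over
    previous pulses (written independently of the package's CDF form)."""
    total = 0.0
    for k in range(-1, n_wrap):
        u = t + k * PERIOD - t0
        total += (
            (1.0 / (2.0 * tau))
            * np.exp(min(sigma**2 / (2 * tau**2) - u / tau, 700.0))
            * erfc((sigma / tau - u / sigma) / np.sqrt(2))
        )
    return total


class TestExpectedDecayCurve:
    def test_pure_background_is_uniform(self):
        model = DecayModel(components=((1.0, 2.0),), background_fraction=1.0)
        probs = expected_decay_curve(model, IRFModel(1.0, 0.2), EDGES)
        assert np.allclose(probs, 1.0 / 256)

    def test_monoexponential_sharp_irf_matches_wrapped_exponential(self):
        # sigma -> 0 limit: the curve is the periodically wrapped
        # exponential; t0 on a bin edge makes every bin purely exponential.
        tau = 2.0
        t0 = EDGES[41]  # exact bin edge
        model = DecayModel(components=((1.0, tau),))
        probs = expected_decay_curve(model, IRFModel(t0, 1e-4), EDGES)
        rel = np.mod(EDGES - t0, PERIOD)
        # exact bin integrals of exp(-t/tau) wrapped on the period
        cdf = -tau * np.exp(-rel / tau)
        mass = np.diff(cdf)
        mass[mass < 0] += tau * (1 - np.exp(-PERIOD / tau))  # wrap bin
        oracle = mass / mass.sum()
        # the two bins flanking the pulse edge carry the residual sigma
        # smear that the sigma=0 oracle lacks; compare everywhere else
        keep = np.ones(256, bool)
        keep[40:42] = False
        assert np.max(np.abs(probs - oracle)[keep] / oracle[keep]) < 1e-6

    def test_biexponential_matches_quadrature_convolution(self):
        model = DecayModel(components=((0.5, 1.0), (0.5, 3.0)))
        irf = IRFModel(1.5, 0.2)
        probs = expected_decay_curve(model, irf, EDGES)
        oracle = np.empty(256)
        for i in range(256):
            val = 0.0
            for frac, tau in model.components:
                v, _ = quad(
                    _oracle_density, EDGES[i], EDGES[i + 1],
                    args=(irf.center_ns, irf.sigma_ns, tau), limit=200,
                )
                val += frac * v
            oracle[i] = val
        oracle /= oracle.sum()
        assert np.max(np.abs(probs - oracle) / oracle) < 1e-6

    def test_sums_to_one_over_randomized_parameters(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = rng.integers(1, 3)
            taus = rng.uniform(0.2, 8.0, n)
            fracs = rng.dirichlet(np.ones(n))
            model = DecayModel(
                components=tuple(zip(fracs, taus)),
                background_fraction=float(rng.uniform(0, 0.5)),
            )
            irf = IRFModel(float(rng.uniform(0, PERIOD)), float(rng.uniform(0.05, 0.5)))
            probs = expected_decay_curve(model, irf, EDGES)
            assert abs(probs.sum() - 1.0) < 1e-9
            assert np.all(probs >= 0)

    def test_nonuniform_bins_rejected(self):
        bad = np.concatenate([[0.0], np.linspace(1.0, PERIOD, 32)])
        model = DecayModel(components=((1.0, 2.0),))
        with pytest.raises(ValueError, match="uniform"):
            expected_decay_curve(model, IRFModel(1.0, 0.1), bad)

    def test_very_long_lifetime_warns_ill_conditioned(self):
        model = DecayModel(components=((1.0, 100 * PERIOD),))
        with pytest.warns(IllConditionedDecayWarning):
            expected_decay_curve(model, IRFModel(1.0, 0.1), EDGES)


class TestSimulateHistogram:
    def test_zero_photons_rejected(self):
        model = DecayModel(components=((1.0, 2.0),))
        with pytest.raises(ValueError, match="n_photons"):
            simulate_histogram(model, IRFModel(1.0, 0.1), 0)

    def test_fixed_seed_reproducible(self):
        model = DecayModel(components=((0.6, 1.0), (0.4, 3.0)))
        irf = IRFModel(0.5, 0.2)
        h1 = simulate_histogram(model, irf, 10_000, seed=7)
        h2 = simulate_histogram(model, irf, 10_000, seed=7)
        assert np.array_equal(h1.counts, h2.counts)
        assert h1.total_photons == 10_000

    def test_empirical_mean_matches_analytic_wrapped_mean(self):
        tau, t0 = 2.0, 0.3
        model = DecayModel(components=((1.0, tau),))
        hist = simulate_histogram(model, IRFModel(t0, 0.05), 10**6, seed=3)
        empirical = float(np.sum(hist.bin_centers * hist.counts) / hist.total_photons)
        # analytic mean of the wrapped density, by quadrature of the
        # un-convolved wrapped exponential (sigma negligible)
        norm = tau * (1 - np.exp(-PERIOD / tau))
        density = lambda t: np.exp(-np.mod(t - t0, PERIOD) / tau) / norm
        mean, _ = quad(lambda t: t * density(t), 0, PERIOD, limit=500, points=[t0])
        assert abs(empirical - mean) / mean < 0.01


class TestFitLifetime:
    @pytest.mark.parametrize("tau", [0.5, 1.0, 2.0, 4.0])
    def test_monoexponential_recovery_within_one_percent(self, tau):
        model = DecayModel(components=((1.0, tau),))
        irf = IRFModel(0.5, 0.1)
        hist = simulate_histogram(model, irf, 10**6, seed=11)
        fit = fit_lifetime(hist, irf=irf, n_components=1)
        assert fit.converged
        assert abs(fit.fitted_components[0][1] - tau) / tau < 0.01

    def test_biexponential_tau8_recovery_at_peredox_scale(self):
        # amplitude-weighted mean lifetime 0.7*0.4 + 0.3*4.5 = 1.63 ns,
        # the resting NADH-sensor lifetime scale
        model = DecayModel(components=((0.7, 0.4), (0.3, 4.5)))
        irf = IRFModel(0.5, 0.1)
        hist = simulate_histogram(model, irf, 5 * 10**5, seed=21)
        fit = fit_lifetime(hist, irf=irf, n_components=2)
        assert fit.converged
        assert abs(fit.tau8 - 1.63) < 0.05

    def test_noiseless_curve_recovers_generating_parameters(self):
        model = DecayModel(components=((0.7, 0.4), (0.3, 4.5)))
        irf = IRFModel(0.5, 0.1)
        probs = expected_decay_curve(model, irf, EDGES)
        hist = TCSPCHistogram(EDGES, np.round(probs * 10**7).astype(int))
        fit = fit_lifetime(hist, irf=irf, n_components=2)
        fitted = sorted(fit.fitted_components, key=lambda c: c[1])
        for (fa, ft), (ta, tt) in zip(fitted, [(0.7, 0.4), (0.3, 4.5)]):
            assert abs(fa - ta) / ta < 0.005
            assert abs(ft - tt) / tt < 0.005

    def test_windowed_and_full_period_fits_agree(self):
        # sanity of the 8-ns window: for fast decays and low background
        # the windowed tau8 matches a (nearly) full-period fit
        model = DecayModel(components=((0.6, 1.0), (0.4, 3.0)))
        irf = IRFModel(0.5, 0.1)
        hist = simulate_histogram(model, irf, 10**6, seed=5)
        fit8 = fit_lifetime(hist, irf=irf, n_components=2, window_after_peak_ns=8.0)
        fit_full = fit_lifetime(hist, irf=irf, n_components=2, window_after_peak_ns=11.9)
        assert abs(fit8.tau8 - fit_full.tau8) / fit_full.tau8 < 0.02

    def test_cofit_irf_still_recovers_lifetime(self):
        model = DecayModel(components=((1.0, 2.0),))
        hist = simulate_histogram(model, IRFModel(0.5, 0.15), 10**6, seed=9)
        fit = fit_lifetime(hist, irf=None, n_components=1)
        assert fit.converged
        assert abs(fit.fitted_components[0][1] - 2.0) / 2.0 < 0.02
        assert abs(fit.fitted_irf.sigma_ns - 0.15) < 0.1

    def test_too_few_photons_rejected(self):
        model = DecayModel(components=((1.0, 2.0),))
        hist = simulate_histogram(model, IRFModel(0.5, 0.1), 99, seed=0)
        with pytest.raises(ValueError, match="100 photons"):
            fit_lifetime(hist, irf=IRFModel(0.5, 0.1))


class TestTau8:
    @pytest.mark.parametrize(
        "components, expected",
        [
            (((1.0, 2.0),), 2.0),
            (((0.5, 1.0), (0.5, 3.0)), 2.0),
            (((0.7, 0.4), (0.3, 4.5)), 1.63),
        ],
    )
    def test_amplitude_weighted_mean(self, components, expected):
        assert amplitude_weighted_lifetime(components) == pytest.approx(expected)

    def test_nonconverged_fit_rejected(self):
        fit = LifetimeFitResult(
            fitted_components=((1.0, 2.0),),
            fitted_irf=IRFModel(0.5, 0.1),
            fitted_background=0.0,
            tau8=float("nan"),
            fit_window_ns=(0.5, 8.5),
            goodness=np.inf,
            converged=False,
        )
        with pytest.raises(ValueError, match="non-converged"):
            tau8_from_fit(fit)

    def test_strictly_increasing_in_each_component_lifetime(self):
        base = ((0.6, 1.0), (0.4, 3.0))
        t8 = amplitude_weighted_lifetime(base)
        for i in range(2):
            for bump in (0.1, 0.5, 1.0):
                comps = list(base)
                a, t = comps[i]
                comps[i] = (a, t + bump)
                assert amplitude_weighted_lifetime(comps) > t8
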