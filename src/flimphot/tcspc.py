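"""Simulation and fitting of TCSPC photon-arrival histograms.

Fluorescence-lifetime photometry reads out analyte binding (NADH on
Peredox, Ca2+ on RCaMP) from the excited-state lifetime of the sensor.
With a pulsed laser at 80 MHz every photon's arrival time relative to
the most recent excitation pulse is histogrammed over one 12.5 ns laser
period.  The histogram is the convolution of a (bi)exponential decay
with a Gaussian instrument response function (IRF), wrapped around the
period because slow decay components inherit residue from all previous
pulses, plus a uniform background of uncorrelated photons.

The lifetime readout used throughout the package is ``tau8``: the
amplitude-weighted mean lifetime of a decay fit restricted to a window
extending 8 ns past the peak of the photon-arrival histogram.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import erfc, erfcx

__all__ = [
    "IRFModel",
    "DecayModel",
    "TCSPCHistogram",
    "LifetimeFitResult",
    "IllConditionedDecayWarning",
    "expected_decay_curve",
    "simulate_histogram",
    "fit_lifetime",
    "tau8_from_fit",
    "amplitude_weighted_lifetime",
]

DEFAULT_LASER_PERIOD_NS = 12.5  # 80 MHz excitation
DEFAULT_N_BINS = 256

_SQRT2 = np.sqrt(2.0)


class IllConditionedDecayWarning(UserWarning):
    """A decay lifetime is so long relative to the laser period that the
    wrapped histogram is nearly uniform and carries little information."""


@dataclass(frozen=True)
class IRFModel:
    """Gaussian instrument response: timing blur of excitation+detection.

    Parameters
    ----------
    center_ns : offset of the IRF peak within the laser period.
    sigma_ns : Gaussian standard deviation (> 0).
    """

    center_ns: float
    sigma_ns: float

    def __post_init__(self) -> None:
        if not self.sigma_ns > 0:
            raise ValueError(f"IRF sigma must be > 0, got {self.sigma_ns}")
        if self.center_ns < 0:
            raise ValueError(f"IRF center must be >= 0, got {self.center_ns}")


@dataclass(frozen=True)
class DecayModel:
    """Mixture of exponential decays plus uniform background.

    ``components`` is a list of ``(amplitude_fraction, lifetime_ns)``
    pairs; fractions are positive and sum to 1.  ``background_fraction``
    is the fraction of photons arriving uniformly in the period
    (ambient light, dark counts).
    """

    components: tuple[tuple[float, float], ...]
    background_fraction: float = 0.0
    laser_period_ns: float = DEFAULT_LASER_PERIOD_NS

    def __post_init__(self) -> None:
        comps = tuple((float(a), float(t)) for a, t in self.components)
        object.__setattr__(self, "components", comps)
        if not comps:
            raise ValueError("DecayModel needs at least one component")
        fracs = np.array([a for a, _ in comps])
        taus = np.array([t for _, t in comps])
        if np.any(fracs <= 0):
            raise ValueError("amplitude fractions must be > 0")
        if abs(fracs.sum() - 1.0) > 1e-9:
            raise ValueError(f"amplitude fractions must sum to 1, got {fracs.sum()}")
        if np.any(taus <= 0):
            raise ValueError("lifetimes must be > 0")
        if not 0 <= self.background_fraction <= 1:
            raise ValueError("background_fraction must be in [0, 1]")
        if not self.laser_period_ns > 0:
            raise ValueError("laser_period_ns must be > 0")

    @property
    def mean_lifetime_ns(self) -> float:
        return float(sum(a * t for a, t in self.components))


@dataclass
class TCSPCHistogram:
    """Binned photon arrival times for one ROI/frame/channel."""

    bin_edges: np.ndarray  # ns, uniform, spanning one laser period
    counts: np.ndarray  # non-negative integer photons per bin
    channel: str = "green"
    laser_period_ns: float = DEFAULT_LASER_PERIOD_NS
    frame_time_s: float | None = None

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.bin_edges.ndim != 1 or self.bin_edges.size < 2:
            raise ValueError("bin_edges must be 1-D with >= 2 entries")
        if self.counts.shape != (self.bin_edges.size - 1,):
            raise ValueError("counts length must be len(bin_edges) - 1")
        widths = np.diff(self.bin_edges)
        if np.any(widths <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if not np.allclose(widths, widths[0], rtol=1e-8):
            raise ValueError("bins must be uniform")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        span = self.bin_edges[-1] - self.bin_edges[0]
        if not np.isclose(span, self.laser_period_ns, rtol=1e-6):
            raise ValueError(
                f"bin_edges span {span} ns != laser period {self.laser_period_ns} ns"
            )

    @property
    def n_bins(self) -> int:
        return self.counts.size

    @property
    def total_photons(self) -> int:
        return int(self.counts.sum())

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def peak_bin(self) -> int:
        """Earliest bin holding the maximum count."""
        return int(np.argmax(self.counts))


@dataclass
class LifetimeFitResult:
    """Result of a decay fit; ``tau8`` is the scalar lifetime readout."""

    fitted_components: tuple[tuple[float, float], ...]
    fitted_irf: IRFModel
    fitted_background: float
    tau8: float
    fit_window_ns: tuple[float, float]
    goodness: float
    converged: bool
    objective: str = "poisson"
    n_photons_in_window: int = 0
    message: str = ""


def _wrapped_component_cdf(
    t: np.ndarray, t0: float, sigma: float, tau: float, period: float
) -> np.ndarray:
    """CDF at times ``t`` of one exp(tau)⊗Gauss(t0, sigma) response summed
    over the current and all previous laser pulses (periodic steady state).

    Uses the analytic form  F(t) = Phi((t-t0)/sigma) - E(t)  with
    E(t) = 0.5 * erfcx((r-u)/sqrt2) * exp(-u^2/2),  u=(t-t0)/sigma, r=sigma/tau,
    rewritten via erfcx for numerical stability far past the pulse.
    """
    # pulses at t0 - k*period, k = -1 (next pulse's early edge) .. K
    n_wrap = int(np.ceil(36.0 * tau / period)) + 2
    ks = np.arange(-1, n_wrap + 1)
    tt = t[None, :] + ks[:, None] * period  # time since pulse at t0
    u = (tt - t0) / sigma
    r = sigma / tau
    x = (r - u) / _SQRT2

    phi = 0.5 * erfc(-u / _SQRT2)
    e_term = np.empty_like(u)
    safe = x > -25.0  # erfcx(-x) overflows past ~26
    xs = np.where(safe, x, 0.0)
    e_term[:] = 0.5 * erfcx(xs) * np.exp(-0.5 * u**2)
    if not np.all(safe):
        us = u[~safe]
        # erfc(very negative) == 2 - erfc(|x|): dominant term exp(r^2/2 - r u)
        lead = np.exp(r * r / 2.0 - r * us)
        corr = 0.5 * erfcx(-x[~safe]) * np.exp(-0.5 * us**2)
        e_term[~safe] = lead - corr
    f = phi - e_term
    return f.sum(axis=0)


def expected_decay_curve(
    model: DecayModel, irf: IRFModel, bin_edges: np.ndarray
) -> np.ndarray:
    """Expected per-bin photon probabilities (summing to 1 over the period).

    Closed-form exponential⊗Gaussian convolution with periodic wrap-around
    of the exponential tail, plus a uniform background term.
    """
    bin_edges = np.asarray(bin_edges, dtype=float)
    widths = np.diff(bin_edges)
    if np.any(widths <= 0) or not np.allclose(widths, widths[0], rtol=1e-8):
        raise ValueError("bin_edges must be strictly increasing and uniform")
    period = model.laser_period_ns
    if not np.isclose(bin_edges[-1] - bin_edges[0], period, rtol=1e-6):
        raise ValueError("bin_edges must span exactly one laser period")
    n_bins = widths.size

    for _, tau in model.components:
        if tau >= 100.0 * period:
            warnings.warn(
                f"lifetime {tau} ns >= 100x laser period {period} ns: "
                "wrapped decay is nearly uniform, fit is ill-conditioned",
                IllConditionedDecayWarning,
                stacklevel=2,
            )

    probs = np.full(n_bins, model.background_fraction / n_bins)
    signal = 1.0 - model.background_fraction
    if signal > 0:
        for frac, tau in model.components:
            cdf = _wrapped_component_cdf(
                bin_edges, irf.center_ns, irf.sigma_ns, tau, period
            )
            mass = np.diff(cdf)
            total = cdf[-1] - cdf[0]
            probs += signal * frac * mass / total
    return probs / probs.sum()


def simulate_histogram(
    model: DecayModel,
    irf: IRFModel,
    n_photons: int,
    n_bins: int = DEFAULT_N_BINS,
    seed: int | np.random.Generator = 0,
    channel: str = "green",
) -> TCSPCHistogram:
    """Multinomial photon realization of the expected decay curve."""
    if n_photons < 1:
        raise ValueError(f"n_photons must be >= 1, got {n_photons}")
    if n_bins < 16:
        raise ValueError(f"n_bins must be >= 16, got {n_bins}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    edges = np.linspace(0.0, model.laser_period_ns, n_bins + 1)
    probs = expected_decay_curve(model, irf, edges)
    counts = rng.multinomial(int(n_photons), probs)
    return TCSPCHistogram(
        bin_edges=edges,
        counts=counts,
        channel=channel,
        laser_period_ns=model.laser_period_ns,
    )


def amplitude_weighted_lifetime(
    components: tuple[tuple[float, float], ...] | list[tuple[float, float]],
) -> float:
    """Sum of a_i * tau_i; the scalar lifetime of a multi-component fit."""
    return float(sum(a * t for a, t in components))


def _window_slice(hist: TCSPCHistogram, window_after_peak_ns: float) -> slice:
    peak = hist.peak_bin()
    centers = hist.bin_centers
    stop = int(np.searchsorted(centers, centers[peak] + window_after_peak_ns, "right"))
    return slice(peak, stop)


def _pack_theta(
    taus: np.ndarray, frac: float | None, bg: float, irf_free: bool, irf: IRFModel
) -> np.ndarray:
    theta = list(np.log(taus))
    if frac is not None:
        theta.append(frac)
    theta.append(bg)
    if irf_free:
        theta += [irf.center_ns, np.log(irf.sigma_ns)]
    return np.asarray(theta)


def fit_lifetime(
    hist: TCSPCHistogram,
    irf: IRFModel | None = None,
    n_components: int = 2,
    window_after_peak_ns: float = 8.0,
    objective: str = "poisson",
    fit_background: bool = False,
    max_iter: int = 500,
) -> LifetimeFitResult:
    """Fit a (bi)exponential⊗Gaussian decay to the histogram window.

    The fit is restricted to bins from the peak-count bin (earliest bin
    with the maximum count) to ``window_after_peak_ns`` past it.  With
    ``irf=None`` the IRF center and width are co-fitted; passing an
    :class:`IRFModel` fixes them.  The default objective is the Poisson
    maximum likelihood of the windowed counts (conditional multinomial);
    ``objective="lsq"`` gives Poisson-weighted least squares.

    The uniform background fraction is fixed at 0 unless
    ``fit_background=True``: a post-peak window carries almost no
    information separating a uniform background from the wrapped tail of
    a slow component, and freeing it visibly biases tau8.

    Returns a :class:`LifetimeFitResult` whose ``tau8`` is the
    amplitude-weighted mean lifetime of the windowed fit.
    """
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    if objective not in ("poisson", "lsq"):
        raise ValueError("objective must be 'poisson' or 'lsq'")
    if hist.total_photons < 100:
        raise ValueError("histogram must contain >= 100 photons to fit")
    period = hist.laser_period_ns
    centers = hist.bin_centers
    peak = hist.peak_bin()
    if window_after_peak_ns > period:
        raise ValueError("window_after_peak_ns must not exceed the laser period")

    sl = _window_slice(hist, window_after_peak_ns)
    counts_w = hist.counts[sl].astype(float)
    n_w = counts_w.sum()
    window = (float(centers[sl.start]), float(centers[sl.stop - 1]))

    irf_free = irf is None
    if irf_free:
        irf0 = IRFModel(center_ns=float(centers[peak]), sigma_ns=0.2)
    else:
        irf0 = irf

    # empirical mean arrival past the peak seeds the lifetime guesses
    rel = centers[sl] - centers[peak]
    mean_arrival = float(np.sum(rel * counts_w) / max(n_w, 1.0))
    mean_arrival = max(mean_arrival, 0.05)
    if n_components == 1:
        taus0 = np.array([mean_arrival])
        frac0 = None
    else:
        taus0 = np.array([0.5 * mean_arrival, 2.0 * mean_arrival])
        frac0 = 0.5

    edges = hist.bin_edges

    def unpack(theta):
        i = n_components
        taus = np.exp(theta[:i])
        if n_components == 2:
            frac = theta[i]
            i += 1
            comps = ((frac, taus[0]), (1.0 - frac, taus[1]))
        else:
            comps = ((1.0, taus[0]),)
        bg = theta[i]
        i += 1
        if irf_free:
            the_irf = IRFModel(center_ns=theta[i], sigma_ns=float(np.exp(theta[i + 1])))
        else:
            the_irf = irf0
        return comps, bg, the_irf

    def nll(theta):
        comps, bg, the_irf = unpack(theta)
        fracs = np.array([max(a, 1e-12) for a, _ in comps])
        fracs = fracs / fracs.sum()
        comps = tuple((f, t) for f, (_, t) in zip(fracs, comps))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", IllConditionedDecayWarning)
            model = DecayModel(
                components=comps, background_fraction=bg, laser_period_ns=period
            )
            probs = expected_decay_curve(model, the_irf, edges)
        p_w = probs[sl]
        q = p_w / p_w.sum()
        q = np.maximum(q, 1e-300)
        if objective == "poisson":
            return -float(np.sum(counts_w * np.log(q)))
        mu = n_w * q
        return 0.5 * float(np.sum((counts_w - mu) ** 2 / np.maximum(mu, 1.0)))

    theta0 = _pack_theta(taus0, frac0, 0.01 if fit_background else 0.0, irf_free, irf0)
    bounds: list[tuple[float, float]] = [(np.log(0.01), np.log(50.0))] * n_components
    if n_components == 2:
        bounds.append((1e-4, 1.0 - 1e-4))
    bounds.append((0.0, 0.9) if fit_background else (0.0, 0.0))
    if irf_free:
        bounds += [(0.0, period), (np.log(0.01), np.log(2.0))]

    res = minimize(
        nll,
        theta0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-10},
    )

    comps, bg, fitted_irf = unpack(res.x)
    fracs = np.array([a for a, _ in comps])
    fracs = fracs / fracs.sum()
    comps = tuple((float(f), float(t)) for f, (_, t) in zip(fracs, comps))

    # degenerate two-component fit: collapse to one component
    if n_components == 2:
        (a1, t1), (a2, t2) = comps
        if abs(t1 - t2) / max(t1, t2) < 1e-2:
            warnings.warn(
                "two-component fit degenerate (lifetimes within 1%); "
                "collapsing to a single component",
                UserWarning,
                stacklevel=2,
            )
            comps = ((1.0, a1 * t1 + a2 * t2),)

    converged = bool(res.success)
    tau8 = amplitude_weighted_lifetime(comps) if converged else float("nan")

    # reduced chi-square-like goodness on the window
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", IllConditionedDecayWarning)
        model = DecayModel(
            components=comps, background_fraction=bg, laser_period_ns=period
        )
        probs = expected_decay_curve(model, fitted_irf, edges)
    q = probs[sl] / probs[sl].sum()
    mu = n_w * q
    dof = max(counts_w.size - len(res.x), 1)
    goodness = float(np.sum((counts_w - mu) ** 2 / np.maximum(mu, 1.0)) / dof)

    return LifetimeFitResult(
        fitted_components=comps,
        fitted_irf=fitted_irf,
        fitted_background=float(bg),
        tau8=tau8,
        fit_window_ns=window,
        goodness=goodness,
        converged=converged,
        objective=objective,
        n_photons_in_window=int(n_w),
        message=str(res.message),
    )


def tau8_from_fit(fit: LifetimeFitResult) -> float:
    """Scalar lifetime readout: amplitude-weighted mean lifetime."""
    if not fit.converged:
        raise ValueError("cannot extract tau8 from a non-converged fit")
    return amplitude_weighted_lifetime(fit.fitted_components)
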