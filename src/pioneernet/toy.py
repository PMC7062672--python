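"""Toy theory for first-spike latency statistics under a rigid activation.

All neurons' star-voltage distributions are translated rigidly along the
voltage axis by the same activation time course,

    u(t) = alpha * exp(-t^2 / (2 sigma_NS^2)),

a Gaussian bump (alpha = 0.56 mV, sigma_NS = 23 ms by default) that
mimics the comparatively slow build-up of a network spike.  The latency
density of a neuron with between-NS star-voltage mean <V> and standard
deviation sigma is approximated by the probability flux through threshold,
half-wave rectified:

    p(tau) = N [u'(tau)]_+ exp(-(V_theta - <V> - u(tau))^2 / (2 sigma^2)),

which is supported on the rising side of the bump only (tau < 0) and is
normalized numerically.  This isolates the effect of a neuron's
sub-threshold statistics on its latency from the effect of the network's
own activity time course.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ConfigurationError


@dataclass
class ToyParams:
    """Rigid activation bump and threshold."""

    alpha: float = 0.56       # mV, bump amplitude
    sigma_ns: float = 23.0    # ms, bump width
    v_theta: float = -50.0    # mV

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.sigma_ns <= 0:
            raise ConfigurationError("alpha and sigma_ns must be positive")


def activation(t, params: ToyParams) -> np.ndarray:
    """u(t): Gaussian activation bump centred at t = 0 (mV)."""
    t = np.asarray(t, dtype=float)
    return params.alpha * np.exp(-t ** 2 / (2.0 * params.sigma_ns ** 2))


def activation_rate(t, params: ToyParams) -> np.ndarray:
    """du/dt (mV/ms); positive on the rising side (t < 0)."""
    t = np.asarray(t, dtype=float)
    return -(t / params.sigma_ns ** 2) * activation(t, params)


def default_tau_grid(params: ToyParams, dt: float = 0.1) -> np.ndarray:
    """Trapezoid grid over the rising side of the bump, [-5 sigma_NS, 0]."""
    return np.arange(-5.0 * params.sigma_ns, 0.0 + dt / 2, dt)


def latency_density(mean_v: float, sigma_v: float, params: ToyParams,
                    tau: np.ndarray = None) -> tuple:
    """Normalized latency density p(tau) for one neuron.

    Returns (tau, p).  Raises when the density integrates to (numerically)
    zero, i.e. when the bump never brings the threshold within reach of
    the voltage distribution.
    """
    if sigma_v <= 0:
        raise ConfigurationError("sigma_v must be positive")
    if tau is None:
        tau = default_tau_grid(params)
    tau = np.asarray(tau, dtype=float)
    flux = np.clip(activation_rate(tau, params), 0.0, None)
    gap = params.v_theta - mean_v - activation(tau, params)
    p = flux * np.exp(-gap ** 2 / (2.0 * sigma_v ** 2))
    norm = np.trapezoid(p, tau)
    if not norm > 0:
        raise FloatingPointError(
            "latency density vanished: threshold unreachable under the bump")
    return tau, p / norm


def predicted_latency_stats(mean_v: np.ndarray, sigma_v: np.ndarray,
                            params: ToyParams = None,
                            tau: np.ndarray = None) -> tuple:
    """Per-neuron (<tau>, 1/CV(tau)) under the rigid activation.

    Neurons whose density vanishes (threshold unreachable) get NaN.
    Returns (mean_tau, inv_cv_tau) arrays.
    """
    if params is None:
        params = ToyParams()
    mean_v = np.atleast_1d(np.asarray(mean_v, dtype=float))
    sigma_v = np.atleast_1d(np.asarray(sigma_v, dtype=float))
    if tau is None:
        tau = default_tau_grid(params)
    out_mean = np.full(mean_v.size, np.nan)
    out_icv = np.full(mean_v.size, np.nan)
    for q in range(mean_v.size):
        if not sigma_v[q] > 0:
            continue
        try:
            t, p = latency_density(mean_v[q], sigma_v[q], params, tau)
        except FloatingPointError:
            continue
        m = np.trapezoid(t * p, t)
        var = np.trapezoid((t - m) ** 2 * p, t)
        out_mean[q] = m
        if var > 0:
            out_icv[q] = -m / np.sqrt(var)
    return out_mean, out_icv


def monte_carlo_latencies(mean_v: float, sigma_v: float, params: ToyParams,
                          n_draws: int = 100_000, seed: int = 0) -> np.ndarray:
    """Direct simulation of the rigid-translation ensemble.

    Each draw freezes a star voltage V0 ~ N(mean_v, sigma_v); the neuron
    fires at the first time V0 + u(tau) reaches threshold, which exists
    when 0 < V_theta - V0 <= alpha and occurs on the rising side at
    tau = -sigma_NS * sqrt(2 ln(alpha / (V_theta - V0))).  Draws that
    never cross (or start above threshold) yield no latency.  Serves as
    an independent check of the flux-formula density.
    """
    rng = np.random.default_rng(seed)
    v0 = rng.normal(mean_v, sigma_v, size=n_draws)
    gap = params.v_theta - v0
    ok = (gap > 0) & (gap <= params.alpha)
    return -params.sigma_ns * np.sqrt(2.0 * np.log(params.alpha / gap[ok]))
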