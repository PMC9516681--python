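"""Position-dependent diffusion coefficients from restrained time series.

For a particle held by a harmonic restraint at z_i, the local diffusion
coefficient follows from the fluctuation statistics of the restrained
coordinate:

    D(z_i) = ⟨δz²⟩² / ∫₀^∞ C_zz(t) dt,      C_zz(t) = ⟨δz(0) δz(t)⟩,

i.e. variance divided by the integrated autocorrelation time. The ACF
integral is truncated at its first zero crossing (noise control; the full
integral of a noisy ACF does not converge), with a fallback cutoff where
the ACF drops below 1% of the variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Profile, TrajectorySeries, WindowSchedule

__all__ = ["AcfResult", "autocorrelation", "estimate_D", "build_D_profile", "EstimationError"]


class EstimationError(RuntimeError):
    """The ACF-integral diffusion estimator failed on this series."""


@dataclass
class AcfResult:
    """Autocorrelation of a restrained coordinate series.

    `acf[0]` equals the (biased, 1/N) sample variance; `tau_int` is the
    integrated autocorrelation time ∫C dt / C(0) up to `cutoff_lag`.
    """

    lags: np.ndarray  # ps
    acf: np.ndarray  # Å²
    variance: float  # Å²
    tau_int: float  # ps
    cutoff_lag: float  # ps

    def __post_init__(self) -> None:
        if not self.variance > 0:
            raise ValueError("variance must be positive")


def _acf_fft(x: np.ndarray, n_lags: int) -> np.ndarray:
    """Biased (1/N) autocovariance for lags 0..n_lags−1 via FFT."""
    n = x.size
    d = x - x.mean()
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(d, nfft)
    ac = np.fft.irfft(f * np.conj(f), nfft)[:n_lags]
    return ac / n


def autocorrelation(series: TrajectorySeries, max_lag: float) -> AcfResult:
    """Biased-estimator autocorrelation C_zz(t) of a coordinate series.

    Parameters
    ----------
    series : TrajectorySeries
        Restrained, equilibrated samples; needs length ≥ 10·max_lag/dt.
    max_lag : float
        Longest lag (ps) to evaluate.
    """
    x = series.values
    n_lags = int(round(max_lag / series.dt)) + 1
    if x.size < 10 * (n_lags - 1):
        raise ValueError(
            f"series too short: {x.size} samples for {n_lags - 1} lags (need 10×)"
        )
    var = float(np.var(x))
    if var <= 0:
        raise ValueError("degenerate input: series is constant (zero variance)")
    acf = _acf_fft(x, n_lags)
    lags = series.dt * np.arange(n_lags)
    # integration cutoff: the first lag where the ACF crosses zero or decays
    # below 1% of the variance, whichever comes first (waiting for an actual
    # zero crossing of a noisy tail integrates accumulated noise and biases
    # D low); full window if neither occurs
    small = np.nonzero(acf < 0.01 * var)[0]
    cut = int(small[0]) if small.size else n_lags - 1
    cut = max(cut, 1)
    # clip the last panel at zero in case the cutoff point dipped negative
    integral = float(np.trapezoid(np.clip(acf[: cut + 1], 0.0, None), dx=series.dt))
    tau = integral / var
    return AcfResult(lags=lags, acf=acf, variance=var, tau_int=tau, cutoff_lag=float(lags[cut]))


def estimate_D(series: TrajectorySeries, max_lag: float | None = None) -> float:
    """Local diffusion coefficient D = ⟨δz²⟩²/∫C_zz dt from one window.

    `max_lag` defaults to one tenth of the series length, capped so the
    short-series precondition of :func:`autocorrelation` holds.
    """
    if max_lag is None:
        max_lag = series.dt * (len(series) // 10)
    res = autocorrelation(series, max_lag)
    if res.cutoff_lag <= series.dt:
        raise EstimationError(
            "ACF crosses zero at or before one sampling interval; the series "
            "is too noisy or too sparsely sampled for the integral estimator — "
            "use a longer or more finely sampled run"
        )
    if res.tau_int <= 0:
        raise EstimationError("non-positive integrated autocorrelation time")
    return res.variance / res.tau_int


def build_D_profile(
    schedule: WindowSchedule,
    estimates,
    target_grid,
) -> Profile:
    """Assemble a D(z) profile from per-window estimates.

    `estimates` maps window centers to one or more D values (dict
    center→value(s), or a sequence aligned with `schedule`). Repeat
    estimates at one center (independent restrained runs) are combined by
    geometric mean, with the standard deviation of log10 D kept as spread.
    Interpolation onto `target_grid` is linear in log D — D varies
    multiplicatively across the interface and must stay positive — with
    constant extrapolation beyond the outermost centers.
    """
    if isinstance(estimates, dict):
        items = sorted(estimates.items())
    else:
        seq = list(estimates)
        if len(seq) != len(schedule):
            raise ValueError("need one estimate (or list) per window")
        grouped: dict[float, list[float]] = {}
        for w, e in zip(schedule, seq):
            grouped.setdefault(w.center, []).extend(np.atleast_1d(e).tolist())
        items = sorted(grouped.items())
    if not items:
        raise ValueError("empty estimate set")
    centers, logD, spread = [], [], []
    for c, vals in items:
        v = np.atleast_1d(np.asarray(vals, dtype=float))
        if np.any(v <= 0):
            raise ValueError(f"non-positive D estimate at z = {c:g} Å")
        centers.append(float(c))
        logD.append(np.mean(np.log(v)))
        spread.append(np.std(np.log10(v), ddof=1) if v.size > 1 else 0.0)
    centers = np.asarray(centers)
    grid = np.asarray(target_grid, dtype=float)
    vals = np.exp(np.interp(grid, centers, np.asarray(logD)))
    err = np.interp(grid, centers, np.asarray(spread))
    return Profile(
        grid,
        vals,
        stderr=err * vals * np.log(10.0),  # propagate log10 spread to D units
        units="Å²/ps",
        meta={"interpolation": "log-linear", "combination": "geometric mean"},
    )
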