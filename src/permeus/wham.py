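"""Weighted histogram analysis method (WHAM) for umbrella-sampling data.

The estimator follows the statsmodels shape: build a :class:`Wham` model
from a window schedule and per-window reaction-coordinate series, call
:meth:`Wham.fit`, and read the PMF, window free energies and diagnostics
off the returned :class:`WhamResults`. Functional wrappers matching the
pipeline stage names (`solve_wham_1d`, `pmf_2d_reweight`,
`halfsplit_error`, `mae_between_profiles`) are provided on top.

Zero conventions: fitted PMFs are reported min-zero (the reference the
resistance integrand uses); `Profile.anchored(z_bulk)` re-references to
bulk for plotting against conventional membrane PMFs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .core import Profile, ThermoState, TrajectorySeries, WindowSchedule

__all__ = [
    "Wham",
    "WhamResults",
    "Profile2D",
    "InsufficientOverlapError",
    "solve_wham_1d",
    "pmf_2d_reweight",
    "halfsplit_error",
    "mae_between_profiles",
]


class InsufficientOverlapError(RuntimeError):
    """Adjacent umbrella histograms do not overlap; WHAM cannot stitch them."""


@dataclass
class Profile2D:
    """A field on a 2D bin grid (z × auxiliary observable); NaN = undefined."""

    z_centers: np.ndarray
    aux_centers: np.ndarray
    values: np.ndarray  # shape (len(z_centers), len(aux_centers))
    units: str = "kcal/mol"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.z_centers.size, self.aux_centers.size):
            raise ValueError("values shape must be (n_z, n_aux)")


def _default_edges(samples: np.ndarray, width: float = 0.5) -> np.ndarray:
    lo = np.floor(samples.min() / width) * width
    hi = np.ceil(samples.max() / width) * width
    if hi <= lo:
        hi = lo + width
    return lo + width * np.arange(round((hi - lo) / width) + 1)


class Wham:
    """1D WHAM estimator for harmonically biased umbrella windows.

    Parameters
    ----------
    schedule : WindowSchedule
        The umbrella windows (any harmonic convention; converted internally).
    series : sequence of TrajectorySeries
        One reaction-coordinate series per window, same order as `schedule`.
    bins : int, array of edges, or None
        Histogram bins. None uses 0.5 Å-wide bins spanning the sampled
        range; an int is a bin count over the sampled range.
    thermo : ThermoState
        Temperature of the lowest (analysis) replica.
    burn_in : float
        Fraction of each series discarded from the front before histogramming.
    """

    def __init__(
        self,
        schedule: WindowSchedule,
        series: list[TrajectorySeries],
        bins=None,
        thermo: ThermoState | None = None,
        burn_in: float = 0.0,
    ) -> None:
        if len(series) != len(schedule):
            raise ValueError("one series per window is required")
        if not 0.0 <= burn_in < 1.0:
            raise ValueError("burn_in must be in [0, 1)")
        self.schedule = schedule
        self.thermo = thermo or ThermoState(300.0)
        self.samples = []
        for s in series:
            v = s.values if isinstance(s, TrajectorySeries) else np.asarray(s, float)
            v = v[int(burn_in * v.size):]
            if v.size == 0:
                raise ValueError("a window has no samples after burn-in")
            self.samples.append(v)
        allv = np.concatenate(self.samples)
        if bins is None:
            self.edges = _default_edges(allv)
        elif np.ndim(bins) == 0:
            self.edges = np.linspace(allv.min(), allv.max(), int(bins) + 1)
        else:
            self.edges = np.asarray(bins, dtype=float)
        if allv.min() < self.edges[0] or allv.max() > self.edges[-1]:
            raise ValueError("bin range does not cover all samples")
        self.centers = 0.5 * (self.edges[:-1] + self.edges[1:])

    def _histograms(self) -> np.ndarray:
        H = np.array([np.histogram(v, self.edges)[0] for v in self.samples])
        occ = H > 0
        # adjacent-window overlap: consecutive windows must share occupied bins
        for k in range(len(self.schedule) - 1):
            if not np.any(occ[k] & occ[k + 1]):
                c0 = self.schedule[k].center
                c1 = self.schedule[k + 1].center
                raise InsufficientOverlapError(
                    f"histograms of windows at z = {c0:g} and {c1:g} Å share no "
                    "occupied bin; add windows or sampling in the gap"
                )
        total = H.sum(axis=0)
        nz = np.nonzero(total)[0]
        interior_empty = np.nonzero(total[nz[0]: nz[-1] + 1] == 0)[0]
        if interior_empty.size:
            z_bad = self.centers[nz[0] + interior_empty]
            raise InsufficientOverlapError(
                f"empty interior bins at z = {np.array2string(z_bad, precision=2)}; "
                "the sampled histograms do not tile the range"
            )
        return H

    def fit(self, tol: float = 1e-7, max_iter: int = 100_000, f_init=None) -> "WhamResults":
        """Self-consistent WHAM iteration.

        Iterates the coupled equations for the unbiased bin probabilities
        p_m and window free energies F_k until the largest change in any
        F_k is below `tol` kcal/mol. `f_init` optionally seeds the window
        free energies (kcal/mol); the converged PMF does not depend on it.
        Non-convergence is flagged on the result and warned about, never
        silent.
        """
        H = self._histograms()
        kT = self.thermo.kT
        beta = self.thermo.beta
        N = H.sum(axis=1).astype(float)  # samples per window
        logN = np.log(N)
        # log Boltzmann factor of each window's bias at each bin center
        b = np.array([-beta * w.energy(self.centers) for w in self.schedule])
        total = H.sum(axis=0)
        occupied = total > 0
        with np.errstate(divide="ignore"):
            log_total = np.where(occupied, np.log(total, where=occupied, out=np.full(total.shape, -np.inf)), -np.inf)
        if f_init is None:
            f = np.zeros(len(self.schedule))  # βF_k
        else:
            f = beta * np.asarray(f_init, dtype=float) * np.ones(len(self.schedule))
        converged = False
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            # p_m ∝ H_m / Σ_k N_k exp(f_k − βU_km)
            log_p = log_total - logsumexp(logN[:, None] + f[:, None] + b, axis=0)
            log_p -= logsumexp(log_p[occupied])
            # f_k = −ln Σ_m p_m exp(−βU_km)
            f_new = -logsumexp(log_p[None, occupied] + b[:, occupied], axis=1)
            delta = np.max(np.abs(f_new - f)) * kT
            f = f_new
            if delta < tol:
                converged = True
                break
        if not converged:
            warnings.warn(
                f"WHAM did not converge in {max_iter} iterations (last ΔF = {delta:.3g} kcal/mol)",
                RuntimeWarning,
                stacklevel=2,
            )
        G = np.full(self.centers.size, np.nan)
        G[occupied] = -kT * log_p[occupied]
        pmf = Profile(
            self.centers,
            G - np.nanmin(G),
            units="kcal/mol",
            meta={"zero": "min", "estimator": "wham", "bins": self.centers.size},
        )
        return WhamResults(
            model=self,
            pmf=pmf,
            window_free_energies=kT * (f - f[0]),
            n_iterations=n_iter,
            converged=converged,
            _f=f,
            _logN=logN,
        )


@dataclass
class WhamResults:
    """Converged (or flagged) WHAM solution.

    `pmf` is min-zero on the bin centers; `window_free_energies` are the
    per-window free energies F_k (kcal/mol, first window = 0).
    """

    model: Wham
    pmf: Profile
    window_free_energies: np.ndarray
    n_iterations: int
    converged: bool
    _f: np.ndarray
    _logN: np.ndarray

    def frame_weights(self) -> list[np.ndarray]:
        """Unbiasing weight of every frame of every window.

        w_t ∝ 1 / Σ_k N_k exp(f_k − βU_k(z_t)); weights are normalized to
        sum to 1 over the whole dataset. These are the per-frame WHAM
        weights used for reweighting onto auxiliary observables.
        """
        beta = self.model.thermo.beta
        out = []
        for v in self.model.samples:
            b = np.array([-beta * w.energy(v) for w in self.model.schedule])
            out.append(np.exp(-logsumexp(self._logN[:, None] + self._f[:, None] + b, axis=0)))
        norm = sum(w.sum() for w in out)
        return [w / norm for w in out]

    def summary(self) -> str:
        lines = [
            "WHAM results",
            "=" * 46,
            f"windows:        {len(self.model.schedule)}",
            f"bins:           {len(self.pmf)} on [{self.model.edges[0]:g}, {self.model.edges[-1]:g}] Å",
            f"temperature:    {self.model.thermo.temperature:g} K",
            f"iterations:     {self.n_iterations}",
            f"converged:      {self.converged}",
            f"PMF range:      0 .. {np.nanmax(self.pmf.values):.3f} kcal/mol (min-zero)",
            "-" * 46,
            "center (Å)   k_half (kcal/mol/Å²)   F_k (kcal/mol)",
        ]
        for w, fk in zip(self.model.schedule, self.window_free_energies):
            lines.append(f"{w.center:9.2f}   {w.k_half:20.3f}   {fk:12.4f}")
        return "\n".join(lines)


def solve_wham_1d(
    schedule: WindowSchedule,
    series: list[TrajectorySeries],
    bins=None,
    thermo: ThermoState | None = None,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    burn_in: float = 0.0,
) -> WhamResults:
    """One-call 1D WHAM: build the model and fit it."""
    return Wham(schedule, series, bins=bins, thermo=thermo, burn_in=burn_in).fit(
        tol=tol, max_iter=max_iter
    )


def pmf_2d_reweight(
    schedule: WindowSchedule,
    z_series: list[TrajectorySeries],
    aux_series: list[np.ndarray],
    bins_z,
    bins_aux,
    thermo: ThermoState | None = None,
    **fit_kw,
) -> Profile2D:
    """2D PMF over (z, auxiliary observable) by reweighting the 1D bias.

    The 1D WHAM solution supplies per-frame unbiasing weights, which are
    histogrammed over (z, aux); the 2D PMF is −kT·ln of the weighted
    density, min-shifted to zero. Bins never visited are NaN (undefined),
    not zero.
    """
    if len(aux_series) != len(z_series):
        raise ValueError("one auxiliary series per window is required")
    for z, a in zip(z_series, aux_series):
        zn = len(z) if isinstance(z, TrajectorySeries) else len(np.asarray(z))
        if zn != len(np.asarray(a)):
            raise ValueError("z and auxiliary series must be frame-aligned per window")
    res = Wham(schedule, z_series, bins=bins_z, thermo=thermo).fit(**fit_kw)
    weights = res.frame_weights()
    z_edges = res.model.edges
    aux_all = np.concatenate([np.asarray(a, float) for a in aux_series])
    if np.ndim(bins_aux) == 0:
        aux_edges = np.histogram_bin_edges(aux_all, int(bins_aux))
    else:
        aux_edges = np.asarray(bins_aux, dtype=float)
    rho = np.zeros((z_edges.size - 1, aux_edges.size - 1))
    for v, a, w in zip(res.model.samples, aux_series, weights):
        rho += np.histogram2d(v, np.asarray(a, float), bins=(z_edges, aux_edges), weights=w)[0]
    kT = res.model.thermo.kT
    with np.errstate(divide="ignore"):
        G = np.where(rho > 0, -kT * np.log(rho, where=rho > 0, out=np.zeros_like(rho)), np.nan)
    G -= np.nanmin(G)
    return Profile2D(
        res.model.centers,
        0.5 * (aux_edges[:-1] + aux_edges[1:]),
        G,
        units="kcal/mol",
        meta={"zero": "min", "converged": res.converged},
    )


def halfsplit_error(
    schedule: WindowSchedule,
    series: list[TrajectorySeries],
    bins=None,
    thermo: ThermoState | None = None,
    **fit_kw,
) -> tuple[Profile, Profile, Profile]:
    """Convergence error from independent first-half / second-half PMFs.

    Each window's series is split in half; WHAM is solved on each half on a
    common bin grid; both PMFs are min-zero aligned. Returns
    (pmf_first, pmf_second, mean PMF carrying the per-bin standard
    deviation of the two halves as `stderr`).
    """
    halves = [s.halves() for s in series]
    full = Wham(schedule, series, bins=bins, thermo=thermo)  # fixes common edges
    edges = full.edges
    results = []
    for part in (0, 1):
        sub = [h[part] for h in halves]
        results.append(Wham(schedule, sub, bins=edges, thermo=thermo).fit(**fit_kw))
    p1 = results[0].pmf.min_zero()
    p2 = results[1].pmf.min_zero()
    both = np.stack([p1.values, p2.values])
    mean = Profile(
        p1.grid,
        both.mean(axis=0),
        stderr=np.std(both, axis=0, ddof=1),
        units="kcal/mol",
        meta={
            "zero": "min",
            "stderr": "half-split sd",
            "converged": results[0].converged and results[1].converged,
        },
    )
    if not mean.meta["converged"]:
        warnings.warn("a half-split WHAM solve did not converge", RuntimeWarning, stacklevel=2)
    return p1, p2, mean


def mae_between_profiles(p1: Profile, p2: Profile, align: str = "min", anchor: float | None = None) -> float:
    """Mean absolute difference between two PMFs after common referencing.

    `align="min"` shifts both profiles min-zero before comparing (constant
    offsets are invisible); `align="anchor"` zeroes both at coordinate
    `anchor` instead (e.g. an unperturbed bulk point). NaN bins present in
    either profile are excluded.
    """
    if p1.grid.shape != p2.grid.shape or not np.allclose(p1.grid, p2.grid):
        raise ValueError("profiles must share an identical grid")
    if align == "min":
        a, b = p1.min_zero(), p2.min_zero()
    elif align == "anchor":
        if anchor is None:
            raise ValueError("anchor coordinate required for align='anchor'")
        a, b = p1.anchored(anchor), p2.anchored(anchor)
    else:
        raise ValueError(f"unknown alignment {align!r}")
    diff = np.abs(a.values - b.values)
    ok = np.isfinite(diff)
    if not ok.any():
        raise ValueError("profiles share no finite bins")
    return float(diff[ok].mean())
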