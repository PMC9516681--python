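"""Self-contained synthetic data with the statistical structure the
analysis pipeline assumes.

A one-dimensional overdamped Langevin walker moves on a membrane-like free
energy G(z) with position-dependent diffusivity D(z), optionally under a
harmonic umbrella restraint; neighboring windows exchange configurations
with Metropolis acceptance, emulating replica-exchange umbrella sampling
along z. A two-state open/closed conformer generator couples dihedral and
3D-frame observables to z so every downstream metric has a ground truth.

The dynamics are Brownian (no inertia): only the stationary density
exp(−β(G+U)) and the local diffusivity matter downstream. With
position-dependent D the Euler–Maruyama step includes the spurious-drift
term D′(z); omitting it would bias the recovered free energy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, NamedTuple

import numpy as np

from .core import (
    ConfigurationError,
    Profile,
    ThermoState,
    TrajectorySeries,
    UmbrellaWindow,
    WindowSchedule,
)
from .metrics import ConformerFrame, DihedralSeries

__all__ = [
    "MembraneModel",
    "make_membrane_model",
    "simulate_langevin",
    "run_us",
    "run_reus",
    "ExchangeLog",
    "IntegrationError",
    "ConformerRules",
    "default_conformer_rules",
    "generate_conformer_series",
    "ConformerEnsemble",
]


class IntegrationError(RuntimeError):
    """The Brownian-dynamics step diverged (time step too large)."""


@dataclass
class MembraneModel:
    """Closed-form membrane free-energy and diffusivity landscape.

    `G`, `dG`, `D`, `dD` are vectorized callables of z (Å) returning
    kcal/mol, kcal/mol/Å, Å²/ps, Å²/ps/Å respectively. z_range is the
    sampled leaflet, [0, z_bulk].
    """

    G: Callable[[np.ndarray], np.ndarray]
    dG: Callable[[np.ndarray], np.ndarray]
    D: Callable[[np.ndarray], np.ndarray]
    dD: Callable[[np.ndarray], np.ndarray]
    z_range: tuple[float, float]
    thermo: ThermoState
    name: str = "custom"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        z = np.linspace(self.z_range[0], self.z_range[1], 1001)
        if np.any(self.D(z) <= 0):
            raise ConfigurationError("D(z) must be positive on the full z range")

    def g_profile(self, n: int = 751) -> Profile:
        z = np.linspace(self.z_range[0], self.z_range[1], n)
        return Profile(z, self.G(z), units="kcal/mol", meta={"model": self.name})

    def d_profile(self, n: int = 751) -> Profile:
        z = np.linspace(self.z_range[0], self.z_range[1], n)
        return Profile(z, self.D(z), units="Å²/ps", meta={"model": self.name})


def _gaussian_sum(amps, centers, widths):
    amps = np.asarray(amps, float)
    centers = np.asarray(centers, float)
    widths = np.asarray(widths, float)

    def g(z):
        z = np.asarray(z, float)
        return np.sum(
            amps * np.exp(-((z[..., None] - centers) ** 2) / (2 * widths**2)), axis=-1
        )

    def dg(z):
        z = np.asarray(z, float)
        dz = z[..., None] - centers
        return np.sum(-amps * dz / widths**2 * np.exp(-(dz**2) / (2 * widths**2)), axis=-1)

    return g, dg


def _sigmoid_logD(d_mem, d_bulk, z_switch, width):
    lm, lb = np.log(d_mem), np.log(d_bulk)

    def D(z):
        z = np.asarray(z, float)
        s = 0.5 * (1 + np.tanh((z - z_switch) / width))
        return np.exp(lm + (lb - lm) * s)

    def dD(z):
        z = np.asarray(z, float)
        s = 0.5 * (1 + np.tanh((z - z_switch) / width))
        ds = 0.5 / (width * np.cosh((z - z_switch) / width) ** 2)
        return np.exp(lm + (lb - lm) * s) * (lb - lm) * ds

    return D, dD


def make_membrane_model(preset: str, thermo: ThermoState | None = None, **params) -> MembraneModel:
    """Build a membrane landscape from a named preset.

    Presets
    -------
    ``flat``
        G ≡ 0, constant D (``d0``, default 0.1 Å²/ps). Free diffusion.
    ``square_barrier``
        A smoothed step of height ``h`` (kcal/mol) for z below half-width
        ``w`` (Å); edge softness ``smooth`` (default 0.5 Å); constant D.
    ``popc_like``
        Bare-phospholipid morphology: a central barrier at z = 0
        (``barrier``, default 4), an interfacial *minimum* near z ≈ 12 Å
        (``well``, default 2.5 deep), a small head-group peak near
        z ≈ 25 Å (``peak``, default 1.0), G → 0 in bulk; D drops from its
        bulk value to a membrane-interior value across the interface.
    ``chol50_like``
        High-cholesterol morphology: the interfacial minimum is gone and G
        rises monotonically from bulk toward the membrane center
        (``barrier``, default 8).
    """
    thermo = thermo or ThermoState(300.0)
    z_bulk = float(params.pop("z_bulk", 37.5))
    zr = (0.0, z_bulk)
    if preset == "flat":
        d0 = float(params.pop("d0", 0.1))
        _check_unused(preset, params)
        zero = lambda z: np.zeros_like(np.asarray(z, float))
        return MembraneModel(
            zero, zero, lambda z: np.full_like(np.asarray(z, float), d0), zero,
            zr, thermo, "flat", {"d0": d0},
        )
    if preset == "square_barrier":
        h = float(params.pop("h", 5.0))
        w = float(params.pop("w", 15.0))
        s = float(params.pop("smooth", 0.5))
        d0 = float(params.pop("d0", 0.1))
        _check_unused(preset, params)

        def G(z):
            return h / (1 + np.exp((np.asarray(z, float) - w) / s))

        def dG(z):
            e = np.exp((np.asarray(z, float) - w) / s)
            return -h * e / (s * (1 + e) ** 2)

        zero = lambda z: np.zeros_like(np.asarray(z, float))
        return MembraneModel(
            G, dG, lambda z: np.full_like(np.asarray(z, float), d0), zero,
            zr, thermo, "square_barrier", {"h": h, "w": w, "smooth": s, "d0": d0},
        )
    if preset == "popc_like":
        barrier = float(params.pop("barrier", 4.0))
        well = float(params.pop("well", 2.5))
        peak = float(params.pop("peak", 1.0))
        d_mem = float(params.pop("d_mem", 0.02))
        d_bulk = float(params.pop("d_bulk", 0.1))
        _check_unused(preset, params)
        G, dG = _gaussian_sum([barrier, -well, peak], [0.0, 12.0, 25.0], [3.5, 3.0, 3.0])
        D, dD = _sigmoid_logD(d_mem, d_bulk, 15.0, 4.0)
        return MembraneModel(
            G, dG, D, dD, zr, thermo, "popc_like",
            {"barrier": barrier, "well": well, "peak": peak, "d_mem": d_mem, "d_bulk": d_bulk},
        )
    if preset == "chol50_like":
        barrier = float(params.pop("barrier", 8.0))
        width = float(params.pop("width", 10.0))
        d_mem = float(params.pop("d_mem", 0.01))
        d_bulk = float(params.pop("d_bulk", 0.1))
        _check_unused(preset, params)
        G, dG = _gaussian_sum([barrier], [0.0], [width])
        D, dD = _sigmoid_logD(d_mem, d_bulk, 15.0, 4.0)
        return MembraneModel(
            G, dG, D, dD, zr, thermo, "chol50_like",
            {"barrier": barrier, "width": width, "d_mem": d_mem, "d_bulk": d_bulk},
        )
    raise ConfigurationError(f"unknown membrane preset {preset!r}")


def _check_unused(preset: str, params: dict) -> None:
    if params:
        raise ConfigurationError(f"unknown parameters for preset {preset!r}: {sorted(params)}")


def _reflect(z: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold positions back into [lo, hi] (reflecting boundaries)."""
    span = hi - lo
    y = np.mod(z - lo, 2 * span)
    return lo + np.minimum(y, 2 * span - y)


def _bd_steps(
    z: np.ndarray,
    n_steps: int,
    dt: float,
    model: MembraneModel,
    k_half: np.ndarray | float | None,
    centers: np.ndarray | float | None,
    rng: np.random.Generator,
    sample_every: int,
    out: list,
    offset: int = 0,
) -> np.ndarray:
    """Advance walkers `z` by `n_steps` Euler–Maruyama steps, appending
    subsampled positions to `out`. `offset` continues the subsampling
    counter across successive calls. Returns the final positions."""
    beta = model.thermo.beta
    lo, hi = model.z_range
    sqrt2dt = np.sqrt(2.0 * dt)
    for i in range(n_steps):
        D = model.D(z)
        force = model.dG(z)
        if k_half is not None:
            force = force + k_half * (z - centers)
        dz = (-beta * D * force + model.dD(z)) * dt + sqrt2dt * np.sqrt(D) * rng.standard_normal(z.shape)
        if np.any(np.abs(dz) > 5.0):
            raise IntegrationError(
                f"divergent Brownian step |Δz| > 5 Å at dt={dt} ps; reduce the time step"
            )
        z = _reflect(z + dz, lo, hi)
        if (offset + i + 1) % sample_every == 0:
            out.append(z.copy())
    return z


def _stability_check(model: MembraneModel, dt: float, k_half: float = 0.0) -> None:
    z = np.linspace(*model.z_range, 501)
    drift = np.abs(model.thermo.beta * model.D(z) * model.dG(z)) + np.abs(model.dD(z))
    spread = (model.z_range[1] - model.z_range[0])
    k_drift = model.thermo.beta * np.max(model.D(z)) * k_half * 2.0  # ~2 Å excursion
    if dt * (np.max(drift) + k_drift) > 0.1 * min(1.0, spread):
        warnings.warn(
            f"dt={dt} ps may be too large for the drift on this landscape",
            RuntimeWarning,
            stacklevel=3,
        )


def simulate_langevin(
    model: MembraneModel,
    bias: UmbrellaWindow | None,
    dt: float,
    n_steps: int,
    seed: int,
    z0: float | None = None,
    sample_every: int = 1,
) -> TrajectorySeries:
    """Overdamped Langevin trajectory of z on G(z) (+ optional umbrella bias).

    Euler–Maruyama: z ← z + [−βD(z)(G+U)′(z) + D′(z)]·dt + √(2D(z)dt)·ξ,
    with reflecting boundaries at the ends of the model's z range. The
    stationary density is ∝ exp(−β(G+U)).
    """
    if n_steps < 1:
        raise ConfigurationError("n_steps must be >= 1")
    rng = np.random.default_rng(seed)
    k_half = None if bias is None else bias.k_half
    center = None if bias is None else bias.center
    _stability_check(model, dt, 0.0 if k_half is None else k_half)
    if z0 is None:
        z0 = center if center is not None else 0.5 * sum(model.z_range)
    z = np.array([float(z0)])
    out: list[np.ndarray] = [z.copy()]
    _bd_steps(z, n_steps, dt, model, k_half, center, rng, sample_every, out)
    return TrajectorySeries(dt * sample_every, np.concatenate(out), t0=0.0, units="Å")


def run_us(
    model: MembraneModel,
    schedule: WindowSchedule,
    dt: float,
    n_steps: int,
    seed: int,
    sample_every: int = 1,
    n_equil_steps: int = 0,
) -> list[TrajectorySeries]:
    """Independent umbrella-sampling runs, one walker per window (no exchange).

    All windows are propagated in lockstep from their restraint centers;
    the first `n_equil_steps` steps are discarded.
    """
    rng = np.random.default_rng(seed)
    centers = schedule.centers
    k_half = schedule.force_constants_half
    _stability_check(model, dt, float(k_half.max()))
    z = centers.astype(float).copy()
    if n_equil_steps:
        z = _bd_steps(z, n_equil_steps, dt, model, k_half, centers, rng, n_equil_steps + 1, [])
    out: list[np.ndarray] = []
    _bd_steps(z, n_steps, dt, model, k_half, centers, rng, sample_every, out)
    samples = np.array(out)  # (n_samples, n_windows)
    return [
        TrajectorySeries(dt * sample_every, samples[:, i], t0=0.0, units="Å")
        for i in range(len(schedule))
    ]


@dataclass
class ExchangeLog:
    """Record of replica-exchange attempts between adjacent windows.

    Arrays are attempt-aligned: `time` (ps), `pair` (lower window index i of
    the attempted (i, i+1) swap), `delta_u` (β-free energy difference ΔU in
    kcal/mol), `draw` (the uniform random number used), `accepted`.
    """

    time: np.ndarray
    pair: np.ndarray
    delta_u: np.ndarray
    draw: np.ndarray
    accepted: np.ndarray
    n_windows: int
    beta: float

    def validate(self) -> None:
        p = np.minimum(1.0, np.exp(-self.beta * self.delta_u))
        if not np.array_equal(self.accepted, self.draw < p):
            raise AssertionError("acceptance flags inconsistent with recorded draws")

    def acceptance_rates(self) -> np.ndarray:
        """Empirical acceptance rate per adjacent pair (NaN if never attempted)."""
        rates = np.full(self.n_windows - 1, np.nan)
        for i in range(self.n_windows - 1):
            sel = self.pair == i
            if np.any(sel):
                rates[i] = self.accepted[sel].mean()
        return rates

    @property
    def mean_acceptance(self) -> float:
        return float(self.accepted.mean())


def run_reus(
    model: MembraneModel,
    schedule: WindowSchedule,
    dt: float,
    n_steps: int,
    exchange_interval_steps: int,
    seed: int,
    sample_every: int = 1,
    n_equil_steps: int = 0,
) -> tuple[list[TrajectorySeries], ExchangeLog]:
    """Replica-exchange umbrella sampling along z (toy Brownian walkers).

    Between exchange attempts each window's walker evolves under its own
    restraint. At each attempt epoch, alternately the even or the odd
    adjacent pairs (i, i+1) propose to swap configurations, accepted with
    the Metropolis probability
    min(1, exp(−β[U_i(z_j) + U_j(z_i) − U_i(z_i) − U_j(z_j)])).
    Returns per-window z series (window-continuous, i.e. each series keeps
    its restraint) and the exchange log.
    """
    if len(schedule) < 2:
        raise ConfigurationError("replica exchange needs at least 2 windows")
    if exchange_interval_steps < 1:
        raise ConfigurationError("exchange_interval_steps must be >= 1")
    rng = np.random.default_rng(seed)
    beta = model.thermo.beta
    centers = schedule.centers
    k_half = schedule.force_constants_half
    _stability_check(model, dt, float(k_half.max()))
    z = centers.astype(float).copy()
    if n_equil_steps:
        z = _bd_steps(z, n_equil_steps, dt, model, k_half, centers, rng, n_equil_steps + 1, [])
    out: list[np.ndarray] = []
    log_t, log_pair, log_du, log_draw, log_acc = [], [], [], [], []
    n_epochs, rem = divmod(n_steps, exchange_interval_steps)
    for epoch in range(n_epochs):
        z = _bd_steps(z, exchange_interval_steps, dt, model, k_half, centers, rng,
                      sample_every, out, offset=epoch * exchange_interval_steps)
        start = epoch % 2  # alternate even / odd adjacent pairs
        pairs = np.arange(start, len(schedule) - 1, 2)
        if pairs.size == 0:
            continue
        zi, zj = z[pairs], z[pairs + 1]
        ui, uj = k_half[pairs], k_half[pairs + 1]
        ci, cj = centers[pairs], centers[pairs + 1]
        du = (
            0.5 * ui * (zj - ci) ** 2
            + 0.5 * uj * (zi - cj) ** 2
            - 0.5 * ui * (zi - ci) ** 2
            - 0.5 * uj * (zj - cj) ** 2
        )
        draw = rng.random(pairs.size)
        acc = draw < np.minimum(1.0, np.exp(-beta * du))
        swap = pairs[acc]
        z[swap], z[swap + 1] = z[swap + 1], z[swap].copy()
        t = (n_equil_steps + (epoch + 1) * exchange_interval_steps) * dt
        log_t.extend([t] * pairs.size)
        log_pair.extend(pairs.tolist())
        log_du.extend(du.tolist())
        log_draw.extend(draw.tolist())
        log_acc.extend(acc.tolist())
    if rem:
        z = _bd_steps(z, rem, dt, model, k_half, centers, rng, sample_every, out,
                      offset=n_epochs * exchange_interval_steps)
    samples = np.array(out)
    series = [
        TrajectorySeries(dt * sample_every, samples[:, i], t0=0.0, units="Å")
        for i in range(len(schedule))
    ]
    log = ExchangeLog(
        np.array(log_t),
        np.array(log_pair, dtype=int),
        np.array(log_du),
        np.array(log_draw),
        np.array(log_acc, dtype=bool),
        n_windows=len(schedule),
        beta=beta,
    )
    return series, log


def exchange_band_schedule() -> WindowSchedule:
    """Uniform schedule whose neighbor exchange acceptance sits in the
    10–20% band on the membrane-like presets at 300 K.

    26 windows at 1.5 Å spacing over [0, 37.5] Å with k = 1.0 kcal/mol/Å²
    (half convention): the restraint width (σ ≈ 0.77 Å) against the 1.5 Å
    spacing gives a mean Metropolis acceptance of roughly 15–20%.
    """
    from .core import build_window_schedule

    return build_window_schedule([(0.0, 37.5, 1.5, 1.0)])


# ---------------------------------------------------------------------------
# Two-state conformer generator
# ---------------------------------------------------------------------------


class ConformerEnsemble(NamedTuple):
    dihedrals: DihedralSeries
    frames: list[ConformerFrame]
    labels: np.ndarray  # True where the generating state was "closed"
    z: np.ndarray


@dataclass
class ConformerRules:
    """Generating rules for the two-state (open/closed) conformer model.

    `closed_probability` maps z (Å) to the probability of the closed state.
    `dihedral_means` holds per-state (n_res, 3) mean (φ, ψ, ω) in degrees;
    `kappa` is the von Mises concentration of the angle noise. `templates`
    holds per-state ConformerFrame geometry; `jitter` is the σ (Å) of the
    Gaussian coordinate noise added per frame (small enough to preserve the
    template's contact geometry).
    """

    closed_probability: Callable[[np.ndarray], np.ndarray]
    dihedral_means: dict[str, np.ndarray]
    templates: dict[str, ConformerFrame]
    kappa: float = 50.0
    jitter: float = 0.03


def _hbond_unit(origin, direction, bonded: bool):
    """One N–H···O=C unit: returns (coords, elements, donor pair, acceptor).

    The donor N sits at `origin`, H 1.0 Å along `direction`; when `bonded`
    the acceptor O continues collinearly at 2.9 Å from N, otherwise it is
    displaced 6 Å away (no hydrogen bond)."""
    u = np.asarray(direction, float)
    u = u / np.linalg.norm(u)
    n = np.asarray(origin, float)
    h = n + 1.0 * u
    o = n + (2.9 if bonded else 6.0) * u
    c = o + 1.23 * np.array([u[1], -u[0], u[2]])  # carbonyl carbon off-axis
    coords = [n, h, o, c]
    elements = ["N", "H", "O", "C"]
    return coords, elements


def _make_template(state: str) -> ConformerFrame:
    """Synthetic stand-in for a cyclic-peptide conformer (not a real
    molecule): four N–H···O units on a 12 Å square, plus a carbon scaffold.

    In the closed state all four units are hydrogen bonded and a ring of
    scaffold carbons sits close enough to partially bury the polar atoms;
    in the open state the units are broken and the scaffold is pushed
    outward, exposing the N/O atoms (higher polar surface area)."""
    bonded = state == "closed"
    corners = [(-6.0, -6.0), (6.0, -6.0), (6.0, 6.0), (-6.0, 6.0)]
    dirs = [(1, 0, 0), (0, 1, 0), (-1, 0, 0), (0, -1, 0)]
    coords: list[np.ndarray] = []
    elements: list[str] = []
    donors: list[tuple[int, int]] = []
    acceptors: list[int] = []
    for (cx, cy), d in zip(corners, dirs):
        base = len(coords)
        xyz, elems = _hbond_unit((cx, cy, 0.0), d, bonded)
        coords.extend(np.asarray(p, float) for p in xyz)
        elements.extend(elems)
        donors.append((base + 1, base))  # (H, N)
        acceptors.append(base + 2)  # O
    # scaffold carbons: a ring above/below the polar plane; tight in the
    # closed state (buries N/O), pushed out in the open state
    r = 7.0 if bonded else 11.0
    zoff = 2.0 if bonded else 4.0
    for i in range(12):
        ang = 2 * np.pi * i / 12
        coords.append(np.array([r * np.cos(ang), r * np.sin(ang), zoff if i % 2 else -zoff]))
        elements.append("C")
    return ConformerFrame(np.array(coords), elements, donors=donors, acceptors=acceptors)


def sigmoid_closed_probability(center: float = 7.0, width: float = 2.0):
    """Closed-state probability decreasing with z: p(z) = σ((center − z)/width).

    Deep in the membrane (small z) the closed, H-bond-shielded conformer
    dominates; in bulk water the open conformer does.
    """

    def p(z):
        return 1.0 / (1.0 + np.exp((np.asarray(z, float) - center) / width))

    return p


def default_conformer_rules(center: float = 7.0, width: float = 2.0) -> ConformerRules:
    """Two-state rules with one cis ω (closed) vs all-trans (open) backbones."""
    n_res = 4
    closed_means = np.tile([-75.0, 100.0, 180.0], (n_res, 1))
    closed_means[0, 2] = 0.0  # one cis peptide bond in the closed state
    open_means = np.tile([-150.0, 155.0, 180.0], (n_res, 1))
    return ConformerRules(
        closed_probability=sigmoid_closed_probability(center, width),
        dihedral_means={"closed": closed_means, "open": open_means},
        templates={"closed": _make_template("closed"), "open": _make_template("open")},
    )


def _wrap_degrees(a: np.ndarray) -> np.ndarray:
    out = np.mod(a + 180.0, 360.0) - 180.0
    out[out == -180.0] = 180.0
    return out


def generate_conformer_series(
    n_frames: int,
    z_series: TrajectorySeries,
    rules: ConformerRules,
    seed: int,
) -> ConformerEnsemble:
    """Emit dihedral series and 3D frames coupled to a z trajectory.

    Frames are drawn at `n_frames` evenly spaced points of `z_series`; at
    each point the state is Bernoulli(closed_probability(z)), dihedrals are
    von Mises about the state's means, and the 3D frame is the state's
    template plus small coordinate jitter. Ground-truth labels are kept.
    """
    if n_frames < 1:
        raise ConfigurationError("n_frames must be >= 1")
    idx = np.linspace(0, len(z_series) - 1, n_frames).round().astype(int)
    z = z_series.values[idx]
    p_closed = np.asarray(rules.closed_probability(z), dtype=float)
    if np.any(p_closed < 0) or np.any(p_closed > 1):
        raise ConfigurationError("closed_probability must map into [0, 1]")
    rng = np.random.default_rng(seed)
    labels = rng.random(n_frames) < p_closed
    n_res = rules.dihedral_means["closed"].shape[0]
    angles = np.empty((n_frames, n_res, 3))
    frames: list[ConformerFrame] = []
    for i, closed in enumerate(labels):
        state = "closed" if closed else "open"
        mu = np.radians(rules.dihedral_means[state])
        angles[i] = _wrap_degrees(np.degrees(rng.vonmises(mu, rules.kappa)))
        tpl = rules.templates[state]
        frames.append(
            ConformerFrame(
                tpl.coords + rules.jitter * rng.standard_normal(tpl.coords.shape),
                tpl.elements,
                tpl.radii.copy(),
                list(tpl.donors),
                list(tpl.acceptors),
                tpl.box,
            )
        )
    return ConformerEnsemble(DihedralSeries(angles), frames, labels, z)
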