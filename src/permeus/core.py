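"""Domain types, physical constants, unit conversions, and replica-schedule
arithmetic shared by every stage of the permeability pipeline.

Conventions used throughout the package:

* energies in kcal/mol, lengths in Å, times in ps, temperatures in K
  (the AMBER unit system);
* the Boltzmann constant is fixed at ``KB = 0.0019872041`` kcal/(mol·K);
* harmonic restraints default to the *half* convention
  ``U(z) = ½ k (z − z0)²``; the *full* convention ``U(z) = k (z − z0)²``
  is supported explicitly because umbrella-sampling tools disagree on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "KB",
    "ThermoState",
    "Profile",
    "TrajectorySeries",
    "UmbrellaWindow",
    "WindowSchedule",
    "TemperatureLadder",
    "rest_lambda",
    "effective_temperature",
    "build_window_schedule",
    "diffusion_unit_convert",
]

#: Boltzmann constant in kcal/(mol·K) (AMBER value).
KB: float = 0.0019872041


class ConfigurationError(ValueError):
    """A schedule, preset, or parameter set is internally inconsistent."""


@dataclass(frozen=True)
class ThermoState:
    """Thermodynamic state of the sampled system.

    Parameters
    ----------
    temperature : float
        Absolute temperature in kelvin. Must be positive.
    """

    temperature: float
    kB: float = KB

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValueError(f"temperature must be > 0 K, got {self.temperature}")

    @property
    def kT(self) -> float:
        """Thermal energy k_B·T in kcal/mol."""
        return self.kB * self.temperature

    @property
    def beta(self) -> float:
        """Inverse temperature β = 1/(k_B·T) in mol/kcal."""
        return 1.0 / self.kT


@dataclass
class Profile:
    """A scalar field sampled on a strictly increasing 1D grid.

    Used for G(z), ΔG(z), D(z), R(z), C_zz(t) and per-z observable means.

    Parameters
    ----------
    grid : array-like
        Strictly increasing coordinates (Å, or ps for lag-time profiles).
    values : array-like
        Field values, same length as `grid`. NaN marks undefined bins.
    stderr : array-like, optional
        Per-point 1σ uncertainty, non-negative where present.
    units : str
        Unit label for `values`.
    meta : dict
        Free-form provenance (zero convention, estimator settings, ...).
    """

    grid: np.ndarray
    values: np.ndarray
    stderr: np.ndarray | None = None
    units: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.ndim != 1:
            raise ValueError("grid must be 1D")
        if not np.all(np.diff(self.grid) > 0):
            raise ValueError("grid must be strictly increasing")
        if self.values.shape != self.grid.shape:
            raise ValueError("values and grid must have identical shape")
        if self.stderr is not None:
            self.stderr = np.asarray(self.stderr, dtype=float)
            if self.stderr.shape != self.grid.shape:
                raise ValueError("stderr and grid must have identical shape")
            with np.errstate(invalid="ignore"):
                if np.any(self.stderr < 0):
                    raise ValueError("stderr must be non-negative")

    def __len__(self) -> int:
        return self.grid.size

    def copy(self) -> "Profile":
        return Profile(
            self.grid.copy(),
            self.values.copy(),
            None if self.stderr is None else self.stderr.copy(),
            self.units,
            dict(self.meta),
        )

    def interp(self, x) -> np.ndarray:
        """Linear interpolation of the values at `x` (constant beyond ends)."""
        return np.interp(np.asarray(x, dtype=float), self.grid, self.values)

    def shifted(self, offset: float) -> "Profile":
        out = self.copy()
        out.values = out.values + offset
        return out

    def min_zero(self) -> "Profile":
        """Shift so the (nan-ignoring) minimum value is exactly zero."""
        out = self.shifted(-np.nanmin(self.values))
        out.meta["zero"] = "min"
        return out

    def anchored(self, z: float) -> "Profile":
        """Shift so the interpolated value at coordinate `z` is zero."""
        out = self.shifted(-float(self.interp(z)))
        out.meta["zero"] = f"anchor@{z:g}"
        return out


@dataclass
class TrajectorySeries:
    """Uniformly spaced time series of one scalar observable.

    Parameters
    ----------
    dt : float
        Sampling interval in ps.
    values : array-like
        Observable samples; must be finite.
    t0 : float
        Time of the first sample in ps.
    units : str
        Unit label of the observable (Å for a reaction coordinate).
    """

    dt: float
    values: np.ndarray
    t0: float = 0.0
    units: str = "Å"

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be 1D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.values.size)

    def halves(self) -> tuple["TrajectorySeries", "TrajectorySeries"]:
        """Split into first-half and second-half series."""
        n = self.values.size // 2
        if n < 1:
            raise ValueError("series too short to split in half")
        return (
            TrajectorySeries(self.dt, self.values[:n], self.t0, self.units),
            TrajectorySeries(self.dt, self.values[n : 2 * n], self.t0 + n * self.dt, self.units),
        )


@dataclass(frozen=True)
class UmbrellaWindow:
    """A harmonic umbrella restraint U(z) about `center`.

    `convention` is ``"half"`` for U = ½k(z−z0)² or ``"full"`` for
    U = k(z−z0)².
    """

    center: float
    k: float
    convention: str = "half"

    def __post_init__(self) -> None:
        # k = 0 is allowed as the degenerate "unbiased window" (plain
        # Boltzmann sampling); negative force constants are not.
        if not self.k >= 0:
            raise ValueError(f"force constant must be >= 0, got {self.k}")
        if self.convention not in ("half", "full"):
            raise ValueError(f"unknown harmonic convention {self.convention!r}")

    @property
    def k_half(self) -> float:
        """Force constant expressed in the half convention U = ½k(z−z0)²."""
        return self.k if self.convention == "half" else 2.0 * self.k

    def as_convention(self, convention: str) -> "UmbrellaWindow":
        if convention == self.convention:
            return self
        if convention == "half":
            return UmbrellaWindow(self.center, 2.0 * self.k, "half")
        if convention == "full":
            return UmbrellaWindow(self.center, self.k / 2.0, "full")
        raise ValueError(f"unknown harmonic convention {convention!r}")

    def energy(self, z) -> np.ndarray:
        dz = np.asarray(z, dtype=float) - self.center
        return 0.5 * self.k_half * dz * dz

    def gradient(self, z) -> np.ndarray:
        return self.k_half * (np.asarray(z, dtype=float) - self.center)


@dataclass
class WindowSchedule:
    """Ordered collection of umbrella windows with strictly increasing centers."""

    windows: list[UmbrellaWindow]

    def __post_init__(self) -> None:
        centers = [w.center for w in self.windows]
        if any(b <= a for a, b in zip(centers, centers[1:])):
            raise ValueError("window centers must be strictly increasing")

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    def __getitem__(self, i) -> UmbrellaWindow:
        return self.windows[i]

    @property
    def centers(self) -> np.ndarray:
        return np.array([w.center for w in self.windows])

    @property
    def force_constants_half(self) -> np.ndarray:
        return np.array([w.k_half for w in self.windows])


@dataclass(frozen=True)
class TemperatureLadder:
    """Solute-tempering rung temperatures; the first rung is the system T."""

    rungs: tuple[float, ...]

    def __post_init__(self) -> None:
        rungs = tuple(float(t) for t in self.rungs)
        object.__setattr__(self, "rungs", rungs)
        if any(t <= 0 for t in rungs):
            raise ValueError("all rung temperatures must be positive")
        if any(b <= a for a, b in zip(rungs, rungs[1:])):
            raise ValueError("rung temperatures must be strictly increasing")

    def __len__(self) -> int:
        return len(self.rungs)

    @property
    def system_temperature(self) -> float:
        return self.rungs[0]

    def lambdas(self) -> np.ndarray:
        """Solute scaling factor λ = T_system/T_rung for every rung."""
        t0 = self.system_temperature
        return np.array([rest_lambda(t0, t) for t in self.rungs])


#: The 8-rung solute-temperature ladder used with 28 umbrella windows
#: (300 K system temperature up to a 980 K effective solute temperature).
DEFAULT_LADDER = TemperatureLadder((300.0, 340.0, 390.0, 455.0, 540.0, 645.0, 785.0, 980.0))


def rest_lambda(T_system: float, T_solute: float) -> float:
    """Solute-tempering scaling factor λ = T_system / T_solute.

    Scaling the solute–solute interaction (and dihedral) energy by λ makes
    the solute sample at the elevated effective temperature T_system/λ
    while the rest of the system stays at T_system.
    """
    if T_system <= 0 or T_solute <= 0:
        raise ValueError("temperatures must be positive")
    return T_system / T_solute


def effective_temperature(lam: float, T_system: float) -> float:
    """Effective solute temperature T_system/λ implied by a scaling factor."""
    if lam <= 0 or T_system <= 0:
        raise ValueError("lambda and temperature must be positive")
    return T_system / lam


def build_window_schedule(
    segments: Sequence[tuple[float, float, float, float]],
    convention: str = "half",
) -> WindowSchedule:
    """Tile reaction-coordinate segments into an umbrella-window schedule.

    Each segment is ``(z_start, z_end, spacing, k)``. The first segment
    contributes windows at both of its endpoints; a later segment whose
    left endpoint coincides with the previous segment's right endpoint
    drops that duplicate, keeping the earlier (finer) segment's window.

    The standard one-leaflet design — (0, 6, 1.0, 1.5) then
    (6, 37.5, 1.5, 0.5) — yields 28 windows.
    """
    if not segments:
        raise ConfigurationError("at least one segment is required")
    windows: list[UmbrellaWindow] = []
    prev_end: float | None = None
    for seg in segments:
        z_start, z_end, spacing, k = (float(x) for x in seg)
        if z_end <= z_start:
            raise ConfigurationError(f"segment end {z_end} must exceed start {z_start}")
        if spacing <= 0:
            raise ConfigurationError("spacing must be positive")
        if prev_end is not None and z_start < prev_end - 1e-9:
            raise ConfigurationError("segments must not overlap")
        n_float = (z_end - z_start) / spacing
        n = round(n_float)
        if abs(n_float - n) > 1e-9 * max(1.0, abs(n_float)):
            raise ConfigurationError(
                f"spacing {spacing} does not evenly tile [{z_start}, {z_end}]"
            )
        centers = z_start + spacing * np.arange(n + 1)
        if prev_end is not None and abs(z_start - prev_end) <= 1e-9:
            centers = centers[1:]  # drop duplicate shared endpoint
        windows.extend(UmbrellaWindow(float(c), k, convention) for c in centers)
        prev_end = z_end
    return WindowSchedule(windows)


#: Segment design of the 28-window one-leaflet schedule:
#: 1.0 Å spacing, k = 1.5 kcal/mol/Å² from 0 to 6 Å near the bilayer center,
#: 1.5 Å spacing, k = 0.5 kcal/mol/Å² from 6 to 37.5 Å out to bulk water.
DEFAULT_SEGMENTS = ((0.0, 6.0, 1.0, 1.5), (6.0, 37.5, 1.5, 0.5))


def default_window_schedule(convention: str = "half") -> WindowSchedule:
    """The 28-window schedule spanning z ∈ [0, 37.5] Å."""
    return build_window_schedule(DEFAULT_SEGMENTS, convention=convention)


def diffusion_unit_convert(D: float) -> float:
    """Convert a diffusion coefficient from Å²/ps to cm²/s.

    1 Å² = 1e−16 cm² and 1 ps = 1e−12 s, hence the factor 1e−4.
    """
    D = float(D)
    if D < 0:
        raise ValueError(f"diffusion coefficient must be >= 0, got {D}")
    return D * 1e-4
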