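"""Membrane permeability from a PMF and a D(z) profile via the modified
inhomogeneous solubility–diffusion model (ISDM).

Local resistance:   R(z) = exp(β·ΔG(z)) / D(z)
Permeability:       P(z_a→z_b) = 1 / ∫_{z_a}^{z_b} R(z) dz

with ΔG(z) referenced to the *global PMF minimum* (not the bulk value):
for a peptide that binds at the membrane interface, escaping that bound
state is part of the permeation barrier. Two endpoint permeabilities are
reported: P_flip, integrated from the PMF minimum z_min to the membrane
center z = 0, and P_out, from z_min to bulk water z = z_bulk. When the
minimum itself lies beyond z = 30 Å (no interfacial binding), P_out is
undefined and P_flip alone is reported.

Unit bookkeeping: with G in kcal/mol, D in Å²/ps and z in Å, ∫R dz is in
ps/Å; multiplying by 1e−4 gives s/cm, so P [cm/s] = 1e4 / ∫R dz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Profile, ThermoState

__all__ = [
    "resistance_profile",
    "permeability_between",
    "symmetrize",
    "SolubilityDiffusionModel",
    "PermeabilityResult",
    "predict",
]

#: z beyond which a PMF minimum counts as "in bulk": no bound interfacial
#: state exists and P_out is undefined.
Z_OUT_EXCLUSION = 30.0


def resistance_profile(pmf: Profile, D: Profile, thermo: ThermoState) -> Profile:
    """Local resistance R(z) = exp(β·ΔG(z))/D(z) on the common grid.

    ΔG is the PMF referenced to its global minimum, so R is invariant to
    constant PMF offsets. Units: ps/Å².
    """
    if pmf.grid.shape != D.grid.shape or not np.allclose(pmf.grid, D.grid):
        raise ValueError("PMF and D profiles must share an identical grid (resample first)")
    if np.any(~np.isfinite(D.values)) or np.any(D.values <= 0):
        raise ValueError("D(z) must be positive and finite everywhere")
    dG = pmf.values - np.nanmin(pmf.values)
    return Profile(
        pmf.grid,
        np.exp(thermo.beta * dG) / D.values,
        units="ps/Å²",
        meta={"reference": "pmf-min", "temperature_K": thermo.temperature},
    )


def _resistance_integral(R: Profile, z_a: float, z_b: float) -> float:
    """∫R dz (ps/Å) between two coordinates by trapezoid on the grid,
    with linearly interpolated endpoint values."""
    lo, hi = sorted((float(z_a), float(z_b)))
    step = np.median(np.diff(R.grid))
    if lo < R.grid[0] - 0.51 * step or hi > R.grid[-1] + 0.51 * step:
        raise ValueError(
            f"integration range [{lo:g}, {hi:g}] extends beyond the R grid "
            f"[{R.grid[0]:g}, {R.grid[-1]:g}] by more than half a bin"
        )
    inner = R.grid[(R.grid > lo) & (R.grid < hi)]
    nodes = np.concatenate(([lo], inner, [hi]))
    vals = np.interp(nodes, R.grid, R.values)
    if np.any(~np.isfinite(vals)):
        raise ValueError("undefined (NaN) resistance inside the integration range")
    return float(np.trapezoid(vals, nodes))


def permeability_between(R: Profile, z_a: float, z_b: float) -> float:
    """Permeability P = 1/∫R dz between two coordinates, in cm/s."""
    if z_a == z_b:
        raise ValueError("degenerate interval: z_a equals z_b")
    return 1e4 / _resistance_integral(R, z_a, z_b)


def symmetrize(profile: Profile) -> Profile:
    """Mirror a one-leaflet profile about z = 0 to span [−z_bulk, z_bulk].

    The membrane is assumed symmetric across its center, so the profile
    computed on one leaflet supplies the other. The z = 0 point is shared.
    Symmetrizing an already mirrored profile is the identity.
    """
    if abs(profile.grid[0]) > 1e-9:
        n = len(profile)
        symmetric = (
            n % 2 == 1
            and np.allclose(profile.grid, -profile.grid[::-1])
            and np.allclose(profile.values, profile.values[::-1])
        )
        if symmetric:  # already mirrored: idempotent
            return profile.copy()
        raise ValueError("grid must start at z = 0 to symmetrize")
    grid = np.concatenate((-profile.grid[:0:-1], profile.grid))
    values = np.concatenate((profile.values[:0:-1], profile.values))
    err = None
    if profile.stderr is not None:
        err = np.concatenate((profile.stderr[:0:-1], profile.stderr))
    out = Profile(grid, values, stderr=err, units=profile.units, meta=dict(profile.meta))
    out.meta["symmetrized"] = True
    return out


@dataclass
class PermeabilityResult:
    """ISDM permeability prediction.

    All permeabilities are in cm/s; `P_out` is None when the PMF minimum
    lies beyond the exclusion coordinate (no interfacial state). `headline`
    combines the defined endpoint values by the rule in `combination`
    (default: the rate-limiting, i.e. smaller, one).
    """

    z_min: float
    P_flip: float | None
    P_out: float | None
    headline: float
    combination: str
    stderr_log10: float | None = None
    meta: dict | None = None

    @staticmethod
    def _log10(p: float | None) -> float | None:
        return None if p is None else float(np.log10(p))

    @property
    def log10_P_flip(self) -> float | None:
        return self._log10(self.P_flip)

    @property
    def log10_P_out(self) -> float | None:
        return self._log10(self.P_out)

    @property
    def log10_headline(self) -> float:
        return float(np.log10(self.headline))

    def summary(self) -> str:
        def fmt(p):
            return "undefined" if p is None else f"{p:.3e} cm/s  (log10 = {np.log10(p):.2f})"

        lines = [
            "Inhomogeneous solubility-diffusion permeability",
            "=" * 52,
            f"PMF minimum z_min:  {self.z_min:.2f} Å",
            f"P_flip  [z_min→0]:      {fmt(self.P_flip)}",
            f"P_out   [z_min→bulk]:   {fmt(self.P_out)}",
            f"headline ({self.combination}):  {fmt(self.headline)}",
        ]
        if self.stderr_log10 is not None:
            lines.append(f"sd(log10 P) half-split: {self.stderr_log10:.2f}")
        return "\n".join(lines)


class SolubilityDiffusionModel:
    """Modified-ISDM permeability model built from a PMF and a D(z) profile.

    Parameters
    ----------
    pmf : Profile
        Free-energy profile over (at least) [0, z_bulk] Å; any zero
        convention (internally re-referenced to its minimum).
    diffusion : Profile
        Position-dependent diffusivity in Å²/ps; interpolated log-linearly
        onto the PMF grid if the grids differ.
    thermo : ThermoState
    z_bulk : float
        Coordinate treated as bulk water (default 37.5 Å).
    combination : {"min", "flip", "out"}
        How the headline value combines P_flip and P_out when both exist.
    """

    def __init__(
        self,
        pmf: Profile,
        diffusion: Profile,
        thermo: ThermoState | None = None,
        z_bulk: float = 37.5,
        combination: str = "min",
    ) -> None:
        if combination not in ("min", "flip", "out"):
            raise ValueError(f"unknown combination rule {combination!r}")
        self.thermo = thermo or ThermoState(300.0)
        self.z_bulk = float(z_bulk)
        self.combination = combination
        step = np.median(np.diff(pmf.grid))
        if pmf.grid[0] > 0.51 * step or pmf.grid[-1] < self.z_bulk - 0.51 * step:
            raise ValueError(
                f"PMF grid [{pmf.grid[0]:g}, {pmf.grid[-1]:g}] does not cover "
                f"[0, {self.z_bulk:g}] Å"
            )
        self.pmf = pmf
        if diffusion.grid.shape == pmf.grid.shape and np.allclose(diffusion.grid, pmf.grid):
            self.diffusion = diffusion
        else:
            vals = np.exp(np.interp(pmf.grid, diffusion.grid, np.log(diffusion.values)))
            self.diffusion = Profile(pmf.grid, vals, units=diffusion.units,
                                     meta={**diffusion.meta, "resampled": True})

    def resistance(self) -> Profile:
        return resistance_profile(self.pmf, self.diffusion, self.thermo)

    def _z_min(self) -> float:
        finite = np.isfinite(self.pmf.values)
        vmin = np.min(self.pmf.values[finite])
        # ties broken toward bulk: the bulk-most minimizing grid point gives
        # the longer, more conservative flip path
        ties = np.nonzero(finite & (self.pmf.values <= vmin + 1e-12))[0]
        return float(self.pmf.grid[ties[-1]])

    def fit(self, pmf_halves: tuple[Profile, Profile] | None = None) -> PermeabilityResult:
        """Evaluate the endpoint permeabilities.

        `pmf_halves` (independent first/second-half PMFs) propagates a
        half-split standard deviation of log10(headline P).
        """
        res = self._evaluate(self.pmf)
        if pmf_halves is not None:
            logs = []
            for half in pmf_halves:
                m = SolubilityDiffusionModel(
                    half, self.diffusion, self.thermo, self.z_bulk, self.combination
                )
                logs.append(m.fit().log10_headline)
            res.stderr_log10 = float(np.std(logs, ddof=1))
        return res

    def _evaluate(self, pmf: Profile) -> PermeabilityResult:
        R = resistance_profile(pmf, self.diffusion, self.thermo)
        finite = np.isfinite(pmf.values)
        vmin = np.min(pmf.values[finite])
        ties = np.nonzero(finite & (pmf.values <= vmin + 1e-12))[0]
        z_min = float(pmf.grid[ties[-1]])
        P_flip = permeability_between(R, 0.0, z_min) if z_min > 0 else None
        if z_min > Z_OUT_EXCLUSION or z_min >= self.z_bulk:
            P_out = None
        else:
            P_out = permeability_between(R, z_min, self.z_bulk)
        defined = [p for p in (P_flip, P_out) if p is not None]
        if not defined:
            raise ValueError("both endpoint permeabilities are degenerate")
        if self.combination == "min" or (self.combination == "flip" and P_flip is None) or (
            self.combination == "out" and P_out is None
        ):
            headline = min(defined)
        elif self.combination == "flip":
            headline = P_flip
        else:
            headline = P_out
        return PermeabilityResult(
            z_min=z_min,
            P_flip=P_flip,
            P_out=P_out,
            headline=headline,
            combination=self.combination,
            meta={"z_bulk": self.z_bulk, "T": self.thermo.temperature},
        )


def predict(
    pmf: Profile,
    diffusion: Profile,
    thermo: ThermoState | None = None,
    z_bulk: float = 37.5,
    combination: str = "min",
    pmf_halves: tuple[Profile, Profile] | None = None,
) -> PermeabilityResult:
    """One-call ISDM prediction (model construction + fit)."""
    return SolubilityDiffusionModel(pmf, diffusion, thermo, z_bulk, combination).fit(pmf_halves)
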