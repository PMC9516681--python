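"""Conformational and membrane observables profiled along the membrane
normal: peptide–water hydrogen bonds, polar surface area (PSA), dihedral
principal component analysis with closed-conformation fractions and cis-ω
counts, the inertia short-axis tilt, and area per lipid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Profile

__all__ = [
    "ConformerFrame",
    "DihedralSeries",
    "PcaModel",
    "count_hbonds",
    "profile_by_z",
    "sasa",
    "psa",
    "dihedral_pca",
    "closed_fraction",
    "hbond_classifier",
    "pc_box_classifier",
    "count_cis_omega",
    "short_axis_angle",
    "area_per_lipid",
    "VDW_RADII",
]

#: Default van der Waals radii (Å) by element, Bondi-style values.
VDW_RADII = {"H": 1.2, "C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "P": 1.8}


@dataclass
class ConformerFrame:
    """One labeled 3D conformer snapshot.

    Parameters
    ----------
    coords : (n, 3) array
        Cartesian coordinates in Å.
    elements : sequence of str
        Element symbol per atom.
    radii : (n,) array, optional
        Van der Waals radii in Å; defaults are looked up by element.
    donors : sequence of (h_index, heavy_index)
        Polar hydrogens with the heavy donor atom they are bonded to.
    acceptors : sequence of int
        Indices of hydrogen-bond acceptor atoms.
    box : (Lx, Ly, Lz) or None
        Orthorhombic box dimensions in Å, when periodic context matters.
    """

    coords: np.ndarray
    elements: list[str]
    radii: np.ndarray | None = None
    donors: list[tuple[int, int]] = field(default_factory=list)
    acceptors: list[int] = field(default_factory=list)
    box: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n, 3)")
        n = self.coords.shape[0]
        self.elements = list(self.elements)
        if len(self.elements) != n:
            raise ValueError("one element label per atom required")
        if self.radii is None:
            self.radii = np.array([VDW_RADII.get(e, 1.7) for e in self.elements])
        else:
            self.radii = np.asarray(self.radii, dtype=float)
        if self.radii.shape != (n,) or np.any(self.radii <= 0):
            raise ValueError("radii must be positive, one per atom")
        for h, d in self.donors:
            if not (0 <= h < n and 0 <= d < n) or h == d:
                raise ValueError(f"donor pair ({h}, {d}) out of range")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]


@dataclass
class DihedralSeries:
    """Backbone dihedral angles per frame and residue.

    `angles` has shape (n_frames, n_residues, 3) with the last axis ordered
    (φ, ψ, ω), in degrees on (−180, 180].
    """

    angles: np.ndarray

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.ndim != 3 or self.angles.shape[2] != 3:
            raise ValueError("angles must have shape (n_frames, n_residues, 3)")
        if np.any(self.angles <= -180.0) or np.any(self.angles > 180.0):
            raise ValueError("angles must lie in (-180, 180] degrees")

    @property
    def n_frames(self) -> int:
        return self.angles.shape[0]

    @property
    def n_residues(self) -> int:
        return self.angles.shape[1]

    @property
    def omega(self) -> np.ndarray:
        return self.angles[:, :, 2]


def count_hbonds(
    frame: ConformerFrame,
    donor_atoms=None,
    acceptor_atoms=None,
    d_max: float = 3.5,
    angle_min: float = 135.0,
) -> int:
    """Count geometric hydrogen bonds in one frame.

    A (donor-H, acceptor) pair is counted when the donor-heavy → acceptor
    distance is ≤ `d_max` Å and the D–H···A angle at the hydrogen is
    ≥ `angle_min` degrees. `donor_atoms` / `acceptor_atoms` restrict the
    donor heavy atoms and acceptors considered (e.g. peptide donors vs
    water acceptors); `None` means all. Pairs where the acceptor is the
    donor heavy atom itself are skipped.
    """
    if not frame.donors or not frame.acceptors:
        raise ValueError("frame has no donor/acceptor role assignments")
    donor_set = None if donor_atoms is None else set(donor_atoms)
    acc = [a for a in frame.acceptors if acceptor_atoms is None or a in set(acceptor_atoms)]
    count = 0
    X = frame.coords
    for h, d in frame.donors:
        if donor_set is not None and d not in donor_set:
            continue
        for a in acc:
            if a == d or a == h:
                continue
            if np.linalg.norm(X[a] - X[d]) > d_max:
                continue
            v1 = X[d] - X[h]
            v2 = X[a] - X[h]
            n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
            if n1 == 0 or n2 == 0:
                continue
            cosang = np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0)
            if np.degrees(np.arccos(cosang)) >= angle_min:
                count += 1
    return count


def profile_by_z(values, z, bins) -> Profile:
    """Bin a per-frame observable by the frame's z coordinate.

    Returns per-bin means with a first-half/second-half split standard
    deviation as `stderr`. Bins with no frames are NaN; bins whose halves
    are not both populated get NaN stderr.
    """
    values = np.asarray(values, dtype=float)
    z = np.asarray(z, dtype=float)
    if values.shape != z.shape:
        raise ValueError("values and z must be frame-aligned")
    edges = np.asarray(bins, dtype=float) if np.ndim(bins) else np.histogram_bin_edges(z, int(bins))
    centers = 0.5 * (edges[:-1] + edges[1:])
    idx = np.digitize(z, edges) - 1
    n_half = values.size // 2
    mean = np.full(centers.size, np.nan)
    err = np.full(centers.size, np.nan)
    for m in range(centers.size):
        sel = idx == m
        if not np.any(sel):
            continue
        mean[m] = values[sel].mean()
        h1 = values[: n_half][sel[:n_half]]
        h2 = values[n_half:][sel[n_half:]]
        if h1.size and h2.size:
            err[m] = np.std([h1.mean(), h2.mean()], ddof=1)
    return Profile(centers, mean, stderr=err, units="", meta={"stderr": "half-split sd"})


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )


def sasa(frame: ConformerFrame, probe_radius: float = 1.4, n_sphere_points: int = 960) -> np.ndarray:
    """Per-atom solvent-accessible surface area via Shrake–Rupley sampling.

    Each atom's accessible sphere (radius r_i + probe) is sampled with a
    deterministic golden-spiral point set; points inside any neighbor's
    accessible sphere are occluded. Returns areas in Å².
    """
    X = frame.coords
    n = frame.n_atoms
    R = frame.radii + probe_radius
    d2 = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=-1)
    np.fill_diagonal(d2, np.inf)
    if np.any(d2 < 1e-12):
        raise ValueError("two atoms share identical coordinates")
    pts = _sphere_points(n_sphere_points)
    areas = np.empty(n)
    for i in range(n):
        neighbors = np.where(d2[i] < (R[i] + R) ** 2)[0]
        surface = X[i] + R[i] * pts
        accessible = np.ones(n_sphere_points, dtype=bool)
        for j in neighbors:
            dj = np.sum((surface - X[j]) ** 2, axis=1)
            accessible &= dj > R[j] ** 2
        areas[i] = 4.0 * np.pi * R[i] ** 2 * accessible.mean()
    return areas


def psa(frame: ConformerFrame, probe_radius: float = 1.4, n_sphere_points: int = 960) -> float:
    """Polar surface area: accessible surface area summed over N and O atoms."""
    polar = np.array([e in ("N", "O") for e in frame.elements])
    if not polar.any():
        return 0.0
    return float(sasa(frame, probe_radius, n_sphere_points)[polar].sum())


@dataclass
class PcaModel:
    """PCA of the sin/cos dihedral embedding.

    `mean` is the embedding mean (length 6·n_residues), `components` the
    orthonormal eigenvectors as rows in descending-eigenvalue order.
    """

    mean: np.ndarray
    components: np.ndarray
    eigenvalues: np.ndarray

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()

    def transform(self, series: DihedralSeries) -> np.ndarray:
        emb = _embed(series)
        return (emb - self.mean) @ self.components.T


def _embed(series: DihedralSeries) -> np.ndarray:
    """Frame embedding: (sin, cos) of every (φ, ψ, ω), shape (n_frames, 6·n_res)."""
    rad = np.radians(series.angles)
    emb = np.concatenate([np.sin(rad), np.cos(rad)], axis=2)
    return emb.reshape(series.n_frames, -1)


def dihedral_pca(series: DihedralSeries) -> tuple[PcaModel, np.ndarray]:
    """Principal component analysis on the sin/cos embedding of (φ, ψ, ω).

    Returns the fitted model and the per-frame projections. The circular
    embedding avoids the ±180° wrap artifact of raw angles.
    """
    if series.n_frames < 2:
        raise ValueError("at least two frames are required")
    emb = _embed(series)
    mean = emb.mean(axis=0)
    centered = emb - mean
    cov = centered.T @ centered / (series.n_frames - 1)
    if np.allclose(cov, 0):
        raise ValueError("degenerate input: dihedral embedding has zero variance")
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    model = PcaModel(mean=mean, components=evecs[:, order].T, eigenvalues=evals)
    return model, centered @ model.components.T


def pc_box_classifier(pc_index: int = 0, bounds: tuple[float, float] = (2.0, 3.0)):
    """Classifier marking frames whose projection on one PC falls in a box.

    The default box (PC1 between 2 and 3) is dataset-specific: the region
    must be read off a projection scatter for each system.
    """

    lo, hi = bounds

    def classify(projection: np.ndarray) -> bool:
        return lo <= projection[pc_index] <= hi

    return classify


def hbond_classifier(min_hbonds: int = 3, d_max: float = 3.5, angle_min: float = 135.0):
    """Classifier marking frames with ≥ `min_hbonds` intramolecular H-bonds.

    Transferable across systems: a closed conformer shields its polar
    groups with intramolecular hydrogen bonds.
    """

    def classify(frame: ConformerFrame) -> bool:
        return count_hbonds(frame, d_max=d_max, angle_min=angle_min) >= min_hbonds

    return classify


def closed_fraction(items, classifier) -> float:
    """Fraction of frames (or projections) classified as closed."""
    items = list(items)
    if not items:
        raise ValueError("empty input")
    return sum(bool(classifier(x)) for x in items) / len(items)


def count_cis_omega(series: DihedralSeries) -> np.ndarray:
    """Per-frame count of residues with a cis peptide bond (|ω| < 90°).

    Exactly ±90° counts as trans.
    """
    return np.sum(np.abs(series.omega) < 90.0, axis=1)


def short_axis_angle(coords, masses=None, axis=(0.0, 0.0, 1.0)) -> float:
    """Tilt of the inertial short axis relative to `axis`, in degrees [0, 90].

    The short axis is the principal axis of inertia with the *largest*
    eigenvalue (mass is most spread perpendicular to it). Unit masses are
    assumed unless `masses` is given. Degenerate top eigenvalues (collinear
    or spherically symmetric geometry) raise ValueError because the axis is
    then undefined.
    """
    X = np.asarray(coords, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3 or X.shape[0] < 3:
        raise ValueError("need at least 3 points of shape (n, 3)")
    m = np.ones(X.shape[0]) if masses is None else np.asarray(masses, dtype=float)
    com = np.average(X, axis=0, weights=m)
    Y = X - com
    r2 = np.sum(Y**2, axis=1)
    inertia = np.diag((m * r2).sum() * np.ones(3)) - np.einsum("i,ij,ik->jk", m, Y, Y)
    evals, evecs = np.linalg.eigh(inertia)
    if evals[2] - evals[1] <= 1e-9 * max(evals[2], 1e-30):
        raise ValueError("degenerate inertia tensor: short axis undefined")
    short = evecs[:, 2]
    a = np.asarray(axis, dtype=float)
    cosang = abs(short @ a) / (np.linalg.norm(short) * np.linalg.norm(a))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def area_per_lipid(box_xy: tuple[float, float], n_lipids_per_leaflet: int) -> float:
    """Lateral box area divided by lipids per leaflet, in Å²."""
    if n_lipids_per_leaflet <= 0:
        raise ValueError("n_lipids_per_leaflet must be positive")
    lx, ly = box_xy
    return float(lx) * float(ly) / n_lipids_per_leaflet
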