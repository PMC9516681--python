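"""Readers and writers for the text formats the pipeline exchanges.

* umbrella metadata + per-window time series in the whitespace-delimited
  dialect of the Grossfield WHAM tool (one metadata line per window:
  ``timeseries-path  center  spring-constant [correl-time] [temperature]``,
  '#' comments), so synthetic datasets can drive third-party WHAM too;
* profiles as TSV with '#' headers recording units and conventions;
* permeability results as JSON;
* conformer frames as extended XYZ with radius/role columns.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .core import Profile, TrajectorySeries, UmbrellaWindow, WindowSchedule
from .metrics import ConformerFrame
from .permeability import PermeabilityResult

__all__ = [
    "read_wham_metadata",
    "write_wham_dataset",
    "write_profile_tsv",
    "read_profile_tsv",
    "write_permeability_json",
    "read_permeability_json",
    "write_frames_xyz",
    "read_frames_xyz",
    "ParseError",
]


class ParseError(ValueError):
    """A text input file violates its documented format."""


def write_wham_dataset(
    directory,
    schedule: WindowSchedule,
    series: list[TrajectorySeries],
    convention: str = "half",
    name: str = "metadata",
) -> Path:
    """Write per-window time series plus a metadata file; returns its path.

    Spring constants are written in the requested harmonic convention
    (recorded in the header comment).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    lines = [
        "# umbrella-sampling metadata (Grossfield-WHAM dialect)",
        f"# columns: timeseries-file  center[Å]  k[kcal/mol/Å²] ({convention} convention"
        + (", U = ½k(z−z0)²)" if convention == "half" else ", U = k(z−z0)²)"),
    ]
    for i, (w, s) in enumerate(zip(schedule, series)):
        fname = f"window_{i:03d}.dat"
        ts_path = directory / fname
        data = np.column_stack([s.times, s.values])
        np.savetxt(ts_path, data, fmt="%.6f %.8f", header="time[ps] z[Å]")
        k = w.as_convention(convention).k
        lines.append(f"{fname} {w.center:.6f} {k:.6f}")
    meta_path = directory / name
    meta_path.write_text("\n".join(lines) + "\n")
    return meta_path


def read_wham_metadata(path, convention: str = "half") -> tuple[WindowSchedule, list[TrajectorySeries]]:
    """Read a metadata file and its per-window time series.

    `convention` states which harmonic convention the file's spring
    constants use; they are converted to the package-internal half
    convention. Timeseries files are resolved relative to the metadata
    file's directory and must have a uniformly increasing time column.
    """
    path = Path(path)
    windows: list[UmbrellaWindow] = []
    series: list[TrajectorySeries] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) < 3:
            raise ParseError(f"{path}:{lineno}: expected 'file center k', got {raw!r}")
        fname = parts[0]
        try:
            center, k = float(parts[1]), float(parts[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric center/spring: {raw!r}") from exc
        ts_path = path.parent / fname
        if not ts_path.exists():
            raise ParseError(f"{path}:{lineno}: timeseries file not found: {ts_path}")
        series.append(_read_timeseries(ts_path))
        windows.append(UmbrellaWindow(center, k, convention).as_convention("half"))
    if not windows:
        raise ParseError(f"{path}: no window records found")
    order = np.argsort([w.center for w in windows])
    return (
        WindowSchedule([windows[i] for i in order]),
        [series[i] for i in order],
    )


def _read_timeseries(path: Path) -> TrajectorySeries:
    t_list, v_list = [], []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ParseError(f"{path}:{lineno}: expected 'time value', got {raw!r}")
        try:
            t_list.append(float(parts[0]))
            v_list.append(float(parts[1]))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric entry: {raw!r}") from exc
    t = np.asarray(t_list)
    if t.size < 2:
        raise ParseError(f"{path}: need at least two samples")
    dts = np.diff(t)
    if np.any(dts <= 0):
        raise ParseError(f"{path}: time column must be strictly increasing")
    return TrajectorySeries(float(dts.mean()), np.asarray(v_list), t0=float(t[0]))


def write_profile_tsv(profile: Profile, path, label: str = "value") -> None:
    """Profile as TSV: '#'-prefixed header (units, conventions), then
    columns z, value[, stderr]."""
    path = Path(path)
    header = [f"units: {profile.units}"]
    header += [f"{k}: {v}" for k, v in sorted(profile.meta.items(), key=lambda kv: str(kv[0]))]
    cols = [profile.grid, profile.values]
    names = ["z", label]
    if profile.stderr is not None:
        cols.append(profile.stderr)
        names.append("stderr")
    header.append("columns: " + "\t".join(names))
    np.savetxt(path, np.column_stack(cols), fmt="%.8g", delimiter="\t", header="\n".join(header))


def read_profile_tsv(path) -> Profile:
    path = Path(path)
    meta: dict = {}
    units = ""
    for raw in path.read_text().splitlines():
        if not raw.startswith("#"):
            break
        body = raw.lstrip("# ").rstrip()
        if ": " in body:
            key, val = body.split(": ", 1)
            if key == "units":
                units = val
            elif key != "columns":
                meta[key] = val
    data = np.loadtxt(path, delimiter="\t", ndmin=2)
    stderr = data[:, 2] if data.shape[1] > 2 else None
    return Profile(data[:, 0], data[:, 1], stderr=stderr, units=units, meta=meta)


def write_permeability_json(result: PermeabilityResult, path) -> None:
    payload = {
        "z_min_A": result.z_min,
        "P_flip_cm_s": result.P_flip,
        "P_out_cm_s": result.P_out,
        "headline_cm_s": result.headline,
        "log10_P_flip": result.log10_P_flip,
        "log10_P_out": result.log10_P_out,
        "log10_headline": result.log10_headline,
        "combination": result.combination,
        "stderr_log10": result.stderr_log10,
        "meta": result.meta,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_permeability_json(path) -> dict:
    return json.loads(Path(path).read_text())


def write_frames_xyz(frames: list[ConformerFrame], path) -> None:
    """Extended XYZ: per-atom ``element x y z radius role`` where role is
    ``A`` (acceptor), ``D:<heavy-index>`` (donor hydrogen) or ``-``."""
    out = []
    for frame in frames:
        roles = ["-"] * frame.n_atoms
        for a in frame.acceptors:
            roles[a] = "A"
        for h, d in frame.donors:
            roles[h] = f"D:{d}"
        out.append(str(frame.n_atoms))
        box = "" if frame.box is None else " box=" + ",".join(f"{b:g}" for b in frame.box)
        out.append(f"element x y z radius role{box}")
        for e, (x, y, z), r, role in zip(frame.elements, frame.coords, frame.radii, roles):
            out.append(f"{e} {x:.6f} {y:.6f} {z:.6f} {r:.4f} {role}")
    Path(path).write_text("\n".join(out) + "\n")


def read_frames_xyz(path) -> list[ConformerFrame]:
    lines = Path(path).read_text().splitlines()
    frames: list[ConformerFrame] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise ParseError(f"{path}:{i + 1}: expected atom count") from exc
        comment = lines[i + 1]
        box = None
        if "box=" in comment:
            box = tuple(float(x) for x in comment.split("box=")[1].split()[0].split(","))
        coords, elements, radii, donors, acceptors = [], [], [], [], []
        for j in range(n):
            parts = lines[i + 2 + j].split()
            elements.append(parts[0])
            coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
            radii.append(float(parts[4]))
            role = parts[5]
            if role == "A":
                acceptors.append(j)
            elif role.startswith("D:"):
                donors.append((j, int(role[2:])))
        frames.append(
            ConformerFrame(np.array(coords), elements, np.array(radii), donors, acceptors, box)
        )
        i += 2 + n
    return frames
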