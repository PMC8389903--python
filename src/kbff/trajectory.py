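"""Trajectory and scalar time-series containers and text I/O.

The single data gateway for all estimators.  Supported on-disk formats:

* ``csv`` — the canonical tabular dialect: a first comment line
  ``# kbff-trajectory {json metadata}`` carrying ``box_length_nm`` and
  ``dt_ps``, then columns ``frame, particle, species, x, y, z``
  (coordinates in nm, optional ``charge`` column in e).
* ``gro`` — concatenated GROMACS coordinate frames (fixed-width text,
  coordinates in nm, cubic box line).
* ``xyz`` — multi-frame XYZ with coordinates in nm and the box length
  carried on the comment line as ``box_length=<nm> time=<ps>``.

Coordinates are stored exactly as read (wrapped by default); unwrapping
for mean-squared displacements is the separate explicit operation
:func:`unwrap`.  Boxes are cubic only; anything else is rejected loudly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Frame",
    "Trajectory",
    "ScalarSeries",
    "read_trajectory",
    "write_trajectory",
    "unwrap",
    "wrap",
    "minimum_image_displacement",
]


@dataclass(frozen=True)
class Frame:
    """One stored configuration: positions (n, 3) in nm, cubic box, time."""

    positions: np.ndarray
    box_length: float
    time: float = 0.0


@dataclass
class Trajectory:
    """Frames of labeled particles in a cubic periodic box.

    positions has shape (n_frames, n_particles, 3) in nm; ``species``
    and ``charges`` are per-particle; ``dt`` is the constant spacing in
    ps between stored frames.
    """

    positions: np.ndarray
    box_length: float
    species: np.ndarray
    charges: np.ndarray = None
    dt: float = 1.0
    time0: float = 0.0

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError(
                f"positions must have shape (n_frames, n_particles, 3), "
                f"got {self.positions.shape}"
            )
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates in trajectory")
        if self.box_length <= 0:
            raise ValueError(f"box_length must be > 0, got {self.box_length}")
        self.species = np.asarray(self.species, dtype=object)
        if self.species.shape[0] != self.n_particles:
            raise ValueError(
                f"species labels ({self.species.shape[0]}) do not match "
                f"particle count ({self.n_particles})"
            )
        if self.charges is None:
            self.charges = np.zeros(self.n_particles)
        self.charges = np.asarray(self.charges, dtype=float)
        if self.charges.shape[0] != self.n_particles:
            raise ValueError("charges array does not match particle count")
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_particles(self) -> int:
        return self.positions.shape[1]

    @property
    def volume(self) -> float:
        return self.box_length**3

    @property
    def times(self) -> np.ndarray:
        return self.time0 + self.dt * np.arange(self.n_frames)

    def __getitem__(self, i: int) -> Frame:
        return Frame(self.positions[i], self.box_length, float(self.times[i]))

    def select(self, species: str) -> np.ndarray:
        """Indices of particles with the given species label."""
        return np.flatnonzero(self.species == species)

    def number_density(self, species: str) -> float:
        return len(self.select(species)) / self.volume


@dataclass
class ScalarSeries:
    """Per-frame scalar or 3-vector observable (e.g. box dipole, ion current)."""

    values: np.ndarray
    dt: float
    name: str = ""
    time0: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim not in (1, 2):
            raise ValueError("values must be (n,) or (n, d)")
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.time0 + self.dt * np.arange(len(self))

    def to_csv(self, path) -> None:
        vals = np.atleast_2d(self.values.T).T
        cols = ["value"] if vals.shape[1] == 1 else ["vx", "vy", "vz"][: vals.shape[1]]
        df = pd.DataFrame(vals, columns=cols)
        df.insert(0, "time", self.times)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, name: str = "") -> "ScalarSeries":
        df = pd.read_csv(path)
        if "time" not in df.columns:
            raise ValueError(f"{path}: missing 'time' column")
        t = df["time"].to_numpy(dtype=float)
        if len(t) < 2:
            raise ValueError(f"{path}: need at least two samples")
        dts = np.diff(t)
        if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-12):
            raise ValueError(f"{path}: time column is not uniformly spaced")
        data = df.drop(columns="time").to_numpy(dtype=float)
        values = data[:, 0] if data.shape[1] == 1 else data
        return cls(values=values, dt=float(dts[0]), name=name, time0=float(t[0]))


# ---------------------------------------------------------------------------
# periodic geometry helpers

def minimum_image_displacement(delta: np.ndarray, box_length: float) -> np.ndarray:
    """Minimum-image convention applied to displacement vectors."""
    return delta - box_length * np.round(delta / box_length)


def wrap(traj: Trajectory) -> Trajectory:
    """Wrap all coordinates into the primary box [0, L)."""
    pos = np.mod(traj.positions, traj.box_length)
    return Trajectory(pos, traj.box_length, traj.species, traj.charges,
                      traj.dt, traj.time0)


def unwrap(traj: Trajectory) -> Trajectory:
    """Undo periodic re-imaging, producing continuous particle tracks.

    Assumes no particle moves more than L/2 between stored frames; a
    frame-to-frame minimum-image step at (or numerically beyond) L/2 is
    ambiguous and raises.  Re-wrapping the output reproduces the input.
    """
    L = traj.box_length
    disp = np.diff(traj.positions, axis=0)
    disp_mi = minimum_image_displacement(disp, L)
    limit = 0.5 * L * (1.0 - 1e-9)
    bad = np.abs(disp_mi) >= limit
    if np.any(bad):
        f = int(np.argwhere(bad)[0][0]) + 1
        raise ValueError(
            f"ambiguous unwrapping: displacement of at least L/2 between "
            f"frames {f - 1} and {f}; store frames more often"
        )
    pos = np.concatenate(
        [traj.positions[:1], traj.positions[0] + np.cumsum(disp_mi, axis=0)],
        axis=0,
    )
    return Trajectory(pos, L, traj.species, traj.charges, traj.dt, traj.time0)


# ---------------------------------------------------------------------------
# readers / writers

def write_trajectory(traj: Trajectory, path, format: str | None = None) -> None:
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        _write_csv(traj, path)
    elif fmt == "gro":
        _write_gro(traj, path)
    elif fmt == "xyz":
        _write_xyz(traj, path)
    else:
        raise ValueError(f"unknown trajectory format {fmt!r}")


def read_trajectory(path, format: str | None = None,
                    forcefield=None) -> Trajectory:
    """Read a trajectory, optionally resolving charges from a force field.

    If ``forcefield`` is given, every species label must be known to it
    (unknown labels raise) and charges are taken from it unless the file
    itself carries charges.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        traj = _read_csv(path)
    elif fmt == "gro":
        traj = _read_gro(path)
    elif fmt == "xyz":
        traj = _read_xyz(path)
    else:
        raise ValueError(f"unknown trajectory format {fmt!r}")
    if forcefield is not None:
        unknown = sorted({s for s in traj.species if s not in forcefield})
        if unknown:
            raise ValueError(f"{path}: unknown species labels {unknown}")
        if not np.any(traj.charges):
            traj.charges = np.array(
                [forcefield[s].charge for s in traj.species], dtype=float
            )
    return traj


def _write_csv(traj: Trajectory, path: Path) -> None:
    meta = {"box_length_nm": traj.box_length, "dt_ps": traj.dt,
            "time0_ps": traj.time0}
    n_f, n_p = traj.n_frames, traj.n_particles
    df = pd.DataFrame({
        "frame": np.repeat(np.arange(n_f), n_p),
        "particle": np.tile(np.arange(n_p), n_f),
        "species": np.tile(traj.species, n_f),
        "x": traj.positions[:, :, 0].ravel(),
        "y": traj.positions[:, :, 1].ravel(),
        "z": traj.positions[:, :, 2].ravel(),
        "charge": np.tile(traj.charges, n_f),
    })
    with open(path, "w") as fh:
        fh.write(f"# kbff-trajectory {json.dumps(meta)}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def _read_csv(path: Path) -> Trajectory:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# kbff-trajectory"):
            raise ValueError(f"{path}: missing kbff-trajectory metadata line")
        meta = json.loads(header.split("kbff-trajectory", 1)[1])
        df = pd.read_csv(fh)
    required = {"frame", "particle", "species", "x", "y", "z"}
    if required - set(df.columns):
        raise ValueError(
            f"{path}: missing columns {sorted(required - set(df.columns))}"
        )
    frames = df["frame"].to_numpy()
    frame_ids = np.unique(frames)
    counts = df.groupby("frame").size()
    if counts.nunique() != 1:
        bad = counts[counts != counts.iloc[0]].index[0]
        raise ValueError(
            f"{path}: inconsistent particle count in frame {bad} "
            f"({counts[bad]} vs {counts.iloc[0]})"
        )
    n_p = int(counts.iloc[0])
    df = df.sort_values(["frame", "particle"], kind="stable")
    pos = df[["x", "y", "z"]].to_numpy(dtype=float).reshape(len(frame_ids), n_p, 3)
    first = df[df["frame"] == frame_ids[0]]
    species = first["species"].astype(str).to_numpy()
    charges = (first["charge"].to_numpy(dtype=float)
               if "charge" in df.columns else None)
    return Trajectory(pos, float(meta["box_length_nm"]), species, charges,
                      float(meta["dt_ps"]), float(meta.get("time0_ps", 0.0)))


def _write_gro(traj: Trajectory, path: Path) -> None:
    L = traj.box_length
    with open(path, "w") as fh:
        for i in range(traj.n_frames):
            t = traj.times[i]
            fh.write(f"kbff frame {i}, t= {t:.4f} ps\n")
            fh.write(f"{traj.n_particles:5d}\n")
            for j in range(traj.n_particles):
                name = str(traj.species[j])[:5]
                x, y, z = traj.positions[i, j]
                fh.write(
                    f"{(j % 99999) + 1:5d}{name:<5s}{name:>5s}"
                    f"{(j % 99999) + 1:5d}{x:8.3f}{y:8.3f}{z:8.3f}\n"
                )
            fh.write(f"{L:10.5f}{L:10.5f}{L:10.5f}\n")


def _read_gro(path: Path) -> Trajectory:
    frames, times, species = [], [], None
    box = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    i, frame_idx = 0, 0
    n_ref = None
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        title = lines[i]
        try:
            n = int(lines[i + 1])
        except (IndexError, ValueError):
            raise ValueError(
                f"{path}: frame {frame_idx}: bad atom-count line"
            ) from None
        if n_ref is None:
            n_ref = n
        elif n != n_ref:
            raise ValueError(
                f"{path}: frame {frame_idx} has {n} particles, expected {n_ref}"
            )
        atom_lines = lines[i + 2: i + 2 + n]
        if len(atom_lines) < n:
            raise ValueError(f"{path}: frame {frame_idx} truncated")
        pos = np.empty((n, 3))
        names = []
        for j, ln in enumerate(atom_lines):
            names.append(ln[10:15].strip())
            pos[j] = [float(ln[20:28]), float(ln[28:36]), float(ln[36:44])]
        box_fields = lines[i + 2 + n].split()
        bx = [float(v) for v in box_fields[:3]]
        if len(box_fields) > 3 and any(float(v) != 0.0 for v in box_fields[3:]):
            raise ValueError(f"{path}: triclinic boxes are not supported")
        if not np.allclose(bx, bx[0]):
            raise ValueError(f"{path}: non-cubic box {bx}; cubic boxes only")
        box = bx[0]
        if species is None:
            species = names
        t = None
        if "t=" in title:
            try:
                t = float(title.split("t=")[1].split()[0])
            except (ValueError, IndexError):
                t = None
        times.append(t)
        frames.append(pos)
        i += 3 + n
        frame_idx += 1
    if not frames:
        raise ValueError(f"{path}: no frames found")
    dt, t0 = _dt_from_times(times)
    return Trajectory(np.array(frames), box, np.array(species, dtype=object),
                      None, dt, t0)


def _write_xyz(traj: Trajectory, path: Path) -> None:
    with open(path, "w") as fh:
        for i in range(traj.n_frames):
            fh.write(f"{traj.n_particles}\n")
            fh.write(
                f"box_length={traj.box_length:.6f} time={traj.times[i]:.6f}\n"
            )
            for j in range(traj.n_particles):
                x, y, z = traj.positions[i, j]
                fh.write(f"{traj.species[j]} {x:.6f} {y:.6f} {z:.6f}\n")


def _read_xyz(path: Path) -> Trajectory:
    frames, times, species = [], [], None
    box = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    i, frame_idx, n_ref = 0, 0, None
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i])
        if n_ref is None:
            n_ref = n
        elif n != n_ref:
            raise ValueError(
                f"{path}: frame {frame_idx} has {n} particles, expected {n_ref}"
            )
        comment = lines[i + 1]
        for tok in comment.split():
            if tok.startswith("box_length="):
                box = float(tok.split("=")[1])
            elif tok.startswith("time="):
                times.append(float(tok.split("=")[1]))
        if len(times) < frame_idx + 1:
            times.append(None)
        atom_lines = lines[i + 2: i + 2 + n]
        if len(atom_lines) < n:
            raise ValueError(
                f"{path}: frame {frame_idx} is missing particles "
                f"({len(atom_lines)} of {n})"
            )
        pos = np.empty((n, 3))
        names = []
        for j, ln in enumerate(atom_lines):
            parts = ln.split()
            if len(parts) < 4:
                raise ValueError(
                    f"{path}: frame {frame_idx} is malformed or missing "
                    f"particles at line {i + 3 + j}"
                )
            names.append(parts[0])
            try:
                pos[j] = [float(p) for p in parts[1:4]]
            except ValueError:
                raise ValueError(
                    f"{path}: frame {frame_idx}: bad coordinates in "
                    f"line {i + 3 + j}"
                ) from None
        if species is None:
            species = names
        frames.append(pos)
        i += 2 + n
        frame_idx += 1
    if not frames:
        raise ValueError(f"{path}: no frames found")
    if box is None:
        raise ValueError(
            f"{path}: no box_length= field on any XYZ comment line"
        )
    dt, t0 = _dt_from_times(times)
    return Trajectory(np.array(frames), box, np.array(species, dtype=object),
                      None, dt, t0)


def _dt_from_times(times) -> tuple[float, float]:
    ts = [t for t in times if t is not None]
    if len(ts) == len(times) and len(ts) >= 2:
        dts = np.diff(ts)
        if np.any(dts <= 0):
            raise ValueError("frame times are not strictly increasing")
        if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
            raise ValueError("frame times are not uniformly spaced")
        return float(dts[0]), float(ts[0])
    return 1.0, 0.0
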