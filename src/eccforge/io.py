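"""Plain-text trajectory and table IO.

Two trajectory formats are supported, both as (possibly multi-frame)
concatenated text blocks:

* GRO: fixed-column GROMACS coordinate files with the trailing box line;
  velocity columns are read when present.  Only cubic boxes (three equal
  diagonal components, no off-diagonal entries) are accepted.
* extended XYZ: comment line carrying ``Lattice="L 0 0 0 L 0 0 0 L"``;
  an optional velocity block is read from columns 5–7.

Species labels are taken from atom names with trailing digits stripped
(``Na1`` → ``Na``).
"""

from __future__ import annotations

import re

import numpy as np

from .trajectory import Frame, Trajectory, TrajectoryError


def _species_from_name(name: str) -> str:
    return re.sub(r"\d+$", "", name.strip())


# -- GRO -------------------------------------------------------------------


def read_gro(path) -> Trajectory:
    with open(path) as fh:
        lines = fh.read().splitlines()
    frames: list[Frame] = []
    species: list[str] = []
    i = 0
    first = True
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        natoms = int(lines[i + 1])
        coords = np.empty((natoms, 3))
        vels = np.empty((natoms, 3))
        have_vel = True
        for j in range(natoms):
            ln = lines[i + 2 + j]
            name = ln[10:15]
            if first:
                species.append(_species_from_name(name))
            parts = ln[20:].split()
            coords[j] = [float(x) for x in parts[:3]]
            if len(parts) >= 6:
                vels[j] = [float(x) for x in parts[3:6]]
            else:
                have_vel = False
        box = [float(x) for x in lines[i + 2 + natoms].split()]
        if len(box) < 3 or not np.allclose(box[:3], box[0]) or any(abs(b) > 1e-12 for b in box[3:]):
            raise TrajectoryError("only cubic boxes are supported")
        frames.append(Frame(coords, box[0], vels if have_vel else None))
        i += natoms + 3
        first = False
    return Trajectory(frames=frames, species=species)


def write_gro(traj: Trajectory, path, title: str = "eccforge") -> None:
    with open(path, "w") as fh:
        for fr in traj.frames:
            fh.write(f"{title}\n{traj.n_particles:5d}\n")
            for j in range(traj.n_particles):
                name = traj.species[j] if traj.species else "X"
                x, y, z = fr.coordinates[j]
                line = f"{1:5d}{'SOL':<5s}{name:>5s}{j + 1:5d}{x:8.3f}{y:8.3f}{z:8.3f}"
                if fr.velocities is not None:
                    vx, vy, vz = fr.velocities[j]
                    line += f"{vx:8.4f}{vy:8.4f}{vz:8.4f}"
                fh.write(line + "\n")
            L = fr.box_edge
            fh.write(f"{L:10.5f}{L:10.5f}{L:10.5f}\n")


# -- extended XYZ ----------------------------------------------------------

_LATTICE_RE = re.compile(r'Lattice="([^"]+)"')


def read_xyz(path) -> Trajectory:
    with open(path) as fh:
        lines = fh.read().splitlines()
    frames: list[Frame] = []
    species: list[str] = []
    i = 0
    first = True
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        natoms = int(lines[i])
        m = _LATTICE_RE.search(lines[i + 1])
        if not m:
            raise TrajectoryError("extended-XYZ comment line lacks a Lattice field")
        cell = np.array([float(x) for x in m.group(1).split()]).reshape(3, 3)
        if not np.allclose(cell, np.diag([cell[0, 0]] * 3)):
            raise TrajectoryError("only cubic boxes are supported")
        coords = np.empty((natoms, 3))
        vels = np.empty((natoms, 3))
        have_vel = True
        for j in range(natoms):
            parts = lines[i + 2 + j].split()
            if first:
                species.append(_species_from_name(parts[0]))
            coords[j] = [float(x) for x in parts[1:4]]
            if len(parts) >= 7:
                vels[j] = [float(x) for x in parts[4:7]]
            else:
                have_vel = False
        frames.append(Frame(coords, cell[0, 0], vels if have_vel else None))
        i += natoms + 2
        first = False
    return Trajectory(frames=frames, species=species)


def write_xyz(traj: Trajectory, path) -> None:
    with open(path, "w") as fh:
        for fr in traj.frames:
            L = fr.box_edge
            fh.write(f"{traj.n_particles}\n")
            props = "species:S:1:pos:R:3" + (":vel:R:3" if fr.velocities is not None else "")
            fh.write(f'Lattice="{L} 0 0 0 {L} 0 0 0 {L}" Properties={props}\n')
            for j in range(traj.n_particles):
                name = traj.species[j] if traj.species else "X"
                x, y, z = fr.coordinates[j]
                line = f"{name} {x:.8g} {y:.8g} {z:.8g}"
                if fr.velocities is not None:
                    vx, vy, vz = fr.velocities[j]
                    line += f" {vx:.8g} {vy:.8g} {vz:.8g}"
                fh.write(line + "\n")


def read_trajectory(path) -> Trajectory:
    """Dispatch on file extension (.gro / .xyz)."""
    p = str(path)
    if p.endswith(".gro"):
        return read_gro(path)
    if p.endswith(".xyz") or p.endswith(".extxyz"):
        return read_xyz(path)
    raise TrajectoryError(f"unrecognized trajectory format: {p}")


# -- tables ----------------------------------------------------------------


def write_table(path, columns: dict[str, np.ndarray]) -> None:
    """Tab-separated table with a '#'-prefixed header row."""
    names = list(columns)
    arr = np.column_stack([np.asarray(columns[n], dtype=float) for n in names])
    np.savetxt(path, arr, delimiter="\t", header="\t".join(names))


def read_table(path) -> dict[str, np.ndarray]:
    with open(path) as fh:
        header = fh.readline().lstrip("#").strip().split("\t")
    arr = np.loadtxt(path, ndmin=2)
    return {name: arr[:, k] for k, name in enumerate(header)}
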