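"""In-memory trajectory container for cubic periodic systems.

Frames hold particle coordinates (nm) and the cubic box edge length L (nm);
particle count and species labels are constant across frames.  Velocities
(nm/ps), when present, share the coordinate layout.  Only cubic boxes are
supported: the minimum-image convention used throughout the analysis
modules is valid for r <= L/2 on a cubic cell only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class TrajectoryError(ValueError):
    pass


@dataclass
class Frame:
    coordinates: np.ndarray  # (N, 3) nm
    box_edge: float  # L, nm
    velocities: np.ndarray | None = None  # (N, 3) nm/ps

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise TrajectoryError("coordinates must be (N, 3)")
        if self.box_edge <= 0:
            raise TrajectoryError("box edge must be positive")
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float)
            if self.velocities.shape != self.coordinates.shape:
                raise TrajectoryError("velocity array shape mismatch")


@dataclass
class Trajectory:
    frames: list[Frame]
    species: list[str] = field(default_factory=list)  # index -> species label

    def __post_init__(self) -> None:
        if not self.frames:
            raise TrajectoryError("trajectory needs at least one frame")
        n = self.frames[0].coordinates.shape[0]
        for fr in self.frames:
            if fr.coordinates.shape[0] != n:
                raise TrajectoryError("particle count varies across frames")
        if self.species and len(self.species) != n:
            raise TrajectoryError("species list length mismatch")

    @property
    def n_particles(self) -> int:
        return self.frames[0].coordinates.shape[0]

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def indices_of(self, species: str) -> np.ndarray:
        """Particle indices of one species label."""
        return np.flatnonzero(np.asarray(self.species) == species)

    def positions(self, species: str | None = None) -> np.ndarray:
        """(n_frames, n, 3) coordinate stack, optionally for one species."""
        stack = np.stack([fr.coordinates for fr in self.frames])
        if species is None:
            return stack
        return stack[:, self.indices_of(species), :]

    def box_edges(self) -> np.ndarray:
        return np.array([fr.box_edge for fr in self.frames])

    def has_velocities(self) -> bool:
        return all(fr.velocities is not None for fr in self.frames)


def minimum_image(dx: np.ndarray, box: float) -> np.ndarray:
    """Minimum-image displacement components for a cubic box of edge ``box``."""
    return dx - box * np.round(dx / box)


def unwrap(traj: Trajectory) -> Trajectory:
    """Remove periodic jumps, producing continuous particle paths.

    Frame-to-frame displacements larger than L/2 in any component are
    interpreted as wrap events; valid when physical per-step motion is
    well below half a box length.
    """
    frames = [Frame(traj.frames[0].coordinates.copy(), traj.frames[0].box_edge,
                    None if traj.frames[0].velocities is None else traj.frames[0].velocities.copy())]
    for fr in traj.frames[1:]:
        prev = frames[-1].coordinates
        step = minimum_image(fr.coordinates - (prev % fr.box_edge) , fr.box_edge)
        # displacement measured between wrapped views, applied to the
        # running unwrapped coordinates
        frames.append(Frame(prev + step, fr.box_edge,
                            None if fr.velocities is None else fr.velocities.copy()))
    return Trajectory(frames=frames, species=list(traj.species))


def detect_wrapping(traj: Trajectory, threshold_frac: float = 0.5) -> bool:
    """True if any frame-to-frame displacement exceeds ``threshold_frac * L``."""
    for a, b in zip(traj.frames[:-1], traj.frames[1:]):
        if np.abs(b.coordinates - a.coordinates).max() > threshold_frac * b.box_edge:
            return True
    return False
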