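"""Shared fixtures: small force fields and synthetic trajectories."""

from __future__ import annotations

import numpy as np
import pytest

from eccforge.forcefield import IonSpecies, PairOverride, ScaledForceField
from eccforge.trajectory import Frame, Trajectory


@pytest.fixture
def toy_ff() -> ScaledForceField:
    """1:1 electrolyte with a neutral LJ solvent and one pair override."""
    return ScaledForceField(
        scaling_factor=0.81,
        species=[
            IonSpecies("M", 1, 0.25, 3.0),
            IonSpecies("X", -1, 0.38, 1.0),
            IonSpecies("W", 0, 0.30, 2.0),
        ],
        overrides=[PairOverride("X", "W", 0.345, 0.75)],
    )


@pytest.fixture
def uniform_trajectory() -> Trajectory:
    """Ideal-gas configurations: 300 particles, 100 frames, L = 3 nm."""
    rng = np.random.default_rng(42)
    L = 3.0
    frames = [Frame(rng.uniform(0, L, (300, 3)), L) for _ in range(100)]
    return Trajectory(frames=frames, species=["A"] * 300)


def brute_force_histogram(coords_a, coords_b, box, edges, same):
    """Reference pair counting: explicit double loop with minimum image."""
    counts = np.zeros(len(edges) - 1)
    for i in range(coords_a.shape[0]):
        for j in range(coords_b.shape[0]):
            if same and i == j:
                continue
            d = coords_a[i] - coords_b[j]
            d -= box * np.round(d / box)
            r = np.sqrt((d**2).sum())
            k = np.searchsorted(edges, r, side="right") - 1
            if 0 <= k < len(counts) and r < edges[-1] and r >= edges[0]:
                counts[k] += 1
    return counts
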