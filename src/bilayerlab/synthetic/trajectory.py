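"""Synthetic grouped bilayer trajectories.

Atoms of each group are drawn independently per frame: z from the group's
Gaussian depth distribution about the box mid-plane, x and y uniform over
the box cross-section. This reproduces the statistical structure the
density and contact analyses assume (stationary per-group depth
distributions in a periodic box) at a fraction of MD cost.
"""

from __future__ import annotations

import warnings as _warnings

import numpy as np

from ..types import DepthDistribution, GroupTrajectory


def gen_trajectory(
    depth: DepthDistribution,
    n_frames: int,
    box: tuple[float, float, float],
    seed: int = 0,
) -> GroupTrajectory:
    """Sample a trajectory whose per-group z follows ``depth`` (nm).

    Group mean depths are taken relative to the bilayer center placed at
    ``Lz/2``; all coordinates are wrapped into ``[0, L)``. Groups with
    ``n_atoms == 0`` are omitted with a warning.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if any(b <= 0 for b in box):
        raise ValueError("box lengths must be positive")
    rng = np.random.default_rng(seed)
    lx, ly, lz = box

    active = []
    for g in depth:
        if g.n_atoms == 0:
            _warnings.warn(f"group {g.label!r} has no atoms and is omitted", stacklevel=2)
        else:
            active.append(g)

    frames: list[dict[str, np.ndarray]] = []
    for _ in range(n_frames):
        frame: dict[str, np.ndarray] = {}
        for g in active:
            xy = rng.uniform(0.0, [lx, ly], size=(g.n_atoms, 2))
            z = (lz / 2.0 + rng.normal(g.mean_z, g.sd_z, size=g.n_atoms)) % lz
            frame[g.label] = np.column_stack([xy, z])
        frames.append(frame)
    masses = {g.label: np.full(g.n_atoms, g.atom_mass) for g in active}
    return GroupTrajectory(frames=frames, masses=masses, box=box)
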