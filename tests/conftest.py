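"""Shared fixtures: small phantoms and toy dose-influence operators.

Everything is generated at test time from seeded code; heavy objects
are session-scoped so the influence matrices are built once.
"""

from __future__ import annotations

import numpy as np
import pytest
import scipy.sparse as sp

from doseshape import (
    VOI,
    BeamSet,
    PhantomSpec,
    Prescription,
    VoxelGrid,
    build_influence,
    generate_phantom,
    voi_dict,
)
from doseshape.dose import BixelGrid, DoseInfluence, KernelParams


@pytest.fixture(scope="session")
def toy16():
    """16^3 grid with a centered box body and three beams.

    Small enough for dense-matrix oracles, large enough that depth
    attenuation and lateral penumbra are both exercised.
    """
    grid = VoxelGrid(dims=(16, 16, 16), spacing=(8.0, 8.0, 8.0))
    mask = np.zeros(grid.dims, dtype=bool)
    mask[2:14, 2:14, 2:14] = True
    body = VOI("body", "body", mask)
    beams = BeamSet(gantry_angles_deg=(0.0, 120.0, 240.0))
    influence = build_influence(grid, body, beams)
    return {"grid": grid, "body": body, "beams": beams, "influence": influence}


@pytest.fixture(scope="session")
def small_phantom():
    """Seeded 32x32x24 phantom at 8 mm spacing with its influence matrix."""
    spec = PhantomSpec(seed=7, dims=(32, 32, 24), spacing=(8.0, 8.0, 8.0))
    grid, vois, rx = generate_phantom(spec)
    vd = voi_dict(vois)
    influence = build_influence(grid, vd["body"], BeamSet())
    return {"spec": spec, "grid": grid, "vois": vd, "rx": rx, "influence": influence}


def make_influence(matrix, n_voxels=None):
    """Wrap an arbitrary sparse matrix as a DoseInfluence for DMR toys.

    The geometric metadata is a dummy single-beam layout; only the
    matrix itself is exercised by the patch/recovery machinery.
    """
    mat = sp.csc_matrix(matrix, dtype=float)
    n_vox, n_bix = mat.shape
    grid = VoxelGrid(dims=(n_vox, 1, 1), spacing=(1.0, 1.0, 1.0))
    beams = BeamSet(gantry_angles_deg=(0.0,))
    bg = BixelGrid(nu=n_bix, nv=1, du=5.0, dv=5.0, u_half=0.0, v_half=0.0)
    return DoseInfluence(
        grid=grid, beams=beams, kernel=KernelParams(), bixel_grids=[bg], matrix_csc=mat
    )


class ToyState:
    """Minimal plan-state stand-in for exercising apply_dmr on raw matrices."""

    def __init__(self, influence, weights):
        from doseshape.dose import compute_dose, incremental_dose

        self.influence = influence
        self.fluence_flat = np.asarray(weights, dtype=float)
        self.dose = (influence.matrix_csc @ self.fluence_flat).reshape(influence.grid.dims)
        self.history = []
        self._incremental = incremental_dose

    def apply_patch(self, bixels, deltas):
        if len(bixels) == 0:
            return
        self.fluence_flat[bixels] += deltas
        np.clip(self.fluence_flat, 0.0, None, out=self.fluence_flat)
        self._incremental(self.influence, self.dose, bixels, deltas, out=self.dose)

    def record(self, result):
        self.history.append(result)
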