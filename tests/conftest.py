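"""Shared fixtures: default phantom, noiseless acquisition, fitted tensors.

Heavy artifacts are session-scoped; everything is generated at test time
from the synthetic-data module.
"""

from __future__ import annotations

import numpy as np
import pytest

from cardiohelix import lv_geometry as geo
from cardiohelix import synthetic_data as syn
from cardiohelix import tensor_model as tm


@pytest.fixture(scope="session")
def default_phantom():
    spec = syn.PhantomSpec()
    fiber, mask, truth = syn.make_lv_phantom(spec)
    return spec, fiber, mask, truth


@pytest.fixture(scope="session")
def noiseless_dwi(default_phantom):
    spec, fiber, mask, _ = default_phantom
    return syn.simulate_dwi(fiber, mask, spec, noise=syn.NoiseModel(kind="none"))


@pytest.fixture(scope="session")
def fitted_eigensystem(noiseless_dwi, default_phantom):
    _, _, mask, _ = default_phantom
    tf = tm.fit_tensor_wls(noiseless_dwi, mask=mask)
    return tf, tm.eigendecompose(tf)


@pytest.fixture(scope="session")
def geometry_bundle(default_phantom):
    spec, _, mask, _ = default_phantom
    mm = geo.MyocardiumMask(mask=mask, voxel_size=spec.voxel_size)
    frame = geo.compute_local_frame(mm)
    depth = geo.compute_transmural_depth(mm)
    rings = geo.make_rings(depth)
    aha = geo.make_aha_segments(mm)
    return mm, frame, depth, rings, aha


@pytest.fixture(scope="session")
def true_tensor_field(default_phantom):
    """Analytic per-voxel tensors implied by the phantom (oracle)."""
    spec, fiber, mask, _ = default_phantom
    dx, dy, r, _ = syn._phantom_geometry(spec)
    xs, ys, zs = np.nonzero(mask)
    rr = r[xs, ys]
    rhat = np.zeros((xs.size, 3))
    rhat[:, 0] = dx[xs, ys] / rr
    rhat[:, 1] = dy[xs, ys] / rr
    e1 = fiber[xs, ys, zs]
    e2 = np.cross(rhat, e1)
    l1, l2, l3 = spec.eigenvalues
    D = (
        l1 * np.einsum("ni,nj->nij", e1, e1)
        + l2 * np.einsum("ni,nj->nij", e2, e2)
        + l3 * np.einsum("ni,nj->nij", rhat, rhat)
    )
    return (xs, ys, zs), D
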