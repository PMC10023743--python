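"""Shared fixtures: all imaging fixtures are generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

import pvvkit as pk


@pytest.fixture(scope="session")
def cylinder_factory():
    """Rasterized single-cylinder phantom (radius mm, length mm, tilt deg)."""

    def make(radius=2.0, length=30.0, tilt=0.0, spacing=(0.5, 0.5, 3.0),
             shape=(160, 160, 40)):
        tree, truth = pk.generate_tree(pk.TreeSpec(
            generations=1, root_radius=radius, root_length=length,
            global_rotation=(tilt, 0.0, 0.0), seed=0,
        ))
        mask, lung = pk.rasterize(tree, shape=shape, spacing=spacing)
        return mask, lung, truth

    return make


@pytest.fixture(scope="session")
def small_tree():
    """A 3-generation tree on a compact near-isotropic grid (fast)."""
    tree, truth = pk.generate_tree(pk.TreeSpec(generations=3, seed=5))
    mask, lung = pk.rasterize(tree, shape=(160, 160, 48), spacing=(0.7, 0.7, 2.0))
    return tree, truth, mask, lung


def make_skeleton(voxels, radius=1.0, spacing=(1.0, 1.0, 1.0), shape=(48, 48, 48)):
    """Hand-built Skeleton from a voxel list (for graph-topology tests)."""
    vox = np.asarray(voxels, dtype=np.int64)
    r = np.full(len(vox), float(radius))
    return pk.Skeleton(voxels=vox, radius=r,
                       component_id=np.ones(len(vox), dtype=np.int64),
                       spacing=spacing, shape=shape)
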