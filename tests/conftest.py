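"""Shared fixtures: analytic phantoms, noise-free scalar maps, skeletons.

Everything is generated programmatically at test time; expensive objects
are session-scoped so the suite builds each phantom once.
"""

from __future__ import annotations

import numpy as np
import pytest

from longtbss import dti
from longtbss.registration import Image
from longtbss.simulate import (
    PhantomSpec,
    Tract,
    default_tracts,
    make_phantom,
    phantom_scalar_maps,
)
from longtbss.skeleton import skeleton_adjacency, skeletonize


def gaussian_blob_image(
    shape=(24, 24, 24),
    voxel_size=2.0,
    transform=None,
    centers=((0.4, 0.5, 0.5), (0.6, 0.45, 0.55)),
    amplitudes=(1.0, 0.7),
    sigma_mm=6.0,
) -> Image:
    """Analytic two-blob phantom, optionally evaluated on a moved frame.

    When ``transform`` (4x4 world mapping) is given the blobs are moved by
    it and evaluated exactly on the unmoved grid — an interpolation-free
    oracle for registration recovery tests.
    """
    affine = np.diag([voxel_size] * 3 + [1.0])
    ii, jj, kk = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    pts = np.stack([ii, jj, kk], axis=-1) * voxel_size
    if transform is not None:
        inv = np.linalg.inv(transform)
        pts = pts @ inv[:3, :3].T + inv[:3, 3]
    data = np.zeros(shape)
    for c, a in zip(centers, amplitudes):
        cm = np.asarray(c) * np.asarray(shape) * voxel_size
        data += a * np.exp(-np.sum((pts - cm) ** 2, axis=-1) / (2 * sigma_mm**2))
    return Image(data, affine)


@pytest.fixture(scope="session")
def blob_image() -> Image:
    return gaussian_blob_image()


@pytest.fixture(scope="session")
def default_scheme() -> dti.GradientScheme:
    return dti.default_scheme()


@pytest.fixture(scope="session")
def straight_tube():
    """48^3 phantom with one straight tube (radius 4, peak FA 0.6) and its
    noise-free scalar maps."""
    spec = PhantomSpec(
        grid_shape=(48, 48, 48),
        tracts=(Tract(name="tube", kind="straight", point=(0.5, 0.5, 0.5),
                      direction=(0, 1, 0), radius=4.0, peak_fa=0.6),),
    )
    phantom = make_phantom(spec)
    return phantom, phantom_scalar_maps(phantom)


@pytest.fixture(scope="session")
def tube_skeleton(straight_tube):
    phantom, maps = straight_tube
    return skeletonize(Image(maps.fa, phantom.affine), threshold=0.2)


@pytest.fixture(scope="session")
def smoke_phantom():
    """24^3 phantom with the default tract pair (smoke-cohort geometry)."""
    spec = PhantomSpec(grid_shape=(24, 24, 24), tracts=default_tracts(radius=3.0))
    phantom = make_phantom(spec)
    return phantom, phantom_scalar_maps(phantom)


@pytest.fixture(scope="session")
def smoke_skeleton_adjacency(smoke_phantom):
    phantom, maps = smoke_phantom
    skel = skeletonize(Image(maps.fa, phantom.affine), threshold=0.2)
    return skel, skeleton_adjacency(skel)


@pytest.fixture()
def isolated_voxel_adjacency():
    """Adjacency of a single skeleton voxel with no neighbors."""
    return np.array([0, 0], dtype=np.int64), np.zeros(0, dtype=np.int64)
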