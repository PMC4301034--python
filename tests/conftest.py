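"""Shared fixtures: small analytic meshes and a miniature plated phantom.

Everything is generated programmatically; no fixture files are stored.
"""

from __future__ import annotations

import numpy as np
import pytest

from minfuse import (CalibrationModel, LabelVolume, MaterialMap, PhantomConfig,
                     Tissue, build_mesh)
from minfuse.fem import LoadCase, VoxelMesh


def uniform_labels(shape, tissue=Tissue.CORTICAL, spacing=(1.0, 1.0, 1.0)):
    """A solid block of one tissue class with an empty nonunion mask."""
    return LabelVolume(
        labels=np.full(shape, tissue, dtype=np.int8),
        nonunion_mask=np.zeros(shape, dtype=bool),
        spacing=spacing,
    )


def bar_materials(shape, E, nu=0.0, spacing=(1.0, 1.0, 1.0)) -> MaterialMap:
    """Homogeneous or per-voxel-E bar of cortical-labelled voxels."""
    labels = uniform_labels(shape, spacing=spacing)
    E_arr = np.broadcast_to(np.asarray(E, dtype=np.float64), shape).copy()
    nu_arr = np.full(shape, float(nu))
    return MaterialMap(E=E_arr, nu=nu_arr, labels=labels)


def consistent_axial_load(mesh: VoxelMesh, sigma: float) -> LoadCase:
    """Uniform axial traction sigma (Pa) on the top face, base fully fixed.

    Nodal forces are the consistent loads of a constant traction on
    bilinear faces: each top-face element spreads ``sigma * A_face`` equally
    over its 4 top nodes, so interior nodes accumulate the correct 4x weight
    relative to corners and the FE solution of a uniform bar is exact.
    """
    k_top = mesh.elem_voxels[:, 2].max()
    top = mesh.elem_voxels[:, 2] == k_top
    hx, hy, _ = mesh.spacing_m
    face_force = sigma * hx * hy / 4.0
    f = np.zeros((mesh.n_nodes, 3))
    for n in mesh.connectivity[top][:, 4:8].ravel():
        f[n, 2] += face_force
    k_bot = mesh.nodes_ijk[:, 2].min()
    fixed = np.flatnonzero(mesh.nodes_ijk[:, 2] == k_bot)
    f[fixed] = 0.0
    return LoadCase.from_node_forces(fixed, f)


@pytest.fixture(scope="session")
def tiny_phantom_config() -> PhantomConfig:
    """A miniature plated-bone phantom that solves in a couple of seconds."""
    return PhantomConfig(
        grid_dims=(16, 16, 32),
        spacing=(1.0, 1.0, 1.0),
        outer_radius=5.0,
        cortical_thickness=1.5,
        gap_halfwidth=1.5,
        plate_thickness=2.0,
        plate_width=6.0,
        plate_z_extent=(4.0, 28.0),
        screw_radius=1.2,
        screw_z_positions=(10.0, 22.0),
        noise_sd=20.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def toy_gap_labels() -> LabelVolume:
    """A ~100-cell nonunion gap in a miniature plated bone (oracle-sized).

    Small enough that every single-cell-removal variant of the fused gap can
    be solved exhaustively, yet it keeps the load topology of the real
    construct: a plate plus screws bridging a 2 mm transverse gap, so the
    near-plate cortex cells carry the load transfer and survive the loop.
    """
    from minfuse import Slab, generate_phantom, mark_nonunion, segment

    cfg = PhantomConfig(
        grid_dims=(12, 12, 24), spacing=(1.0, 1.0, 1.0), outer_radius=4.0,
        cortical_thickness=1.5, gap_halfwidth=1.0, plate_thickness=2.0,
        plate_width=4.0, plate_z_extent=(3.0, 21.0), screw_radius=1.0,
        screw_z_positions=(8.0, 16.0), noise_sd=0.0)
    labels = segment(generate_phantom(cfg))
    zc = cfg.gap_center()
    return mark_nonunion(labels, Slab(z=(zc - cfg.gap_halfwidth,
                                         zc + cfg.gap_halfwidth)))


@pytest.fixture(scope="session")
def toy_model() -> CalibrationModel:
    return CalibrationModel()
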