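"""Connectivity fingerprints and seed-to-voxel maps.

A *fingerprint* is the vector of Fisher-z correlations between one
seed-mask voxel and every grey-matter voxel (the seed mask itself
included).  Stacking fingerprints gives the seed x GM
:class:`ConnectivityMatrix` that drives the parcellation; averaging a
seed's voxel time courses and correlating with GM gives a
:class:`SeedMap` for group inference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ConnectivityMatrix",
    "SeedMap",
    "fisher_z",
    "inverse_fisher",
    "mask_to_gm_matrix",
    "group_fixed_effects",
    "sphere_seed",
    "seed_to_voxel_map",
]

R_CLIP = 1.0 - 1e-7


@dataclass
class ConnectivityMatrix:
    """Fisher-z connectivity of every seed voxel to every GM voxel."""

    values: np.ndarray           # (n_seed, n_gm), z units
    seed_voxel_index: np.ndarray  # (n_seed, 3)
    gm_voxel_index: np.ndarray    # (n_gm, 3)
    subject_id: str = ""

    def __post_init__(self):
        if self.values.shape != (len(self.seed_voxel_index),
                                 len(self.gm_voxel_index)):
            raise ValueError("matrix shape does not match voxel indices")
        if not np.isfinite(self.values).all():
            raise ValueError("connectivity matrix contains non-finite entries")


@dataclass
class SeedMap:
    """Per-GM-voxel Fisher-z map for one seed and one subject."""

    values: np.ndarray
    gm_voxel_index: np.ndarray
    seed_descriptor: str = ""
    subject_id: str = ""


def fisher_z(r, clip: float = R_CLIP):
    """Fisher r-to-z (atanh), with |r| = 1 clipped just inside the domain."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1.0 + 1e-12):
        raise ValueError("correlations must satisfy |r| <= 1")
    out = np.arctanh(np.clip(r, -clip, clip))
    return out if out.ndim else float(out)


def inverse_fisher(z):
    """Inverse Fisher transform (tanh)."""
    out = np.tanh(np.asarray(z, dtype=float))
    return out if out.ndim else float(out)


def _standardize(ts):
    """Demean/unit-norm columns of a (time x voxel) array; returns the
    standardized array and a validity flag per voxel."""
    ts = np.asarray(ts, dtype=float)
    c = ts - ts.mean(axis=0, keepdims=True)
    norm = np.linalg.norm(c, axis=0)
    ok = norm > 1e-12
    c[:, ok] /= norm[ok]
    return c, ok


def _mask_index(mask):
    return np.argwhere(np.asarray(mask, dtype=bool))


def mask_to_gm_matrix(data, seed_mask, gm_mask, keep=None,
                      subject_id: str = "") -> ConnectivityMatrix:
    """Correlate every seed-mask voxel with every grey-matter voxel.

    ``data`` is a 4D volume; correlations use retained volumes only
    (``keep`` boolean over time, optional).  Zero-variance voxels are
    excluded from the GM index (and, if in the seed, from the seed index)
    with a logged count; perfect correlations are clipped before the
    Fisher transform.
    """
    data = np.asarray(data, dtype=float)
    seed_idx = _mask_index(seed_mask)
    gm_idx = _mask_index(gm_mask)
    if len(seed_idx) == 0 or len(gm_idx) == 0:
        raise ValueError("empty seed or GM mask")
    if keep is not None:
        data = data[..., np.asarray(keep, dtype=bool)]
    seed_ts = data[tuple(seed_idx.T)].T   # (time, n_seed)
    gm_ts = data[tuple(gm_idx.T)].T
    s_std, s_ok = _standardize(seed_ts)
    g_std, g_ok = _standardize(gm_ts)
    if (~s_ok).any() or (~g_ok).any():
        logger.info("excluding %d zero-variance voxel(s) from the "
                    "connectivity matrix", int((~s_ok).sum() + (~g_ok).sum()))
    r = s_std[:, s_ok].T @ g_std[:, g_ok]
    return ConnectivityMatrix(values=fisher_z(np.clip(r, -1.0, 1.0)),
                              seed_voxel_index=seed_idx[s_ok],
                              gm_voxel_index=gm_idx[g_ok],
                              subject_id=subject_id)


def group_fixed_effects(matrices) -> np.ndarray:
    """Fixed-effects group matrix: mean of the Fisher-z matrices across
    subjects, transformed back to correlation units."""
    matrices = list(matrices)
    if not matrices:
        raise ValueError("need at least one subject matrix")
    ref = matrices[0]
    for m in matrices[1:]:
        if (not np.array_equal(m.seed_voxel_index, ref.seed_voxel_index)
                or not np.array_equal(m.gm_voxel_index, ref.gm_voxel_index)):
            raise ValueError("voxel indices differ across subjects")
    mean_z = np.mean([m.values for m in matrices], axis=0)
    return inverse_fisher(mean_z)


def sphere_seed(centre_mm, radius_mm, affine, shape) -> np.ndarray:
    """Voxels whose world-space centre lies within ``radius_mm`` of
    ``centre_mm``.  Returns an (n, 3) voxel index array."""
    affine = np.asarray(affine, dtype=float)
    centre_mm = np.asarray(centre_mm, dtype=float)
    grid = np.indices(shape).reshape(3, -1).T
    world = grid @ affine[:3, :3].T + affine[:3, 3]
    d = np.linalg.norm(world - centre_mm, axis=1)
    vox = grid[d <= radius_mm + 1e-9]
    if len(vox) == 0:
        raise ValueError("sphere contains no voxels")
    return vox


def seed_to_voxel_map(data, seed_voxels, gm_mask, keep=None,
                      seed_descriptor: str = "", subject_id: str = "") -> SeedMap:
    """Unweighted mean seed time course correlated with every GM voxel,
    Fisher-z transformed."""
    data = np.asarray(data, dtype=float)
    seed_voxels = np.asarray(seed_voxels, dtype=int)
    if seed_voxels.size == 0:
        raise ValueError("empty seed")
    for axis in range(3):
        if (seed_voxels[:, axis] < 0).any() or \
                (seed_voxels[:, axis] >= data.shape[axis]).any():
            raise ValueError("seed voxels outside the data volume")
    if keep is not None:
        data = data[..., np.asarray(keep, dtype=bool)]
    gm_idx = _mask_index(gm_mask)
    seed_ts = data[tuple(seed_voxels.T)].mean(axis=0)  # (time,)
    gm_ts = data[tuple(gm_idx.T)].T
    s_std, s_ok = _standardize(seed_ts[:, None])
    if not s_ok[0]:
        raise ValueError("seed time course has zero variance")
    g_std, g_ok = _standardize(gm_ts)
    r = (s_std[:, 0] @ g_std[:, g_ok])
    values = np.zeros(len(gm_idx))
    values[g_ok] = fisher_z(np.clip(r, -1.0, 1.0))
    return SeedMap(values=values[g_ok], gm_voxel_index=gm_idx[g_ok],
                   seed_descriptor=seed_descriptor, subject_id=subject_id)
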