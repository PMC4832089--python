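"""Synthetic multi-subject phantoms with known parcel structure.

Every downstream stage of the toolkit (scrubbing, fingerprint clustering,
Dice matching, permutation inference) is validated against data whose true
structure is known.  The phantom plants:

* ``K`` disjoint parcels inside a designated seed mask, each sharing a
  latent time series;
* ``K`` disjoint network targets outside the mask, whose latent series
  correlates with the corresponding parcel latent at ``signal_corr``;
* temporally autocorrelated (AR(1)) latents, mimicking band-limited BOLD;
* motion "spike" events that displace the head and step the global
  intensity, so FD- and DVARS-based scrubbing can each be exercised;
* optionally, a between-group difference in the connectivity-vs-log(age)
  slope for one designated parcel/network pair, the effect the group-level
  permutation GLM is meant to detect.

Voxel noise is additive on top of the unit-variance latents, so the
realized voxel-to-voxel correlation is ``signal_corr / (1 + noise_sd**2)``;
``signal_corr`` itself is the latent (noise-free) coupling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BoldSeries",
    "PhantomMasks",
    "PhantomSpec",
    "CohortSpec",
    "GroundTruth",
    "default_phantom_spec",
    "make_phantom_subject",
    "make_cohort",
]


@dataclass
class BoldSeries:
    """One subject's 4D functional data plus sampling metadata.

    ``data`` is indexed (x, y, z, t); ``affine`` maps voxel indices to
    world (mm) coordinates; ``tr`` is the sampling interval in seconds.
    """

    data: np.ndarray
    tr: float
    affine: np.ndarray

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[-1]


@dataclass
class PhantomMasks:
    """Binary tissue masks on the phantom grid."""

    seed: np.ndarray
    gm: np.ndarray
    wm: np.ndarray
    csf: np.ndarray


@dataclass
class GroundTruth:
    """What was planted: the answer key for recovery experiments."""

    parcel_labels: np.ndarray          # 1..K per seed-mask voxel (index order)
    seed_voxel_index: np.ndarray       # (n_seed, 3) voxel coordinates
    network_map: dict                   # parcel label -> (n, 3) voxel coords
    planted_slopes: dict                # group -> z-units per log-year
    spike_frames: list

    def to_json(self) -> str:
        payload = {
            "parcel_labels": self.parcel_labels.tolist(),
            "seed_voxel_index": self.seed_voxel_index.tolist(),
            "network_map": {str(k): np.asarray(v).tolist()
                            for k, v in self.network_map.items()},
            "planted_slopes": self.planted_slopes,
            "spike_frames": list(self.spike_frames),
        }
        return json.dumps(payload, indent=1)


class GeometryError(ValueError):
    """Raised when parcel/network voxel sets overlap or are empty."""


@dataclass
class PhantomSpec:
    """Parameters of one synthetic subject.

    ``parcel_geometry`` and ``network_geometry`` are lists (length K) of
    voxel-index arrays; parcels must be disjoint and lie inside the seed
    mask, networks disjoint from each other and from every parcel.
    """

    grid_shape: tuple = (12, 12, 6)
    voxel_size: tuple = (3.0, 3.0, 3.0)
    n_timepoints: int = 200
    tr: float = 2.0
    n_parcels: int = 6
    parcel_geometry: list = None
    network_geometry: list = None
    signal_corr: float = 0.7
    noise_sd: float = 1.0
    ar_coeff: float = 0.3
    spike_frames: list = field(default_factory=list)
    seed: int = 0
    spike_motion_mm: float = 1.0
    spike_intensity_pct: float = 2.0
    baseline: float = 1000.0

    def __post_init__(self):
        if self.parcel_geometry is None or self.network_geometry is None:
            parcels, networks = _default_geometry(self.grid_shape, self.n_parcels)
            if self.parcel_geometry is None:
                self.parcel_geometry = parcels
            if self.network_geometry is None:
                self.network_geometry = networks
        self.parcel_geometry = [np.asarray(p, dtype=int) for p in self.parcel_geometry]
        self.network_geometry = [np.asarray(p, dtype=int) for p in self.network_geometry]
        self.validate()

    def validate(self):
        if not (0.0 <= self.signal_corr < 1.0 + 1e-12):
            raise ValueError("signal_corr must lie in [0, 1]")
        if len(self.parcel_geometry) != self.n_parcels:
            raise GeometryError("need one parcel voxel set per parcel")
        if len(self.network_geometry) != self.n_parcels:
            raise GeometryError("need one network voxel set per parcel")
        seen = set()
        for name, sets in (("parcel", self.parcel_geometry),
                           ("network", self.network_geometry)):
            for vox in sets:
                if vox.size == 0:
                    raise GeometryError(f"empty {name} voxel set")
                keys = {tuple(v) for v in vox}
                if seen & keys:
                    raise GeometryError("parcel/network voxel sets overlap")
                seen |= keys

    def masks(self) -> PhantomMasks:
        """Tissue masks implied by the geometry.

        Grey matter is everything except two small corner blocks reserved
        for white matter and CSF (so tissue-PC extraction has somewhere to
        look); the seed mask is the union of the parcels.
        """
        shape = tuple(self.grid_shape)
        seed = np.zeros(shape, dtype=bool)
        for vox in self.parcel_geometry:
            seed[tuple(vox.T)] = True
        wm = np.zeros(shape, dtype=bool)
        csf = np.zeros(shape, dtype=bool)
        wm[0:2, shape[1] - 2:, 0:2] = True
        csf[2:4, shape[1] - 2:, 0:2] = True
        # WM/CSF blocks must not collide with planted structure
        for vox in self.parcel_geometry + self.network_geometry:
            if wm[tuple(vox.T)].any() or csf[tuple(vox.T)].any():
                raise GeometryError("WM/CSF blocks overlap planted geometry")
        gm = ~(wm | csf)
        return PhantomMasks(seed=seed, gm=gm, wm=wm, csf=csf)

    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.voxel_size
        return aff


def _default_geometry(grid_shape, n_parcels):
    """2x2x2 parcel blocks along x at the front of the grid; matching
    network blocks at the back, spatially separated from the seed."""
    nx, ny, nz = grid_shape
    if 2 * n_parcels > nx or ny < 9 or nz < 5:
        raise GeometryError("grid too small for the default geometry")
    parcels, networks = [], []
    for k in range(n_parcels):
        xs = slice(2 * k, 2 * k + 2)
        parcels.append(_block(xs, slice(1, 3), slice(1, 3)))
        networks.append(_block(xs, slice(7, 9), slice(3, 5)))
    return parcels, networks


def _block(xs, ys, zs):
    grid = np.mgrid[xs, ys, zs]
    return grid.reshape(3, -1).T


def _ar1(rng, n, phi):
    """Unit-marginal-variance AR(1) series."""
    e = rng.standard_normal(n)
    if phi == 0.0:
        return e
    x = np.empty(n)
    x[0] = e[0]
    c = np.sqrt(1.0 - phi * phi)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + c * e[t]
    return x


def default_phantom_spec(**overrides) -> PhantomSpec:
    """The default study phantom: K=6 parcels, latent coupling 0.7,
    unit voxel noise, 200 volumes at TR 2 s on a 12x12x6 grid of 3 mm
    voxels."""
    return PhantomSpec(**overrides)


def make_phantom_subject(spec: PhantomSpec, subject_seed: int,
                         pair_corr: Sequence[float] | None = None):
    """Simulate one subject.

    Parameters
    ----------
    spec : PhantomSpec
    subject_seed : int
        Combined with ``spec.seed`` to give a reproducible per-subject
        stream; identical (spec, subject_seed) yields bit-identical output.
    pair_corr : sequence of float, optional
        Per-parcel latent coupling overriding ``spec.signal_corr``; used by
        :func:`make_cohort` to modulate one pair's connectivity with age.

    Returns
    -------
    (BoldSeries, PhantomMasks, motion DataFrame, GroundTruth)
    """
    spec.validate()
    masks = spec.masks()
    rng = np.random.default_rng([int(spec.seed), int(subject_seed)])
    T = spec.n_timepoints
    shape = tuple(spec.grid_shape)
    K = spec.n_parcels
    if pair_corr is None:
        pair_corr = [spec.signal_corr] * K
    pair_corr = np.asarray(pair_corr, dtype=float)
    if np.any(pair_corr < 0) or np.any(pair_corr >= 1.0):
        raise ValueError("pair correlations must lie in [0, 1)")

    data = np.zeros(shape + (T,))
    labels = []
    coords = []
    network_map = {}
    for k in range(K):
        u = _ar1(rng, T, spec.ar_coeff)
        w = _ar1(rng, T, spec.ar_coeff)
        c = pair_corr[k]
        v = c * u + np.sqrt(1.0 - c * c) * w
        pvox = spec.parcel_geometry[k]
        nvox = spec.network_geometry[k]
        data[tuple(pvox.T)] = u + spec.noise_sd * rng.standard_normal((len(pvox), T))
        data[tuple(nvox.T)] = v + spec.noise_sd * rng.standard_normal((len(nvox), T))
        labels.extend([k + 1] * len(pvox))
        coords.append(pvox)
        network_map[k + 1] = nvox

    # background grey matter: independent unit-variance noise, so no voxel
    # is degenerate and the sampling null is exercised
    planted = np.zeros(shape, dtype=bool)
    for vox in spec.parcel_geometry + spec.network_geometry:
        planted[tuple(vox.T)] = True
    bg = masks.gm & ~planted
    data[bg] = rng.standard_normal((int(bg.sum()), T))

    # WM/CSF compartments share a tissue latent so PCA finds real structure
    for tissue in (masks.wm, masks.csf):
        h = _ar1(rng, T, spec.ar_coeff)
        n = int(tissue.sum())
        data[tissue] = 0.8 * h + 0.6 * rng.standard_normal((n, T))

    brain = masks.gm | masks.wm | masks.csf
    data[brain] += spec.baseline

    # motion: still head except sustained displacement steps at spike frames;
    # the intensity steps in lockstep, so FD and DVARS each flag exactly
    # the spike frame
    motion = np.zeros((T, 6))
    step = spec.baseline * spec.spike_intensity_pct / 100.0
    for i, s in enumerate(spec.spike_frames):
        if not 0 <= s < T:
            raise ValueError(f"spike frame {s} outside the series")
        sign = 1.0 if i % 2 == 0 else -1.0
        motion[s:, 0] += sign * spec.spike_motion_mm
        data[brain, s:] += sign * step

    motion_df = pd.DataFrame(
        motion, columns=["tx_mm", "ty_mm", "tz_mm", "rx_rad", "ry_rad", "rz_rad"])

    seed_index = np.vstack(coords)
    truth = GroundTruth(
        parcel_labels=np.asarray(labels, dtype=int),
        seed_voxel_index=seed_index,
        network_map=network_map,
        planted_slopes={},
        spike_frames=list(spec.spike_frames),
    )
    bold = BoldSeries(data=data, tr=spec.tr, affine=spec.affine())
    return bold, masks, motion_df, truth


class CohortError(ValueError):
    pass


@dataclass
class CohortSpec:
    """A two-group cohort with an optional planted Group x Age effect.

    ``interaction_slope`` is the difference (group A minus group B) in the
    slope of Fisher-z connectivity on log(age in years) for the designated
    parcel/network pair (parcel 1 by default).  Slopes are split
    symmetrically (+d/2 and -d/2) around the base coupling.
    """

    n_per_group: int = 10
    age_range: tuple = (7.0, 32.0)
    interaction_slope: float = 0.0
    centre_labels: tuple = ("c1", "c2")
    phantom: PhantomSpec = None
    groups: tuple = ("A", "B")
    target_parcel: int = 1
    fiq_mean: float = 108.0
    fiq_sd: float = 12.0

    def __post_init__(self):
        if self.phantom is None:
            self.phantom = default_phantom_spec()
        if self.n_per_group < 2:
            raise CohortError("need at least 2 subjects per group")
        if len(self.centre_labels) < 1:
            raise CohortError("need at least one centre label")


def make_cohort(spec: CohortSpec):
    """Simulate a cohort.

    Returns ``(subjects, covariates, truth)`` where ``subjects`` is a list
    of per-subject tuples as returned by :func:`make_phantom_subject`,
    ``covariates`` is a DataFrame with columns (subject_id, group,
    age_years, fiq, centre), and ``truth`` records the planted slopes.

    Ages are uniform over ``age_range``; centre assignment cycles through
    ``centre_labels`` within each group so blocks stay balanced.
    """
    ph = spec.phantom
    rng = np.random.default_rng([int(ph.seed), 987654321])
    k0 = spec.target_parcel - 1
    if not 0 <= k0 < ph.n_parcels:
        raise CohortError("target_parcel outside 1..K")
    lo, hi = spec.age_range
    log_mid = 0.5 * (np.log(lo) + np.log(hi))
    half = spec.interaction_slope / 2.0
    slopes = {spec.groups[0]: +half, spec.groups[1]: -half}
    base_z = np.arctanh(min(ph.signal_corr, 1 - 1e-7))

    subjects, rows = [], []
    sid = 0
    for g in spec.groups:
        for i in range(spec.n_per_group):
            age = rng.uniform(lo, hi)
            fiq = float(np.clip(rng.normal(spec.fiq_mean, spec.fiq_sd), 81, 140))
            centre = spec.centre_labels[i % len(spec.centre_labels)]
            z_pair = base_z + slopes[g] * (np.log(age) - log_mid)
            pair = [ph.signal_corr] * ph.n_parcels
            pair[k0] = float(np.tanh(np.clip(z_pair, 0.0, 8.0)))
            out = make_phantom_subject(ph, subject_seed=sid + 1, pair_corr=pair)
            subjects.append(out)
            rows.append({"subject_id": f"sub-{sid:03d}", "group": g,
                         "age_years": age, "fiq": fiq, "centre": centre})
            sid += 1

    covariates = pd.DataFrame(rows)
    truth = subjects[0][3]
    truth = GroundTruth(
        parcel_labels=truth.parcel_labels,
        seed_voxel_index=truth.seed_voxel_index,
        network_map=truth.network_map,
        planted_slopes=slopes,
        spike_frames=list(ph.spike_frames),
    )
    return subjects, covariates, truth
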