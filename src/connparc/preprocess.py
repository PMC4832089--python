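"""Single-subject denoising: scrubbing, motion regression, band-pass.

The stages follow the common resting-state recipe: censor volumes with
excessive framewise displacement (FD) or signal change (DVARS), regress a
24-parameter motion expansion plus the leading principal components of the
white-matter and CSF compartments, and band-pass filter 0.009-0.2 Hz.
All operations act on 2D (time x voxel) arrays; NIfTI handling lives at
the pipeline layer.

Default stage order is scrub -> regress -> band-pass, with confounds
censored identically to the data; the alternative band-pass-first order is
available via :class:`ConfoundCleaner`'s ``order`` parameter and every run
records which order was used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sp_linalg
from scipy import signal as sp_signal
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "MotionParams",
    "CensorMask",
    "NuisanceSet",
    "framewise_displacement",
    "dvars",
    "scrub",
    "friston24",
    "tissue_pcs",
    "bandpass",
    "smooth",
    "regress_nuisance",
    "build_nuisance",
    "ConfoundCleaner",
]

MOTION_COLUMNS = ("tx_mm", "ty_mm", "tz_mm", "rx_rad", "ry_rad", "rz_rad")


class DegenerateSeriesError(ValueError):
    """All volumes censored, or a normalization is undefined."""


@dataclass
class CensorMask:
    """Per-volume keep flags plus the thresholds that produced them."""

    keep: np.ndarray
    fd_thresh: float
    dvars_thresh: float

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())

    def to_dict(self):
        return {"keep": self.keep.astype(int).tolist(),
                "fd_thresh": self.fd_thresh, "dvars_thresh": self.dvars_thresh}


@dataclass
class NuisanceSet:
    """Named confound matrix (volumes x regressors)."""

    matrix: np.ndarray
    names: list
    warnings: list = field(default_factory=list)


def _as_motion(m) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[1] != 6:
        raise ValueError(f"motion parameters must be (n_volumes, 6), got {m.shape}")
    return m


def framewise_displacement(m, head_radius_mm: float = 50.0) -> np.ndarray:
    """Power-style FD: sum of absolute backward differences of the six
    rigid-body parameters, rotations converted to arc length on a sphere
    of ``head_radius_mm``.  FD[0] = 0 by convention."""
    m = _as_motion(m)
    d = np.abs(np.diff(m, axis=0))
    d[:, 3:] *= head_radius_mm
    fd = np.zeros(m.shape[0])
    fd[1:] = d.sum(axis=1)
    return fd


def dvars(data, mask=None) -> np.ndarray:
    """DVARS as percent of the within-mask temporal mean.

    ``data`` is either a 2D (time x voxel) array (mask ignored) or a 4D
    volume with a 3D boolean ``mask``.  DVARS[t] is the RMS over voxels of
    the backward difference, divided by the grand temporal mean, x100;
    DVARS[0] = 0.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim == 4:
        if mask is None:
            raise ValueError("4D input requires a mask")
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("empty mask")
        ts = data[mask].T  # (time, voxel)
    elif data.ndim == 2:
        ts = data
    else:
        raise ValueError("data must be 2D (time x voxel) or 4D")
    grand_mean = ts.mean()
    if abs(grand_mean) < 1e-12:
        raise DegenerateSeriesError("zero temporal mean; DVARS undefined")
    out = np.zeros(ts.shape[0])
    diff = np.diff(ts, axis=0)
    out[1:] = np.sqrt(np.mean(diff ** 2, axis=1)) / abs(grand_mean) * 100.0
    return out


def scrub(fd, dvars_pct, fd_thresh: float = 0.5,
          dvars_thresh: float = 0.5) -> CensorMask:
    """Censor volumes with FD or DVARS strictly above threshold."""
    fd = np.asarray(fd, dtype=float)
    dvars_pct = np.asarray(dvars_pct, dtype=float)
    if fd.shape != dvars_pct.shape:
        raise ValueError("FD and DVARS series must have equal length")
    keep = ~((fd > fd_thresh) | (dvars_pct > dvars_thresh))
    if not keep.any():
        raise DegenerateSeriesError("every volume was censored")
    if keep.sum() < 2:
        warnings.warn("fewer than 2 volumes survive scrubbing; downstream "
                      "stages will fail", RuntimeWarning)
    return CensorMask(keep=keep, fd_thresh=fd_thresh, dvars_thresh=dvars_thresh)


def friston24(m) -> np.ndarray:
    """24-parameter motion expansion: the 6 parameters, the same shifted
    back one volume (first row zero-filled), and both blocks squared."""
    m = _as_motion(m)
    if m.shape[0] < 2:
        raise ValueError("need at least 2 volumes")
    shifted = np.zeros_like(m)
    shifted[1:] = m[:-1]
    return np.hstack([m, shifted, m ** 2, shifted ** 2])


def tissue_pcs(ts, n_components: int = 3):
    """Leading principal component time series of a tissue compartment.

    ``ts`` is (time x voxel); voxels are demeaned in time before the SVD.
    Components are ordered by explained variance and mutually orthogonal.
    If the data rank is below ``n_components``, the available components
    are returned with a warning.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError("tissue series must be 2D (time x voxel)")
    if ts.shape[1] < n_components:
        raise ValueError("mask has fewer voxels than requested components")
    centered = ts - ts.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    tol = s.max(initial=0.0) * max(centered.shape) * np.finfo(float).eps
    rank = int((s > tol).sum())
    k = min(n_components, rank)
    if k < n_components:
        warnings.warn(f"tissue data rank {rank} < {n_components}; "
                      f"returning {k} components", RuntimeWarning)
    return u[:, :k] * s[:k]


def bandpass(ts, low: float = 0.009, high: float = 0.2, tr: float = 2.0,
             order: int = 2) -> np.ndarray:
    """Zero-phase Butterworth band-pass; removes the temporal mean.

    ``high`` must stay below the Nyquist frequency 1/(2 tr).
    """
    ts = np.asarray(ts, dtype=float)
    nyq = 0.5 / tr
    if high >= nyq:
        raise ValueError(f"high cutoff {high} Hz >= Nyquist {nyq} Hz")
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    ts = ts - ts.mean(axis=0, keepdims=True)
    sos = sp_signal.butter(order, [low / nyq, high / nyq], btype="band",
                           output="sos")
    out = sp_signal.sosfiltfilt(sos, ts, axis=0)
    return out - out.mean(axis=0, keepdims=True)


def smooth(data, fwhm_mm: float, voxel_size) -> np.ndarray:
    """Optional isotropic Gaussian smoothing of a 3D or 4D volume.

    ``fwhm_mm`` is the kernel full width at half maximum; smoothing is
    applied in space only (never across time).  Off by default in the
    pipeline; provided for parity with conventional volumetric
    preprocessing.
    """
    from scipy import ndimage
    data = np.asarray(data, dtype=float)
    voxel_size = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
    sigma_mm = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sigma_vox = sigma_mm / voxel_size
    if data.ndim == 3:
        return ndimage.gaussian_filter(data, sigma=sigma_vox)
    if data.ndim == 4:
        return ndimage.gaussian_filter(
            data, sigma=tuple(sigma_vox) + (0.0,))
    raise ValueError("expected a 3D or 4D volume")


def regress_nuisance(ts, confounds, keep=None, add_intercept: bool = True):
    """Project confounds out of every voxel time series.

    Censored volumes (``keep`` false) are excluded from both the fit and
    the output.  Collinear confound columns are dropped with a warning via
    a rank-revealing QR.  Residuals are orthogonal to every retained
    confound column over the retained volumes.
    """
    ts = np.asarray(ts, dtype=float)
    confounds = np.asarray(confounds, dtype=float)
    if confounds.ndim == 1:
        confounds = confounds[:, None]
    if confounds.shape[0] != ts.shape[0]:
        raise ValueError("confounds and series must cover the same volumes")
    if keep is None:
        keep = np.ones(ts.shape[0], dtype=bool)
    else:
        keep = np.asarray(keep, dtype=bool)
    y = ts[keep]
    x = confounds[keep]
    if add_intercept:
        x = np.column_stack([np.ones(x.shape[0]), x])
    # rank-revealing column selection
    q, r, piv = sp_linalg.qr(x, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max(initial=0.0) * max(x.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank < x.shape[1]:
        warnings.warn(f"dropping {x.shape[1] - rank} collinear confound "
                      "column(s)", RuntimeWarning)
        x = x[:, np.sort(piv[:rank])]
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ beta


def build_nuisance(motion, wm_ts, csf_ts, censor: CensorMask | None = None,
                   n_tissue_pcs: int = 3) -> NuisanceSet:
    """Assemble the full confound matrix: 24 motion columns plus the
    leading WM and CSF principal components (computed on retained volumes
    only, then re-embedded as full-length columns with censored rows
    zero-filled — those rows never enter any fit)."""
    m24 = friston24(motion)
    T = m24.shape[0]
    keep = censor.keep if censor is not None else np.ones(T, dtype=bool)
    names = [f"motion_{i:02d}" for i in range(24)]
    cols = [m24]
    warns = []
    for label, ts in (("wm", wm_ts), ("csf", csf_ts)):
        pcs = tissue_pcs(np.asarray(ts)[keep], n_components=n_tissue_pcs)
        full = np.zeros((T, pcs.shape[1]))
        full[keep] = pcs
        cols.append(full)
        names.extend(f"{label}_pc{i + 1}" for i in range(pcs.shape[1]))
        if pcs.shape[1] < n_tissue_pcs:
            warns.append(f"{label}: rank-deficient, {pcs.shape[1]} PCs")
    return NuisanceSet(matrix=np.hstack(cols), names=names, warnings=warns)


class ConfoundCleaner(BaseEstimator, TransformerMixin):
    """Scrub, regress and band-pass a (time x voxel) series.

    scikit-learn style transformer.  ``fit`` derives the censor mask and
    confound matrix from the motion table and tissue series supplied as
    fit parameters; ``transform`` returns the cleaned series restricted to
    retained volumes.

    Parameters
    ----------
    fd_thresh, dvars_thresh : censoring thresholds (mm, percent).
    low, high, tr : band-pass edges (Hz) and sampling interval (s).
    n_tissue_pcs : components per tissue compartment.
    order : ``"scrub-regress-bandpass"`` (default) or
        ``"scrub-bandpass-regress"`` (confounds filtered identically).
    head_radius_mm : rotation-to-arc-length radius for FD.
    """

    def __init__(self, fd_thresh=0.5, dvars_thresh=0.5, low=0.009, high=0.2,
                 tr=2.0, n_tissue_pcs=3, order="scrub-regress-bandpass",
                 head_radius_mm=50.0):
        self.fd_thresh = fd_thresh
        self.dvars_thresh = dvars_thresh
        self.low = low
        self.high = high
        self.tr = tr
        self.n_tissue_pcs = n_tissue_pcs
        self.order = order
        self.head_radius_mm = head_radius_mm

    def fit(self, X, y=None, *, motion=None, wm_ts=None, csf_ts=None):
        X = np.asarray(X, dtype=float)
        if motion is None:
            motion = np.zeros((X.shape[0], 6))
        motion = _as_motion(np.asarray(motion, dtype=float))
        fd = framewise_displacement(motion, self.head_radius_mm)
        dv = dvars(X)
        self.censor_ = scrub(fd, dv, self.fd_thresh, self.dvars_thresh)
        self.fd_ = fd
        self.dvars_ = dv
        if wm_ts is None or csf_ts is None:
            m24 = friston24(motion)
            self.nuisance_ = NuisanceSet(
                matrix=m24, names=[f"motion_{i:02d}" for i in range(24)])
        else:
            self.nuisance_ = build_nuisance(
                motion, wm_ts, csf_ts, self.censor_, self.n_tissue_pcs)
        self.stage_log_ = self.order.split("-")
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        keep = self.censor_.keep
        conf = self.nuisance_.matrix
        if self.order == "scrub-regress-bandpass":
            resid = regress_nuisance(X, conf, keep=keep)
            return bandpass(resid, self.low, self.high, self.tr)
        elif self.order == "scrub-bandpass-regress":
            filt = bandpass(X[keep], self.low, self.high, self.tr)
            fconf = bandpass(conf[keep] - conf[keep].mean(0), self.low,
                             self.high, self.tr)
            return regress_nuisance(filt, fconf)
        raise ValueError(f"unknown stage order {self.order!r}")
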