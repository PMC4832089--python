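"""File-format helpers: NIfTI-1 volumes, motion/covariate TSVs, JSON."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import BoldSeries
from .preprocess import MOTION_COLUMNS

__all__ = [
    "save_nifti", "load_nifti", "load_bold", "save_bold",
    "save_motion_tsv", "load_motion_tsv",
    "save_covariates_tsv", "load_covariates_tsv",
    "save_json", "load_json",
]


def save_nifti(data, affine, path):
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), np.asarray(affine))
    nib.save(img, str(path))


def load_nifti(path):
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def save_bold(bold: BoldSeries, path):
    img = nib.Nifti1Image(np.asarray(bold.data, dtype=np.float64), bold.affine)
    img.header.set_zooms(tuple(img.header.get_zooms()[:3]) + (bold.tr,))
    nib.save(img, str(path))


def load_bold(path) -> BoldSeries:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 else 1.0
    return BoldSeries(data=np.asarray(img.get_fdata()), tr=tr,
                      affine=img.affine)


def save_motion_tsv(motion: pd.DataFrame, path):
    motion.to_csv(path, sep="\t", index=False)


def load_motion_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MOTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"motion table missing columns {missing}")
    return df[list(MOTION_COLUMNS)]


def save_covariates_tsv(cov: pd.DataFrame, path):
    cov.to_csv(path, sep="\t", index=False)


def load_covariates_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_json(obj, path):
    Path(path).write_text(json.dumps(obj, indent=1, default=_coerce))


def load_json(path):
    return json.loads(Path(path).read_text())


def _coerce(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
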