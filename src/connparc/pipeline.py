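"""Config-driven orchestration: simulate -> filter -> preprocess ->
connectivity -> parcellate -> atlas -> seedmaps -> glm.

Each stage reads the previous stage's on-disk outputs from the workspace
directory, so stages can be toggled and rerun independently; every run
writes a provenance record (resolved config, config hash, stage log).
Identical config and seeds reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .phantom import PhantomSpec, CohortSpec, make_cohort
from .preprocess import ConfoundCleaner, framewise_displacement
from .connectivity import (ConnectivityMatrix, mask_to_gm_matrix,
                           group_fixed_effects, seed_to_voxel_map)
from .parcellation import FingerprintParcellation, subject_solution
from .matching import (match_clusters, replication_rates,
                       build_probability_maps, winner_take_all)
from .glm import permutation_glm

logger = logging.getLogger(__name__)

STAGES = ("simulate", "filter", "preprocess", "connectivity", "parcellate",
          "atlas", "seedmaps", "glm")


@dataclass
class CohortFilterRules:
    """Subject- and centre-level inclusion rules."""

    max_mean_fd: float = 0.5
    min_iq: float = 80.0
    max_age: float = 40.0
    min_group_size_per_centre: int = 7

    def __post_init__(self):
        for f in ("max_mean_fd", "min_iq", "max_age"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")


def filter_cohort(covariates: pd.DataFrame, mean_fd,
                  rules: CohortFilterRules):
    """Apply exclusion rules; returns (retained ids, exclusion log).

    Subject rules first (mean FD, IQ, age, optional manifest-level flags
    in an ``exclude_flag`` column), then centres left with fewer than
    ``min_group_size_per_centre`` subjects in either group are dropped
    wholesale.  Every exclusion is logged with its triggering rule(s).
    """
    cov = covariates.reset_index(drop=True)
    fd = pd.Series(mean_fd)
    log = []
    excluded = set()
    for _, row in cov.iterrows():
        sid = row["subject_id"]
        reasons = []
        if fd.get(sid, 0.0) > rules.max_mean_fd:
            reasons.append("mean_fd")
        if row.get("fiq", np.inf) < rules.min_iq:
            reasons.append("min_iq")
        if row.get("age_years", 0.0) > rules.max_age:
            reasons.append("max_age")
        if bool(row.get("exclude_flag", False)):
            reasons.append("manifest_flag")
        if reasons:
            excluded.add(sid)
            log.append({"subject_id": sid, "rules": reasons})
    remaining = cov[~cov["subject_id"].isin(excluded)]
    for centre, sub in remaining.groupby("centre"):
        sizes = sub.groupby("group").size()
        groups = cov["group"].unique()
        if any(sizes.get(g, 0) < rules.min_group_size_per_centre
               for g in groups):
            for sid in sub["subject_id"]:
                excluded.add(sid)
                log.append({"subject_id": sid, "rules": ["centre_too_small"]})
    retained = [s for s in cov["subject_id"] if s not in excluded]
    if not retained:
        raise ValueError("cohort filter removed every subject")
    return retained, log


@dataclass
class PipelineConfig:
    """Resolved parameters of a full run; round-trips through JSON."""

    output_dir: str = "connparc_out"
    stages: tuple = STAGES
    seed: int = 0
    simulate: dict = field(default_factory=lambda: {
        "n_per_group": 4, "n_timepoints": 120, "n_parcels": 6,
        "signal_corr": 0.7, "noise_sd": 1.0, "interaction_slope": 0.0,
        "spike_frames": []})
    filter: dict = field(default_factory=lambda: asdict(CohortFilterRules(
        min_group_size_per_centre=1)))
    preprocess: dict = field(default_factory=lambda: {
        "fd_thresh": 0.5, "dvars_thresh": 0.5, "low": 0.009, "high": 0.2,
        "n_tissue_pcs": 3, "order": "scrub-regress-bandpass"})
    parcellate: dict = field(default_factory=lambda: {
        "n_levels": 100, "metric": "corrdist", "n_clusters": None})
    atlas: dict = field(default_factory=lambda: {"threshold": 0.25})
    glm: dict = field(default_factory=lambda: {
        "contrast": "group_x_age", "n_perm": 200, "forming_z": 3.1,
        "seed_cluster": 1})

    def to_json(self) -> str:
        d = asdict(self)
        d["stages"] = list(self.stages)
        return json.dumps(d, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        d["stages"] = tuple(d.get("stages", STAGES))
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


class PipelineError(RuntimeError):
    pass


def _subject_ids(workdir):
    cov = cio.load_covariates_tsv(workdir / "covariates.tsv")
    return list(cov["subject_id"]), cov


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in order; returns the provenance
    record (also written to ``provenance.json`` in the output directory).
    Raises :class:`PipelineError` naming the missing input when a stage's
    prerequisites are absent."""
    workdir = Path(config.output_dir)
    workdir.mkdir(parents=True, exist_ok=True)
    provenance = {"config_hash": config.config_hash(), "seed": config.seed,
                  "stages_run": [], "events": []}
    for stage in config.stages:
        if stage not in STAGES:
            raise PipelineError(f"unknown stage {stage!r}")
        logger.info("pipeline stage: %s", stage)
        _STAGE_FUNCS[stage](config, workdir, provenance)
        provenance["stages_run"].append(stage)
    provenance["resolved_config"] = json.loads(config.to_json())
    cio.save_json(provenance, workdir / "provenance.json")
    return provenance


def _stage_simulate(config, workdir, prov):
    p = dict(config.simulate)
    if p.get("n_per_group", 0) < 1:
        raise PipelineError("no subjects requested ('no subjects' error)")
    phantom = PhantomSpec(
        n_timepoints=p.get("n_timepoints", 120),
        n_parcels=p.get("n_parcels", 6),
        signal_corr=p.get("signal_corr", 0.7),
        noise_sd=p.get("noise_sd", 1.0),
        spike_frames=list(p.get("spike_frames", [])),
        seed=config.seed)
    spec = CohortSpec(n_per_group=p.get("n_per_group", 4),
                      interaction_slope=p.get("interaction_slope", 0.0),
                      phantom=phantom)
    subjects, cov, truth = make_cohort(spec)
    masks = subjects[0][1]
    for name, m in (("seed", masks.seed), ("gm", masks.gm),
                    ("wm", masks.wm), ("csf", masks.csf)):
        cio.save_nifti(m.astype(float), phantom.affine(),
                       workdir / f"mask_{name}.nii")
    for (bold, _, motion, _), sid in zip(subjects, cov["subject_id"]):
        cio.save_bold(bold, workdir / f"{sid}_bold.nii")
        cio.save_motion_tsv(motion, workdir / f"{sid}_motion.tsv")
        cio.save_nifti(masks.gm.astype(float), phantom.affine(),
                       workdir / f"{sid}_gmprob.nii")
    cio.save_covariates_tsv(cov, workdir / "covariates.tsv")
    (workdir / "ground_truth.json").write_text(truth.to_json())
    prov["events"].append({"stage": "simulate", "n_subjects": len(subjects)})


def _stage_filter(config, workdir, prov):
    cov_path = workdir / "covariates.tsv"
    if not cov_path.exists():
        raise PipelineError(f"missing input: {cov_path}")
    cov = cio.load_covariates_tsv(cov_path)
    mean_fd = {}
    for sid in cov["subject_id"]:
        mpath = workdir / f"{sid}_motion.tsv"
        if not mpath.exists():
            raise PipelineError(f"missing input: {mpath}")
        fd = framewise_displacement(cio.load_motion_tsv(mpath).to_numpy())
        mean_fd[sid] = float(fd.mean())
    rules = CohortFilterRules(**config.filter)
    retained, log = filter_cohort(cov, mean_fd, rules)
    cio.save_json({"retained": retained, "excluded": log, "mean_fd": mean_fd},
                  workdir / "cohort_filter.json")
    prov["events"].append({"stage": "filter", "n_retained": len(retained),
                           "n_excluded": len(log)})


def _retained(workdir):
    f = workdir / "cohort_filter.json"
    ids, cov = _subject_ids(workdir)
    if f.exists():
        ids = cio.load_json(f)["retained"]
    return ids, cov


def _stage_preprocess(config, workdir, prov):
    ids, _ = _retained(workdir)
    p = config.preprocess
    gm, _ = cio.load_nifti(workdir / "mask_gm.nii")
    wm, _ = cio.load_nifti(workdir / "mask_wm.nii")
    csf, _ = cio.load_nifti(workdir / "mask_csf.nii")
    gm, wm, csf = gm > 0.5, wm > 0.5, csf > 0.5
    brain = gm | wm | csf
    for sid in ids:
        bold = cio.load_bold(workdir / f"{sid}_bold.nii")
        motion = cio.load_motion_tsv(workdir / f"{sid}_motion.tsv").to_numpy()
        ts = bold.data[brain].T
        cleaner = ConfoundCleaner(
            fd_thresh=p["fd_thresh"], dvars_thresh=p["dvars_thresh"],
            low=p["low"], high=p["high"], tr=bold.tr,
            n_tissue_pcs=p["n_tissue_pcs"], order=p["order"])
        cleaner.fit(ts, motion=motion, wm_ts=bold.data[wm].T,
                    csf_ts=bold.data[csf].T)
        cleaned = cleaner.transform(ts)
        out = np.zeros(brain.shape + (cleaned.shape[0],))
        out[brain] = cleaned.T
        cio.save_bold(type(bold)(data=out, tr=bold.tr, affine=bold.affine),
                      workdir / f"{sid}_clean.nii")
        cio.save_json(cleaner.censor_.to_dict(), workdir / f"{sid}_censor.json")
        pd.DataFrame(cleaner.nuisance_.matrix,
                     columns=cleaner.nuisance_.names).to_csv(
            workdir / f"{sid}_confounds.tsv", sep="\t", index=False)
    prov["events"].append({"stage": "preprocess", "n_subjects": len(ids),
                           "order": p["order"]})


def _stage_connectivity(config, workdir, prov):
    ids, _ = _retained(workdir)
    seed, _ = cio.load_nifti(workdir / "mask_seed.nii")
    gm, _ = cio.load_nifti(workdir / "mask_gm.nii")
    seed, gm = seed > 0.5, gm > 0.5
    for sid in ids:
        path = workdir / f"{sid}_clean.nii"
        if not path.exists():
            raise PipelineError(f"missing input: {path}")
        bold = cio.load_bold(path)
        mat = mask_to_gm_matrix(bold.data, seed, gm, subject_id=sid)
        np.save(workdir / f"{sid}_connmat.npy", mat.values)
        cio.save_json({"subject_id": sid,
                       "seed_voxel_index": mat.seed_voxel_index,
                       "gm_voxel_index": mat.gm_voxel_index},
                      workdir / f"{sid}_connmat.json")
    prov["events"].append({"stage": "connectivity", "n_subjects": len(ids)})


def _load_matrices(workdir, ids):
    mats = []
    for sid in ids:
        vals = np.load(workdir / f"{sid}_connmat.npy")
        meta = cio.load_json(workdir / f"{sid}_connmat.json")
        mats.append(ConnectivityMatrix(
            values=vals,
            seed_voxel_index=np.asarray(meta["seed_voxel_index"]),
            gm_voxel_index=np.asarray(meta["gm_voxel_index"]),
            subject_id=sid))
    return mats


def _stage_parcellate(config, workdir, prov):
    ids, _ = _retained(workdir)
    mats = _load_matrices(workdir, ids)
    group_r = group_fixed_effects(mats)
    p = config.parcellate
    model = FingerprintParcellation(n_clusters=p.get("n_clusters"),
                                    n_levels=p.get("n_levels", 100),
                                    metric=p.get("metric", "corrdist"))
    model.fit(group_r, subject_matrices=None if p.get("n_clusters") else mats)
    sol = model.solution_
    _, aff = cio.load_nifti(workdir / "mask_seed.nii")
    vol = np.zeros(cio.load_nifti(workdir / "mask_seed.nii")[0].shape)
    vol[tuple(mats[0].seed_voxel_index.T)] = sol.labels
    cio.save_nifti(vol, aff, workdir / "group_parcellation.nii")
    record = {"k": sol.k, "cut_level": sol.cut_level,
              "labels": sol.labels}
    if getattr(model, "profile_", None) is not None:
        pr = model.profile_
        record["silhouette_t_max"] = float(np.nanmax(pr.t_scores))
        record["local_maxima_k"] = [int(pr.k_per_level[i])
                                    for i in pr.local_maxima]
    cio.save_json(record, workdir / "group_parcellation.json")
    prov["events"].append({"stage": "parcellate", "k": sol.k})


def _stage_atlas(config, workdir, prov):
    ids, cov_df = _retained(workdir)
    mats = _load_matrices(workdir, ids)
    rec = cio.load_json(workdir / "group_parcellation.json")
    from .parcellation import ParcelSolution
    group_sol = ParcelSolution(labels=np.asarray(rec["labels"]),
                               k=rec["k"], cut_level=rec["cut_level"])
    voxel_index = mats[0].seed_voxel_index
    grid_shape = cio.load_nifti(workdir / "mask_seed.nii")[0].shape
    reports = []
    masks_by_cluster = {lab: [] for lab in np.unique(group_sol.labels)}
    for mat in mats:
        sub_sol = subject_solution(mat, group_sol.k)
        rep = match_clusters(group_sol, sub_sol, voxel_index,
                             subject_id=mat.subject_id)
        reports.append(rep)
        for m in rep.matches:
            vol = np.zeros(grid_shape, dtype=bool)
            vox = voxel_index[sub_sol.labels == m.subject_cluster]
            vol[tuple(vox.T)] = True
            masks_by_cluster[m.group_cluster].append(vol)
    groups = cov_df.set_index("subject_id").loc[ids, "group"].to_numpy()
    rates, chi2 = replication_rates(reports, groups=groups)
    atlas = build_probability_maps(masks_by_cluster, n_subjects=len(ids))
    atlas = winner_take_all(atlas, threshold=config.atlas["threshold"])
    _, aff = cio.load_nifti(workdir / "mask_seed.nii")
    for i, lab in enumerate(atlas.cluster_labels):
        cio.save_nifti(atlas.probabilities[i], aff,
                       workdir / f"atlas_prob_cluster{lab}.nii")
    cio.save_nifti(atlas.wta_labels.astype(float), aff,
                   workdir / "atlas_wta.nii")
    dice_stats = {}
    for lab in atlas.cluster_labels:
        ds = [r.dice_for(lab) for r in reports if r.dice_for(lab) is not None]
        dice_stats[int(lab)] = {"mean": float(np.mean(ds)) if ds else None,
                                "sd": float(np.std(ds, ddof=1))
                                if len(ds) > 1 else None}
    cio.save_json({"replication_pct": {int(k): v for k, v in rates.items()},
                   "chi2_group_p": {int(k): v for k, v in chi2.items()},
                   "dice": dice_stats,
                   "threshold": config.atlas["threshold"]},
                  workdir / "atlas_report.json")
    prov["events"].append({"stage": "atlas",
                           "min_replication": min(rates.values())})


def _stage_seedmaps(config, workdir, prov):
    ids, _ = _retained(workdir)
    wta, _ = cio.load_nifti(workdir / "atlas_wta.nii")
    gm, _ = cio.load_nifti(workdir / "mask_gm.nii")
    gm = gm > 0.5
    labels = sorted(int(v) for v in np.unique(wta) if v > 0)
    for sid in ids:
        bold = cio.load_bold(workdir / f"{sid}_clean.nii")
        for lab in labels:
            seed_vox = np.argwhere(wta == lab)
            smap = seed_to_voxel_map(bold.data, seed_vox, gm,
                                     seed_descriptor=f"cluster{lab}",
                                     subject_id=sid)
            vol = np.zeros(gm.shape)
            vol[tuple(smap.gm_voxel_index.T)] = smap.values
            cio.save_nifti(vol, bold.affine,
                           workdir / f"{sid}_seedmap_cluster{lab}.nii")
    prov["events"].append({"stage": "seedmaps", "clusters": labels})


def _stage_glm(config, workdir, prov):
    ids, cov_df = _retained(workdir)
    p = config.glm
    lab = p.get("seed_cluster", 1)
    gm, aff = cio.load_nifti(workdir / "mask_gm.nii")
    gm = gm > 0.5
    gm_idx = np.argwhere(gm)
    maps, gm_vals = [], []
    for sid in ids:
        path = workdir / f"{sid}_seedmap_cluster{lab}.nii"
        if not path.exists():
            raise PipelineError(f"missing input: {path}")
        vol, _ = cio.load_nifti(path)
        maps.append(vol[gm])
        gvol, _ = cio.load_nifti(workdir / f"{sid}_gmprob.nii")
        gm_vals.append(gvol[gm])
    cov = cov_df.set_index("subject_id").loc[ids].reset_index()
    if "mean_fd" not in cov.columns:
        fdinfo = cio.load_json(workdir / "cohort_filter.json")["mean_fd"] \
            if (workdir / "cohort_filter.json").exists() else {}
        cov["mean_fd"] = [fdinfo.get(s, 0.0) for s in ids]
    use_gm = p.get("voxel_dependent_gm", False)
    res = permutation_glm(
        np.asarray(maps), cov, contrast=p["contrast"],
        n_perm=p["n_perm"], seed=config.seed,
        gm=np.asarray(gm_vals) if use_gm else None,
        voxel_index=gm_idx, grid_shape=gm.shape, forming_z=p["forming_z"])
    vol = np.zeros(gm.shape)
    vol[gm] = res.zmap
    cio.save_nifti(vol, aff, workdir / f"glm_z_{p['contrast']}.nii")
    pvol = np.ones(gm.shape)
    pvol[gm] = res.p_fwe_voxel
    cio.save_nifti(pvol, aff, workdir / f"glm_pfwe_{p['contrast']}.nii")
    res.cluster_table.to_csv(workdir / f"glm_clusters_{p['contrast']}.tsv",
                             sep="\t", index=False)
    prov["events"].append({"stage": "glm", "contrast": p["contrast"],
                           "min_p_fwe": float(res.p_fwe_voxel.min()),
                           "n_clusters": int(len(res.cluster_table))})


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "filter": _stage_filter,
    "preprocess": _stage_preprocess,
    "connectivity": _stage_connectivity,
    "parcellate": _stage_parcellate,
    "atlas": _stage_atlas,
    "seedmaps": _stage_seedmaps,
    "glm": _stage_glm,
}
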