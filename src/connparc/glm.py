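"""Permutation-based group inference on seed-to-voxel connectivity.

The model regresses per-subject Fisher-z maps on scanning centre, mean
framewise displacement, full-scale IQ, log(age), group, a Group x Age
interaction and, optionally, voxel-dependent grey-matter density with a
Group x GM interaction (the GM columns change at every voxel analysed).
Inference is by sign-free subject permutation in the Freedman-Lane scheme:
nuisance-only residuals are permuted within scanning-centre blocks, the
full model is refit, and the maximum statistic over voxels (or the maximum
suprathreshold cluster extent) forms the family-wise-error null.

Also here: seed-type network-strength comparison (probability-map seeds
vs spheres) via a split-plot ANOVA, Cohen's d, and the sphere-grid
decomposition of a probability map into non-overlapping small spheres
with per-sphere effect sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .connectivity import seed_to_voxel_map, sphere_seed

__all__ = [
    "DesignSpec",
    "GlmResult",
    "build_design",
    "permutation_glm",
    "cluster_extent_fwe",
    "network_strength",
    "anova_table",
    "cohens_d",
    "sphere_grid_effects",
    "PermutationGLM",
]

REQUIRED_COVARIATES = ("group", "age_years", "fiq", "centre")


@dataclass
class DesignSpec:
    """Covariate table plus encoding conventions for the group model."""

    covariates: pd.DataFrame
    age_transform: str = "log"     # natural log per the skewed-age convention

    def __post_init__(self):
        missing = [c for c in REQUIRED_COVARIATES
                   if c not in self.covariates.columns]
        if missing:
            raise ValueError(f"covariate table missing columns: {missing}")


def build_design(covariates: pd.DataFrame, gm_values=None):
    """Design matrix for one voxel.

    Columns: intercept, centre dummies (reference-coded), mean FD, FIQ,
    log(age), group (+1/-1), group x log(age), and — when per-subject
    ``gm_values`` are given — GM and group x GM.  Continuous covariates
    are mean-centred before interactions are formed.  All-zero columns
    (e.g. GM after centring a constant) are dropped with a warning; any
    remaining rank deficiency raises an error naming the involved columns.

    Returns ``(X, names)``.
    """
    cov = covariates
    n = len(cov)
    cols, names = [np.ones(n)], ["intercept"]

    centres = sorted(cov["centre"].astype(str).unique())
    for c in centres[1:]:
        cols.append((cov["centre"].astype(str) == c).to_numpy(float))
        names.append(f"centre_{c}")

    for col, name in (("mean_fd", "mean_fd"), ("fiq", "fiq")):
        if col in cov.columns:
            v = cov[col].to_numpy(float)
            cols.append(v - v.mean())
            names.append(name)

    age = cov["age_years"].to_numpy(float)
    if (age <= 0).any():
        raise ValueError("ages must be positive for the log transform")
    log_age = np.log(age)
    log_age_c = log_age - log_age.mean()
    cols.append(log_age_c)
    names.append("log_age")

    glabels = sorted(cov["group"].astype(str).unique())
    if len(glabels) != 2:
        raise ValueError(f"exactly two groups required, got {glabels}")
    group = np.where(cov["group"].astype(str) == glabels[0], 1.0, -1.0)
    cols.append(group)
    names.append("group")
    cols.append(group * log_age_c)
    names.append("group_x_age")

    if gm_values is not None:
        gm = np.asarray(gm_values, dtype=float)
        gm_c = gm - gm.mean()
        cols.append(gm_c)
        names.append("gm")
        cols.append(group * gm_c)
        names.append("group_x_gm")

    X = np.column_stack(cols)
    zero = np.abs(X).max(axis=0) < 1e-12
    if zero.any():
        dropped = [names[i] for i in np.flatnonzero(zero)]
        warnings.warn(f"dropping all-zero design column(s): {dropped}",
                      RuntimeWarning)
        X = X[:, ~zero]
        names = [nm for nm, z in zip(names, zero) if not z]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"design matrix is rank deficient; check columns "
                         f"{names}")
    return X, names


@dataclass
class GlmResult:
    """Per-voxel statistics and permutation FWE inference for one contrast."""

    contrast: str
    beta: np.ndarray
    tmap: np.ndarray
    zmap: np.ndarray
    df: float
    p_fwe_voxel: np.ndarray
    null_max_stat: np.ndarray
    cluster_table: pd.DataFrame = None
    null_max_extent: np.ndarray = None
    design_names: list = field(default_factory=list)


def _block_permutations(blocks, n_perm, rng):
    """Subject permutations restricted within exchangeability blocks."""
    blocks = np.asarray(blocks)
    idx_by_block = [np.flatnonzero(blocks == b) for b in np.unique(blocks)]
    perms = np.empty((n_perm, len(blocks)), dtype=int)
    base = np.arange(len(blocks))
    for i in range(n_perm):
        p = base.copy()
        for idx in idx_by_block:
            p[idx] = rng.permutation(idx)
        perms[i] = p
    return perms


def _t_to_z(t, df):
    """Convert t statistics to standard-normal quantiles, sign preserved."""
    t = np.asarray(t, dtype=float)
    p = stats.t.sf(np.abs(t), df)
    p = np.clip(p, 1e-300, 0.5)
    return np.sign(t) * stats.norm.isf(p)


def _fit_contrast(X, Y, j):
    """OLS t statistic of column ``j`` for every column of Y (n x v)."""
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y
    resid = Y - X @ beta
    df = X.shape[0] - X.shape[1]
    rss = np.einsum("ij,ij->j", resid, resid)
    a = (pinv @ pinv.T)[j, j]
    se = np.sqrt(np.maximum(rss, 1e-300) / df * a)
    return beta[j], beta[j] / se, df


def permutation_glm(maps, covariates, contrast="group_x_age",
                    n_perm=1000, seed=0, gm=None, voxel_index=None,
                    grid_shape=None, forming_z=None, blocks="centre"):
    """Freedman-Lane permutation GLM over a stack of subject maps.

    Parameters
    ----------
    maps : (n_subjects, n_voxels) Fisher-z values.
    covariates : DataFrame with group/age_years/fiq/centre (and mean_fd).
    contrast : design column to test (two-sided).
    gm : optional (n_subjects, n_voxels) grey-matter values making the GM
        columns voxel-dependent.
    voxel_index, grid_shape : voxel coordinates of the map columns and the
        volume shape; required for cluster-extent inference.
    forming_z : cluster-forming threshold on \\|z\\|; enables the
        permutation max-cluster-extent null.
    blocks : covariate column defining exchangeability blocks (default
        scanning centre), or None for free permutation.
    """
    Y = np.asarray(maps, dtype=float)
    n, v = Y.shape
    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    rng = np.random.default_rng(seed)
    blk = covariates[blocks].to_numpy() if blocks else np.zeros(n, dtype=int)
    perms = _block_permutations(blk, n_perm, rng)

    want_clusters = forming_z is not None
    if want_clusters and (voxel_index is None or grid_shape is None):
        raise ValueError("cluster inference needs voxel_index and grid_shape")

    if gm is None:
        X, names = build_design(covariates)
        if contrast not in names:
            raise ValueError(f"contrast {contrast!r} not estimable; design "
                             f"columns are {names}")
        j = names.index(contrast)
        beta_obs, t_obs, df = _fit_contrast(X, Y, j)
        Z = np.delete(X, j, axis=1)
        pz = np.linalg.pinv(Z)
        fitted = Z @ (pz @ Y)
        resid = Y - fitted
        null_max = np.empty(n_perm)
        null_ext = np.empty(n_perm) if want_clusters else None
        for i in range(n_perm):
            Ystar = fitted + resid[perms[i]]
            _, t_star, _ = _fit_contrast(X, Ystar, j)
            null_max[i] = np.abs(t_star).max()
            if want_clusters:
                z_star = _t_to_z(t_star, df)
                null_ext[i] = _max_extent(z_star, voxel_index, grid_shape,
                                          forming_z)
    else:
        gm = np.asarray(gm, dtype=float)
        if gm.shape != Y.shape:
            raise ValueError("gm must match maps shape")
        t_obs = np.empty(v)
        beta_obs = np.empty(v)
        t_null = np.empty((n_perm, v))
        df = None
        names = None
        for vx in range(v):
            X, names_v = build_design(covariates, gm_values=gm[:, vx])
            if contrast not in names_v:
                raise ValueError(f"contrast {contrast!r} not estimable at "
                                 f"voxel {vx}")
            j = names_v.index(contrast)
            y = Y[:, [vx]]
            b, t, df_v = _fit_contrast(X, y, j)
            beta_obs[vx], t_obs[vx] = b[0], t[0]
            df = df_v if df is None else min(df, df_v)
            names = names_v
            Z = np.delete(X, j, axis=1)
            pz = np.linalg.pinv(Z)
            fitted = (Z @ (pz @ y)).ravel()
            resid = (y.ravel() - fitted)
            Ystar = fitted[None, :] + resid[perms]       # (n_perm, n)
            _, t_star, _ = _fit_contrast(X, Ystar.T, j)
            t_null[:, vx] = t_star
        null_max = np.abs(t_null).max(axis=1)
        if want_clusters:
            null_ext = np.empty(n_perm)
            for i in range(n_perm):
                z_star = _t_to_z(t_null[i], df)
                null_ext[i] = _max_extent(z_star, voxel_index, grid_shape,
                                          forming_z)
        else:
            null_ext = None

    p_fwe = (1.0 + (null_max[:, None] >= np.abs(t_obs)[None, :]).sum(axis=0)) \
        / (1.0 + n_perm)
    zmap = _t_to_z(t_obs, df)
    result = GlmResult(contrast=contrast, beta=beta_obs, tmap=t_obs,
                       zmap=zmap, df=df, p_fwe_voxel=p_fwe,
                       null_max_stat=null_max, design_names=list(names))
    if want_clusters:
        result.null_max_extent = null_ext
        result.cluster_table = cluster_extent_fwe(
            zmap, voxel_index=voxel_index, grid_shape=grid_shape,
            forming_z=forming_z, null_max_extents=null_ext)
    return result


def _components(zmap, voxel_index, grid_shape, forming_z, connectivity=6):
    """Connected suprathreshold components; returns (label_vol, n, vol)."""
    vol = np.zeros(grid_shape)
    vol[tuple(np.asarray(voxel_index).T)] = zmap
    supra = np.abs(vol) > forming_z
    if connectivity == 6:
        structure = ndimage.generate_binary_structure(3, 1)
    elif connectivity == 18:
        structure = ndimage.generate_binary_structure(3, 2)
    elif connectivity == 26:
        structure = ndimage.generate_binary_structure(3, 3)
    else:
        raise ValueError("connectivity must be 6, 18 or 26")
    lab, n = ndimage.label(supra, structure=structure)
    return lab, n, vol


def _max_extent(zmap, voxel_index, grid_shape, forming_z, connectivity=6):
    lab, n, _ = _components(zmap, voxel_index, grid_shape, forming_z,
                            connectivity)
    if n == 0:
        return 0
    return int(np.bincount(lab.ravel())[1:].max())


def cluster_extent_fwe(zmap, voxel_index, grid_shape, forming_z=3.1,
                       null_max_extents=None, connectivity=6) -> pd.DataFrame:
    """Cluster table for a z map under a forming threshold.

    Clusters are face-connected components of \\|z\\| > ``forming_z``.
    If a permutation null of maximum cluster extents is supplied, each
    cluster receives a family-wise-error p-value
    ``(1 + #{null >= size}) / (1 + n_perm)``.  An empty map yields an
    empty table.
    """
    zmap = np.asarray(zmap, dtype=float)
    lab, n, vol = _components(zmap, voxel_index, grid_shape, forming_z,
                              connectivity)
    rows = []
    for c in range(1, n + 1):
        vox = np.argwhere(lab == c)
        zs = vol[tuple(vox.T)]
        peak = vox[np.argmax(np.abs(zs))]
        row = {"cluster": c, "size": len(vox),
               "peak_x": int(peak[0]), "peak_y": int(peak[1]),
               "peak_z": int(peak[2]), "peak_stat": float(zs[np.argmax(np.abs(zs))])}
        if null_max_extents is not None:
            null = np.asarray(null_max_extents)
            row["p_fwe"] = float((1 + (null >= len(vox)).sum())
                                 / (1 + len(null)))
        rows.append(row)
    cols = ["cluster", "size", "peak_x", "peak_y", "peak_z", "peak_stat"]
    if null_max_extents is not None:
        cols.append("p_fwe")
    return pd.DataFrame(rows, columns=cols)


def anova_table(values: pd.DataFrame, dv="strength", within="seed_type",
                subject="subject", between=None):
    """Split-plot (mixed) ANOVA by explicit sums of squares.

    ``values`` is a long-format table.  With ``between=None`` this is a
    one-way repeated-measures ANOVA on the within factor; with a between
    factor the table reports the between main effect, the within main
    effect, and their interaction (balanced designs assumed).
    Returns a dict of ``{effect: (F, df1, df2, p)}``.
    """
    df = values
    grand = df[dv].mean()
    subj_means = df.groupby(subject)[dv].mean()
    a = df[within].nunique()
    n_subj = df[subject].nunique()
    ss_total = ((df[dv] - grand) ** 2).sum()
    ss_between_subj = a * ((subj_means - grand) ** 2).sum()
    within_means = df.groupby(within)[dv].mean()
    ss_within_f = n_subj * ((within_means - grand) ** 2).sum()

    out = {}

    def _f(ss_num, df1, ss_den, df2):
        # a numerically-zero numerator is a genuine zero effect even if
        # the error SS also degenerates (identical observations)
        if ss_num < 1e-12 * max(ss_total, 1e-300):
            return 0.0, 1.0
        F = (ss_num / df1) / (ss_den / df2)
        return float(F), float(stats.f.sf(F, df1, df2))

    if between is None:
        cell = df.groupby([subject, within])[dv].mean().unstack()
        ss_err = ((cell.sub(cell.mean(axis=1), axis=0)
                   .sub(cell.mean(axis=0), axis=1) + grand) ** 2).sum().sum()
        df1, df2 = a - 1, (n_subj - 1) * (a - 1)
        F, p = _f(ss_within_f, df1, ss_err, df2)
        out[within] = (F, df1, df2, p)
        return out

    g = df[[subject, between]].drop_duplicates().set_index(subject)[between]
    glevels = g.unique()
    ngroups = len(glevels)
    grp_means = df.groupby(between)[dv].mean()
    counts = g.value_counts()
    ss_group = a * sum(counts[lv] * (grp_means[lv] - grand) ** 2
                       for lv in glevels)
    ss_subj_within = ss_between_subj - ss_group
    df_g, df_sw = ngroups - 1, n_subj - ngroups
    F_g, p_g = _f(ss_group, df_g, ss_subj_within, df_sw)
    out[between] = (F_g, df_g, df_sw, p_g)

    cell_tg = df.groupby([within, between])[dv].mean()
    ss_inter = 0.0
    for (t, lv), m in cell_tg.items():
        ss_inter += counts[lv] * (m - within_means[t] - grp_means[lv]
                                  + grand) ** 2
    ss_within_total = ss_total - ss_between_subj
    ss_err_w = ss_within_total - ss_within_f - ss_inter
    df_w, df_i = a - 1, (a - 1) * (ngroups - 1)
    df_err = (n_subj - ngroups) * (a - 1)
    F_w, p_w = _f(ss_within_f, df_w, ss_err_w, df_err)
    F_i, p_i = _f(ss_inter, df_i, ss_err_w, df_err)
    out[within] = (F_w, df_w, df_err, p_w)
    out[f"{between}_x_{within}"] = (F_i, df_i, df_err, p_i)
    return out


def network_strength(maps_by_seed_type: dict, network_mask, groups=None):
    """Mean Fisher-z within a network mask, per subject and seed type.

    ``maps_by_seed_type`` maps a seed-type name (e.g. ``"probability"``,
    ``"sphere4"``, ``"sphere8"``) to an (n_subjects, n_voxels) array; the
    mask is a boolean over the same voxel axis, identical for all seed
    types.  Returns the long-format strength table and the ANOVA dict
    (seed-type main effect; plus group and Group x Seed-type terms when
    ``groups`` is given).
    """
    network_mask = np.asarray(network_mask, dtype=bool)
    if not network_mask.any():
        raise ValueError("empty network mask")
    rows = []
    for st, maps in maps_by_seed_type.items():
        maps = np.asarray(maps, dtype=float)
        strengths = maps[:, network_mask].mean(axis=1)
        for i, s in enumerate(strengths):
            row = {"subject": i, "seed_type": st, "strength": s}
            if groups is not None:
                row["group"] = groups[i]
            rows.append(row)
    table = pd.DataFrame(rows)
    effects = anova_table(table, between="group" if groups is not None
                          else None)
    return table, effects


def cohens_d(a, b) -> float:
    """Cohen's d with the (n-1)-weighted pooled standard deviation."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 observations")
    na, nb = len(a), len(b)
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                     / (na + nb - 2))
    if pooled < 1e-300:
        warnings.warn("zero pooled SD: Cohen's d undefined", RuntimeWarning)
        return np.nan
    return float((a.mean() - b.mean()) / pooled)


def sphere_grid_effects(prob_vol, affine, subject_data, gm_mask,
                        network_mask, groups, radius_mm=4.0, threshold=0.25,
                        keep_list=None) -> tuple:
    """Decompose a probability map into non-overlapping small spheres and
    measure each sphere's seed connectivity.

    Spheres are placed greedily from the probability peak outward over the
    suprathreshold support (centres in the support, spheres pairwise
    disjoint).  For every sphere: per-subject network strength (mean
    Fisher-z of the sphere-seed map within ``network_mask``), the group
    Cohen's d, and the sphere's mean probability.  Also returns the
    Pearson correlation between per-sphere strength and probability for
    each group (nan with a warning when degenerate).
    """
    prob_vol = np.asarray(prob_vol, dtype=float)
    support = prob_vol > threshold
    if not support.any():
        raise ValueError("no suprathreshold support for sphere placement")
    cand = np.argwhere(support)
    order = np.lexsort((cand[:, 2], cand[:, 1], cand[:, 0],
                        -prob_vol[tuple(cand.T)]))
    cand = cand[order]
    affine = np.asarray(affine, dtype=float)
    taken = np.zeros(prob_vol.shape, dtype=bool)
    spheres = []
    for c in cand:
        world = affine[:3, :3] @ c + affine[:3, 3]
        vox = sphere_seed(world, radius_mm, affine, prob_vol.shape)
        if taken[tuple(vox.T)].any():
            continue
        taken[tuple(vox.T)] = True
        spheres.append((c, vox))
    if not spheres:
        raise ValueError("support smaller than one sphere")

    groups = np.asarray(groups)
    glevels = sorted(np.unique(groups))
    rows = []
    strength_mat = np.zeros((len(spheres), len(subject_data)))
    for si, (centre, vox) in enumerate(spheres):
        for pi, data in enumerate(subject_data):
            keep = keep_list[pi] if keep_list is not None else None
            smap = seed_to_voxel_map(data, vox, gm_mask, keep=keep)
            net = network_mask[tuple(smap.gm_voxel_index.T)]
            strength_mat[si, pi] = smap.values[net].mean()
        svals = strength_mat[si]
        d = cohens_d(svals[groups == glevels[0]], svals[groups == glevels[1]])
        rows.append({"sphere": si, "centre_x": int(centre[0]),
                     "centre_y": int(centre[1]), "centre_z": int(centre[2]),
                     "mean_prob": float(prob_vol[tuple(vox.T)].mean()),
                     "cohens_d": d,
                     **{f"strength_{g}": float(svals[groups == g].mean())
                        for g in glevels}})
    table = pd.DataFrame(rows)
    corrs = {}
    for g in glevels:
        s = table[f"strength_{g}"].to_numpy()
        p = table["mean_prob"].to_numpy()
        if len(s) < 3 or np.std(s) < 1e-12 or np.std(p) < 1e-12:
            warnings.warn(f"strength-probability correlation undefined for "
                          f"group {g}", RuntimeWarning)
            corrs[g] = np.nan
        else:
            corrs[g] = float(stats.pearsonr(s, p)[0])
    return table, corrs


class PermutationGLM:
    """Estimator wrapper over :func:`permutation_glm`.

    scikit-learn style: parameters at construction, data at ``fit``,
    results in trailing-underscore attributes (``tmap_``, ``zmap_``,
    ``p_fwe_voxel_``, ``cluster_table_``).
    """

    def __init__(self, contrast="group_x_age", n_perm=1000, forming_z=None,
                 blocks="centre", random_state=0):
        self.contrast = contrast
        self.n_perm = n_perm
        self.forming_z = forming_z
        self.blocks = blocks
        self.random_state = random_state

    def get_params(self, deep=True):
        return {"contrast": self.contrast, "n_perm": self.n_perm,
                "forming_z": self.forming_z, "blocks": self.blocks,
                "random_state": self.random_state}

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None, *, covariates, gm=None, voxel_index=None,
            grid_shape=None):
        res = permutation_glm(
            X, covariates, contrast=self.contrast, n_perm=self.n_perm,
            seed=self.random_state, gm=gm, voxel_index=voxel_index,
            grid_shape=grid_shape, forming_z=self.forming_z,
            blocks=self.blocks)
        self.result_ = res
        self.tmap_ = res.tmap
        self.zmap_ = res.zmap
        self.p_fwe_voxel_ = res.p_fwe_voxel
        self.cluster_table_ = res.cluster_table
        return self
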