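"""Voxel-wise group statistics with cluster-extent familywise correction.

The group model is a repeated-measures ANCOVA per voxel: within-subject
factors load (low/medium/high) and chromophore (HbO/HbR), with age (months)
as a continuous between-subject covariate, including its interactions with
the within factors. It is computed by projecting each participant's cell
means onto orthonormal within-subject contrasts and regressing the contrast
scores on centred age — the classical univariate mixed-model decomposition —
vectorised across voxels.

Familywise error over voxels is controlled by cluster-extent correction: the
minimum cluster size is the (1−α) quantile of the maximum suprathreshold
cluster size under Monte-Carlo smooth Gaussian null fields matched to the
residual smoothness (the approach behind AFNI's 3dClustSim).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from . import behavioral
from .forward_model import MaskVolume, VoxelGrid

__all__ = [
    "GroupDataset",
    "EffectMap",
    "ClusterRecord",
    "EFFECTS",
    "CHROMOPHORE_PRIORITY",
    "voxelwise_anova",
    "estimate_smoothness",
    "cluster_threshold_mc",
    "extract_clusters",
    "classify_voxels_by_priority",
    "canonical_pattern_rate",
    "brain_behavior_correlation",
    "demographic_regression",
    "ideal_pattern_radar",
    "cluster_overlap",
    "stack_group_dataset",
]

LOADS = ("low", "medium", "high")
CHROMS = ("HbO", "HbR")

EFFECTS = (
    "age",
    "load",
    "load_x_age",
    "chromophore",
    "chromophore_x_age",
    "chromophore_x_load",
    "chromophore_x_load_x_age",
)

#: Effect-priority order for voxel classification (highest first); only
#: chromophore-involving effects are ever labelled.
CHROMOPHORE_PRIORITY = (
    "chromophore_x_load_x_age",
    "chromophore_x_load",
    "chromophore_x_age",
    "chromophore",
)

FWHM_PER_SIGMA = float(np.sqrt(8.0 * np.log(2.0)))  # ≈ 2.3548


@dataclass
class GroupDataset:
    """values[participant, load, chromophore, masked voxel] + age covariate."""

    values: np.ndarray  # (P, 3, 2, V)
    age: np.ndarray  # (P,) months
    mask: MaskVolume
    participant_ids: tuple = ()

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.age = np.asarray(self.age, dtype=float)
        P = self.values.shape[0]
        if self.values.ndim != 4 or self.values.shape[1:3] != (3, 2):
            raise ValueError("values must be (P, 3 loads, 2 chromophores, V)")
        if self.values.shape[3] != self.mask.n_true:
            raise ValueError("voxel axis must match mask size")
        if self.age.shape != (P,):
            raise ValueError("one age per participant required")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("complete cases required")
        if not self.participant_ids:
            self.participant_ids = tuple(f"p{i:03d}" for i in range(P))

    @property
    def n_participants(self) -> int:
        return self.values.shape[0]


@dataclass
class EffectMap:
    """Per-voxel F and p for one ANOVA effect (masked voxels only)."""

    label: str
    F: np.ndarray
    p: np.ndarray
    df: tuple
    mask: MaskVolume
    valid: np.ndarray = None  # False where error variance degenerate

    def __post_init__(self):
        if self.valid is None:
            self.valid = np.ones_like(self.F, dtype=bool)

    def volume(self, what: str = "F") -> np.ndarray:
        flat = np.zeros(self.mask.grid.n_voxels)
        if what == "p":
            flat += 1.0
        flat[self.mask.indices()] = getattr(self, what)
        return flat.reshape(self.mask.grid.dims)


@dataclass
class ClusterRecord:
    """A surviving suprathreshold cluster."""

    effect: str
    hemisphere: str  # "L" | "R"
    size_voxels: int
    size_mm3: float
    centre_of_mass: tuple  # grid-frame mm
    member_voxels: np.ndarray  # flat C-order grid indices
    mean_hbo: np.ndarray | None = None  # (P, 3 loads) cluster-mean HbO betas
    mean_hbr: np.ndarray | None = None


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k−1, k) orthonormal rows, each summing to zero (Helmert-style)."""
    H = np.zeros((k - 1, k))
    for i in range(1, k):
        H[i - 1, :i] = 1.0
        H[i - 1, i] = -i
        H[i - 1] /= np.linalg.norm(H[i - 1])
    return H


def _stratum(u: np.ndarray, age_c: np.ndarray):
    """Regress contrast scores (P, C, V) on [1, centred age] per contrast.

    Returns (SS_mean, SS_age, SS_err) each (V,), summed over contrasts.
    """
    P = u.shape[0]
    saa = float((age_c**2).sum())
    b0 = u.mean(axis=0)  # (C, V)
    b1 = np.tensordot(age_c, u, axes=(0, 0)) / saa  # (C, V)
    resid = u - b0[None] - age_c[:, None, None] * b1[None]
    ss_mean = P * (b0**2).sum(axis=0)
    ss_age = saa * (b1**2).sum(axis=0)
    ss_err = (resid**2).sum(axis=(0, 1))
    return ss_mean, ss_age, ss_err


def voxelwise_anova(data: GroupDataset) -> dict:
    """Repeated-measures ANCOVA per voxel; returns {effect label: EffectMap}.

    Each within-subject effect is tested against its own subject-interaction
    error stratum; the age main effect against between-subject error.
    """
    P = data.n_participants
    if P < 3:
        raise ValueError("need at least 3 participants")
    y = data.values  # (P, 3, 2, V)
    V = y.shape[3]
    age_c = data.age - data.age.mean()
    if age_c.std() == 0:
        raise ValueError("age covariate has zero variance")

    C_load = _orthonormal_contrasts(3)  # (2, 3)
    C_chrom = _orthonormal_contrasts(2)  # (1, 2)

    out = {}

    # overall data scale per voxel, for degenerate-variance detection
    scale = (y**2).sum(axis=(0, 1, 2)) + 1e-300

    def make(label, ss_eff, df_eff, ss_err, df_err):
        tol = 1e-12 * scale
        zero_eff = ss_eff <= tol
        degenerate = (ss_err <= tol) & ~zero_eff
        ms_err = np.where(ss_err > tol, ss_err, 1.0) / df_err
        F = np.where(zero_eff, 0.0, (ss_eff / df_eff) / ms_err)
        F = np.where(degenerate, 0.0, F)
        p = stats.f.sf(F, df_eff, df_err)
        p = np.where(degenerate, 1.0, p)
        out[label] = EffectMap(label=label, F=F, p=p, df=(df_eff, df_err),
                               mask=data.mask, valid=~degenerate)

    # between-subject stratum: participant means over the 6 cells
    m = y.mean(axis=(1, 2))[:, None, :]  # (P, 1, V)
    _, ss_age, ss_err_b = _stratum(m, age_c)
    make("age", ss_age, 1, ss_err_b, P - 2)

    # load stratum (collapse chromophore)
    z = y.mean(axis=2)  # (P, 3, V)
    u = np.einsum("cl,plv->pcv", C_load, z)
    ss_l, ss_la, ss_e = _stratum(u, age_c)
    make("load", ss_l, 2, ss_e, 2 * (P - 2))
    make("load_x_age", ss_la, 2, ss_e, 2 * (P - 2))

    # chromophore stratum (collapse load)
    w = y.mean(axis=1)  # (P, 2, V)
    u = np.einsum("ck,pkv->pcv", C_chrom, w)
    ss_c, ss_ca, ss_e = _stratum(u, age_c)
    make("chromophore", ss_c, 1, ss_e, P - 2)
    make("chromophore_x_age", ss_ca, 1, ss_e, P - 2)

    # load × chromophore stratum
    cells = y.reshape(P, 6, V)
    C_lc = np.stack([np.outer(cl, C_chrom[0]).ravel() for cl in C_load])
    u = np.einsum("cx,pxv->pcv", C_lc, cells)
    ss_lc, ss_lca, ss_e = _stratum(u, age_c)
    make("chromophore_x_load", ss_lc, 2, ss_e, 2 * (P - 2))
    make("chromophore_x_load_x_age", ss_lca, 2, ss_e, 2 * (P - 2))

    return out


def estimate_smoothness(resid_maps: np.ndarray, mask: MaskVolume) -> np.ndarray:
    """Gaussian-equivalent FWHM (mm, per axis) from residual spatial derivatives.

    Uses the lag-one autocorrelation of standardised residuals:
    ρ = 1 − var(diff)/(2·var); FWHM = √(8 ln 2)·σ with σ² = −Δx²/(4 ln ρ).
    Estimates are floored at one voxel size (sampling cannot resolve less).
    """
    maps = np.asarray(resid_maps, dtype=float)
    if maps.ndim == 3:
        maps = maps[None]
    if maps.shape[0] < 2:
        raise ValueError("need at least 2 residual maps")
    m = mask.data
    if m.sum() < 2:
        raise ValueError("mask too small for smoothness estimation")
    fwhm = np.empty(3)
    spacing = np.array(mask.grid.spacing)
    # standardise each map within the mask
    vals = maps[:, m]
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    std_maps = np.zeros_like(maps)
    std_maps[:, m] = (vals - mu) / sd
    for ax in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[ax] = slice(0, -1)
        sl_b[ax] = slice(1, None)
        pair = m[tuple(sl_a)] & m[tuple(sl_b)]
        if not pair.any():
            fwhm[ax] = spacing[ax]
            continue
        a = std_maps[(slice(None),) + tuple(sl_a)][:, pair]
        b = std_maps[(slice(None),) + tuple(sl_b)][:, pair]
        vdiff = ((a - b) ** 2).mean()
        var = 0.5 * (a**2 + b**2).mean()
        rho = 1.0 - vdiff / (2.0 * var) if var > 0 else 0.0
        rho_floor = np.exp(-(FWHM_PER_SIGMA**2) / 4.0)  # FWHM = one voxel
        rho = min(max(rho, rho_floor), 0.9999)
        sigma = np.sqrt(-spacing[ax] ** 2 / (4.0 * np.log(rho)))
        fwhm[ax] = FWHM_PER_SIGMA * sigma
    return fwhm


def _connectivity_structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 18:
        return ndimage.generate_binary_structure(3, 2)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValueError("connectivity must be 6, 18 or 26")


def cluster_threshold_mc(
    mask: MaskVolume,
    fwhm,
    voxel_p: float = 0.01,
    alpha: float = 0.05,
    n_iter: int = 1000,
    seed: int = 0,
    connectivity: int = 6,
) -> int:
    """Monte-Carlo minimum cluster size controlling familywise error at α.

    Smooth Gaussian null fields (matched to ``fwhm``) are thresholded
    two-sided at ``voxel_p``; the returned size is the smallest integer c
    with P(max cluster ≥ c) ≤ α under the null.
    """
    if not (0 < voxel_p < 1) or not (0 < alpha <= 1):
        raise ValueError("voxel_p in (0,1), alpha in (0,1]")
    if n_iter < 100:
        warnings.warn("n_iter < 100; cluster threshold will be unstable")
    rng = np.random.default_rng(seed)
    fwhm = np.broadcast_to(np.asarray(fwhm, dtype=float), (3,))
    spacing = np.array(mask.grid.spacing)
    sigma_vox = fwhm / FWHM_PER_SIGMA / spacing
    zthr = stats.norm.isf(voxel_p / 2.0)
    structure = _connectivity_structure(connectivity)
    m = mask.data
    max_sizes = np.empty(n_iter, dtype=int)
    for it in range(n_iter):
        field = rng.standard_normal(mask.grid.dims)
        if np.any(sigma_vox > 0.05):
            field = ndimage.gaussian_filter(field, sigma=sigma_vox)
        vals = field[m]
        z = np.zeros_like(field)
        z[m] = (vals - vals.mean()) / vals.std()
        supra = (np.abs(z) > zthr) & m
        if not supra.any():
            max_sizes[it] = 0
            continue
        labels, n = ndimage.label(supra, structure=structure)
        max_sizes[it] = int(np.bincount(labels.ravel())[1:].max())
    for c in range(1, max_sizes.max() + 2):
        if (max_sizes >= c).mean() <= alpha:
            return c
    return int(max_sizes.max() + 1)


def extract_clusters(
    effect: EffectMap,
    voxel_p: float = 0.01,
    min_size: int = 21,
    connectivity: int = 6,
    dataset: GroupDataset | None = None,
) -> list:
    """Connected suprathreshold components of size ≥ ``min_size``.

    Centre of mass is the F-weighted mean coordinate. With ``dataset``
    given, per-participant cluster-mean HbO/HbR betas per load are attached.
    """
    grid = effect.mask.grid
    pvol = effect.volume("p")
    valid = np.zeros(grid.dims, dtype=bool)
    valid.ravel()[effect.mask.indices()[effect.valid]] = True
    supra = (pvol < voxel_p) & effect.mask.data & valid
    labels, n = ndimage.label(supra, structure=_connectivity_structure(connectivity))
    Fvol = effect.volume("F")
    coords = grid.voxel_coords_mm().reshape(grid.dims + (3,))
    vox_mm3 = float(np.prod(grid.spacing))
    x_mid = grid.origin[0] + (grid.dims[0] - 1) * grid.spacing[0] / 2.0
    # map flat grid index → position within the mask's voxel axis
    mask_pos = -np.ones(grid.n_voxels, dtype=int)
    mask_pos[effect.mask.indices()] = np.arange(effect.mask.n_true)
    records = []
    for lab in range(1, n + 1):
        member = labels == lab
        size = int(member.sum())
        if size < min_size:
            continue
        wts = Fvol[member]
        if wts.sum() <= 0:
            wts = np.ones(size)
        com = tuple((coords[member] * wts[:, None]).sum(axis=0) / wts.sum())
        flat_idx = np.flatnonzero(member.ravel())
        mean_hbo = mean_hbr = None
        if dataset is not None:
            pos = mask_pos[flat_idx]
            pos = pos[pos >= 0]
            mean_hbo = dataset.values[:, :, 0, :][:, :, pos].mean(axis=2)
            mean_hbr = dataset.values[:, :, 1, :][:, :, pos].mean(axis=2)
        records.append(
            ClusterRecord(
                effect=effect.label,
                hemisphere="L" if com[0] < x_mid else "R",
                size_voxels=size,
                size_mm3=size * vox_mm3,
                centre_of_mass=com,
                member_voxels=flat_idx,
                mean_hbo=mean_hbo,
                mean_hbr=mean_hbr,
            )
        )
    records.sort(key=lambda r: -r.size_voxels)
    return records


def classify_voxels_by_priority(significance: dict) -> np.ndarray:
    """Label each voxel by its highest-priority significant chromophore effect.

    ``significance`` maps effect label → boolean volume. Returns an int
    volume: 0 = unlabeled, 1..4 = priority rank (1 = chromophore×load×age).
    Effects without a chromophore term never label a voxel.
    """
    shapes = {np.asarray(v).shape for v in significance.values()}
    if len(shapes) > 1:
        raise ValueError("significance masks on different grids")
    shape = shapes.pop() if shapes else None
    if shape is None:
        raise ValueError("no significance masks given")
    labeled = np.zeros(shape, dtype=int)
    for rank, eff in enumerate(CHROMOPHORE_PRIORITY, start=1):
        if eff not in significance:
            continue
        sig = np.asarray(significance[eff], dtype=bool)
        labeled[(labeled == 0) & sig] = rank
    return labeled


def canonical_pattern_rate(hbo: np.ndarray, hbr: np.ndarray) -> float:
    """Fraction of (participant, cluster) entries with opposite-signed betas.

    A zero beta on either chromophore counts as no canonical pattern.
    """
    hbo = np.asarray(hbo, dtype=float)
    hbr = np.asarray(hbr, dtype=float)
    if hbo.shape != hbr.shape or hbo.size == 0:
        raise ValueError("HbO and HbR beta arrays must match and be nonempty")
    return float((np.sign(hbo) * np.sign(hbr) < 0).mean())


def brain_behavior_correlation(cluster_hbo, behavior, alpha: float = 0.05) -> dict:
    """Pearson r between cluster-mean HbO betas and a behavioural measure.

    Two-sided p; the mean ± 3 SD outlier-robustness check is applied. No
    multiple-comparison correction is applied by default.
    """
    x = np.asarray(cluster_hbo, dtype=float)
    y = np.asarray(behavior, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need paired data with n ≥ 4")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(x, y)
    rob = behavioral.outlier_robustness(x, y, alpha=alpha)
    return {"r": float(r), "p": float(p), "robust": rob["robust"],
            "robustness": rob}


def demographic_regression(cluster_hbo, demographics: pd.DataFrame,
                           entry_p: float = 0.05) -> dict:
    """Stepwise (forward) regression of cluster HbO activation on demographics."""
    return behavioral.forward_regression(demographics, cluster_hbo,
                                         entry_p=entry_p)


def ideal_pattern_radar(values: pd.DataFrame, benefit: dict) -> pd.Series:
    """Median-split classification of per-participant effect values.

    For each effect (column), a participant is *ideal* when strictly above
    the median if greater activation is beneficial (``benefit == 'greater'``)
    or strictly below when suppression is beneficial. Median ties are
    non-ideal. Returns ideal-effect counts per participant.
    """
    if len(values) < 2:
        raise ValueError("need ≥ 2 participants")
    counts = pd.Series(0, index=values.index)
    for col in values.columns:
        direction = benefit[col]
        med = values[col].median()
        if direction == "greater":
            ideal = values[col] > med
        elif direction == "suppression":
            ideal = values[col] < med
        else:
            raise ValueError(f"benefit must be 'greater' or 'suppression', got {direction!r}")
        counts += ideal.astype(int)
    return counts


def cluster_overlap(map_a: np.ndarray, map_b: np.ndarray) -> dict:
    """Voxelwise intersection/union/unique partition of two labelled maps."""
    a = np.asarray(map_a) != 0
    b = np.asarray(map_b) != 0
    if a.shape != b.shape:
        raise ValueError("maps on different grids")
    inter = a & b
    return {
        "intersection": inter,
        "union": a | b,
        "a_only": a & ~b,
        "b_only": b & ~a,
        "counts": {
            "intersection": int(inter.sum()),
            "union": int((a | b).sum()),
            "a_only": int((a & ~b).sum()),
            "b_only": int((b & ~a).sum()),
        },
    }


def stack_group_dataset(maps: list, ages, mask: MaskVolume,
                        participant_ids: tuple = ()) -> GroupDataset:
    """Stack per-participant VoxelBetaMaps into a GroupDataset."""
    vals = []
    for vm in maps:
        if tuple(vm.conditions) != LOADS:
            raise ValueError("expected low/medium/high conditions")
        vals.append(np.stack([vm.hbo, vm.hbr], axis=1))  # (3, 2, V)
    return GroupDataset(values=np.stack(vals), age=np.asarray(ages, float),
                        mask=mask, participant_ids=tuple(participant_ids))
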