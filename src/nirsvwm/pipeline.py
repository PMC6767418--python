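"""Configuration, file I/O and the end-to-end pipeline driver.

Stage order: behave → preprocess → glm → masks → reconstruct → group.
Tables are written as CSV, volumes as NIfTI, configuration and logs as JSON;
signal containers use long-format CSV. A serialized config plus the seed
fully determines a run.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import behavioral, fnirs_preprocess as pp, forward_model as fm, glm
from . import group_stats as gs
from . import image_recon as ir
from . import synthetic_data as sd

__all__ = ["PipelineConfig", "run_pipeline", "write_coding_log",
           "read_coding_log", "write_intensity_csv", "read_intensity_csv"]

LOADS = behavioral.LOADS


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the pipeline, with study defaults.

    Provenance: tMotion/tMask/StdevThresh/AmpThresh, the 0.016–0.5 Hz band,
    the 1e-4 OD mask threshold, 75% coverage and cluster α = 0.05 follow the
    study protocol; the rest are package defaults.
    """

    n_participants: int = 34
    n_trials_per_load: int = 12
    trial_s: float = 10.0
    iti_s: float = 5.0
    fs: float = 10.0
    grid_dims: tuple = (20, 20, 10)
    grid_spacing: tuple = (2.0, 2.0, 2.0)
    depth_scale: float = 10.0
    banana_width: float = 4.0
    # preprocessing
    tmotion: float = 1.0
    tmask: float = 1.0
    stdev_thresh: float = 50.0
    amp_thresh: float = 0.67
    band: tuple = (0.016, 0.5)
    dpf: tuple = (6.0, 6.0)
    tpca_variance_frac: float = 0.97
    reject_window: tuple = (-1.0, 10.0)
    # masks / reconstruction
    od_threshold: float = 1e-4
    coverage: float = 0.75
    lambda_policy: str = "auto"
    # group stats
    voxel_p: float = 0.01
    alpha: float = 0.05
    cluster_n_iter: int = 1000
    connectivity: int = 6
    entry_p: float = 0.05
    chance: float = 0.5

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "PipelineConfig":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        raw = json.loads(text)
        kw = {}
        for f in dataclasses.fields(cls):
            if f.name in raw:
                v = raw[f.name]
                kw[f.name] = tuple(v) if isinstance(v, list) else v
        return cls(**kw)


# ---------------------------------------------------------------------------
# file formats


def write_coding_log(trials: list, path) -> None:
    """Coding-log CSV: one row per look event."""
    rows = []
    for tr in trials:
        for ev in tr.looks:
            rows.append(
                {"participant": tr.participant_id, "trial": tr.trial_index,
                 "load": tr.load_class, "n_items": tr.n_items,
                 "changing_side": tr.changing_side, "look_side": ev.side,
                 "onset_ms": ev.onset, "offset_ms": ev.offset,
                 "trial_duration_ms": tr.trial_duration}
            )
        if not tr.looks:
            rows.append(
                {"participant": tr.participant_id, "trial": tr.trial_index,
                 "load": tr.load_class, "n_items": tr.n_items,
                 "changing_side": tr.changing_side, "look_side": "",
                 "onset_ms": np.nan, "offset_ms": np.nan,
                 "trial_duration_ms": tr.trial_duration}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_coding_log(path) -> list:
    df = pd.read_csv(path)
    trials = []
    for (pid, idx), g in df.groupby(["participant", "trial"], sort=True):
        first = g.iloc[0]
        looks = [
            behavioral.LookEvent(side=r.look_side, onset=float(r.onset_ms),
                                 offset=float(r.offset_ms))
            for r in g.itertuples()
            if isinstance(r.look_side, str) and r.look_side in ("left", "right")
        ]
        trials.append(
            behavioral.TrialCoding(
                participant_id=str(pid), trial_index=int(idx),
                load_class=first["load"], n_items=int(first["n_items"]),
                changing_side=first["changing_side"], looks=looks,
                trial_duration=float(first["trial_duration_ms"]),
            )
        )
    return trials


def write_intensity_csv(series: pp.ChannelTimeSeries, path) -> None:
    """Long-format signal CSV plus a JSON sidecar with onsets and metadata."""
    n_ch, n_b, n_t = series.data.shape
    ch = np.repeat(np.arange(n_ch), n_b * n_t)
    bd = np.tile(np.repeat(np.arange(n_b), n_t), n_ch)
    tt = np.tile(np.arange(n_t), n_ch * n_b)
    pd.DataFrame(
        {"channel": ch, "band": bd, "sample": tt, "value": series.data.ravel()}
    ).to_csv(path, index=False)
    sidecar = {
        "fs": series.fs,
        "stage": series.stage,
        "bands": list(series.bands),
        "channel_ids": list(series.channel_ids),
        "onsets": {k: list(map(float, v)) for k, v in series.onsets.items()},
    }
    Path(str(path)).with_suffix(".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True))


def read_intensity_csv(path) -> pp.ChannelTimeSeries:
    df = pd.read_csv(path)
    meta = json.loads(Path(str(path)).with_suffix(".json").read_text())
    n_ch = df["channel"].nunique()
    n_b = df["band"].nunique()
    n_t = df["sample"].nunique()
    data = df.sort_values(["channel", "band", "sample"])["value"].to_numpy()
    return pp.ChannelTimeSeries(
        data=data.reshape(n_ch, n_b, n_t),
        fs=float(meta["fs"]),
        channel_ids=tuple(meta["channel_ids"]),
        bands=tuple(meta["bands"]),
        onsets={k: np.array(v) for k, v in meta["onsets"].items()},
        stage=meta["stage"],
    )


def save_volume(vol: np.ndarray, grid: fm.VoxelGrid, path) -> None:
    img = nib.Nifti1Image(np.asarray(vol, dtype=np.float64), grid.affine())
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# stage helpers


def preprocess_recording(raw: pp.ChannelTimeSeries, geometry,
                         config: PipelineConfig):
    """intensity → OD → tPCA → detection → trial rejection → band-pass → MBLL.

    Returns (concentration series, retained onsets, motion mask).
    """
    od = pp.intensity_to_od(raw)
    pre_mask = pp.detect_motion_by_channel(
        od, config.tmotion, config.tmask, config.stdev_thresh, config.amp_thresh)
    od = pp.tpca_motion_correct(od, pre_mask, config.tpca_variance_frac)
    mask = pp.detect_motion_by_channel(
        od, config.tmotion, config.tmask, config.stdev_thresh, config.amp_thresh)
    retained = pp.reject_trials(raw.onsets, mask, config.reject_window)
    od = pp.bandpass(od, *config.band)
    ext = pp.ExtinctionTable(dpf=config.dpf)
    conc = pp.od_to_concentration(od, ext, geometry)
    return conc, retained, mask


def glm_betas(conc: pp.ChannelTimeSeries, retained: dict,
              config: PipelineConfig):
    """Separate HbO/HbR GLM fits with chromophore-specific kernels."""
    betas = []
    for chrom_i, params in ((0, glm.HRF_HBO), (1, glm.HRF_HBR)):
        kernel = glm.hrf_kernel(params, 1.0 / conc.fs)
        design = glm.build_design(retained, conc.n_times, conc.fs, kernel)
        if design.missing_conditions:
            raise ValueError(
                f"conditions without retained trials: {design.missing_conditions}")
        sub = conc.copy_with()
        sub.data = conc.data[:, chrom_i:chrom_i + 1, :]
        sub.bands = (conc.bands[chrom_i],)
        betas.append(glm.fit_ols(design, sub))
    b0, b1 = betas
    beta = np.concatenate([b0.beta, b1.beta], axis=2)
    return glm.ChannelBetas(
        beta=beta, conditions=b0.conditions, channel_ids=conc.channel_ids,
        chromophores=("HbO", "HbR"),
        resid_var=np.concatenate([b0.resid_var, b1.resid_var], axis=1),
    )


# ---------------------------------------------------------------------------
# full pipeline


def run_pipeline(config: PipelineConfig, out_dir, seed: int = 0,
                 cohort_config: sd.CohortConfig | None = None,
                 noise: sd.NoiseConfig | None = None) -> dict:
    """Synthetic-manifest end-to-end run. Returns the results summary dict.

    Writes demographics/metrics/cluster CSVs, mask and effect NIfTIs, and a
    JSON log with per-stage exclusion counts into ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_json(out / "config.json")
    if cohort_config is None:
        cohort_config = sd.CohortConfig(depth_scale=config.depth_scale)
    if noise is None:
        noise = sd.NoiseConfig()
    log = {"seed": seed, "exclusions": {}, "counts": {}}
    rng = np.random.default_rng(seed)

    grid = fm.VoxelGrid(dims=config.grid_dims, spacing=config.grid_spacing)
    geometry = fm.default_frontal_probe(grid)
    profiles = fm.synth_sensitivity(geometry, grid, config.depth_scale,
                                    config.banana_width)

    records, truths = sd.simulate_cohort(
        config.n_participants, int(rng.integers(2**31)), cohort_config,
        grid=grid, geometry=geometry)
    demo = pd.DataFrame([asdict(r) for r in records])
    demo.to_csv(out / "demographics.csv", index=False)

    # --- behave ------------------------------------------------------------
    all_trials, per_part = [], []
    for rec, truth in zip(records, truths):
        trials = sd.simulate_looking_session(
            truth, config.n_trials_per_load, config.trial_s,
            seed=int(rng.integers(2**31)), age_months=rec.age_months)
        all_trials.extend(trials)
        agg = behavioral.aggregate_participant(trials)
        row = {"participant": rec.participant_id, "included": agg["included"]}
        for ld in LOADS:
            for met in ("tlt", "mld", "sr", "cp"):
                row[f"{met}_{ld}"] = agg["means"].loc[ld, met]
        per_part.append(row)
    write_coding_log(all_trials, out / "coding_log.csv")
    behav = pd.DataFrame(per_part).set_index("participant")
    behav.to_csv(out / "behavior_by_load.csv")
    excluded_behav = behav.index[~behav["included"]].tolist()
    log["exclusions"]["behavioural"] = excluded_behav

    chance_results = {
        ld: behavioral.chance_test(behav[f"cp_{ld}"].dropna(), config.chance)
        for ld in LOADS
    }
    cp_table = behav[[f"cp_{ld}" for ld in LOADS]].dropna()
    anova_cp = behavioral.load_anova(cp_table)
    ses_reg = behavioral.forward_regression(
        demo.set_index("participant_id").loc[cp_table.index,
                                             ["ses_score"]],
        behav.loc[cp_table.index, "cp_medium"], entry_p=config.entry_p)

    # --- preprocess + glm + reconstruct ------------------------------------
    subject_mask = fm.build_subject_mask(profiles, config.od_threshold)
    age_groups: dict = {}
    for rec in records:
        band = min(int(rec.age_months // 12), 3)
        age_groups.setdefault(band, []).append(subject_mask)
    age_masks = [fm.build_group_mask(v, config.coverage)
                 for v in age_groups.values()]
    final_mask = fm.intersect_age_masks(age_masks)
    final_mask.save(out / "intersection_mask.nii")
    log["counts"]["mask_voxels"] = final_mask.n_true

    ext = pp.ExtinctionTable(dpf=config.dpf)
    L = ir.assemble_L(profiles, ext, final_mask)
    voxel_maps, ages, kept_ids, excluded_fnirs = [], [], [], []
    for rec, truth in zip(records, truths):
        raw = sd.simulate_fnirs_recording(
            geometry, profiles, truth, noise, seed=int(rng.integers(2**31)),
            fs=config.fs, n_trials_per_load=config.n_trials_per_load,
            trial_s=config.trial_s, iti_s=config.iti_s, ext=ext)
        conc, retained, _ = preprocess_recording(raw, geometry, config)
        if any(len(v) == 0 for v in retained.values()):
            excluded_fnirs.append(rec.participant_id)
            continue
        betas = glm_betas(conc, retained, config)
        Y = ir.channel_betas_to_od(betas, ext, geometry)
        vm = ir.tikhonov_solve(L, Y, config.lambda_policy)
        voxel_maps.append(vm)
        ages.append(rec.age_months)
        kept_ids.append(rec.participant_id)
    log["exclusions"]["fnirs"] = excluded_fnirs
    log["counts"]["participants_in_group"] = len(kept_ids)
    if len(kept_ids) < 3:
        raise RuntimeError("too few participants with usable fNIRS data")

    # --- group -------------------------------------------------------------
    dataset = gs.stack_group_dataset(voxel_maps, ages, final_mask,
                                     tuple(kept_ids))
    effects = gs.voxelwise_anova(dataset)
    # residual proxy: per-participant deviation from cell means, HbO at each load
    resid = dataset.values - dataset.values.mean(axis=0, keepdims=True)
    resid_maps = np.stack([
        _to_volume(resid[i, 1, 0], final_mask) for i in range(len(kept_ids))
    ])
    fwhm = gs.estimate_smoothness(resid_maps, final_mask)
    min_size = gs.cluster_threshold_mc(
        final_mask, fwhm, config.voxel_p, config.alpha,
        config.cluster_n_iter, seed=int(rng.integers(2**31)),
        connectivity=config.connectivity)
    log["counts"]["cluster_threshold_voxels"] = int(min_size)

    cluster_rows, clusters_by_effect = [], {}
    for label, emap in effects.items():
        save_volume(emap.volume("F"), grid, out / f"effect_{label}_F.nii")
        recs = gs.extract_clusters(emap, config.voxel_p, min_size,
                                   config.connectivity, dataset)
        clusters_by_effect[label] = recs
        for r in recs:
            cluster_rows.append(
                {"effect": label, "hemisphere": r.hemisphere,
                 "size_voxels": r.size_voxels, "size_mm3": r.size_mm3,
                 "com_x": r.centre_of_mass[0], "com_y": r.centre_of_mass[1],
                 "com_z": r.centre_of_mass[2]})
    pd.DataFrame(cluster_rows,
                 columns=["effect", "hemisphere", "size_voxels", "size_mm3",
                          "com_x", "com_y", "com_z"]
                 ).to_csv(out / "clusters.csv", index=False)

    significance = {
        lab: (emap.volume("p") < config.voxel_p) & final_mask.data
        for lab, emap in effects.items()
    }
    labeled = gs.classify_voxels_by_priority(
        {k: v for k, v in significance.items()
         if k in gs.CHROMOPHORE_PRIORITY})
    save_volume(labeled.astype(float), grid, out / "priority_labels.nii")

    # associations on the largest chromophore-involving cluster, if any
    assoc = {}
    demo_kept = demo.set_index("participant_id").loc[kept_ids]
    behav_kept = behav.loc[kept_ids]
    canon = np.nan
    target = None
    for lab in gs.CHROMOPHORE_PRIORITY:
        if clusters_by_effect.get(lab):
            target = clusters_by_effect[lab][0]
            break
    if target is not None:
        hbo_med = target.mean_hbo[:, 1]
        canon = gs.canonical_pattern_rate(target.mean_hbo, target.mean_hbr)
        cp_med = behav_kept["cp_medium"].to_numpy()
        ok = np.isfinite(cp_med)
        if ok.sum() >= 4:
            assoc["cp_medium_vs_hbo"] = gs.brain_behavior_correlation(
                hbo_med[ok], cp_med[ok])
        assoc["demographics_vs_hbo_high"] = {
            k: v for k, v in gs.demographic_regression(
                target.mean_hbo[:, 2],
                demo_kept[["maternal_education", "income", "ses_score"]],
                config.entry_p).items() if k != "model"}

    summary = {
        "chance_tests": {ld: {"t": r[0], "p": r[1], "d": r[2]}
                         for ld, r in chance_results.items()},
        "cp_load_anova": {k: v for k, v in anova_cp.items() if k != "pairwise"},
        "ses_regression": {k: v for k, v in ses_reg.items() if k != "model"},
        "fwhm_mm": [float(f) for f in fwhm],
        "cluster_threshold_voxels": int(min_size),
        "n_clusters": int(sum(len(v) for v in clusters_by_effect.values())),
        "canonical_pattern_rate": None if np.isnan(canon) else float(canon),
        "associations": assoc,
        "log": log,
    }
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=_jsonable))
    return summary


def _to_volume(flat_masked: np.ndarray, mask: fm.MaskVolume) -> np.ndarray:
    vol = np.zeros(mask.grid.n_voxels)
    vol[mask.indices()] = flat_masked
    return vol.reshape(mask.grid.dims)


def _jsonable(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    return str(o)
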