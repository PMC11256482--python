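"""End-to-end orchestration of the DBM study.

mask -> bias-correct -> per-timepoint mean-control template -> rigid + demons
registration -> log-Jacobian maps -> permutation voxel statistics -> signed
clusters -> atlas overlap -> DTI/CBV maps -> ROI study table -> ANOVA and
correlation matrices. Every stage logs parameters, seeds and output checksums
to a JSON run manifest; reruns with the same config and seed are idempotent.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import atlas as atlas_mod
from .cohort import read_bvals_bvecs
from .imageio import RunManifest, Volume, checksum, read_labels, read_volume, write_field, write_volume
from .morphometry import log_jacobian_of_field
from .phantom import ContrastProtocol, DWIProtocol
from .preprocess import bias_correct, brain_mask, whole_brain_volume
from .quantmaps import cbv_map, delta_r2star, dti_scalars, fit_dti
from .register import build_template, register_affine, register_nonlinear
from .roi_analysis import anchored_matrix, extract_roi_means, pearson_matrix, two_way_anova_lsd
from .stats_voxel import cluster_proportions, fwe_correct, label_clusters


@dataclass
class RunConfig:
    """All knobs of one study run; every stochastic stage has an explicit seed."""

    cohort_dir: str
    out_dir: str
    timepoints: tuple = ("1M", "3M", "6M")
    alpha: float = 0.01
    n_perm: int = 500
    connectivity: int = 26
    seed: int = 0
    te: float = 0.013
    gamma_dchi_b0: float | None = None  # None -> ContrastProtocol default
    affine_levels: tuple = (4, 2)
    levels: tuple = (4, 2, 1)
    iterations: tuple = (60, 40, 20)
    sigma_update: float = 1.0
    sigma_total: float = 0.5
    smooth_fwhm_mm: float = 3.0  # Gaussian smoothing of logJ maps before stats
    variance_fwhm_mm: float = 6.0  # variance smoothing of the permutation pseudo-t
    template_iterations: int = 1
    run_quantmaps: bool = True
    run_roi_stats: bool = True
    cache: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        from .imageio import load_config

        cfg = load_config(path)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(cfg) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("timepoints", "levels", "iterations", "affine_levels"):
            if key in cfg:
                cfg[key] = tuple(cfg[key])
        return cls(**cfg)


def _params_key(path: Path, params: dict) -> str:
    blob = json.dumps({"file": checksum(path), "params": params}, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_dbm_study(config: RunConfig) -> dict:
    """Execute the full study; returns the report bundle as a dict.

    The report holds, per timepoint: cluster table, signed-voxel proportions,
    majority structures, and — when quantitative maps are enabled — the ROI
    study table with ANOVA and correlation results.
    """
    root = Path(config.cohort_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(out / "manifest.json")
    manifest.log("config", parameters=asdict(config), seed=config.seed)

    meta = pd.read_csv(root / "metadata.csv")
    missing = [tp for tp in config.timepoints if tp not in set(meta["timepoint"])]
    if missing:
        raise RuntimeError(f"stage=load: timepoints {missing} absent from metadata")

    atlas_labels = read_labels(root / "phantom" / "labels.nii.gz")
    atlas_ref = read_volume(root / "phantom" / "template_t2w.nii.gz")
    naming = atlas_mod.load_naming_table(root / "phantom" / "label_names.csv")

    reg_params = {
        "affine_levels": list(config.affine_levels),
        "levels": list(config.levels), "iterations": list(config.iterations),
        "sigma_update": config.sigma_update, "sigma_total": config.sigma_total,
        "smooth_fwhm_mm": config.smooth_fwhm_mm,
    }
    cache_dir = out / "cache"

    report: dict = {"timepoints": {}, "config": asdict(config)}
    study_rows: list[dict] = []
    roi_masks: dict[str, np.ndarray] = {}
    roi_sign: dict[str, int] = {}

    preprocessed: dict[tuple[str, str], tuple[Volume, np.ndarray]] = {}
    for tp in config.timepoints:
        sub = meta[meta["timepoint"] == tp]
        for row in sub.itertuples():
            try:
                vol = read_volume(root / row.t2w)
                mask = brain_mask(vol)
                corrected = bias_correct(vol, mask)
            except Exception as exc:
                raise RuntimeError(f"stage=preprocess subject={row.subject_id} tp={tp}: {exc}") from exc
            masked = corrected.copy_with(np.where(mask.data, corrected.data, 0.0))
            preprocessed[(row.subject_id, tp)] = (masked, mask.data)
        manifest.log("preprocess", parameters={"timepoint": tp, "n": len(sub)})

    for tp in config.timepoints:
        sub = meta[meta["timepoint"] == tp]
        controls = sub[sub["group"] == "control"]["subject_id"].tolist()
        irradiated = sub[sub["group"] == "irradiated"]["subject_id"].tolist()
        if not controls:
            raise RuntimeError(f"stage=template tp={tp}: no control subjects")

        template, ctl_transforms = build_template(
            [preprocessed[(sid, tp)][0] for sid in controls],
            iterations=config.template_iterations, levels=config.affine_levels,
            return_transforms=True,
        )
        ctl_rigid = dict(zip(controls, ctl_transforms))
        tpl_mask = brain_mask(template).data
        write_volume(template, out / f"template_{tp}.nii.gz")
        manifest.log("template", parameters={"timepoint": tp, "n_controls": len(controls)},
                     outputs=[str(out / f"template_{tp}.nii.gz")])

        logj_maps: dict[str, Volume] = {}
        results: dict[str, object] = {}
        for sid in controls + irradiated:
            vol, _ = preprocessed[(sid, tp)]
            src = root / sub[sub["subject_id"] == sid]["t2w"].iloc[0]
            key = _params_key(src, reg_params)
            cpath = cache_dir / f"logj_{sid}_{tp}_{key}.nii.gz"
            fpath = cache_dir / f"field_{sid}_{tp}_{key}.nii.gz"
            if config.cache and cpath.exists() and fpath.exists():
                from .imageio import read_field
                from .register import AffineTransform, RegistrationResult

                logj_maps[sid] = read_volume(cpath)
                results[sid] = RegistrationResult(
                    affine=AffineTransform.identity(), field=read_field(fpath)
                )
                continue
            try:
                # template-building already aligned the controls to template space
                rigid = ctl_rigid.get(sid) or register_affine(
                    vol, template, kind="rigid", levels=config.affine_levels)
                result = register_nonlinear(
                    vol, template, init=rigid, mask=tpl_mask,
                    levels=config.levels, iterations=config.iterations,
                    sigma_update=config.sigma_update, sigma_total=config.sigma_total,
                )
            except Exception as exc:
                raise RuntimeError(f"stage=register subject={sid} tp={tp}: {exc}") from exc
            results[sid] = result
            jmap = log_jacobian_of_field(result.field, mask=tpl_mask)
            logj_maps[sid] = jmap.log_jacobian
            if config.cache:
                write_volume(jmap.log_jacobian, cpath)
                write_field(result.field, fpath)
        manifest.log("register", parameters={"timepoint": tp, **reg_params})

        if config.smooth_fwhm_mm > 0:
            from scipy.ndimage import gaussian_filter

            sig_vox = (config.smooth_fwhm_mm / 2.355) / template.spacing
            logj_maps = {
                s: v.copy_with(gaussian_filter(np.asarray(v.data, float), sig_vox))
                for s, v in logj_maps.items()
            }
        maps_irr = [logj_maps[s] for s in irradiated]
        maps_ctl = [logj_maps[s] for s in controls]
        var_fwhm_vox = float(config.variance_fwhm_mm / template.spacing.min())
        sig, statmap, info = fwe_correct(
            maps_irr, maps_ctl, tpl_mask, alpha=config.alpha,
            n_perm=config.n_perm, seed=config.seed,
            variance_fwhm_vox=var_fwhm_vox,
        )
        clusters = label_clusters(sig, connectivity=config.connectivity)
        neg_pct, pos_pct = cluster_proportions(clusters, tpl_mask)
        write_volume(statmap.t, out / f"tmap_{tp}.nii.gz")
        write_volume(sig, out / f"sigmask_{tp}.nii.gz")
        clusters.to_frame().to_csv(out / f"clusters_{tp}.csv", index=False)
        manifest.log("voxel_stats", parameters={"timepoint": tp, "alpha": config.alpha,
                                                "n_perm": info["n_permutations"]},
                     seed=config.seed,
                     outputs=[str(out / f"tmap_{tp}.nii.gz"), str(out / f"sigmask_{tp}.nii.gz")])

        warped_atlas, _ = atlas_mod.register_atlas(atlas_labels, atlas_ref, template)
        overlap = atlas_mod.clusters_to_structures(clusters, warped_atlas, naming)
        overlap.to_frame().to_csv(out / f"atlas_overlap_{tp}.csv", index=False)

        majority = overlap.majority(0) if len(clusters) else None
        report["timepoints"][tp] = {
            "n_control": len(controls),
            "n_irradiated": len(irradiated),
            "whole_brain_mm3": whole_brain_volume(Volume(data=tpl_mask, affine=template.affine)),
            "negative_pct": neg_pct,
            "positive_pct": pos_pct,
            "n_clusters": len(clusters),
            "largest_cluster_sign": clusters.clusters[0].sign if len(clusters) else 0,
            "majority_structure": majority.name if majority else None,
            "majority_fraction": majority.fraction if majority else None,
        }

        if len(clusters):
            dominant = clusters.clusters[0]
            roi = np.zeros_like(tpl_mask, dtype=bool)
            roi[dominant.voxels[:, 0], dominant.voxels[:, 1], dominant.voxels[:, 2]] = True
            roi_masks[f"DBM-{tp}"] = roi
            roi_sign[f"DBM-{tp}"] = dominant.sign

        if config.run_quantmaps:
            contrast = ContrastProtocol() if config.gamma_dchi_b0 is None else None
            for sid in controls + irradiated:
                row = sub[sub["subject_id"] == sid].iloc[0]
                try:
                    bvals, bvecs = read_bvals_bvecs(root / row["bval"], root / row["bvec"])
                    dwi = read_volume(root / row["dwi"])
                    protocol = DWIProtocol(bvals=bvals, bvecs=bvecs)
                    tensors = fit_dti(dwi, protocol, mask=np.asarray(dwi.data)[..., 0] > 0)
                    md, ad, rd = dti_scalars(tensors)
                    pre = read_volume(root / row["t2star_pre"])
                    post = read_volume(root / row["t2star_post"])
                    dr2s, _ = delta_r2star(pre, post, te=config.te)
                    cbv = cbv_map(dr2s, protocol=contrast, gamma_dchi_b0=config.gamma_dchi_b0).cbv
                except Exception as exc:
                    raise RuntimeError(f"stage=quantmaps subject={sid} tp={tp}: {exc}") from exc
                # subject maps share the T2w grid; reuse the T2w warp when available
                res = results.get(sid)
                warped = {}
                for name, vol in (("JD", logj_maps[sid]), ("CBV", cbv), ("MD", md), ("AD", ad), ("RD", rd)):
                    if name == "JD" or res is None:
                        warped[name] = vol  # JD already lives in template space
                    else:
                        from .register import apply_transform
                        warped[name] = apply_transform(vol, res, interpolation="linear")
                study_rows.append({"subject_id": sid, "group": row["group"], "timepoint": tp,
                                   "_maps": warped})
            manifest.log("quantmaps", parameters={"timepoint": tp, "te": config.te})

    # ROI means for every recorded DBM cluster ROI
    study_table = None
    if config.run_quantmaps and study_rows and roi_masks:
        rows = []
        for entry in study_rows:
            for roi_name, roi in roi_masks.items():
                rec = {"subject_id": entry["subject_id"], "group": entry["group"],
                       "timepoint": entry["timepoint"], "roi": roi_name,
                       "roi_provenance": "dbm_cluster"}
                for pname, vol in entry["_maps"].items():
                    rec[pname] = extract_roi_means(vol, roi)
                rows.append(rec)
        study_table = pd.DataFrame(rows)
        study_table.to_csv(out / "study_table.csv", index=False)
        manifest.log("roi_table", outputs=[str(out / "study_table.csv")])

    if config.run_roi_stats and study_table is not None:
        roi_stats = {}
        for roi_name in roi_masks:
            sub_tbl = study_table[study_table["roi"] == roi_name]
            entry = {}
            for param in ("JD", "CBV", "MD", "AD", "RD"):
                try:
                    res = two_way_anova_lsd(sub_tbl, param)
                    res.table.to_csv(out / f"anova_{roi_name}_{param}.csv", index=False)
                    entry[param] = {"anova_p": dict(zip(res.table["effect"], res.table["p"]))}
                except ValueError:
                    entry[param] = {"anova_p": None}
            pooled = pearson_matrix(sub_tbl)
            pooled.r.to_csv(out / f"correlation_pooled_{roi_name}.csv")
            anchor_tp = roi_name.split("-")[1]
            try:
                anchored = anchored_matrix(sub_tbl, anchor_param="JD", anchor_time=anchor_tp)
                anchored.r.to_csv(out / f"correlation_anchored_{roi_name}.csv")
                entry["anchored_r"] = anchored.r.iloc[0].to_dict()
                entry["anchored_p"] = anchored.p.iloc[0].to_dict()
            except ValueError:
                entry["anchored_r"] = None
            roi_stats[roi_name] = entry
        report["roi_stats"] = roi_stats
        manifest.log("roi_stats")

    with open(out / "report.json", "w") as fh:
        json.dump(_jsonify(report), fh, indent=2)
    manifest.log("done", outputs=[str(out / "report.json")])
    return report


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
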