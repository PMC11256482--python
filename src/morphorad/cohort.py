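"""Synthesis of two-group longitudinal study cohorts on disk.

Each subject is a degraded copy of the clean phantom: a subject-specific
anatomical jitter (weak random Gaussian blobs), a per-session rigid pose, a
smooth multiplicative bias field, and Rician magnitude noise. Irradiated
subjects additionally receive the planted focal effects (volume change, MD
change, CBV change) of their timepoint, scaled by a per-subject latent
severity so that macro- and microstructural changes are coupled across
subjects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .imageio import Volume, write_volume
from .phantom import (
    LABEL_NAMES,
    ContrastProtocol,
    DWIProtocol,
    FocalDeformationSpec,
    PhantomSpec,
    add_rician_noise,
    default_dwi_protocol,
    invert_field,
    make_bias_field,
    make_deformation,
    make_phantom,
    resample_through_map,
    simulate_dwi,
    simulate_t2star,
    tissue_cbv_field,
    tissue_tensor_field,
    write_label_names,
)

NAME_TO_LABEL = {v: k for k, v in LABEL_NAMES.items()}

# control-group reference values used to size the planted effects: the study
# conditions are a corpus-callosum MD drop and contraction in the early phase
# and a cortical expansion plus CBV drop in the late phase.
_MD_CC = (586.04, 762.44)      # irradiated, control (um^2/s) at 1M
_MD_CTX = (629.55, 820.70)     # at 1M
_CBV_CC = (2.36, 3.20)         # % at 6M
_CBV_CTX = (5.13, 6.83)        # % at 6M


@dataclass
class CohortEffect:
    """A planted group difference at one timepoint inside one structure."""

    timepoint: str
    structure: str
    volume_ratio: float = 1.0
    md_scale: float = 1.0
    cbv_scale: float = 1.0
    sigma_mm: float | None = None

    def __post_init__(self) -> None:
        if self.volume_ratio <= 0:
            raise ValueError("volume_ratio must be > 0")
        if self.structure not in NAME_TO_LABEL:
            raise ValueError(f"unknown structure {self.structure!r}")


def default_effects() -> list[CohortEffect]:
    # contraction and expansion are log-symmetric: ln(1/0.9) = -ln(0.9)
    return [
        CohortEffect("1M", "corpus_callosum", volume_ratio=0.9, md_scale=_MD_CC[0] / _MD_CC[1]),
        CohortEffect("1M", "cortex", md_scale=_MD_CTX[0] / _MD_CTX[1]),
        CohortEffect("6M", "corpus_callosum", cbv_scale=_CBV_CC[0] / _CBV_CC[1]),
        CohortEffect("6M", "cortex", volume_ratio=1.0 / 0.9, cbv_scale=_CBV_CTX[0] / _CBV_CTX[1]),
    ]


@dataclass
class CohortDesign:
    phantom: PhantomSpec = dc_field(default_factory=PhantomSpec)
    n_control: int = 6
    n_irradiated: int = 6
    timepoints: tuple = ("1M", "3M", "6M")
    effects: list[CohortEffect] = dc_field(default_factory=default_effects)
    severity_range: tuple = (0.8, 1.2)  # inter-animal response to the controlled dose
    jitter_blobs: int = 2
    jitter_log_ratio_sd: float = 0.01
    jitter_sigma_mm: float = 1.5
    rigid_rot_sd_deg: float = 1.0
    rigid_trans_sd_mm: float = 0.2
    dwi: DWIProtocol | None = None
    contrast: ContrastProtocol = dc_field(default_factory=ContrastProtocol)
    include_microstructure: bool = True  # write DWI and T2* pairs
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 2 or self.n_irradiated < 2:
            raise ValueError("need n >= 2 per group (group statistics undefined below that)")
        if self.dwi is None:
            self.dwi = default_dwi_protocol()


@dataclass
class CohortDataset:
    root: Path
    metadata: pd.DataFrame
    labels_path: Path
    template_path: Path
    label_names_path: Path
    truth: dict


def _effect_center_sigma(labels: Volume, structure: str, sigma_mm: float | None) -> tuple[np.ndarray, float]:
    """Blob centre (world mm) and radius for a structure's focal effect.

    The cortex effect sits in the dorsal cortical shell (the structure's
    centroid would fall in deep grey matter); other structures use their
    centroid.
    """
    lab = np.asarray(labels.data)
    code = NAME_TO_LABEL[structure]
    mask = lab == code
    if not mask.any():
        raise ValueError(f"structure {structure} empty in label map")
    ijk = np.argwhere(mask)
    world = labels.voxel_to_world(ijk)
    if structure == "cortex":
        # mid-dorsal cortical shell: deep enough that the deformation is
        # surrounded by tissue on all sides (a blob at the brain surface is
        # half-unobservable), dorsal enough to stay clear of deep grey matter
        zmax = world[:, 2].max()
        band = world[(world[:, 2] >= 0.5 * zmax) & (world[:, 2] <= 0.8 * zmax)]
        center = band.mean(axis=0)
    else:
        center = world.mean(axis=0)
    # default radius: a regional effect spanning >= 4-5 voxels at the analysis
    # resolution (smaller blobs are not resolvable by the deformation field)
    # while staying mostly within the structure it is planted in
    sigma = sigma_mm if sigma_mm is not None else 3.0
    return center, sigma


def _random_rigid(rng: np.random.Generator, rot_sd_deg: float, trans_sd_mm: float) -> np.ndarray:
    angles = rng.normal(0.0, rot_sd_deg, 3)
    R = Rotation.from_euler("xyz", angles, degrees=True).as_matrix()
    t = rng.normal(0.0, trans_sd_mm, 3)
    M = np.eye(4)
    M[:3, :3] = R
    M[:3, 3] = t
    return M


def write_bvals_bvecs(protocol: DWIProtocol, prefix: str | Path) -> tuple[Path, Path]:
    """FSL-style plain-text b-table: one row of b-values, three rows of components."""
    prefix = Path(prefix)
    bval_path = prefix.with_suffix(".bval")
    bvec_path = prefix.with_suffix(".bvec")
    np.savetxt(bval_path, protocol.bvals[None, :], fmt="%.1f")
    np.savetxt(bvec_path, protocol.bvecs.T, fmt="%.6f")
    return bval_path, bvec_path


def read_bvals_bvecs(bval_path: str | Path, bvec_path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    bvals = np.loadtxt(bval_path).ravel()
    bvecs = np.loadtxt(bvec_path)
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    return bvals, bvecs


def make_cohort(design: CohortDesign, out_dir: str | Path, seed: int | None = None) -> CohortDataset:
    """Write the full synthetic study to out_dir and return its inventory.

    Layout: phantom/ (clean template, labels, naming table), subjects/<id>/<tp>/
    with t2w, dwi (+ .bval/.bvec) and t2star pre/post NIfTI volumes, plus
    metadata.csv and ground_truth.json at the root. Fully reproducible from
    the seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = design.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    clean, labels = make_phantom(design.phantom)
    template_path = write_volume(clean, out / "phantom" / "template_t2w.nii.gz")
    labels_path = write_volume(labels, out / "phantom" / "labels.nii.gz")
    names_path = write_label_names(out / "phantom" / "label_names.csv")

    protocol = design.dwi
    contrast = design.contrast
    grid = clean.world_grid()
    brain_semi = 0.4 * design.phantom.fov * design.phantom.brain_scale

    subjects = [(f"ctl{i + 1:02d}", "control") for i in range(design.n_control)]
    subjects += [(f"irr{i + 1:02d}", "irradiated") for i in range(design.n_irradiated)]

    rows: list[dict] = []
    truth: dict = {"seed": seed, "subjects": {}}

    for sid, group in subjects:
        srng = np.random.default_rng(rng.integers(0, 2 ** 31 - 1))
        severity = float(srng.uniform(*design.severity_range))
        # subject-constant anatomical jitter
        jitter = []
        for _ in range(design.jitter_blobs):
            c = srng.uniform(-0.6, 0.6, 3) * brain_semi
            ratio = float(np.exp(srng.normal(0.0, design.jitter_log_ratio_sd)))
            jitter.append(FocalDeformationSpec(center=tuple(c), sigma=design.jitter_sigma_mm, volume_ratio=ratio))
        truth["subjects"][sid] = {"group": group, "severity": severity, "timepoints": {}}

        for tp in design.timepoints:
            specs = list(jitter)
            applied = {}
            if group == "irradiated":
                for eff in design.effects:
                    if eff.timepoint != tp or eff.volume_ratio == 1.0:
                        continue
                    center, sig = _effect_center_sigma(labels, eff.structure, eff.sigma_mm)
                    ratio = float(eff.volume_ratio ** severity)
                    specs.append(FocalDeformationSpec(center=tuple(center), sigma=sig, volume_ratio=ratio))
                    applied[eff.structure] = ratio

            import warnings as _w
            with _w.catch_warnings():
                _w.simplefilter("ignore")  # random jitter blobs may sit near each other
                fwd, analytic_jac = make_deformation(specs, clean)
            inv = invert_field(fwd)
            rigid = _random_rigid(srng, design.rigid_rot_sd_deg, design.rigid_trans_sd_mm)
            rinv = np.linalg.inv(rigid)

            # template->subject map is rigid o Phi_blobs; subjects are sampled
            # through its inverse: phantom(Phi^-1(R^-1 y))
            z = grid @ rinv[:3, :3].T + rinv[:3, 3]
            from .phantom import _interpolate_field
            w_at_z = _interpolate_field(inv, z)
            coords = z + w_at_z

            bias = make_bias_field(clean, design.phantom.bias_amplitude, srng)
            anat = resample_through_map(clean, coords, order=1)
            if design.phantom.psf_fwhm_mm > 0:
                from scipy.ndimage import gaussian_filter as _gf

                anat = _gf(anat, (design.phantom.psf_fwhm_mm / 2.355) / clean.spacing)
            t2w = clean.copy_with(anat * bias)
            t2w = t2w.copy_with(add_rician_noise(t2w.data, design.phantom.noise_sigma_abs, srng))

            # microstructural parameter fields in template space, warped identically
            md_map = np.ones(clean.shape3)
            cbv_map = np.ones(clean.shape3)
            if group == "irradiated":
                for eff in design.effects:
                    if eff.timepoint != tp:
                        continue
                    code = NAME_TO_LABEL[eff.structure]
                    sel = np.asarray(labels.data) == code
                    if eff.md_scale != 1.0:
                        md_map[sel] *= float(eff.md_scale ** severity)
                    if eff.cbv_scale != 1.0:
                        cbv_map[sel] *= float(eff.cbv_scale ** severity)

            subj_dir = out / "subjects" / sid / tp
            subj_dir.mkdir(parents=True, exist_ok=True)
            p_t2w = write_volume(t2w, subj_dir / "t2w.nii.gz")
            p_dwi = p_bval = p_bvec = p_pre = p_post = None
            if design.include_microstructure:
                tensors = tissue_tensor_field(labels, md_map)
                cbv = tissue_cbv_field(labels, cbv_map)
                warped_tensors = np.empty_like(tensors)
                for j in range(3):
                    for k in range(j, 3):
                        comp = resample_through_map(clean.copy_with(tensors[..., j, k]), coords, order=1)
                        warped_tensors[..., j, k] = comp
                        warped_tensors[..., k, j] = comp
                warped_cbv = np.clip(resample_through_map(cbv, coords, order=1), 0.0, None)
                s0_field = resample_through_map(clean, coords, order=1) * (
                    protocol.s0 / design.phantom.intensities["cortex"])

                dwi = simulate_dwi(
                    warped_tensors, protocol, clean.affine, s0=s0_field,
                    noise_sigma=design.phantom.noise_sigma * protocol.s0, rng=srng,
                )
                pre_base = clean.copy_with(s0_field)
                pre, post = simulate_t2star(
                    clean.copy_with(warped_cbv, units="%"), contrast, pre_base,
                    noise_sigma=design.phantom.noise_sigma * protocol.s0, rng=srng,
                )
                p_dwi = write_volume(dwi, subj_dir / "dwi.nii.gz")
                p_bval, p_bvec = write_bvals_bvecs(protocol, subj_dir / "dwi")
                p_pre = write_volume(pre, subj_dir / "t2star_pre.nii.gz")
                p_post = write_volume(post, subj_dir / "t2star_post.nii.gz")

            lab_arr = np.asarray(labels.data)
            logj_analytic = np.log(analytic_jac(grid))
            mean_logj = {
                name: float(logj_analytic[lab_arr == code].mean())
                for code, name in LABEL_NAMES.items()
                if code != 0
            }
            truth["subjects"][sid]["timepoints"][tp] = {
                "applied_volume_ratios": applied,
                "md_scale": {n: float(md_map[lab_arr == c].mean()) for c, n in LABEL_NAMES.items() if c != 0},
                "cbv_scale": {n: float(cbv_map[lab_arr == c].mean()) for c, n in LABEL_NAMES.items() if c != 0},
                "mean_logj": mean_logj,
                "rigid": rigid.tolist(),
            }
            rel = lambda p: str(p.relative_to(out)) if p is not None else ""
            rows.append({
                "subject_id": sid,
                "group": group,
                "timepoint": tp,
                "t2w": rel(p_t2w),
                "dwi": rel(p_dwi),
                "bval": rel(p_bval),
                "bvec": rel(p_bvec),
                "t2star_pre": rel(p_pre),
                "t2star_post": rel(p_post),
            })

    metadata = pd.DataFrame(rows)
    metadata.to_csv(out / "metadata.csv", index=False)
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)

    return CohortDataset(
        root=out, metadata=metadata, labels_path=labels_path,
        template_path=template_path, label_names_path=names_path, truth=truth,
    )


def make_parameter_table(
    n_control: int = 6,
    n_irradiated: int = 6,
    timepoints: tuple = ("1M", "3M", "6M"),
    roi: str = "corpus_callosum",
    seed: int = 0,
    couple_md: bool = True,
) -> pd.DataFrame:
    """Per-subject ROI-mean parameter table with a planted JD-MD coupling.

    Lightweight statistical twin of the imaging cohort: irradiated subjects
    share one latent severity across parameters and times, so JD at the early
    timepoint and MD at the early timepoint co-vary. Used to exercise the ROI
    statistics (ANOVA, LSD, correlation matrices) without running registration.
    """
    rng = np.random.default_rng(seed)
    if roi == "corpus_callosum":
        base = {"JD": 0.0, "CBV": _CBV_CC[1], "MD": _MD_CC[1], "AD": 1500.0, "RD": 393.7}
        jd_tp, jd_logratio = "1M", np.log(0.9)
        md_drop = 1.0 - _MD_CC[0] / _MD_CC[1]
        cbv_tp, cbv_drop = "6M", 1.0 - _CBV_CC[0] / _CBV_CC[1]
    elif roi == "cortex":
        base = {"JD": 0.0, "CBV": _CBV_CTX[1], "MD": _MD_CTX[1], "AD": 820.7, "RD": 820.7}
        jd_tp, jd_logratio = "6M", np.log(1.1)
        md_drop = 1.0 - _MD_CTX[0] / _MD_CTX[1]
        cbv_tp, cbv_drop = "6M", 1.0 - _CBV_CTX[0] / _CBV_CTX[1]
    else:
        raise ValueError("roi must be 'corpus_callosum' or 'cortex'")

    # measurement noise on ROI means; the planted severity term carries the
    # biological between-animal variance, so total irradiated SDs land near
    # the reported group SDs (e.g. MD ~ 48 um^2/s, CBV ~ 1.2 %)
    noise = {"JD": 0.010, "CBV": 0.8, "MD": 25.0, "AD": 60.0, "RD": 30.0}
    rows = []
    for group, n in (("control", n_control), ("irradiated", n_irradiated)):
        for i in range(n):
            sid = f"{group[:3]}{i + 1:02d}"
            severity = rng.uniform(0.6, 1.4) if group == "irradiated" else 0.0
            for tp in timepoints:
                row = {"subject_id": sid, "group": group, "timepoint": tp}
                jd = severity * jd_logratio if tp == jd_tp else 0.0
                md = base["MD"] * (1.0 - (md_drop * severity if (couple_md and tp == "1M") else 0.0))
                cbv = base["CBV"] * (1.0 - (cbv_drop * severity if tp == cbv_tp else 0.0))
                row["JD"] = jd + rng.normal(0.0, noise["JD"])
                row["MD"] = md + rng.normal(0.0, noise["MD"])
                row["CBV"] = max(0.0, cbv + rng.normal(0.0, noise["CBV"]))
                row["AD"] = base["AD"] + rng.normal(0.0, noise["AD"])
                row["RD"] = base["RD"] + rng.normal(0.0, noise["RD"])
                rows.append(row)
    return pd.DataFrame(rows)
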