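"""End-to-end study orchestration.

Reads a cohort laid out as ``subjects.tsv`` + ``bundles/*.tck`` +
``volumes/*.nii[.gz]``, runs dissection, outlier removal, mirroring and ICP
alignment, joint parameterization, binned (normalized) scalar profiles, and
the group / crowding / etiology contrasts with TFCE-corrected sectional
statistics, Barnard's exact test and the logistic crowding models.

Patients contribute only their contralesional hemisphere; controls
contribute both (by default each control hemisphere enters the matching
side's contrast).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from tractcrowd.errors import ConfigError
from tractcrowd.geometry import (
    curvature_profile,
    filter_by_rois,
    icp_align,
    load_roi_presets,
    mirror_bundle,
    representative_streamline,
    resample_streamline,
)
from tractcrowd.io_formats import (
    Bundle,
    SubjectRecord,
    read_scalar_volume,
    read_streamlines,
    read_subjects,
)
from tractcrowd.parameterization import (
    JointParameterization,
    OutlierFilterParams,
    ProfileRow,
    bin_scalar_profile,
    bin_vertex_values,
    extract_core,
    joint_parameterize,
    normalize_profile,
    remove_outliers,
)
from tractcrowd.stats import (
    TFCEParams,
    TFCEResult,
    barnard_exact,
    classify_crowding,
    fit_crowding_models,
    permutation_fwe,
    whole_tract_compare,
)

log = logging.getLogger("tractcrowd")


@dataclass
class AnalysisConfig:
    """Knobs of a full study run; every random step derives from ``seed``."""

    tract_name: str = "AF"
    metrics: tuple[str, ...] = ("FA", "curvature")
    contrasts: tuple[str, ...] = ("group", "crowding", "etiology_crowding")
    roi_preset: str | None = None  # e.g. "af"; None skips ROI dissection
    n_resample: int = 50
    outlier_nu: float = 0.1
    knn: int = 10
    max_isomap_points: int = 20000
    min_subject_coverage: float = 0.8
    min_vertex_density: float = 5.0
    n_bins: int = 7
    tfce: TFCEParams = field(default_factory=TFCEParams)
    crowding_threshold: float = 10.0
    alpha: float = 0.05
    normalize_by_skeleton: bool = True
    control_hemispheres: str = "matched"  # matched | both
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must be in (0, 1)")
        if self.control_hemispheres not in ("matched", "both"):
            raise ConfigError("control_hemispheres must be matched/both")
        known = ("group", "crowding", "etiology_crowding")
        for c in self.contrasts:
            if c not in known:
                raise ConfigError(f"unknown contrast {c!r}; known: {known}")


@dataclass
class ContrastResult:
    contrast: str
    hemisphere: str
    metric: str
    n_a: int
    n_b: int
    whole_p: float
    whole_d: float
    tfce: TFCEResult


@dataclass
class StudyReport:
    contrasts: list[ContrastResult]
    barnard_p: float | None
    barnard_table: list[list[int]] | None
    models: list
    core: tuple[float, float]
    attrition: dict
    out_dir: Path | None = None


def _load_cohort_bundles(
    data_dir: Path, subjects: list[SubjectRecord], tract_name: str
) -> list[Bundle]:
    """Bundles in deterministic order; patients contralesional side only."""
    bundles = []
    for rec in sorted(subjects, key=lambda r: r.subject_id):
        if rec.group == "patient":
            sides = [rec.contralesional_hemisphere] if rec.contralesional_hemisphere != "n/a" else []
        else:
            sides = ["left", "right"]
        for side in sides:
            path = data_dir / "bundles" / f"sub-{rec.subject_id}_hemi-{side}_{tract_name}.tck"
            if not path.exists():
                log.warning("missing bundle file %s; skipping", path)
                continue
            bundles.append(read_streamlines(path))
    return bundles


def _find_volume(data_dir: Path, subject_id: str, metric: str) -> Path | None:
    for ext in (".nii.gz", ".nii"):
        p = data_dir / "volumes" / f"sub-{subject_id}_{metric}{ext}"
        if p.exists():
            return p
    return None


def prepare_bundles(
    bundles: list[Bundle], config: AnalysisConfig
) -> tuple[list[Bundle], list[Bundle], dict]:
    """Dissection, resampling, outlier removal, mirroring and ICP alignment.

    Returns ``(aligned, native, attrition)``: ``aligned`` holds every bundle
    in a common (left-hemisphere) frame for the joint parameterization,
    ``native`` the same streamlines (same order, same vertex indexing) in
    their original world frame, where scalar volumes are sampled.
    Right-side bundles are mirrored across the midsagittal plane before ICP
    because a rigid transform cannot map an arch onto its reflection.
    """
    rois = load_roi_presets(config.roi_preset) if config.roi_preset else None
    attrition: dict = {}
    prepared: list[Bundle] = []
    for b in bundles:
        key = f"{b.subject_id}/{b.hemisphere}"
        entry = {"initial": len(b)}
        if rois is not None:
            b = filter_by_rois(b, rois[b.hemisphere])
        entry["after_roi"] = len(b)
        if len(b) == 0:
            log.warning("bundle %s empty after ROI dissection; dropped", key)
            attrition[key] = entry
            continue
        b = b.with_streamlines(resample_streamline(s, config.n_resample) for s in b)
        kept, _ = remove_outliers(
            b, OutlierFilterParams(nu=config.outlier_nu), seed=config.seed
        )
        entry["after_outlier"] = len(kept)
        log.info(
            "%s: %d -> %d (ROI) -> %d (outlier removal)",
            key, entry["initial"], entry["after_roi"], entry["after_outlier"],
        )
        attrition[key] = entry
        prepared.append(kept)
    if not prepared:
        raise ConfigError("no bundles survived preparation")

    # original hemisphere labels are kept on the aligned bundles so contrasts
    # can still split by side; geometry lives in the left frame after this.
    aligned: list[Bundle] = []
    reference = None
    for b in prepared:
        geom = mirror_bundle(b) if b.hemisphere == "right" else b
        rep = representative_streamline(geom)
        if reference is None:
            reference = rep
            aligned_geom = geom
        else:
            # representatives follow the bundle-majority vertex order, which
            # the cohort convention ties to anatomy (posterior start), so the
            # reversed-order fit must not compete: an arc is nearly congruent
            # to its own reversal and would be flipped half the time
            transform = icp_align(rep, reference, orientation="fixed")
            aligned_geom = transform.apply_bundle(geom)
        aligned.append(
            Bundle(
                streamlines=aligned_geom.streamlines,
                subject_id=b.subject_id,
                hemisphere=b.hemisphere,
                tract_name=b.tract_name,
            )
        )
    return aligned, prepared, attrition


def compute_profiles(
    native: list[Bundle],
    jp: JointParameterization,
    subjects: list[SubjectRecord],
    data_dir: Path,
    config: AnalysisConfig,
) -> dict[str, dict[tuple[str, str], ProfileRow]]:
    """Per-metric {(subject, hemisphere): ProfileRow} with normalization.

    ``native`` must be index-aligned with the parameterization but live in
    the original world frame, where the scalar volumes are defined.
    """
    by_id = {r.subject_id: r for r in subjects}
    out: dict[str, dict[tuple[str, str], ProfileRow]] = {m: {} for m in config.metrics}
    for i, b in enumerate(native):
        rec = by_id[b.subject_id]
        for metric in config.metrics:
            if metric == "curvature":
                values = np.stack([curvature_profile(s).kappa for s in b.streamlines])
                row = bin_vertex_values(jp, i, values)
                row.metric_name = "curvature"
            else:
                vol_path = _find_volume(data_dir, b.subject_id, metric)
                if vol_path is None:
                    log.warning("no %s volume for %s; skipping", metric, b.subject_id)
                    continue
                volume = read_scalar_volume(vol_path, metric_name=metric)
                row = bin_scalar_profile(jp, b, volume, bundle_index=i)
                if config.normalize_by_skeleton:
                    skel = (
                        rec.skeleton_mean_fa
                        if metric == "FA"
                        else rec.extras.get(f"skeleton_mean_{metric.lower()}", np.nan)
                    )
                    if np.isfinite(skel) and skel > 0:
                        row = normalize_profile(row, skel)
            out[metric][(b.subject_id, b.hemisphere)] = row
    return out


def _profile_matrix(
    rows: dict[tuple[str, str], ProfileRow],
    members_a: list[tuple[str, str]],
    members_b: list[tuple[str, str]],
    n_bins: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stack (subjects x bins) profiles and whole-tract vectors for a contrast."""
    def stack(members):
        mat = np.full((len(members), n_bins), np.nan)
        whole = np.full(len(members), np.nan)
        for i, key in enumerate(members):
            if key in rows:
                mat[i] = rows[key].bin_means
                whole[i] = rows[key].whole_tract_mean
        return mat, whole

    mat_a, whole_a = stack(members_a)
    mat_b, whole_b = stack(members_b)
    return mat_a, mat_b, whole_a, whole_b


def run_study(
    config: AnalysisConfig, data_dir: str | Path, out_dir: str | Path | None = None
) -> StudyReport:
    """Execute the full analysis; see module docstring."""
    data_dir = Path(data_dir)
    subjects = read_subjects(data_dir / "subjects.tsv")
    bundles = _load_cohort_bundles(data_dir, subjects, config.tract_name)
    aligned, native, attrition = prepare_bundles(bundles, config)

    anchor = None
    if config.roi_preset:
        for roi in load_roi_presets(config.roi_preset)["left"]:
            if roi.label == "temporal":
                anchor = roi.center
    jp = joint_parameterize(
        aligned,
        knn=config.knn,
        max_points=config.max_isomap_points,
        anchor=anchor,
        seed=config.seed,
    )
    jp = extract_core(
        jp,
        aligned,
        min_subject_coverage=config.min_subject_coverage,
        min_vertex_density=config.min_vertex_density,
    )
    jp.n_bins = config.n_bins
    profiles = compute_profiles(native, jp, subjects, data_dir, config)

    patients = [r for r in subjects if r.group == "patient"]
    controls = [r for r in subjects if r.group == "control"]
    crowding_of = {
        r.subject_id: classify_crowding(r, config.crowding_threshold) for r in patients
    }

    contrast_members: list[tuple[str, str, list, list]] = []
    for hemi in ("left", "right"):
        pats = [
            (r.subject_id, hemi) for r in patients if r.contralesional_hemisphere == hemi
        ]
        if config.control_hemispheres == "matched":
            ctls = [(r.subject_id, hemi) for r in controls]
        else:
            ctls = [(r.subject_id, h) for r in controls for h in ("left", "right")]
        if "group" in config.contrasts:
            contrast_members.append(("group", hemi, pats, ctls))
        if "crowding" in config.contrasts:
            crowd = [k for k in pats if (c := crowding_of[k[0]]) and c.crowding]
            nocrowd = [k for k in pats if (c := crowding_of[k[0]]) and not c.crowding]
            contrast_members.append(("crowding", hemi, crowd, nocrowd))
        if "etiology_crowding" in config.contrasts:
            cc = [
                k
                for k in pats
                if (c := crowding_of[k[0]])
                and c.crowding
                and _etiology(patients, k[0]) == "congenital"
            ]
            anc = [
                k
                for k in pats
                if (c := crowding_of[k[0]])
                and not c.crowding
                and _etiology(patients, k[0]) == "acquired"
            ]
            contrast_members.append(("etiology_crowding", hemi, cc, anc))

    results: list[ContrastResult] = []
    for contrast, hemi, members_a, members_b in contrast_members:
        if len(members_a) < 2 or len(members_b) < 2:
            log.warning(
                "contrast %s/%s skipped: group sizes %d vs %d",
                contrast, hemi, len(members_a), len(members_b),
            )
            continue
        for metric in config.metrics:
            rows = profiles[metric]
            mat_a, mat_b, whole_a, whole_b = _profile_matrix(
                rows, members_a, members_b, config.n_bins
            )
            try:
                whole_p, whole_d = whole_tract_compare(whole_a, whole_b)
            except ValueError as exc:
                log.warning("%s/%s/%s whole-tract comparison skipped: %s",
                            contrast, hemi, metric, exc)
                continue
            stacked = np.vstack([mat_a, mat_b])
            labels = np.zeros(len(stacked), dtype=bool)
            labels[: len(mat_a)] = True
            tfce = permutation_fwe(stacked, labels, config.tfce, alpha=config.alpha)
            results.append(
                ContrastResult(
                    contrast=contrast,
                    hemisphere=hemi,
                    metric=metric,
                    n_a=len(members_a),
                    n_b=len(members_b),
                    whole_p=whole_p,
                    whole_d=whole_d,
                    tfce=tfce,
                )
            )

    barnard_p = None
    barnard_table = None
    labeled = [(r, crowding_of[r.subject_id]) for r in patients if crowding_of[r.subject_id]]
    etio_known = [(r, c) for r, c in labeled if r.etiology in ("congenital", "acquired")]
    if etio_known:
        tbl = np.zeros((2, 2), dtype=int)
        for r, c in etio_known:
            tbl[0 if c.crowding else 1, 0 if r.etiology == "congenital" else 1] += 1
        barnard_table = tbl.tolist()
        if tbl[:, 0].sum() > 0 and tbl[:, 1].sum() > 0:
            barnard_p = barnard_exact(tbl)
        else:
            log.warning("Barnard test skipped: an etiology column is empty")

    models = []
    fa_rows = profiles.get("FA", {})
    whole_fa = {
        r.subject_id: fa_rows[(r.subject_id, r.contralesional_hemisphere)].whole_tract_mean
        for r in patients
        if (r.subject_id, r.contralesional_hemisphere) in fa_rows
    }
    try:
        models = fit_crowding_models(subjects, whole_fa, config.crowding_threshold)
    except ValueError as exc:
        log.warning("logistic models skipped: %s", exc)

    report = StudyReport(
        contrasts=results,
        barnard_p=barnard_p,
        barnard_table=barnard_table,
        models=models,
        core=jp.core,
        attrition=attrition,
    )
    if out_dir is not None:
        report.out_dir = Path(out_dir)
        write_report(report, config, Path(out_dir))
    return report


def _etiology(patients: list[SubjectRecord], subject_id: str) -> str:
    for r in patients:
        if r.subject_id == subject_id:
            return r.etiology
    return "n/a"


def write_report(report: StudyReport, config: AnalysisConfig, out_dir: Path) -> None:
    """TSV bin tables, a JSON summary and simple per-contrast bin plots."""
    out_dir.mkdir(parents=True, exist_ok=True)
    for res in report.contrasts:
        df = pd.DataFrame(
            {
                "bin": np.arange(1, len(res.tfce.z_obs) + 1),
                "z": np.round(res.tfce.z_obs, 10),
                "tfce": np.round(res.tfce.tfce_obs, 10),
                "p_corrected": np.round(res.tfce.p_corrected, 10),
                "significant": res.tfce.significant,
            }
        )
        stem = f"bins_{res.contrast}_{res.hemisphere}_{res.metric}"
        df.to_csv(out_dir / f"{stem}.tsv", sep="\t", index=False)
        _plot_contrast(res, out_dir / f"{stem}.png")
    whole = pd.DataFrame(
        [
            {
                "contrast": r.contrast,
                "hemisphere": r.hemisphere,
                "metric": r.metric,
                "n_a": r.n_a,
                "n_b": r.n_b,
                "p": round(r.whole_p, 10),
                "cohens_d": round(r.whole_d, 10),
            }
            for r in report.contrasts
        ]
    )
    whole.to_csv(out_dir / "whole_tract.tsv", sep="\t", index=False)
    summary = {
        "core": list(report.core),
        "barnard_p": report.barnard_p,
        "barnard_table": report.barnard_table,
        "models": [m.to_dict() for m in report.models],
        "attrition": report.attrition,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
            if k != "tfce"
        },
        "tfce_params": asdict(config.tfce),
    }
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)


def _plot_contrast(res: ContrastResult, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    bins = np.arange(1, len(res.tfce.z_obs) + 1)
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.axhline(0.0, color="grey", lw=0.5)
    ax.plot(bins, res.tfce.z_obs, "o-", label="z")
    for b, sig in zip(bins, res.tfce.significant):
        if sig:
            ax.annotate("*", (b, res.tfce.z_obs[b - 1]), fontsize=14, ha="center",
                        xytext=(0, 8), textcoords="offset points")
    ax.set_xlabel("bin")
    ax.set_ylabel("z score")
    ax.set_title(f"{res.contrast} / {res.hemisphere} / {res.metric}")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
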