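"""Synthetic cohorts with the statistical structure the analysis assumes.

Generates arc-shaped left/right bundles (noisy copies of a planar circular
arc with a controllable fraction of displaced outlier streamlines), FA
volumes with an optional localized between-group effect of specified
Cohen's d confined to one of the seven along-arc segments, and VIQ/PIQ
scores with a specified crowding prevalence.  Everything is a pure function
of (spec, seed).

The localized effect is injected in *world space* over the arc segment whose
ideal arc-length fraction falls in ((effect_bin-1)/7, effect_bin/7], so the
analysis pipeline — not the generator — must recover the affected bin.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import NamedTuple

import numpy as np

from tractcrowd.io_formats import (
    Bundle,
    ScalarVolume,
    SubjectRecord,
    write_scalar_volume,
    write_streamlines,
    write_subjects,
)

_FA_CLIP = (0.05, 0.95)
_HEMI_X_OFFSET = 20.0  # mm between midsagittal plane and each arc's plane
_OUTLIER_SHIFT_FACTOR = 15.0  # displacement in units of jitter_sd_mm


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort; see module docstring."""

    n_group_a: int = 10
    n_group_b: int = 10
    streamlines_per_bundle: int = 50
    n_vertices: int = 50
    arc_radius_mm: float = 30.0
    arc_span_deg: float = 120.0
    jitter_sd_mm: float = 1.0
    outlier_fraction: float = 0.1
    effect_bin: int | None = None
    effect_size_d: float = 0.0
    effect_hemisphere: str = "both"  # left | right | both
    effect_target: str = "group_a"  # group_a | crowding
    fa_baseline: float = 0.5
    fa_noise_sd: float = 0.05
    fa_spatial_noise_sd: float = 0.02
    crowding_prevalence: float = 0.5
    contralesional_side: str = "split"  # split | left | right
    voxel_mm: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_group_a < 2 or self.n_group_b < 2:
            raise ValueError("group counts must be >= 2")
        if not 0.0 <= self.outlier_fraction < 0.5:
            raise ValueError("outlier_fraction must be in [0, 0.5)")
        if self.effect_size_d < 0:
            raise ValueError("effect_size_d must be >= 0")
        if self.effect_bin is not None and not 1 <= self.effect_bin <= 7:
            raise ValueError("effect_bin must be in 1..7 or None")
        lo = self.fa_baseline - 4 * self.fa_noise_sd
        hi = self.fa_baseline + 4 * self.fa_noise_sd
        if not (0.0 < lo and hi < 1.0):
            raise ValueError("fa_baseline +/- 4*fa_noise_sd must stay within (0, 1)")
        if self.effect_hemisphere not in ("left", "right", "both"):
            raise ValueError("effect_hemisphere must be left/right/both")
        if self.effect_target not in ("group_a", "crowding"):
            raise ValueError("effect_target must be group_a/crowding")
        if not 0.0 <= self.crowding_prevalence <= 1.0:
            raise ValueError("crowding_prevalence must be in [0, 1]")
        if self.contralesional_side not in ("split", "left", "right"):
            raise ValueError("contralesional_side must be split/left/right")


class SyntheticCohort(NamedTuple):
    subjects: list[SubjectRecord]
    bundles: dict[tuple[str, str], Bundle]  # (subject_id, hemisphere) -> Bundle
    volumes: dict[str, ScalarVolume]  # subject_id -> FA volume (covers both arcs)


_ARC_POSTERIOR_SHARE = 0.65  # asymmetric span: the posterior limb dips lower


def _phi_range(spec: CohortSpec) -> tuple[float, float]:
    """(start, end) polar angles of the arc in the y-z plane, radians."""
    span = np.deg2rad(spec.arc_span_deg)
    start = np.pi / 2 + _ARC_POSTERIOR_SHARE * span
    return start, start - span


def arc_template(spec: CohortSpec, side: str) -> np.ndarray:
    """Ideal noiseless arc for one hemisphere, (n_vertices, 3) world mm.

    The arc lies in the plane x = +/-20 mm and follows a circle of radius
    ``arc_radius_mm`` in the y-z plane over ``arc_span_deg``, starting
    (vertex 0) at its posterior/inferior end, y < 0.  The span is
    deliberately asymmetric about the apex so that the curve is not
    congruent to its own reversal — otherwise rigid alignment could not
    distinguish the two ends.  The right arc is the exact mirror image
    (x -> -x) of the left.
    """
    start, end = _phi_range(spec)
    phi = np.linspace(start, end, spec.n_vertices)
    x = -_HEMI_X_OFFSET if side == "left" else _HEMI_X_OFFSET
    return np.column_stack(
        [
            np.full(spec.n_vertices, x),
            spec.arc_radius_mm * np.cos(phi),
            spec.arc_radius_mm * np.sin(phi),
        ]
    )


def arc_fraction_of_points(spec: CohortSpec, points: np.ndarray) -> np.ndarray:
    """Ideal arc-length fraction in [0, 1] of world points, by angle.

    Measured from the arc's posterior end (vertex 0 of the template);
    points outside the angular span get values < 0 or > 1.
    """
    pts = np.atleast_2d(points)
    start, _ = _phi_range(spec)
    span = np.deg2rad(spec.arc_span_deg)
    phi = np.arctan2(pts[:, 2], pts[:, 1])
    # map angles into (start - 2*pi, start] so the fraction is continuous
    # across the -y axis for arcs dipping below the horizontal
    phi = np.where(phi > start, phi - 2 * np.pi, phi)
    return (start - phi) / span


def make_arc_bundle(
    spec: CohortSpec,
    side: str,
    rng: np.random.Generator,
    subject_id: str = "",
    tract_name: str = "AF",
) -> Bundle:
    """Noisy copies of the hemisphere's template arc.

    Each streamline adds per-vertex Gaussian jitter with SD
    ``jitter_sd_mm``, smoothed along the streamline (correlation length a
    few vertices) so the curves stay rectifiable like real tractography
    output; an exact ``round(outlier_fraction * n)`` subset is additionally
    displaced as a whole by ``15 * jitter_sd_mm``, i.e. well beyond 10
    jitter SDs from the arc.
    """
    if side not in ("left", "right"):
        raise ValueError("side must be left/right")
    template = arc_template(spec, side)
    n = spec.streamlines_per_bundle
    pad = 16  # 4 smoothing SDs per side, keeps edge variance exact
    white = rng.normal(0.0, 1.0, size=(n, spec.n_vertices + 2 * pad, 3))
    noise = spec.jitter_sd_mm * _smooth_unit_noise(white)[:, pad:-pad]
    streamlines = template[None] + noise
    n_out = int(round(spec.outlier_fraction * n))
    if n_out:
        idx = rng.choice(n, size=n_out, replace=False)
        direction = rng.normal(size=(n_out, 3))
        direction /= np.linalg.norm(direction, axis=1, keepdims=True)
        shift = _OUTLIER_SHIFT_FACTOR * spec.jitter_sd_mm * direction
        streamlines[idx] += shift[:, None, :]
    return Bundle(
        streamlines=list(streamlines),
        subject_id=subject_id,
        hemisphere=side,
        tract_name=tract_name,
    )


def _smooth_unit_noise(white: np.ndarray, sigma_vertices: float = 4.0) -> np.ndarray:
    """Smooth white noise along the vertex axis, restoring unit variance.

    Callers pad the vertex axis so boundary handling does not distort the
    variance of the retained segment.
    """
    from scipy.ndimage import gaussian_filter1d

    smoothed = gaussian_filter1d(white, sigma=sigma_vertices, axis=1, mode="constant")
    impulse = np.zeros(white.shape[1])
    impulse[white.shape[1] // 2] = 1.0
    kernel = gaussian_filter1d(impulse, sigma=sigma_vertices, mode="constant")
    return smoothed / np.sqrt(np.sum(kernel**2))


def _fa_volume(
    spec: CohortSpec,
    base_value: float,
    effect_delta: float,
    effect_sides: tuple[str, ...],
    rng: np.random.Generator,
) -> ScalarVolume:
    """Subject FA volume covering both arcs on a regular grid.

    The tract-free background is the constant ``fa_baseline`` (the
    skeleton-mean normalizer), so dividing by it preserves the
    between-subject FA variance carried by the tract itself.  Voxels in a
    tube around either arc take the subject's tract level ``base_value``
    plus mild spatial texture; the effect, if any, is added in a
    world-space wedge: tube voxels whose ideal arc-length fraction falls in
    ((b-1)/7, b/7], on the requested side(s).
    """
    v = spec.voxel_mm
    r = spec.arc_radius_mm
    xs = np.arange(-(_HEMI_X_OFFSET + 12), _HEMI_X_OFFSET + 12 + v, v)
    ys = np.arange(-(r + 12), r + 12 + v, v)
    zs = np.arange(-12, r + 12 + v, v)
    grid = np.full((len(xs), len(ys), len(zs)), spec.fa_baseline)
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    frac = arc_fraction_of_points(
        spec, np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    ).reshape(grid.shape)
    radial = np.abs(np.sqrt(gy**2 + gz**2) - r)
    band = max(4.0 * spec.jitter_sd_mm, 6.0)
    on_side = (np.abs(gx - _HEMI_X_OFFSET) <= band) | (
        np.abs(gx + _HEMI_X_OFFSET) <= band
    )
    margin = 0.05
    tube = (radial <= band) & on_side & (frac >= -margin) & (frac <= 1.0 + margin)
    texture = rng.normal(0.0, spec.fa_spatial_noise_sd, size=grid.shape)
    grid = np.where(tube, base_value + texture, grid)
    if effect_delta != 0.0 and spec.effect_bin is not None:
        lo, hi = (spec.effect_bin - 1) / 7.0, spec.effect_bin / 7.0
        wedge = tube & (frac > lo) & (frac <= hi)
        side_ok = np.zeros_like(wedge)
        if "left" in effect_sides:
            side_ok |= np.abs(gx + _HEMI_X_OFFSET) <= band
        if "right" in effect_sides:
            side_ok |= np.abs(gx - _HEMI_X_OFFSET) <= band
        grid = grid + effect_delta * (wedge & side_ok)
    grid = np.clip(grid, *_FA_CLIP)
    affine = np.diag([v, v, v, 1.0])
    affine[:3, 3] = [xs[0], ys[0], zs[0]]
    return ScalarVolume(grid=grid, affine=affine, metric_name="FA")


def make_cohort(spec: CohortSpec, tract_name: str = "AF") -> SyntheticCohort:
    """Generate subjects, per-hemisphere bundles and FA volumes.

    Group a are "patient" records (with a contralesional hemisphere,
    etiology and surgery/onset ages), group b "control".  A
    ``crowding_prevalence`` fraction of group a gets VIQ - PIQ >= 10 exactly
    (rounded count).  Each subject's FA level along the tract tube is
    ``fa_baseline + N(0, fa_noise_sd)``; targeted subjects additionally get
    ``effect_size_d * fa_noise_sd`` added inside the effect wedge.  The
    skeleton-mean normalizer equals the volume's tract-free background
    (the constant ``fa_baseline``).
    """
    rng = np.random.default_rng(spec.seed)
    ids_a = [f"p{i + 1:02d}" for i in range(spec.n_group_a)]
    ids_b = [f"c{i + 1:02d}" for i in range(spec.n_group_b)]

    # contralesional hemisphere: balanced split among patients (shuffled),
    # or forced to one side
    if spec.contralesional_side == "split":
        n_right = spec.n_group_a // 2
        contra = np.array(["left"] * (spec.n_group_a - n_right) + ["right"] * n_right)
        rng.shuffle(contra)
    else:
        contra = np.array([spec.contralesional_side] * spec.n_group_a)

    n_crowd = int(round(spec.crowding_prevalence * spec.n_group_a))
    crowd_idx = set(rng.choice(spec.n_group_a, size=n_crowd, replace=False).tolist())

    effect_sides = {
        "both": ("left", "right"),
        "left": ("left",),
        "right": ("right",),
    }[spec.effect_hemisphere]

    subjects: list[SubjectRecord] = []
    bundles: dict[tuple[str, str], Bundle] = {}
    volumes: dict[str, ScalarVolume] = {}

    for k, sid in enumerate(ids_a + ids_b):
        is_patient = k < spec.n_group_a
        crowding = is_patient and k in crowd_idx
        if is_patient:
            viq = float(np.round(rng.normal(80.0, 10.0), 1))
            delta = rng.uniform(12.0, 30.0) if crowding else rng.uniform(-10.0, 8.0)
            piq = float(np.round(viq - delta, 1))
            etiology = "congenital" if crowding else ("congenital" if rng.random() < 0.6 else "acquired")
            age_scan = float(np.round(rng.uniform(12.0, 44.0), 1))
            age_surgery = float(np.round(rng.uniform(0.7, age_scan - 1.0), 1))
            age_onset = float(np.round(rng.uniform(0.0, min(age_surgery, 10.0)), 1))
        else:
            viq = float(np.round(rng.normal(100.0, 10.0), 1))
            piq = float(np.round(viq - rng.uniform(-8.0, 8.0), 1))
            etiology = "n/a"
            age_scan = float(np.round(rng.uniform(15.0, 54.0), 1))
            age_surgery = np.nan
            age_onset = np.nan

        base = float(np.clip(rng.normal(spec.fa_baseline, spec.fa_noise_sd), *_FA_CLIP))
        targeted = (
            is_patient if spec.effect_target == "group_a" else crowding
        ) and spec.effect_bin is not None
        delta_fa = spec.effect_size_d * spec.fa_noise_sd if targeted else 0.0
        volumes[sid] = _fa_volume(spec, base, delta_fa, effect_sides, rng)

        for side in ("left", "right"):
            bundles[(sid, side)] = make_arc_bundle(
                spec, side, rng, subject_id=sid, tract_name=tract_name
            )

        subjects.append(
            SubjectRecord(
                subject_id=sid,
                group="patient" if is_patient else "control",
                contralesional_hemisphere=contra[k] if is_patient else "n/a",
                etiology=etiology,
                viq=viq,
                piq=piq,
                age_at_scan=age_scan,
                age_at_surgery=age_surgery,
                age_at_onset=age_onset,
                skeleton_mean_fa=spec.fa_baseline,
            )
        )
    return SyntheticCohort(subjects=subjects, bundles=bundles, volumes=volumes)


def simulate_bin_profiles(
    n_group_a: int,
    n_group_b: int,
    rng: np.random.Generator,
    n_bins: int = 7,
    effect_bin: int | None = None,
    effect_size_d: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Bin-profile matrix drawn directly from the generator's statistical model.

    Unit-variance Gaussian noise per subject and bin; group a is shifted by
    ``effect_size_d`` (exactly Cohen's d in distribution) in ``effect_bin``.
    Returns ``(profiles, labels)`` with boolean labels marking group a.
    Used for permutation-calibration studies where the geometric pipeline
    would only add runtime, not statistical content.
    """
    s = n_group_a + n_group_b
    profiles = rng.standard_normal((s, n_bins))
    labels = np.zeros(s, dtype=bool)
    labels[:n_group_a] = True
    if effect_bin is not None and effect_size_d != 0.0:
        profiles[labels, effect_bin - 1] += effect_size_d
    return profiles, labels


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> Path:
    """Write a cohort to disk in the layout the pipeline reads.

    ``subjects.tsv`` plus ``bundles/sub-<id>_hemi-<side>_<tract>.tck`` and
    ``volumes/sub-<id>_FA.nii.gz``.
    """
    out = Path(out_dir)
    (out / "bundles").mkdir(parents=True, exist_ok=True)
    (out / "volumes").mkdir(parents=True, exist_ok=True)
    write_subjects(cohort.subjects, out / "subjects.tsv")
    for (sid, side), bundle in cohort.bundles.items():
        name = f"sub-{sid}_hemi-{side}_{bundle.tract_name or 'AF'}.tck"
        write_streamlines(bundle, out / "bundles" / name)
    for sid, vol in cohort.volumes.items():
        write_scalar_volume(vol, out / "volumes" / f"sub-{sid}_FA.nii.gz")
    return out


def null_spec(spec: CohortSpec) -> CohortSpec:
    """Copy of ``spec`` with the localized effect switched off."""
    return replace(spec, effect_bin=None, effect_size_d=0.0)
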