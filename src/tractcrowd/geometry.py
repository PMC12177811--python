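"""Streamline geometry: resampling, curvature, ROI dissection, mirroring,
medoid representatives and rigid ICP alignment."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy.spatial import cKDTree

from tractcrowd.errors import ConfigError, GeometryError
from tractcrowd.io_formats import Bundle, Streamline, as_streamline

_ROI_ROLES = ("endpoint_sphere", "waypoint", "exclusion")


@dataclass
class ROISpec:
    """A spherical region of interest in world mm."""

    center: np.ndarray
    diameter: float
    role: str = "waypoint"
    label: str = ""

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=np.float64).reshape(3)
        if self.diameter <= 0:
            raise ValueError("ROI diameter must be positive")
        if self.role not in _ROI_ROLES:
            raise ValueError(f"ROI role must be one of {_ROI_ROLES}, got {self.role!r}")

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Strict-inequality membership test for (V, 3) points."""
        d = np.linalg.norm(np.atleast_2d(points) - self.center, axis=1)
        return d < self.diameter / 2.0


@dataclass
class RigidTransform:
    """Proper rigid transform x -> R x + t.

    ICP attaches fit diagnostics (``rmsd``, ``n_iter``, ``converged``).
    """

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rmsd: float | None = None
    n_iter: int | None = None
    converged: bool | None = None

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation must be proper (det = +1)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=np.float64) @ self.rotation.T + self.translation

    def apply_bundle(self, bundle: Bundle) -> Bundle:
        return bundle.with_streamlines(self.apply(s) for s in bundle)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(
            rotation=self.rotation.T, translation=-self.rotation.T @ self.translation
        )


@dataclass
class CurvatureProfile:
    """Per-vertex curvature (1/mm) of a uniformly resampled streamline."""

    kappa: np.ndarray
    delta_s: float

    def __post_init__(self) -> None:
        self.kappa = np.asarray(self.kappa, dtype=np.float64)
        if self.kappa.ndim != 1 or len(self.kappa) < 3:
            raise ValueError("kappa must be 1-D with length >= 3")
        if self.kappa[0] != 0.0 or self.kappa[-1] != 0.0:
            raise ValueError("endpoint curvature must be zero")
        if not np.all(np.isfinite(self.kappa)) or np.any(self.kappa < 0):
            raise ValueError("curvature must be finite and non-negative")


def arc_lengths(points: np.ndarray) -> np.ndarray:
    """Cumulative arc length (piecewise linear), starting at 0."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_streamline(s: Streamline, n: int = 50) -> Streamline:
    """Resample to ``n`` vertices at equal arc-length spacing.

    Endpoints are preserved exactly; interior vertices are linear
    interpolations on the original polyline.
    """
    pts = as_streamline(s)
    if n < 2:
        raise ValueError("need at least 2 output vertices")
    cum = arc_lengths(pts)
    total = cum[-1]
    if total <= 0:
        raise GeometryError("cannot resample zero-length streamline")
    target = np.linspace(0.0, total, n)
    out = np.column_stack([np.interp(target, cum, pts[:, k]) for k in range(3)])
    out[0], out[-1] = pts[0], pts[-1]
    return out


def curvature_profile(s: Streamline, spacing_rtol: float = 0.1) -> CurvatureProfile:
    """Discrete curvature via the second central difference in arc length.

    kappa_i = ||x_{i+1} - 2 x_i + x_{i-1}|| / ds^2 for interior vertices,
    with ds = total length / (V - 1); endpoint values are undefined and set
    to zero.  Requires uniform vertex spacing (relative tolerance
    ``spacing_rtol``), i.e. the output of :func:`resample_streamline`.
    """
    pts = as_streamline(s)
    if len(pts) < 3:
        raise GeometryError("curvature needs at least 3 vertices")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = seg.sum()
    ds = total / (len(pts) - 1)
    if ds <= 0:
        raise GeometryError("zero-length streamline")
    if np.any(np.abs(seg - ds) > spacing_rtol * ds):
        raise GeometryError("streamline spacing is not uniform; resample first")
    second = pts[2:] - 2.0 * pts[1:-1] + pts[:-2]
    kappa = np.zeros(len(pts))
    kappa[1:-1] = np.linalg.norm(second, axis=1) / ds**2
    return CurvatureProfile(kappa=kappa, delta_s=ds)


def filter_by_rois(bundle: Bundle, rois: Sequence[ROISpec]) -> Bundle:
    """Dissect a bundle with endpoint-sphere / waypoint / exclusion rules.

    A streamline is retained iff its two terminal vertices lie one in each
    endpoint sphere (either orientation), every waypoint ROI is traversed by
    at least one vertex, and no vertex enters any exclusion ROI.  "Inside"
    is strict Euclidean distance < diameter/2; "termination" refers to the
    first and last vertex only, so the test is symmetric in point order.
    """
    endpoints = [r for r in rois if r.role == "endpoint_sphere"]
    waypoints = [r for r in rois if r.role == "waypoint"]
    exclusions = [r for r in rois if r.role == "exclusion"]
    if endpoints and len(endpoints) != 2:
        raise ConfigError(
            f"endpoint filtering needs exactly 2 endpoint spheres, got {len(endpoints)}"
        )

    kept = []
    for s in bundle:
        if endpoints:
            a, b = endpoints
            first, last = s[0], s[-1]
            ok = (a.contains(first)[0] and b.contains(last)[0]) or (
                b.contains(first)[0] and a.contains(last)[0]
            )
            if not ok:
                continue
        if any(not w.contains(s).any() for w in waypoints):
            continue
        if any(x.contains(s).any() for x in exclusions):
            continue
        kept.append(s)
    return bundle.with_streamlines(kept)


def mirror_bundle(b: Bundle) -> Bundle:
    """Reflect across the midsagittal plane (x -> -x) and flip the label."""
    flipped = "right" if b.hemisphere == "left" else "left"
    mirrored = [s * np.array([-1.0, 1.0, 1.0]) for s in b]
    return Bundle(
        streamlines=mirrored,
        subject_id=b.subject_id,
        hemisphere=flipped,
        tract_name=b.tract_name,
    )


def harmonize_orientations(bundle: Bundle) -> Bundle:
    """Flip streamlines whose vertex order disagrees with the bundle majority.

    Uses the first streamline as provisional reference, then a second pass
    against the majority-oriented mean curve.  Requires a common vertex count.
    """
    arrs = _common_vertex_stack(bundle)
    ref = arrs[0]
    flipped = _flip_to_reference(arrs, ref)
    mean_curve = flipped.mean(axis=0)
    flipped = _flip_to_reference(arrs, mean_curve)
    return bundle.with_streamlines(list(flipped))


def _flip_to_reference(arrs: np.ndarray, ref: np.ndarray) -> np.ndarray:
    d_fwd = np.mean(np.linalg.norm(arrs - ref, axis=2), axis=1)
    d_rev = np.mean(np.linalg.norm(arrs[:, ::-1] - ref, axis=2), axis=1)
    out = arrs.copy()
    out[d_rev < d_fwd] = arrs[d_rev < d_fwd, ::-1]
    return out


def _common_vertex_stack(bundle: Bundle) -> np.ndarray:
    if len(bundle) == 0:
        raise GeometryError("empty bundle")
    counts = {len(s) for s in bundle}
    if len(counts) != 1:
        raise GeometryError("streamlines must share a vertex count; resample first")
    return np.stack(bundle.streamlines)


def representative_streamline(b: Bundle) -> Streamline:
    """Medoid streamline: minimizes summed mean point-to-point distance.

    Orientations are harmonized first so distances are meaningful.  The
    returned curve is an actual bundle member (in harmonized orientation),
    which keeps the representative anatomically realized.
    """
    harmonized = harmonize_orientations(b)
    arrs = np.stack(harmonized.streamlines)
    diffs = np.linalg.norm(arrs[:, None] - arrs[None, :], axis=3)  # (n, n, V)
    mean_dist = diffs.mean(axis=2)
    return arrs[int(np.argmin(mean_dist.sum(axis=1)))].copy()


def _kabsch(moving: np.ndarray, fixed: np.ndarray) -> RigidTransform:
    """Least-squares proper rigid fit mapping moving onto fixed."""
    mu_m, mu_f = moving.mean(axis=0), fixed.mean(axis=0)
    h = (moving - mu_m).T @ (fixed - mu_f)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return RigidTransform(rotation=rot, translation=mu_f - rot @ mu_m)


def icp_align(
    moving: Streamline,
    fixed: Streamline,
    max_iter: int = 200,
    tol: float = 1e-6,
    orientation: str = "free",
) -> RigidTransform:
    """Iterative closest point rigid registration of two point sequences.

    Alternates nearest-vertex correspondence with a least-squares proper
    rigid fit until the RMSD improvement drops below ``tol`` mm or
    ``max_iter`` is reached.  RMSD is non-increasing across iterations.
    Because a curve's tangential self-similarity makes pure nearest-vertex
    ICP slide along the curve, the iteration is started from the identity
    and from index-correspondence fits and the best-RMSD result is kept.

    ``orientation="free"`` also tries the reversed-vertex-order fit, which
    is appropriate when the two curves' directions are unrelated; use
    ``"fixed"`` when both follow a shared start-to-end convention — a
    near-reversal-symmetric curve (e.g. a circular arc) is otherwise
    aligned back-to-front half the time.  On non-convergence the best
    transform found is returned with ``converged=False`` and a warning.
    """
    if orientation not in ("free", "fixed"):
        raise ValueError("orientation must be free/fixed")
    mov = as_streamline(moving)
    fix = as_streamline(fixed)
    tree = cKDTree(fix)

    inits = [RigidTransform()]
    if len(mov) == len(fix):
        inits.append(_kabsch(mov, fix))
        if orientation == "free":
            inits.append(_kabsch(mov, fix[::-1]))

    best = RigidTransform()
    best_rmsd = np.inf
    best_iters = 0
    any_converged = False
    for init in inits:
        current = init
        pts = current.apply(mov)
        prev_rmsd = np.inf
        converged = False
        it = 0
        run_best, run_best_rmsd = current, np.inf
        for it in range(1, max_iter + 1):
            _, idx = tree.query(pts)
            step = _kabsch(pts, fix[idx])
            current = step.compose(current)
            pts = current.apply(mov)
            _, idx = tree.query(pts)
            rmsd = float(np.sqrt(np.mean(np.sum((pts - fix[idx]) ** 2, axis=1))))
            if rmsd < run_best_rmsd:
                run_best_rmsd, run_best = rmsd, current
            if prev_rmsd - rmsd < tol:
                converged = True
                break
            prev_rmsd = rmsd
        any_converged |= converged
        if run_best_rmsd < best_rmsd:
            best_rmsd, best, best_iters = run_best_rmsd, run_best, it
    if not any_converged:
        warnings.warn("ICP did not converge; returning best transform so far", stacklevel=2)
    return RigidTransform(
        rotation=best.rotation,
        translation=best.translation,
        rmsd=best_rmsd,
        n_iter=best_iters,
        converged=any_converged,
    )


def load_roi_presets(name_or_path: str | Path) -> dict[str, list[ROISpec]]:
    """Load ROI sets from YAML, keyed by hemisphere.

    ``name_or_path`` is either a path or the name of a shipped preset
    (``"af"``, ``"ilf"``).  The YAML layout is::

        left:
          - {center: [-60, -45, 0], diameter: 20, role: endpoint_sphere, label: temporal}
        right:
          - ...
    """
    path = Path(name_or_path)
    if not path.exists():
        path = Path(__file__).parent / "data" / f"{name_or_path}_rois.yaml"
    if not path.exists():
        raise ConfigError(f"no ROI preset or file named {name_or_path!r}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    out: dict[str, list[ROISpec]] = {}
    for hemi, entries in raw.items():
        out[hemi] = [
            ROISpec(
                center=e["center"],
                diameter=float(e["diameter"]),
                role=e.get("role", "waypoint"),
                label=e.get("label", ""),
            )
            for e in entries
        ]
    return out
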