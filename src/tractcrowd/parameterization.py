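"""Joint 1-D bundle parameterization and binned scalar profiles.

Outlier streamlines are removed with a one-class SVM (RBF kernel, default
nu = 0.1).  The pooled vertex cloud of all subjects and hemispheres (right
bundles mirrored and ICP-aligned beforehand) is embedded into one dimension
with ISOMAP, affinely rescaled to [0, 1], restricted to the well-supported
core, and cut into 7 equal-width bins.  Per-subject per-bin scalar means
form the rows of the profile matrices that the statistics stage compares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.sparse.csgraph import connected_components
from sklearn.manifold import Isomap
from sklearn.neighbors import kneighbors_graph
from sklearn.svm import OneClassSVM

from tractcrowd.errors import CoreExtractionError, GeometryError
from tractcrowd.io_formats import Bundle, ScalarVolume, sample_scalar_at_points


@dataclass(frozen=True)
class OutlierFilterParams:
    """One-class-SVM settings; kernel width follows the median heuristic."""

    nu: float = 0.1
    max_width_sample: int = 500

    def __post_init__(self) -> None:
        if not 0.0 < self.nu < 1.0:
            raise ValueError("nu must be in (0, 1)")


@dataclass
class JointParameterization:
    """Shared [0, 1] coordinate for every vertex of every bundle.

    ``coords[i]`` is an (n_streamlines, V) array aligned with ``keys[i]``
    (subject_id, hemisphere).  ``core`` is the retained t-interval on the
    raw scale; bin edges live on the core re-normalized to [0, 1].
    """

    keys: list[tuple[str, str]]
    coords: list[np.ndarray]
    core: tuple[float, float] = (0.0, 1.0)
    n_bins: int = 7
    knn: int = 10

    @property
    def bin_edges(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.n_bins + 1)

    def core_coords(self, index: int) -> np.ndarray:
        """Core-normalized t for one bundle; values outside [0, 1] are off-core."""
        lo, hi = self.core
        return (self.coords[index] - lo) / (hi - lo)

    def index_of(self, subject_id: str, hemisphere: str) -> int:
        return self.keys.index((subject_id, hemisphere))

    def bin_of(self, t_core: np.ndarray) -> np.ndarray:
        """Bin labels 1..n_bins for core-normalized t; 0 marks off-core.

        Bins are half-open [(k-1)/n, k/n) with the last bin closed at 1.
        """
        t = np.asarray(t_core)
        labels = np.floor(t * self.n_bins).astype(int) + 1
        labels[np.asarray(t) == 1.0] = self.n_bins
        labels[(t < 0.0) | (t > 1.0)] = 0
        return labels


def remove_outliers(
    b: Bundle,
    params: OutlierFilterParams = OutlierFilterParams(),
    seed: int = 0,
) -> tuple[Bundle, Bundle]:
    """Split a bundle into (kept, removed) with a one-class SVM.

    Streamlines must share a vertex count; features are the flattened
    vertex coordinates.  The RBF width uses the median pairwise squared
    distance of a (seeded) subsample.  About a ``nu`` fraction ends up with
    a negative decision value and is removed.  Bundles of fewer than 10
    streamlines are returned unfiltered with a warning.
    """
    if len({len(s) for s in b}) > 1:
        raise GeometryError("streamlines must share a vertex count; resample first")
    n = len(b)
    if n < 10:
        warnings.warn("fewer than 10 streamlines; skipping outlier removal", stacklevel=2)
        return b, b.with_streamlines([])
    x = np.stack(b.streamlines).reshape(n, -1)
    rng = np.random.default_rng(seed)
    sub = x[rng.choice(n, size=min(n, params.max_width_sample), replace=False)]
    d2 = np.sum((sub[:, None] - sub[None, :]) ** 2, axis=2)
    med = np.median(d2[np.triu_indices(len(sub), k=1)])
    gamma = 1.0 / med if med > 0 else "scale"
    svm = OneClassSVM(kernel="rbf", nu=params.nu, gamma=gamma)
    svm.fit(x)
    decision = svm.decision_function(x)
    # margin points sit at decision 0 up to solver noise; keep them
    keep = decision >= -1e-8 * max(1.0, np.abs(decision).max())
    kept = b.with_streamlines([s for s, k in zip(b.streamlines, keep) if k])
    removed = b.with_streamlines([s for s, k in zip(b.streamlines, keep) if not k])
    return kept, removed


def joint_parameterize(
    bundles: Sequence[Bundle],
    knn: int = 10,
    max_points: int = 20000,
    anchor: np.ndarray | None = None,
    seed: int = 0,
) -> JointParameterization:
    """1-D ISOMAP embedding of the pooled vertex cloud of all bundles.

    A k-NN geodesic graph plus classical MDS yields one coordinate per
    vertex; it is affinely rescaled so min = 0 and max = 1 over all
    vertices.  If the pooled cloud exceeds ``max_points`` vertices a seeded
    subsample serves as landmarks and the remainder is projected with the
    ISOMAP out-of-sample extension.  A disconnected graph doubles ``knn``
    up to 4 times before erroring.

    The coordinate's sign is anchored: if ``anchor`` (world mm, e.g. the
    temporal endpoint-sphere center) is given, t = 0 lies at the anchor end;
    otherwise t increases along the majority vertex order of the
    streamlines.
    """
    if not bundles:
        raise ValueError("no bundles given")
    arrays = [np.stack(b.streamlines) for b in bundles]
    flat = np.concatenate([a.reshape(-1, 3) for a in arrays])
    n_total = len(flat)

    rng = np.random.default_rng(seed)
    if n_total > max_points:
        landmark_idx = np.sort(rng.choice(n_total, size=max_points, replace=False))
    else:
        landmark_idx = np.arange(n_total)
    landmarks = flat[landmark_idx]

    k = knn
    last_exc: Exception | None = None
    embedding = None
    model = None
    for _ in range(4):
        graph = kneighbors_graph(landmarks, n_neighbors=min(k, len(landmarks) - 1))
        n_comp, _ = connected_components(graph, directed=False)
        if n_comp > 1:
            k *= 2
            continue
        try:
            model = Isomap(n_neighbors=min(k, len(landmarks) - 1), n_components=1)
            embedding = model.fit_transform(landmarks)[:, 0]
            break
        except Exception as exc:  # pragma: no cover - sklearn internal failures
            last_exc = exc
            k *= 2
    if embedding is None or model is None:
        raise GeometryError(f"ISOMAP graph stayed disconnected up to k={k}") from last_exc

    t = np.empty(n_total)
    t[landmark_idx] = embedding
    rest = np.setdiff1d(np.arange(n_total), landmark_idx, assume_unique=True)
    if len(rest):
        for start in range(0, len(rest), 50000):
            chunk = rest[start : start + 50000]
            t[chunk] = model.transform(flat[chunk])[:, 0]

    t = (t - t.min()) / (t.max() - t.min())

    # split back into per-bundle (n_streamlines, V) blocks
    coords: list[np.ndarray] = []
    offset = 0
    for a in arrays:
        size = a.shape[0] * a.shape[1]
        coords.append(t[offset : offset + size].reshape(a.shape[0], a.shape[1]))
        offset += size

    if anchor is not None:
        anchor = np.asarray(anchor, dtype=np.float64).reshape(3)
        d = np.linalg.norm(flat - anchor, axis=1)
        near = t[d <= np.quantile(d, 0.05)]
        flip = near.mean() > 0.5
    else:
        starts = np.concatenate([c[:, 0] for c in coords])
        ends = np.concatenate([c[:, -1] for c in coords])
        flip = starts.mean() > ends.mean()
    if flip:
        coords = [1.0 - c for c in coords]

    return JointParameterization(
        keys=[(b.subject_id, b.hemisphere) for b in bundles],
        coords=coords,
        knn=k,
    )


def extract_core(
    jp: JointParameterization,
    bundles: Sequence[Bundle],
    min_subject_coverage: float = 0.8,
    min_vertex_density: float = 5.0,
    cell_width: float = 0.01,
    min_core_length: float = 0.3,
) -> JointParameterization:
    """Restrict the parameterization to its well-supported core interval.

    The core is the largest contiguous run of ``cell_width``-wide t-cells in
    which (a) at least ``min_subject_coverage`` of subjects cover the cell
    (a subject covers a cell when its t-range spans the cell midpoint) and
    (b) the vertex count per covering subject, estimated with a small
    moving window so that the finite vertex spacing along streamlines does
    not punch spurious holes, is at least ``min_vertex_density``.  Bins are
    subsequently defined on the core re-normalized to [0, 1].
    """
    from scipy.ndimage import uniform_filter1d

    subjects = sorted({sid for sid, _ in jp.keys})
    n_cells = int(round(1.0 / cell_width))
    counts = np.zeros((len(subjects), n_cells), dtype=np.int64)
    t_min = np.full(len(subjects), np.inf)
    t_max = np.full(len(subjects), -np.inf)
    sub_index = {s: i for i, s in enumerate(subjects)}
    for (sid, _), coords in zip(jp.keys, jp.coords):
        i = sub_index[sid]
        flat = coords.ravel()
        cells = np.clip((flat / cell_width).astype(int), 0, n_cells - 1)
        counts[i] += np.bincount(cells, minlength=n_cells)
        t_min[i] = min(t_min[i], flat.min())
        t_max[i] = max(t_max[i], flat.max())
    midpoints = (np.arange(n_cells) + 0.5) * cell_width
    covered = (t_min[:, None] <= midpoints[None, :]) & (midpoints[None, :] <= t_max[:, None])
    coverage = covered.mean(axis=0)
    n_cov = np.maximum(covered.sum(axis=0), 1)
    window = 2 * max(1, n_cells // max(jp.coords[0].shape[1], 1)) + 3
    smoothed_counts = uniform_filter1d(
        counts.sum(axis=0).astype(np.float64), size=window, mode="nearest"
    )
    density = smoothed_counts / n_cov
    good = (coverage >= min_subject_coverage) & (density >= min_vertex_density)
    lo_cell, hi_cell = _longest_true_run(good)
    if lo_cell is None:
        raise CoreExtractionError("no t-cell satisfies the coverage/density thresholds")
    lo, hi = lo_cell * cell_width, (hi_cell + 1) * cell_width
    lo, hi = max(0.0, lo), min(1.0, hi)
    if hi - lo < min_core_length:
        raise CoreExtractionError(
            f"core [{lo:.2f}, {hi:.2f}] shorter than {min_core_length}; bundle too inconsistent"
        )
    return replace(jp, core=(lo, hi))


def _longest_true_run(mask: np.ndarray) -> tuple[int | None, int | None]:
    best_len, best = 0, (None, None)
    start = None
    for i, v in enumerate(np.append(mask, False)):
        if v and start is None:
            start = i
        elif not v and start is not None:
            if i - start > best_len:
                best_len, best = i - start, (start, i - 1)
            start = None
    return best


@dataclass
class ProfileRow:
    """Per-bin scalar means for one subject/hemisphere/metric."""

    bin_means: np.ndarray  # length n_bins, NaN where a bin is empty
    bin_counts: np.ndarray
    whole_tract_mean: float
    metric_name: str = ""


def bin_vertex_values(
    jp: JointParameterization,
    bundle_index: int,
    values: np.ndarray,
) -> ProfileRow:
    """Aggregate per-vertex ``values`` (n_streamlines, V) into bin means.

    Vertices outside the core and NaN samples are excluded; an empty bin
    yields NaN (dropped pairwise downstream).
    """
    t_core = jp.core_coords(bundle_index).ravel()
    vals = np.asarray(values, dtype=np.float64).ravel()
    if vals.shape != t_core.shape:
        raise ValueError("values shape does not match the parameterized bundle")
    labels = jp.bin_of(t_core)
    ok = (labels > 0) & np.isfinite(vals)
    means = np.full(jp.n_bins, np.nan)
    counts = np.zeros(jp.n_bins, dtype=np.int64)
    for k in range(1, jp.n_bins + 1):
        sel = ok & (labels == k)
        counts[k - 1] = sel.sum()
        if counts[k - 1]:
            means[k - 1] = vals[sel].mean()
    whole = vals[ok].mean() if ok.any() else np.nan
    return ProfileRow(bin_means=means, bin_counts=counts, whole_tract_mean=float(whole))


def bin_scalar_profile(
    jp: JointParameterization,
    bundle: Bundle,
    volume: ScalarVolume,
    bundle_index: int | None = None,
) -> ProfileRow:
    """Sample ``volume`` at the bundle's vertices and aggregate into bins."""
    if bundle_index is None:
        bundle_index = jp.index_of(bundle.subject_id, bundle.hemisphere)
    stacked = np.stack(bundle.streamlines)
    samples = sample_scalar_at_points(volume, stacked.reshape(-1, 3)).reshape(
        stacked.shape[0], stacked.shape[1]
    )
    row = bin_vertex_values(jp, bundle_index, samples)
    row.metric_name = volume.metric_name
    return row


def normalize_profile(row: ProfileRow, skeleton_mean: float) -> ProfileRow:
    """Divide bin means and the whole-tract mean by the skeleton mean."""
    if not np.isfinite(skeleton_mean) or skeleton_mean <= 0:
        raise ValueError(f"skeleton mean must be positive, got {skeleton_mean}")
    return ProfileRow(
        bin_means=row.bin_means / skeleton_mean,
        bin_counts=row.bin_counts.copy(),
        whole_tract_mean=row.whole_tract_mean / skeleton_mean,
        metric_name=row.metric_name,
    )
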