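"""CAP discovery: seed-frame selection, pooling, k-means and elbow selection.

Frames where the seed component is most active (top 20%/30% per
subject) are pooled across subjects, restricted to non-noise
components, and clustered with k-means under Pearson correlation
distance (1 - r; Euclidean selectable). The number of states is chosen
by scanning k and locating the elbow of the cluster validity index,
the ratio of mean within-cluster distance to mean between-centroid
distance.

k-means is implemented here (Lloyd iterations with k-means++ seeding
and multiple restarts) because the correlation metric is not available
in standard Euclidean-only implementations; centroids are plain means
of member frames, assignments use the configured distance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .cohort import ComponentTimeSeries

logger = logging.getLogger(__name__)

METRICS = ("correlation", "euclidean")


class ClusteringError(ValueError):
    pass


def round_half_away_from_zero(x: float) -> int:
    """5.5 -> 6, 46.5 -> 47 (numpy's bankers rounding would give 46)."""
    return int(np.sign(x) * np.floor(np.abs(x) + 0.5))


# ---------------------------------------------------------------------------
# frame selection & pooling


@dataclass(frozen=True)
class SelectedFrames:
    """Indices of one subject's supra-threshold seed frames."""

    subject_id: str
    fraction: float
    indices: np.ndarray  # sorted ascending, 0-based
    seed_values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "indices", np.asarray(self.indices, dtype=np.int64))
        object.__setattr__(self, "seed_values", np.asarray(self.seed_values, float))


def select_top_frames(
    seed_series: np.ndarray, fraction: float, subject_id: str = ""
) -> SelectedFrames:
    """Select the top ``fraction`` of frames by signed seed activation.

    The selected count is ``round_half_away_from_zero(fraction * T)``
    (155 frames -> 31 at 20%, 47 at 30%). Frames are ranked by seed
    value descending, ties broken toward the earlier frame; the returned
    indices are sorted ascending.
    """
    values = np.asarray(seed_series, dtype=float)
    if values.ndim != 1:
        raise ClusteringError("seed series must be 1-D")
    if not (0 < fraction <= 1):
        raise ClusteringError(f"fraction must lie in (0, 1], got {fraction}")
    t = values.size
    m = round_half_away_from_zero(fraction * t)
    if m < 1:
        raise ClusteringError(
            f"fraction {fraction} selects no frames from {t}-frame series"
        )
    order = np.argsort(-values, kind="stable")  # stable => earlier frame wins ties
    idx = np.sort(order[:m])
    return SelectedFrames(
        subject_id=subject_id, fraction=fraction, indices=idx, seed_values=values[idx]
    )


@dataclass(frozen=True)
class PooledFrames:
    """All subjects' selected frames stacked subject-major, non-noise columns only."""

    data: np.ndarray  # (N, C')
    subject_index: tuple[str, ...]  # per-row subject id
    frame_index: np.ndarray  # per-row frame position in the subject's series
    component_ids: tuple[str, ...]
    network_labels: tuple[str, ...]

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]


def pool_frames(
    subjects: Sequence[ComponentTimeSeries],
    selected: Sequence[SelectedFrames],
) -> PooledFrames:
    """Stack selected frames across subjects, dropping noise components."""
    if len(subjects) != len(selected):
        raise ClusteringError("one SelectedFrames per subject required")
    ref = subjects[0]
    keep = ~ref.noise_flags
    comp_ids = tuple(np.array(ref.component_ids)[keep])
    networks = tuple(np.array(ref.network_labels)[keep])
    rows, sub_idx, frame_idx = [], [], []
    for ts, sel in zip(subjects, selected):
        if ts.component_ids != ref.component_ids or not np.array_equal(
            ts.noise_flags, ref.noise_flags
        ):
            raise ClusteringError(
                f"{ts.subject_id}: component set differs from {ref.subject_id}"
            )
        if sel.subject_id and sel.subject_id != ts.subject_id:
            raise ClusteringError(
                f"selection for {sel.subject_id} paired with subject {ts.subject_id}"
            )
        rows.append(ts.data[sel.indices][:, keep])
        sub_idx.extend([ts.subject_id] * sel.indices.size)
        frame_idx.extend(sel.indices.tolist())
    return PooledFrames(
        data=np.vstack(rows),
        subject_index=tuple(sub_idx),
        frame_index=np.asarray(frame_idx, dtype=np.int64),
        component_ids=comp_ids,
        network_labels=networks,
    )


# ---------------------------------------------------------------------------
# k-means under correlation / euclidean distance


def _row_standardize(x: np.ndarray) -> np.ndarray:
    """Center each row and scale to unit norm; zero-variance rows map to 0."""
    z = x - x.mean(axis=1, keepdims=True)
    nrm = np.linalg.norm(z, axis=1, keepdims=True)
    return np.divide(z, nrm, out=np.zeros_like(z), where=nrm > 0)


def _distances(x: np.ndarray, centroids: np.ndarray, metric: str,
               x_std: np.ndarray | None = None) -> np.ndarray:
    """(N, k) distances: 1 - Pearson r, or squared Euclidean."""
    if metric == "correlation":
        xs = _row_standardize(x) if x_std is None else x_std
        return 1.0 - xs @ _row_standardize(centroids).T
    return cdist(x, centroids, "sqeuclidean")


def _kmeanspp_init(x: np.ndarray, k: int, metric: str, rng: np.random.Generator,
                   x_std: np.ndarray | None) -> np.ndarray:
    n = x.shape[0]
    centers = [int(rng.integers(n))]
    d = _distances(x, x[centers], metric, x_std)[:, 0]
    for _ in range(1, k):
        d = np.maximum(d, 0)
        tot = d.sum()
        if tot <= 0:
            centers.append(int(rng.integers(n)))
        else:
            centers.append(int(rng.choice(n, p=d / tot)))
        d = np.minimum(d, _distances(x, x[[centers[-1]]], metric, x_std)[:, 0])
    return x[centers].copy()


@dataclass(frozen=True)
class CapSolution:
    """One k-means solution over pooled frames."""

    k: int
    centroids: np.ndarray  # (k, C')
    labels: np.ndarray  # (N,)
    objective: float  # total within-cluster distance
    metric: str
    n_init: int
    rng_seed: int


def kmeans_cluster(
    pooled: PooledFrames | np.ndarray,
    k: int,
    metric: str = "correlation",
    n_init: int = 100,
    max_iter: int = 500,
    rng_seed: int = 0,
) -> CapSolution:
    """Best-of-``n_init`` Lloyd k-means under the configured distance.

    Centroids are means of member frames; empty clusters are repaired by
    reseeding to the frame farthest from its current centroid. The
    objective is the summed distance of frames to their own centroid
    (1 - r for the correlation metric, squared Euclidean otherwise).

    Under the correlation metric, frames are row-standardized (zero
    mean, unit norm) before clustering and centroids are means of the
    standardized frames, so assignments are invariant to adding a
    constant to, or positively rescaling, any individual frame.
    """
    x = pooled.data if isinstance(pooled, PooledFrames) else np.asarray(pooled, float)
    if metric == "correlation":
        x = _row_standardize(x)
    n = x.shape[0]
    if k < 2:
        raise ClusteringError("k must be >= 2")
    if n < k:
        raise ClusteringError(f"cannot form {k} clusters from {n} frames")
    if metric not in METRICS:
        raise ClusteringError(f"metric must be one of {METRICS}")
    x_std = _row_standardize(x) if metric == "correlation" else None
    rng = np.random.default_rng(rng_seed)

    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for _ in range(n_init):
        centroids = _kmeanspp_init(x, k, metric, rng, x_std)
        labels = np.full(n, -1, dtype=np.int64)
        for _ in range(max_iter):
            d = _distances(x, centroids, metric, x_std)
            new_labels = d.argmin(axis=1)
            # repair empty clusters with the worst-fit frame
            for j in np.setdiff1d(np.arange(k), new_labels):
                far = int(d[np.arange(n), new_labels].argmax())
                new_labels[far] = j
                d[far, :] = np.inf
                d[far, j] = 0.0
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
            centroids = np.vstack([x[labels == j].mean(axis=0) for j in range(k)])
        obj = float(
            _distances(x, centroids, metric, x_std)[np.arange(n), labels].sum()
        )
        if best is None or obj < best[0]:
            best = (obj, labels.copy(), centroids.copy())

    obj, labels, centroids = best
    return CapSolution(
        k=k, centroids=centroids, labels=labels, objective=obj,
        metric=metric, n_init=n_init, rng_seed=rng_seed,
    )


# ---------------------------------------------------------------------------
# cluster validity & elbow


def compute_cvi(pooled: PooledFrames | np.ndarray, solution: CapSolution) -> float:
    """Mean within-cluster distance over mean between-centroid distance.

    Distances follow the solution's metric: 1 - r for correlation,
    plain Euclidean for the euclidean metric.
    """
    x = pooled.data if isinstance(pooled, PooledFrames) else np.asarray(pooled, float)
    if solution.k < 2:
        raise ClusteringError("CVI undefined for k < 2")
    if solution.metric == "correlation":
        within = _distances(x, solution.centroids, "correlation")[
            np.arange(x.shape[0]), solution.labels
        ]
        cd = 1.0 - _row_standardize(solution.centroids) @ _row_standardize(
            solution.centroids
        ).T
    else:
        within = np.linalg.norm(x - solution.centroids[solution.labels], axis=1)
        cd = cdist(solution.centroids, solution.centroids, "euclidean")
    iu = np.triu_indices(solution.k, 1)
    between = float(cd[iu].mean())
    if between == 0:
        raise ClusteringError("coincident centroids: between-cluster distance is 0")
    return float(within.mean()) / between


@dataclass(frozen=True)
class CviCurve:
    k_values: tuple[int, ...]
    cvi: tuple[float, ...]
    elbow_k: int
    method: str
    solutions: dict[int, CapSolution] = field(default_factory=dict, repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.k_values, "cvi": self.cvi})


def find_elbow(
    k_values: Sequence[int], cvi: Sequence[float], method: str = "chord"
) -> int:
    """Locate the elbow of a validity curve.

    ``chord``: the k whose (normalized) point lies farthest below the
    straight line joining the curve's endpoints. ``line``: the k with
    the most negative residual under a single least-squares line fit to
    the whole curve. A curve with no downward curvature is degenerate;
    a warning is emitted and the smallest k returned.
    """
    k_arr = np.asarray(k_values, dtype=float)
    c_arr = np.asarray(cvi, dtype=float)
    if k_arr.size != c_arr.size or k_arr.size < 3:
        raise ClusteringError("need >= 3 (k, cvi) points to locate an elbow")
    kn = (k_arr - k_arr[0]) / (k_arr[-1] - k_arr[0])
    span = c_arr.max() - c_arr.min()
    cn = (c_arr - c_arr.min()) / span if span > 0 else np.zeros_like(c_arr)
    if method == "chord":
        chord = cn[0] + (cn[-1] - cn[0]) * kn
        drop = chord - cn  # positive where the curve dips below the chord
    elif method == "line":
        coef = np.polyfit(kn, cn, 1)
        drop = np.polyval(coef, kn) - cn
    else:
        raise ClusteringError("elbow method must be 'chord' or 'line'")
    if drop.max() <= 1e-12:
        warnings.warn(
            "validity curve has no downward curvature; falling back to smallest k",
            RuntimeWarning,
        )
        return int(k_values[0])
    return int(np.asarray(k_values)[int(drop.argmax())])


def scan_k_and_find_elbow(
    pooled: PooledFrames | np.ndarray,
    k_range: Sequence[int] = tuple(range(2, 21)),
    metric: str = "correlation",
    n_init: int = 20,
    max_iter: int = 500,
    rng_seed: int = 0,
    elbow_method: str = "chord",
) -> CviCurve:
    """Cluster the pooled matrix at each k and pick the CVI elbow.

    Every k uses the same restart count and a k-specific sub-seed so
    the scan is reproducible; the full curve and every solution are
    retained for audit.
    """
    k_range = tuple(int(k) for k in k_range)
    solutions: dict[int, CapSolution] = {}
    cvi = []
    for k in k_range:
        sol = kmeans_cluster(
            pooled, k, metric=metric, n_init=n_init, max_iter=max_iter,
            rng_seed=rng_seed + k,
        )
        solutions[k] = sol
        cvi.append(compute_cvi(pooled, sol))
        logger.debug("k=%d cvi=%.4f objective=%.4f", k, cvi[-1], sol.objective)
    elbow = find_elbow(k_range, cvi, method=elbow_method)
    return CviCurve(
        k_values=k_range, cvi=tuple(cvi), elbow_k=elbow, method=elbow_method,
        solutions=solutions,
    )


# ---------------------------------------------------------------------------
# centroid characterization


def top_components(
    centroid: np.ndarray,
    component_ids: Sequence[str],
    network_labels: Sequence[str],
    n: int = 10,
) -> pd.DataFrame:
    """The ``n`` most coactive components of one centroid, with networks.

    Sorted by centroid value descending; ties resolve to the earlier
    component id in the input ordering.
    """
    centroid = np.asarray(centroid, dtype=float)
    if n > centroid.size:
        raise ClusteringError(f"asked for {n} components but centroid has {centroid.size}")
    order = np.argsort(-centroid, kind="stable")[:n]
    return pd.DataFrame(
        {
            "component_id": np.asarray(component_ids)[order],
            "network": np.asarray(network_labels)[order],
            "value": centroid[order],
        }
    )


def match_centroids(
    solution_a: CapSolution, solution_b: CapSolution
) -> pd.DataFrame:
    """Optimal one-to-one centroid matching by summed Pearson correlation.

    Used to check that two independently clustered groups recover the
    same states. The assignment maximizes summed |r| (centroid sign is
    arbitrary in CAP decompositions); the reported correlations keep
    their sign. Returns (state_a, state_b, correlation) rows.
    """
    a, b = solution_a.centroids, solution_b.centroids
    if a.shape[1] != b.shape[1]:
        raise ClusteringError("centroid dimensionality differs between solutions")
    if a.shape[0] != b.shape[0]:
        raise ClusteringError("solutions have different k; cannot match one-to-one")
    corr = _row_standardize(a) @ _row_standardize(b).T
    rows, cols = linear_sum_assignment(-np.abs(corr))
    return pd.DataFrame(
        {"state_a": rows, "state_b": cols, "correlation": corr[rows, cols]}
    )
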