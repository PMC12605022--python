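"""EEG microstate analysis: GFP, polarity-insensitive modified k-means,
model selection, backfitting, and temporal parameters.

The clustering model treats every scalp map as a direction in channel
space: a map ``x`` and its negation ``-x`` express the same microstate.
Templates are therefore principal axes (eigenvectors of the within-cluster
scatter), not centroids, and assignment maximises the squared projection.

Conventions used throughout:

* maps are average-referenced (zero mean across channels);
* templates are zero-mean, unit Euclidean norm;
* spatial correlation between two zero-mean maps is the cosine of the
  angle between them, so for unit-norm templates ``corr(x, T) = x.T / |x|``;
* GFP is the population standard deviation across channels, i.e.
  ``|x| / sqrt(C)`` for an average-referenced map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.signal import find_peaks
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

from .recording import EEGRecording, Montage

__all__ = [
    "GFPSeries",
    "Segmentation",
    "ModifiedKMeans",
    "compute_gfp",
    "modified_kmeans",
    "compute_gev",
    "cross_validation_criterion",
    "select_k",
    "backfit",
    "smooth_labels",
    "compute_parameters",
    "expected_coverage",
    "match_templates",
    "canonical_microstate_maps",
    "name_states",
]

UNASSIGNED = -1


# ---------------------------------------------------------------------------
# GFP


@dataclass
class GFPSeries:
    """Global field power per sample plus the indices of its local maxima."""

    values: np.ndarray
    peak_indices: np.ndarray


def compute_gfp(
    rec: EEGRecording, min_peak_separation_ms: float = 0.0
) -> GFPSeries:
    """Global field power: the spatial (population) SD of each sample's map.

    Peaks are strict local maxima of the GFP curve; an optional minimum
    separation (in ms) suppresses maxima closer than that distance.
    Peak search never crosses a splice boundary of the recording.
    """
    if rec.n_channels < 3:
        raise ValueError("GFP needs at least 3 channels")
    x = rec.data - rec.data.mean(axis=0, keepdims=True)
    gfp = np.sqrt(np.mean(x**2, axis=0))
    distance = max(1, int(round(min_peak_separation_ms * rec.sfreq / 1000.0)))
    peaks: list[np.ndarray] = []
    for lo, hi in _chunks(rec.n_samples, rec.splice_boundaries):
        idx, _ = find_peaks(gfp[lo:hi], distance=distance)
        peaks.append(idx + lo)
    peak_indices = (
        np.concatenate(peaks) if peaks else np.array([], dtype=int)
    )
    return GFPSeries(values=gfp, peak_indices=peak_indices)


def _chunks(n_samples: int, boundaries) -> list[tuple[int, int]]:
    """Contiguous stretches of a (possibly spliced) record."""
    cuts = [0] + sorted(int(b) for b in boundaries) + [n_samples]
    return [(a, b) for a, b in zip(cuts[:-1], cuts[1:]) if b > a]


# ---------------------------------------------------------------------------
# Modified k-means


class ModifiedKMeans(ClusterMixin, BaseEstimator):
    """Polarity-insensitive modified k-means for scalp topographies.

    Parameters
    ----------
    n_clusters : int
        Number of microstate classes K.
    n_init : int, default 50
        Random restarts; the model with the highest global explained
        variance (GEV) is kept.
    max_iter : int, default 300
        Iteration cap per restart.
    tol : float, default 1e-7
        Convergence threshold on the relative GEV change.
    random_state : int | numpy Generator | None
        Seed; identical seeds give identical fits.

    Attributes
    ----------
    templates_ : (K, C) array — zero-mean unit-norm topographies.
    labels_ : (n_maps,) assignment of the training maps.
    gev_ : float — total GEV on the training maps.
    gev_per_state_ : (K,) array summing to ``gev_``.
    sigma2_ : float — residual variance of the training maps.
    cv_ : float — cross-validation criterion (see
        :func:`cross_validation_criterion`).
    """

    def __init__(
        self,
        n_clusters: int = 4,
        n_init: int = 50,
        max_iter: int = 300,
        tol: float = 1e-7,
        random_state=None,
    ):
        self.n_clusters = n_clusters
        self.n_init = n_init
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be (n_maps, n_channels)")
        n, C = X.shape
        K = self.n_clusters
        if n < K:
            raise ValueError(f"need at least {K} maps, got {n}")
        X = X - X.mean(axis=1, keepdims=True)
        norms2 = np.sum(X**2, axis=1)
        if np.count_nonzero(norms2 > 0) < K:
            raise ValueError("fewer distinct non-zero maps than clusters")
        denom = norms2.sum()
        rng = np.random.default_rng(self.random_state)

        best = None
        for _ in range(self.n_init):
            res = self._fit_once(X, norms2, denom, K, rng)
            if best is None or res[2] > best[2]:
                best = res
        templates, labels, gev, n_iter, converged = best

        self.templates_ = templates
        self.labels_ = labels
        self.n_iter_ = n_iter
        self.converged_ = converged
        proj2 = (X @ templates.T) ** 2
        chosen = proj2[np.arange(n), labels]
        self.gev_ = float(chosen.sum() / denom)
        per_state = np.zeros(K)
        for k in range(K):
            per_state[k] = chosen[labels == k].sum() / denom
        self.gev_per_state_ = per_state
        self.sigma2_ = float((norms2 - chosen).sum() / (n * (C - 1)))
        self.cv_ = (
            cross_validation_criterion(self.sigma2_, C, K)
            if K < C - 1
            else np.nan
        )
        return self

    def _fit_once(self, X, norms2, denom, K, rng):
        n, C = X.shape
        idx = rng.choice(np.flatnonzero(norms2 > 0), size=K, replace=False)
        T = X[idx] / np.sqrt(norms2[idx])[:, None]
        prev_gev = -np.inf
        labels = np.zeros(n, dtype=int)
        converged = False
        for it in range(self.max_iter):
            proj2 = (X @ T.T) ** 2
            labels = np.argmax(proj2, axis=1)  # ties -> lowest index
            fit = proj2[np.arange(n), labels]
            for k in range(K):
                if not np.any(labels == k):
                    # re-seed empty cluster from the worst-fit map
                    worst = int(np.argmin(fit / np.maximum(norms2, 1e-300)))
                    labels[worst] = k
                    fit[worst] = np.inf
            for k in range(K):
                T[k] = _principal_axis(X[labels == k])
            gev = (X @ T.T)[np.arange(n), labels]
            gev = float(np.sum(gev**2) / denom)
            if abs(gev - prev_gev) < self.tol * max(abs(prev_gev), 1e-12):
                converged = True
                break
            prev_gev = gev
        return T, labels, gev, it + 1, converged

    def predict(self, X):
        """Polarity-insensitive assignment of maps to fitted templates."""
        check_is_fitted(self, "templates_")
        X = np.asarray(X, dtype=float)
        X = X - X.mean(axis=1, keepdims=True)
        return np.argmax((X @ self.templates_.T) ** 2, axis=1)


def _principal_axis(X: np.ndarray) -> np.ndarray:
    """Unit-norm principal eigenvector of ``X.T X`` with a fixed sign."""
    S = X.T @ X
    _, vecs = np.linalg.eigh(S)
    t = vecs[:, -1]
    pivot = int(np.argmax(np.abs(t)))
    if t[pivot] < 0:
        t = -t
    return t


def modified_kmeans(
    peak_maps, n_clusters, n_restarts=50, max_iter=300, tol=1e-7, seed=None
) -> ModifiedKMeans:
    """Functional wrapper over :class:`ModifiedKMeans`."""
    return ModifiedKMeans(
        n_clusters=n_clusters,
        n_init=n_restarts,
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    ).fit(np.asarray(peak_maps, dtype=float))


# ---------------------------------------------------------------------------
# GEV / CV / model selection


def compute_gev(maps, templates, labels) -> tuple[float, np.ndarray]:
    """Global explained variance of labelled maps.

    GEV = sum_t (GFP_t * corr(x_t, T_{L(t)}))^2 / sum_t GFP_t^2, which for
    average-referenced maps and unit-norm templates reduces to
    sum (x_t . T)^2 / sum |x_t|^2. Unassigned samples contribute zero to
    the numerator but stay in the denominator.
    """
    X = np.asarray(maps, dtype=float)
    X = X - X.mean(axis=1, keepdims=True)
    templates = np.asarray(templates, dtype=float)
    labels = np.asarray(labels, dtype=int)
    norms2 = np.sum(X**2, axis=1)
    denom = norms2.sum()
    if denom <= 0:
        raise ValueError("all-zero GFP: GEV undefined")
    K = templates.shape[0]
    per_state = np.zeros(K)
    assigned = labels >= 0
    if np.any(assigned):
        proj2 = np.einsum(
            "ij,ij->i", X[assigned], templates[labels[assigned]]
        ) ** 2
        np.add.at(per_state, labels[assigned], proj2)
    per_state /= denom
    return float(per_state.sum()), per_state


def cross_validation_criterion(sigma2: float, n_channels: int, k: int) -> float:
    """Predictive residual-variance criterion for choosing K.

    CV = sigma2 * ((C - 1) / (C - 1 - K))**2; the correction factor
    penalises model complexity relative to the C-1 degrees of freedom an
    average-referenced map carries.
    """
    if k >= n_channels - 1:
        raise ValueError("K must be < C - 1 for the CV criterion")
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    c = n_channels - 1
    return float(sigma2 * (c / (c - k)) ** 2)


def select_k(
    models: list[ModifiedKMeans], rule: str = "cv", forced_k: int | None = None
) -> tuple[ModifiedKMeans, dict]:
    """Choose one model from fits over a range of K.

    ``rule='cv'`` (default) minimises the CV criterion; ``forced_k``
    overrides and returns the model with that K (the convention used when
    reporting the classical four microstate classes). The decision is
    returned as metadata so it can be recorded with the outputs.
    """
    if not models:
        raise ValueError("empty model list")
    if forced_k is not None:
        for m in models:
            if m.n_clusters == forced_k:
                return m, {"rule": "forced", "k": forced_k}
        raise ValueError(f"no fitted model with K={forced_k}")
    if rule == "cv":
        cvs = [m.cv_ for m in models]
        best = int(np.argmin(cvs))
        return models[best], {
            "rule": "cv",
            "k": models[best].n_clusters,
            "cv_values": {m.n_clusters: float(m.cv_) for m in models},
        }
    if rule == "gev_elbow":
        gev = np.array([m.gev_ for m in models])
        if len(gev) < 3:
            best = int(np.argmax(gev))
        else:
            # elbow = largest drop in marginal GEV gain
            best = int(np.argmax(-np.diff(np.diff(gev)))) + 1
        return models[best], {"rule": "gev_elbow", "k": models[best].n_clusters}
    raise ValueError(f"unknown rule {rule!r}")


# ---------------------------------------------------------------------------
# Backfitting and temporal parameters


@dataclass
class Segmentation:
    """Per-sample microstate labels (``-1`` marks unassigned samples)."""

    labels: np.ndarray
    sfreq: float
    splice_boundaries: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.splice_boundaries = sorted(int(b) for b in self.splice_boundaries)


def backfit(
    templates: np.ndarray,
    rec: EEGRecording,
    gfp: GFPSeries | None = None,
    mode: str = "peaks",
) -> Segmentation:
    """Label every sample of ``rec`` with its best-matching template.

    ``mode='peaks'`` (default): GFP peaks are labelled by the largest
    squared spatial correlation and every other sample inherits the label
    of the nearest peak in time, never across a splice boundary; a spliced
    stretch without any peak stays unassigned. ``mode='all'`` labels each
    sample directly. Polarity is ignored; ties go to the lowest state
    index.
    """
    templates = np.asarray(templates, dtype=float)
    if templates.shape[1] != rec.n_channels:
        raise ValueError("template channel count does not match recording")
    X = rec.data - rec.data.mean(axis=0, keepdims=True)
    proj2 = (X.T @ templates.T) ** 2  # (n_samples, K)
    if mode == "all":
        labels = np.argmax(proj2, axis=1)
        return Segmentation(labels, rec.sfreq, rec.splice_boundaries)
    if mode != "peaks":
        raise ValueError(f"unknown mode {mode!r}")
    if gfp is None:
        gfp = compute_gfp(rec)
    peaks = gfp.peak_indices
    if peaks.size == 0:
        raise ValueError("no GFP peaks found; cannot backfit in peak mode")
    peak_labels = np.argmax(proj2[peaks], axis=1)
    labels = np.full(rec.n_samples, UNASSIGNED, dtype=int)
    for lo, hi in _chunks(rec.n_samples, rec.splice_boundaries):
        inside = (peaks >= lo) & (peaks < hi)
        if not np.any(inside):
            continue  # peakless spliced stretch stays unassigned
        p = peaks[inside]
        pl = peak_labels[inside]
        t = np.arange(lo, hi)
        nearest = np.searchsorted(p, t)
        nearest = np.clip(nearest, 0, p.size - 1)
        left = np.clip(nearest - 1, 0, p.size - 1)
        use_left = np.abs(t - p[left]) <= np.abs(p[nearest] - t)
        labels[lo:hi] = pl[np.where(use_left, left, nearest)]
    return Segmentation(labels, rec.sfreq, rec.splice_boundaries)


def _runs(seg: Segmentation) -> list[tuple[int, int, int]]:
    """(start, stop, label) runs, split at splice boundaries."""
    out = []
    for lo, hi in _chunks(len(seg.labels), seg.splice_boundaries):
        lab = seg.labels[lo:hi]
        change = np.flatnonzero(np.diff(lab)) + 1
        starts = np.concatenate(([0], change)) + lo
        stops = np.concatenate((change, [hi - lo])) + lo
        out.extend(
            (int(a), int(b), int(seg.labels[a])) for a, b in zip(starts, stops)
        )
    return out


def smooth_labels(
    seg: Segmentation,
    rec: EEGRecording,
    templates: np.ndarray,
    min_duration_ms: float = 0.0,
) -> Segmentation:
    """Absorb segments shorter than ``min_duration_ms`` into a neighbour.

    A short segment is re-labelled to whichever temporally adjacent
    segment's template correlates better (in squared spatial correlation)
    with the short segment's own samples. ``0`` disables smoothing, the
    default, so that the segmentation reflects the raw backfit.
    """
    if min_duration_ms <= 0:
        return Segmentation(
            seg.labels.copy(), seg.sfreq, seg.splice_boundaries
        )
    templates = np.asarray(templates, dtype=float)
    X = rec.data - rec.data.mean(axis=0, keepdims=True)
    proj2 = (X.T @ templates.T) ** 2
    norm2 = np.maximum(np.sum(X**2, axis=0), 1e-300)
    corr2 = proj2 / norm2[:, None]
    min_len = min_duration_ms * seg.sfreq / 1000.0
    labels = seg.labels.copy()
    for _ in range(100):
        work = Segmentation(labels, seg.sfreq, seg.splice_boundaries)
        runs = _runs(work)
        changed = False
        for i, (a, b, lab) in enumerate(runs):
            if lab == UNASSIGNED or (b - a) >= min_len:
                continue
            cands = []
            if i > 0 and runs[i - 1][2] not in (UNASSIGNED, lab):
                if runs[i - 1][1] == a:  # same chunk
                    cands.append(runs[i - 1][2])
            if i + 1 < len(runs) and runs[i + 1][2] not in (UNASSIGNED, lab):
                if runs[i + 1][0] == b:
                    cands.append(runs[i + 1][2])
            if not cands:
                continue
            scores = [float(corr2[a:b, k].mean()) for k in cands]
            labels[a:b] = cands[int(np.argmax(scores))]
            changed = True
        if not changed:
            break
    return Segmentation(labels, seg.sfreq, seg.splice_boundaries)


def compute_parameters(
    seg: Segmentation,
    n_states: int | None = None,
    include_edge_segments: bool = True,
) -> "pd.DataFrame":
    """Per-state Duration (ms), Occurrence (1/s), Coverage and segment count.

    Duration is the mean length of the state's segments, Occurrence the
    number of its segments per second of labelled recording, Coverage the
    fraction of labelled samples it occupies. Segments touching a record
    edge or splice boundary are included by default; with
    ``include_edge_segments=False`` they are excluded from the Duration
    and Occurrence statistics (Coverage always uses all labelled samples).
    """
    import pandas as pd

    labels = seg.labels
    labelled = int(np.sum(labels >= 0))
    if labelled == 0:
        raise ValueError("no labelled samples")
    if n_states is None:
        n_states = int(labels.max()) + 1
    total_time_s = labelled / seg.sfreq
    runs = _runs(seg)
    edges = {0, len(labels)} | set(seg.splice_boundaries)
    rows = []
    for k in range(n_states):
        seg_lens = [
            b - a
            for a, b, lab in runs
            if lab == k
            and (include_edge_segments or (a not in edges and b not in edges))
        ]
        n_segs = len(seg_lens)
        duration_ms = (
            1000.0 * float(np.mean(seg_lens)) / seg.sfreq if n_segs else np.nan
        )
        occurrence = n_segs / total_time_s
        coverage = float(np.sum(labels == k)) / labelled
        rows.append(
            {
                "state": k,
                "duration_ms": duration_ms,
                "occurrence_hz": occurrence,
                "coverage": coverage,
                "n_segments": n_segs,
            }
        )
    return pd.DataFrame(rows)


def expected_coverage(occurrence_hz: float, duration_ms: float) -> float:
    """Coverage implied by Occurrence x Duration.

    Coverage is the fraction of time occupied by a state, so when edge
    effects are negligible it equals segments/second times mean segment
    length in seconds. Used as a consistency check on reported parameter
    triads.
    """
    return occurrence_hz * duration_ms / 1000.0


# ---------------------------------------------------------------------------
# Template matching and naming


def match_templates(
    templates_a: np.ndarray, templates_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal one-to-one matching of two template sets of equal K.

    Returns ``(permutation, signs, abs_corr)`` where
    ``templates_b[permutation[i]]`` is the partner of ``templates_a[i]``,
    ``signs[i]`` is the polarity of the match and ``abs_corr`` the full
    K x K absolute spatial-correlation table. Maximises total absolute
    correlation via the Hungarian method.
    """
    A = _normalize_rows(np.asarray(templates_a, dtype=float))
    B = _normalize_rows(np.asarray(templates_b, dtype=float))
    if A.shape[0] != B.shape[0]:
        raise ValueError("template sets must have equal K")
    corr = A @ B.T
    rows, cols = linear_sum_assignment(-np.abs(corr))
    perm = np.empty(A.shape[0], dtype=int)
    perm[rows] = cols
    signs = np.sign(corr[rows, perm[rows]]).astype(int)
    signs[signs == 0] = 1
    return perm, signs, np.abs(corr)


def _normalize_rows(X: np.ndarray) -> np.ndarray:
    X = X - X.mean(axis=1, keepdims=True)
    n = np.linalg.norm(X, axis=1, keepdims=True)
    return X / np.maximum(n, 1e-300)


def canonical_microstate_maps(montage: Montage) -> np.ndarray:
    """Synthetic stand-ins for the four classical microstate topographies.

    Built from linear gradients of the electrode positions: A (left
    posterior - right anterior diagonal), B (right posterior - left
    anterior diagonal), C (anterior-posterior, occipital maximum) and D
    (fronto-central radial maximum). These are idealised geometric maps,
    not empirical group averages; they only serve to give fitted states a
    stable A-D naming convention.
    """
    x, y, z = montage.positions.T
    maps = np.stack([-(x + y), x - y, -y, z])
    return _normalize_rows(maps)


def name_states(templates: np.ndarray, montage: Montage) -> list[str]:
    """Name fitted templates by absolute-correlation matching to the
    canonical maps: the four best-matching states get A-D, any further
    states get E, F, ... in fitted order."""
    canon = canonical_microstate_maps(montage)
    T = _normalize_rows(np.asarray(templates, dtype=float))
    corr = np.abs(T @ canon.T)  # (K, 4)
    rows, cols = linear_sum_assignment(-corr)
    letters = "ABCDEFGH"
    names = [""] * T.shape[0]
    for r, c in zip(rows, cols):
        names[r] = letters[c]
    nxt = canon.shape[0]
    for i, n in enumerate(names):
        if not n:
            names[i] = letters[nxt]
            nxt += 1
    return names
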