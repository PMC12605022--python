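"""Microstate-conditioned source-space connectivity.

Sensor data at the GFP peaks of one microstate class are projected into
source space with an sLORETA (standardised minimum-norm) inverse built
from a fixed-orientation leadfield, averaged into parcellation regions
with sign alignment, and correlated (Pearson) region-by-region. Edge
lists thresholded on |r| are the exchange format for circos-style plots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import pinvh
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .microstates import GFPSeries, Segmentation, compute_gfp
from .recording import EEGRecording

__all__ = [
    "Leadfield",
    "Parcellation",
    "ConnectivityMatrix",
    "SLORETAInverse",
    "build_sloreta_inverse",
    "apply_inverse",
    "extract_state_data",
    "parcellate",
    "pearson_connectivity",
    "threshold_edges",
    "summarize_connectivity",
]


@dataclass
class Leadfield:
    """Fixed-orientation forward operator: ``gain`` maps S sources to C sensors."""

    gain: np.ndarray  # (C, S)
    source_positions: np.ndarray  # (S, 3)
    alpha: float = 0.0  # Tikhonov regularisation used at inversion

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=float)
        self.source_positions = np.asarray(self.source_positions, dtype=float)
        if not np.all(np.isfinite(self.gain)):
            raise ValueError("leadfield gain must be finite")
        if self.gain.shape[1] < 2:
            raise ValueError("need at least 2 sources")
        if self.source_positions.shape != (self.gain.shape[1], 3):
            raise ValueError("source_positions must be (S, 3)")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")

    @property
    def n_sources(self) -> int:
        return self.gain.shape[1]


@dataclass
class Parcellation:
    """Assignment of every source to exactly one named region."""

    region_of_source: np.ndarray  # (S,) int labels into region_names
    region_names: list[str]

    def __post_init__(self) -> None:
        self.region_of_source = np.asarray(self.region_of_source, dtype=int)
        if len(self.region_names) < 2:
            raise ValueError("need at least 2 regions")
        if self.region_of_source.min() < 0 or self.region_of_source.max() >= len(
            self.region_names
        ):
            raise ValueError("region labels out of range")

    @property
    def n_regions(self) -> int:
        return len(self.region_names)

    def members(self, region: int) -> np.ndarray:
        return np.flatnonzero(self.region_of_source == region)


@dataclass
class ConnectivityMatrix:
    """Region-by-region Pearson correlations for one microstate class."""

    values: np.ndarray  # (R, R), symmetric, unit diagonal; NaN = undefined
    region_names: list[str]
    state: int
    n_samples: int
    undefined_regions: list[int] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Inverse operator


class SLORETAInverse(TransformerMixin, BaseEstimator):
    """sLORETA inverse operator as a scikit-learn transformer.

    ``fit`` takes a :class:`Leadfield`; ``transform`` maps sensor samples
    (``n_samples x n_channels``) to standardised source estimates
    (``n_samples x n_sources``).

    With ``H`` the average-reference projector and ``G = H @ gain``, the
    minimum-norm kernel is ``K = G.T (G G.T + alpha H)^+`` and the
    sLORETA estimate of source j divides the minimum-norm estimate by
    ``sqrt((K G)_jj)``, the resolution-based standardisation that gives
    the method its zero localisation error on noiseless single sources.
    """

    def __init__(self, alpha: float = 0.0):
        self.alpha = alpha

    def fit(self, leadfield: Leadfield, y=None):
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        gain = leadfield.gain
        C = gain.shape[0]
        H = np.eye(C) - np.full((C, C), 1.0 / C)
        G = H @ gain
        M = G @ G.T + self.alpha * H
        rank = np.linalg.matrix_rank(M)
        if self.alpha == 0 and rank < C - 1:
            warnings.warn(
                "rank-deficient sensor covariance at alpha=0; "
                "falling back to the pseudo-inverse",
                RuntimeWarning,
            )
        kernel = G.T @ pinvh(M)
        resolution_diag = np.einsum("sc,cs->s", kernel, G)
        std = np.sqrt(np.clip(resolution_diag, 1e-300, None))
        self.n_channels_ = C
        self.n_sources_ = gain.shape[1]
        self.projector_ = H
        self.kernel_ = kernel  # minimum-norm kernel (S x C)
        self.standardization_ = std
        self.w_ = kernel / std[:, None]  # standardised kernel
        return self

    def transform(self, X):
        check_is_fitted(self, "w_")
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != self.n_channels_:
            raise ValueError(
                f"expected {self.n_channels_} channels, got {X.shape[-1]}"
            )
        return (X @ self.projector_) @ self.w_.T


def build_sloreta_inverse(lf: Leadfield) -> SLORETAInverse:
    """Build and fit an :class:`SLORETAInverse` with the leadfield's alpha."""
    return SLORETAInverse(alpha=lf.alpha).fit(lf)


def apply_inverse(inverse: SLORETAInverse, data: np.ndarray) -> np.ndarray:
    """Apply a fitted inverse to ``channels x samples`` data.

    Returns ``sources x samples``; linear in the data.
    """
    data = np.asarray(data, dtype=float)
    if data.shape[0] != inverse.n_channels_:
        raise ValueError("channel count mismatch")
    return inverse.transform(data.T).T


# ---------------------------------------------------------------------------
# State-conditioned extraction and parcellation


def extract_state_data(
    rec: EEGRecording,
    seg: Segmentation,
    state: int,
    gfp: GFPSeries | None = None,
    mode: str = "peaks",
) -> tuple[np.ndarray, int]:
    """Collect the sensor columns belonging to one microstate.

    ``mode='peaks'`` (default) keeps only GFP-peak samples labelled
    ``state``; ``mode='all'`` keeps every labelled sample. Column order
    preserves time. A state absent from the segmentation yields an
    explicit empty ``(C, 0)`` result.
    """
    if len(seg.labels) != rec.n_samples:
        raise ValueError("segmentation does not match recording length")
    if mode == "peaks":
        if gfp is None:
            gfp = compute_gfp(rec)
        idx = gfp.peak_indices
        idx = idx[seg.labels[idx] == state]
    elif mode == "all":
        idx = np.flatnonzero(seg.labels == state)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return rec.data[:, idx], int(idx.size)


def parcellate(source_ts: np.ndarray, parcellation: Parcellation) -> np.ndarray:
    """Average member-source series into region series with sign alignment.

    Fixed-orientation source estimates carry arbitrary polarity, so each
    member source is first flipped to correlate positively with the
    region's first principal temporal direction, then averaged. Returns
    ``n_regions x n_samples``.
    """
    source_ts = np.asarray(source_ts, dtype=float)
    if source_ts.shape[0] != parcellation.region_of_source.size:
        raise ValueError("source series do not match parcellation")
    out = np.empty((parcellation.n_regions, source_ts.shape[1]))
    for r in range(parcellation.n_regions):
        members = parcellation.members(r)
        if members.size == 0:
            raise ValueError(f"region {parcellation.region_names[r]!r} is empty")
        Y = source_ts[members]
        if members.size == 1:
            out[r] = Y[0]
            continue
        # first principal temporal direction of the region
        _, _, vt = np.linalg.svd(Y, full_matrices=False)
        pc = vt[0]
        signs = np.sign(Y @ pc)
        signs[signs == 0] = 1.0
        out[r] = (signs[:, None] * Y).mean(axis=0)
    return out


def pearson_connectivity(
    region_ts: np.ndarray, state: int, region_names: list[str] | None = None
) -> ConnectivityMatrix:
    """Pairwise Pearson correlation of region series for one microstate.

    Constant (zero-variance) series give undefined correlations: their
    rows and columns are reported as NaN and the region index is flagged,
    never silently zeroed.
    """
    Y = np.asarray(region_ts, dtype=float)
    if Y.ndim != 2 or Y.shape[1] < 3:
        raise ValueError("need region x samples input with >= 3 samples")
    names = region_names or [f"region_{i}" for i in range(Y.shape[0])]
    sd = Y.std(axis=1)
    undefined = np.flatnonzero(sd == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(Y)
    r[undefined, :] = np.nan
    r[:, undefined] = np.nan
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    # enforce exact symmetry against floating-point asymmetry
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(
        values=r,
        region_names=list(names),
        state=state,
        n_samples=Y.shape[1],
        undefined_regions=[int(i) for i in undefined],
    )


def threshold_edges(cm: ConnectivityMatrix, threshold: float) -> pd.DataFrame:
    """Upper-triangle pairs with ``|r| >= threshold``, strongest first."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    i, j = np.triu_indices(len(cm.region_names), k=1)
    r = cm.values[i, j]
    keep = np.abs(r) >= threshold
    keep &= np.isfinite(r)
    order = np.argsort(-np.abs(r[keep]), kind="stable")
    return pd.DataFrame(
        {
            "region_a": [cm.region_names[a] for a in i[keep][order]],
            "region_b": [cm.region_names[b] for b in j[keep][order]],
            "r": r[keep][order],
        }
    )


def summarize_connectivity(
    cms: list[ConnectivityMatrix], fisher: bool = False, magnitude: bool = True
) -> dict:
    """Pool upper-triangle correlations across subjects for one state.

    Returns mean, SD (ddof=1) and n of the pooled edge values. By
    default edges are pooled as |r| (``magnitude=True``): with
    fixed-orientation sources and sign-aligned parcel averaging the
    polarity of a region pair is arbitrary, so only the correlation
    magnitude is comparable across subjects. With ``fisher=True`` the
    mean is taken on the Fisher-z scale and mapped back; the SD is
    always reported on the r scale.
    """
    if not cms:
        raise ValueError("no connectivity matrices")
    names = cms[0].region_names
    for cm in cms:
        if cm.region_names != names:
            raise ValueError("mixed parcellations cannot be pooled")
    i, j = np.triu_indices(len(names), k=1)
    pooled = np.concatenate([cm.values[i, j] for cm in cms])
    pooled = pooled[np.isfinite(pooled)]
    if magnitude:
        pooled = np.abs(pooled)
    if pooled.size == 0:
        raise ValueError("no finite edge values to pool")
    if fisher:
        z = np.arctanh(np.clip(pooled, -1 + 1e-12, 1 - 1e-12))
        mean = float(np.tanh(z.mean()))
    else:
        mean = float(pooled.mean())
    sd = float(pooled.std(ddof=1)) if pooled.size > 1 else 0.0
    return {
        "mean": mean,
        "sd": sd,
        "n": int(pooled.size),
        "state": cms[0].state,
        "fisher": fisher,
    }
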