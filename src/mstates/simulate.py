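"""Ground-truthed synthetic EEG cohorts for microstate and connectivity
analysis.

The generator emulates the statistical structure the downstream analysis
assumes, so that every stage can be tested by parameter recovery:

* a small set of zero-mean, unit-norm template topographies;
* a semi-Markov state sequence with geometric segment lengths above a
  physiological minimum duration (resting microstates are quasi-stable
  for roughly 80-120 ms);
* an alpha-band-like amplitude — per segment a signed sinusoid holding
  a whole number of half-cycles, so the GFP of the noiseless signal is
  exactly a rectified sinusoid whose troughs coincide with state
  transitions (the classical observation that motivates GFP-peak-based
  clustering) and each segment integrates to zero, surviving the 1 Hz
  high-pass of preprocessing intact;
* additive white sensor noise scaled to a requested amplitude SNR
  (RMS of the noiseless signal over RMS of the noise, whole record);
* optionally, inter-regional source correlations planted through a toy
  single-shell spherical head model, for connectivity recovery tests.

Everything is deterministic given a seed; cohorts derive one seed per
subject from the master seed via ``numpy.random.SeedSequence`` keyed on
``(master_seed, group_index, subject_index)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .connectivity import Leadfield, Parcellation
from .recording import EEGRecording, Montage, standard_1020_montage

__all__ = [
    "GroundTruth",
    "SimulationConfig",
    "Subject",
    "Cohort",
    "generate_templates",
    "generate_label_sequence",
    "generate_eeg",
    "generate_forward_model",
    "generate_connected_sources",
    "generate_cohort",
    "simulate_parameter_tables",
]


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must recover."""

    templates: Optional[np.ndarray] = None  # (K, C) zero-mean unit-norm
    label_sequence: Optional[np.ndarray] = None  # (T,) int
    mean_durations: Optional[np.ndarray] = None  # (K,) ms
    transition_matrix: Optional[np.ndarray] = None  # (K, K) row-stochastic
    snr: float = np.inf
    leadfield_truth: Optional[Leadfield] = None
    region_correlation_truth: Optional[dict] = None  # state -> (R, R)
    region_latent: Optional[np.ndarray] = None  # (R, T) latent region series
    envelope: Optional[np.ndarray] = None  # (T,) amplitude envelope

    def __post_init__(self) -> None:
        if self.templates is not None:
            T = np.asarray(self.templates, dtype=float)
            if not np.allclose(T.mean(axis=1), 0, atol=1e-9):
                raise ValueError("templates must be zero-mean")
            if not np.allclose(np.linalg.norm(T, axis=1), 1, atol=1e-9):
                raise ValueError("templates must be unit-norm")
        if self.transition_matrix is not None:
            P = np.asarray(self.transition_matrix, dtype=float)
            if not np.allclose(P.sum(axis=1), 1, atol=1e-9):
                raise ValueError("transition rows must sum to 1")
            if not np.allclose(np.diag(P), 0):
                raise ValueError("transition diagonal must be 0")
        if self.mean_durations is not None and np.any(
            np.asarray(self.mean_durations) <= 0
        ):
            raise ValueError("mean durations must be positive")


@dataclass
class SimulationConfig:
    """Study conditions for a two-group synthetic cohort.

    Defaults are the conditions the acceptance studies run at: 19-channel
    10-20 montage, 4 states, 250 Hz, 60 s records, alpha-rate (10 Hz)
    envelope, amplitude SNR 4, mean state duration 100 ms with a 50 ms
    floor, and group sizes 17 (A, 'healthy-like') vs 23 (B,
    'patient-like'). Group B applies the per-state multipliers to mean
    duration and occurrence, and the global multiplier to the planted
    region correlations.
    """

    n_channels: int = 19
    n_states: int = 4
    sfreq: float = 250.0
    record_length: float = 60.0  # seconds
    envelope_frequency: float = 10.0  # Hz
    envelope_floor: float = 0.0
    snr: float = 4.0
    amplitude: float = 10.0  # uV scale of the noiseless signal
    mean_duration_ms: float = 100.0
    min_duration_ms: float = 50.0
    max_abs_corr: float = 0.5
    seed: int = 0
    n_group_a: int = 17
    n_group_b: int = 23
    duration_multipliers: tuple = (1.0, 1.0, 1.0, 1.0)  # group B, per state
    occurrence_multipliers: tuple = (1.0, 1.0, 1.0, 1.0)  # group B, per state
    # connectivity component (disabled when source_mix == 0)
    source_mix: float = 0.0  # RMS of source component relative to microstates
    n_sources: int = 48
    n_regions: int = 6
    connectivity_strength: float = 0.6
    connectivity_multiplier: float = 1.0  # group B scaling of planted r
    source_band: tuple = (1.0, 30.0)  # Hz; band of the source latents

    def __post_init__(self) -> None:
        if self.n_states >= self.n_channels:
            raise ValueError("need n_states < n_channels")
        for name in (
            "n_channels",
            "n_states",
            "sfreq",
            "record_length",
            "envelope_frequency",
            "snr",
            "amplitude",
            "mean_duration_ms",
            "n_group_a",
            "n_group_b",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if len(self.duration_multipliers) != self.n_states:
            raise ValueError("one duration multiplier per state required")
        if len(self.occurrence_multipliers) != self.n_states:
            raise ValueError("one occurrence multiplier per state required")


# ---------------------------------------------------------------------------
# Templates and label sequences


def generate_templates(
    K: int,
    montage: Montage,
    max_abs_corr: float = 0.5,
    seed=None,
    max_tries: int = 500,
) -> np.ndarray:
    """Draw K zero-mean unit-norm topographies with bounded pairwise overlap.

    Pairwise absolute spatial correlation is kept <= ``max_abs_corr``
    (for zero-mean unit-norm maps this is just the absolute dot product).
    ``max_abs_corr=0`` requests exactly orthogonal maps via Gram-Schmidt.
    Raises ``RuntimeError`` if the bound is infeasible after bounded
    retries.
    """
    C = montage.n_channels
    if not 0 <= max_abs_corr < 1:
        raise ValueError("max_abs_corr must be in [0, 1)")
    if K >= C:
        raise ValueError("need K < channel count")
    rng = np.random.default_rng(seed)
    if max_abs_corr == 0:
        if K > C - 1:
            raise RuntimeError("cannot fit K orthogonal zero-mean maps")
        maps = []
        while len(maps) < K:
            v = rng.standard_normal(C)
            v -= v.mean()
            for m in maps:
                v -= (v @ m) * m
            n = np.linalg.norm(v)
            if n > 1e-8:
                maps.append(v / n)
        return np.array(maps)
    for _ in range(max_tries):
        X = rng.standard_normal((K, C))
        X -= X.mean(axis=1, keepdims=True)
        X /= np.linalg.norm(X, axis=1, keepdims=True)
        corr = np.abs(X @ X.T)
        np.fill_diagonal(corr, 0.0)
        if corr.max() <= max_abs_corr:
            return X
    raise RuntimeError(
        f"could not draw {K} maps with pairwise |corr| <= {max_abs_corr} "
        f"in {max_tries} tries"
    )


def generate_label_sequence(
    K: int,
    n_samples: int,
    sfreq: float,
    mean_durations,
    transition_matrix: np.ndarray | None = None,
    seed=None,
    min_samples: int = 2,
) -> np.ndarray:
    """Piecewise-constant state sequence with geometric segment lengths.

    Segment lengths are ``min_samples - 1 + Geometric(p)`` with ``p``
    chosen so the mean equals the requested per-state mean duration
    (memoryless above the floor, matching Markov-chain semantics).
    Consecutive segments always differ in state; the default transition
    matrix is uniform over the other states.
    """
    if n_samples == 0:
        return np.array([], dtype=int)
    means = np.broadcast_to(
        np.asarray(mean_durations, dtype=float), (K,)
    ) * sfreq / 1000.0
    if np.any(means < min_samples):
        raise ValueError(f"mean durations must be >= {min_samples} samples")
    if transition_matrix is None:
        if K == 1:
            P = np.zeros((1, 1))
        else:
            P = np.full((K, K), 1.0 / (K - 1))
            np.fill_diagonal(P, 0.0)
    else:
        P = np.asarray(transition_matrix, dtype=float)
        if P.shape != (K, K):
            raise ValueError("transition matrix must be (K, K)")
        if K > 1 and (
            not np.allclose(P.sum(axis=1), 1) or not np.allclose(np.diag(P), 0)
        ):
            raise ValueError("rows must sum to 1 with zero diagonal")
    rng = np.random.default_rng(seed)
    labels = np.empty(n_samples, dtype=int)
    state = int(rng.integers(K))
    pos = 0
    while pos < n_samples:
        m = means[state]
        p = 1.0 if m <= min_samples else 1.0 / (m - min_samples + 1.0)
        length = min_samples - 1 + rng.geometric(p)
        length = min(length, n_samples - pos)
        labels[pos : pos + length] = state
        pos += length
        if K > 1:
            state = int(rng.choice(K, p=P[state]))
    return labels


# ---------------------------------------------------------------------------
# EEG synthesis


def _segment_envelope(
    labels: np.ndarray, sfreq: float, freq: float, floor: float
) -> np.ndarray:
    """Signed sinusoidal amplitude with per-segment phase reset.

    The amplitude coefficient oscillates at ``freq`` and restarts at zero
    phase at every state transition, so the *global field power* of the
    noiseless signal is exactly a rectified sinusoid whose troughs
    coincide with transitions. The signed (polarity-alternating) form
    keeps the signal inside the analysis band — a nonnegative envelope
    would carry a large within-segment DC component that a 1 Hz
    high-pass smears across segment boundaries. Microstate analysis is
    polarity-insensitive, so the alternation is invisible downstream.
    ``floor > 0`` adds a square-wave pedestal so |a(t)| never drops
    below ``floor`` (GFP troughs stay labelable).
    """
    n = labels.size
    if n == 0:
        return np.zeros(0)
    cuts = np.concatenate(
        ([0], np.flatnonzero(np.diff(labels)) + 1, [n])
    )
    a = np.empty(n)
    t = np.arange(n)
    for lo, hi in zip(cuts[:-1], cuts[1:]):
        length = hi - lo
        # whole number of half-cycles per segment: the per-segment
        # frequency is nudged around `freq` so the amplitude is zero at
        # both segment ends and integrates to zero within the segment
        n_half = max(1, int(round(2 * freq * length / sfreq)))
        s = np.sin(np.pi * n_half * (t[lo:hi] - lo) / length)
        sgn = np.where(s >= 0, 1.0, -1.0)
        a[lo:hi] = sgn * (floor + (1.0 - floor) * np.abs(s))
    return a


def _microstate_signal(
    templates: np.ndarray,
    labels: np.ndarray,
    sfreq: float,
    envelope_frequency: float,
    envelope_floor: float,
    amplitude: float,
) -> tuple[np.ndarray, np.ndarray]:
    a = amplitude * _segment_envelope(
        labels, sfreq, envelope_frequency, envelope_floor
    )
    return templates[labels].T * a, a


def _add_noise(clean: np.ndarray, snr: float, rng) -> np.ndarray:
    if snr <= 0:
        raise ValueError("snr must be positive")
    if np.isinf(snr):
        return clean.copy()
    rms = np.sqrt(np.mean(clean**2))
    noise = rng.standard_normal(clean.shape) * (rms / snr)
    return clean + noise


def generate_eeg(
    templates: np.ndarray,
    label_sequence: np.ndarray,
    sfreq: float,
    envelope_frequency: float = 10.0,
    snr: float = 4.0,
    seed=None,
    montage: Montage | None = None,
    envelope_floor: float = 0.0,
    amplitude: float = 10.0,
) -> tuple[EEGRecording, GroundTruth]:
    """Synthesise sensor EEG from templates and a state sequence.

    ``data(t) = a(t) * template[label(t)] + noise`` with ``a(t)`` the
    phase-locked rectified-sinusoid envelope and white sensor noise
    scaled so the whole-record amplitude SNR equals ``snr``
    (``numpy.inf`` disables noise). The noiseless signal is exactly
    average-referenced per sample because templates are zero-mean.
    """
    templates = np.asarray(templates, dtype=float)
    labels = np.asarray(label_sequence, dtype=int)
    K, C = templates.shape
    if labels.size and (labels.min() < 0 or labels.max() >= K):
        raise ValueError("label sequence indexes outside the template set")
    if montage is None:
        montage = _default_montage(C)
    rng = np.random.default_rng(seed)
    clean, a = _microstate_signal(
        templates, labels, sfreq, envelope_frequency, envelope_floor, amplitude
    )
    data = _add_noise(clean, snr, rng)
    rec = EEGRecording(data=data, sfreq=sfreq, montage=montage)
    truth = GroundTruth(
        templates=templates,
        label_sequence=labels,
        snr=snr,
        envelope=a,
    )
    return rec, truth


def _default_montage(n_channels: int) -> Montage:
    std = standard_1020_montage()
    if n_channels == std.n_channels:
        return std
    # generic ring montage for non-19-channel synthetic data
    phi = 2 * np.pi * np.arange(n_channels) / n_channels
    pos = np.column_stack(
        [np.cos(phi) * 0.9, np.sin(phi) * 0.9, np.full(n_channels, 0.436)]
    )
    return Montage([f"ch{i}" for i in range(n_channels)], pos)


# ---------------------------------------------------------------------------
# Toy forward model


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n)
    golden = (1 + 5**0.5) / 2
    z = 1 - (2 * i + 1) / n
    r = np.sqrt(np.clip(1 - z**2, 0, None))
    phi = 2 * np.pi * i / golden
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _radial_dipole_gain(
    sensors: np.ndarray, sources: np.ndarray
) -> np.ndarray:
    """Surface potential of radial dipoles in a homogeneous sphere.

    For a radial dipole at fractional eccentricity f and an electrode at
    angular distance gamma (cos gamma = x), the analytic surface
    potential is proportional to ``2(x - f)/s^3 + (1/s - 1)/f`` with
    ``s = sqrt(1 - 2 f x + f^2)`` (closed form of the Legendre series for
    an insulated single-shell sphere). Overall conductivity constants are
    irrelevant because columns are normalised afterwards.
    """
    R = np.linalg.norm(sensors, axis=1)
    sens_u = sensors / R[:, None]
    b = np.linalg.norm(sources, axis=1)
    src_u = sources / b[:, None]
    f = (b / R.mean())[None, :]
    x = sens_u @ src_u.T
    s = np.sqrt(np.clip(1 - 2 * f * x + f**2, 1e-12, None))
    return 2 * (x - f) / s**3 + (1.0 / s - 1.0) / np.maximum(f, 1e-9)


def _farthest_point_seeds(points: np.ndarray, k: int) -> np.ndarray:
    """Deterministic farthest-point sampling (start at the topmost point)."""
    seeds = [int(np.argmax(points[:, 2]))]
    d = np.linalg.norm(points - points[seeds[0]], axis=1)
    for _ in range(1, k):
        nxt = int(np.argmax(d))
        seeds.append(nxt)
        d = np.minimum(d, np.linalg.norm(points - points[nxt], axis=1))
    return np.array(seeds)


def generate_forward_model(
    n_sources: int,
    montage: Montage,
    n_regions: int = 6,
    seed=None,
    source_radius: float = 0.8,
    alpha: float = 0.0,
    identity: bool = False,
) -> tuple[Leadfield, Parcellation]:
    """Toy spherical head model: radial dipoles, sensors on the sphere.

    Sources sit on a Fibonacci lattice at ``source_radius`` (upper part
    of the sphere, z > -0.5), each assigned to exactly one of
    ``n_regions`` contiguous regions (Voronoi cells of farthest-point
    seeds). Leadfield columns are scaled to unit norm. ``identity=True``
    is a testing hook that returns the identity gain with sources at the
    sensors (requires ``n_sources == n_channels``).
    """
    if n_regions < 2 or n_sources < n_regions:
        raise ValueError("need n_sources >= n_regions >= 2")
    if identity:
        if n_sources != montage.n_channels:
            raise ValueError("identity leadfield requires n_sources == C")
        lf = Leadfield(
            gain=np.eye(n_sources),
            source_positions=montage.positions.copy(),
            alpha=alpha,
        )
        pos = montage.positions
    else:
        n_cand = max(int(np.ceil(n_sources / 0.7)), n_sources + 8)
        while True:
            cand = _fibonacci_sphere(n_cand)
            cand = cand[cand[:, 2] > -0.5]
            if cand.shape[0] >= n_sources:
                break
            n_cand = int(n_cand * 1.5) + 8
        pos = cand[:n_sources] * source_radius
        d = np.linalg.norm(
            montage.positions[:, None, :] - pos[None, :, :], axis=2
        )
        if d.min() < 1e-9:
            raise ValueError("a source is colocated with a sensor")
        gain = _radial_dipole_gain(montage.positions, pos)
        gain = gain / np.linalg.norm(gain, axis=0, keepdims=True)
        lf = Leadfield(gain=gain, source_positions=pos, alpha=alpha)
        C = montage.n_channels
        H = np.eye(C) - np.full((C, C), 1.0 / C)
        rank = np.linalg.matrix_rank(H @ gain)
        if rank < min(C - 1, n_sources):
            raise RuntimeError("toy leadfield is rank-deficient")
    seeds = _farthest_point_seeds(pos, n_regions)
    dist = np.linalg.norm(pos[:, None, :] - pos[seeds][None, :, :], axis=2)
    region_of_source = np.argmin(dist, axis=1)
    region_of_source[seeds] = np.arange(n_regions)  # seeds anchor their cells
    parc = Parcellation(
        region_of_source=region_of_source,
        region_names=[f"region_{i}" for i in range(n_regions)],
    )
    return lf, parc


# ---------------------------------------------------------------------------
# Correlated sources


def _correlation_factor(corr: np.ndarray) -> np.ndarray:
    corr = np.asarray(corr, dtype=float)
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError("target correlation matrix must be symmetric")
    if not np.allclose(np.diag(corr), 1, atol=1e-10):
        raise ValueError("target correlation matrix must have unit diagonal")
    w, v = np.linalg.eigh(corr)
    if w.min() < -1e-8:
        raise ValueError("target correlation matrix is not PSD")
    return v @ np.diag(np.sqrt(np.clip(w, 0, None)))


def _correlated_source_signal(
    leadfield: Leadfield,
    parcellation: Parcellation,
    per_state_region_correlation: dict,
    labels: np.ndarray,
    rng,
    sfreq: float | None = None,
    band: tuple | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless sensor signal carrying planted region correlations.

    Region-level latent series start as white noise (optionally
    band-limited to ``band`` Hz so the planted activity lives inside the
    analysis band — instantaneous correlations are exactly preserved
    under a common filter); at each sample the factor of the active
    state's target correlation matrix is applied, every source copies
    its region's latent value, and the result is projected through the
    leadfield.
    """
    R = parcellation.n_regions
    T = labels.size
    factors = {
        int(s): _correlation_factor(m)
        for s, m in per_state_region_correlation.items()
    }
    z = rng.standard_normal((R, T))
    if band is not None:
        from scipy.signal import butter, sosfiltfilt

        if sfreq is None:
            raise ValueError("band-limited latents need sfreq")
        sos = butter(4, list(band), btype="bandpass", fs=sfreq, output="sos")
        z = sosfiltfilt(sos, z, axis=1)
        z /= np.maximum(z.std(axis=1, keepdims=True), 1e-300)
    latent = np.empty((R, T))
    for s, F in factors.items():
        idx = labels == s
        latent[:, idx] = F @ z[:, idx]
    leftover = ~np.isin(labels, list(factors))
    latent[:, leftover] = z[:, leftover]
    source_ts = latent[parcellation.region_of_source]
    return leadfield.gain @ source_ts, latent


def generate_connected_sources(
    leadfield: Leadfield,
    parcellation: Parcellation,
    per_state_region_correlation: dict,
    label_sequence: np.ndarray,
    sfreq: float,
    snr: float = np.inf,
    seed=None,
    montage: Montage | None = None,
    band: tuple | None = None,
) -> tuple[EEGRecording, GroundTruth]:
    """Sensor EEG whose region series carry planted per-state correlations.

    ``per_state_region_correlation`` maps state index to a symmetric PSD
    unit-diagonal (R, R) target. Latents are white by default
    (``band=(low, high)`` band-limits them without changing the planted
    instantaneous correlations). The emitted latent region series are
    returned in ``GroundTruth.region_latent`` so recovery can be checked
    directly.
    """
    labels = np.asarray(label_sequence, dtype=int)
    rng = np.random.default_rng(seed)
    clean, latent = _correlated_source_signal(
        leadfield,
        parcellation,
        per_state_region_correlation,
        labels,
        rng,
        sfreq=sfreq,
        band=band,
    )
    if montage is None:
        montage = _default_montage(clean.shape[0])
    data = _add_noise(clean, snr, rng)
    rec = EEGRecording(data=data, sfreq=sfreq, montage=montage)
    truth = GroundTruth(
        label_sequence=labels,
        snr=snr,
        leadfield_truth=leadfield,
        region_correlation_truth={
            int(s): np.asarray(m, dtype=float)
            for s, m in per_state_region_correlation.items()
        },
        region_latent=latent,
    )
    return rec, truth


# ---------------------------------------------------------------------------
# Cohorts


@dataclass
class Subject:
    subject_id: str
    group: str
    seed: int
    recording: EEGRecording
    truth: GroundTruth


@dataclass
class Cohort:
    config: SimulationConfig
    montage: Montage
    templates: np.ndarray
    leadfield: Optional[Leadfield]
    parcellation: Optional[Parcellation]
    groups: dict  # "A"/"B" -> list[Subject]

    def manifest(self) -> dict:
        """JSON-serialisable ground-truth summary of the cohort."""
        cfg = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(self.config).items()
        }
        return {
            "config": cfg,
            "templates": np.asarray(self.templates).tolist(),
            "subjects": [
                {
                    "subject_id": s.subject_id,
                    "group": s.group,
                    "seed": s.seed,
                    "mean_durations_ms": np.asarray(
                        s.truth.mean_durations
                    ).tolist(),
                }
                for g in self.groups.values()
                for s in g
            ],
        }


def _subject_seed(master_seed: int, group_idx: int, subj_idx: int) -> int:
    ss = np.random.SeedSequence([int(master_seed), group_idx, subj_idx])
    return int(ss.generate_state(1)[0] % (2**31))


def _equicorrelation(n_regions: int, strength: float) -> np.ndarray:
    """All-pairs equicorrelation target (PSD for strength in [0, 1))."""
    if not -1.0 / (n_regions - 1) < strength < 1:
        raise ValueError("equicorrelation strength out of the PSD range")
    corr = np.full((n_regions, n_regions), float(strength))
    np.fill_diagonal(corr, 1.0)
    return corr


def _pairing_correlation(
    n_regions: int, state: int, strength: float
) -> np.ndarray:
    """Disjoint-pair coupling target, pairs rotated per state (PSD).

    Pairwise (differential) coupling is what sensor EEG can actually
    see: a component shared by *all* regions projects to a nearly
    uniform scalp pattern that the average reference removes, so a
    globally coherent target would be planted but unrecoverable. Each
    state couples a different set of region pairs at ``strength``.
    """
    order = np.roll(np.arange(n_regions), state)
    corr = np.eye(n_regions)
    for i in range(0, n_regions - 1, 2):
        a, b = order[i], order[i + 1]
        corr[a, b] = corr[b, a] = float(strength)
    return corr


def generate_cohort(config: SimulationConfig) -> Cohort:
    """Two-group cohort of synthetic recordings with full ground truth.

    Group A uses the base study conditions; group B applies the
    configured per-state duration and occurrence multipliers (occurrence
    effects enter through the transition matrix) and, when a source
    component is mixed in (``source_mix > 0``), scales the planted region
    correlations by ``connectivity_multiplier``.
    """
    cfg = config
    montage = _default_montage(cfg.n_channels)
    rng_global = np.random.default_rng(cfg.seed)
    templates = generate_templates(
        cfg.n_states, montage, cfg.max_abs_corr, seed=rng_global
    )
    leadfield = parcellation = None
    corr_by_group = {"A": None, "B": None}
    if cfg.source_mix > 0:
        leadfield, parcellation = generate_forward_model(
            cfg.n_sources, montage, cfg.n_regions, seed=cfg.seed
        )
        corr_by_group = {
            "A": {
                k: _pairing_correlation(
                    cfg.n_regions, k, cfg.connectivity_strength
                )
                for k in range(cfg.n_states)
            },
            "B": {
                k: _pairing_correlation(
                    cfg.n_regions,
                    k,
                    cfg.connectivity_strength * cfg.connectivity_multiplier,
                )
                for k in range(cfg.n_states)
            },
        }

    n_samples = int(round(cfg.record_length * cfg.sfreq))
    min_samples = max(2, int(round(cfg.min_duration_ms * cfg.sfreq / 1000.0)))
    base_means = np.full(cfg.n_states, cfg.mean_duration_ms)
    groups: dict = {}
    for g_idx, (gname, n_subj) in enumerate(
        [("A", cfg.n_group_a), ("B", cfg.n_group_b)]
    ):
        if n_subj < 1:
            raise ValueError("cohort sizes must be >= 1")
        if gname == "B":
            means = base_means * np.asarray(cfg.duration_multipliers)
            w = np.asarray(cfg.occurrence_multipliers, dtype=float)
        else:
            means = base_means.copy()
            w = np.ones(cfg.n_states)
        P = np.tile(w, (cfg.n_states, 1))
        np.fill_diagonal(P, 0.0)
        P /= P.sum(axis=1, keepdims=True)
        subjects = []
        for s_idx in range(n_subj):
            seed = _subject_seed(cfg.seed, g_idx, s_idx)
            rng = np.random.default_rng(seed)
            labels = generate_label_sequence(
                cfg.n_states,
                n_samples,
                cfg.sfreq,
                means,
                transition_matrix=P,
                seed=rng,
                min_samples=min_samples,
            )
            clean, env = _microstate_signal(
                templates,
                labels,
                cfg.sfreq,
                cfg.envelope_frequency,
                cfg.envelope_floor,
                cfg.amplitude,
            )
            latent = None
            if cfg.source_mix > 0:
                src, latent = _correlated_source_signal(
                    leadfield,
                    parcellation,
                    corr_by_group[gname],
                    labels,
                    rng,
                    sfreq=cfg.sfreq,
                    band=tuple(cfg.source_band),
                )
                ms_rms = np.sqrt(np.mean(clean**2))
                src_rms = np.sqrt(np.mean(src**2))
                clean = clean + cfg.source_mix * (ms_rms / src_rms) * src
            data = _add_noise(clean, cfg.snr, rng)
            rec = EEGRecording(data=data, sfreq=cfg.sfreq, montage=montage)
            truth = GroundTruth(
                templates=templates,
                label_sequence=labels,
                mean_durations=means,
                transition_matrix=P,
                snr=cfg.snr,
                leadfield_truth=leadfield,
                region_correlation_truth=corr_by_group[gname],
                region_latent=latent,
                envelope=env,
            )
            subjects.append(
                Subject(
                    subject_id=f"{gname}{s_idx + 1:02d}",
                    group=gname,
                    seed=seed,
                    recording=rec,
                    truth=truth,
                )
            )
        groups[gname] = subjects
    return Cohort(
        config=cfg,
        montage=montage,
        templates=templates,
        leadfield=leadfield,
        parcellation=parcellation,
        groups=groups,
    )


# ---------------------------------------------------------------------------
# Parameter-level cohorts (for statistics calibration studies)


def simulate_parameter_tables(
    n_a: int,
    n_b: int,
    seed=None,
    states=("A", "B", "C", "D"),
    duration_mean_ms: float = 100.0,
    occurrence_mean_hz: float = 3.0,
    within_group_cv: float = 0.10,
    duration_multipliers=None,
    occurrence_multipliers=None,
):
    """Tidy per-subject microstate parameter tables for two groups.

    Per-subject Duration and Occurrence are drawn around the group means
    with fractional SD ``within_group_cv`` (low within-group noise);
    Coverage is the implied occurrence x duration, renormalised across
    states. Group B applies the per-state multipliers to the means. This
    is the light-weight cohort used for type-I-error and power
    calibration of the group comparisons, where the quantity under test
    is the statistics layer rather than the EEG decomposition.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    K = len(states)
    ones = np.ones(K)
    mults = {
        "A": (ones, ones),
        "B": (
            ones if duration_multipliers is None else np.asarray(duration_multipliers),
            ones if occurrence_multipliers is None else np.asarray(occurrence_multipliers),
        ),
    }
    tables = {}
    for gname, n_subj in [("A", n_a), ("B", n_b)]:
        dmult, omult = mults[gname]
        rows = []
        for s_idx in range(n_subj):
            dur = np.maximum(
                rng.normal(
                    duration_mean_ms * dmult,
                    within_group_cv * duration_mean_ms * dmult,
                ),
                1.0,
            )
            occ = np.maximum(
                rng.normal(
                    occurrence_mean_hz * omult,
                    within_group_cv * occurrence_mean_hz * omult,
                ),
                0.01,
            )
            cov = occ * dur / 1000.0
            cov = cov / cov.sum()
            sid = f"{gname}{s_idx + 1:02d}"
            for k, st in enumerate(states):
                rows.append((sid, st, "duration_ms", dur[k]))
                rows.append((sid, st, "occurrence_hz", occ[k]))
                rows.append((sid, st, "coverage", cov[k]))
        tables[gname] = pd.DataFrame(
            rows, columns=["subject", "state", "metric", "value"]
        )
    return tables["A"], tables["B"]
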