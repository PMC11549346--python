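"""Synthetic source-parcel MEG epochs with planted, recoverable structure.

Generates trials × 72 parcels × time arrays that carry exactly the
statistical features the downstream analyses assume, so the whole chain
is testable without any recording:

* tone-specific multivariate parcel patterns carried by an evoked kernel
  (Gaussian bump peaking ~100 ms after tone onset),
* block-wise *within-triplet pattern convergence* in the high-regularity
  condition (tone patterns morph linearly toward their triplet centroid
  across the 5 blocks, restricted to a 110–130 ms band),
* trial-wise response gain in designated encoder parcels coupled to the
  ideal observer's scalar prediction-error trajectory,
* a planted *synergistic* parcel pair (one parcel carries shared noise
  plus a PE-coupled term, the other the shared noise alone, so only
  their difference is informative),
* spatially correlated Gaussian noise with exponentially decaying
  covariance over parcel centroid distance (optional AR(1) in time).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .observer import ObserverTrace
from .sequences import Sequence

__all__ = [
    "ParcelAtlas",
    "GenConfig",
    "EpochArray",
    "make_atlas",
    "parcel_neighbors",
    "encoder_region",
    "generate_epochs",
    "generate_subjects",
]

N_PARCELS = 72
SFREQ_HZ = 200.0
EPOCH_START_S = -0.050
EPOCH_STOP_S = 0.330


@dataclass(frozen=True)
class ParcelAtlas:
    """72 pseudo-anatomical parcels: two mirrored hemispheric clusters."""

    parcel_ids: tuple[str, ...]
    centroids: np.ndarray  # (72, 3), arbitrary units
    hemispheres: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.parcel_ids) != N_PARCELS:
            raise ValueError(f"atlas must hold {N_PARCELS} parcels")
        c = np.asarray(self.centroids)
        if c.shape != (N_PARCELS, 3):
            raise ValueError("centroids must be (72, 3)")
        if np.unique(c, axis=0).shape[0] != N_PARCELS:
            raise ValueError("centroids must be pairwise distinct")


def make_atlas(seed: int = 0) -> ParcelAtlas:
    """Reproducible atlas: 36 left-hemisphere centroids mirrored to the right."""
    rng = np.random.default_rng(seed)
    left = rng.normal(loc=(-4.0, 0.0, 0.0), scale=(1.5, 2.5, 2.5), size=(36, 3))
    right = left * np.array([-1.0, 1.0, 1.0])
    centroids = np.vstack([left, right])
    ids = tuple(f"L{i:02d}" for i in range(36)) + tuple(f"R{i:02d}" for i in range(36))
    hemis = ("L",) * 36 + ("R",) * 36
    return ParcelAtlas(ids, centroids, hemis)


def parcel_neighbors(atlas: ParcelAtlas, k: int = 5) -> np.ndarray:
    """k nearest other parcels per parcel, by Euclidean centroid distance.

    Returns an (n_parcels, k) index array; a parcel is never its own
    neighbour.  Exact distance ties are broken by parcel index (with a
    warning), which only matters for degenerate synthetic geometries.
    """
    c = np.asarray(atlas.centroids)
    n = c.shape[0]
    if not 0 < k < n:
        raise ValueError("k must be in [1, n_parcels)")
    d = np.linalg.norm(c[:, None, :] - c[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    # stable argsort => ties resolved by parcel id
    order = np.argsort(d, axis=1, kind="stable")
    finite_ties = (d[:, :, None] == d[:, None, :]) & np.isfinite(d)[:, :, None]
    if (finite_ties.sum(axis=(1, 2)) > n).any():
        import warnings

        warnings.warn("tied centroid distances; breaking ties by parcel id")
    return order[:, :k]


@dataclass
class GenConfig:
    """Knobs of the generator; defaults are the reference study conditions.

    ``pattern_snr`` scales the evoked tone patterns against unit-scale
    noise; ``gamma_max`` is the within-triplet convergence reached in the
    final block (high regularity only); ``beta_pe`` couples trial gain in
    the encoder parcels to the standardised PE trajectory;
    ``synergy_pair`` plants one synergistic edge.
    """

    n_trials: int = 2400
    sfreq_hz: float = SFREQ_HZ
    epoch_window_s: tuple[float, float] = (EPOCH_START_S, EPOCH_STOP_S)
    pattern_snr: float = 1.0
    gamma_max: float = 0.6
    beta_pe: float = 0.5
    encoder_parcels: tuple[int, ...] | None = None  # None: anchor's region
    encoder_anchor: int = 20
    encoder_offset: float = 1.0
    synergy_pair: tuple[int, int, float, float] = (10, 46, 3.0, 2.0)
    noise_spatial_scale: float = 2.0
    ar1_coef: float = 0.0
    kernel_peak_s: float = 0.100
    kernel_sd_s: float = 0.020
    morph_band_s: tuple[float, float] = (0.110, 0.130)
    n_blocks: int = 5
    seed: int = 0
    n_subjects: int = 24

    def __post_init__(self) -> None:
        lo, hi = self.epoch_window_s
        if not (lo <= -0.050 and hi >= 0.120):
            raise ValueError(
                "epoch window must contain the -50-0 ms baseline and the "
                "90-120 ms analysis windows"
            )
        for name in ("pattern_snr", "gamma_max", "beta_pe", "noise_spatial_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0 <= self.gamma_max <= 1:
            raise ValueError("gamma_max must lie in [0, 1]")

    @property
    def times(self) -> np.ndarray:
        lo, hi = self.epoch_window_s
        n = int(round((hi - lo) * self.sfreq_hz)) + 1
        return lo + np.arange(n) / self.sfreq_hz


@dataclass
class EpochArray:
    """Source-level epochs (trials × parcels × time) with trial metadata."""

    data: np.ndarray
    times: np.ndarray
    tone: np.ndarray  # tone index per trial
    triplet_id: np.ndarray
    block: np.ndarray  # 1..n_blocks, contiguous equal partitions
    condition: str
    pe: np.ndarray  # scalar PE aligned to the eliciting tone; NaN for trial 0

    def __post_init__(self) -> None:
        n = self.data.shape[0]
        for name in ("tone", "triplet_id", "block", "pe"):
            if getattr(self, name).shape[0] != n:
                raise ValueError(f"trial_meta field {name} length mismatch")
        if self.data.shape[2] != self.times.size:
            raise ValueError("time axis mismatch")

    @property
    def n_trials(self) -> int:
        return int(self.data.shape[0])

    @property
    def n_parcels(self) -> int:
        return int(self.data.shape[1])

    def time_window(self, lo: float, hi: float) -> np.ndarray:
        """Indices of samples with lo ≤ t ≤ hi (inclusive, 1e-9 slack)."""
        idx = np.flatnonzero((self.times >= lo - 1e-9) & (self.times <= hi + 1e-9))
        if idx.size == 0:
            raise ValueError(f"window ({lo}, {hi}) outside epoch range")
        return idx


def encoder_region(atlas: ParcelAtlas, anchor: int, k: int = 5) -> tuple[int, ...]:
    """The PE-encoder parcels: a spatially contiguous region (anchor plus
    its k nearest neighbours, i.e. exactly one searchlight)."""
    nbrs = parcel_neighbors(atlas, k)
    return (int(anchor),) + tuple(int(p) for p in nbrs[anchor])


def _block_ids(n_trials: int, n_blocks: int) -> np.ndarray:
    edges = np.linspace(0, n_trials, n_blocks + 1).astype(int)
    block = np.empty(n_trials, dtype=np.int64)
    for b in range(n_blocks):
        block[edges[b] : edges[b + 1]] = b + 1
    return block


def _spatial_noise_chol(atlas: ParcelAtlas, scale: float) -> np.ndarray:
    c = np.asarray(atlas.centroids)
    d = np.linalg.norm(c[:, None, :] - c[None, :, :], axis=-1)
    cov = np.exp(-d / max(scale, 1e-9))
    cov += 1e-6 * np.eye(cov.shape[0])
    return np.linalg.cholesky(cov)


def generate_epochs(
    seq: Sequence,
    trace: ObserverTrace,
    atlas: ParcelAtlas,
    cfg: GenConfig,
) -> EpochArray:
    """Simulate one subject/condition's epochs from a sequence and PE trace.

    Trials are the first ``cfg.n_trials`` tone presentations of ``seq``.
    The PE of trial k (k ≥ 1) is the scalar error elicited by tone k, i.e.
    entry k−1 of the trace; trial 0 carries NaN and is dropped by the
    encoding analyses.
    """
    if len(trace) != len(seq) - 1:
        raise ValueError("trace length must equal len(seq) - 1")
    n_trials = cfg.n_trials
    if n_trials > len(seq):
        raise ValueError("n_trials exceeds sequence length")

    rng = np.random.default_rng(cfg.seed)
    times = cfg.times
    n_t = times.size
    n_p = N_PARCELS

    tone = seq.tones[:n_trials].copy()
    triplet_id = seq.triplet_ids[:n_trials].copy()
    block = _block_ids(n_trials, cfg.n_blocks)

    pe = np.full(n_trials, np.nan)
    pe[1:] = trace.pe[: n_trials - 1]
    pe_z = np.zeros(n_trials)
    finite = np.isfinite(pe)
    mu, sd = pe[finite].mean(), pe[finite].std()
    pe_z[finite] = (pe[finite] - mu) / (sd if sd > 0 else 1.0)

    # evoked kernel and the learning-morph band
    kernel = np.exp(-0.5 * ((times - cfg.kernel_peak_s) / cfg.kernel_sd_s) ** 2)
    band = (times >= cfg.morph_band_s[0] - 1e-9) & (times <= cfg.morph_band_s[1] + 1e-9)

    encoders = (
        list(cfg.encoder_parcels)
        if cfg.encoder_parcels is not None
        else list(encoder_region(atlas, cfg.encoder_anchor))
    )
    pi, pj, shared_sd, coupling = cfg.synergy_pair
    if {pi, pj} & set(encoders):
        import warnings

        warnings.warn("synergy pair overlaps the encoder region")

    # tone-specific parcel patterns and triplet centroids; encoder parcels
    # additionally carry a consistent-polarity evoked offset so the
    # multiplicative PE gain is visible to correlation-based estimators
    patterns = rng.normal(size=(12, n_p)) * cfg.pattern_snr
    patterns[:, encoders] += cfg.encoder_offset * cfg.pattern_snr
    inventory = seq.triplet_inventory()
    centroid_of_tone = patterns.copy()
    if seq.regularity == "high" and len(inventory) == 4:
        for trip in inventory:
            cen = patterns[list(trip)].mean(axis=0)
            for t in trip:
                centroid_of_tone[t] = cen

    # per-trial morph coefficient: linear 0 -> gamma_max over blocks (high only)
    if seq.regularity == "high" and cfg.n_blocks > 1:
        gamma = cfg.gamma_max * (block - 1) / (cfg.n_blocks - 1)
    else:
        gamma = np.zeros(n_trials)

    base = patterns[tone]  # (trials, parcels)
    morphed = base + gamma[:, None] * (centroid_of_tone[tone] - base)

    # gain on encoder parcels coupled to standardised PE
    gain = np.ones((n_trials, n_p))
    if cfg.beta_pe:
        gain[:, encoders] = (1.0 + cfg.beta_pe * pe_z)[:, None]

    sig = np.empty((n_trials, n_p, n_t))
    out_band = base[:, :, None] * kernel[None, None, :]
    sig[...] = out_band
    if band.any():
        sig[:, :, band] = morphed[:, :, None] * kernel[None, None, band]
    sig *= gain[:, :, None]

    # planted synergistic pair: only (parcel_i - parcel_j) tracks the PE
    if shared_sd or coupling:
        shared = rng.normal(scale=shared_sd, size=n_trials)
        sig[:, pi, :] += (shared + coupling * pe_z)[:, None] * kernel[None, :]
        sig[:, pj, :] += shared[:, None] * kernel[None, :]

    # spatially correlated Gaussian noise, optional AR(1) in time
    chol = _spatial_noise_chol(atlas, cfg.noise_spatial_scale)
    white = rng.standard_normal(size=(n_trials, n_p, n_t))
    if cfg.ar1_coef:
        rho = cfg.ar1_coef
        for k in range(1, n_t):
            white[:, :, k] = rho * white[:, :, k - 1] + np.sqrt(1 - rho**2) * white[:, :, k]
    noise = np.einsum("pq,nqt->npt", chol, white)
    data = sig + noise

    return EpochArray(data, times, tone, triplet_id, block, seq.regularity, pe)


def generate_subjects(
    seq: Sequence,
    trace: ObserverTrace,
    atlas: ParcelAtlas,
    cfg: GenConfig,
    n_subjects: int | None = None,
) -> list[EpochArray]:
    """Independent virtual subjects via per-subject seed offsets."""
    n_subjects = cfg.n_subjects if n_subjects is None else n_subjects
    out = []
    for s in range(n_subjects):
        sub_cfg = _replace_seed(cfg, (cfg.seed + 7919 * (s + 1)) % (2**31 - 1))
        out.append(generate_epochs(seq, trace, atlas, sub_cfg))
    return out


def _replace_seed(cfg: GenConfig, seed: int) -> GenConfig:
    from dataclasses import replace

    return replace(cfg, seed=seed)
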