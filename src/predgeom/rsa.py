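"""Representational similarity analysis with the cross-validated
Mahalanobis (crossnobis) distance.

RDMs are computed per learning block and per time sample with a 10-fold
cross-validation scheme: for tones a, b and fold f,

    d_f(a, b) = (μ_a^train − μ_b^train)ᵀ Σ̂⁻¹ (μ_a^test − μ_b^test)

with Σ̂ the Ledoit–Wolf-shrunk covariance of the training-set residuals
(trial minus its tone mean, pooled over all tones).  Averaging over folds
gives an unbiased estimate of the squared Mahalanobis distance, which may
legitimately be negative under the null.  RDM entries are then reordered
so that the four 3×3 diagonal blocks collect the within-triplet pairs of
the high-regularity inventory, summarised as within/between means and a
model-based Spearman fit, and regressed on the block counter 1…5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr
from sklearn.covariance import ledoit_wolf

from .synthetic_data import EpochArray, ParcelAtlas, parcel_neighbors

__all__ = [
    "RDMSeries",
    "GeometrySummary",
    "theoretical_rdm",
    "split_blocks",
    "cvmd",
    "cvmd_rdm",
    "triplet_order",
    "order_rdm",
    "within_between",
    "model_rsa",
    "block_slope",
    "geometry_summary",
    "searchlight_rsa",
]

N_TONES = 12
N_BLOCKS = 5
N_FOLDS = 10


@dataclass
class RDMSeries:
    """cvMD RDMs, shape (blocks, time, 12, 12), plus the tone ordering."""

    values: np.ndarray
    times: np.ndarray
    ordering: np.ndarray  # permutation mapping RDM axes to triplet order


@dataclass
class GeometrySummary:
    """Within/between-triplet means and model fit per (block, time)."""

    within: np.ndarray  # (blocks, time)
    between: np.ndarray
    model_rho: np.ndarray
    times: np.ndarray

    def slopes(self) -> dict[str, np.ndarray]:
        """Time-resolved OLS slopes of each summary across blocks."""
        return {
            "within": _slopes_along_blocks(self.within),
            "between": _slopes_along_blocks(self.between),
            "model_rho": _slopes_along_blocks(self.model_rho),
        }


def theoretical_rdm() -> np.ndarray:
    """Model RDM: 0 for same-triplet tone pairs, 1 otherwise (triplet order)."""
    m = np.ones((N_TONES, N_TONES))
    for b in range(4):
        m[3 * b : 3 * b + 3, 3 * b : 3 * b + 3] = 0.0
    return m


def split_blocks(epochs: EpochArray, n_blocks: int = N_BLOCKS) -> np.ndarray:
    """Contiguous equal partition of trials into blocks; returns 1-based ids.

    If the trial count is not divisible the final block absorbs the
    remainder (with a warning).
    """
    n = epochs.n_trials
    if n_blocks > n:
        raise ValueError("more blocks than trials")
    if n % n_blocks:
        warnings.warn("trials not divisible by n_blocks; last block absorbs remainder")
    size = n // n_blocks
    block = np.minimum(np.arange(n) // size, n_blocks - 1) + 1
    return block


def _fold_ids(tones: np.ndarray, n_folds: int) -> np.ndarray:
    """Stratified-by-tone folds, contiguous chunks in trial order per tone."""
    folds = np.empty(tones.size, dtype=np.int64)
    for t in np.unique(tones):
        idx = np.flatnonzero(tones == t)
        if idx.size < n_folds:
            raise ValueError(
                f"tone {t} has only {idx.size} trials; need >= {n_folds} per fold"
            )
        edges = np.linspace(0, idx.size, n_folds + 1).astype(int)
        for f in range(n_folds):
            folds[idx[edges[f] : edges[f + 1]]] = f
    return folds


def cvmd(
    X: np.ndarray, tones: np.ndarray, n_folds: int = N_FOLDS
) -> np.ndarray:
    """Cross-validated Mahalanobis RDM from one (trials × features) slice.

    Returns a symmetric 12×12 matrix (tone-index order, zero diagonal).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("X must be (trials, >=2 features)")
    folds = _fold_ids(tones, n_folds)
    labels = np.arange(N_TONES)
    rdm = np.zeros((N_TONES, N_TONES))
    for f in range(n_folds):
        te = folds == f
        tr = ~te
        Xtr, ttr = X[tr], tones[tr]
        Xte, tte = X[te], tones[te]
        mu_tr = np.empty((N_TONES, X.shape[1]))
        mu_te = np.empty((N_TONES, X.shape[1]))
        resid = Xtr.copy()
        for t in labels:
            mtr = ttr == t
            mte = tte == t
            if not mtr.any() or not mte.any():
                raise ValueError(f"tone {t} missing from a fold (stratification error)")
            mu_tr[t] = Xtr[mtr].mean(axis=0)
            mu_te[t] = Xte[mte].mean(axis=0)
            resid[mtr] -= mu_tr[t]
        cov, _ = ledoit_wolf(resid, assume_centered=True)
        try:
            prec = np.linalg.inv(cov)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "shrunk covariance singular despite Ledoit-Wolf regularisation"
            ) from exc
        dtr = mu_tr[:, None, :] - mu_tr[None, :, :]
        dte = mu_te[:, None, :] - mu_te[None, :, :]
        rdm += np.einsum("abi,ij,abj->ab", dtr, prec, dte)
    rdm /= n_folds
    return 0.5 * (rdm + rdm.T)


def cvmd_rdm(
    epochs: EpochArray,
    features: np.ndarray | None = None,
    n_folds: int = N_FOLDS,
    n_blocks: int = N_BLOCKS,
    time_indices: np.ndarray | None = None,
) -> RDMSeries:
    """Block- and time-resolved crossnobis RDMs over a parcel subset."""
    feats = np.arange(epochs.n_parcels) if features is None else np.asarray(features)
    tidx = np.arange(epochs.times.size) if time_indices is None else np.asarray(time_indices)
    block = split_blocks(epochs, n_blocks)
    values = np.empty((n_blocks, tidx.size, N_TONES, N_TONES))
    for b in range(1, n_blocks + 1):
        sel = block == b
        Xb = epochs.data[np.ix_(sel, feats, tidx)]
        tb = epochs.tone[sel]
        for k in range(tidx.size):
            values[b - 1, k] = cvmd(Xb[:, :, k], tb, n_folds)
    return RDMSeries(values, epochs.times[tidx], np.arange(N_TONES))


def triplet_order(inventory: list[tuple[int, int, int]]) -> np.ndarray:
    """Tone permutation (t1 tone1, t1 tone2, t1 tone3, t2 tone1, …)."""
    if len(inventory) != 4:
        raise ValueError("inventory must hold 4 triplets")
    flat = [t for trip in inventory for t in trip]
    if sorted(flat) != list(range(N_TONES)):
        raise ValueError("inventory must disjointly cover all 12 tones")
    return np.array(flat)


def order_rdm(rdm: np.ndarray, inventory: list[tuple[int, int, int]]) -> np.ndarray:
    """Permute RDM rows/columns into the high-regularity triplet order."""
    perm = triplet_order(inventory)
    return rdm[np.ix_(perm, perm)]


def _within_mask() -> np.ndarray:
    mask = np.zeros((N_TONES, N_TONES), dtype=bool)
    for b in range(4):
        mask[3 * b : 3 * b + 3, 3 * b : 3 * b + 3] = True
    np.fill_diagonal(mask, False)
    return mask


def within_between(rdm_ordered: np.ndarray) -> tuple[float, float]:
    """Mean cvMD inside the four 3×3 triplet blocks vs outside them.

    Self-pairs (the exact diagonal) are excluded; the between mean uses
    the upper triangle only (the matrix is symmetric).
    """
    w_mask = _within_mask()
    iu = np.triu_indices(N_TONES, 1)
    upper_within = w_mask[iu]
    within = float(rdm_ordered[iu][upper_within].mean())
    between = float(rdm_ordered[iu][~upper_within].mean())
    return within, between


def model_rsa(rdm_ordered: np.ndarray, theory: np.ndarray | None = None) -> float:
    """Spearman correlation of the RDM upper triangle with the model RDM.

    Positive values indicate within-triplet distances below between-triplet
    distances.  Returns NaN (with a warning) for zero-variance RDMs.
    """
    theory = theoretical_rdm() if theory is None else theory
    iu = np.triu_indices(N_TONES, 1)
    x = rdm_ordered[iu]
    if np.std(x) == 0:
        warnings.warn("zero-variance RDM; model fit undefined")
        return float("nan")
    rho, _ = spearmanr(x, theory[iu])
    return float(rho)


def block_slope(values: np.ndarray) -> float:
    """OLS slope of 5 block values against the counter x = 1…5."""
    v = np.asarray(values, dtype=float)
    if v.size != N_BLOCKS:
        raise ValueError("expected one value per block")
    if not np.all(np.isfinite(v)):
        warnings.warn("non-finite block values; slope undefined")
        return float("nan")
    x = np.arange(1, N_BLOCKS + 1, dtype=float)
    xc = x - x.mean()
    return float((xc @ (v - v.mean())) / (xc @ xc))


def _slopes_along_blocks(arr: np.ndarray) -> np.ndarray:
    """OLS slope along axis 0 (blocks) for every remaining index."""
    x = np.arange(1, arr.shape[0] + 1, dtype=float)
    xc = x - x.mean()
    centred = arr - arr.mean(axis=0, keepdims=True)
    return np.tensordot(xc, centred, axes=(0, 0)) / (xc @ xc)


def geometry_summary(
    series: RDMSeries, inventory: list[tuple[int, int, int]]
) -> GeometrySummary:
    """Within/between means and model-RSA fit for every (block, time) RDM."""
    n_b, n_t = series.values.shape[:2]
    within = np.empty((n_b, n_t))
    between = np.empty((n_b, n_t))
    rho = np.empty((n_b, n_t))
    for b in range(n_b):
        for k in range(n_t):
            ordered = order_rdm(series.values[b, k], inventory)
            within[b, k], between[b, k] = within_between(ordered)
            rho[b, k] = model_rsa(ordered)
    return GeometrySummary(within, between, rho, series.times)


def searchlight_rsa(
    epochs: EpochArray,
    atlas: ParcelAtlas,
    inventory: list[tuple[int, int, int]],
    window: tuple[float, float] = (0.110, 0.120),
    k_neighbors: int = 5,
    n_folds: int = N_FOLDS,
    n_blocks: int = N_BLOCKS,
) -> dict[str, np.ndarray]:
    """Per-parcel block slopes of the geometry summaries in a time window.

    Each searchlight uses the parcel plus its ``k_neighbors`` nearest
    neighbours as features, with the data averaged over the window samples
    before the crossnobis computation.  Returns per-parcel slope maps
    (length 72) for within, between and the model fit.
    """
    tidx = epochs.time_window(*window)
    nbrs = parcel_neighbors(atlas, k_neighbors)
    block = split_blocks(epochs, n_blocks)
    Xw = epochs.data[:, :, tidx].mean(axis=2)  # (trials, parcels)
    maps = {k: np.empty(epochs.n_parcels) for k in ("within", "between", "model_rho")}
    for p in range(epochs.n_parcels):
        feats = np.concatenate([[p], nbrs[p]])
        within = np.empty(n_blocks)
        between = np.empty(n_blocks)
        rho = np.empty(n_blocks)
        for b in range(1, n_blocks + 1):
            sel = block == b
            rdm = cvmd(Xw[np.ix_(sel, feats)], epochs.tone[sel], n_folds)
            ordered = order_rdm(rdm, inventory)
            within[b - 1], between[b - 1] = within_between(ordered)
            rho[b - 1] = model_rsa(ordered)
        maps["within"][p] = block_slope(within)
        maps["between"][p] = block_slope(between)
        maps["model_rho"][p] = block_slope(rho)
    return maps
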