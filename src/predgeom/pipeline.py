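"""Desk-scale orchestration of the full study: sequences → observer →
synthetic epochs → RSA → GCMI → PID → group statistics → report.

``run_all`` executes the chain for a cohort of virtual subjects in both
regularity conditions and writes per-stage CSV/JSON outputs plus a
headline report.  The demo defaults are deliberately reduced (200
triplets, 8 subjects, 1000 permutations, 5 folds) so a full run fits on
one CPU in minutes; the study-scale parameters (800 triplets, 24
subjects, 10 000 permutations, 10 folds) are plain config values.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import infoenc, io, pid, rsa, stats
from .observer import fit_decay_models, run_observer
from .sequences import generate_sequence
from .synthetic_data import GenConfig, make_atlas, generate_epochs

__all__ = ["RunConfig", "run_all", "representational_shift", "load_config"]


@dataclass
class RunConfig:
    """Resolved configuration of one full run (YAML-loadable)."""

    n_triplets: int = 200
    seq_seed: int = 11
    variant: int = 0
    pe_mode: str = "entropy_weighted_norm"
    n_subjects: int = 8
    n_blocks: int = 5
    folds: int = 5
    rsa_window: tuple[float, float] = (0.110, 0.120)
    pid_window: tuple[float, float] = (0.090, 0.120)
    baseline: tuple[float, float] = (-0.050, 0.0)
    n_perm: int = 1000
    seed: int = 0
    decay_restarts: int = 100
    gen: GenConfig = field(default_factory=GenConfig)

    def __post_init__(self) -> None:
        if isinstance(self.gen, dict):
            self.gen = GenConfig(**self.gen)
        self.rsa_window = tuple(self.rsa_window)
        self.pid_window = tuple(self.pid_window)
        self.baseline = tuple(self.baseline)
        # trials follow the sequence length
        self.gen = replace(self.gen, n_trials=3 * self.n_triplets, seed=self.seed)


def load_config(path: str | Path) -> RunConfig:
    import yaml

    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    return RunConfig(**raw)


def _adaptive_folds(tones: np.ndarray, block: np.ndarray, requested: int) -> int:
    """Largest usable fold count given the rarest tone in any block."""
    min_count = min(
        np.bincount(tones[block == b], minlength=12).min()
        for b in np.unique(block)
    )
    folds = min(requested, int(min_count))
    if folds < requested:
        warnings.warn(
            f"reducing folds from {requested} to {folds} (rarest tone/block count)"
        )
    if folds < 2:
        raise ValueError("not enough trials per tone per block for cross-validation")
    return folds


def representational_shift(
    model_slope_maps: np.ndarray, cluster_parcels: np.ndarray
) -> np.ndarray:
    """Per-subject representational-shift scalar.

    The shift is the model-RSA block slope (how strongly the
    within-triplet geometry emerges over learning) averaged over the
    parcels of a cluster; ``model_slope_maps`` is (subjects × parcels).
    """
    cluster_parcels = np.asarray(cluster_parcels)
    if cluster_parcels.size == 0:
        raise ValueError("cluster must contain at least one parcel")
    return np.asarray(model_slope_maps)[:, cluster_parcels].mean(axis=1)


def _subject_analyses(epochs, atlas, inventory, cfg: RunConfig) -> dict:
    folds = _adaptive_folds(epochs.tone, rsa.split_blocks(epochs, cfg.n_blocks), cfg.folds)
    tidx = epochs.time_window(*cfg.rsa_window)
    # whole-brain RSA on the window average
    Xw = epochs.data[:, :, tidx].mean(axis=2, keepdims=True)
    win_epochs = replace_data(epochs, Xw, epochs.times[tidx[:1]])
    series = rsa.cvmd_rdm(win_epochs, n_folds=folds, n_blocks=cfg.n_blocks)
    summ = rsa.geometry_summary(series, inventory)
    slopes = summ.slopes()
    sl_maps = rsa.searchlight_rsa(
        epochs, atlas, inventory, cfg.rsa_window, n_folds=folds, n_blocks=cfg.n_blocks
    )
    gcmi_map = infoenc.searchlight_gcmi(
        epochs, atlas, window=cfg.pid_window, baseline=cfg.baseline
    )
    net = pid.pid_network(epochs, window=cfg.pid_window, baseline=cfg.baseline)
    return {
        "within_slope": float(slopes["within"][0]),
        "between_slope": float(slopes["between"][0]),
        "model_slope": float(slopes["model_rho"][0]),
        "searchlight_model_slope": sl_maps["model_rho"],
        "searchlight_within_slope": sl_maps["within"],
        "gcmi_map": gcmi_map,
        "global_redundancy": net.global_redundancy,
        "global_synergy": net.global_synergy,
        "synergy": net.synergy,
        "redundancy": net.redundancy,
        "centrality_synergy": net.centrality_synergy,
        "centrality_redundancy": net.centrality_redundancy,
    }


def replace_data(epochs, data, times):
    """EpochArray with substituted data/time axes (metadata preserved)."""
    from .synthetic_data import EpochArray

    return EpochArray(
        data, times, epochs.tone, epochs.triplet_id, epochs.block,
        epochs.condition, epochs.pe,
    )


def run_all(cfg: RunConfig, out_dir: str | Path) -> dict:
    """Execute the full pipeline and write stage outputs plus a report.

    Returns the report dict: headline indicators (slope contrasts, PE
    encoding, synergy/redundancy contrast, shift–encoding correlations)
    with every number also persisted under ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    timings: dict[str, float] = {}
    report: dict = {"config": _cfg_dict(cfg), "stages": {}}

    # --- sequences and observer -------------------------------------------
    seqs = {
        "high": generate_sequence("high", cfg.n_triplets, cfg.seq_seed, variant=cfg.variant),
        "low": generate_sequence("low", cfg.n_triplets, cfg.seq_seed + 1),
    }
    traces = {c: run_observer(s, cfg.pe_mode) for c, s in seqs.items()}
    for c in seqs:
        io.save_sequence(seqs[c], out / f"seq_{c}.tsv")
        io.save_trace(traces[c], out / f"trace_{c}.tsv")
    decay = fit_decay_models(traces["high"].pe, cfg.decay_restarts, seed=cfg.seed)
    report["stages"]["observer"] = {
        "final_accuracy": {c: float(traces[c].accuracy[-1]) for c in traces},
        "mean_pe": {c: float(traces[c].pe.mean()) for c in traces},
        "decay_fit_high": {
            "exp_bic": decay.exp_bic,
            "lin_bic": decay.lin_bic,
            "winner": decay.winner,
            "exp_params": list(decay.exp_params),
        },
    }
    timings["sequences_observer"] = time.time() - t0

    # --- synthetic cohort and per-subject analyses ------------------------
    atlas = make_atlas(cfg.seed)
    inventory = seqs["high"].triplet_inventory()
    per_subject: dict[str, list[dict]] = {"high": [], "low": []}
    t1 = time.time()
    for cond in ("high", "low"):
        for s in range(cfg.n_subjects):
            sub_seed = (cfg.seed + 7919 * (s + 1) + (0 if cond == "high" else 104729)) % (
                2**31 - 1
            )
            gen = replace(cfg.gen, seed=sub_seed)
            epochs = generate_epochs(seqs[cond], traces[cond], atlas, gen)
            per_subject[cond].append(_subject_analyses(epochs, atlas, inventory, cfg))
    timings["simulate_and_subject_analyses"] = time.time() - t1

    # --- group statistics --------------------------------------------------
    t2 = time.time()

    def stack(cond: str, key: str) -> np.ndarray:
        return np.asarray([d[key] for d in per_subject[cond]])

    hr_within = stack("high", "within_slope")
    lr_within = stack("low", "within_slope")
    hr_model = stack("high", "model_slope")
    lr_model = stack("low", "model_slope")

    from scipy.stats import ttest_rel

    t_within = ttest_rel(hr_within, lr_within)
    t_model = ttest_rel(hr_model, lr_model)

    sl_hr = stack("high", "searchlight_model_slope")
    sl_lr = stack("low", "searchlight_model_slope")
    adj = stats.spatial_adjacency(atlas.centroids)
    clus = stats.cluster_permutation_paired(
        sl_hr, sl_lr, adjacency=adj, n_perm=cfg.n_perm, seed=cfg.seed
    )
    if clus.clusters:
        biggest = int(np.argmax(np.abs(clus.cluster_stats)))
        cluster_parcels = clus.clusters[biggest]
        cluster_p = float(clus.p_values[biggest])
    else:
        cluster_parcels = np.array([int(np.argmax(np.abs(clus.t_obs)))])
        cluster_p = float("nan")
        warnings.warn("no suprathreshold searchlight cluster; using peak parcel")

    shift = representational_shift(sl_hr, cluster_parcels)
    gcmi_hr = stack("high", "gcmi_map")
    enc = gcmi_hr[:, cluster_parcels].mean(axis=1)
    cent_syn = stack("high", "centrality_synergy")[:, cluster_parcels].mean(axis=1)
    cent_red = stack("high", "centrality_redundancy")[:, cluster_parcels].mean(axis=1)

    r_enc, p_enc = stats.correlate_bonferroni(enc, shift, m_tests=2)
    r_syn, p_syn = stats.correlate_bonferroni(cent_syn, shift, m_tests=2)
    r_red, p_red = stats.correlate_bonferroni(cent_red, shift, m_tests=2)

    syn_vs_red = {
        cond: {
            "t": float(ttest_rel(stack(cond, "global_synergy"), stack(cond, "global_redundancy")).statistic),
            "p": float(ttest_rel(stack(cond, "global_synergy"), stack(cond, "global_redundancy")).pvalue),
            "d": stats.cohens_d_paired(
                stack(cond, "global_synergy"), stack(cond, "global_redundancy")
            ),
        }
        for cond in ("high", "low")
    }

    nbs = stats.nbs_paired(
        stack("high", "synergy"),
        np.zeros_like(stack("high", "synergy")),
        n_perm=min(cfg.n_perm, 500),
        seed=cfg.seed,
    )

    report["stages"]["group"] = {
        "within_slope": {
            "high_mean": float(hr_within.mean()),
            "low_mean": float(lr_within.mean()),
            "t": float(t_within.statistic),
            "p": float(t_within.pvalue),
            "d": stats.cohens_d_paired(hr_within, lr_within),
        },
        "model_slope": {
            "high_mean": float(hr_model.mean()),
            "low_mean": float(lr_model.mean()),
            "t": float(t_model.statistic),
            "p": float(t_model.pvalue),
            "d": stats.cohens_d_paired(hr_model, lr_model),
        },
        "searchlight_cluster": {
            "parcels": cluster_parcels.tolist(),
            "p": cluster_p,
        },
        "correlations": {
            "shift_vs_gcmi": {"r": r_enc, "p_bonferroni": p_enc},
            "shift_vs_synergy_centrality": {"r": r_syn, "p_bonferroni": p_syn},
            "shift_vs_redundancy_centrality": {"r": r_red, "p_bonferroni": p_red},
        },
        "synergy_vs_redundancy": syn_vs_red,
        "nbs_synergy_components": {
            "sizes": nbs.component_sizes.tolist(),
            "p_values": nbs.p_values.tolist(),
        },
    }
    timings["group_stats"] = time.time() - t2
    report["timings_s"] = {k: round(v, 2) for k, v in timings.items()}
    report["seeds"] = {"seq_seed": cfg.seq_seed, "seed": cfg.seed}

    # persist stage tables
    rows = []
    for cond in ("high", "low"):
        for s, d in enumerate(per_subject[cond]):
            rows.append(
                {
                    "condition": cond,
                    "subject": s,
                    "within_slope": d["within_slope"],
                    "between_slope": d["between_slope"],
                    "model_slope": d["model_slope"],
                    "global_redundancy": d["global_redundancy"],
                    "global_synergy": d["global_synergy"],
                }
            )
    pd.DataFrame(rows).to_csv(out / "subject_summaries.csv", index=False)
    io.save_json(report, out / "report.json")
    (out / "resolved_config.json").write_text(json.dumps(_cfg_dict(cfg), indent=2))
    return report


def _cfg_dict(cfg: RunConfig) -> dict:
    d = asdict(cfg)
    return d
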