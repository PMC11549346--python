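"""Serialisation: sequences as TSV + JSON sidecar, observer traces as TSV,
epoch arrays and information networks as HDF5, stats results as JSON."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .observer import ObserverTrace
from .pid import InfoNetwork
from .sequences import Sequence, ToneSet, sequence_to_frame
from .synthetic_data import EpochArray

__all__ = [
    "save_sequence",
    "load_sequence",
    "save_trace",
    "load_trace",
    "save_epochs",
    "load_epochs",
    "save_network",
    "load_network",
    "save_json",
]


def save_sequence(seq: Sequence, path: str | Path) -> Path:
    """Write a tone stream as TSV with a JSON sidecar (<path>.json)."""
    path = Path(path)
    sequence_to_frame(seq).to_csv(path, sep="\t", index=False)
    sidecar = {
        "regularity": seq.regularity,
        "seed": seq.seed,
        "toneset": {
            "frequencies_hz": list(seq.toneset.frequencies_hz),
            "labels": list(seq.toneset.labels),
        },
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))
    return path


def load_sequence(path: str | Path) -> Sequence:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta = json.loads(Path(str(path) + ".json").read_text())
    ts = ToneSet(
        tuple(meta["toneset"]["frequencies_hz"]), tuple(meta["toneset"]["labels"])
    )
    return Sequence(
        df["tone_index"].to_numpy(),
        df["triplet_id"].to_numpy(),
        meta["regularity"],
        ts,
        meta.get("seed"),
    )


def save_trace(trace: ObserverTrace, path: str | Path) -> Path:
    """Trace as TSV; the trained weight matrix goes to <path stem>_W.csv."""
    path = Path(path)
    pd.DataFrame(
        {
            "transition": np.arange(len(trace)),
            "pe_scalar": trace.pe,
            "loss": trace.loss,
            "omega": trace.omega,
            "correct": trace.correct.astype(int),
            "accuracy": trace.accuracy,
        }
    ).to_csv(path, sep="\t", index=False)
    np.savetxt(path.with_name(path.stem + "_W.csv"), trace.W_final, delimiter=",")
    return path


def load_trace(path: str | Path, pe_mode: str = "entropy_weighted_norm") -> ObserverTrace:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    W = np.loadtxt(path.with_name(path.stem + "_W.csv"), delimiter=",")
    return ObserverTrace(
        df["pe_scalar"].to_numpy(),
        df["loss"].to_numpy(),
        df["omega"].to_numpy(),
        df["correct"].to_numpy().astype(bool),
        df["accuracy"].to_numpy(),
        W,
        pe_mode,
    )


def save_epochs(epochs: EpochArray, path: str | Path, **attrs) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, compression="gzip", compression_opts=1)
        f.create_dataset("time", data=epochs.times)
        g = f.create_group("trial_meta")
        g.create_dataset("tone", data=epochs.tone)
        g.create_dataset("triplet_id", data=epochs.triplet_id)
        g.create_dataset("block", data=epochs.block)
        g.create_dataset("pe", data=epochs.pe)
        f.attrs["condition"] = epochs.condition
        for k, v in attrs.items():
            f.attrs[k] = v
    return path


def load_epochs(path: str | Path) -> EpochArray:
    with h5py.File(path, "r") as f:
        return EpochArray(
            f["data"][...],
            f["time"][...],
            f["trial_meta/tone"][...],
            f["trial_meta/triplet_id"][...],
            f["trial_meta/block"][...],
            str(f.attrs["condition"]),
            f["trial_meta/pe"][...],
        )


def save_network(net: InfoNetwork, path: str | Path, **attrs) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("redundancy", data=net.redundancy)
        f.create_dataset("synergy", data=net.synergy)
        f.create_dataset("centrality_redundancy", data=net.centrality_redundancy)
        f.create_dataset("centrality_synergy", data=net.centrality_synergy)
        f.create_dataset("strength_redundancy", data=net.strength_redundancy)
        f.create_dataset("strength_synergy", data=net.strength_synergy)
        f.attrs["global_redundancy"] = net.global_redundancy
        f.attrs["global_synergy"] = net.global_synergy
        for k, v in attrs.items():
            f.attrs[k] = v
    return path


def load_network(path: str | Path) -> InfoNetwork:
    with h5py.File(path, "r") as f:
        return InfoNetwork(
            f["redundancy"][...],
            f["synergy"][...],
            float(f.attrs["global_redundancy"]),
            float(f.attrs["global_synergy"]),
            f["centrality_redundancy"][...],
            f["centrality_synergy"][...],
            f["strength_redundancy"][...],
            f["strength_synergy"][...],
        )


def save_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON-serialisable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, default=_default))
    return path
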