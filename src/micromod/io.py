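"""File interchange: HDF5 sessions, CSV spike/trial tables, TSV results."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .events import SpikeTrainSet, TrialTable
from .granger import BandGC, GCMatrix
from .layout import ArrayLayout
from .multilayer import MultilayerPartition
from .session import SessionRecording

__all__ = [
    "write_session_h5",
    "read_session_h5",
    "write_spikes_csv",
    "read_spikes_csv",
    "write_trials_csv",
    "read_trials_csv",
    "write_network_tsv",
    "read_network_tsv",
    "write_partition_tsv",
    "read_partition_tsv",
    "write_band_tsv",
    "write_json",
    "read_json",
]


def write_session_h5(path, rec: SessionRecording) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("lfp", data=rec.lfp.astype(np.float32))
        f.create_dataset("coords", data=rec.layout.coords)
        f.create_dataset("fs", data=float(rec.fs))
        f.create_dataset("retained_channels", data=rec.retained_channels)
        f.attrs["session_id"] = rec.session_id
        f.attrs["rows"] = rec.layout.rows
        f.attrs["cols"] = rec.layout.cols
        f.attrs["pitch"] = rec.layout.pitch


def read_session_h5(path) -> SessionRecording:
    with h5py.File(path, "r") as f:
        coords = np.array(f["coords"])
        coords.setflags(write=False)
        layout = ArrayLayout(
            rows=int(f.attrs["rows"]),
            cols=int(f.attrs["cols"]),
            pitch=float(f.attrs["pitch"]),
            coords=coords,
        )
        return SessionRecording(
            lfp=np.array(f["lfp"], dtype=float),
            fs=float(f["fs"][()]),
            layout=layout,
            retained_channels=np.array(f["retained_channels"]),
            session_id=str(f.attrs["session_id"]),
        )


def write_spikes_csv(path, spikes: SpikeTrainSet, units_path=None) -> None:
    spikes.spikes.to_csv(path, index=False, columns=["unit_id", "spike_time_s"])
    if units_path is not None:
        spikes.units.to_csv(units_path, index=False)


def read_spikes_csv(path, units_path=None) -> SpikeTrainSet:
    sp = pd.read_csv(path)
    if units_path is not None and Path(units_path).exists():
        units = pd.read_csv(units_path)
    else:
        units = pd.DataFrame({"unit_id": np.sort(sp["unit_id"].unique())})
    return SpikeTrainSet(spikes=sp, units=units)


def write_trials_csv(path, trials: TrialTable, baselines_path=None) -> None:
    trials.trials.to_csv(path, index=False, columns=["trial", "onset_s", "category", "correct"])
    if baselines_path is not None:
        write_json(baselines_path, {"baseline_periods": trials.baseline_periods})


def read_trials_csv(path, baselines_path=None) -> TrialTable:
    df = pd.read_csv(path)
    baselines = []
    if baselines_path is not None and Path(baselines_path).exists():
        baselines = [tuple(b) for b in read_json(baselines_path)["baseline_periods"]]
    return TrialTable(trials=df, baseline_periods=baselines)


def write_network_tsv(path, gcm: GCMatrix) -> None:
    n = gcm.n_channels
    rows = []
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            rows.append(
                {
                    "source": j,
                    "target": i,
                    "F": gcm.F[i, j],
                    "p": gcm.pvals[i, j] if gcm.pvals is not None else np.nan,
                    "significant": bool(gcm.mask[i, j]) if gcm.mask is not None else True,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_network_tsv(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    n = int(max(df["source"].max(), df["target"].max())) + 1
    a = np.zeros((n, n))
    a[df["target"].to_numpy(), df["source"].to_numpy()] = df["F"].to_numpy()
    return a


def write_partition_tsv(path, part: MultilayerPartition) -> None:
    n, S = part.labels.shape
    rows = [
        {"electrode": i, "layer": s, "community": int(part.labels[i, s])}
        for s in range(S)
        for i in range(n)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_partition_tsv(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    n = df["electrode"].max() + 1
    S = df["layer"].max() + 1
    labels = np.zeros((n, S), dtype=int)
    labels[df["electrode"].to_numpy(), df["layer"].to_numpy()] = df["community"].to_numpy()
    return labels


def write_band_tsv(path, band: BandGC) -> None:
    rows = []
    first = next(iter(band.values.values()))
    n = first.shape[0]
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            row = {"source": j, "target": i}
            for name, mat in band.values.items():
                row[name] = mat[i, j]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, cls=_NumpyEncoder))


def read_json(path):
    return json.loads(Path(path).read_text())
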