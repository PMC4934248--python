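"""Plain-text artifact formats: stream CSVs, matrix/label TSVs, model JSON."""

from __future__ import annotations

import json
import pathlib

import numpy as np
import pandas as pd

from .hmm import HMMParams
from .anomaly import OSVMModel
from .sensing import SensorStream

__all__ = [
    "write_stream_csv", "read_stream_csv",
    "write_dataset", "read_dataset",
    "write_matrix_tsv", "read_matrix_tsv",
    "write_labels_tsv", "read_labels_tsv",
    "write_detector", "read_detector",
]


def write_stream_csv(path, stream: SensorStream) -> None:
    """Stream CSV (`t,ch1..chM`) plus a metadata sidecar JSON next to it."""
    path = pathlib.Path(path)
    m, t = stream.values.shape
    df = pd.DataFrame(stream.values.T,
                      columns=[f"ch{j + 1}" for j in range(m)])
    df.insert(0, "t", np.arange(t) / stream.sampling_rate)
    df.to_csv(path, index=False, float_format="%.6f")
    side = dict(stream.metadata)
    side.setdefault("sampling_rate", stream.sampling_rate)
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(side, fh, indent=2, sort_keys=True)


def read_stream_csv(path) -> SensorStream:
    path = pathlib.Path(path)
    df = pd.read_csv(path)
    values = df[[c for c in df.columns if c != "t"]].to_numpy().T
    meta = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)
    fs = meta.get("sampling_rate")
    if fs is None:
        tcol = df["t"].to_numpy()
        fs = 1.0 / np.median(np.diff(tcol)) if len(tcol) > 1 else 25.0
    return SensorStream(values=values, sampling_rate=float(fs), metadata=meta)


def write_dataset(outdir, streams, prefix: str = "stream") -> pathlib.Path:
    """Write streams + sidecars and a JSON manifest; returns the manifest path."""
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, s in enumerate(streams):
        name = f"{prefix}_{i:04d}.csv"
        write_stream_csv(outdir / name, s)
        entries.append({"stream": name, "sidecar": name.replace(".csv", ".json")})
    manifest = outdir / "manifest.json"
    with open(manifest, "w") as fh:
        json.dump(entries, fh, indent=2)
    return manifest


def read_dataset(manifest_path) -> list[SensorStream]:
    manifest_path = pathlib.Path(manifest_path)
    with open(manifest_path) as fh:
        entries = json.load(fh)
    return [read_stream_csv(manifest_path.parent / e["stream"]) for e in entries]


def write_matrix_tsv(path, matrix: np.ndarray, ids=None) -> None:
    matrix = np.asarray(matrix)
    if ids is None:
        ids = [str(i) for i in range(matrix.shape[0])]
    pd.DataFrame(matrix, index=ids, columns=ids).to_csv(path, sep="\t")


def read_matrix_tsv(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t", index_col=0).to_numpy()


def write_labels_tsv(path, labels, ids=None) -> None:
    labels = np.asarray(labels)
    if ids is None:
        ids = [str(i) for i in range(len(labels))]
    pd.DataFrame({"sample": ids, "cluster": labels}).to_csv(path, sep="\t", index=False)


def read_labels_tsv(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t")["cluster"].to_numpy()


def write_detector(path, cluster_models: list[HMMParams], osvm: OSVMModel,
                   metadata: dict | None = None) -> None:
    """Serialize the trained detector (cluster HMMs + OSVM) to JSON."""
    payload = {
        "cluster_models": [m.to_dict() for m in cluster_models],
        "osvm": osvm.to_dict(),
        "metadata": metadata or {},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def read_detector(path):
    with open(path) as fh:
        payload = json.load(fh)
    models = [HMMParams.from_dict(d) for d in payload["cluster_models"]]
    return models, OSVMModel.from_dict(payload["osvm"]), payload.get("metadata", {})
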