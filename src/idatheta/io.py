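"""Plain-text I/O: epochs as columnar CSV with a JSON sidecar."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .spectral import EpochSet


def write_epochs(epochs: EpochSet, csv_path: str | Path) -> Path:
    """Write trials x channels x samples as long CSV + JSON sidecar.

    CSV columns: trial, sample, then one column per channel.  The sidecar
    (same stem, .json) records srate, channel names, window and padding so
    the EpochSet can be reconstructed exactly.
    """
    csv_path = Path(csv_path)
    n_trials, _, n_samples = epochs.data.shape
    idx = pd.MultiIndex.from_product(
        [range(1, n_trials + 1), range(n_samples)], names=["trial", "sample"])
    df = pd.DataFrame(
        epochs.data.transpose(0, 2, 1).reshape(-1, len(epochs.channels)),
        index=idx, columns=list(epochs.channels))
    df.to_csv(csv_path, float_format="%.6g")
    sidecar = {
        "srate": epochs.srate,
        "channels": list(epochs.channels),
        "window": list(epochs.window),
        "pad": epochs.pad,
        "n_trials": n_trials,
        "n_samples": n_samples,
    }
    side_path = csv_path.with_suffix(".json")
    side_path.write_text(json.dumps(sidecar, indent=2))
    return side_path


def read_epochs(csv_path: str | Path) -> EpochSet:
    """Inverse of :func:`write_epochs`."""
    csv_path = Path(csv_path)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    df = pd.read_csv(csv_path)
    channels = meta["channels"]
    data = (df[channels].to_numpy(float)
            .reshape(meta["n_trials"], meta["n_samples"], len(channels))
            .transpose(0, 2, 1))
    return EpochSet(data=data, srate=meta["srate"], channels=tuple(channels),
                    window=tuple(meta["window"]), pad=meta["pad"])


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable))


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if hasattr(o, "__dict__"):
        return o.__dict__
    return str(o)
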