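"""Plain-text input/output: TSV tables, square matrices, JSON summaries."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd


def write_table(df: pd.DataFrame, path):
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_matrix(values, path, labels=None):
    """Square matrix as TSV with an ROI header row/column."""
    values = np.asarray(values)
    if labels is None:
        labels = [f"roi{i:03d}" for i in range(values.shape[1])]
    df = pd.DataFrame(values, columns=labels)
    df.insert(0, "roi", labels[:values.shape[0]] if values.shape[0] == len(labels)
              else list(range(values.shape[0])))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_matrix(path):
    df = pd.read_csv(path, sep="\t")
    labels = list(df.columns[1:])
    return df.iloc[:, 1:].to_numpy(dtype=float), labels


def write_timecourse(values, path):
    """Volumes x regions matrix as headerless TSV."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, np.asarray(values, dtype=float), delimiter="\t", fmt="%.8g")


def read_timecourse(path):
    return np.loadtxt(path, delimiter="\t", ndmin=2)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        return super().default(o)


def write_json(obj, path):
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, cls=_NumpyEncoder)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
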