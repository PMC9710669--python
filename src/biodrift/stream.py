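"""Expression streams: ordered, labeled Z-scored expression profiles.

An :class:`ExpressionStream` is the in-memory form of the data stream the
online learner consumes: one Z-scored feature vector per sample, a class
label (breast-cancer subtype in the motivating application) and a source
tag identifying the cohort the profile came from.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class LabeledInstance:
    """One sample drawn from a stream."""

    x: np.ndarray          # feature vector, stream feature order
    y: int                 # class code into ``class_names``
    source: str            # cohort tag
    sample_id: str


@dataclass
class ExpressionStream:
    """A finite, ordered stream of labeled expression profiles.

    ``X`` is samples x features (float), ``y`` integer class codes into
    ``class_names``; ``sources`` carries the per-sample cohort tag.
    """

    feature_names: list[str]
    X: np.ndarray
    y: np.ndarray
    sources: np.ndarray
    class_names: list[str]
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        self.sources = np.asarray(self.sources, dtype=object)
        n, p = self.X.shape
        if p != len(self.feature_names):
            raise ValueError("X width does not match feature_names")
        if len(self.y) != n or len(self.sources) != n:
            raise ValueError("label/source length does not match X")
        if not self.sample_ids:
            self.sample_ids = [f"s{i:05d}" for i in range(n)]
        if len(self.y) and (self.y.min() < 0 or self.y.max() >= len(self.class_names)):
            raise ValueError("class codes out of range")

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def __iter__(self):
        for i in range(len(self)):
            yield LabeledInstance(self.X[i], int(self.y[i]),
                                  str(self.sources[i]), self.sample_ids[i])

    def feature_indices(self, names) -> np.ndarray:
        """Column indices of the given gene identifiers, in their order."""
        lookup = {f: i for i, f in enumerate(self.feature_names)}
        missing = [f for f in names if f not in lookup]
        if missing:
            raise KeyError(f"features not in stream: {missing}")
        return np.array([lookup[f] for f in names], dtype=int)


def write_stream(stream: ExpressionStream, path: str | Path,
                 config: dict | None = None) -> None:
    """Write a stream as gzip TSV plus a JSON sidecar with its provenance.

    Columns: sample_id, source, label, then one column per gene.
    """
    path = Path(path)
    df = pd.DataFrame(stream.X, columns=stream.feature_names)
    df.insert(0, "label", [stream.class_names[c] for c in stream.y])
    df.insert(0, "source", stream.sources)
    df.insert(0, "sample_id", stream.sample_ids)
    with gzip.open(path, "wt") as fh:
        df.to_csv(fh, sep="\t", index=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = {"class_names": stream.class_names,
            "n_instances": len(stream),
            "n_features": stream.n_features,
            "config": config or {}}
    sidecar.write_text(json.dumps(meta, indent=1, default=str))


def read_stream(path: str | Path) -> ExpressionStream:
    """Read a stream written by :func:`write_stream`."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", compression="gzip")
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        class_names = json.loads(sidecar.read_text())["class_names"]
    else:
        class_names = sorted(df["label"].unique())
    code = {c: i for i, c in enumerate(class_names)}
    feats = [c for c in df.columns if c not in ("sample_id", "source", "label")]
    return ExpressionStream(
        feature_names=feats,
        X=df[feats].to_numpy(dtype=float),
        y=np.array([code[v] for v in df["label"]]),
        sources=df["source"].to_numpy(dtype=object),
        class_names=list(class_names),
        sample_ids=[str(s) for s in df["sample_id"]],
    )
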