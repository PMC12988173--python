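"""On-disk formats: feature/metadata CSV, tree JSON, frame PNG directories.

CSV numerics are written with 12+ significant digits so write -> read
round-trips are lossless at double precision for the values this pipeline
produces. Feature-table columns are validated against the
``<channel><statistic>_<index>_<code>`` naming convention on read.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import List, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import ParseError
from .pipeline import FEATURE_KEY_RE, FrameSequence
from .tree import DecisionTree, Leaf, Split, TreeParams

FLOAT_FORMAT = "%.17g"


def write_feature_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, float_format=FLOAT_FORMAT, index_label="subject_id")


def read_feature_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="subject_id")
    for col in df.columns:
        if not FEATURE_KEY_RE.match(col):
            raise ParseError(f"invalid feature key {col!r}", column=col)
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad[0] if len(bad) else None
            raise ParseError("non-numeric feature value", row=row, column=col)
    return df


def write_metadata_csv(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, float_format=FLOAT_FORMAT, index_label="subject_id")


def read_metadata_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="subject_id")
    if "group" not in df.columns:
        raise ParseError("metadata must contain a 'group' column", column="group")
    return df


def _json_default(o):
    if isinstance(o, np.integer):
        return int(o)
    if isinstance(o, np.floating):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _node_to_dict(node, classes):
    if isinstance(node, Leaf):
        return {
            "kind": "leaf",
            "label": node.label,
            "probs": [node.proportions.get(c, 0.0) for c in classes],
            "n": node.n,
        }
    return {
        "kind": "split",
        "feature": node.feature,
        "threshold": node.threshold,
        "left": _node_to_dict(node.left, classes),
        "right": _node_to_dict(node.right, classes),
    }


def _node_from_dict(d, classes):
    if d["kind"] == "leaf":
        return Leaf(
            label=d["label"],
            proportions=dict(zip(classes, (float(p) for p in d["probs"]))),
            n=int(d["n"]),
        )
    return Split(
        feature=d["feature"],
        threshold=float(d["threshold"]),
        left=_node_from_dict(d["left"], classes),
        right=_node_from_dict(d["right"], classes),
    )


def write_tree_json(tree: DecisionTree, path, seed=None) -> None:
    payload = {
        "root": _node_to_dict(tree.root, tree.classes),
        "params": dataclasses.asdict(tree.params),
        "classes": list(tree.classes),
        "pos_label": tree.pos_label,
        "feature_names": tree.feature_names,
        "seed": seed,
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=_json_default))


def read_tree_json(path) -> DecisionTree:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"invalid tree JSON: {exc}") from exc
    classes = tuple(payload["classes"])
    return DecisionTree(
        root=_node_from_dict(payload["root"], classes),
        params=TreeParams(**payload["params"]),
        classes=classes,
        pos_label=payload["pos_label"],
        feature_names=list(payload.get("feature_names", [])),
    )


def write_frames(sequence: FrameSequence, directory) -> List[Path]:
    """Dump a sequence as zero-padded PNGs (frame_01.png, ...)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, frame in enumerate(sequence.frames, start=1):
        p = directory / f"frame_{k:02d}.png"
        iio.imwrite(p, frame.pixels)
        paths.append(p)
    return paths


def write_mask(mask: np.ndarray, path) -> None:
    iio.imwrite(Path(path), (mask.astype(np.uint8) * 255))


def read_mask(path) -> np.ndarray:
    return np.asarray(iio.imread(Path(path))) > 0
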