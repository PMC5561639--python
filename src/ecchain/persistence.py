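"""Versioned, checksummed, endianness-fixed model serialization.

A stored model is a single self-describing binary container::

    bytes 0..3   magic  b"ECCM"
    bytes 4..7   format version, uint32 little-endian
    bytes 8..15  header length H, uint64 little-endian
    H bytes      header, UTF-8 JSON: model metadata, array shapes, and the
                 SHA-256 hex digest of the body
    rest         body: the concatenated node arrays in little-endian order
                 (chain orders int32, split features int32, thresholds and
                 positive fractions float64)

Every tree in a model has the same node count (2**(depth+1) - 1), so all
chains stack into four dense arrays.  Loading verifies magic, version and
checksum and reproduces a model whose predictions are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import struct
from pathlib import Path

import numpy as np

from .chain import ChainModel, ECCModel
from .forest import ForestModel
from .tree import FlatTree, TreeParams

__all__ = ["ModelFormatError", "store_model", "load_model", "FORMAT_VERSION"]

MAGIC = b"ECCM"
FORMAT_VERSION = 1


class ModelFormatError(ValueError):
    """The file is not a valid stored model (magic, version or checksum)."""


def store_model(model: ECCModel, path: str | Path) -> None:
    """Serialize an ECC model; the round trip through ``load_model`` is exact."""
    k, m = model.k, model.m
    forest_size = model.forest_size
    n_nodes = model.params.n_nodes

    orders = np.empty((k, m), dtype="<i4")
    feats = np.empty((k, m, forest_size, n_nodes), dtype="<i4")
    thresholds = np.empty((k, m, forest_size, n_nodes), dtype="<f8")
    fractions = np.empty((k, m, forest_size, n_nodes), dtype="<f8")
    for c, chain in enumerate(model.chains):
        orders[c] = chain.order
        for i, forest in enumerate(chain.forests):
            for t, tree in enumerate(forest.trees):
                feats[c, i, t] = tree.split_feature
                thresholds[c, i, t] = tree.split_threshold
                fractions[c, i, t] = tree.pos_fraction

    body = b"".join(a.tobytes() for a in (orders, feats, thresholds, fractions))
    header = {
        "format_version": FORMAT_VERSION,
        "k": k,
        "m": m,
        "p": model.p,
        "forest_size": forest_size,
        "depth": model.params.depth,
        "mtry": model.params.mtry,
        "min_node_size": model.params.min_node_size,
        "threshold": model.threshold,
        "label_names": model.label_names,
        "feature_names": model.feature_names,
        "body_sha256": hashlib.sha256(body).hexdigest(),
        "body_length": len(body),
    }
    header_bytes = json.dumps(header).encode("utf-8")
    with open(path, "wb") as fh:
        fh.write(MAGIC)
        fh.write(struct.pack("<I", FORMAT_VERSION))
        fh.write(struct.pack("<Q", len(header_bytes)))
        fh.write(header_bytes)
        fh.write(body)


def load_model(path: str | Path) -> ECCModel:
    """Deserialize a model stored by :func:`store_model`."""
    raw = Path(path).read_bytes()
    if len(raw) < 16 or raw[:4] != MAGIC:
        raise ModelFormatError(f"{path} is not a stored ECC model (bad magic)")
    (version,) = struct.unpack("<I", raw[4:8])
    if version != FORMAT_VERSION:
        raise ModelFormatError(
            f"{path} has format version {version}; this build reads {FORMAT_VERSION}"
        )
    (header_len,) = struct.unpack("<Q", raw[8:16])
    if len(raw) < 16 + header_len:
        raise ModelFormatError(f"{path} is truncated inside the header")
    try:
        header = json.loads(raw[16 : 16 + header_len].decode("utf-8"))
    except (UnicodeDecodeError, json.JSONDecodeError) as exc:
        raise ModelFormatError(f"{path} has a corrupt header: {exc}") from exc
    body = raw[16 + header_len :]
    if len(body) != header["body_length"]:
        raise ModelFormatError(
            f"{path} body is {len(body)} bytes, header says {header['body_length']}"
        )
    if hashlib.sha256(body).hexdigest() != header["body_sha256"]:
        raise ModelFormatError(f"{path} failed its integrity checksum")

    k, m, p = header["k"], header["m"], header["p"]
    forest_size, depth = header["forest_size"], header["depth"]
    params = TreeParams(
        depth=depth, mtry=header["mtry"], min_node_size=header["min_node_size"]
    )
    n_nodes = params.n_nodes

    off = 0

    def take(dtype: str, shape: tuple[int, ...]) -> np.ndarray:
        nonlocal off
        arr = np.frombuffer(body, dtype=dtype, count=int(np.prod(shape)), offset=off)
        off += arr.nbytes
        return arr.reshape(shape)

    orders = take("<i4", (k, m))
    feats = take("<i4", (k, m, forest_size, n_nodes))
    thresholds = take("<f8", (k, m, forest_size, n_nodes))
    fractions = take("<f8", (k, m, forest_size, n_nodes))

    chains: list[ChainModel] = []
    for c in range(k):
        forests: list[ForestModel] = []
        for i in range(m):
            trees = [
                FlatTree(
                    split_feature=feats[c, i, t].astype(np.int64),
                    split_threshold=thresholds[c, i, t].astype(np.float64),
                    pos_fraction=fractions[c, i, t].astype(np.float64),
                    depth=depth,
                    n_features=p + i,
                )
                for t in range(forest_size)
            ]
            forests.append(ForestModel(trees, forest_size, params, p + i))
        chains.append(ChainModel(np.asarray(orders[c], dtype=np.int64), forests, p, m))

    return ECCModel(
        chains=chains,
        threshold=header["threshold"],
        p=p,
        m=m,
        label_names=list(header["label_names"]),
        feature_names=list(header["feature_names"]),
        params=params,
        forest_size=forest_size,
    )
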