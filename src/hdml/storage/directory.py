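"""Plain-directory backend (storage-pluggability demonstrator).

Groups map to directories.  Each group carries a ``_node.json`` with its
attributes and link entries; each dataset becomes a ``<name>.dataset.json``
sidecar (dtype token, shape, attributes, encoding) plus, for numeric data,
a raw little-endian C-order ``<name>.bin`` array file — bit-exact and
diff-able.  Text data and scalars are inlined in the sidecar.  Writing the
same tree twice yields byte-identical output (JSON keys sorted, no
timestamps), which is the backend's write-determinism contract.

This layout is deliberately simple: it demonstrates that builders carry no
storage-format assumptions, not that the package speaks any particular
cloud-store dialect.
"""

from __future__ import annotations

import json
import shutil
from pathlib import Path

import numpy as np

from ..builders import DatasetBuilder, GroupBuilder, LinkBuilder
from ..errors import StorageError
from . import attach_specifications

__all__ = ["write", "read", "NAME"]

NAME = "dir"

_NODE_FILE = "_node.json"
_SIDECAR_SUFFIX = ".dataset.json"
_BIN_SUFFIX = ".bin"

_NUMERIC = {
    "int8", "int16", "int32", "int64",
    "uint8", "uint16", "uint32", "uint64",
    "float32", "float64",
}


def _check_name(name):
    if name == _NODE_FILE or name.endswith(_SIDECAR_SUFFIX) or name.endswith(_BIN_SUFFIX):
        raise StorageError(f"child name {name!r} collides with a reserved sidecar name")
    if "/" in name or name in (".", ".."):
        raise StorageError(f"invalid child name {name!r}")


def _encode_attr(value):
    if isinstance(value, str):
        return {"t": "str", "v": value}
    if isinstance(value, bool):
        return {"t": "bool", "v": value}
    if isinstance(value, int):
        return {"t": "int", "v": value}
    if isinstance(value, float):
        return {"t": "float", "v": value}
    if isinstance(value, list):
        return {"t": "str_list", "v": [str(x) for x in value]}
    if isinstance(value, np.ndarray):
        return {
            "t": "array",
            "dtype": value.dtype.name,
            "shape": list(value.shape),
            "v": value.ravel(order="C").tolist(),
        }
    raise StorageError(f"cannot encode attribute value of type {type(value)}")


def _decode_attr(obj):
    t = obj["t"]
    if t in ("str", "bool", "int", "float", "str_list"):
        return obj["v"]
    if t == "array":
        return np.array(obj["v"], dtype=obj["dtype"]).reshape(obj["shape"])
    raise StorageError(f"unknown attribute encoding {t!r}")


def _dump_json(path, obj):
    path.write_text(
        json.dumps(obj, sort_keys=True, indent=1, ensure_ascii=False) + "\n",
        encoding="utf-8",
    )


def write(root, path, registry=None):
    """Write a builder tree as a directory; an existing destination
    directory is replaced.  With ``registry``, embeds the schema documents
    under ``specifications/``."""
    if registry is not None:
        clone = GroupBuilder(root.name, dict(root.attributes))
        clone.groups, clone.datasets, clone.links = (
            dict(root.groups), dict(root.datasets), dict(root.links),
        )
        root = attach_specifications(clone, registry)
    path = Path(path)
    if path.exists():
        if not path.is_dir():
            raise StorageError(f"{path} exists and is not a directory")
        shutil.rmtree(path)
    _write_group(root, path, is_root=True)


def _write_group(builder, path, is_root=False):
    path.mkdir(parents=True)
    node = {"attributes": {k: _encode_attr(v) for k, v in sorted(builder.attributes.items())}}
    if is_root:
        node["name"] = builder.name
    links = {name: lb.target for name, lb in sorted(builder.links.items())}
    if links:
        node["links"] = links
    _dump_json(path / _NODE_FILE, node)
    for name in list(builder.groups) + list(builder.datasets):
        _check_name(name)
    for name, sub in sorted(builder.groups.items()):
        _write_group(sub, path / name)
    for name, ds in sorted(builder.datasets.items()):
        _write_dataset(ds, path, name)


def _write_dataset(builder, dirpath, name):
    data, dtype = builder.data, builder.dtype
    sidecar = {
        "dtype": dtype,
        "attributes": {k: _encode_attr(v) for k, v in sorted(builder.attributes.items())},
    }
    if dtype in ("text", "isodatetime"):
        sidecar["encoding"] = "json"
        sidecar["data"] = data
        sidecar["scalar"] = isinstance(data, str)
    elif dtype == "bool" or dtype in _NUMERIC:
        if isinstance(data, np.ndarray):
            arr = data.astype(np.uint8) if dtype == "bool" else data
            arr = np.ascontiguousarray(arr)
            if arr.dtype.byteorder == ">":
                arr = arr.astype(arr.dtype.newbyteorder("<"))
            sidecar["encoding"] = "binary"
            sidecar["shape"] = list(data.shape)
            sidecar["data_file"] = name + _BIN_SUFFIX
            (dirpath / (name + _BIN_SUFFIX)).write_bytes(arr.tobytes(order="C"))
        else:
            sidecar["encoding"] = "json"
            sidecar["scalar"] = True
            sidecar["data"] = bool(data) if dtype == "bool" else data
    else:
        raise StorageError(f"unwritable dtype {dtype!r} for dataset {name!r}")
    _dump_json(dirpath / (name + _SIDECAR_SUFFIX), sidecar)


def read(path):
    """Read a directory layout back into a builder tree."""
    path = Path(path)
    if not path.is_dir():
        raise StorageError(f"{path} is not a readable directory backend store")
    node = _load_node(path)
    root = GroupBuilder(node.get("name", "root"),
                        {k: _decode_attr(v) for k, v in node["attributes"].items()})
    _read_children(path, root, node)
    return root


def _load_node(path):
    node_file = path / _NODE_FILE
    if not node_file.exists():
        raise StorageError(f"{path} has no {_NODE_FILE}; not a backend store")
    try:
        return json.loads(node_file.read_text(encoding="utf-8"))
    except json.JSONDecodeError as e:
        raise StorageError(f"corrupt node file {node_file}: {e}") from e


def _read_children(path, builder, node):
    for name, target in node.get("links", {}).items():
        builder.add(LinkBuilder(name, target))
    for entry in sorted(path.iterdir()):
        if entry.is_dir():
            sub_node = _load_node(entry)
            sub = builder.add(
                GroupBuilder(entry.name,
                             {k: _decode_attr(v) for k, v in sub_node["attributes"].items()})
            )
            _read_children(entry, sub, sub_node)
        elif entry.name.endswith(_SIDECAR_SUFFIX):
            name = entry.name[: -len(_SIDECAR_SUFFIX)]
            builder.add(_read_dataset(path, name))


def _read_dataset(dirpath, name):
    sidecar = json.loads(
        (dirpath / (name + _SIDECAR_SUFFIX)).read_text(encoding="utf-8")
    )
    dtype = sidecar["dtype"]
    attrs = {k: _decode_attr(v) for k, v in sidecar["attributes"].items()}
    if sidecar["encoding"] == "json":
        data = sidecar["data"]
    else:
        raw = (dirpath / sidecar["data_file"]).read_bytes()
        np_dtype = np.uint8 if dtype == "bool" else np.dtype(dtype)
        arr = np.frombuffer(raw, dtype=np_dtype).reshape(sidecar["shape"])
        data = arr.astype(bool) if dtype == "bool" else arr.copy()
    return DatasetBuilder(name, data, dtype=dtype, attributes=attrs)
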