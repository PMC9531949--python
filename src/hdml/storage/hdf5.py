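"""HDF5 backend: builder primitives map one-to-one onto HDF5 primitives.

Groups become HDF5 groups, datasets HDF5 datasets, attributes HDF5
attributes and links soft links.  Two dtype tokens need translation
metadata because HDF5 has no native counterpart: ``bool`` data is stored
as uint8 and ``isodatetime`` as UTF-8 text, each with the declared token
recorded in the reserved ``_hdml_dtype`` attribute so reads restore it.
"""

from __future__ import annotations

import h5py
import numpy as np

from ..builders import DatasetBuilder, GroupBuilder, LinkBuilder
from ..errors import StorageError
from . import attach_specifications

__all__ = ["write", "read", "NAME"]

NAME = "hdf5"

_DTYPE_MARKER = "_hdml_dtype"
_ROOT_NAME = "_hdml_root_name"
_STR = h5py.string_dtype(encoding="utf-8")


def write(root, path, registry=None):
    """Write a builder tree to an HDF5 file.

    With ``registry`` given, the registered specification documents are
    embedded under the reserved ``/specifications`` group, making the file
    self-describing.
    """
    if registry is not None:
        root = _shallow_copy(root)
        attach_specifications(root, registry)
    try:
        with h5py.File(path, "w", track_order=True) as f:
            f.attrs[_ROOT_NAME] = root.name
            _write_attrs(f, root.attributes)
            for child in root.children():
                _write_child(f, child, "/")
    except (TypeError, ValueError, OSError) as e:
        if isinstance(e, StorageError):
            raise
        raise StorageError(f"cannot write {path}: {e}") from e


def _shallow_copy(root):
    clone = GroupBuilder(root.name, dict(root.attributes))
    clone.groups = dict(root.groups)
    clone.datasets = dict(root.datasets)
    clone.links = dict(root.links)
    return clone


def _write_child(h5group, child, path):
    here = path.rstrip("/") + "/" + child.name
    if isinstance(child, LinkBuilder):
        h5group[child.name] = h5py.SoftLink(child.target)
        return
    if isinstance(child, GroupBuilder):
        sub = h5group.create_group(child.name, track_order=True)
        _write_attrs(sub, child.attributes)
        for grandchild in child.children():
            _write_child(sub, grandchild, here)
        return
    _write_dataset(h5group, child, here)


def _write_dataset(h5group, builder, path):
    data, dtype = builder.data, builder.dtype
    marker = None
    if dtype in ("text", "isodatetime"):
        if dtype == "isodatetime":
            marker = "isodatetime"
        if isinstance(data, str):
            ds = h5group.create_dataset(builder.name, data=data, dtype=_STR)
        else:
            ds = h5group.create_dataset(
                builder.name, data=np.array(data, dtype=object), dtype=_STR
            )
    elif dtype == "bool":
        marker = "bool"
        if isinstance(data, np.ndarray):
            ds = h5group.create_dataset(builder.name, data=data.astype(np.uint8))
        else:
            ds = h5group.create_dataset(builder.name, data=np.uint8(bool(data)))
    elif isinstance(dtype, str):
        arr = data if isinstance(data, np.ndarray) else np.dtype(dtype).type(data)
        ds = h5group.create_dataset(builder.name, data=arr)
    else:
        raise StorageError(f"unwritable dtype {dtype!r} at {path}")
    if marker:
        ds.attrs[_DTYPE_MARKER] = marker
    _write_attrs(ds, builder.attributes)


def _write_attrs(node, attributes):
    for name, value in attributes.items():
        if isinstance(value, str):
            node.attrs[name] = value
        elif isinstance(value, list):
            node.attrs.create(name, np.array(value, dtype=object), dtype=_STR)
        else:
            node.attrs[name] = value


def read(path):
    """Read an HDF5 file back into a builder tree (inverse of
    :func:`write`); soft links come back as link builders."""
    try:
        with h5py.File(path, "r") as f:
            name = f.attrs.get(_ROOT_NAME, "root")
            root = GroupBuilder(str(name), _read_attrs(f))
            _read_children(f, root)
        return root
    except OSError as e:
        raise StorageError(f"cannot read {path}: {e}") from e


def _read_children(h5group, builder):
    for name in h5group:
        link = h5group.get(name, getlink=True)
        if isinstance(link, h5py.SoftLink):
            builder.add(LinkBuilder(name, link.path))
            continue
        node = h5group[name]
        if isinstance(node, h5py.Group):
            sub = builder.add(GroupBuilder(name, _read_attrs(node)))
            _read_children(node, sub)
        else:
            builder.add(_read_dataset(name, node))


def _read_dataset(name, ds):
    marker = ds.attrs.get(_DTYPE_MARKER)
    if isinstance(marker, bytes):
        marker = marker.decode()
    attrs = _read_attrs(ds)
    if h5py.check_string_dtype(ds.dtype):
        raw = ds.asstr()[()]
        data = raw if ds.shape == () else [str(x) for x in raw]
        dtype = marker or "text"
    elif marker == "bool":
        raw = ds[()]
        data = raw.astype(bool) if isinstance(raw, np.ndarray) else bool(raw)
        dtype = "bool"
    else:
        raw = ds[()]
        if isinstance(raw, np.ndarray):
            data, dtype = raw, raw.dtype.name
        else:
            data, dtype = raw.item() if hasattr(raw, "item") else raw, np.dtype(ds.dtype).name
    return DatasetBuilder(name, data, dtype=dtype, attributes=attrs)


def _read_attrs(node):
    out = {}
    for name, value in node.attrs.items():
        if name in (_DTYPE_MARKER, _ROOT_NAME):
            continue
        out[name] = value
    return out
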