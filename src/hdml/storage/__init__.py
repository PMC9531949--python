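"""Pluggable storage backends.

Backends translate builder primitives to the primitives of a storage
format and back; the round-trip contract is structural equality of the
builder tree (dtype-, attribute- and data-preserving).  Two backends ship:

* :mod:`hdml.storage.hdf5` — groups/datasets/attributes map to their HDF5
  counterparts and links to soft links; the primary backend.
* :mod:`hdml.storage.directory` — a plain-directory demonstrator (in the
  spirit of Zarr-style stores): groups are directories, datasets are raw
  little-endian array files with JSON sidecars, attributes and links live
  in per-node JSON.  Byte-deterministic, diff-able, and deliberately not a
  real Zarr store.

Written files are self-describing: the specification documents of every
registered namespace are embedded under the reserved ``/specifications``
group, sufficient to re-validate the file starting from an empty registry.
"""

from __future__ import annotations

from ..builders import DatasetBuilder, GroupBuilder, SPEC_GROUP
from ..core_schema import namespace_documents
from ..spec_language import parse_spec_document
from ..type_system import TypeRegistry, register_namespace

__all__ = [
    "specifications_builder",
    "attach_specifications",
    "detach_specifications",
    "load_embedded_specifications",
    "get_backend",
]


def specifications_builder(reg):
    """Builder group caching every registered namespace's documents:
    ``/specifications/<namespace>/<version>/<document>``."""
    spec_group = GroupBuilder(SPEC_GROUP)
    for ns_name in sorted(reg.namespaces):
        ns = reg.namespaces[ns_name]
        ns_group = spec_group.add(GroupBuilder(ns_name))
        ver_group = ns_group.add(GroupBuilder(ns.version))
        for doc_name, text in namespace_documents(reg, ns_name):
            ver_group.add(DatasetBuilder(doc_name, text, dtype="text"))
    return spec_group


def attach_specifications(root, reg):
    """Embed schema documents into ``root`` (idempotent: replaces any
    existing cache)."""
    root.groups.pop(SPEC_GROUP, None)
    root.add(specifications_builder(reg))
    return root


def detach_specifications(root):
    root.groups.pop(SPEC_GROUP, None)
    return root


def load_embedded_specifications(root):
    """Rebuild a :class:`TypeRegistry` purely from a file's embedded
    specification documents (the self-description property)."""
    spec_group = root.groups.get(SPEC_GROUP)
    reg = TypeRegistry()
    if spec_group is None:
        return reg
    parsed = {}  # ns name -> (namespace, specs, docs)
    for ns_name, ns_group in spec_group.groups.items():
        for ver_group in ns_group.groups.values():
            namespace, specs, docs = None, [], []
            for doc_name, ds in sorted(ver_group.datasets.items()):
                text = ds.data
                ns_part, spec_part = parse_spec_document(text)
                if ns_part is not None:
                    namespace = ns_part
                specs.extend(spec_part)
                docs.append((doc_name, text))
            if namespace is not None:
                parsed[namespace.name] = (namespace, specs, docs)
    # register in dependency order (imports first)
    remaining = dict(parsed)
    while remaining:
        progressed = False
        for name in list(remaining):
            ns, specs, docs = remaining[name]
            if all(imp in reg.namespaces for imp in ns.imported_namespaces()):
                register_namespace(reg, ns, specs, source_documents=docs)
                del remaining[name]
                progressed = True
        if not progressed:  # unresolvable imports; register nothing further
            break
    return reg


def get_backend(name):
    """Backend module by token (``hdf5`` or ``dir``)."""
    from . import directory, hdf5

    backends = {"hdf5": hdf5, "dir": directory, "directory": directory}
    if name not in backends:
        raise ValueError(f"unknown backend {name!r}; use 'hdf5' or 'dir'")
    return backends[name]
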