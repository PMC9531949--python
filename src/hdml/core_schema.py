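"""Loading of the shipped mini core schema into a type registry.

The core schema is plain specification documents under
``hdml/schema/`` — the package does not special-case its own types beyond
the container classes in :mod:`hdml.containers`; everything else (building,
validation, storage) is driven by these documents exactly as it is for
user extensions.
"""

from __future__ import annotations

from importlib import resources

from .spec_language import parse_spec_document, serialize_spec_document
from .type_system import TypeRegistry, register_namespace

__all__ = [
    "CORE_NAMESPACE",
    "CORE_VERSION",
    "load_core_namespace",
    "core_registry",
    "namespace_documents",
    "load_namespace_file",
]

CORE_NAMESPACE = "mini-core"
CORE_VERSION = "0.1.0"

_NAMESPACE_DOC = "mini-core.namespace.yaml"
_SCHEMA_DOC = "mini-core.yaml"


def _read_schema_file(name):
    return resources.files("hdml").joinpath("schema", name).read_text()


def load_core_namespace():
    """Parse the shipped schema documents; returns
    ``(namespace, specs, source_documents)``."""
    ns_text = _read_schema_file(_NAMESPACE_DOC)
    schema_text = _read_schema_file(_SCHEMA_DOC)
    ns, _ = parse_spec_document(ns_text)
    _, specs = parse_spec_document(schema_text)
    docs = [(_NAMESPACE_DOC, ns_text), (_SCHEMA_DOC, schema_text)]
    return ns, specs, docs


def core_registry():
    """A fresh registry with the mini core schema registered."""
    reg = TypeRegistry()
    ns, specs, docs = load_core_namespace()
    register_namespace(reg, ns, specs, source_documents=docs)
    return reg


def load_namespace_file(reg, path):
    """Register a namespace document from disk; ``source`` schema entries
    are read relative to the document's directory."""
    from pathlib import Path

    path = Path(path)
    ns_text = path.read_text()
    ns, specs = parse_spec_document(ns_text)
    docs = [(path.name, ns_text)]
    if ns is None:
        raise ValueError(f"{path} contains no namespace definition")
    for src in ns.schema_sources:
        if src.source:
            schema_path = path.parent / src.source
            text = schema_path.read_text()
            _, more = parse_spec_document(text)
            specs.extend(more)
            docs.append((schema_path.name, text))
    register_namespace(reg, ns, specs, source_documents=docs)
    return reg


def namespace_documents(reg, ns_name):
    """The specification documents of a registered namespace as
    ``[(document_name, text), ...]`` — verbatim sources when known,
    regenerated deterministically otherwise (used for embedding schema in
    written files)."""
    if ns_name in reg._raw_docs:
        return list(reg._raw_docs[ns_name])
    ns = reg.namespaces[ns_name]
    specs = [spec for (n, _), spec in reg.entries.items() if n == ns_name]
    ns_doc = serialize_spec_document(ns, [])
    types_doc = serialize_spec_document(None, specs)
    return [
        (f"{ns_name}.namespace.yaml", ns_doc),
        (f"{ns_name}.types.yaml", types_doc),
    ]
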