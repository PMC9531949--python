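"""The specification language: four primitive structures plus namespaces.

A hierarchical data model is declared with exactly four node kinds —
**groups**, **datasets**, **attributes** and **links** — each described by a
spec class (:class:`GroupSpec`, :class:`DatasetSpec`, :class:`AttributeSpec`,
:class:`LinkSpec`).  Group and dataset specs may introduce a new *neurodata
type* (``type_def``) or include/extend an existing one (``type_inc``), which
is how class-like reuse through inheritance and composition enters the
language.  A :class:`Namespace` is a named, versioned collection of type
definitions with ordered schema sources and optional imports from other
namespaces.

Documents are a small YAML dialect (JSON, being a YAML subset, is accepted
unchanged): a *namespace* document carries a top-level ``namespaces:`` list;
a *schema* document carries top-level ``groups:`` and/or ``datasets:`` lists.
:func:`parse_spec_document` and :func:`serialize_spec_document` round-trip
losslessly; unknown keys are preserved-as-warnings rather than errors so
documents written by a newer dialect still load.

The dtype vocabulary is closed: fixed-width integers and floats, ``bool``,
``text``, ``isodatetime``, object/region references to a named type, and
compound (struct) dtypes.  Shapes are lists of extents where ``null`` means
"any extent"; a list of lists declares alternative shapes; an absent shape
means scalar.  Quantities use the ``'?' '*' '+' n`` grammar resolved by
:func:`resolve_quantity`.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Optional, Union

import yaml

from .errors import SpecError, SpecSyntaxError
from .issues import ValidationIssue

__all__ = [
    "AttributeSpec",
    "DatasetSpec",
    "GroupSpec",
    "LinkSpec",
    "Namespace",
    "SchemaSource",
    "RefDtype",
    "CompoundDtype",
    "SpecWarning",
    "PRIMITIVE_DTYPES",
    "PRIMITIVE_KINDS",
    "parse_spec_document",
    "serialize_spec_document",
    "resolve_quantity",
    "check_spec_wellformed",
    "UNBOUNDED",
]


class SpecWarning(UserWarning):
    """Non-fatal oddity in a specification document (e.g. unknown key)."""


#: The closed scalar dtype vocabulary.
PRIMITIVE_DTYPES = frozenset(
    {
        "int8", "int16", "int32", "int64",
        "uint8", "uint16", "uint32", "uint64",
        "float32", "float64",
        "bool", "text", "isodatetime",
    }
)

#: The four primitive structure kinds the language can express.
PRIMITIVE_KINDS = ("group", "dataset", "attribute", "link")

_TYPE_NAME_RE = re.compile(r"^[A-Za-z][A-Za-z0-9]*$")
_NAMESPACE_NAME_RE = re.compile(r"^[A-Za-z][A-Za-z0-9-]*$")
_SEMVER_RE = re.compile(r"^\d+\.\d+\.\d+$")

#: Sentinel for an unbounded maximum quantity.
UNBOUNDED = None


# ---------------------------------------------------------------------------
# dtype variants beyond plain tokens
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RefDtype:
    """Reference dtype: a pointer to an object (or a row region of a table)
    of a given neurodata type."""

    reftype: str  # 'object' | 'region'
    target_type: str

    def __post_init__(self):
        if self.reftype not in ("object", "region"):
            raise SpecError(f"unknown reftype {self.reftype!r}")


@dataclass(frozen=True)
class CompoundDtype:
    """Struct dtype: an ordered sequence of (name, scalar dtype) fields."""

    fields: tuple  # tuple[(name, dtype-token), ...]


Dtype = Union[str, RefDtype, CompoundDtype]


# ---------------------------------------------------------------------------
# the four primitives
# ---------------------------------------------------------------------------

@dataclass
class AttributeSpec:
    """A named scalar or small-array annotation attached to a group or
    dataset."""

    name: str
    dtype: Dtype
    doc: str = ""
    shape: Optional[tuple] = None  # None => scalar
    required: bool = True
    default_value: object = None

    kind = "attribute"


@dataclass
class DatasetSpec:
    """An n-dimensional array node; may define or include a neurodata type."""

    name: Optional[str] = None
    type_def: Optional[str] = None
    type_inc: Optional[str] = None
    dtype: Optional[Dtype] = None
    shape: Optional[tuple] = None
    dims: Optional[tuple] = None
    quantity: Union[int, str] = 1
    attributes: list = field(default_factory=list)
    doc: str = ""

    kind = "dataset"


@dataclass
class GroupSpec:
    """A container node holding groups, datasets, links and attributes; may
    define or include a neurodata type."""

    name: Optional[str] = None
    type_def: Optional[str] = None
    type_inc: Optional[str] = None
    quantity: Union[int, str] = 1
    groups: list = field(default_factory=list)
    datasets: list = field(default_factory=list)
    links: list = field(default_factory=list)
    attributes: list = field(default_factory=list)
    doc: str = ""

    kind = "group"


@dataclass
class LinkSpec:
    """A named pointer to a node of a given neurodata type elsewhere in the
    same tree."""

    target_type: str
    name: Optional[str] = None
    quantity: Union[int, str] = 1
    doc: str = ""

    kind = "link"


TypeSpec = Union[GroupSpec, DatasetSpec]


@dataclass
class SchemaSource:
    """One entry of a namespace's ordered schema list: either a source file
    or an import of (a subset of) another namespace's types."""

    source: Optional[str] = None
    namespace: Optional[str] = None
    types: Optional[tuple] = None


@dataclass
class Namespace:
    name: str
    version: str
    doc: str = ""
    authors: list = field(default_factory=list)
    schema_sources: list = field(default_factory=list)

    def imported_namespaces(self):
        return [s.namespace for s in self.schema_sources if s.namespace]


# ---------------------------------------------------------------------------
# quantity grammar
# ---------------------------------------------------------------------------

def resolve_quantity(token):
    """Map a quantity token to ``(min_occurs, max_occurs)``.

    ``'?'`` -> (0, 1); ``'*'`` -> (0, unbounded); ``'+'`` -> (1, unbounded);
    a positive integer ``n`` -> (n, n).  ``max_occurs`` is ``None`` when
    unbounded.
    """
    if token == "?":
        return (0, 1)
    if token == "*":
        return (0, UNBOUNDED)
    if token == "+":
        return (1, UNBOUNDED)
    if isinstance(token, int) and not isinstance(token, bool) and token > 0:
        return (token, token)
    raise SpecError(f"unknown quantity token {token!r}")


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _warn_unknown(keys, known, where):
    for k in keys:
        if k not in known:
            warnings.warn(
                f"unknown key {k!r} in {where}; ignored", SpecWarning, stacklevel=4
            )


def _parse_dtype(node, where):
    if node is None:
        return None
    if isinstance(node, str):
        if node not in PRIMITIVE_DTYPES:
            raise SpecError(f"unknown dtype token {node!r} in {where}")
        return node
    if isinstance(node, dict):
        _warn_unknown(node, {"reftype", "target_type"}, where)
        try:
            return RefDtype(node["reftype"], node["target_type"])
        except KeyError as e:
            raise SpecError(f"reference dtype in {where} missing key {e}") from None
    if isinstance(node, list):
        fields = []
        for f in node:
            if not isinstance(f, dict) or "name" not in f or "dtype" not in f:
                raise SpecError(f"compound dtype field in {where} needs name and dtype")
            _warn_unknown(f, {"name", "dtype", "doc"}, where)
            sub = f["dtype"]
            if sub not in PRIMITIVE_DTYPES:
                raise SpecError(f"unknown dtype token {sub!r} in compound of {where}")
            fields.append((f["name"], sub))
        return CompoundDtype(tuple(fields))
    raise SpecError(f"cannot interpret dtype {node!r} in {where}")


def _parse_shape(node, where):
    if node is None:
        return None
    if not isinstance(node, list):
        raise SpecError(f"shape must be a list in {where}")
    if node and all(isinstance(s, list) for s in node):
        return tuple(_parse_shape(s, where) for s in node)
    out = []
    for s in node:
        if s is None:
            out.append(None)
        elif isinstance(s, int) and not isinstance(s, bool) and s > 0:
            out.append(s)
        else:
            raise SpecError(f"bad shape extent {s!r} in {where}")
    return tuple(out)


def _parse_quantity(node, where):
    if node is None:
        return 1
    resolve_quantity(node)  # raises on unknown tokens
    return node


def _def_label(mapping, fallback):
    return mapping.get("name") or mapping.get("type_def") or mapping.get("type_inc") or fallback


def _require_doc(mapping, where):
    if "doc" not in mapping or mapping["doc"] is None:
        raise SpecError(f"definition {where} is missing mandatory key 'doc'")
    return str(mapping["doc"])


_ATTR_KEYS = {"name", "dtype", "doc", "shape", "required", "default_value"}


def _parse_attribute(node, parent):
    where = f"attribute {node.get('name', '?')!r} of {parent}"
    _warn_unknown(node, _ATTR_KEYS, where)
    if not node.get("name"):
        raise SpecError(f"{where}: attribute name is mandatory")
    return AttributeSpec(
        name=node["name"],
        dtype=_parse_dtype(node.get("dtype"), where),
        doc=_require_doc(node, where),
        shape=_parse_shape(node.get("shape"), where),
        required=bool(node.get("required", True)),
        default_value=node.get("default_value"),
    )


_DATASET_KEYS = {
    "name", "type_def", "type_inc", "dtype", "shape", "dims",
    "quantity", "attributes", "doc",
}


def _parse_dataset(node, parent):
    where = f"dataset {_def_label(node, '?')!r} of {parent}"
    _warn_unknown(node, _DATASET_KEYS, where)
    _check_identity(node, where)
    dims = node.get("dims")
    return DatasetSpec(
        name=node.get("name"),
        type_def=node.get("type_def"),
        type_inc=node.get("type_inc"),
        dtype=_parse_dtype(node.get("dtype"), where),
        shape=_parse_shape(node.get("shape"), where),
        dims=tuple(dims) if dims is not None else None,
        quantity=_parse_quantity(node.get("quantity"), where),
        attributes=[_parse_attribute(a, where) for a in node.get("attributes") or []],
        doc=_require_doc(node, where),
    )


_GROUP_KEYS = {
    "name", "type_def", "type_inc", "quantity", "groups", "datasets",
    "links", "attributes", "doc",
}


def _parse_group(node, parent):
    where = f"group {_def_label(node, '?')!r} of {parent}"
    _warn_unknown(node, _GROUP_KEYS, where)
    _check_identity(node, where)
    return GroupSpec(
        name=node.get("name"),
        type_def=node.get("type_def"),
        type_inc=node.get("type_inc"),
        quantity=_parse_quantity(node.get("quantity"), where),
        groups=[_parse_group(g, where) for g in node.get("groups") or []],
        datasets=[_parse_dataset(d, where) for d in node.get("datasets") or []],
        links=[_parse_link(l, where) for l in node.get("links") or []],
        attributes=[_parse_attribute(a, where) for a in node.get("attributes") or []],
        doc=_require_doc(node, where),
    )


_LINK_KEYS = {"name", "target_type", "quantity", "doc"}


def _parse_link(node, parent):
    where = f"link {node.get('name') or node.get('target_type', '?')!r} of {parent}"
    _warn_unknown(node, _LINK_KEYS, where)
    if not node.get("target_type"):
        raise SpecError(f"{where}: target_type is mandatory")
    return LinkSpec(
        target_type=node["target_type"],
        name=node.get("name"),
        quantity=_parse_quantity(node.get("quantity"), where),
        doc=_require_doc(node, where),
    )


def _check_identity(node, where):
    if not (node.get("name") or node.get("type_def") or node.get("type_inc")):
        raise SpecError(
            f"{where}: at least one of name, type_def, type_inc is mandatory"
        )


_NS_KEYS = {"name", "version", "doc", "authors", "schema"}
_SOURCE_KEYS = {"source", "namespace", "types"}


def _parse_namespace(node):
    where = f"namespace {node.get('name', '?')!r}"
    _warn_unknown(node, _NS_KEYS, where)
    for key in ("name", "version"):
        if not node.get(key):
            raise SpecError(f"{where}: missing mandatory key {key!r}")
    name, version = node["name"], str(node["version"])
    if not _NAMESPACE_NAME_RE.match(name):
        raise SpecError(f"{where}: bad namespace name {name!r}")
    if not _SEMVER_RE.match(version):
        raise SpecError(f"{where}: version {version!r} is not MAJOR.MINOR.PATCH")
    sources = []
    for s in node.get("schema") or []:
        _warn_unknown(s, _SOURCE_KEYS, where)
        if not (s.get("source") or s.get("namespace")):
            raise SpecError(f"{where}: schema entry needs source or namespace")
        types = s.get("types")
        sources.append(
            SchemaSource(
                source=s.get("source"),
                namespace=s.get("namespace"),
                types=tuple(types) if types is not None else None,
            )
        )
    return Namespace(
        name=name,
        version=version,
        doc=_require_doc(node, where),
        authors=list(node.get("authors") or []),
        schema_sources=sources,
    )


_DOC_KEYS = {"namespaces", "groups", "datasets"}


def parse_spec_document(text):
    """Parse a specification document into ``(namespace | None, type specs)``.

    The document may be a namespace document (``namespaces:``), a schema
    document (``groups:`` / ``datasets:``) or both in one file.  Unknown
    keys anywhere raise :class:`SpecWarning` rather than failing, so
    forward-compatible dialect additions do not break older readers.

    Raises :class:`SpecSyntaxError` (with line/column) on malformed text and
    :class:`SpecError` on grammatical violations naming the offending
    definition.
    """
    try:
        doc = yaml.safe_load(text)
    except yaml.MarkedYAMLError as e:
        mark = e.problem_mark
        raise SpecSyntaxError(
            str(e),
            line=mark.line + 1 if mark else None,
            column=mark.column + 1 if mark else None,
        ) from e
    except yaml.YAMLError as e:  # pragma: no cover - unmarked parser errors
        raise SpecSyntaxError(str(e)) from e

    if doc is None:
        return None, []
    if not isinstance(doc, dict):
        raise SpecError("document root must be a mapping")
    _warn_unknown(doc, _DOC_KEYS, "document root")

    namespace = None
    ns_list = doc.get("namespaces") or []
    if len(ns_list) > 1:
        raise SpecError("at most one namespace per document")
    if ns_list:
        namespace = _parse_namespace(ns_list[0])

    specs = []
    for g in doc.get("groups") or []:
        spec = _parse_group(g, "document root")
        _require_top_level_type(spec)
        specs.append(spec)
    for d in doc.get("datasets") or []:
        spec = _parse_dataset(d, "document root")
        _require_top_level_type(spec)
        specs.append(spec)
    return namespace, specs


def _require_top_level_type(spec):
    if not spec.type_def:
        raise SpecError(
            f"top-level {spec.kind} {spec.name or spec.type_inc!r} must carry type_def"
        )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_SERIALIZABLE_LITERALS = (str, int, float, bool, type(None))


def _dump_dtype(dtype):
    if dtype is None or isinstance(dtype, str):
        return dtype
    if isinstance(dtype, RefDtype):
        return {"reftype": dtype.reftype, "target_type": dtype.target_type}
    if isinstance(dtype, CompoundDtype):
        return [{"name": n, "dtype": d} for n, d in dtype.fields]
    raise SpecError(f"cannot serialize dtype {dtype!r}")


def _dump_shape(shape):
    if shape is None:
        return None
    if shape and all(isinstance(s, tuple) for s in shape):
        return [_dump_shape(s) for s in shape]
    return [s for s in shape]


def _put(out, key, value):
    if value is not None and value != [] and value != ():
        out[key] = value


def _dump_attribute(a):
    out = {"name": a.name, "dtype": _dump_dtype(a.dtype), "doc": a.doc}
    _put(out, "shape", _dump_shape(a.shape))
    if not a.required:
        out["required"] = False
    if a.default_value is not None:
        if not isinstance(a.default_value, _SERIALIZABLE_LITERALS + (list,)):
            raise SpecError(
                f"unserializable default_value {a.default_value!r} on attribute {a.name!r}"
            )
        out["default_value"] = a.default_value
    return out


def _dump_dataset(d):
    out = {}
    _put(out, "name", d.name)
    _put(out, "type_def", d.type_def)
    _put(out, "type_inc", d.type_inc)
    _put(out, "dtype", _dump_dtype(d.dtype))
    _put(out, "shape", _dump_shape(d.shape))
    _put(out, "dims", list(d.dims) if d.dims is not None else None)
    if d.quantity != 1:
        out["quantity"] = d.quantity
    _put(out, "attributes", [_dump_attribute(a) for a in d.attributes])
    out["doc"] = d.doc
    return out


def _dump_group(g):
    out = {}
    _put(out, "name", g.name)
    _put(out, "type_def", g.type_def)
    _put(out, "type_inc", g.type_inc)
    if g.quantity != 1:
        out["quantity"] = g.quantity
    _put(out, "groups", [_dump_group(c) for c in g.groups])
    _put(out, "datasets", [_dump_dataset(c) for c in g.datasets])
    _put(out, "links", [_dump_link(c) for c in g.links])
    _put(out, "attributes", [_dump_attribute(a) for a in g.attributes])
    out["doc"] = g.doc
    return out


def _dump_link(l):
    out = {}
    _put(out, "name", l.name)
    out["target_type"] = l.target_type
    if l.quantity != 1:
        out["quantity"] = l.quantity
    out["doc"] = l.doc
    return out


def serialize_spec_document(namespace, specs):
    """Serialize a namespace and/or type specs back to the YAML dialect.

    Key order is deterministic so output is diff-able;
    ``parse_spec_document(serialize_spec_document(ns, specs))`` reproduces
    the inputs structurally.
    """
    doc = {}
    if namespace is not None:
        ns = {
            "name": namespace.name,
            "version": namespace.version,
            "doc": namespace.doc,
        }
        _put(ns, "authors", list(namespace.authors))
        schema = []
        for s in namespace.schema_sources:
            entry = {}
            _put(entry, "source", s.source)
            _put(entry, "namespace", s.namespace)
            _put(entry, "types", list(s.types) if s.types is not None else None)
            schema.append(entry)
        _put(ns, "schema", schema)
        doc["namespaces"] = [ns]
    groups = [_dump_group(s) for s in specs if isinstance(s, GroupSpec)]
    datasets = [_dump_dataset(s) for s in specs if isinstance(s, DatasetSpec)]
    _put(doc, "groups", groups)
    _put(doc, "datasets", datasets)
    return yaml.safe_dump(doc, sort_keys=False, default_flow_style=False)


# ---------------------------------------------------------------------------
# well-formedness
# ---------------------------------------------------------------------------

def _issue(path, rule, msg):
    return ValidationIssue("error", path, rule, msg)


def check_spec_wellformed(spec, path=""):
    """Check a spec tree's structural invariants; returns issues, raises
    nothing.  An empty list means all invariants hold recursively."""
    issues = []
    label = spec.name or spec.type_def or spec.type_inc or "<anonymous>"
    here = f"{path}/{label}"

    if isinstance(spec, AttributeSpec):
        if not spec.name:
            issues.append(_issue(here, "spec-name", "attribute name is empty"))
        if isinstance(spec.dtype, str) and spec.dtype not in PRIMITIVE_DTYPES:
            issues.append(_issue(here, "spec-dtype", f"unknown dtype {spec.dtype!r}"))
        if spec.dtype is None:
            issues.append(_issue(here, "spec-dtype", "attribute needs a dtype"))
        return issues

    if isinstance(spec, LinkSpec):
        if not spec.target_type:
            issues.append(_issue(here, "spec-link-target", "empty target_type"))
        return issues

    if not (spec.name or spec.type_def or spec.type_inc):
        issues.append(
            _issue(here, "spec-identity", "needs one of name/type_def/type_inc")
        )
    for tname in (spec.type_def, spec.type_inc):
        if tname is not None and not _TYPE_NAME_RE.match(tname):
            issues.append(_issue(here, "spec-type-name", f"bad type name {tname!r}"))

    if isinstance(spec, DatasetSpec):
        if spec.dims is not None and spec.shape is not None:
            shapes = spec.shape if spec.shape and isinstance(spec.shape[0], tuple) else (spec.shape,)
            if all(len(spec.dims) != len(s) for s in shapes):
                issues.append(
                    _issue(here, "spec-dims", "len(dims) does not match any shape")
                )
        for a in spec.attributes:
            issues.extend(check_spec_wellformed(a, here))
        return issues

    # GroupSpec
    for kind, children in (
        ("groups", spec.groups), ("datasets", spec.datasets), ("links", spec.links)
    ):
        seen = set()
        for child in children:
            if child.name is not None:
                if child.name in seen:
                    issues.append(
                        _issue(here, "spec-dup-name", f"duplicate {kind} name {child.name!r}")
                    )
                seen.add(child.name)
            elif not (getattr(child, "type_inc", None) or getattr(child, "type_def", None)
                      or isinstance(child, LinkSpec)):
                issues.append(
                    _issue(here, "spec-anonymous", f"anonymous child in {kind} lacks a type")
                )
            issues.extend(check_spec_wellformed(child, here))
    for a in spec.attributes:
        issues.extend(check_spec_wellformed(a, here))
    return issues
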