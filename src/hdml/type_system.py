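"""Namespace registration and neurodata-type resolution.

Neurodata types behave like classes: a type may *extend* another type
(``type_inc`` at the root of its definition) and *compose* other types as
children.  :func:`resolve_type` flattens a type over its ancestor chain into
a self-contained :class:`ResolvedGroupSpec` / :class:`ResolvedDatasetSpec`:
the root ancestor is laid down first and each descendant overlays it, with
name-keyed override of children and attributes.  Refinements may only
*narrow* what an ancestor allows — a dtype may shrink to a subset of its
values, a wildcard extent may be pinned, an optional attribute may become
required — never the reverse, so any instance valid for a subtype is valid
for every ancestor's constraints it inherits.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

from .errors import (
    ConflictError,
    CycleError,
    DependencyError,
    RefinementError,
    UnknownTypeError,
)
from .spec_language import (
    AttributeSpec,
    CompoundDtype,
    DatasetSpec,
    GroupSpec,
    LinkSpec,
    Namespace,
    RefDtype,
)

__all__ = [
    "TypeRegistry",
    "ResolvedGroupSpec",
    "ResolvedDatasetSpec",
    "register_namespace",
    "resolve_type",
    "is_subtype",
    "dtype_narrows",
    "shape_refines",
]


# ---------------------------------------------------------------------------
# dtype / shape narrowing relations
# ---------------------------------------------------------------------------

_INTS = ("int8", "int16", "int32", "int64")
_UINTS = ("uint8", "uint16", "uint32", "uint64")


def _build_narrowing_table():
    table = {}
    for i, t in enumerate(_INTS):
        # a signed int admits smaller signed ints and strictly-smaller uints
        table[t] = set(_INTS[: i + 1]) | set(_UINTS[:i])
    for i, t in enumerate(_UINTS):
        table[t] = set(_UINTS[: i + 1])
    table["float64"] = {"float64", "float32"}
    table["float32"] = {"float32"}
    table["bool"] = {"bool"}
    table["text"] = {"text", "isodatetime"}
    table["isodatetime"] = {"isodatetime"}
    return table


#: token -> set of tokens whose every value is representable in it
NARROWER_THAN = _build_narrowing_table()


def dtype_narrows(child, parent, subtype_fn=None):
    """True iff every value admitted by ``child`` is admitted by ``parent``.

    ``parent`` of ``None`` (unconstrained) admits anything.  Reference
    dtypes narrow when the target type narrows (``subtype_fn`` decides;
    without one, only equal targets pass).  Compound dtypes must be equal.
    """
    if parent is None:
        return True
    if child is None:
        return False
    if isinstance(parent, str):
        return isinstance(child, str) and child in NARROWER_THAN.get(parent, ())
    if isinstance(parent, RefDtype):
        if not isinstance(child, RefDtype) or child.reftype != parent.reftype:
            return False
        if child.target_type == parent.target_type:
            return True
        return subtype_fn is not None and subtype_fn(child.target_type, parent.target_type)
    if isinstance(parent, CompoundDtype):
        return child == parent
    return False


def _alternatives(shape):
    """Normalize a shape spec to a list of alternative shape tuples."""
    if shape is None:
        return None  # scalar
    if shape and isinstance(shape[0], tuple):
        return list(shape)
    return [shape]


def _shape_matches(child, parent):
    if len(child) != len(parent):
        return False
    for c, p in zip(child, parent):
        if p is None:
            continue  # wildcard admits any extent
        if c != p:
            return False
    return True


def shape_refines(child, parent):
    """True iff ``child`` admits no array shape that ``parent`` rejects."""
    palts = _alternatives(parent)
    calts = _alternatives(child)
    if palts is None:
        return calts is None
    if calts is None:
        return False
    return all(any(_shape_matches(c, p) for p in palts) for c in calts)


def shape_admits(shape_spec, actual_shape):
    """True iff concrete ``actual_shape`` satisfies a shape spec (with
    wildcards and alternatives); scalar spec admits only scalars (``None``)."""
    alts = _alternatives(shape_spec)
    if alts is None:
        return actual_shape is None or actual_shape == ()
    if actual_shape is None:
        return False
    return any(
        len(a) == len(actual_shape)
        and all(p is None or p == x for p, x in zip(a, actual_shape))
        for a in alts
    )


# ---------------------------------------------------------------------------
# resolved specs
# ---------------------------------------------------------------------------

@dataclass
class ResolvedGroupSpec(GroupSpec):
    #: ancestor type names, nearest parent first
    ancestry: list = field(default_factory=list)
    namespace: str = ""


@dataclass
class ResolvedDatasetSpec(DatasetSpec):
    ancestry: list = field(default_factory=list)
    namespace: str = ""


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

class TypeRegistry:
    """Holds registered namespaces and their raw type specs, plus a
    resolution cache.  Keys are ``(namespace_name, type_name)``."""

    def __init__(self):
        self.namespaces: dict[str, Namespace] = {}
        self.entries: dict[tuple, object] = {}
        self._cache: dict[tuple, object] = {}
        self._raw_docs: dict[str, list] = {}  # ns -> [(doc name, text)] for embedding

    # -- lookup ------------------------------------------------------------

    def visible_namespaces(self, ns_name):
        """Namespaces searched when ``ns_name`` references a bare type name:
        itself first, then its imports in declaration order."""
        ns = self.namespaces.get(ns_name)
        if ns is None:
            raise UnknownTypeError(f"namespace {ns_name!r} not registered")
        out = [ns_name]
        for src in ns.schema_sources:
            if src.namespace:
                out.append(src.namespace)
        return out

    def find_type(self, ns_name, type_name):
        """Resolve a bare type name from the point of view of a namespace;
        returns ``(owning_namespace, raw_spec)``."""
        for cand in self.visible_namespaces(ns_name):
            key = (cand, type_name)
            if key in self.entries:
                if cand != ns_name:
                    # respect an import's type subset, if declared
                    for src in self.namespaces[ns_name].schema_sources:
                        if src.namespace == cand and src.types is not None:
                            if type_name not in src.types:
                                continue
                return cand, self.entries[key]
        raise UnknownTypeError(
            f"type {type_name!r} not visible from namespace {ns_name!r}"
        )

    def locate(self, type_ref):
        """Accept ``(ns, name)`` or a bare name searched across namespaces
        in registration order."""
        if isinstance(type_ref, tuple):
            ns, name = type_ref
            if (ns, name) not in self.entries:
                raise UnknownTypeError(f"type {name!r} not in namespace {ns!r}")
            return ns, name
        for ns in self.namespaces:
            if (ns, type_ref) in self.entries:
                return ns, type_ref
        raise UnknownTypeError(f"type {type_ref!r} not registered")

    def __contains__(self, type_ref):
        try:
            self.locate(type_ref)
            return True
        except UnknownTypeError:
            return False


def register_namespace(reg, ns, specs, source_documents=None):
    """Register a namespace and its type specs; returns ``reg``.

    Re-registering an identical (name, version) pair is a no-op; a
    different version of an already-registered name is a conflict (one
    version per namespace per registry).  All imported namespaces must
    already be present and every ``type_inc`` / link target reachable, and
    ancestry must be acyclic — violations raise before the registry is
    mutated.

    ``source_documents`` optionally carries ``[(document_name, text), ...]``
    so storage backends can embed the verbatim schema in written files.
    """
    existing = reg.namespaces.get(ns.name)
    if existing is not None:
        if existing.version == ns.version:
            return reg
        raise ConflictError(
            f"namespace {ns.name!r} already registered at version "
            f"{existing.version}; got {ns.version}"
        )

    for imported in ns.imported_namespaces():
        if imported not in reg.namespaces:
            raise DependencyError(
                f"namespace {ns.name!r} imports unregistered {imported!r}"
            )

    new_entries = {}
    for spec in specs:
        if not spec.type_def:
            raise ConflictError(f"spec {spec.name!r} lacks type_def")
        key = (ns.name, spec.type_def)
        if key in new_entries:
            raise ConflictError(
                f"duplicate type {spec.type_def!r} in namespace {ns.name!r}"
            )
        new_entries[key] = spec

    # stage, then verify references and acyclicity against the staged view
    staged = copy.copy(reg.entries)
    staged.update(new_entries)
    staged_reg = copy.copy(reg)
    staged_reg.entries = staged
    staged_reg.namespaces = dict(reg.namespaces, **{ns.name: ns})

    for (ns_name, type_name), spec in new_entries.items():
        for ref in _collect_type_refs(spec):
            try:
                staged_reg.find_type(ns_name, ref)
            except UnknownTypeError:
                raise DependencyError(
                    f"type {type_name!r} in {ns_name!r} references "
                    f"unresolvable type {ref!r}"
                ) from None
        _check_acyclic(staged_reg, ns_name, type_name)

    reg.namespaces[ns.name] = ns
    reg.entries.update(new_entries)
    if source_documents is not None:
        reg._raw_docs[ns.name] = list(source_documents)
    return reg


def _collect_type_refs(spec):
    refs = []
    if getattr(spec, "type_inc", None):
        refs.append(spec.type_inc)
    if isinstance(spec, LinkSpec):
        refs.append(spec.target_type)
    dtype = getattr(spec, "dtype", None)
    if isinstance(dtype, RefDtype):
        refs.append(dtype.target_type)
    if isinstance(spec, GroupSpec):
        for child in spec.groups + spec.datasets + spec.links:
            refs.extend(_collect_type_refs(child))
    for a in getattr(spec, "attributes", []):
        if isinstance(a.dtype, RefDtype):
            refs.append(a.dtype.target_type)
    return refs


def _check_acyclic(reg, ns_name, type_name):
    seen = []
    ns, name = ns_name, type_name
    while True:
        if (ns, name) in seen:
            chain = " -> ".join(n for _, n in seen + [(ns, name)])
            raise CycleError(f"inheritance cycle: {chain}")
        seen.append((ns, name))
        spec = reg.entries[(ns, name)]
        if not spec.type_inc:
            return
        ns, spec_parent = reg.find_type(ns, spec.type_inc)
        name = spec.type_inc


# ---------------------------------------------------------------------------
# resolution (flattening over the ancestor chain)
# ---------------------------------------------------------------------------

def _ancestor_chain(reg, ns_name, type_name):
    """Raw specs from root ancestor down to the type itself, as
    ``[(ns, name, spec), ...]``."""
    chain = []
    ns, name = ns_name, type_name
    while True:
        spec = reg.entries[(ns, name)]
        chain.append((ns, name, spec))
        if not spec.type_inc:
            break
        ns, _ = reg.find_type(ns, spec.type_inc)
        name = spec.type_inc
    chain.reverse()
    return chain


def _child_key(child):
    if child.name is not None:
        return ("name", child.name)
    if isinstance(child, LinkSpec):
        return ("type", child.target_type)
    return ("type", child.type_def or child.type_inc)


def _merge_attributes(base_attrs, child_attrs, where, subtype_fn):
    merged = {a.name: copy.deepcopy(a) for a in base_attrs}
    order = [a.name for a in base_attrs]
    for a in child_attrs:
        if a.name in merged:
            old = merged[a.name]
            if not dtype_narrows(a.dtype, old.dtype, subtype_fn):
                raise RefinementError(
                    f"{where}: attribute {a.name!r} widens dtype "
                    f"{old.dtype!r} -> {a.dtype!r}"
                )
            if not shape_refines(a.shape, old.shape):
                raise RefinementError(
                    f"{where}: attribute {a.name!r} widens shape"
                )
            if old.required and not a.required:
                raise RefinementError(
                    f"{where}: attribute {a.name!r} demoted required -> optional"
                )
            merged[a.name] = copy.deepcopy(a)
        else:
            merged[a.name] = copy.deepcopy(a)
            order.append(a.name)
    return [merged[n] for n in order]


def _overlay(base, child, where, subtype_fn):
    """Merge ``child`` (nearer the leaf) over ``base``; returns a new spec.

    Children and attributes are keyed by name (or by type for anonymous
    children); matching entries are overlaid recursively, new entries
    appended.  Dataset dtype/shape and attribute constraints may only
    narrow.
    """
    if base.kind != child.kind:
        raise RefinementError(f"{where}: cannot overlay {child.kind} over {base.kind}")
    out = copy.deepcopy(base)
    out.name = child.name if child.name is not None else base.name
    out.doc = child.doc or base.doc
    out.quantity = child.quantity

    if isinstance(child, DatasetSpec):
        if child.dtype is not None:
            if not dtype_narrows(child.dtype, base.dtype, subtype_fn):
                raise RefinementError(
                    f"{where}: dtype widened {base.dtype!r} -> {child.dtype!r}"
                )
            out.dtype = copy.deepcopy(child.dtype)
        if child.shape is not None:
            if base.shape is not None and not shape_refines(child.shape, base.shape):
                raise RefinementError(f"{where}: shape widened")
            out.shape = child.shape
        if child.dims is not None:
            out.dims = child.dims
        out.attributes = _merge_attributes(
            base.attributes, child.attributes, where, subtype_fn
        )
        return out

    if isinstance(child, LinkSpec):
        if child.target_type != base.target_type:
            if subtype_fn is None or not subtype_fn(child.target_type, base.target_type):
                raise RefinementError(
                    f"{where}: link target widened {base.target_type!r} -> "
                    f"{child.target_type!r}"
                )
            out.target_type = child.target_type
        return out

    # GroupSpec
    out.attributes = _merge_attributes(base.attributes, child.attributes, where, subtype_fn)
    for attr in ("groups", "datasets", "links"):
        base_children = {_child_key(c): c for c in getattr(out, attr)}
        order = [_child_key(c) for c in getattr(out, attr)]
        for c in getattr(child, attr):
            key = _child_key(c)
            if key in base_children:
                base_children[key] = _overlay(
                    base_children[key], c, f"{where}/{key[1]}", subtype_fn
                )
            else:
                base_children[key] = copy.deepcopy(c)
                order.append(key)
        setattr(out, attr, [base_children[k] for k in order])
    return out


def resolve_type(reg, ns_name, type_name):
    """Flatten a registered type over its ancestor chain.

    The root ancestor's definition is merged first and each descendant
    overlays it; the result carries no ``type_inc`` at its root and lists
    its ancestry nearest-parent-first.  Results are cached; resolution is
    idempotent and pure.
    """
    if (ns_name, type_name) not in reg.entries:
        ns_name, type_name = _locate_or_raise(reg, ns_name, type_name)
    key = (ns_name, type_name)
    if key in reg._cache:
        return reg._cache[key]

    def subtype_fn(a, b):
        try:
            return is_subtype(reg, a, b)
        except UnknownTypeError:
            return False

    chain = _ancestor_chain(reg, ns_name, type_name)
    _, _, root = chain[0]
    merged = copy.deepcopy(root)
    for ns_i, name_i, spec in chain[1:]:
        merged = _overlay(merged, spec, f"{ns_i}:{name_i}", subtype_fn)

    ancestry = [name for _, name, _ in reversed(chain[:-1])]
    cls = ResolvedGroupSpec if isinstance(merged, GroupSpec) else ResolvedDatasetSpec
    resolved = cls(**{f: getattr(merged, f) for f in _spec_fields(merged)})
    resolved.type_def = type_name
    resolved.type_inc = None
    resolved.ancestry = ancestry
    resolved.namespace = ns_name
    reg._cache[key] = resolved
    return resolved


def _locate_or_raise(reg, ns_name, type_name):
    if ns_name in reg.namespaces:
        return reg.find_type(ns_name, type_name)
    raise UnknownTypeError(f"type {type_name!r} not in namespace {ns_name!r}")


def _spec_fields(spec):
    if isinstance(spec, GroupSpec):
        return (
            "name", "type_def", "type_inc", "quantity", "groups", "datasets",
            "links", "attributes", "doc",
        )
    return (
        "name", "type_def", "type_inc", "dtype", "shape", "dims", "quantity",
        "attributes", "doc",
    )


def apply_inline_spec(reg, resolved, inline_spec):
    """Overlay a slot's inline refinements (a child spec with ``type_inc``)
    onto a node's own resolved type.  Used when an instance of a subtype
    occupies a slot declared for one of its ancestors: the node is checked
    against its actual type narrowed by whatever the slot adds."""

    def subtype_fn(a, b):
        try:
            return is_subtype(reg, a, b)
        except UnknownTypeError:
            return False

    merged = _overlay(
        resolved, inline_spec, f"inline slot for {resolved.type_def}", subtype_fn
    )
    merged.type_def = resolved.type_def
    merged.type_inc = None
    return merged


def resolve_child(reg, ns_name, child_spec):
    """Resolve a child spec that includes a type: the included type is
    resolved first, then the inline refinements are overlaid (two-phase)."""
    inc = child_spec.type_inc
    if inc is None:
        return child_spec
    owner, _ = reg.find_type(ns_name, inc)
    base = resolve_type(reg, owner, inc)

    def subtype_fn(a, b):
        try:
            return is_subtype(reg, a, b)
        except UnknownTypeError:
            return False

    merged = _overlay(base, child_spec, f"{ns_name}:<child {inc}>", subtype_fn)
    merged.type_inc = inc
    merged.type_def = None
    return merged


# ---------------------------------------------------------------------------
# subtype relation
# ---------------------------------------------------------------------------

def is_subtype(reg, a, b):
    """True iff ``a`` is ``b`` or inherits from it (reflexive, transitive).

    Type refs are bare names or ``(namespace, name)`` pairs; unknown types
    raise :class:`UnknownTypeError`.
    """
    ns_a, name_a = reg.locate(a)
    ns_b, name_b = reg.locate(b)
    ns, name = ns_a, name_a
    while True:
        if (ns, name) == (ns_b, name_b):
            return True
        spec = reg.entries[(ns, name)]
        if not spec.type_inc:
            return False
        ns, _ = reg.find_type(ns, spec.type_inc)
        name = spec.type_inc
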