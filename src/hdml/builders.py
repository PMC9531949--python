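"""Storage-agnostic builder trees and the spec-driven object mapper.

Builders mirror the four specification-language primitives: a
:class:`GroupBuilder` holds named child groups, datasets and links plus
attributes; a :class:`DatasetBuilder` holds an array or scalar with a
declared dtype token; a :class:`LinkBuilder` points at another node by
absolute path.  Builders carry no storage concepts — backends translate
them to their own primitives, and the same tree writes identically through
every backend.

The object mapper is table-free: :func:`build` places container fields at
the node the resolved spec names (named children at spec names, typed
anonymous children at container-supplied names, links for the second and
later references to a shared container), and :func:`construct` inverts it.
Exactly two documented mappings go beyond that rule: the rate+starting_time
timing form is stored as a ``starting_time`` dataset carrying a ``rate``
attribute, and region/index references are stored as explicit index arrays
with a target-path attribute (``table`` / ``target``).
"""

from __future__ import annotations

import copy
import warnings

import numpy as np

from .containers import (
    CONTAINER_CLASSES,
    Container,
    Data,
    DynamicTableRegion,
    VectorIndex,
)
from .errors import ConstructError, MappingError
from .issues import ValidationIssue
from .spec_language import DatasetSpec, LinkSpec, resolve_quantity
from .type_system import is_subtype, resolve_child, resolve_type

__all__ = [
    "GroupBuilder",
    "DatasetBuilder",
    "LinkBuilder",
    "build",
    "construct",
    "resolve_links",
    "get_node",
    "iter_nodes",
    "ConstructWarning",
    "RESERVED_ATTRS",
    "SPEC_GROUP",
]

#: attribute keys reserved for type annotation
RESERVED_ATTRS = ("neurodata_type", "namespace", "object_id")
#: reserved root group holding embedded specification documents
SPEC_GROUP = "specifications"


class ConstructWarning(UserWarning):
    """Unknown node or attribute preserved in a container's escape hatch."""


# ---------------------------------------------------------------------------
# data normalization
# ---------------------------------------------------------------------------

_NUMERIC_TOKENS = {
    "int8", "int16", "int32", "int64",
    "uint8", "uint16", "uint32", "uint64",
    "float32", "float64", "bool",
}


def infer_dtype(data):
    if isinstance(data, str):
        return "text"
    if isinstance(data, bool) or isinstance(data, np.bool_):
        return "bool"
    if isinstance(data, (int, np.integer)):
        return "int64"
    if isinstance(data, (float, np.floating)):
        return "float64"
    if isinstance(data, (list, tuple)) and all(isinstance(x, str) for x in data):
        return "text"
    arr = np.asarray(data)
    if arr.dtype.kind in "US" or arr.dtype == object:
        return "text"
    name = arr.dtype.name
    if name in _NUMERIC_TOKENS:
        return name
    raise MappingError(f"cannot infer a dtype token for {arr.dtype}")


def normalize_data(data, dtype):
    """Coerce dataset payloads to the canonical in-memory form for a dtype
    token: numpy arrays for numeric data, python scalars for scalars, str /
    list-of-str for text."""
    if dtype is None:
        dtype = infer_dtype(data)
    if dtype in ("text", "isodatetime"):
        if isinstance(data, str):
            return data, dtype
        if isinstance(data, np.ndarray):
            data = data.tolist()
        return [str(x) for x in data], dtype
    if isinstance(dtype, str) and dtype in _NUMERIC_TOKENS:
        if np.isscalar(data) and not isinstance(data, str):
            return np.dtype(dtype).type(data).item(), dtype
        arr = np.asarray(data)
        if arr.ndim == 0:
            return np.dtype(dtype).type(arr[()]).item(), dtype
        if arr.dtype != np.dtype(dtype):
            arr = arr.astype(dtype)
        return arr, dtype
    # compound / reference dtypes pass through untouched
    return data, dtype


def normalize_attr(value):
    if isinstance(value, np.bool_):
        return bool(value)
    if isinstance(value, np.integer):
        return int(value)
    if isinstance(value, np.floating):
        return float(value)
    if isinstance(value, bytes):
        return value.decode("utf-8")
    if isinstance(value, np.ndarray):
        if value.ndim == 0:
            return normalize_attr(value[()])
        if value.dtype.kind in "US" or value.dtype == object:
            return [str(x) for x in value.tolist()]
        return value
    if isinstance(value, (list, tuple)):
        return [normalize_attr(v) for v in value]
    return value


def _attrs_equal(a, b):
    if isinstance(a, np.ndarray) or isinstance(b, np.ndarray):
        a, b = np.asarray(a), np.asarray(b)
        return a.dtype == b.dtype and np.array_equal(a, b)
    if isinstance(a, list) and isinstance(b, list):
        return len(a) == len(b) and all(_attrs_equal(x, y) for x, y in zip(a, b))
    return type(a) is type(b) and a == b


def _data_equal(a, b):
    if isinstance(a, np.ndarray) or isinstance(b, np.ndarray):
        a, b = np.asarray(a), np.asarray(b)
        return a.dtype == b.dtype and a.shape == b.shape and np.array_equal(a, b)
    return _attrs_equal(a, b)


# ---------------------------------------------------------------------------
# builder node kinds
# ---------------------------------------------------------------------------

class _Builder:
    def __init__(self, name, attributes=None):
        self.name = name
        self.attributes = {
            k: normalize_attr(v) for k, v in (attributes or {}).items()
        }

    def set_attribute(self, name, value):
        self.attributes[name] = normalize_attr(value)

    @property
    def neurodata_type(self):
        return self.attributes.get("neurodata_type")


class GroupBuilder(_Builder):
    kind = "group"

    def __init__(self, name, attributes=None):
        super().__init__(name, attributes)
        self.groups = {}
        self.datasets = {}
        self.links = {}

    def _check_free(self, name):
        if name in self.groups or name in self.datasets or name in self.links:
            raise MappingError(f"duplicate child name {name!r} under {self.name!r}")

    def add(self, child):
        self._check_free(child.name)
        bucket = {"group": self.groups, "dataset": self.datasets,
                  "link": self.links}[child.kind]
        bucket[child.name] = child
        return child

    def children(self):
        """All children in deterministic (sorted-name) order."""
        merged = {**self.groups, **self.datasets, **self.links}
        return [merged[k] for k in sorted(merged)]

    def get(self, name):
        return self.groups.get(name) or self.datasets.get(name) or self.links.get(name)

    def __eq__(self, other):
        if not isinstance(other, GroupBuilder):
            return NotImplemented
        if self.name != other.name:
            return False
        if self.attributes.keys() != other.attributes.keys():
            return False
        if not all(
            _attrs_equal(v, other.attributes[k]) for k, v in self.attributes.items()
        ):
            return False
        return (
            self.groups == other.groups
            and self.datasets == other.datasets
            and self.links == other.links
        )

    __hash__ = None

    def __repr__(self):
        return f"<GroupBuilder {self.name!r} children={sorted({**self.groups, **self.datasets, **self.links})}>"


class DatasetBuilder(_Builder):
    kind = "dataset"

    def __init__(self, name, data, dtype=None, attributes=None):
        super().__init__(name, attributes)
        self.data, self.dtype = normalize_data(data, dtype)

    @property
    def shape(self):
        if isinstance(self.data, np.ndarray):
            return self.data.shape
        if isinstance(self.data, list):
            return (len(self.data),)
        return None  # scalar

    def __eq__(self, other):
        if not isinstance(other, DatasetBuilder):
            return NotImplemented
        if self.name != other.name or self.dtype != other.dtype:
            return False
        if self.attributes.keys() != other.attributes.keys():
            return False
        if not all(
            _attrs_equal(v, other.attributes[k]) for k, v in self.attributes.items()
        ):
            return False
        return _data_equal(self.data, other.data)

    __hash__ = None

    def __repr__(self):
        return f"<DatasetBuilder {self.name!r} dtype={self.dtype} shape={self.shape}>"


class LinkBuilder:
    kind = "link"

    def __init__(self, name, target):
        self.name = name
        self.target = target  # absolute path within the tree

    def __eq__(self, other):
        if not isinstance(other, LinkBuilder):
            return NotImplemented
        return self.name == other.name and self.target == other.target

    __hash__ = None

    def __repr__(self):
        return f"<LinkBuilder {self.name!r} -> {self.target}>"


# ---------------------------------------------------------------------------
# tree navigation
# ---------------------------------------------------------------------------

def iter_nodes(root, path="/"):
    """Yield ``(path, node)`` over the whole tree, root first, children in
    sorted-name order."""
    yield path, root
    if isinstance(root, GroupBuilder):
        for child in root.children():
            child_path = path.rstrip("/") + "/" + child.name
            if isinstance(child, GroupBuilder):
                yield from iter_nodes(child, child_path)
            else:
                yield child_path, child


def get_node(root, path, follow_links=True):
    """Resolve an absolute path to a node, or ``None`` when dangling."""
    node = root
    for part in [p for p in path.split("/") if p]:
        if not isinstance(node, GroupBuilder):
            return None
        node = node.get(part)
        if node is None:
            return None
        if isinstance(node, LinkBuilder) and follow_links:
            node = get_node(root, node.target, follow_links=True)
            if node is None:
                return None
    return node


def resolve_links(root):
    """Verify every link target exists; dangling links are reported as
    issues (never exceptions) with their tree path."""
    issues = []
    for path, node in iter_nodes(root):
        if isinstance(node, LinkBuilder):
            if get_node(root, node.target, follow_links=False) is None:
                issues.append(
                    ValidationIssue(
                        "error", path, "link-target",
                        f"link target {node.target!r} does not exist",
                    )
                )
    return issues


# ---------------------------------------------------------------------------
# container -> builder
# ---------------------------------------------------------------------------

class _BuildContext:
    def __init__(self, reg):
        self.reg = reg
        self.placed = {}         # id(container) -> path
        self.pending_attrs = []  # (builder, attr_name, target_container)
        self.pending_links = []  # (parent_builder, link_name, target_container)

    def subtype(self, a, b):
        try:
            return is_subtype(self.reg, a, b)
        except Exception:
            return False


def build(container, reg):
    """Translate a container tree into a builder tree under spec control.

    Raises :class:`MappingError` when a field has no spec placement or a
    required spec entry has no field, naming the offending path.
    """
    ctx = _BuildContext(reg)
    root = _build_node(container, container.name, "/", ctx)
    _finalize_build(root, ctx)
    return root


def _finalize_build(root, ctx):
    for builder, attr, target in ctx.pending_attrs:
        path = ctx.placed.get(id(target))
        if path is None:
            raise MappingError(
                f"reference target {target.name!r} is not placed in the tree"
            )
        builder.set_attribute(attr, path)
    for parent, name, target in ctx.pending_links:
        path = ctx.placed.get(id(target))
        if path is None:
            raise MappingError(
                f"link target {target.name!r} is not placed in the tree"
            )
        parent.add(LinkBuilder(name, path))


def _annotate(builder, container):
    builder.set_attribute("neurodata_type", container.neurodata_type)
    builder.set_attribute("namespace", container.namespace)
    builder.set_attribute("object_id", container.object_id)


def _child_path(path, name):
    return path.rstrip("/") + "/" + name


def _build_node(container, name, path, ctx):
    if id(container) in ctx.placed:
        return LinkBuilder(name, ctx.placed[id(container)])
    resolved = resolve_type(ctx.reg, container.namespace, container.neurodata_type)
    if isinstance(resolved, DatasetSpec):
        builder = _build_dataset_node(container, name, resolved, ctx)
        planned_links = ()
    else:
        builder, planned_links = _build_group_node(container, name, path, resolved, ctx)
    _annotate(builder, container)
    ctx.placed[id(container)] = path
    _emit_extras(builder, container)
    _check_required(builder, resolved, path, planned_links)
    return builder


def _emit_extras(builder, container):
    for name, item in container.extras.items():
        if isinstance(item, (GroupBuilder, DatasetBuilder, LinkBuilder)):
            builder.add(copy.deepcopy(item))
        else:
            builder.set_attribute(name, item)


def _build_dataset_node(container, name, resolved, ctx):
    if not isinstance(container, Data) and "data" not in container.fields:
        raise MappingError(f"dataset-typed container {name!r} carries no data")
    builder = DatasetBuilder(name, container.fields["data"], dtype=resolved.dtype)
    spec_attrs = {a.name for a in resolved.attributes}
    for fname, value in sorted(container.fields.items()):
        if fname == "data" or value is None:
            continue
        if isinstance(value, Container):
            # documented mapping: index/region references become path attrs
            if fname in ("target", "table"):
                ctx.pending_attrs.append((builder, fname, value))
                continue
            raise MappingError(
                f"dataset field {name}.{fname} holds a container but is not "
                "a reference mapping"
            )
        if fname in spec_attrs:
            builder.set_attribute(fname, value)
        else:
            raise MappingError(f"field {fname!r} of {name!r} is not in the spec")
    return builder


def _anonymous_specs(resolved, kind):
    pool = resolved.groups if kind == "group" else resolved.datasets
    return [s for s in pool if s.name is None and s.type_inc]


def _match_anonymous(value, resolved, ctx, where):
    kind = "dataset" if isinstance(value, Data) else "group"
    candidates = [
        s for s in _anonymous_specs(resolved, kind)
        if ctx.subtype(
            (value.namespace, value.neurodata_type), s.type_inc
        ) or ctx.subtype(value.neurodata_type, s.type_inc)
    ]
    if not candidates:
        raise MappingError(
            f"{where}: type {value.neurodata_type!r} matches no spec slot"
        )
    # most-specific wins: the candidate whose included type every other
    # candidate's type also admits
    def depth(s):
        try:
            ns, nm = ctx.reg.locate(s.type_inc)
            return len(resolve_type(ctx.reg, ns, nm).ancestry)
        except Exception:
            return 0
    candidates.sort(key=depth, reverse=True)
    if len(candidates) > 1 and depth(candidates[0]) == depth(candidates[1]):
        raise MappingError(f"{where}: ambiguous spec slot for {value.neurodata_type!r}")
    return candidates[0]


def _build_group_node(container, name, path, resolved, ctx):
    builder = GroupBuilder(name)
    planned_links = set()
    ctx.placed[id(container)] = path  # allow children to link back to self
    spec_attrs = {a.name: a for a in resolved.attributes}
    named_groups = {s.name: s for s in resolved.groups if s.name}
    named_datasets = {s.name: s for s in resolved.datasets if s.name}
    named_links = {s.name: s for s in resolved.links if s.name}

    fields = dict(container.fields)
    # documented mapping: regular-sampling timing stored as a starting_time
    # dataset carrying the rate attribute
    if "rate" in fields:
        st = DatasetBuilder(
            "starting_time", float(fields.pop("starting_time", 0.0)),
            dtype="float64",
        )
        st.set_attribute("rate", float(fields.pop("rate")))
        builder.add(st)

    for fname in sorted(fields):
        value = fields[fname]
        if value is None:
            continue
        where = _child_path(path, fname)
        if fname in spec_attrs:
            builder.set_attribute(fname, value)
        elif fname in named_links:
            if not isinstance(value, Container):
                raise MappingError(f"{where}: link field must hold a container")
            ctx.pending_links.append((builder, fname, value))
            planned_links.add(fname)
        elif fname in named_datasets and not isinstance(value, Container):
            spec = named_datasets[fname]
            builder.add(DatasetBuilder(fname, value, dtype=spec.dtype))
        elif fname in named_datasets or fname in named_groups:
            spec = named_datasets.get(fname) or named_groups[fname]
            if isinstance(value, Container):
                builder.add(_build_node(value, fname, where, ctx))
            elif isinstance(value, dict):
                sub = GroupBuilder(fname)
                builder.add(sub)
                _fill_untyped_group(sub, value, where, ctx)
            else:
                raise MappingError(f"{where}: cannot map value of type {type(value)}")
        elif isinstance(value, Container):
            _match_anonymous(value, resolved, ctx, where)  # raises when unplaceable
            builder.add(_build_node(value, fname, where, ctx))
        else:
            raise MappingError(f"field {fname!r} of {name!r} is not in the spec")
    return builder, planned_links


def _fill_untyped_group(builder, members, path, ctx):
    for mname in sorted(members):
        member = members[mname]
        where = _child_path(path, mname)
        if isinstance(member, Container):
            builder.add(_build_node(member, mname, where, ctx))
        elif isinstance(member, dict):
            sub = GroupBuilder(mname)
            builder.add(sub)
            _fill_untyped_group(sub, member, where, ctx)
        else:
            raise MappingError(f"{where}: expected a container")


def _check_required(builder, resolved, path, planned_links=()):
    label = resolved.type_def or resolved.name
    for a in resolved.attributes:
        pending = a.name in getattr(builder, "attributes", {})
        if isinstance(builder, DatasetBuilder) and a.name in ("target", "table"):
            pending = True  # reference attrs are filled at finalize time
        if a.required and a.default_value is None and not pending:
            raise MappingError(
                f"missing required attribute {a.name!r} at {path} (spec {label})"
            )
    if isinstance(resolved, DatasetSpec):
        return
    for spec in list(resolved.groups) + list(resolved.datasets) + list(resolved.links):
        if spec.name is None:
            continue
        min_occurs, _ = resolve_quantity(spec.quantity)
        present = builder.get(spec.name) is not None or spec.name in planned_links
        if min_occurs >= 1 and not present:
            raise MappingError(
                f"missing required {spec.kind} {spec.name!r} at {path} (spec {label})"
            )


# ---------------------------------------------------------------------------
# builder -> container
# ---------------------------------------------------------------------------

class _ConstructContext:
    def __init__(self, reg):
        self.reg = reg
        self.by_path = {}   # path -> container
        self.pending = []   # (container, field_name, target_path)
        self.pending_dict = []  # (dict, key, target_path)

    def subtype(self, a, b):
        try:
            return is_subtype(self.reg, a, b)
        except Exception:
            return False


def construct(root_builder, reg):
    """Translate a builder tree back into containers (inverse of
    :func:`build`).

    Unannotated extra nodes and unknown attributes are preserved in the
    container's escape-hatch ``extras`` bag and reported with a
    :class:`ConstructWarning`; shared nodes reached through links come back
    reference-identical.
    """
    if root_builder.neurodata_type is None:
        raise ConstructError("root builder carries no neurodata_type annotation")
    ctx = _ConstructContext(reg)
    root = _construct_node(root_builder, "/", ctx)
    for holder, fname, target in ctx.pending:
        resolved = ctx.by_path.get(target)
        if resolved is None:
            raise ConstructError(f"reference to {target!r} cannot be resolved")
        holder.fields[fname] = resolved
    for d, key, target in ctx.pending_dict:
        resolved = ctx.by_path.get(target)
        if resolved is None:
            raise ConstructError(f"link to {target!r} cannot be resolved")
        d[key] = resolved
    return root


def _resolved_spec_for(builder, path, ctx):
    t = builder.attributes.get("neurodata_type")
    ns = builder.attributes.get("namespace")
    try:
        if ns:
            return resolve_type(ctx.reg, ns, t)
        ns, t = ctx.reg.locate(t)
        return resolve_type(ctx.reg, ns, t)
    except Exception as e:
        raise ConstructError(f"cannot resolve type {t!r} at {path}: {e}") from e


def _container_class(resolved):
    for name in [resolved.type_def] + list(resolved.ancestry):
        if name in CONTAINER_CLASSES:
            return CONTAINER_CLASSES[name]
    return Data if isinstance(resolved, DatasetSpec) else Container


def _construct_node(builder, path, ctx):
    resolved = _resolved_spec_for(builder, path, ctx)
    cls = _container_class(resolved)
    fields = {}
    container = cls._from_fields(
        name=builder.name,
        neurodata_type=builder.attributes["neurodata_type"],
        namespace=builder.attributes.get("namespace", ""),
        object_id=builder.attributes.get("object_id") or None,
        fields=fields,
    )
    ctx.by_path[path] = container

    spec_attrs = {a.name for a in resolved.attributes}
    path_attr_fields = _reference_attr_names(builder, ctx)
    for aname, avalue in builder.attributes.items():
        if aname in RESERVED_ATTRS:
            continue
        if aname in path_attr_fields:
            ctx.pending.append((container, aname, avalue))
        elif aname in spec_attrs:
            container.fields[aname] = avalue
        else:
            container.extras[aname] = avalue
            warnings.warn(
                f"unknown attribute {aname!r} at {path} preserved in extras",
                ConstructWarning, stacklevel=3,
            )

    if isinstance(builder, DatasetBuilder):
        container.fields["data"] = builder.data
        return container

    named_groups = {s.name: s for s in resolved.groups if s.name}
    named_datasets = {s.name: s for s in resolved.datasets if s.name}
    named_links = {s.name: s for s in resolved.links if s.name}

    for child in builder.children():
        if path == "/" and child.name == SPEC_GROUP:
            continue  # reserved schema cache, not user data
        cpath = _child_path(path, child.name)
        cname = child.name
        if isinstance(child, LinkBuilder):
            ctx.pending.append((container, cname, child.target))
            continue
        typed = getattr(child, "neurodata_type", None) is not None
        if typed:
            container.fields[cname] = _construct_node(child, cpath, ctx)
            continue
        if isinstance(child, DatasetBuilder):
            spec = named_datasets.get(cname)
            if spec is None:
                container.extras[cname] = child
                warnings.warn(
                    f"unknown dataset {cname!r} at {path} preserved in extras",
                    ConstructWarning, stacklevel=3,
                )
                continue
            if "rate" in child.attributes and any(
                a.name == "rate" for a in spec.attributes
            ):
                # inverse of the documented timing mapping
                container.fields["starting_time"] = child.data
                container.fields["rate"] = child.attributes["rate"]
            else:
                container.fields[cname] = child.data
                for aname, avalue in child.attributes.items():
                    if aname not in RESERVED_ATTRS:
                        container.fields.setdefault(aname, avalue)
            continue
        # untyped group child
        if cname in named_groups and named_groups[cname].type_inc is None:
            container.fields[cname] = _construct_untyped_group(child, cpath, ctx)
        else:
            container.extras[cname] = child
            warnings.warn(
                f"unknown group {cname!r} at {path} preserved in extras",
                ConstructWarning, stacklevel=3,
            )
    return container


def _construct_untyped_group(builder, path, ctx):
    members = {}
    for child in builder.children():
        cpath = _child_path(path, child.name)
        if isinstance(child, LinkBuilder):
            ctx.pending_dict.append((members, child.name, child.target))
        elif getattr(child, "neurodata_type", None) is not None:
            members[child.name] = _construct_node(child, cpath, ctx)
        elif isinstance(child, GroupBuilder):
            members[child.name] = _construct_untyped_group(child, cpath, ctx)
        else:
            members[child.name] = child.data
    return members


def _reference_attr_names(builder, ctx):
    """Attribute names on this node that hold tree paths (the documented
    region/index reference mapping), decided by the node's type."""
    t = builder.attributes.get("neurodata_type")
    if t is None:
        return ()
    names = []
    if ctx.subtype(t, "VectorIndex"):
        names.append("target")
    if ctx.subtype(t, "DynamicTableRegion"):
        names.append("table")
    return tuple(names)
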