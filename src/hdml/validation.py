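"""Schema-driven validation of builder trees.

Every typed node is checked against its resolved spec.  The rule
catalogue (rule ids are stable tokens):

======================== ============== =======================================
rule id                  severity       checks
======================== ============== =======================================
required-presence        error          required child/attribute present
dtype-compat             error          stored dtype is the spec dtype or a
                                        documented narrowing (e.g. int32 data
                                        against an int64 spec passes; the
                                        reverse fails)
shape-conform            error          array shape matches the spec shape,
                                        honouring wildcards and alternatives
quantity-bounds          error          count of typed anonymous children
                                        within the spec quantity bounds
timestamps-nondecreasing error          timestamps datasets are sorted
ragged-index             error          ragged index arrays non-decreasing and
                                        ending at the target column length
link-target              error          link/region targets exist and are of
                                        (a subtype of) the declared type
unknown-typed-child      warning        node or attribute matches no spec slot
missing-recommended      best_practice  optional recommended metadata absent
======================== ============== =======================================

A tree without any type annotations yields exactly one ``untyped-tree``
warning.  Severities can be re-graded per rule via ``severity_overrides``.
"""

from __future__ import annotations

import numpy as np

from .builders import (
    DatasetBuilder,
    GroupBuilder,
    LinkBuilder,
    RESERVED_ATTRS,
    SPEC_GROUP,
    get_node,
)
from .issues import ValidationIssue
from .spec_language import DatasetSpec, LinkSpec, RefDtype, resolve_quantity
from .type_system import (
    NARROWER_THAN,
    apply_inline_spec,
    is_subtype,
    resolve_type,
    shape_admits,
)

__all__ = ["RULES", "validate_builders", "format_report", "validate_file"]

RULES = (
    "required-presence",
    "dtype-compat",
    "shape-conform",
    "quantity-bounds",
    "timestamps-nondecreasing",
    "ragged-index",
    "link-target",
    "unknown-typed-child",
    "missing-recommended",
)

_DEFAULT_SEVERITY = {rule: "error" for rule in RULES}
_DEFAULT_SEVERITY["unknown-typed-child"] = "warning"
_DEFAULT_SEVERITY["missing-recommended"] = "best_practice"
_DEFAULT_SEVERITY["untyped-tree"] = "warning"


class _Validator:
    def __init__(self, root, reg, severity_overrides=None):
        self.root = root
        self.reg = reg
        self.issues = []
        self.severity = dict(_DEFAULT_SEVERITY, **(severity_overrides or {}))

    def report(self, rule, path, message):
        self.issues.append(
            ValidationIssue(self.severity[rule], path, rule, message)
        )

    def subtype(self, a, b):
        try:
            return is_subtype(self.reg, a, b)
        except Exception:
            return False

    # -- node dispatch -----------------------------------------------------

    def visit_typed(self, builder, path, inline_spec=None):
        t = builder.attributes.get("neurodata_type")
        ns = builder.attributes.get("namespace")
        try:
            if ns:
                resolved = resolve_type(self.reg, ns, t)
            else:
                ns, t = self.reg.locate(t)
                resolved = resolve_type(self.reg, ns, t)
        except Exception:
            self.report("unknown-typed-child", path, f"unresolvable type {t!r}")
            return
        if inline_spec is not None and inline_spec.type_inc:
            try:
                resolved = apply_inline_spec(self.reg, resolved, inline_spec)
            except Exception:
                pass  # slot refinements that cannot merge fall back to the type
        if isinstance(builder, DatasetBuilder):
            self.check_dataset(builder, path, resolved)
        else:
            self.check_group(builder, path, resolved)

    # -- attribute checks --------------------------------------------------

    def check_attributes(self, builder, path, resolved):
        spec_attrs = {a.name: a for a in resolved.attributes}
        for a in resolved.attributes:
            if a.name in builder.attributes:
                self.check_attr_value(builder.attributes[a.name], a, path)
            elif a.required and a.default_value is None:
                self.report(
                    "required-presence", path,
                    f"required attribute {a.name!r} missing "
                    f"(type {resolved.type_def or resolved.name})",
                )
            else:
                self.report(
                    "missing-recommended", path,
                    f"optional attribute {a.name!r} not set",
                )
        for name in builder.attributes:
            if name in RESERVED_ATTRS or name in spec_attrs:
                continue
            self.report(
                "unknown-typed-child", path,
                f"attribute {name!r} matches no spec entry",
            )

    def check_attr_value(self, value, spec, path):
        where = f"{path}@{spec.name}"
        if isinstance(spec.dtype, RefDtype):
            if not isinstance(value, str):
                self.report("dtype-compat", where, "reference attribute must be a path")
            return
        token = spec.dtype
        ok = True
        if isinstance(value, np.ndarray):
            ok = value.dtype.name in NARROWER_THAN.get(token, ())
            if ok and not shape_admits(spec.shape, value.shape):
                self.report("shape-conform", where, f"shape {value.shape} not allowed")
        elif isinstance(value, list):
            ok = token == "text" and all(isinstance(x, str) for x in value)
            if ok and not shape_admits(spec.shape, (len(value),)):
                self.report("shape-conform", where, f"length {len(value)} not allowed")
        elif isinstance(value, str):
            ok = token in ("text", "isodatetime")
        elif isinstance(value, bool):
            ok = token == "bool"
        elif isinstance(value, int):
            ok = token.startswith(("int", "uint")) if isinstance(token, str) else False
        elif isinstance(value, float):
            ok = token in ("float32", "float64")
        if not ok:
            self.report(
                "dtype-compat", where,
                f"value of kind {type(value).__name__} incompatible with dtype {token!r}",
            )

    # -- dataset checks ----------------------------------------------------

    def check_dataset(self, builder, path, spec):
        self.check_attributes(builder, path, spec)
        if spec.dtype is not None and not isinstance(spec.dtype, RefDtype):
            stored = builder.dtype
            if stored != spec.dtype and (
                not isinstance(spec.dtype, str)
                or stored not in NARROWER_THAN.get(spec.dtype, ())
            ):
                self.report(
                    "dtype-compat", path,
                    f"dtype {stored!r} incompatible with spec dtype {spec.dtype!r}",
                )
        if spec.shape is not None or builder.shape is not None:
            if not shape_admits(spec.shape, builder.shape):
                self.report(
                    "shape-conform", path,
                    f"shape {builder.shape} not admitted by spec {spec.shape}",
                )
        if builder.name == "timestamps" and isinstance(builder.data, np.ndarray):
            if builder.data.size and np.any(np.diff(builder.data) < 0):
                self.report(
                    "timestamps-nondecreasing", path, "timestamps decrease"
                )
        t = builder.attributes.get("neurodata_type")
        if t and self.subtype(t, "VectorIndex"):
            self.check_ragged_index(builder, path)
            self.check_reference(builder, path, "target", "VectorData")
        if t and self.subtype(t, "DynamicTableRegion"):
            self.check_reference(builder, path, "table", "DynamicTable")

    def check_ragged_index(self, builder, path):
        idx = np.asarray(builder.data)
        if idx.size and np.any(np.diff(idx) < 0):
            self.report("ragged-index", path, "index offsets decrease")
            return
        target_path = builder.attributes.get("target")
        if isinstance(target_path, str):
            target = get_node(self.root, target_path)
            if isinstance(target, DatasetBuilder) and idx.size:
                n = (
                    len(target.data)
                    if not isinstance(target.data, np.ndarray)
                    else target.data.shape[0]
                )
                if int(idx[-1]) != n:
                    self.report(
                        "ragged-index", path,
                        f"last offset {int(idx[-1])} != target length {n}",
                    )

    def check_reference(self, builder, path, attr, required_type):
        target_path = builder.attributes.get(attr)
        if not isinstance(target_path, str):
            return
        target = get_node(self.root, target_path)
        if target is None:
            self.report(
                "link-target", path,
                f"{attr} path {target_path!r} does not exist",
            )
            return
        t = getattr(target, "attributes", {}).get("neurodata_type")
        if t is not None and not self.subtype(t, required_type):
            self.report(
                "link-target", path,
                f"{attr} target is {t!r}, not a {required_type}",
            )

    # -- group checks ------------------------------------------------------

    def check_group(self, builder, path, resolved):
        self.check_attributes(builder, path, resolved)
        named = {}
        for s in list(resolved.groups) + list(resolved.datasets) + list(resolved.links):
            if s.name:
                named[s.name] = s
        anon_groups = [s for s in resolved.groups if not s.name and s.type_inc]
        anon_datasets = [s for s in resolved.datasets if not s.name and s.type_inc]
        anon_links = [s for s in resolved.links if not s.name]
        anon_counts = {id(s): 0 for s in anon_groups + anon_datasets + anon_links}

        seen = set()
        for child in builder.children():
            if path == "/" and child.name == SPEC_GROUP:
                continue  # reserved schema cache
            cpath = path.rstrip("/") + "/" + child.name
            spec = named.get(child.name)
            if spec is not None:
                seen.add(child.name)
                self.check_named_child(child, cpath, spec)
                continue
            match = self.match_anonymous(child, anon_groups, anon_datasets, anon_links, cpath)
            if match is None:
                if isinstance(child, LinkBuilder):
                    self.check_link(child, cpath, None)
                kind = getattr(child, "kind", "node")
                t = getattr(child, "attributes", {}).get("neurodata_type")
                self.report(
                    "unknown-typed-child", cpath,
                    f"{kind} of type {t!r} matches no spec entry"
                    if t else f"untyped {kind} matches no spec entry",
                )
                continue
            anon_counts[id(match)] += 1
            if isinstance(child, LinkBuilder):
                self.check_link(child, cpath, match)
            else:
                self.visit_typed(child, cpath, inline_spec=match)

        # named requirements and quantities
        for name, spec in named.items():
            min_occurs, _ = resolve_quantity(spec.quantity)
            if name not in seen and min_occurs >= 1:
                self.report(
                    "required-presence", path,
                    f"required {spec.kind} {name!r} missing "
                    f"(type {resolved.type_def or resolved.name})",
                )
        for spec in anon_groups + anon_datasets + anon_links:
            min_occurs, max_occurs = resolve_quantity(spec.quantity)
            n = anon_counts[id(spec)]
            label = spec.target_type if isinstance(spec, LinkSpec) else spec.type_inc
            if n < min_occurs or (max_occurs is not None and n > max_occurs):
                self.report(
                    "quantity-bounds", path,
                    f"{n} children of type {label!r}; spec allows "
                    f"[{min_occurs}, {'inf' if max_occurs is None else max_occurs}]",
                )

    def check_named_child(self, child, cpath, spec):
        if isinstance(spec, LinkSpec):
            if isinstance(child, LinkBuilder):
                self.check_link(child, cpath, spec)
            else:
                self.report(
                    "unknown-typed-child", cpath,
                    f"expected a link at {spec.name!r}",
                )
            return
        if isinstance(child, LinkBuilder):
            # a link standing in for a named child: follow and type-check
            self.check_link(child, cpath, spec if spec.type_inc else None)
            return
        expected_kind = "dataset" if isinstance(spec, DatasetSpec) else "group"
        if child.kind != expected_kind:
            self.report(
                "unknown-typed-child", cpath,
                f"{child.kind} found where spec declares a {expected_kind}",
            )
            return
        if getattr(child, "neurodata_type", None):
            self.visit_typed(child, cpath, inline_spec=spec if spec.type_inc else None)
        elif isinstance(child, DatasetBuilder):
            self.check_dataset(child, cpath, spec)
        else:
            self.check_group(child, cpath, spec)

    def check_link(self, link, cpath, spec):
        target = get_node(self.root, link.target, follow_links=False)
        if target is None:
            self.report(
                "link-target", cpath,
                f"link target {link.target!r} does not exist",
            )
            return
        required = None
        if isinstance(spec, LinkSpec):
            required = spec.target_type
        elif spec is not None:
            required = spec.type_inc
        if required:
            t = getattr(target, "attributes", {}).get("neurodata_type")
            if t is None or not self.subtype(t, required):
                self.report(
                    "link-target", cpath,
                    f"link target type {t!r} is not a {required!r}",
                )

    def match_anonymous(self, child, anon_groups, anon_datasets, anon_links, cpath):
        if isinstance(child, LinkBuilder):
            target = get_node(self.root, child.target)
            t = getattr(target, "attributes", {}).get("neurodata_type") if target else None
            pools = [
                (anon_links, lambda s: s.target_type),
                (anon_groups, lambda s: s.type_inc),
                (anon_datasets, lambda s: s.type_inc),
            ]
            if t is None:
                return None
            candidates = [
                s for pool, target_of in pools for s in pool
                if self.subtype(t, target_of(s))
            ]
        else:
            t = getattr(child, "attributes", {}).get("neurodata_type")
            if t is None:
                return None
            pool = anon_datasets if isinstance(child, DatasetBuilder) else anon_groups
            candidates = [s for s in pool if self.subtype(t, s.type_inc)]
        if not candidates:
            return None
        if len(candidates) == 1:
            return candidates[0]

        def depth(s):
            ref = s.target_type if isinstance(s, LinkSpec) else s.type_inc
            try:
                ns, nm = self.reg.locate(ref)
                return len(resolve_type(self.reg, ns, nm).ancestry)
            except Exception:
                return 0

        candidates.sort(key=depth, reverse=True)
        if depth(candidates[0]) == depth(candidates[1]):
            self.report(
                "unknown-typed-child", cpath,
                f"type {t!r} matches several spec slots ambiguously",
            )
        return candidates[0]


def validate_builders(root, reg, severity_overrides=None):
    """Validate a builder tree against the registered schemas.

    Returns graded issues; never raises on invalid data.  A tree whose
    root carries no type annotation yields a single ``untyped-tree``
    warning.
    """
    v = _Validator(root, reg, severity_overrides)
    if root.attributes.get("neurodata_type") is None:
        v.report("untyped-tree", "/", "tree carries no type annotations")
        return v.issues
    v.visit_typed(root, "/")
    return v.issues


def format_report(issues, as_json=False):
    """Render issues as a stable text report (errors first, then by path)
    or as its machine-readable JSON equivalent with identical content."""
    ordered = sorted(issues, key=lambda i: i.sort_key())
    if as_json:
        import json

        return json.dumps(
            {
                "summary": {
                    "errors": sum(1 for i in issues if i.severity == "error"),
                    "warnings": sum(1 for i in issues if i.severity == "warning"),
                    "best_practice": sum(
                        1 for i in issues if i.severity == "best_practice"
                    ),
                },
                "issues": [
                    {
                        "severity": i.severity,
                        "path": i.path,
                        "rule_id": i.rule_id,
                        "message": i.message,
                    }
                    for i in ordered
                ],
            },
            indent=2,
        )
    if not issues:
        return "PASS: no issues found\n"
    lines = [
        f"{i.severity.upper():>13}  {i.path}  [{i.rule_id}] {i.message}"
        for i in ordered
    ]
    n_err = sum(1 for i in issues if i.severity == "error")
    verdict = "FAIL" if n_err else "PASS"
    lines.append(
        f"{verdict}: {n_err} errors, "
        f"{sum(1 for i in issues if i.severity == 'warning')} warnings, "
        f"{sum(1 for i in issues if i.severity == 'best_practice')} best-practice notes"
    )
    return "\n".join(lines) + "\n"


def validate_file(path, backend="hdf5", registry=None):
    """Read a file with a backend and validate it.

    Without an explicit registry the file's own embedded specifications
    are used (self-describing files need nothing else).  Returns
    ``(issues, builder_tree)``.
    """
    from .storage import get_backend, load_embedded_specifications

    root = get_backend(backend).read(path)
    reg = registry if registry is not None else load_embedded_specifications(root)
    return validate_builders(root, reg), root
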