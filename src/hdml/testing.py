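"""Seeded random generators of specs, builder trees and type hierarchies.

These drive the package's property checks: round-trip fidelity of the
specification language and the storage backends, and agreement of the
inheritance resolver with brute-force oracles, are all exercised on trees
drawn from these generators.  Everything is driven by a caller-supplied
``numpy.random.Generator`` so runs are reproducible.
"""

from __future__ import annotations

import numpy as np

from .builders import DatasetBuilder, GroupBuilder, LinkBuilder, iter_nodes
from .spec_language import (
    AttributeSpec,
    DatasetSpec,
    GroupSpec,
    LinkSpec,
    Namespace,
    SchemaSource,
)

__all__ = [
    "random_spec_tree",
    "random_namespace",
    "random_builder_tree",
    "random_type_hierarchy",
]

_SCALAR_DTYPES = (
    "int8", "int16", "int32", "int64", "uint8", "uint16", "uint32",
    "uint64", "float32", "float64", "bool", "text", "isodatetime",
)
_NUMERIC_DTYPES = tuple(d for d in _SCALAR_DTYPES if d not in ("text", "isodatetime"))
_QUANTITIES = ("?", "*", "+", 1, 2, 3)

_WORDS = (
    "alpha", "beta", "gamma", "delta", "epsilon", "zeta", "eta", "theta",
    "iota", "kappa", "lam", "mu", "nu", "xi", "omicron", "pi", "rho",
    "sigma", "tau", "upsilon",
)


def _name(rng, taken):
    while True:
        n = f"{_WORDS[rng.integers(len(_WORDS))]}{rng.integers(100)}"
        if n not in taken:
            taken.add(n)
            return n


def _maybe(rng, p=0.5):
    return rng.random() < p


def _random_shape(rng):
    if _maybe(rng, 0.3):
        return None  # scalar
    ndim = int(rng.integers(1, 3))
    one = tuple(
        None if _maybe(rng, 0.5) else int(rng.integers(1, 5)) for _ in range(ndim)
    )
    if _maybe(rng, 0.2):
        other = tuple(
            None if _maybe(rng, 0.5) else int(rng.integers(1, 5))
            for _ in range(int(rng.integers(1, 3)))
        )
        return (one, other)
    return one


def _random_attribute(rng, taken):
    dtype = _SCALAR_DTYPES[rng.integers(len(_SCALAR_DTYPES))]
    default = None
    if dtype in ("int32", "int64") and _maybe(rng, 0.3):
        default = int(rng.integers(0, 10))
    elif dtype == "text" and _maybe(rng, 0.3):
        default = "fallback"
    return AttributeSpec(
        name=_name(rng, taken),
        dtype=dtype,
        doc="random attribute",
        shape=None if _maybe(rng, 0.7) else (int(rng.integers(1, 4)),),
        required=bool(_maybe(rng, 0.7)),
        default_value=default,
    )


def _random_dataset_spec(rng, taken, typed=False):
    taken_attrs = set()
    return DatasetSpec(
        name=None if typed else _name(rng, taken),
        type_def=_name(rng, taken).capitalize() if typed else None,
        dtype=None if _maybe(rng, 0.2) else _SCALAR_DTYPES[rng.integers(len(_SCALAR_DTYPES))],
        shape=_random_shape(rng),
        quantity=_QUANTITIES[rng.integers(len(_QUANTITIES))] if not typed else 1,
        attributes=[
            _random_attribute(rng, taken_attrs) for _ in range(rng.integers(0, 3))
        ],
        doc="random dataset",
    )


def random_spec_tree(rng, depth=3):
    """A random well-formed group type spec of bounded depth."""
    taken = set()
    return _random_group_spec(rng, taken, depth, typed=True)


def _random_group_spec(rng, taken, depth, typed=False):
    # ``taken`` is the sibling namespace this spec's own name draws from;
    # ``child_names`` is the namespace shared by its children
    child_names = set()
    groups = []
    if depth > 0:
        groups = [
            _random_group_spec(rng, child_names, depth - 1)
            for _ in range(rng.integers(0, 3))
        ]
    taken_attrs = set()
    return GroupSpec(
        name=None if typed else _name(rng, taken),
        type_def=_name(rng, taken).capitalize() if typed else None,
        quantity=1 if typed else _QUANTITIES[rng.integers(len(_QUANTITIES))],
        groups=groups,
        datasets=[
            _random_dataset_spec(rng, child_names)
            for _ in range(rng.integers(0, 3))
        ],
        links=[
            LinkSpec(
                name=_name(rng, child_names),
                target_type="Anchor",
                quantity=_QUANTITIES[rng.integers(len(_QUANTITIES))],
                doc="random link",
            )
            for _ in range(rng.integers(0, 2))
        ],
        attributes=[
            _random_attribute(rng, taken_attrs) for _ in range(rng.integers(0, 3))
        ],
        doc="random group",
    )


def random_namespace(rng, n_types=2):
    """A random namespace plus matching top-level type specs."""
    taken = set()
    specs = [random_spec_tree(rng, depth=int(rng.integers(0, 3))) for _ in range(n_types)]
    specs.append(
        GroupSpec(type_def="Anchor", doc="link-target anchor type")
    )
    name = f"test-ns-{rng.integers(1000)}"
    ns = Namespace(
        name=name,
        version=f"{rng.integers(0, 3)}.{rng.integers(0, 9)}.{rng.integers(0, 9)}",
        doc="random namespace",
        authors=["generator"],
        schema_sources=[SchemaSource(source=f"{name}.yaml")],
    )
    return ns, specs


# ---------------------------------------------------------------------------
# builder trees
# ---------------------------------------------------------------------------

def _random_attr_value(rng):
    choice = rng.integers(6)
    if choice == 0:
        return f"véleur-{rng.integers(100)}"  # exercises unicode
    if choice == 1:
        return int(rng.integers(-1000, 1000))
    if choice == 2:
        return float(rng.normal())
    if choice == 3:
        return bool(_maybe(rng))
    if choice == 4:
        return [f"s{int(i)}" for i in rng.integers(0, 9, size=rng.integers(1, 4))]
    dtype = _NUMERIC_DTYPES[rng.integers(len(_NUMERIC_DTYPES))]
    return _random_array(rng, dtype, max_ndim=1)


def _random_array(rng, dtype, max_ndim=2):
    shape = tuple(int(rng.integers(0, 5)) for _ in range(int(rng.integers(1, max_ndim + 1))))
    if dtype == "bool":
        return rng.integers(0, 2, size=shape).astype(bool)
    if dtype.startswith("uint"):
        return rng.integers(0, 100, size=shape).astype(dtype)
    if dtype.startswith("int"):
        return rng.integers(-100, 100, size=shape).astype(dtype)
    return rng.normal(size=shape).astype(dtype)


def _random_dataset_builder(rng, name):
    kind = rng.integers(5)
    if kind == 0:
        data = f"texte-{rng.integers(100)}"
        return DatasetBuilder(name, data, dtype="text")
    if kind == 1:
        data = [f"w{int(i)}" for i in rng.integers(0, 9, size=rng.integers(0, 4))]
        return DatasetBuilder(name, data, dtype="text")
    if kind == 2:  # scalar numeric
        dtype = _NUMERIC_DTYPES[rng.integers(len(_NUMERIC_DTYPES))]
        value = bool(_maybe(rng)) if dtype == "bool" else (
            float(rng.normal()) if dtype.startswith("float") else int(rng.integers(0, 100))
        )
        return DatasetBuilder(name, value, dtype=dtype)
    dtype = _NUMERIC_DTYPES[rng.integers(len(_NUMERIC_DTYPES))]
    return DatasetBuilder(name, _random_array(rng, dtype))


def random_builder_tree(rng, depth=3, n_links=2):
    """A random builder tree with mixed dtypes, unicode attributes and
    valid internal links."""
    root = GroupBuilder("root")
    taken = set()

    def fill(group, d):
        for _ in range(int(rng.integers(0, 3))):
            group.set_attribute(_name(rng, taken), _random_attr_value(rng))
        for _ in range(int(rng.integers(1, 4))):
            ds = _random_dataset_builder(rng, _name(rng, taken))
            for _ in range(int(rng.integers(0, 2))):
                ds.set_attribute(_name(rng, taken), _random_attr_value(rng))
            group.add(ds)
        if d > 0:
            for _ in range(int(rng.integers(0, 3))):
                sub = GroupBuilder(_name(rng, taken))
                group.add(sub)
                fill(sub, d - 1)

    fill(root, depth)
    paths = [p for p, n in iter_nodes(root) if p != "/" and not isinstance(n, LinkBuilder)]
    for _ in range(min(n_links, len(paths))):
        target = paths[rng.integers(len(paths))]
        root.add(LinkBuilder(_name(rng, taken), target))
    return root


# ---------------------------------------------------------------------------
# inheritance hierarchies
# ---------------------------------------------------------------------------

_NARROWING_CHAINS = {
    "int64": ("int64", "int32", "int16", "int8"),
    "uint64": ("uint64", "uint32", "uint16", "uint8"),
    "float64": ("float64", "float32"),
    "text": ("text", "isodatetime"),
}


def random_type_hierarchy(rng, depth=3, max_fields=8):
    """A random inheritance chain ``T0 <- T1 <- ...`` honouring the
    narrowing-only refinement rule.

    Returns ``(namespace, specs)`` where each spec extends the previous
    one, overriding some inherited entries (narrowing dtypes, upgrading
    required flags) and adding new ones.
    """
    taken = set()
    base_dtypes = list(_NARROWING_CHAINS)

    def fresh_attr(names):
        dtype = base_dtypes[rng.integers(len(base_dtypes))]
        return AttributeSpec(
            name=_name(rng, names), dtype=dtype, doc="field",
            required=bool(_maybe(rng, 0.5)),
        )

    def fresh_dataset(names):
        dtype = base_dtypes[rng.integers(len(base_dtypes))]
        return DatasetSpec(
            name=_name(rng, names), dtype=dtype,
            shape=(None,) if _maybe(rng, 0.7) else None,
            quantity="?" if _maybe(rng, 0.3) else 1,
            doc="field",
        )

    def narrowed(dtype, rng):
        chain = _NARROWING_CHAINS[
            next(k for k, v in _NARROWING_CHAINS.items() if dtype in v)
        ]
        start = chain.index(dtype)
        return chain[int(rng.integers(start, len(chain)))]

    specs = []
    names_per_level = set()
    n_fields = int(rng.integers(1, max_fields // 2 + 1))
    root = GroupSpec(
        type_def=f"T0x{rng.integers(1000)}",
        attributes=[fresh_attr(names_per_level) for _ in range(n_fields)],
        datasets=[fresh_dataset(names_per_level) for _ in range(n_fields)],
        doc="root type",
    )
    specs.append(root)
    prev = root
    for level in range(1, depth + 1):
        attrs, datasets = [], []
        for a in prev.attributes:
            if _maybe(rng, 0.4):  # override, narrowing only
                attrs.append(
                    AttributeSpec(
                        name=a.name, dtype=narrowed(a.dtype, rng), doc="override",
                        required=a.required or bool(_maybe(rng, 0.5)),
                    )
                )
        for d in prev.datasets:
            if _maybe(rng, 0.4):
                datasets.append(
                    DatasetSpec(
                        name=d.name, dtype=narrowed(d.dtype, rng),
                        shape=d.shape, quantity=d.quantity, doc="override",
                    )
                )
        for _ in range(int(rng.integers(0, max_fields // 2 + 1))):
            if _maybe(rng):
                attrs.append(fresh_attr(names_per_level))
            else:
                datasets.append(fresh_dataset(names_per_level))
        child = GroupSpec(
            type_def=f"T{level}x{rng.integers(1000)}",
            type_inc=prev.type_def,
            attributes=attrs,
            datasets=datasets,
            doc=f"level-{level} type",
        )
        specs.append(child)
        prev = child
    name = f"hier-{rng.integers(10000)}"
    ns = Namespace(
        name=name, version="0.1.0", doc="random hierarchy",
        schema_sources=[SchemaSource(source=f"{name}.yaml")],
    )
    return ns, specs
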