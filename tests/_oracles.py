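"""Independent brute-force oracles used by the test suite.

These deliberately re-derive expected results with the most naive
implementation available (plain dict merges, repeated parent lookups,
step-by-step accumulation) so they share no code path with the package
internals they check.
"""

from __future__ import annotations

from hdml.spec_language import AttributeSpec, DatasetSpec


def naive_resolve(raw_by_name, type_name):
    """Sequential dict-based flattening of an inheritance chain.

    Returns ``(ancestry, attrs, datasets)`` where attrs/datasets are
    name-keyed dicts of ``(dtype, shape, quantity/required)`` tuples,
    merged root ancestor first with child-wins override of scalar fields.
    """
    chain = []
    cur = type_name
    while cur is not None:
        spec = raw_by_name[cur]
        chain.append(spec)
        cur = spec.type_inc
    chain.reverse()

    attrs, datasets = {}, {}
    for spec in chain:
        for a in spec.attributes:
            attrs[a.name] = (a.dtype, a.shape, a.required)
        for d in spec.datasets:
            if d.name in datasets:
                base_dtype, base_shape, _ = datasets[d.name]
                datasets[d.name] = (
                    d.dtype if d.dtype is not None else base_dtype,
                    d.shape if d.shape is not None else base_shape,
                    d.quantity,
                )
            else:
                datasets[d.name] = (d.dtype, d.shape, d.quantity)
    ancestry = [s.type_def for s in reversed(chain[:-1])]
    return ancestry, attrs, datasets


def transitive_supertypes(raw_by_name, type_name):
    """All supertypes (including the type itself) by repeated parent
    lookup."""
    out = set()
    cur = type_name
    while cur is not None:
        out.add(cur)
        cur = raw_by_name[cur].type_inc
    return out


def accumulated_timestamps(rate, start, n):
    """Step-by-step accumulation of a constant sampling interval."""
    out, t, dt = [], float(start), 1.0 / float(rate)
    for _ in range(n):
        out.append(t)
        t = t + dt
    return out
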