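"""Type registration, inheritance resolution and the subtype relation."""

import numpy as np
import pytest

from _oracles import naive_resolve, transitive_supertypes
from hdml.errors import (
    ConflictError,
    CycleError,
    DependencyError,
    RefinementError,
    UnknownTypeError,
)
from hdml.spec_language import (
    AttributeSpec,
    DatasetSpec,
    GroupSpec,
    Namespace,
    SchemaSource,
)
from hdml.testing import random_type_hierarchy
from hdml.type_system import (
    TypeRegistry,
    dtype_narrows,
    is_subtype,
    register_namespace,
    resolve_type,
    shape_refines,
)


def _ns(name="test", imports=(), version="0.1.0"):
    return Namespace(
        name=name, version=version, doc="test namespace",
        schema_sources=[SchemaSource(namespace=i) for i in imports],
    )


class TestRegistration:
    def test_register_core_then_extension_importing_core(self, reg):
        import copy

        r = copy.deepcopy(reg)
        ext = _ns("ext-one", imports=("mini-core",))
        child = GroupSpec(type_def="FancySeries", type_inc="TimeSeries", doc="d")
        register_namespace(r, ext, [child])
        assert is_subtype(r, ("ext-one", "FancySeries"), ("mini-core", "TimeSeries"))
        resolved = resolve_type(r, "ext-one", "FancySeries")
        assert {d.name for d in resolved.datasets} >= {"data", "timestamps"}

    def test_register_empty_namespace_only_touches_table(self):
        r = TypeRegistry()
        register_namespace(r, _ns("empty"), [])
        assert "empty" in r.namespaces
        assert r.entries == {}

    def test_reregistering_same_version_is_a_noop(self):
        r = TypeRegistry()
        spec = GroupSpec(type_def="A", doc="d")
        register_namespace(r, _ns(), [spec])
        register_namespace(r, _ns(), [spec])
        assert list(r.entries) == [("test", "A")]

    def test_different_version_conflicts(self):
        r = TypeRegistry()
        register_namespace(r, _ns(version="0.1.0"), [])
        with pytest.raises(ConflictError, match="version"):
            register_namespace(r, _ns(version="0.2.0"), [])

    def test_duplicate_type_in_namespace_conflicts(self):
        r = TypeRegistry()
        specs = [GroupSpec(type_def="A", doc="d"), GroupSpec(type_def="A", doc="d")]
        with pytest.raises(ConflictError, match="duplicate"):
            register_namespace(r, _ns(), specs)

    def test_unregistered_import_is_a_dependency_error(self):
        r = TypeRegistry()
        with pytest.raises(DependencyError, match="missing-ns"):
            register_namespace(r, _ns(imports=("missing-ns",)), [])

    def test_unresolvable_parent_is_a_dependency_error(self):
        r = TypeRegistry()
        orphan = GroupSpec(type_def="B", type_inc="NoSuchParent", doc="d")
        with pytest.raises(DependencyError, match="NoSuchParent"):
            register_namespace(r, _ns(), [orphan])

    def test_inheritance_cycle_rejected_at_registration(self):
        r = TypeRegistry()
        a = GroupSpec(type_def="A", type_inc="B", doc="d")
        b = GroupSpec(type_def="B", type_inc="A", doc="d")
        with pytest.raises(CycleError):
            register_namespace(r, _ns(), [a, b])


class TestResolution:
    def test_electrical_series_inherits_and_requires_electrodes(self, reg):
        resolved = resolve_type(reg, "mini-core", "ElectricalSeries")
        names = [d.name for d in resolved.datasets]
        assert "data" in names and "timestamps" in names
        electrodes = next(d for d in resolved.datasets if d.name == "electrodes")
        assert electrodes.type_inc == "DynamicTableRegion"
        assert resolved.ancestry == ["TimeSeries"]
        assert resolved.type_inc is None

    def test_type_without_parent_resolves_to_itself(self, reg):
        raw = reg.entries[("mini-core", "DynamicTable")]
        resolved = resolve_type(reg, "mini-core", "DynamicTable")
        assert resolved.ancestry == []
        assert [a.name for a in resolved.attributes] == [a.name for a in raw.attributes]
        assert [d.name for d in resolved.datasets if d.name] == [
            d.name for d in raw.datasets if d.name
        ]

    def test_resolution_is_idempotent_and_cached(self, reg):
        first = resolve_type(reg, "mini-core", "Units")
        second = resolve_type(reg, "mini-core", "Units")
        assert first is second
        # a fresh registry resolves to an equal structure
        from hdml.core_schema import core_registry

        other = resolve_type(core_registry(), "mini-core", "Units")
        assert other == first

    def test_widening_dtype_refinement_rejected(self):
        r = TypeRegistry()
        parent = GroupSpec(
            type_def="P", doc="d",
            datasets=[DatasetSpec(name="v", dtype="int32", doc="d")],
        )
        child = GroupSpec(
            type_def="C", type_inc="P", doc="d",
            datasets=[DatasetSpec(name="v", dtype="int64", doc="d")],
        )
        register_namespace(r, _ns(), [parent, child])
        with pytest.raises(RefinementError, match="widen"):
            resolve_type(r, "test", "C")

    def test_demoting_required_attribute_rejected(self):
        r = TypeRegistry()
        parent = GroupSpec(
            type_def="P", doc="d",
            attributes=[AttributeSpec("a", "text", doc="d", required=True)],
        )
        child = GroupSpec(
            type_def="C", type_inc="P", doc="d",
            attributes=[AttributeSpec("a", "text", doc="d", required=False)],
        )
        register_namespace(r, _ns(), [parent, child])
        with pytest.raises(RefinementError, match="required"):
            resolve_type(r, "test", "C")

    def test_upgrading_optional_to_required_allowed(self):
        r = TypeRegistry()
        parent = GroupSpec(
            type_def="P", doc="d",
            attributes=[AttributeSpec("a", "text", doc="d", required=False)],
        )
        child = GroupSpec(
            type_def="C", type_inc="P", doc="d",
            attributes=[AttributeSpec("a", "text", doc="d", required=True)],
        )
        register_namespace(r, _ns(), [parent, child])
        resolved = resolve_type(r, "test", "C")
        assert resolved.attributes[0].required is True

    def test_required_entries_of_root_survive_to_leaf(self, reg):
        # for any chain A <: B <: C, every required entry of C appears in A
        resolved = resolve_type(reg, "mini-core", "PlaneSegmentation")
        root_attrs = {
            a.name for a in reg.entries[("mini-core", "DynamicTable")].attributes
        }
        assert root_attrs <= {a.name for a in resolved.attributes}


class TestOracles:
    def test_resolver_matches_naive_merge_on_random_hierarchies(self, subtests=None):
        disagreements = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            ns, specs = random_type_hierarchy(
                rng, depth=int(rng.integers(1, 4)), max_fields=8
            )
            r = TypeRegistry()
            register_namespace(r, ns, specs)
            raw = {s.type_def: s for s in specs}
            for s in specs:
                resolved = resolve_type(r, ns.name, s.type_def)
                ancestry, attrs, datasets = naive_resolve(raw, s.type_def)
                got_attrs = {
                    a.name: (a.dtype, a.shape, a.required)
                    for a in resolved.attributes
                }
                got_datasets = {
                    d.name: (d.dtype, d.shape, d.quantity)
                    for d in resolved.datasets
                }
                if (
                    resolved.ancestry != ancestry
                    or got_attrs != attrs
                    or got_datasets != datasets
                ):
                    disagreements += 1
        assert disagreements == 0

    def test_subtype_matches_transitive_closure(self):
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            ns, specs = random_type_hierarchy(rng, depth=3)
            r = TypeRegistry()
            register_namespace(r, ns, specs)
            raw = {s.type_def: s for s in specs}
            names = list(raw)
            for a in names:
                closure = transitive_supertypes(raw, a)
                for b in names:
                    assert is_subtype(r, (ns.name, a), (ns.name, b)) == (b in closure)


class TestSubtype:
    def test_reflexive(self, reg):
        assert is_subtype(reg, "TimeSeries", "TimeSeries")

    def test_known_chain(self, reg):
        assert is_subtype(reg, "ElectricalSeries", "TimeSeries")
        assert not is_subtype(reg, "TimeSeries", "ElectricalSeries")
        assert is_subtype(reg, "VectorIndex", "VectorData")

    def test_unknown_type_raises(self, reg):
        with pytest.raises(UnknownTypeError):
            is_subtype(reg, "Phantom", "TimeSeries")


class TestNarrowing:
    @pytest.mark.parametrize(
        "child,parent,ok",
        [
            ("int32", "int64", True),
            ("int64", "int32", False),
            ("uint8", "int16", True),
            ("uint16", "int16", False),
            ("float32", "float64", True),
            ("float64", "float32", False),
            ("isodatetime", "text", True),
            ("text", "isodatetime", False),
            ("bool", "bool", True),
            ("int8", None, True),
        ],
    )
    def test_dtype_narrowing_table(self, child, parent, ok):
        assert dtype_narrows(child, parent) is ok

    @pytest.mark.parametrize(
        "child,parent,ok",
        [
            ((3,), (None,), True),
            ((None,), (3,), False),
            ((3, 4), (None, 4), True),
            (None, None, True),
            (None, (None,), False),
            (((3,), (3, 3)), ((None,), (None, None)), True),
            (((3,), (3, 3, 3)), ((None,),), False),
        ],
    )
    def test_shape_refinement(self, child, parent, ok):
        assert shape_refines(child, parent) is ok
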