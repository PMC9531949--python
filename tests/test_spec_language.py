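"""Specification-language grammar, parsing and round-trip fidelity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hdml.errors import SpecError, SpecSyntaxError
from hdml.spec_language import (
    AttributeSpec,
    DatasetSpec,
    GroupSpec,
    LinkSpec,
    PRIMITIVE_KINDS,
    SpecWarning,
    check_spec_wellformed,
    parse_spec_document,
    resolve_quantity,
    serialize_spec_document,
)
from hdml.testing import random_namespace

TIMESERIES_DOC = """
groups:
- type_def: TimeSeries
  doc: A measurement sampled over time.
  attributes:
  - {name: unit, dtype: text, doc: Unit of measurement.}
  datasets:
  - {name: data, shape: [[null], [null, null]], doc: The samples.}
  - {name: timestamps, dtype: float64, shape: [[null]], quantity: '?',
     doc: Sample times in seconds.}
"""


def test_group_type_with_dataset_children_parses():
    ns, specs = parse_spec_document(TIMESERIES_DOC)
    assert ns is None
    (spec,) = specs
    assert spec.type_def == "TimeSeries"
    assert [d.name for d in spec.datasets] == ["data", "timestamps"]
    assert spec.datasets[1].dtype == "float64"
    assert spec.attributes[0].dtype == "text"


def test_empty_document_parses_to_nothing():
    assert parse_spec_document("") == (None, [])


def test_exactly_four_primitive_kinds():
    # the parser's output alphabet is exactly groups, datasets,
    # attributes and links — no fifth node kind is representable
    assert len(PRIMITIVE_KINDS) == 4
    kinds = {cls.kind for cls in (GroupSpec, DatasetSpec, AttributeSpec, LinkSpec)}
    assert kinds == set(PRIMITIVE_KINDS)


def test_random_spec_trees_round_trip():
    for seed in range(100):
        rng = np.random.default_rng(seed)
        ns, specs = random_namespace(rng, n_types=2)
        text = serialize_spec_document(ns, specs)
        ns2, specs2 = parse_spec_document(text)
        assert ns2 == ns
        assert specs2 == specs


def test_serialized_output_is_deterministic():
    rng = np.random.default_rng(7)
    ns, specs = random_namespace(rng)
    assert serialize_spec_document(ns, specs) == serialize_spec_document(ns, specs)


def test_namespace_sources_keep_order():
    from hdml.spec_language import Namespace, SchemaSource

    ns = Namespace(
        name="two-sources", version="1.0.0", doc="d",
        schema_sources=[SchemaSource(source="a.yaml"), SchemaSource(source="b.yaml")],
    )
    text = serialize_spec_document(ns, [])
    ns2, _ = parse_spec_document(text)
    assert [s.source for s in ns2.schema_sources] == ["a.yaml", "b.yaml"]


def test_attribute_default_value_round_trips():
    spec = GroupSpec(
        type_def="WithDefault", doc="d",
        attributes=[AttributeSpec("level", "int32", doc="d", required=False,
                                  default_value=3)],
    )
    text = serialize_spec_document(None, [spec])
    assert "default_value: 3" in text
    _, (spec2,) = parse_spec_document(text)
    assert spec2 == spec


def test_unserializable_default_value_errors():
    spec = GroupSpec(
        type_def="Bad", doc="d",
        attributes=[AttributeSpec("x", "int32", doc="d", default_value=object())],
    )
    with pytest.raises(SpecError):
        serialize_spec_document(None, [spec])


@pytest.mark.parametrize(
    "token,expected",
    [("?", (0, 1)), ("*", (0, None)), ("+", (1, None)), (1, (1, 1)), (3, (3, 3))],
)
def test_quantity_grammar(token, expected):
    assert resolve_quantity(token) == expected


@given(st.integers(min_value=1, max_value=10**6))
@settings(derandomize=True, max_examples=50)
def test_integer_quantities_are_exact_counts(n):
    assert resolve_quantity(n) == (n, n)


@pytest.mark.parametrize("token", ["x", 0, -2, 1.5, None, True])
def test_unknown_quantity_token_is_a_spec_error(token):
    with pytest.raises(SpecError):
        resolve_quantity(token)


def test_syntax_error_reports_position():
    with pytest.raises(SpecSyntaxError) as e:
        parse_spec_document("groups:\n- {type_def: X, doc: [unclosed}\n")
    assert e.value.line is not None


def test_missing_doc_names_offending_definition():
    with pytest.raises(SpecError, match="Broken"):
        parse_spec_document("groups:\n- type_def: Broken\n")


def test_missing_identity_is_a_spec_error():
    with pytest.raises(SpecError, match="name, type_def, type_inc"):
        parse_spec_document("groups:\n- doc: nameless and typeless\n")


def test_unknown_keys_warn_but_parse():
    doc = "groups:\n- type_def: Tolerant\n  doc: ok\n  color: blue\n"
    with pytest.warns(SpecWarning, match="color"):
        _, specs = parse_spec_document(doc)
    assert specs[0].type_def == "Tolerant"


def test_unknown_dtype_token_rejected():
    with pytest.raises(SpecError, match="dtype"):
        parse_spec_document(
            "datasets:\n- {type_def: D, dtype: complex128, doc: d}\n"
        )


class TestWellformedness:
    def test_dims_shape_length_mismatch_is_one_issue(self):
        spec = DatasetSpec(name="d", shape=(None, None), dims=("time",), doc="d")
        issues = check_spec_wellformed(spec)
        assert len(issues) == 1
        assert issues[0].rule_id == "spec-dims"

    def test_anonymous_untyped_child_is_one_issue(self):
        spec = GroupSpec(
            type_def="Parent", doc="d", datasets=[DatasetSpec(doc="orphan")]
        )
        issues = check_spec_wellformed(spec)
        assert [i.rule_id for i in issues] == ["spec-anonymous", "spec-identity"]

    def test_duplicate_child_names_flagged(self):
        spec = GroupSpec(
            type_def="Dup", doc="d",
            datasets=[DatasetSpec(name="a", doc="d"), DatasetSpec(name="a", doc="d")],
        )
        assert any(i.rule_id == "spec-dup-name" for i in check_spec_wellformed(spec))

    def test_shipped_core_schema_is_wellformed(self):
        from hdml.core_schema import load_core_namespace

        _, specs, _ = load_core_namespace()
        assert specs, "core schema should define types"
        for spec in specs:
            assert check_spec_wellformed(spec) == []

    def test_pure_function_same_issues_twice(self):
        spec = DatasetSpec(name="d", shape=(None, None), dims=("t",), doc="d")
        assert check_spec_wellformed(spec) == check_spec_wellformed(spec)
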