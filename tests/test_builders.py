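"""Object mapping: container -> builder -> container round trips, shared
containers as links, and the escape hatch for unknown data."""

import numpy as np
import pytest

from conftest import random_container
from hdml.builders import (
    ConstructWarning,
    DatasetBuilder,
    GroupBuilder,
    LinkBuilder,
    build,
    construct,
    get_node,
    iter_nodes,
    resolve_links,
)
from hdml.containers import Container, SessionRoot, TimeSeries, add_to_session
from hdml.errors import ConstructError, MappingError


def _ts(name="ts", n=4):
    return TimeSeries(
        name, np.arange(n, dtype=np.float64), unit="volts", rate=10.0,
        starting_time=0.25, description="a series",
    )


class TestBuild:
    def test_rate_form_maps_to_starting_time_dataset_with_rate_attr(self, reg):
        b = build(_ts(), reg)
        assert isinstance(b, GroupBuilder)
        assert b.attributes["neurodata_type"] == "TimeSeries"
        assert b.attributes["namespace"] == "mini-core"
        assert "object_id" in b.attributes
        data = b.datasets["data"]
        assert data.dtype == "float64"
        st = b.datasets["starting_time"]
        assert st.data == 0.25 and st.attributes["rate"] == 10.0
        assert "timestamps" not in b.datasets

    def test_minimal_container_builds_exactly_required_nodes(self, reg):
        ts = TimeSeries("m", np.zeros(2), unit="v", rate=1.0)  # no description
        b = build(ts, reg)
        assert sorted(b.datasets) == ["data", "starting_time"]
        assert b.groups == {} and b.links == {}
        assert sorted(
            k for k in b.attributes
            if k not in ("neurodata_type", "namespace", "object_id")
        ) == ["unit"]

    def test_missing_required_field_is_a_mapping_error(self, reg):
        bare = Container("nounit", "TimeSeries",
                         fields={"data": np.zeros(2), "rate": 1.0,
                                 "starting_time": 0.0})
        with pytest.raises(MappingError, match="unit"):
            build(bare, reg)

    def test_unknown_field_is_a_mapping_error(self, reg):
        ts = _ts()
        ts.fields["mystery"] = 42
        with pytest.raises(MappingError, match="mystery"):
            build(ts, reg)

    def test_round_trip_on_random_valid_containers(self, reg):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            c = random_container(rng, reg)
            back = construct(build(c, reg), reg)
            assert back == c, f"seed {seed} round trip failed"


class TestSharing:
    def test_second_reference_becomes_a_link(self, reg):
        root = SessionRoot(session_description="d", identifier="i",
                           session_start_time="2022-01-01T00:00:00+00:00")
        shared = _ts("shared")
        add_to_session(root, "acquisition", shared)
        add_to_session(root, "stimulus", shared)
        tree = build(root, reg)
        kinds = {
            name: ("link" if isinstance(g.get("shared"), LinkBuilder) else "group")
            for name, g in (("acquisition", tree.groups["acquisition"]),
                            ("stimulus", tree.groups["stimulus"]))
        }
        assert sorted(kinds.values()) == ["group", "link"]

    def test_reconstruction_restores_reference_identity(self, reg):
        root = SessionRoot(session_description="d", identifier="i",
                           session_start_time="2022-01-01T00:00:00+00:00")
        shared = _ts("shared")
        add_to_session(root, "acquisition", shared)
        add_to_session(root, "stimulus", shared)
        back = construct(build(root, reg), reg)
        assert back.acquisition["shared"] is back.stimulus["shared"]
        assert back == root


class TestConstruct:
    def test_inverse_of_build(self, reg, session_container, session_tree):
        assert construct(session_tree, reg) == session_container

    def test_untyped_root_is_a_construct_error(self, reg):
        with pytest.raises(ConstructError, match="neurodata_type"):
            construct(GroupBuilder("root"), reg)

    def test_unknown_extra_dataset_preserved_with_warning(self, reg):
        tree = build(_ts(), reg)
        tree.add(DatasetBuilder("surprise", np.arange(3)))
        with pytest.warns(ConstructWarning, match="surprise"):
            back = construct(tree, reg)
        assert "surprise" in back.extras
        # the escape hatch re-emits the node on the next build
        again = build(back, reg)
        assert again.datasets["surprise"] == tree.datasets["surprise"]
        assert again == tree

    def test_unknown_type_annotation_is_a_construct_error(self, reg):
        tree = build(_ts(), reg)
        tree.attributes["neurodata_type"] = "Martian"
        with pytest.raises(ConstructError, match="Martian"):
            construct(tree, reg)


class TestLinks:
    def test_valid_tree_has_no_dangling_links(self, session_tree):
        assert resolve_links(session_tree) == []

    def test_dangling_link_reported_with_path(self, reg):
        tree = build(_ts(), reg)
        tree.add(LinkBuilder("ghost", "/no/such/node"))
        issues = resolve_links(tree)
        assert len(issues) == 1
        assert issues[0].path == "/ghost"
        assert issues[0].rule_id == "link-target"

    def test_injected_dangle_count_matches_issue_count(self, reg):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            from hdml.testing import random_builder_tree

            tree = random_builder_tree(rng, depth=2, n_links=2)
            n_injected = int(rng.integers(0, 4))
            for i in range(n_injected):
                tree.add(LinkBuilder(f"dangle{i}", f"/missing/{i}"))
            assert len(resolve_links(tree)) == n_injected

    def test_get_node_follows_links(self, reg):
        tree = build(_ts(), reg)
        tree.add(LinkBuilder("alias", "/data"))
        assert get_node(tree, "/alias") is tree.datasets["data"]


def test_iter_nodes_is_sorted_and_complete(session_tree):
    paths = [p for p, _ in iter_nodes(session_tree)]
    assert paths[0] == "/"
    assert len(paths) == len(set(paths))
    # children of every group appear in sorted order
    by_parent = {}
    for p in paths[1:]:
        parent, _, name = p.rpartition("/")
        by_parent.setdefault(parent or "/", []).append(name)
    for names in by_parent.values():
        assert names == sorted(names)
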