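"""Backend round trips, cross-backend equivalence, determinism and
self-describing files."""

import numpy as np
import pytest

from hdml.builders import DatasetBuilder, GroupBuilder, build, construct
from hdml.errors import StorageError
from hdml.storage import (
    directory,
    get_backend,
    hdf5,
    load_embedded_specifications,
)
from hdml.testing import random_builder_tree
from hdml.validation import validate_builders


@pytest.mark.parametrize("backend", ["hdf5", "dir"])
class TestRoundTrip:
    def _dest(self, tmp_path, backend, i=0):
        return str(tmp_path / (f"t{i}.h5" if backend == "hdf5" else f"t{i}.store"))

    def test_random_trees_round_trip(self, tmp_path, backend):
        be = get_backend(backend)
        for seed in range(40):
            tree = random_builder_tree(np.random.default_rng(seed))
            dest = self._dest(tmp_path, backend, seed)
            be.write(tree, dest)
            assert be.read(dest) == tree, f"seed {seed}"

    def test_session_round_trip(self, tmp_path, backend, reg, session_tree):
        be = get_backend(backend)
        dest = self._dest(tmp_path, backend)
        be.write(session_tree, dest)
        assert be.read(dest) == session_tree

    def test_zero_length_dataset_preserved(self, tmp_path, backend):
        tree = GroupBuilder("root")
        tree.add(DatasetBuilder("empty", np.empty((0, 3), dtype=np.float32)))
        be = get_backend(backend)
        dest = self._dest(tmp_path, backend)
        be.write(tree, dest)
        back = be.read(dest).datasets["empty"]
        assert back.data.shape == (0, 3)
        assert back.dtype == "float32"

    def test_unicode_attributes_survive(self, tmp_path, backend):
        tree = GroupBuilder("root", {"résumé": "héllo wörld ∆t≤1µs"})
        be = get_backend(backend)
        dest = self._dest(tmp_path, backend)
        be.write(tree, dest)
        assert be.read(dest).attributes["résumé"] == "héllo wörld ∆t≤1µs"


class TestBackendEquivalence:
    def test_random_trees_agree_across_backends(self, tmp_path):
        for seed in range(40):
            tree = random_builder_tree(np.random.default_rng(seed))
            h5 = str(tmp_path / f"e{seed}.h5")
            store = str(tmp_path / f"e{seed}.store")
            hdf5.write(tree, h5)
            directory.write(tree, store)
            assert hdf5.read(h5) == directory.read(store) == tree

    def test_session_agrees_across_backends(self, tmp_path, reg, session_tree):
        h5 = str(tmp_path / "s.h5")
        store = str(tmp_path / "s.store")
        hdf5.write(session_tree, h5, registry=reg)
        directory.write(session_tree, store, registry=reg)
        assert hdf5.read(h5) == directory.read(store)

    def test_double_conversion_is_identity(self, tmp_path, session_tree):
        a = str(tmp_path / "a.h5")
        b = str(tmp_path / "b.store")
        c = str(tmp_path / "c.h5")
        hdf5.write(session_tree, a)
        directory.write(hdf5.read(a), b)
        hdf5.write(directory.read(b), c)
        assert hdf5.read(c) == session_tree


class TestDeterminism:
    def test_directory_backend_writes_identical_bytes(self, tmp_path, reg,
                                                      session_tree):
        d1, d2 = tmp_path / "w1", tmp_path / "w2"
        directory.write(session_tree, d1, registry=reg)
        directory.write(session_tree, d2, registry=reg)
        files1 = sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file())
        files2 = sorted(p.relative_to(d2) for p in d2.rglob("*") if p.is_file())
        assert files1 == files2
        for rel in files1:
            assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes(), rel

    def test_hdf5_rewrite_is_structurally_equal(self, tmp_path, session_tree):
        a, b = str(tmp_path / "a.h5"), str(tmp_path / "b.h5")
        hdf5.write(session_tree, a)
        hdf5.write(session_tree, b)
        assert hdf5.read(a) == hdf5.read(b)


class TestSelfDescription:
    def test_empty_root_writes_root_plus_specifications(self, tmp_path, reg):
        dest = str(tmp_path / "empty.h5")
        hdf5.write(GroupBuilder("root"), dest, registry=reg)
        back = hdf5.read(dest)
        assert sorted(back.groups) == ["specifications"]
        assert back.datasets == {} and back.links == {}
        assert "mini-core" in back.groups["specifications"].groups

    def test_minimal_session_file_has_acquisition_and_types(self, tmp_path, reg,
                                                            session_tree):
        dest = str(tmp_path / "s.h5")
        hdf5.write(session_tree, dest, registry=reg)
        back = hdf5.read(dest)
        assert "acquisition" in back.groups
        raw = back.groups["acquisition"].groups["raw_ephys"]
        assert raw.attributes["neurodata_type"] == "ElectricalSeries"
        assert raw.attributes["namespace"] == "mini-core"

    def test_embedded_specs_validate_file_from_empty_registry(self, tmp_path, reg,
                                                              session_tree,
                                                              session_container):
        dest = str(tmp_path / "s.h5")
        hdf5.write(session_tree, dest, registry=reg)
        back = hdf5.read(dest)
        file_reg = load_embedded_specifications(back)
        assert "mini-core" in file_reg.namespaces
        issues = validate_builders(back, file_reg)
        assert [i for i in issues if i.severity == "error"] == []
        assert construct(back, file_reg) == session_container

    def test_writing_without_registry_embeds_nothing(self, tmp_path, session_tree):
        dest = str(tmp_path / "bare.h5")
        hdf5.write(session_tree, dest)
        assert "specifications" not in hdf5.read(dest).groups


class TestErrors:
    def test_unreadable_hdf5_is_a_storage_error(self, tmp_path):
        bad = tmp_path / "corrupt.h5"
        bad.write_bytes(b"this is not an hdf5 file")
        with pytest.raises(StorageError):
            hdf5.read(str(bad))

    def test_missing_directory_store_is_a_storage_error(self, tmp_path):
        with pytest.raises(StorageError):
            directory.read(str(tmp_path / "nowhere"))

    def test_reserved_sidecar_name_collision_rejected(self, tmp_path):
        tree = GroupBuilder("root")
        tree.add(GroupBuilder("_node.json"))
        with pytest.raises(StorageError, match="reserved"):
            directory.write(tree, tmp_path / "x")

    def test_unknown_backend_token_rejected(self):
        with pytest.raises(ValueError, match="backend"):
            get_backend("tape")
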