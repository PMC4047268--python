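import zipfile

import pytest
from hypothesis import given, settings, strategies as st

from qsardb.errors import IntegrityError, InvalidIdentifier, MissingDescriptor
from qsardb.schema import (
    Archive,
    Compound,
    Descriptor,
    Model,
    Prediction,
    Property,
)
from qsardb.storage import (
    ARCHIVE_DESCRIPTOR,
    DirectoryBackend,
    ZipBackend,
    cargo_path,
    container_subdir,
    load_archive,
    registry_path,
    save_archive,
)
from qsardb.synth import SyntheticSpec, generate_archive


class TestPaths:
    @pytest.mark.parametrize(
        "ct,subdir",
        [
            (Compound, "compounds"),
            (Property, "properties"),
            (Descriptor, "descriptors"),
            (Model, "models"),
            (Prediction, "predictions"),
        ],
    )
    def test_container_subdir(self, ct, subdir):
        assert container_subdir(ct) == subdir

    def test_registry_paths(self):
        assert registry_path(Compound) == "compounds/compounds.xml"
        assert registry_path(Model) == "models/models.xml"

    def test_descriptor_path_constant(self):
        assert ARCHIVE_DESCRIPTOR == "archive.xml"

    def test_cargo_paths(self):
        assert cargo_path(Compound, "1", "smiles") == "compounds/1/smiles"
        assert cargo_path(Property, "p1", "values") == "properties/p1/values"
        assert cargo_path(Model, "m1", "org.dmg.pmml") == "models/m1/org.dmg.pmml"

    def test_cargo_path_rejects_bad_ids(self):
        with pytest.raises(InvalidIdentifier):
            cargo_path(Compound, "a b", "smiles")
        with pytest.raises(InvalidIdentifier):
            cargo_path(Compound, "1", "a/b")

    @given(
        cid=st.from_regex(r"[A-Za-z0-9._-]{1,10}", fullmatch=True),
        cargo=st.from_regex(r"[A-Za-z0-9._-]{1,10}", fullmatch=True),
    )
    def test_cargo_path_shape(self, cid, cargo):
        path = cargo_path(Compound, cid, cargo)
        assert path == f"compounds/{cid}/{cargo}"


class TestSaveLayout:
    def test_raw_archive_lists_two_subdirs(self, tmp_path):
        archive = Archive()
        archive.compounds.add(Compound(id="1"))
        archive.properties.add(Property(id="p1"))
        save_archive(archive, DirectoryBackend(tmp_path / "a"))
        listing = sorted(p.name for p in (tmp_path / "a").iterdir())
        assert listing == ["archive.xml", "compounds", "properties"]

    def test_fully_developed_archive_lists_five_subdirs(self, tmp_path, synthetic_archive):
        save_archive(synthetic_archive, DirectoryBackend(tmp_path / "a"))
        dirs = sorted(p.name for p in (tmp_path / "a").iterdir() if p.is_dir())
        assert dirs == ["compounds", "descriptors", "models", "predictions", "properties"]

    def test_empty_archive_is_descriptor_only(self, tmp_path):
        save_archive(Archive(), DirectoryBackend(tmp_path / "a"))
        assert [p.name for p in (tmp_path / "a").iterdir()] == ["archive.xml"]

    def test_save_replaces_existing_content(self, tmp_path):
        root = tmp_path / "a"
        archive = Archive()
        archive.compounds.add(Compound(id="1"))
        save_archive(archive, DirectoryBackend(root))
        save_archive(Archive(), DirectoryBackend(root))
        assert [p.name for p in root.iterdir()] == ["archive.xml"]

    def test_cargo_desync_is_integrity_error(self, tmp_path):
        archive = Archive()
        c = Compound(id="1")
        c.payloads["smiles"] = b"C\n"  # attached but not declared
        archive.compounds.add(c)
        with pytest.raises(IntegrityError):
            save_archive(archive, DirectoryBackend(tmp_path / "a"))


class TestLoad:
    def test_missing_descriptor(self, tmp_path):
        (tmp_path / "a").mkdir()
        with pytest.raises(MissingDescriptor):
            load_archive(DirectoryBackend(tmp_path / "a"))

    def test_round_trip_directory(self, tmp_path, synthetic_archive):
        save_archive(synthetic_archive, DirectoryBackend(tmp_path / "a"))
        assert load_archive(DirectoryBackend(tmp_path / "a")) == synthetic_archive

    def test_round_trip_zip(self, tmp_path, synthetic_archive):
        save_archive(synthetic_archive, ZipBackend(tmp_path / "a.qdb.zip"))
        assert load_archive(ZipBackend(tmp_path / "a.qdb.zip")) == synthetic_archive

    def test_backends_interchangeable(self, tmp_path, synthetic_archive):
        save_archive(synthetic_archive, DirectoryBackend(tmp_path / "a"))
        from_dir = load_archive(DirectoryBackend(tmp_path / "a"))
        save_archive(from_dir, ZipBackend(tmp_path / "a.qdb.zip"))
        assert load_archive(ZipBackend(tmp_path / "a.qdb.zip")) == synthetic_archive

    def test_extra_root_file_preserved(self, tmp_path, synthetic_archive):
        root = tmp_path / "a"
        save_archive(synthetic_archive, DirectoryBackend(root))
        (root / "license.txt").write_bytes(b"free as in beer\n")
        loaded = load_archive(DirectoryBackend(root))
        assert loaded.extras == {"license.txt": b"free as in beer\n"}
        save_archive(loaded, DirectoryBackend(tmp_path / "b"))
        assert (tmp_path / "b" / "license.txt").read_bytes() == b"free as in beer\n"

    def test_save_load_save_byte_identical(self, tmp_path, synthetic_archive):
        save_archive(synthetic_archive, DirectoryBackend(tmp_path / "a"))
        loaded = load_archive(DirectoryBackend(tmp_path / "a"))
        save_archive(loaded, DirectoryBackend(tmp_path / "b"))
        files_a = {
            p.relative_to(tmp_path / "a").as_posix(): p.read_bytes()
            for p in (tmp_path / "a").rglob("*") if p.is_file()
        }
        files_b = {
            p.relative_to(tmp_path / "b").as_posix(): p.read_bytes()
            for p in (tmp_path / "b").rglob("*") if p.is_file()
        }
        assert files_a == files_b

    def test_zip_writes_are_reproducible(self, tmp_path, synthetic_archive):
        save_archive(synthetic_archive, ZipBackend(tmp_path / "a.qdb.zip"))
        save_archive(synthetic_archive, ZipBackend(tmp_path / "b.qdb.zip"))
        assert (tmp_path / "a.qdb.zip").read_bytes() == (tmp_path / "b.qdb.zip").read_bytes()

    def test_zip_entry_paths_match_directory_paths(self, tmp_path, synthetic_archive):
        save_archive(synthetic_archive, DirectoryBackend(tmp_path / "a"))
        save_archive(synthetic_archive, ZipBackend(tmp_path / "a.qdb.zip"))
        dir_paths = sorted(
            p.relative_to(tmp_path / "a").as_posix()
            for p in (tmp_path / "a").rglob("*") if p.is_file()
        )
        with zipfile.ZipFile(tmp_path / "a.qdb.zip") as zf:
            zip_paths = sorted(n for n in zf.namelist() if not n.endswith("/"))
        assert dir_paths == zip_paths
        assert zip_paths[0] != "./archive.xml"  # no leading ./

    def test_undeclared_cargo_file_attached_on_load(self, tmp_path, synthetic_archive):
        root = tmp_path / "a"
        save_archive(synthetic_archive, DirectoryBackend(root))
        (root / "compounds" / "1" / "rogue.bin").write_bytes(b"x")
        loaded = load_archive(DirectoryBackend(root))
        compound = loaded.compounds.get("1")
        assert compound.payloads["rogue.bin"] == b"x"
        assert "rogue.bin" not in compound.cargos


class TestRandomizedRoundTrip:
    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000), n=st.integers(0, 6), sigma=st.sampled_from([0.0, 0.1]))
    def test_property_round_trip(self, tmp_path_factory, seed, n, sigma):
        archive = generate_archive(
            SyntheticSpec(n_compounds=n, noise_sigma=sigma, seed=seed)
        )
        root = tmp_path_factory.mktemp("rt") / "a"
        save_archive(archive, DirectoryBackend(root))
        assert load_archive(DirectoryBackend(root)) == archive
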