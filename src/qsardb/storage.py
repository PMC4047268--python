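"""Persistence: directory-tree and ZIP backends sharing one path dialect.

Both backends address content through identical relative paths built from
three conventions: the archive descriptor lives at ``archive.xml``, each
non-empty registry at ``<subdir>/<subdir>.xml`` (subdir = plural lowercase
type name), and each cargo at ``<subdir>/<containerId>/<cargoId>``.

The registry XML dialect is defined by this module's writer/reader pair:
lowercase attribute elements nested under one element per container, under
a registry root element carrying a versioned namespace.  The writer is
canonical (fixed element order, 1-tab indentation, LF newlines) so that
save-load-save is byte identical.
"""

from __future__ import annotations

import io
import os
import shutil
import tempfile
import zipfile
import xml.etree.ElementTree as ET
from pathlib import Path

from .errors import (
    IntegrityError,
    InvalidIdentifier,
    MissingDescriptor,
    ParseError,
    StorageError,
)
from .schema import (
    Archive,
    Compound,
    Container,
    CONCRETE_TYPES,
    Descriptor,
    Model,
    Prediction,
    PredictionType,
    Property,
    validate_identifier,
)

NAMESPACE = "urn:qsardb:registry:1"

ARCHIVE_DESCRIPTOR = "archive.xml"

#: plural-form subdirectory names, fixed by enumeration (not derived at
#: run time: English pluralization of "property" is irregular)
_SUBDIRS: dict[type[Container], str] = {
    Compound: "compounds",
    Property: "properties",
    Descriptor: "descriptors",
    Model: "models",
    Prediction: "predictions",
}

_SINGULAR: dict[type[Container], str] = {
    t: t.__name__.lower() for t in CONCRETE_TYPES
}


def container_subdir(container_type: type[Container]) -> str:
    """Subdirectory name for a concrete container type, e.g. ``compounds``."""
    try:
        return _SUBDIRS[container_type]
    except KeyError:
        raise TypeError(f"not a concrete container type: {container_type}") from None


def registry_path(container_type: type[Container]) -> str:
    """Registry XML path, e.g. ``compounds/compounds.xml``."""
    subdir = container_subdir(container_type)
    return f"{subdir}/{subdir}.xml"


def cargo_path(container_type: type[Container], container_id: str, cargo_id: str) -> str:
    """Cargo payload path, e.g. ``compounds/1/smiles``."""
    if not validate_identifier(container_id):
        raise InvalidIdentifier(f"invalid container identifier: {container_id!r}")
    if not validate_identifier(cargo_id):
        raise InvalidIdentifier(f"invalid cargo identifier: {cargo_id!r}")
    return f"{container_subdir(container_type)}/{container_id}/{cargo_id}"


# -- XML writing -------------------------------------------------------------


def _sub(parent: ET.Element, tag: str, text: str) -> ET.Element:
    el = ET.SubElement(parent, tag)
    el.text = text
    return el


def _container_to_xml(parent: ET.Element, c: Container) -> None:
    el = ET.SubElement(parent, _SINGULAR[type(c)])
    _sub(el, "id", c.id)
    if c.name:
        _sub(el, "name", c.name)
    if c.description:
        _sub(el, "description", c.description)
    if isinstance(c, Compound):
        if c.cas is not None:
            _sub(el, "cas", c.cas)
        if c.inchi is not None:
            _sub(el, "inchi", c.inchi)
    elif isinstance(c, Property):
        if c.endpoint is not None:
            _sub(el, "endpoint", c.endpoint)
        if c.species is not None:
            _sub(el, "species", c.species)
    elif isinstance(c, Descriptor):
        if c.application is not None:
            _sub(el, "application", c.application)
    elif isinstance(c, Model):
        _sub(el, "property-id", c.property_id)
    elif isinstance(c, Prediction):
        _sub(el, "model-id", c.model_id)
        if c.application is not None:
            _sub(el, "application", c.application)
        _sub(el, "type", c.type.value)
    if c.labels:
        labels = ET.SubElement(el, "labels")
        for label in c.labels:
            _sub(labels, "label", label)
    if c.cargos:
        cargos = ET.SubElement(el, "cargos")
        for cargo in c.cargos:
            _sub(cargos, "cargo", cargo)


def _serialize(root: ET.Element) -> bytes:
    ET.indent(root, space="\t")
    buf = io.BytesIO()
    ET.ElementTree(root).write(buf, encoding="UTF-8", xml_declaration=True)
    return buf.getvalue() + b"\n"


def write_descriptor_xml(archive: Archive) -> bytes:
    root = ET.Element("archive", {"xmlns": NAMESPACE})
    _sub(root, "name", archive.name)
    _sub(root, "description", archive.description)
    return _serialize(root)


def write_registry_xml(archive: Archive, container_type: type[Container]) -> bytes:
    root = ET.Element(container_subdir(container_type), {"xmlns": NAMESPACE})
    for c in archive.registry(container_type):
        _container_to_xml(root, c)
    return _serialize(root)


# -- XML reading -------------------------------------------------------------


def _q(tag: str) -> str:
    return f"{{{NAMESPACE}}}{tag}"


def _text(el: ET.Element, tag: str) -> str | None:
    child = el.find(_q(tag))
    if child is None:
        return None
    return child.text or ""


def _parse_xml(payload: bytes, path: str) -> ET.Element:
    try:
        return ET.fromstring(payload)
    except ET.ParseError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def _container_from_xml(el: ET.Element, container_type: type[Container], path: str) -> Container:
    cid = _text(el, "id")
    if cid is None:
        raise ParseError(f"{path}: container element without <id>")
    c = container_type(id=cid)
    c.name = _text(el, "name") or ""
    c.description = _text(el, "description") or ""
    if isinstance(c, Compound):
        c.cas = _text(el, "cas")
        c.inchi = _text(el, "inchi")
    elif isinstance(c, Property):
        c.endpoint = _text(el, "endpoint")
        c.species = _text(el, "species")
    elif isinstance(c, Descriptor):
        c.application = _text(el, "application")
    elif isinstance(c, Model):
        c.property_id = _text(el, "property-id") or ""
    elif isinstance(c, Prediction):
        c.model_id = _text(el, "model-id") or ""
        c.application = _text(el, "application")
        type_text = _text(el, "type") or "training"
        try:
            c.type = PredictionType(type_text)
        except ValueError:
            raise ParseError(f"{path}: unknown prediction type {type_text!r}") from None
    labels = el.find(_q("labels"))
    if labels is not None:
        c.labels = [(lab.text or "") for lab in labels.findall(_q("label"))]
    cargos = el.find(_q("cargos"))
    if cargos is not None:
        c.cargos = [(car.text or "") for car in cargos.findall(_q("cargo"))]
    return c


# -- backends ----------------------------------------------------------------


class StorageBackend:
    """Abstract flat namespace of relative '/'-separated paths."""

    def list_paths(self) -> list[str]:
        raise NotImplementedError

    def read(self, path: str) -> bytes:
        raise NotImplementedError

    def write_all(self, entries: dict[str, bytes]) -> None:
        """Replace the entire content with *entries*, atomically."""
        raise NotImplementedError


class DirectoryBackend(StorageBackend):
    kind = "directory"

    def __init__(self, root: str | os.PathLike):
        self.root = Path(root)

    def list_paths(self) -> list[str]:
        if not self.root.is_dir():
            raise StorageError(f"not a directory: {self.root}")
        paths = []
        for p in sorted(self.root.rglob("*")):
            if p.is_file():
                paths.append(p.relative_to(self.root).as_posix())
        return paths

    def read(self, path: str) -> bytes:
        try:
            return (self.root / path).read_bytes()
        except OSError as exc:
            raise StorageError(f"cannot read {path}: {exc}") from exc

    def write_all(self, entries: dict[str, bytes]) -> None:
        parent = self.root.resolve().parent
        parent.mkdir(parents=True, exist_ok=True)
        tmp = Path(tempfile.mkdtemp(dir=parent, prefix=".qdb-save-"))
        try:
            for path, payload in entries.items():
                target = tmp / path
                target.parent.mkdir(parents=True, exist_ok=True)
                target.write_bytes(payload)
            if self.root.exists():
                old = Path(tempfile.mkdtemp(dir=parent, prefix=".qdb-old-"))
                os.replace(self.root, old / "a")
                try:
                    os.replace(tmp, self.root)
                finally:
                    shutil.rmtree(old, ignore_errors=True)
            else:
                os.replace(tmp, self.root)
        except OSError as exc:
            shutil.rmtree(tmp, ignore_errors=True)
            raise StorageError(f"cannot save archive at {self.root}: {exc}") from exc


class ZipBackend(StorageBackend):
    """ZIP archive backend; the recommended file name ends in ``.qdb.zip``.

    Entries are written in deterministic order with a fixed timestamp so
    that identical content produces byte-identical ZIP files.
    """

    kind = "zip"

    _EPOCH = (1980, 1, 1, 0, 0, 0)

    def __init__(self, location: str | os.PathLike):
        self.location = Path(location)

    def list_paths(self) -> list[str]:
        try:
            with zipfile.ZipFile(self.location) as zf:
                return sorted(
                    n for n in zf.namelist() if not n.endswith("/")
                )
        except (OSError, zipfile.BadZipFile) as exc:
            raise StorageError(f"cannot open {self.location}: {exc}") from exc

    def read(self, path: str) -> bytes:
        try:
            with zipfile.ZipFile(self.location) as zf:
                return zf.read(path)
        except KeyError as exc:
            raise StorageError(f"no entry {path} in {self.location}") from exc
        except (OSError, zipfile.BadZipFile) as exc:
            raise StorageError(f"cannot read {path}: {exc}") from exc

    def write_all(self, entries: dict[str, bytes]) -> None:
        self.location.parent.mkdir(parents=True, exist_ok=True)
        fd, tmp = tempfile.mkstemp(dir=self.location.parent, suffix=".tmp")
        os.close(fd)
        try:
            with zipfile.ZipFile(tmp, "w", zipfile.ZIP_DEFLATED) as zf:
                for path, payload in entries.items():
                    info = zipfile.ZipInfo(path, date_time=self._EPOCH)
                    info.compress_type = zipfile.ZIP_DEFLATED
                    info.external_attr = 0o644 << 16
                    zf.writestr(info, payload)
            os.replace(tmp, self.location)
        except OSError as exc:
            os.unlink(tmp)
            raise StorageError(f"cannot save archive at {self.location}: {exc}") from exc


def open_backend(location: str | os.PathLike) -> StorageBackend:
    """Pick a backend by inspecting *location* (existing dir or zip name)."""
    p = Path(location)
    if p.is_dir():
        return DirectoryBackend(p)
    if p.suffix == ".zip" or str(p).endswith(".qdb.zip"):
        return ZipBackend(p)
    return DirectoryBackend(p)


# -- save / load -------------------------------------------------------------


def _archive_entries(archive: Archive) -> dict[str, bytes]:
    """Deterministically ordered path->bytes mapping for the whole archive."""
    entries: dict[str, bytes] = {ARCHIVE_DESCRIPTOR: write_descriptor_xml(archive)}
    for ct in CONCRETE_TYPES:
        registry = archive.registry(ct)
        if len(registry) == 0:
            continue  # empty registries produce no subdirectory
        entries[registry_path(ct)] = write_registry_xml(archive, ct)
        for c in registry:
            declared = set(c.cargos)
            attached = set(c.payloads)
            if declared != attached:
                raise IntegrityError(
                    f"{container_subdir(ct)}/{c.id}: cargos list {sorted(declared)} "
                    f"disagrees with attached payloads {sorted(attached)}"
                )
            for cargo_id in c.cargos:
                entries[cargo_path(ct, c.id, cargo_id)] = c.payloads[cargo_id]
    cargo_paths = sorted(p for p in entries if p != ARCHIVE_DESCRIPTOR)
    ordered = {ARCHIVE_DESCRIPTOR: entries[ARCHIVE_DESCRIPTOR]}
    for p in cargo_paths:
        ordered[p] = entries[p]
    for p in sorted(archive.extras):
        if p in ordered:
            raise IntegrityError(f"extra file shadows archive content: {p}")
        ordered[p] = archive.extras[p]
    return ordered


def save_archive(archive: Archive, backend: StorageBackend) -> None:
    """Persist *archive*; existing content at the backend root is replaced."""
    backend.write_all(_archive_entries(archive))


def load_archive(backend: StorageBackend) -> Archive:
    """Inverse of :func:`save_archive`; tolerates imperfect archives.

    Files under a known container's directory that are not declared in its
    cargos list are still attached as payloads (validation reports the
    mismatch); anything else unrecognized is kept in ``Archive.extras``.
    """
    paths = backend.list_paths()
    if ARCHIVE_DESCRIPTOR not in paths:
        raise MissingDescriptor(f"no {ARCHIVE_DESCRIPTOR} found")
    root = _parse_xml(backend.read(ARCHIVE_DESCRIPTOR), ARCHIVE_DESCRIPTOR)
    archive = Archive(
        name=_text(root, "name") or "",
        description=_text(root, "description") or "",
    )
    consumed = {ARCHIVE_DESCRIPTOR}
    subdir_of = {container_subdir(ct): ct for ct in CONCRETE_TYPES}
    for ct in CONCRETE_TYPES:
        rpath = registry_path(ct)
        if rpath not in paths:
            continue
        consumed.add(rpath)
        reg_root = _parse_xml(backend.read(rpath), rpath)
        registry = archive.registry(ct)
        for el in reg_root.findall(_q(_SINGULAR[ct])):
            registry.add(_container_from_xml(el, ct, rpath))
    for path in paths:
        if path in consumed:
            continue
        parts = path.split("/")
        if len(parts) == 3 and parts[0] in subdir_of:
            ct = subdir_of[parts[0]]
            container = archive.registry(ct).find(parts[1])
            if container is not None:
                container.payloads[parts[2]] = backend.read(path)
                continue
        archive.extras[path] = backend.read(path)
    return archive
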