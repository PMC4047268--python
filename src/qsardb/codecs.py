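"""Codecs for the system cargo formats.

values / references  tab-separated tables, no header, no quoting; values
                     are kept verbatim (a numeric token is never reformatted)
ucum                 a unit contract string, trimmed, not interpreted
bibtex               entry keys and types only; field text kept raw
bodo                 a small YAML mapping with an ontology reference and a
                     free-form implementations list
structure            opaque payloads whose cargo identifier derives from the
                     Chemical MIME name
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import yaml

from .errors import (
    BibtexParseError,
    DuplicateCompoundRow,
    EmptyUnit,
    MalformedRow,
    MissingField,
    NotChemicalMime,
    YamlParseError,
)

# simplified-US numeric: '.' decimal separator, optional sign and exponent,
# no grouping separators of any kind
_NUMERIC_RE = re.compile(
    r"""^[+-]?
        (?:\d+(?:\.\d*)?|\.\d+)
        (?:[eE][+-]?\d+)?$""",
    re.VERBOSE,
)


@dataclass(frozen=True)
class ValueToken:
    """One table cell: the verbatim text plus its normal/abnormal reading."""

    raw: str
    kind: str  # "normal" | "abnormal"
    numeric: float | None = None

    @property
    def is_normal(self) -> bool:
        return self.kind == "normal"


def classify_value(raw: str) -> ValueToken:
    """Partition a non-empty token into a normal (numeric) or abnormal value.

    Grouping separators make a token abnormal: "1,204" is an error code as
    far as this codec is concerned, not a number.
    """
    if _NUMERIC_RE.match(raw):
        return ValueToken(raw=raw, kind="normal", numeric=float(raw))
    return ValueToken(raw=raw, kind="abnormal")


@dataclass
class ParameterTable:
    """Compound-id-keyed table of parameter values.

    ``rows`` preserves input order; extra columns beyond the first two are
    kept verbatim so that parse-serialize is the identity.
    """

    rows: list[tuple[str, ValueToken, list[str]]] = field(default_factory=list)

    def ids(self) -> list[str]:
        return [cid for cid, _, _ in self.rows]

    def get(self, cid: str) -> ValueToken | None:
        for row_id, token, _ in self.rows:
            if row_id == cid:
                return token
        return None

    def add(self, cid: str, raw: str, extras: list[str] | None = None) -> None:
        if any(cid == row_id for row_id, _, _ in self.rows):
            raise DuplicateCompoundRow(f"duplicate row for compound {cid!r}")
        self.rows.append((cid, classify_value(raw), list(extras or ())))


@dataclass
class ReferenceTable:
    rows: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class BodoRecord:
    ontology_reference: str
    implementations: list = field(default_factory=list)


def _split_lines(payload: bytes) -> list[str]:
    text = payload.decode("utf-8")
    # accept CRLF input; LF is canonical on write
    text = text.replace("\r\n", "\n")
    if text.endswith("\n"):
        text = text[:-1]
    return text.split("\n") if text else []


def parse_values(payload: bytes) -> ParameterTable:
    table = ParameterTable()
    seen: set[str] = set()
    for lineno, line in enumerate(_split_lines(payload), start=1):
        cols = line.split("\t")
        if len(cols) < 2:
            raise MalformedRow(f"line {lineno}: expected >=2 columns, got {len(cols)}")
        cid, raw = cols[0], cols[1]
        if cid in seen:
            raise DuplicateCompoundRow(f"line {lineno}: duplicate row for {cid!r}")
        seen.add(cid)
        table.rows.append((cid, classify_value(raw), cols[2:]))
    return table


def serialize_values(table: ParameterTable) -> bytes:
    lines = []
    for cid, token, extras in table.rows:
        lines.append("\t".join([cid, token.raw, *extras]))
    return ("".join(line + "\n" for line in lines)).encode("utf-8")


def parse_references(payload: bytes) -> ReferenceTable:
    table = ReferenceTable()
    for lineno, line in enumerate(_split_lines(payload), start=1):
        cols = line.split("\t")
        if len(cols) < 2:
            raise MalformedRow(f"line {lineno}: expected 2 columns, got {len(cols)}")
        table.rows.append((cols[0], cols[1]))
    return table


def serialize_references(table: ReferenceTable) -> bytes:
    return ("".join(f"{cid}\t{key}\n" for cid, key in table.rows)).encode("utf-8")


# -- BibTeX ------------------------------------------------------------------

_BIBTEX_ENTRY_RE = re.compile(r"@\s*([A-Za-z]+)\s*[{(]\s*([^,\s{}()]+)\s*,")


def parse_bibtex_keys(payload: bytes) -> list[tuple[str, str]]:
    """Extract ``(entry_type, key)`` pairs from a BibTeX database.

    Only the entry headers are interpreted; field content is opaque.
    Duplicate keys are preserved (resolution must flag them as ambiguous).
    """
    try:
        text = payload.decode("utf-8")
    except UnicodeDecodeError as exc:
        raise BibtexParseError(f"not decodable as UTF-8: {exc}") from exc
    entries = []
    for m in _BIBTEX_ENTRY_RE.finditer(text):
        entry_type = m.group(1).lower()
        if entry_type in ("comment", "preamble", "string"):
            continue
        entries.append((entry_type, m.group(2)))
    if not entries and "@" in text:
        raise BibtexParseError("no parseable BibTeX entries found")
    return entries


@dataclass(frozen=True)
class ReferenceFinding:
    row: int  # 1-based row number in the references table
    compound_id: str
    key: str
    reason: str  # "unresolved" | "ambiguous"


def resolve_references(refs: ReferenceTable, bibtex: bytes) -> list[ReferenceFinding]:
    """Check every reference row against the sibling BibTeX cargo."""
    entries = parse_bibtex_keys(bibtex)
    counts: dict[str, int] = {}
    for _, key in entries:
        counts[key] = counts.get(key, 0) + 1
    findings = []
    for row, (cid, key) in enumerate(refs.rows, start=1):
        n = counts.get(key, 0)
        if n == 0:
            findings.append(ReferenceFinding(row, cid, key, "unresolved"))
        elif n > 1:
            findings.append(ReferenceFinding(row, cid, key, "ambiguous"))
    return findings


# -- structure cargos --------------------------------------------------------

_CHEMICAL_MIME_PREFIX = "chemical/x-"

#: cargo identifiers this library recognizes as structure cargos
STRUCTURE_CARGO_IDS = frozenset(
    {
        "smiles",
        "daylight-smiles",
        "cml",
        "mdl-molfile",
        "mdl-sdfile",
        "inchi",
        "pdb",
        "xyz",
        "mol2",
    }
)


def structure_cargo_id(chemical_mime: str) -> str:
    """Cargo identifier for a Chemical MIME type.

    The prefix ``chemical/x-`` is stripped; every SMILES flavour other than
    the default Daylight one collapses to the shorthand ``smiles``.
    """
    if not chemical_mime.startswith(_CHEMICAL_MIME_PREFIX):
        raise NotChemicalMime(f"not a chemical MIME type: {chemical_mime!r}")
    suffix = chemical_mime[len(_CHEMICAL_MIME_PREFIX):]
    if suffix.endswith("smiles") and suffix != "daylight-smiles":
        return "smiles"
    return suffix


# -- BODO --------------------------------------------------------------------


def parse_bodo(payload: bytes) -> BodoRecord:
    try:
        doc = yaml.safe_load(payload)
    except yaml.YAMLError as exc:
        raise YamlParseError(f"bad YAML: {exc}") from exc
    if not isinstance(doc, dict):
        raise YamlParseError("BODO cargo must be a YAML mapping")
    if "ontologyReference" not in doc or not doc["ontologyReference"]:
        raise MissingField("missing field 'ontologyReference'")
    implementations = doc.get("implementations") or []
    if not isinstance(implementations, list):
        raise YamlParseError("'implementations' must be a list")
    return BodoRecord(
        ontology_reference=str(doc["ontologyReference"]),
        implementations=implementations,
    )


def serialize_bodo(record: BodoRecord) -> bytes:
    doc = {"ontologyReference": record.ontology_reference}
    if record.implementations:
        doc["implementations"] = record.implementations
    return yaml.safe_dump(doc, sort_keys=True).encode("utf-8")


# -- UCUM --------------------------------------------------------------------


def parse_ucum(payload: bytes) -> str:
    """Trimmed unit string; shallow syntax check only, no unit algebra."""
    text = payload.decode("utf-8").strip()
    if not text:
        raise EmptyUnit("empty unit string")
    if any(not (0x20 <= ord(ch) < 0x7F) for ch in text):
        raise EmptyUnit(f"unit contains non-printable or non-ASCII characters: {text!r}")
    return text


def serialize_ucum(unit: str) -> bytes:
    return unit.strip().encode("ascii")


# -- extension cargo identifiers ---------------------------------------------


def is_qualified_extension_id(cargo_id: str, system_ids: set[str] | frozenset[str]) -> bool:
    """True iff *cargo_id* is a well-formed extension identifier.

    Extension identifiers carry a reverse-domain namespace: at least two
    dot-separated labels before the final simple name (``org.dmg.pmml``).
    System identifiers are never extension identifiers.
    """
    if cargo_id in system_ids:
        return False
    parts = cargo_id.split(".")
    return len(parts) >= 3 and all(parts)
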