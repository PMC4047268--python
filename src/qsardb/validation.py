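"""Archive-wide integrity checking and chemical-identifier validation.

Rules (findings carry these identifiers):

r1   declared cargos list equals the attached payload set
r2   strong relationships resolve (Model.propertyId, Prediction.modelId)
r3   values/references rows reference existing Compounds
r4   references resolve into the sibling BibTeX cargo
r5   identifier charset; case-insensitive id collisions (warning)
r6   CAS checksum and standard-InChI prefix
r7   Prediction.type is a recognized constant
r8   non-system cargo identifiers are namespace-qualified
r9   PMML variables resolve with the correct registry prefix
r10  parameter tables have at most one row per compound

Validation never mutates the archive and never raises for content problems:
imperfect archives must remain inspectable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from . import codecs, pmml
from .errors import MalformedCas, ParseError, QdbError
from .schema import (
    Archive,
    Compound,
    CONCRETE_TYPES,
    Container,
    Descriptor,
    Model,
    Parameter,
    Prediction,
    PredictionType,
    Property,
    system_cargo_ids,
    validate_identifier,
)
from .storage import container_subdir

_CAS_RE = re.compile(r"^(\d{2,7})-(\d{2})-(\d)$")

STANDARD_INCHI_PREFIX = "InChI=1S"


def cas_checksum(casrn: str) -> bool:
    """Check-digit test for a CAS registry number.

    Digits left of the check digit are weighted 1, 2, 3, ... counting from
    the right; the weighted sum modulo 10 must equal the check digit.
    """
    m = _CAS_RE.match(casrn)
    if not m:
        raise MalformedCas(f"not shaped like a CAS RN: {casrn!r}")
    digits = m.group(1) + m.group(2)
    check = int(m.group(3))
    total = sum(int(d) * w for w, d in enumerate(reversed(digits), start=1))
    return total % 10 == check


def append_cas_check_digit(base: str) -> str:
    """Format base digits (>=4) as a checksum-correct CAS RN."""
    if not base.isdigit() or len(base) < 4 or len(base) > 9:
        raise MalformedCas(f"bad CAS base digits: {base!r}")
    total = sum(int(d) * w for w, d in enumerate(reversed(base), start=1))
    return f"{base[:-2]}-{base[-2:]}-{total % 10}"


def is_standard_inchi(inchi: str) -> bool:
    return inchi.startswith(STANDARD_INCHI_PREFIX)


@dataclass(frozen=True)
class Finding:
    severity: str  # "error" | "warning"
    rule: str  # "r1".."r10"
    path: str  # container reference or archive path
    message: str

    def __str__(self) -> str:
        return f"{self.severity}\t{self.rule}\t{self.path}\t{self.message}"


def _ref(container_type: type[Container], cid: str, cargo: str | None = None) -> str:
    path = f"{container_subdir(container_type)}/{cid}"
    return f"{path}/{cargo}" if cargo else path


def validate_archive(archive: Archive) -> list[Finding]:
    """Run every rule over *archive* and return the findings, errors first
    within the original discovery order of each rule pass."""
    findings: list[Finding] = []
    compound_ids = set(archive.compounds.ids())

    for ct in CONCRETE_TYPES:
        for c in archive.registry(ct):
            _check_container(archive, ct, c, compound_ids, findings)

    # r5 case-insensitive collision check is registry-wide
    for ct in CONCRETE_TYPES:
        lowered: dict[str, str] = {}
        for cid in archive.registry(ct).ids():
            folded = cid.lower()
            if folded in lowered and lowered[folded] != cid:
                findings.append(
                    Finding(
                        "warning", "r5", _ref(ct, cid),
                        f"id collides case-insensitively with {lowered[folded]!r}",
                    )
                )
            else:
                lowered.setdefault(folded, cid)
    return findings


def _check_container(
    archive: Archive,
    ct: type[Container],
    c: Container,
    compound_ids: set[str],
    findings: list[Finding],
) -> None:
    ref = _ref(ct, c.id)

    # r5: identifier charset
    if not validate_identifier(c.id):
        findings.append(Finding("error", "r5", ref, f"illegal identifier {c.id!r}"))

    # r1: declared cargos vs attached payloads
    declared, attached = set(c.cargos), set(c.payloads)
    for cargo_id in sorted(attached - declared):
        findings.append(
            Finding("error", "r1", _ref(ct, c.id, cargo_id),
                    "payload attached but not listed in cargos")
        )
    for cargo_id in sorted(declared - attached):
        findings.append(
            Finding("error", "r1", _ref(ct, c.id, cargo_id),
                    "cargo listed but no payload attached")
        )

    # r8: extension cargo ids must be qualified
    system_ids = system_cargo_ids(ct) | (
        codecs.STRUCTURE_CARGO_IDS if ct is Compound else frozenset()
    )
    for cargo_id in c.cargos:
        if cargo_id in system_ids:
            continue
        if not codecs.is_qualified_extension_id(cargo_id, system_ids):
            findings.append(
                Finding("error", "r8", _ref(ct, c.id, cargo_id),
                        "extension cargo identifier is not namespace-qualified")
            )

    # r2: strong relationships
    if isinstance(c, Model):
        if c.property_id not in archive.properties:
            msg = f"propertyId {c.property_id!r} does not resolve in the property registry"
            if c.property_id in archive.descriptors:
                msg += " (it names a Descriptor)"
            findings.append(Finding("error", "r2", ref, msg))
    if isinstance(c, Prediction):
        if c.model_id not in archive.models:
            findings.append(
                Finding("error", "r2", ref,
                        f"modelId {c.model_id!r} does not resolve in the model registry")
            )
        # r7: enum check (loaders may force the enum; re-check raw value)
        if not isinstance(c.type, PredictionType):
            findings.append(
                Finding("error", "r7", ref, f"unknown prediction type {c.type!r}")
            )

    # r6: chemical identifiers
    if isinstance(c, Compound):
        if c.cas is not None:
            try:
                if not cas_checksum(c.cas):
                    findings.append(
                        Finding("error", "r6", ref, f"CAS RN {c.cas!r} fails its check digit")
                    )
            except MalformedCas:
                findings.append(
                    Finding("error", "r6", ref, f"CAS RN {c.cas!r} is malformed")
                )
        if c.inchi is not None and not is_standard_inchi(c.inchi):
            findings.append(
                Finding("error", "r6", ref,
                        f"InChI does not start with {STANDARD_INCHI_PREFIX!r}")
            )

    # r3/r4/r10: parameter table cargos
    if isinstance(c, Parameter):
        _check_parameter_cargos(ct, c, compound_ids, findings)

    # r9: PMML variable resolution
    if isinstance(c, Model) and c.has_cargo("pmml"):
        _check_pmml(archive, ct, c, findings)


def _check_parameter_cargos(
    ct: type[Container],
    c: Container,
    compound_ids: set[str],
    findings: list[Finding],
) -> None:
    if c.has_cargo("values"):
        path = _ref(ct, c.id, "values")
        try:
            table = codecs.parse_values(c.cargo("values"))
        except codecs.DuplicateCompoundRow as exc:
            findings.append(Finding("error", "r10", path, str(exc)))
            table = None
        except ParseError as exc:
            findings.append(Finding("error", "r3", path, str(exc)))
            table = None
        if table is not None:
            for cid in table.ids():
                if cid not in compound_ids:
                    findings.append(
                        Finding("error", "r3", path,
                                f"row references unknown compound {cid!r}")
                    )
    if c.has_cargo("references"):
        path = _ref(ct, c.id, "references")
        try:
            refs = codecs.parse_references(c.cargo("references"))
        except ParseError as exc:
            findings.append(Finding("error", "r3", path, str(exc)))
            return
        seen: set[str] = set()
        for cid, _ in refs.rows:
            if cid not in compound_ids:
                findings.append(
                    Finding("error", "r3", path,
                            f"row references unknown compound {cid!r}")
                )
            if cid in seen:
                findings.append(
                    Finding("error", "r10", path, f"duplicate row for compound {cid!r}")
                )
            seen.add(cid)
        if c.has_cargo("bibtex"):
            try:
                for f in codecs.resolve_references(refs, c.cargo("bibtex")):
                    findings.append(
                        Finding("error", "r4", path,
                                f"row {f.row}: key {f.key!r} is {f.reason} "
                                "in the BibTeX cargo")
                    )
            except codecs.BibtexParseError as exc:
                findings.append(Finding("error", "r4", path, str(exc)))
        else:
            findings.append(
                Finding("error", "r4", path,
                        "references cargo present but no BibTeX cargo to resolve against")
            )


def _check_pmml(
    archive: Archive, ct: type[Container], c: Container, findings: list[Finding]
) -> None:
    path = _ref(ct, c.id, "pmml")
    try:
        regression = pmml.read_pmml(c.cargo("pmml"))
    except QdbError as exc:
        findings.append(Finding("error", "r9", path, str(exc)))
        return
    if regression.property_id not in archive.properties:
        findings.append(
            Finding("error", "r9", path,
                    f"target {regression.target_ref!r} does not resolve "
                    "in the property registry")
        )
    for ref, did in zip(regression.term_refs, regression.descriptor_ids):
        if did not in archive.descriptors:
            msg = f"term {ref!r} does not resolve in the descriptor registry"
            if did in archive.properties:
                msg += " (it names a Property)"
            findings.append(Finding("error", "r9", path, msg))
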