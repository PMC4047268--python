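"""Build archives from tabular raw data via column mappings.

A mapping assigns one table column a role:

  attribute cells    -> Compound id/name/cas/inchi
  structure cells    -> one structure cargo per compound (e.g. ``smiles``)
  parameter cells    -> a Property or Descriptor container with a values
                        cargo (one row per compound; empty cells become the
                        "N/A" error code, never silently dropped)
  reference cells    -> a references cargo on an existing parameter

Optionally a linear regression equation attaches a Model (PMML cargo) plus
the training Prediction obtained by evaluating it over all compounds.

Equation grammar (fixed here, documented in the README):

    property_id = intercept + c1*descriptor_id1 - c2*descriptor_id2 ...

with '*' multiplication and signed decimal coefficients.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from . import codecs, pmml
from .codecs import ParameterTable, serialize_values
from .errors import DuplicateCompoundRow, MappingError, UnresolvedIdentifier
from .schema import (
    Archive,
    Compound,
    Descriptor,
    Model,
    Prediction,
    PredictionType,
    Property,
)


@dataclass(frozen=True)
class ColumnMapping:
    column: int | str  # index, or header name when the table has a header
    role: str  # "attribute" | "structure" | "values" | "references"
    kind: str | None = None  # attribute kind: id|name|cas|inchi
    format: str | None = None  # structure format (cargo identifier)
    parameter_id: str | None = None
    parameter_role: str | None = None  # "property" | "descriptor"


@dataclass(frozen=True)
class RegressionSpec:
    property_id: str
    terms: list[tuple[str, float]]
    intercept: float


_MAP_SPEC_RE = re.compile(r"^(?P<col>[^=]+)=(?P<role>[^:]+)(?::(?P<arg>.+))?$")


def parse_mapping(spec: str) -> ColumnMapping:
    """Parse one CLI ``--map`` argument, e.g. ``0=id`` or ``2=property:pLC50``."""
    m = _MAP_SPEC_RE.match(spec)
    if not m:
        raise MappingError(f"bad mapping spec: {spec!r}")
    col: int | str = m.group("col")
    if col.isdigit():
        col = int(col)
    role, arg = m.group("role"), m.group("arg")
    if role in ("id", "name", "cas", "inchi"):
        return ColumnMapping(column=col, role="attribute", kind=role)
    if role == "cargo":
        if not arg:
            raise MappingError(f"cargo mapping needs a format: {spec!r}")
        return ColumnMapping(column=col, role="structure", format=arg)
    if role in ("property", "descriptor"):
        if not arg:
            raise MappingError(f"{role} mapping needs a parameter id: {spec!r}")
        return ColumnMapping(
            column=col, role="values", parameter_id=arg, parameter_role=role
        )
    if role == "refs":
        if not arg:
            raise MappingError(f"refs mapping needs a parameter id: {spec!r}")
        return ColumnMapping(column=col, role="references", parameter_id=arg)
    raise MappingError(f"unknown mapping role {role!r} in {spec!r}")


_EQ_TERM_RE = re.compile(
    r"""\s*(?P<sign>[+-])\s*
        (?:(?P<coeff>\d+(?:\.\d*)?|\.\d+)(?:[eE][+-]?\d+)?)
        (?:\s*\*\s*(?P<name>[A-Za-z0-9._-]+))?\s*""",
    re.VERBOSE,
)


def parse_equation(text: str) -> RegressionSpec:
    """Parse ``p = a + b*x - c*y`` into a :class:`RegressionSpec`."""
    if "=" not in text:
        raise MappingError(f"equation needs '=': {text!r}")
    lhs, rhs = text.split("=", 1)
    property_id = lhs.strip()
    if not property_id:
        raise MappingError("equation has an empty left-hand side")
    rhs = rhs.strip()
    if not rhs.startswith(("+", "-")):
        rhs = "+" + rhs
    intercept = 0.0
    terms: list[tuple[str, float]] = []
    pos = 0
    while pos < len(rhs):
        m = _EQ_TERM_RE.match(rhs, pos)
        if not m or m.end() == pos:
            raise MappingError(f"cannot parse equation near {rhs[pos:]!r}")
        value = float(rhs[m.start("coeff"):m.end()].split("*")[0])
        if m.group("sign") == "-":
            value = -value
        if m.group("name"):
            terms.append((m.group("name"), value))
        else:
            intercept += value
        pos = m.end()
    return RegressionSpec(property_id=property_id, terms=terms, intercept=intercept)


def _looks_numeric(cell: str) -> bool:
    return codecs.classify_value(cell).is_normal if cell else False


def detect_header(rows: list[list[str]], mappings: list[ColumnMapping]) -> bool:
    """First row is a header iff a mapped values column is non-numeric there
    while numeric in at least one later row."""
    if len(rows) < 2:
        return False
    value_cols = [
        m.column for m in mappings if m.role == "values" and isinstance(m.column, int)
    ]
    for col in value_cols:
        if col >= len(rows[0]):
            continue
        head = rows[0][col]
        if head and not _looks_numeric(head):
            if any(col < len(r) and _looks_numeric(r[col]) for r in rows[1:]):
                return True
    return False


def _resolve_columns(
    mappings: list[ColumnMapping], header: list[str] | None
) -> list[tuple[ColumnMapping, int]]:
    resolved = []
    for m in mappings:
        if isinstance(m.column, int):
            resolved.append((m, m.column))
        else:
            if header is None:
                raise MappingError(
                    f"mapping {m.column!r} names a header but the table has none"
                )
            try:
                resolved.append((m, header.index(m.column)))
            except ValueError:
                raise MappingError(f"no column named {m.column!r}") from None
    id_maps = [m for m in mappings if m.role == "attribute" and m.kind == "id"]
    if len(id_maps) > 1:
        raise MappingError("at most one id column mapping is allowed")
    return resolved


def convert_table(
    rows: list[list[str]],
    mappings: list[ColumnMapping],
    *,
    has_header: bool | None = None,
    name: str = "",
    description: str = "",
) -> Archive:
    """Build an archive with one Compound per data row.

    Compound ids come from the mapped id column, or are assigned
    sequentially ("1", "2", ...) when none is mapped.
    """
    archive = Archive(name=name, description=description)
    if has_header is None:
        has_header = detect_header(rows, mappings)
    header = rows[0] if has_header and rows else None
    data_rows = rows[1:] if has_header else rows
    resolved = _resolve_columns(mappings, header)

    for m, col in resolved:
        if m.role == "values":
            registry = (
                archive.properties if m.parameter_role == "property"
                else archive.descriptors
            )
            if m.parameter_id not in registry:
                param = (
                    Property(id=m.parameter_id) if m.parameter_role == "property"
                    else Descriptor(id=m.parameter_id)
                )
                registry.add(param)

    tables: dict[tuple[str, str], ParameterTable] = {}
    refs: dict[str, codecs.ReferenceTable] = {}

    for i, row in enumerate(data_rows, start=1):
        cid = str(i)
        for m, col in resolved:
            if m.role == "attribute" and m.kind == "id" and col < len(row):
                cid = row[col].strip()
        if not cid:
            raise MappingError(f"row {i}: empty compound id")
        if cid in archive.compounds:
            raise DuplicateCompoundRow(f"row {i}: duplicate compound id {cid!r}")
        compound = Compound(id=cid)
        for m, col in resolved:
            cell = row[col].strip() if col < len(row) else ""
            if m.role == "attribute":
                if m.kind == "name":
                    compound.name = cell
                elif m.kind == "cas" and cell:
                    compound.cas = cell
                elif m.kind == "inchi" and cell:
                    compound.inchi = cell
            elif m.role == "structure" and cell:
                compound.add_cargo(m.format, (cell + "\n").encode("utf-8"))
            elif m.role == "values":
                key = (m.parameter_role, m.parameter_id)
                tables.setdefault(key, ParameterTable()).add(cid, cell or "N/A")
            elif m.role == "references" and cell:
                refs.setdefault(m.parameter_id, codecs.ReferenceTable()).rows.append(
                    (cid, cell)
                )
        archive.compounds.add(compound)

    for (role, pid), table in tables.items():
        registry = archive.properties if role == "property" else archive.descriptors
        registry.get(pid).add_cargo("values", serialize_values(table))
    for pid, table in refs.items():
        for registry in (archive.properties, archive.descriptors):
            param = registry.find(pid)
            if param is not None:
                param.add_cargo("references", codecs.serialize_references(table))
                break
        else:
            raise MappingError(f"refs mapping targets unknown parameter {pid!r}")
    return archive


def attach_regression(
    archive: Archive,
    spec: RegressionSpec,
    *,
    model_id: str = "m1",
    prediction_id: str = "m1-training",
    application: str | None = None,
) -> Archive:
    """Attach a Model (PMML) and its training Prediction to *archive*."""
    if spec.property_id not in archive.properties:
        raise UnresolvedIdentifier(
            f"property {spec.property_id!r} does not resolve in the property registry"
        )
    for did, _ in spec.terms:
        if did not in archive.descriptors:
            msg = f"descriptor {did!r} does not resolve in the descriptor registry"
            if did in archive.properties:
                msg += " (terms must be Descriptors, not Properties)"
            raise UnresolvedIdentifier(msg)

    regression = pmml.PmmlRegression(
        target_ref=pmml.make_prefixed_id(Property, spec.property_id),
        term_refs=[pmml.make_prefixed_id(Descriptor, d) for d, _ in spec.terms],
        coefficients=[c for _, c in spec.terms],
        intercept=spec.intercept,
    )
    model = Model(id=model_id, property_id=spec.property_id)
    model.add_cargo("pmml", pmml.write_pmml(regression))
    archive.models.add(model)

    prediction = Prediction(
        id=prediction_id,
        model_id=model_id,
        type=PredictionType.TRAINING,
        application=application,
    )
    prediction.add_cargo(
        "values", serialize_values(evaluate_over_archive(archive, regression))
    )
    archive.predictions.add(prediction)
    return archive


def evaluate_over_archive(
    archive: Archive, regression: pmml.PmmlRegression
) -> ParameterTable:
    """Evaluate a regression over every compound using descriptor values cargos."""
    term_tables: dict[str, ParameterTable] = {}
    for ref, did in zip(regression.term_refs, regression.descriptor_ids):
        descriptor = archive.descriptors.get(did)
        if descriptor.has_cargo("values"):
            term_tables[ref] = codecs.parse_values(descriptor.cargo("values"))
        else:
            term_tables[ref] = ParameterTable()
    inputs: dict[str, dict[str, codecs.ValueToken]] = {}
    for compound in archive.compounds:
        per_term: dict[str, codecs.ValueToken] = {}
        for ref, table in term_tables.items():
            token = table.get(compound.id)
            if token is not None:
                per_term[ref] = token
        inputs[compound.id] = per_term
    return pmml.evaluate(regression, inputs)
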