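"""Linear-regression PMML: build, parse and evaluate.

The writer emits one pinned PMML dialect; the reader accepts any PMML
version whose regression vocabulary matches and rejects every other model
type explicitly.  Variables are disambiguated across the property and
descriptor registries with prefixed identifiers ("properties/<id>",
"descriptors/<id>") that coincide with the containers' abstract archive
paths.
"""

from __future__ import annotations

import io
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

from .codecs import ParameterTable, ValueToken, classify_value
from .errors import InvalidIdentifier, MalformedPmml, UnsupportedModelType
from .schema import Container, Descriptor, Property, validate_identifier
from .storage import container_subdir

PMML_VERSION = "4.2"
PMML_NAMESPACE = "http://www.dmg.org/PMML-4_2"

#: value written for predictions that cannot be computed
NOT_AVAILABLE = "N/A"

_PREFIXED = {
    Property: container_subdir(Property) + "/",
    Descriptor: container_subdir(Descriptor) + "/",
}

#: PMML top-level model elements other than RegressionModel (subset; any
#: unrecognized child with a functionName attribute is also rejected)
_OTHER_MODEL_ELEMENTS = {
    "NeuralNetwork",
    "TreeModel",
    "SupportVectorMachineModel",
    "ClusteringModel",
    "GeneralRegressionModel",
    "NaiveBayesModel",
    "MiningModel",
    "RuleSetModel",
    "SequenceModel",
    "Scorecard",
    "TimeSeriesModel",
    "AssociationModel",
    "BayesianNetworkModel",
    "GaussianProcessModel",
    "NearestNeighborModel",
    "TextModel",
}


def make_prefixed_id(container_type: type[Container], cid: str) -> str:
    """Registry-qualified variable name, e.g. ``descriptors/logp``."""
    if container_type not in _PREFIXED:
        raise TypeError(f"only Property and Descriptor ids are prefixed, not {container_type}")
    if not validate_identifier(cid):
        raise InvalidIdentifier(f"invalid identifier: {cid!r}")
    return _PREFIXED[container_type] + cid


def parse_prefixed_id(name: str) -> tuple[type[Container], str]:
    """Inverse of :func:`make_prefixed_id`."""
    for container_type, prefix in _PREFIXED.items():
        if name.startswith(prefix):
            cid = name[len(prefix):]
            if validate_identifier(cid):
                return container_type, cid
    raise MalformedPmml(f"DataField name without a recognized registry prefix: {name!r}")


@dataclass
class PmmlRegression:
    """Single-target linear model: target = intercept + sum(coeff * term)."""

    target_ref: str  # "properties/<id>"
    term_refs: list[str]  # ["descriptors/<id>", ...]
    coefficients: list[float]
    intercept: float = 0.0

    def __post_init__(self):
        if len(self.term_refs) != len(self.coefficients):
            raise ValueError(
                f"{len(self.term_refs)} terms but {len(self.coefficients)} coefficients"
            )

    @property
    def property_id(self) -> str:
        return parse_prefixed_id(self.target_ref)[1]

    @property
    def descriptor_ids(self) -> list[str]:
        return [parse_prefixed_id(ref)[1] for ref in self.term_refs]


def _fmt(x: float) -> str:
    # repr round-trips doubles exactly through float()
    return repr(float(x))


def write_pmml(model: PmmlRegression) -> bytes:
    if parse_prefixed_id(model.target_ref)[0] is not Property:
        raise MalformedPmml(f"target must be a property reference: {model.target_ref!r}")
    for ref in model.term_refs:
        if parse_prefixed_id(ref)[0] is not Descriptor:
            raise MalformedPmml(f"terms must be descriptor references: {ref!r}")
    root = ET.Element("PMML", {"xmlns": PMML_NAMESPACE, "version": PMML_VERSION})
    header = ET.SubElement(root, "Header")
    ET.SubElement(header, "Application", {"name": "qsardb"})
    dd = ET.SubElement(
        root, "DataDictionary", {"numberOfFields": str(1 + len(model.term_refs))}
    )
    ET.SubElement(
        dd, "DataField",
        {"name": model.target_ref, "optype": "continuous", "dataType": "double"},
    )
    for ref in model.term_refs:
        ET.SubElement(
            dd, "DataField",
            {"name": ref, "optype": "continuous", "dataType": "double"},
        )
    rm = ET.SubElement(
        root, "RegressionModel",
        {"functionName": "regression", "targetFieldName": model.target_ref},
    )
    ms = ET.SubElement(rm, "MiningSchema")
    ET.SubElement(ms, "MiningField", {"name": model.target_ref, "usageType": "target"})
    for ref in model.term_refs:
        ET.SubElement(ms, "MiningField", {"name": ref})
    rt = ET.SubElement(rm, "RegressionTable", {"intercept": _fmt(model.intercept)})
    for ref, coeff in zip(model.term_refs, model.coefficients):
        ET.SubElement(rt, "NumericPredictor", {"name": ref, "coefficient": _fmt(coeff)})
    ET.indent(root, space="\t")
    buf = io.BytesIO()
    ET.ElementTree(root).write(buf, encoding="UTF-8", xml_declaration=True)
    return buf.getvalue() + b"\n"


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def read_pmml(payload: bytes) -> PmmlRegression:
    """Parse a regression PMML document (any PMML namespace version)."""
    try:
        root = ET.fromstring(payload)
    except ET.ParseError as exc:
        raise MalformedPmml(f"not well-formed XML: {exc}") from exc
    if _local(root.tag) != "PMML":
        raise MalformedPmml(f"root element is <{_local(root.tag)}>, expected <PMML>")
    regression = None
    for child in root:
        tag = _local(child.tag)
        if tag == "RegressionModel":
            regression = child
        elif tag in _OTHER_MODEL_ELEMENTS or "functionName" in child.attrib:
            raise UnsupportedModelType(f"unsupported PMML model type: <{tag}>")
    if regression is None:
        raise MalformedPmml("no <RegressionModel> element found")

    fields: list[str] = []
    for dd in root:
        if _local(dd.tag) == "DataDictionary":
            for df in dd:
                if _local(df.tag) == "DataField":
                    name = df.get("name", "")
                    parse_prefixed_id(name)  # raises MalformedPmml with the name
                    fields.append(name)

    target_ref = regression.get("targetFieldName")
    if target_ref is None:
        for ms in regression:
            if _local(ms.tag) == "MiningSchema":
                for mf in ms:
                    if mf.get("usageType") == "target":
                        target_ref = mf.get("name")
    if target_ref is None:
        raise MalformedPmml("regression model does not name a target field")
    if parse_prefixed_id(target_ref)[0] is not Property:
        raise MalformedPmml(f"target must be a property reference: {target_ref!r}")

    table = None
    for child in regression:
        if _local(child.tag) == "RegressionTable":
            table = child
            break
    if table is None:
        raise MalformedPmml("no <RegressionTable> element found")
    try:
        intercept = float(table.get("intercept", "0"))
    except ValueError:
        raise MalformedPmml(f"bad intercept: {table.get('intercept')!r}") from None
    term_refs: list[str] = []
    coefficients: list[float] = []
    for np_el in table:
        if _local(np_el.tag) != "NumericPredictor":
            continue
        name = np_el.get("name", "")
        if parse_prefixed_id(name)[0] is not Descriptor:
            raise MalformedPmml(f"terms must be descriptor references: {name!r}")
        try:
            coefficients.append(float(np_el.get("coefficient", "")))
        except ValueError:
            raise MalformedPmml(
                f"bad coefficient for {name!r}: {np_el.get('coefficient')!r}"
            ) from None
        term_refs.append(name)
    return PmmlRegression(
        target_ref=target_ref,
        term_refs=term_refs,
        coefficients=coefficients,
        intercept=intercept,
    )


def evaluate(
    model: PmmlRegression,
    descriptor_values: dict[str, dict[str, ValueToken]],
) -> ParameterTable:
    """Apply the model to per-compound term values.

    A compound with any missing or abnormal term value degrades to the
    "N/A" error code instead of being dropped.
    """
    table = ParameterTable()
    for cid, terms in descriptor_values.items():
        y = model.intercept
        ok = True
        for ref, coeff in zip(model.term_refs, model.coefficients):
            token = terms.get(ref)
            if token is None or not token.is_normal:
                ok = False
                break
            y += coeff * token.numeric
        raw = _fmt(y) if ok else NOT_AVAILABLE
        table.rows.append((cid, classify_value(raw), []))
    return table
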