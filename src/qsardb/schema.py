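"""Core type system: containers, registries and the archive object.

Containers form a two-level hierarchy.  ``Container`` is the abstract root
holding identity and description; ``Parameter`` is an abstract intermediate
for value-carrying containers (Property, Descriptor, Prediction).  The five
concrete types are Compound, Property, Descriptor, Model and Prediction.

Relationships between containers are "strong" when declared through an
attribute (Model.property_id, Prediction.model_id) and "weak" when declared
only inside cargo payloads (values tables referencing compound ids).  Strong
relationships are enforced at removal time; weak ones are left to validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .errors import (
    BrokenChain,
    DuplicateIdentifier,
    InvalidIdentifier,
    NotFound,
    RelationshipViolation,
)

#: Characters allowed in container and cargo identifiers besides letters/digits.
_ID_EXTRA = {".", "-", "_"}


def validate_identifier(token: str) -> bool:
    """Return True iff *token* is a legal container or cargo identifier.

    Legal identifiers are non-empty, contain no whitespace and no path
    separators, and consist only of ASCII letters, digits, '.', '-' and '_'.
    """
    if not token:
        return False
    for ch in token:
        if ch.isspace() or ch in ("/", "\\"):
            return False
        if not (ch.isascii() and (ch.isalnum() or ch in _ID_EXTRA)):
            return False
    return True


class PredictionType(str, Enum):
    TRAINING = "training"
    VALIDATION = "validation"
    TESTING = "testing"


@dataclass
class Container:
    """Abstract base for all registry members.

    ``cargos`` is the *declared* list of cargo identifiers; ``payloads``
    maps identifiers to attached bytes.  The two must agree for the archive
    to be valid, but they are stored separately so that inconsistent
    archives remain loadable and inspectable.
    """

    id: str
    name: str = ""
    description: str = ""
    labels: list[str] = field(default_factory=list)
    cargos: list[str] = field(default_factory=list)
    payloads: dict[str, bytes] = field(default_factory=dict)

    #: system cargo identifiers introduced at this level of the hierarchy
    SYSTEM_CARGOS: tuple[str, ...] = ("bibtex",)
    #: attribute names introduced at this level (capitalized display form)
    OWN_ATTRIBUTES: tuple[str, ...] = ("Id", "Name", "Description", "Labels", "Cargos")

    def add_cargo(self, cargo_id: str, payload: bytes) -> None:
        """Attach *payload* and record *cargo_id* in the declared list."""
        if not validate_identifier(cargo_id):
            raise InvalidIdentifier(f"invalid cargo identifier: {cargo_id!r}")
        if cargo_id not in self.cargos:
            self.cargos.append(cargo_id)
        self.payloads[cargo_id] = payload

    def remove_cargo(self, cargo_id: str) -> None:
        if cargo_id in self.cargos:
            self.cargos.remove(cargo_id)
        self.payloads.pop(cargo_id, None)

    def cargo(self, cargo_id: str) -> bytes:
        try:
            return self.payloads[cargo_id]
        except KeyError:
            raise NotFound(f"cargo {cargo_id!r} not attached to {self.id!r}") from None

    def has_cargo(self, cargo_id: str) -> bool:
        return cargo_id in self.payloads

    def __eq__(self, other) -> bool:
        if type(self) is not type(other):
            return NotImplemented
        return self._state() == other._state()

    def _state(self) -> tuple:
        return (
            self.id,
            self.name,
            self.description,
            tuple(self.labels),
            tuple(self.cargos),
            tuple(sorted(self.payloads.items())),
        )


@dataclass(eq=False)
class Parameter(Container):
    """Abstract value-carrying container (no attributes of its own)."""

    SYSTEM_CARGOS = ("ucum", "values", "references")
    OWN_ATTRIBUTES = ()


@dataclass(eq=False)
class Compound(Container):
    cas: str | None = None
    inchi: str | None = None

    SYSTEM_CARGOS = ("structure",)
    OWN_ATTRIBUTES = ("Cas", "Inchi")

    def _state(self):
        return super()._state() + (self.cas, self.inchi)


@dataclass(eq=False)
class Property(Parameter):
    endpoint: str | None = None
    species: str | None = None

    SYSTEM_CARGOS = ()
    OWN_ATTRIBUTES = ("Endpoint", "Species")

    def _state(self):
        return super()._state() + (self.endpoint, self.species)


@dataclass(eq=False)
class Descriptor(Parameter):
    application: str | None = None

    SYSTEM_CARGOS = ("bodo",)
    OWN_ATTRIBUTES = ("Application",)

    def _state(self):
        return super()._state() + (self.application,)


@dataclass(eq=False)
class Model(Container):
    property_id: str = ""

    SYSTEM_CARGOS = ("pmml",)
    OWN_ATTRIBUTES = ("PropertyId",)

    def _state(self):
        return super()._state() + (self.property_id,)


@dataclass(eq=False)
class Prediction(Parameter):
    model_id: str = ""
    application: str | None = None
    type: PredictionType = PredictionType.TRAINING

    SYSTEM_CARGOS = ()
    OWN_ATTRIBUTES = ("ModelId", "Application", "Type")

    def _state(self):
        return super()._state() + (self.model_id, self.application, self.type)


#: concrete container types, in archive build-up order
CONCRETE_TYPES: tuple[type[Container], ...] = (
    Compound,
    Property,
    Descriptor,
    Model,
    Prediction,
)

ABSTRACT_TYPES: tuple[type[Container], ...] = (Container, Parameter)


class Registry:
    """Ordered, id-unique list of containers of one concrete type."""

    def __init__(self, container_type: type[Container]):
        if container_type not in CONCRETE_TYPES:
            raise TypeError(f"not a concrete container type: {container_type}")
        self.container_type = container_type
        self._members: list[Container] = []
        self._index: dict[str, Container] = {}

    def __len__(self) -> int:
        return len(self._members)

    def __iter__(self):
        return iter(self._members)

    def __contains__(self, cid: str) -> bool:
        return cid in self._index

    def __eq__(self, other) -> bool:
        if not isinstance(other, Registry):
            return NotImplemented
        return (
            self.container_type is other.container_type
            and self._members == other._members
        )

    def ids(self) -> list[str]:
        return [c.id for c in self._members]

    def get(self, cid: str) -> Container:
        try:
            return self._index[cid]
        except KeyError:
            raise NotFound(
                f"no {self.container_type.__name__} with id {cid!r}"
            ) from None

    def find(self, cid: str) -> Container | None:
        return self._index.get(cid)

    def add(self, container: Container) -> Container:
        if not isinstance(container, self.container_type):
            raise TypeError(
                f"expected {self.container_type.__name__}, got {type(container).__name__}"
            )
        if not validate_identifier(container.id):
            raise InvalidIdentifier(f"invalid identifier: {container.id!r}")
        if container.id in self._index:
            raise DuplicateIdentifier(
                f"{self.container_type.__name__} id {container.id!r} already registered"
            )
        self._members.append(container)
        self._index[container.id] = container
        return container

    def remove(self, cid: str) -> Container:
        container = self.get(cid)
        self._members.remove(container)
        del self._index[cid]
        return container


class Archive:
    """Root object: a name, a description and five container registries."""

    def __init__(self, name: str = "", description: str = ""):
        self.name = name
        self.description = description
        self.compounds = Registry(Compound)
        self.properties = Registry(Property)
        self.descriptors = Registry(Descriptor)
        self.models = Registry(Model)
        self.predictions = Registry(Prediction)
        #: unrecognized files preserved verbatim on round trip (path -> bytes)
        self.extras: dict[str, bytes] = {}

    def registries(self) -> dict[type[Container], Registry]:
        return {
            Compound: self.compounds,
            Property: self.properties,
            Descriptor: self.descriptors,
            Model: self.models,
            Prediction: self.predictions,
        }

    def registry(self, container_type: type[Container]) -> Registry:
        try:
            return self.registries()[container_type]
        except KeyError:
            raise TypeError(f"no registry for {container_type}") from None

    def __eq__(self, other) -> bool:
        if not isinstance(other, Archive):
            return NotImplemented
        return (
            self.name == other.name
            and self.description == other.description
            and all(
                self.registry(t) == other.registry(t) for t in CONCRETE_TYPES
            )
            and self.extras == other.extras
        )

    # -- strong-relationship management -------------------------------------

    def dependents_of(self, container_type: type[Container], cid: str) -> list[str]:
        """Ids of containers whose strong relationship points at (*type*, *cid*).

        Left-hand sides store no back-references, so this scans the
        right-hand-side registries only (two at most).
        """
        deps: list[str] = []
        if container_type is Property:
            deps.extend(m.id for m in self.models if m.property_id == cid)
        elif container_type is Model:
            deps.extend(p.id for p in self.predictions if p.model_id == cid)
        return deps

    def remove_container(self, container_type: type[Container], cid: str) -> Container:
        """Remove a container, refusing while strong relationships point at it."""
        registry = self.registry(container_type)
        registry.get(cid)  # NotFound if absent
        deps = self.dependents_of(container_type, cid)
        if deps:
            raise RelationshipViolation(
                f"{container_type.__name__} {cid!r} is referenced by: "
                + ", ".join(deps),
                dependents=deps,
            )
        return registry.remove(cid)

    def resolve_prediction_chain(self, prediction_id: str) -> tuple[Model, Property]:
        """Follow Prediction -> Model -> Property along the strong chain."""
        prediction = self.predictions.get(prediction_id)
        model = self.models.find(prediction.model_id)
        if model is None:
            raise BrokenChain(
                f"prediction {prediction_id!r}: model {prediction.model_id!r} not found"
            )
        prop = self.properties.find(model.property_id)
        if prop is None:
            raise BrokenChain(
                f"model {model.id!r}: property {model.property_id!r} not found"
            )
        return model, prop


# -- schema introspection ----------------------------------------------------


def _inherited(ct: type[Container], attr: str) -> list[str]:
    """Collect tuple-attribute *attr* from proper ancestors, root first."""
    out: list[str] = []
    for base in reversed(ct.__mro__):
        if base is ct or not issubclass(base, Container) or base is object:
            continue
        if issubclass(base, Container):
            own = base.__dict__.get(attr)
            if own:
                out.extend(own)
    return out


def describe_schema() -> dict:
    """Introspect the implemented container hierarchy.

    Counts are derived from the live class definitions, never hard-coded,
    so the report stays truthful if the hierarchy evolves.
    """
    report: dict = {
        "abstract_types": [t.__name__ for t in ABSTRACT_TYPES],
        "concrete_types": [t.__name__ for t in CONCRETE_TYPES],
        "types": {},
    }
    for ct in ABSTRACT_TYPES + CONCRETE_TYPES:
        report["types"][ct.__name__] = {
            "own_attributes": list(ct.__dict__.get("OWN_ATTRIBUTES", ())),
            "inherited_attributes": _inherited(ct, "OWN_ATTRIBUTES"),
            "own_system_cargos": list(ct.__dict__.get("SYSTEM_CARGOS", ())),
            "inherited_system_cargos": _inherited(ct, "SYSTEM_CARGOS"),
        }
    return report


def system_cargo_ids(container_type: type[Container]) -> set[str]:
    """All system cargo identifiers applicable to *container_type*."""
    ids: set[str] = set()
    for base in container_type.__mro__:
        if issubclass(base, Container) if isinstance(base, type) else False:
            ids.update(base.__dict__.get("SYSTEM_CARGOS", ()))
    # "structure" stands for the whole family of structure cargo ids; the
    # concrete identifiers come from Chemical MIME names (see cargo codecs).
    return ids
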