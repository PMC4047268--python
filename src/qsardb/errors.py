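"""Exception hierarchy shared by all qsardb modules."""


class QdbError(Exception):
    """Base class for all qsardb errors."""


class InvalidIdentifier(QdbError):
    pass


class DuplicateIdentifier(QdbError):
    pass


class NotFound(QdbError):
    pass


class RelationshipViolation(QdbError):
    """Raised when removing a container that other containers still reference.

    ``dependents`` lists the identifiers of the referencing containers.
    """

    def __init__(self, message: str, dependents: list[str] | None = None):
        super().__init__(message)
        self.dependents = dependents or []


class BrokenChain(QdbError):
    pass


class StorageError(QdbError):
    pass


class IntegrityError(StorageError):
    pass


class ParseError(QdbError):
    pass


class MissingDescriptor(StorageError):
    pass


class MalformedRow(ParseError):
    pass


class DuplicateCompoundRow(ParseError):
    pass


class BibtexParseError(ParseError):
    pass


class NotChemicalMime(QdbError):
    pass


class YamlParseError(ParseError):
    pass


class MissingField(ParseError):
    pass


class EmptyUnit(ParseError):
    pass


class MalformedCas(QdbError):
    pass


class UnsupportedModelType(QdbError):
    pass


class MalformedPmml(ParseError):
    pass


class MappingError(QdbError):
    pass


class UnresolvedIdentifier(QdbError):
    pass


class NoOverlap(QdbError):
    pass


class NoTrainingPrediction(QdbError):
    pass


class QuerySyntaxError(QdbError):
    """Query expression could not be parsed; ``position`` is a 0-based offset."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position
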