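"""On-demand statistics and set operations over archives.

Nothing computed here is ever written back into an archive: goodness-of-fit
numbers are secondary data, recomputed from the stored values whenever
needed.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

from . import codecs
from .errors import NoOverlap, NoTrainingPrediction, QdbError, QuerySyntaxError
from .schema import (
    Archive,
    CONCRETE_TYPES,
    PredictionType,
    Registry,
)
from .storage import container_subdir


@dataclass
class FitReport:
    """Paired experimental-vs-predicted statistics for one Prediction.

    Only compounds where both sides hold normal values enter ``n``.
    ``r_squared``/``rmse`` are None when undefined (n < 2 or zero variance
    in the experimental values).  Residuals are predicted - experimental.
    """

    prediction_id: str
    n: int
    r_squared: float | None
    rmse: float | None
    residuals: dict[str, float] = field(default_factory=dict)


def compute_fit(archive: Archive, prediction_id: str) -> FitReport:
    model, prop = archive.resolve_prediction_chain(prediction_id)
    prediction = archive.predictions.get(prediction_id)
    if not prop.has_cargo("values"):
        raise QdbError(f"property {prop.id!r} has no values cargo")
    if not prediction.has_cargo("values"):
        raise QdbError(f"prediction {prediction_id!r} has no values cargo")
    experimental = codecs.parse_values(prop.cargo("values"))
    predicted = codecs.parse_values(prediction.cargo("values"))

    exp_by_id = {cid: tok for cid, tok, _ in experimental.rows}
    pairs: list[tuple[str, float, float]] = []
    for cid, pred_tok, _ in predicted.rows:
        exp_tok = exp_by_id.get(cid)
        if exp_tok is None or not exp_tok.is_normal or not pred_tok.is_normal:
            continue
        pairs.append((cid, exp_tok.numeric, pred_tok.numeric))
    if not pairs:
        raise NoOverlap(
            f"prediction {prediction_id!r} and property {prop.id!r} share no "
            "compounds with normal values"
        )

    n = len(pairs)
    residuals = {cid: y_hat - y for cid, y, y_hat in pairs}
    ss_res = sum((y_hat - y) ** 2 for _, y, y_hat in pairs)
    mean = sum(y for _, y, _ in pairs) / n
    ss_tot = sum((y - mean) ** 2 for _, y, _ in pairs)
    if n < 2 or ss_tot == 0.0:
        r_squared = None
        rmse = None if n < 2 else math.sqrt(ss_res / n)
    else:
        r_squared = 1.0 - ss_res / ss_tot  # may go negative; never clamped
        rmse = math.sqrt(ss_res / n)
    return FitReport(
        prediction_id=prediction_id,
        n=n,
        r_squared=r_squared,
        rmse=rmse,
        residuals=residuals,
    )


def _prediction_compound_ids(prediction) -> set[str]:
    if not prediction.has_cargo("values"):
        return set()
    return set(codecs.parse_values(prediction.cargo("values")).ids())


def classify_validation_subtype(archive: Archive, prediction_id: str) -> str:
    """"internal", "external" or "mixed" relative to the model's training set."""
    prediction = archive.predictions.get(prediction_id)
    if prediction.type is not PredictionType.VALIDATION:
        raise QdbError(f"prediction {prediction_id!r} is not a validation prediction")
    training = None
    for other in archive.predictions:
        if other.model_id == prediction.model_id and other.type is PredictionType.TRAINING:
            training = other
            break
    if training is None:
        raise NoTrainingPrediction(
            f"model {prediction.model_id!r} has no training prediction"
        )
    validation_ids = _prediction_compound_ids(prediction)
    training_ids = _prediction_compound_ids(training)
    if validation_ids <= training_ids:
        return "internal"
    if validation_ids.isdisjoint(training_ids):
        return "external"
    return "mixed"


# -- label query language ----------------------------------------------------
#
# grammar:  expr   := term ("OR" term)*
#           term   := factor ("AND" factor)*
#           factor := "NOT" factor | "(" expr ")" | label
# keywords are case-sensitive; labels share the identifier charset.

_TOKEN_RE = re.compile(r"\s*(?:(?P<paren>[()])|(?P<word>[A-Za-z0-9._-]+))")


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0
        self.tokens: list[tuple[str, int]] = []
        pos = 0
        while pos < len(text):
            m = _TOKEN_RE.match(text, pos)
            if not m or m.end() == pos:
                stripped = text[pos:].lstrip()
                if not stripped:
                    break
                raise QuerySyntaxError(
                    f"unexpected character {stripped[0]!r}",
                    len(text) - len(stripped),
                )
            self.tokens.append((m.group("paren") or m.group("word"), m.start()))
            pos = m.end()
        self.i = 0

    def peek(self) -> str | None:
        return self.tokens[self.i][0] if self.i < len(self.tokens) else None

    def here(self) -> int:
        return self.tokens[self.i][1] if self.i < len(self.tokens) else len(self.text)

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise QuerySyntaxError("unexpected end of expression", len(self.text))
        self.i += 1
        return tok

    def parse(self):
        node = self.expr()
        if self.peek() is not None:
            raise QuerySyntaxError(f"unexpected token {self.peek()!r}", self.here())
        return node

    def expr(self):
        node = self.term()
        while self.peek() == "OR":
            self.take()
            rhs = self.term()
            node = ("or", node, rhs)
        return node

    def term(self):
        node = self.factor()
        while self.peek() == "AND":
            self.take()
            rhs = self.factor()
            node = ("and", node, rhs)
        return node

    def factor(self):
        tok = self.peek()
        if tok == "NOT":
            self.take()
            return ("not", self.factor())
        if tok == "(":
            self.take()
            node = self.expr()
            if self.peek() != ")":
                raise QuerySyntaxError("expected ')'", self.here())
            self.take()
            return node
        if tok is None or tok in (")", "AND", "OR"):
            raise QuerySyntaxError(
                f"expected a label, got {tok!r}" if tok else "expected a label",
                self.here(),
            )
        return ("label", self.take())


def parse_query(expression: str):
    """Parse a label query into an AST (exposed for testing)."""
    return _Parser(expression).parse()


def _eval(node, labels: set[str]) -> bool:
    op = node[0]
    if op == "label":
        return node[1] in labels
    if op == "not":
        return not _eval(node[1], labels)
    if op == "and":
        return _eval(node[1], labels) and _eval(node[2], labels)
    return _eval(node[1], labels) or _eval(node[2], labels)


def query_labels(registry: Registry, expression: str) -> list[str]:
    """Ids of registry members whose labels satisfy *expression*, in order."""
    ast = parse_query(expression)
    return [c.id for c in registry if _eval(ast, set(c.labels))]


# -- summary -----------------------------------------------------------------


def summarize(archive: Archive) -> dict:
    """Container counts, per-container cargo counts and the root listing."""
    per_type: dict[str, int] = {}
    cargo_counts: dict[str, int] = {}
    root_listing = ["archive.xml"]
    for ct in CONCRETE_TYPES:
        registry = archive.registry(ct)
        subdir = container_subdir(ct)
        per_type[subdir] = len(registry)
        if len(registry):
            root_listing.append(subdir)
        for c in registry:
            cargo_counts[f"{subdir}/{c.id}"] = len(c.cargos)
    return {
        "name": archive.name,
        "containers": per_type,
        "cargos": cargo_counts,
        "root": root_listing,
    }
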