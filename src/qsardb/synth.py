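"""Deterministic synthetic archives for tests and demonstrations.

The generator builds a fully developed archive — compounds with
checksum-correct CAS numbers and structure cargos, descriptor values drawn
uniform(0, 1), a property derived from a known linear model plus optional
Gaussian noise, the model itself as a PMML cargo, and its training
prediction.  Identical specs produce byte-identical serialized archives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import codecs, pmml
from .codecs import ParameterTable, serialize_values
from .conversion import evaluate_over_archive
from .schema import (
    Archive,
    Compound,
    Descriptor,
    Model,
    Prediction,
    PredictionType,
    Property,
)
from .validation import append_cas_check_digit

#: small fixed alphabet of real single-line SMILES strings
SMILES_ALPHABET = (
    "C",
    "CC",
    "CCO",
    "CC(=O)O",
    "c1ccccc1",
    "Cc1ccccc1",
    "CCN(CC)CC",
    "C1CCCCC1",
    "OC(=O)c1ccccc1",
    "ClCCl",
)


@dataclass(frozen=True)
class SyntheticSpec:
    n_compounds: int = 10
    n_descriptors: int = 2
    coefficients: tuple[float, ...] = (1.0, -0.5)
    intercept: float = 0.25
    noise_sigma: float = 0.0
    abnormal_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_compounds < 0:
            raise ValueError("n_compounds must be >= 0")
        if len(self.coefficients) != self.n_descriptors:
            raise ValueError("need one coefficient per descriptor")
        if not (0.0 <= self.abnormal_fraction <= 1.0):
            raise ValueError("abnormal_fraction must be in [0, 1]")
        if self.noise_sigma < 0.0:
            raise ValueError("noise_sigma must be >= 0")


def _fmt(x: float) -> str:
    return repr(float(x))


def generate_archive(spec: SyntheticSpec) -> Archive:
    rng = np.random.default_rng(spec.seed)
    archive = Archive(
        name=f"Synthetic linear data set (seed {spec.seed})",
        description=(
            f"{spec.n_compounds} compounds, {spec.n_descriptors} descriptors, "
            f"noise sigma {spec.noise_sigma}"
        ),
    )

    for i in range(1, spec.n_compounds + 1):
        base = "".join(str(d) for d in rng.integers(0, 10, size=5))
        compound = Compound(
            id=str(i),
            name=f"compound-{i}",
            cas=append_cas_check_digit(base),
        )
        compound.add_cargo(
            "smiles",
            (SMILES_ALPHABET[int(rng.integers(0, len(SMILES_ALPHABET)))] + "\n").encode(),
        )
        archive.compounds.add(compound)

    x = rng.uniform(0.0, 1.0, size=(spec.n_compounds, spec.n_descriptors))
    for j in range(spec.n_descriptors):
        descriptor = Descriptor(
            id=f"d{j + 1}",
            name=f"descriptor {j + 1}",
            application="qsardb-synth 0.1",
        )
        table = ParameterTable()
        for i in range(spec.n_compounds):
            table.add(str(i + 1), _fmt(x[i, j]))
        descriptor.add_cargo("values", serialize_values(table))
        descriptor.add_cargo("ucum", codecs.serialize_ucum("1"))
        archive.descriptors.add(descriptor)

    # accumulate in the same order as the model evaluator so that sigma=0
    # property values and training predictions are bit-identical
    y = np.empty(spec.n_compounds)
    for i in range(spec.n_compounds):
        acc = spec.intercept
        for j in range(spec.n_descriptors):
            acc += spec.coefficients[j] * x[i, j]
        y[i] = acc
    if spec.noise_sigma > 0:
        y = y + rng.normal(0.0, spec.noise_sigma, size=spec.n_compounds)
    abnormal = rng.uniform(size=spec.n_compounds) < spec.abnormal_fraction

    prop = Property(id="p1", name="synthetic endpoint", endpoint="synthetic")
    table = ParameterTable()
    for i in range(spec.n_compounds):
        table.add(str(i + 1), "N/A" if abnormal[i] else _fmt(y[i]))
    prop.add_cargo("values", serialize_values(table))
    prop.add_cargo("ucum", codecs.serialize_ucum("1"))
    archive.properties.add(prop)

    regression = pmml.PmmlRegression(
        target_ref=pmml.make_prefixed_id(Property, "p1"),
        term_refs=[
            pmml.make_prefixed_id(Descriptor, f"d{j + 1}")
            for j in range(spec.n_descriptors)
        ],
        coefficients=list(spec.coefficients),
        intercept=spec.intercept,
    )
    model = Model(id="m1", name="synthetic linear model", property_id="p1")
    model.add_cargo("pmml", pmml.write_pmml(regression))
    archive.models.add(model)

    training = Prediction(
        id="m1-training",
        name="training run",
        model_id="m1",
        application="qsardb-synth 0.1",
        type=PredictionType.TRAINING,
    )
    training.add_cargo(
        "values", serialize_values(evaluate_over_archive(archive, regression))
    )
    archive.predictions.add(training)
    return archive
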