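import pytest

from qsardb import codecs
from qsardb.schema import (
    Archive,
    Compound,
    Descriptor,
    Model,
    Prediction,
    PredictionType,
    Property,
)
from qsardb import pmml
from qsardb.codecs import ParameterTable, serialize_values
from qsardb.synth import SyntheticSpec, generate_archive


@pytest.fixture
def chain_archive() -> Archive:
    """Small hand-built archive with a full Property<-Model<-Prediction chain."""
    archive = Archive(name="chain fixture")
    for i in ("1", "2", "3"):
        archive.compounds.add(Compound(id=i, name=f"compound {i}"))

    prop = Property(id="p1", endpoint="toxicity")
    table = ParameterTable()
    table.add("1", "5.24")
    table.add("2", "4.1")
    table.add("3", "N/A")
    prop.add_cargo("values", serialize_values(table))
    archive.properties.add(prop)

    descriptor = Descriptor(id="logp", application="calc 1.0")
    dtable = ParameterTable()
    dtable.add("1", "2.0")
    dtable.add("2", "1.5")
    dtable.add("3", "0.5")
    descriptor.add_cargo("values", serialize_values(dtable))
    archive.descriptors.add(descriptor)

    regression = pmml.PmmlRegression(
        target_ref="properties/p1",
        term_refs=["descriptors/logp"],
        coefficients=[0.5],
        intercept=1.2,
    )
    model = Model(id="m1", property_id="p1")
    model.add_cargo("pmml", pmml.write_pmml(regression))
    archive.models.add(model)

    prediction = Prediction(id="t1", model_id="m1", type=PredictionType.TRAINING)
    ptable = ParameterTable()
    ptable.add("1", "2.2")
    ptable.add("2", "1.95")
    ptable.add("3", "1.45")
    prediction.add_cargo("values", serialize_values(ptable))
    archive.predictions.add(prediction)
    return archive


@pytest.fixture
def synthetic_archive() -> Archive:
    return generate_archive(SyntheticSpec(n_compounds=8, seed=7))
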