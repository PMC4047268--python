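import math

import pytest
from hypothesis import given, settings, strategies as st

from qsardb.analytics import (
    classify_validation_subtype,
    compute_fit,
    parse_query,
    query_labels,
    summarize,
)
from qsardb.codecs import ParameterTable, serialize_values
from qsardb.errors import (
    NoOverlap,
    NoTrainingPrediction,
    QuerySyntaxError,
)
from qsardb.schema import (
    Archive,
    Compound,
    Prediction,
    PredictionType,
    Registry,
)
from qsardb.storage import DirectoryBackend, save_archive
from qsardb.synth import SyntheticSpec, generate_archive


def add_prediction(archive, pid, ptype, values):
    prediction = Prediction(id=pid, model_id="m1", type=ptype)
    table = ParameterTable()
    for cid, raw in values.items():
        table.add(cid, raw)
    prediction.add_cargo("values", serialize_values(table))
    archive.predictions.add(prediction)
    return prediction


class TestComputeFit:
    def test_perfect_fit(self, chain_archive):
        prediction = chain_archive.predictions.get("t1")
        prop = chain_archive.properties.get("p1")
        prediction.payloads["values"] = prop.payloads["values"]
        report = compute_fit(chain_archive, "t1")
        assert report.r_squared == pytest.approx(1.0)
        assert report.rmse == pytest.approx(0.0)

    def test_abnormal_pairs_excluded(self, chain_archive):
        # property has N/A for compound 3, so only 2 pairs remain
        report = compute_fit(chain_archive, "t1")
        assert report.n == 2
        assert set(report.residuals) == {"1", "2"}

    def test_residual_sign_is_predicted_minus_experimental(self, chain_archive):
        report = compute_fit(chain_archive, "t1")
        assert report.residuals["1"] == pytest.approx(2.2 - 5.24)

    def test_constant_predictions_nonpositive_r2(self, chain_archive):
        add_prediction(
            chain_archive, "const", PredictionType.VALIDATION,
            {"1": "3.0", "2": "3.0"},
        )
        report = compute_fit(chain_archive, "const")
        # hand oracle: y = (5.24, 4.1), mean 4.67; ss_tot = 2*0.57^2 = 0.6498
        # residuals = (3-5.24, 3-4.1); ss_res = 2.24^2 + 1.1^2 = 6.2276
        expected = 1.0 - 6.2276 / 0.6498
        assert report.r_squared == pytest.approx(expected)
        assert report.r_squared < 0  # reported, not clamped

    def test_na_prediction_row_reduces_n(self, synthetic_archive):
        prop = synthetic_archive.properties.get("p1")
        training = synthetic_archive.predictions.get("m1-training")
        table = ParameterTable()
        from qsardb.codecs import parse_values

        rows = [
            (cid, tok.raw)
            for cid, tok, _ in parse_values(training.cargo("values")).rows
        ]
        for i, (cid, raw) in enumerate(rows):
            table.add(cid, "N/A" if i == 0 else raw)
        training.payloads["values"] = serialize_values(table)
        report = compute_fit(synthetic_archive, "m1-training")
        assert report.n == len(rows) - 1

    def test_no_overlap(self, chain_archive):
        add_prediction(chain_archive, "none", PredictionType.VALIDATION, {"3": "1.0"})
        with pytest.raises(NoOverlap):
            compute_fit(chain_archive, "none")

    def test_single_pair_undefined(self, chain_archive):
        add_prediction(chain_archive, "one", PredictionType.VALIDATION, {"1": "5.0"})
        report = compute_fit(chain_archive, "one")
        assert report.n == 1
        assert report.r_squared is None

    @pytest.mark.parametrize("sigma,floor", [(0.0, 1.0), (0.01, 0.95)])
    def test_noise_scaling(self, sigma, floor):
        archive = generate_archive(
            SyntheticSpec(n_compounds=50, noise_sigma=sigma, seed=11)
        )
        report = compute_fit(archive, "m1-training")
        assert report.r_squared >= floor
        if sigma == 0.0:
            assert report.r_squared == pytest.approx(1.0)
            assert report.rmse == pytest.approx(0.0)

    def test_monotone_in_noise(self):
        r2 = []
        for sigma in (0.0, 0.01, 0.1):
            archive = generate_archive(
                SyntheticSpec(n_compounds=100, noise_sigma=sigma, seed=3)
            )
            r2.append(compute_fit(archive, "m1-training").r_squared)
        assert r2[0] > r2[1] > r2[2]


class TestValidationSubtype:
    def setup_archive(self, training_ids, validation_ids):
        archive = generate_archive(SyntheticSpec(n_compounds=8, seed=5))
        training = archive.predictions.get("m1-training")
        table = ParameterTable()
        for cid in training_ids:
            table.add(cid, "1.0")
        training.payloads["values"] = serialize_values(table)
        add_prediction(
            archive, "val", PredictionType.VALIDATION,
            {cid: "1.0" for cid in validation_ids},
        )
        return archive

    def test_internal(self):
        archive = self.setup_archive({"1", "2", "3"}, {"1", "2"})
        assert classify_validation_subtype(archive, "val") == "internal"

    def test_external(self):
        archive = self.setup_archive({"1", "2", "3"}, {"7", "8"})
        assert classify_validation_subtype(archive, "val") == "external"

    def test_mixed(self):
        archive = self.setup_archive({"1", "2", "3"}, {"3", "7"})
        assert classify_validation_subtype(archive, "val") == "mixed"

    def test_no_training_prediction(self):
        archive = self.setup_archive({"1"}, {"1"})
        archive.predictions.remove("m1-training")
        with pytest.raises(NoTrainingPrediction):
            classify_validation_subtype(archive, "val")

    def test_invariant_to_registry_order(self):
        # same sets, predictions registered in the opposite order
        a = self.setup_archive({"1", "2", "3"}, {"3", "7"})
        b = generate_archive(SyntheticSpec(n_compounds=8, seed=5))
        training = b.predictions.remove("m1-training")
        add_prediction(b, "val", PredictionType.VALIDATION,
                       {"3": "1.0", "7": "1.0"})
        table = ParameterTable()
        for cid in ("1", "2", "3"):
            table.add(cid, "1.0")
        training.payloads["values"] = serialize_values(table)
        b.predictions.add(training)
        assert classify_validation_subtype(a, "val") == classify_validation_subtype(b, "val")


def labeled_registry(assignments):
    registry = Registry(Compound)
    for cid, labels in assignments.items():
        registry.add(Compound(id=cid, labels=list(labels)))
    return registry


def brute_force(registry, predicate):
    return [c.id for c in registry if predicate(set(c.labels))]


class TestQueryLabels:
    def test_single_label(self):
        registry = labeled_registry({"c1": ["train"], "c2": ["test"]})
        assert query_labels(registry, "train") == ["c1"]

    def test_and_not(self):
        registry = labeled_registry(
            {"a": ["train"], "b": ["train", "outlier"], "c": ["test"]}
        )
        assert query_labels(registry, "train AND NOT outlier") == ["a"]

    def test_registry_order_preserved(self):
        registry = labeled_registry({"z": ["x"], "a": ["x"]})
        assert query_labels(registry, "x") == ["z", "a"]

    def test_precedence_not_and_or(self):
        registry = labeled_registry(
            {"1": ["a"], "2": ["b"], "3": ["a", "b"], "4": []}
        )
        # NOT a OR b AND a == (NOT a) OR (b AND a)
        assert query_labels(registry, "NOT a OR b AND a") == ["2", "3", "4"]

    def test_syntax_error_carries_position(self):
        with pytest.raises(QuerySyntaxError) as excinfo:
            parse_query("a AND (b OR")
        assert excinfo.value.position == 11

    @pytest.mark.parametrize("bad", ["", "AND b", "a b", "(a", "a)", "a OR"])
    def test_rejects(self, bad):
        with pytest.raises(QuerySyntaxError):
            parse_query(bad)

    @settings(max_examples=200, deadline=None)
    @given(
        data=st.lists(
            st.sets(st.sampled_from(["a", "b", "c"])), min_size=0, max_size=8
        )
    )
    def test_de_morgan(self, data):
        registry = labeled_registry(
            {f"c{i}": labels for i, labels in enumerate(data)}
        )
        assert query_labels(registry, "NOT (a OR b)") == query_labels(
            registry, "NOT a AND NOT b"
        )
        assert query_labels(registry, "NOT (a AND b)") == query_labels(
            registry, "NOT a OR NOT b"
        )

    @settings(max_examples=100, deadline=None)
    @given(
        data=st.lists(
            st.sets(st.sampled_from(["a", "b", "c"])), min_size=0, max_size=6
        )
    )
    def test_matches_brute_force(self, data):
        registry = labeled_registry(
            {f"c{i}": labels for i, labels in enumerate(data)}
        )
        cases = {
            "a": lambda s: "a" in s,
            "a AND b": lambda s: "a" in s and "b" in s,
            "a OR b AND NOT c": lambda s: "a" in s or ("b" in s and "c" not in s),
            "(a OR b) AND NOT c": lambda s: ("a" in s or "b" in s) and "c" not in s,
        }
        for expression, predicate in cases.items():
            assert query_labels(registry, expression) == brute_force(registry, predicate)


class TestSummarize:
    def test_empty_archive(self):
        summary = summarize(Archive())
        assert all(v == 0 for v in summary["containers"].values())
        assert summary["root"] == ["archive.xml"]

    def test_fully_developed(self, synthetic_archive):
        summary = summarize(synthetic_archive)
        assert len(summary["root"]) == 6  # archive.xml + five subdirectories
        assert all(v > 0 for v in summary["containers"].values())

    def test_counts_match_directory_listing(self, tmp_path, synthetic_archive):
        save_archive(synthetic_archive, DirectoryBackend(tmp_path / "a"))
        summary = summarize(synthetic_archive)
        for subdir, count in summary["containers"].items():
            entries = [
                p for p in (tmp_path / "a" / subdir).iterdir() if p.is_dir()
            ] if (tmp_path / "a" / subdir).exists() else []
            assert len(entries) == count
        on_disk = sorted(p.name for p in (tmp_path / "a").iterdir())
        assert on_disk == sorted(summary["root"])
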