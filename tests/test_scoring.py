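import io
import itertools

import numpy as np
import pytest

from translokit.scoring import (
    FeatureSpec,
    FeatureWeightTable,
    ProteinFeatures,
    ScoringError,
    TranslocationClass,
    binarize,
    classify,
    normalize,
    published_model,
    raw_tes,
    read_feature_table,
    score_cohort,
    write_feature_table,
)


def _toy_table(weights):
    return FeatureWeightTable(
        features=tuple(
            FeatureSpec(f"GO:{i:07d}", "go_term", w, term_id=f"GO:{i:07d}")
            for i, w in enumerate(weights, start=1)
        )
    )


class TestPublishedModel:
    def test_nineteen_features_by_kind(self, model_high):
        kinds = [f.kind for f in model_high]
        assert len(model_high) == 19
        assert kinds.count("go_term") == 15
        assert kinds.count("degree_below") == 2
        assert kinds.count("bridgeness_below") == 2

    def test_degree_and_bridgeness_cutpoints(self, model_high):
        thresholds = {
            f.feature_id: f.threshold for f in model_high if f.threshold is not None
        }
        assert thresholds == {
            "degree<14.5": 14.5,
            "degree<62.5": 62.5,
            "bridgeness<2.5e-06": 2.5e-06,
            "bridgeness<0.000292": 0.000292,
        }

    def test_high_precision_coefficients(self, model_high):
        weights = {f.feature_id: f.weight for f in model_high}
        assert weights["GO:0009887"] == 2.675
        assert weights["GO:0005737"] == 1.353
        assert weights["degree<62.5"] == -0.497

    def test_two_decimal_table_variant(self, model_table):
        weights = {f.feature_id: f.weight for f in model_table}
        assert weights["GO:0009887"] == 2.68
        assert weights["degree<62.5"] == -0.50

    def test_unknown_precision_rejected(self):
        with pytest.raises(ScoringError):
            published_model(precision="approximate")


class TestBinarize:
    def test_worked_example_active_set(self, protein_a, model_high):
        x = binarize(protein_a, model_high)
        active = {f.feature_id for f, xi in zip(model_high, x) if xi}
        assert active == {"GO:0009887", "GO:0005737", "degree<62.5"}

    def test_degree_cuts_are_cumulative(self, model_high):
        p = ProteinFeatures("p", degree=10)
        active = {
            f.feature_id for f, xi in zip(model_high, binarize(p, model_high)) if xi
        }
        assert {"degree<14.5", "degree<62.5"} <= active

    def test_hub_with_no_annotations_is_all_false(self, model_high):
        p = ProteinFeatures("hub", degree=100)
        assert not binarize(p, model_high).any()

    def test_undefined_topology_indicators_false(self, model_high):
        p = ProteinFeatures("p", go_terms=frozenset({"GO:0005737"}))
        active = {
            f.feature_id for f, xi in zip(model_high, binarize(p, model_high)) if xi
        }
        assert active == {"GO:0005737"}


class TestRawTES:
    def test_worked_example_scores_3_531(self, protein_a, model_high):
        assert raw_tes(binarize(protein_a, model_high), model_high) == pytest.approx(
            3.531, abs=1e-12
        )

    def test_all_false_is_zero(self, model_high):
        assert raw_tes(np.zeros(19, dtype=int), model_high) == 0.0

    def test_positive_go_block_sums_to_9_95(self, model_table):
        x = np.array([int(f.kind == "go_term" and f.weight > 0) for f in model_table])
        assert x.sum() == 9
        assert raw_tes(x, model_table) == pytest.approx(9.95, abs=1e-12)

    def test_length_mismatch_rejected(self, model_high):
        with pytest.raises(ScoringError):
            raw_tes(np.zeros(7), model_high)

    def test_matches_bruteforce_over_all_subsets(self):
        table = _toy_table([0.5, -1.2, 2.675, 0.0, -0.36, 1.353, -0.497])
        for bits in itertools.product([0, 1], repeat=7):
            expected = sum(w * b for w, b in zip(table.weights, bits))
            assert raw_tes(np.array(bits), table) == pytest.approx(expected, abs=1e-12)

    def test_activating_positive_feature_never_decreases_score(self):
        table = _toy_table([0.7, -0.3, 1.1, -2.0])
        rng = np.random.default_rng(0)
        for _ in range(50):
            x = rng.integers(0, 2, size=4)
            for i, spec in enumerate(table):
                y = x.copy()
                y[i] = 1
                delta = raw_tes(y, table) - raw_tes(x, table)
                assert delta >= 0 if spec.weight >= 0 else delta <= 0


class TestNormalize:
    def test_linear_map(self):
        assert normalize([1.0, 2.0, 3.0]) == pytest.approx([0.0, 0.5, 1.0])

    def test_extremes_map_to_unit_interval_ends(self):
        scores = np.array([3.2, -1.0, 0.4, 7.7])
        norm = normalize(scores)
        assert norm[np.argmax(scores)] == 1.0
        assert norm[np.argmin(scores)] == 0.0

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=20)
        assert normalize(3.7 * x + 11.0) == pytest.approx(normalize(x))

    def test_constant_cohort_rejected(self):
        with pytest.raises(ScoringError, match="degenerate"):
            normalize([2.0, 2.0, 2.0])

    def test_frozen_reference_mode(self):
        norm = normalize([5.0], reference=(0.0, 10.0))
        assert norm[0] == 0.5


class TestClassify:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (0.9807, TranslocationClass.HIGH_CONFIDENCE),
            (0.50, TranslocationClass.LOW_CONFIDENCE),
            (0.4487, TranslocationClass.LOW_CONFIDENCE),
            (0.6167, TranslocationClass.LOW_CONFIDENCE),
            (0.2, TranslocationClass.NON_TRANSLOCATING),
        ],
    )
    def test_three_class_partition(self, value, expected):
        assert classify(value) is expected

    def test_inverted_thresholds_rejected(self):
        with pytest.raises(ScoringError):
            classify(0.5, lower=0.7, upper=0.3)


class TestScoreCohort:
    def test_engineered_cohort_hits_all_three_classes(self, model_high):
        cohort = [
            ProteinFeatures("none"),
            ProteinFeatures(
                "mid",
                go_terms=frozenset({"GO:0009887", "GO:0006109", "GO:0044459"}),
                degree=100,
            ),
            ProteinFeatures(
                "top",
                go_terms=frozenset(
                    f.term_id for f in model_high if f.kind == "go_term" and f.weight > 0
                ),
                degree=100,
            ),
        ]
        results = score_cohort(cohort, model_high)
        labels = {r.protein_id: r.label for r in results}
        assert labels == {
            "none": TranslocationClass.NON_TRANSLOCATING,
            "mid": TranslocationClass.LOW_CONFIDENCE,
            "top": TranslocationClass.HIGH_CONFIDENCE,
        }

    def test_output_order_and_partition(self, model_high):
        rng = np.random.default_rng(2)
        cohort = [
            ProteinFeatures(f"P{i}", degree=float(rng.integers(1, 200)))
            for i in range(40)
        ]
        cohort.append(ProteinFeatures("Pmax", go_terms=frozenset({"GO:0009887"})))
        results = score_cohort(cohort, model_high)
        assert [r.protein_id for r in results] == [p.protein_id for p in cohort]
        counts = {cls: 0 for cls in TranslocationClass}
        for r in results:
            counts[r.label] += 1
        assert sum(counts.values()) == len(cohort)


class TestFeatureTableIO:
    def test_round_trip(self, protein_a):
        features = [
            protein_a,
            ProteinFeatures("P2", degree=3.0, bridgeness=1e-5),
            ProteinFeatures("P3"),
        ]
        buf = io.StringIO()
        write_feature_table(features, buf)
        buf.seek(0)
        back = read_feature_table(buf)
        assert back == features

    def test_missing_column_rejected(self):
        with pytest.raises(ScoringError, match="go_terms"):
            read_feature_table(io.StringIO("protein_id\tdegree\nP1\t3\n"))
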