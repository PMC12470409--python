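import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ttafoods import DOMAINS, InvalidArgumentError
from ttafoods.evaluate import (
    ALL_METHODS,
    VARIANT_METHODS,
    AblationCell,
    ablation_grid,
    ablation_table,
    export_distance_distributions,
    parse_method,
    run_cross_domain,
    weighted_metrics,
    wilcoxon_signed_rank,
)


def exact_wilcoxon_enumeration(diffs):
    """Oracle: two-sided p by exhaustive enumeration of all sign assignments."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    total = ranks.sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.asarray(ws)
    p_le = (ws <= w_obs + 1e-12).mean()
    p_ge = (ws >= w_obs - 1e-12).mean()
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestWeightedMetrics:
    def test_perfect_predictions(self):
        r = weighted_metrics([0, 1, 2, 3, 4], [0, 1, 2, 3, 4], n_classes=5)
        assert r.accuracy == r.precision == r.recall == r.f1 == 100.0

    def test_hand_built_confusion_matrix_oracle(self):
        # y_true=(0,0,1,1,2,2), y_pred=(0,1,1,1,2,0):
        #   class 0: TP=1 FP=1 FN=1 → P=R=F1=1/2
        #   class 1: TP=2 FP=1 FN=0 → P=2/3, R=1, F1=4/5
        #   class 2: TP=1 FP=0 FN=1 → P=1, R=1/2, F1=2/3
        # supports all equal → weighted = plain means
        r = weighted_metrics([0, 0, 1, 1, 2, 2], [0, 1, 1, 1, 2, 0], n_classes=3)
        assert r.accuracy == pytest.approx(100 * 4 / 6)
        assert r.precision == pytest.approx(100 * (0.5 + 2 / 3 + 1.0) / 3)
        assert r.recall == pytest.approx(100 * (0.5 + 1.0 + 0.5) / 3)
        assert r.f1 == pytest.approx(100 * (0.5 + 0.8 + 2 / 3) / 3)
        assert r.per_class[1] == {
            "precision": pytest.approx(100 * 2 / 3),
            "recall": 100.0,
            "f1": pytest.approx(80.0),
            "support": 2,
        }

    def test_weighted_equals_support_weighted_mean(self, rng):
        y_true = rng.integers(0, 4, size=60)
        y_pred = rng.integers(0, 4, size=60)
        r = weighted_metrics(y_true, y_pred, n_classes=4)
        support = np.array([r.per_class[c]["support"] for c in range(4)])
        for metric in ("precision", "recall", "f1"):
            per = np.array([r.per_class[c][metric] for c in range(4)])
            assert getattr(r, metric) == pytest.approx(
                float((per * support).sum() / support.sum()), abs=1e-9
            )

    def test_absent_predicted_class_precision_zero(self):
        r = weighted_metrics([0, 1, 2], [0, 1, 1], n_classes=3)
        assert r.per_class[2]["precision"] == 0.0
        assert 0 <= r.f1 <= 100

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidArgumentError):
            weighted_metrics([], [], n_classes=3)

    def test_out_of_range_labels_rejected(self):
        with pytest.raises(InvalidArgumentError):
            weighted_metrics([0, 5], [0, 1], n_classes=3)


class TestWilcoxon:
    def test_all_positive_unit_diffs(self):
        res = wilcoxon_signed_rank([1, 1, 1, 1, 1])
        assert res.statistic == 15.0
        assert res.p_value == pytest.approx(0.0625)  # 2 * P(W+ >= 15) = 2/32
        assert res.p_value == pytest.approx(exact_wilcoxon_enumeration([1, 1, 1, 1, 1]))

    def test_zero_diffs_dropped(self):
        res = wilcoxon_signed_rank([0.0, 0.0, 0.0])
        assert res.n == 0 and res.p_value == 1.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 11))
        d = np.round(rng.normal(size=n), 1)  # rounding induces ties and zeros
        res = wilcoxon_signed_rank(d)
        if res.n == 0:
            assert res.p_value == 1.0
        else:
            assert res.p_value == pytest.approx(exact_wilcoxon_enumeration(d), abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_scipy_exact_without_ties(self, seed):
        rng = np.random.default_rng(100 + seed)
        d = rng.normal(size=12)
        res = wilcoxon_signed_rank(d)
        ref = stats.wilcoxon(d, method="exact")
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_large_n_close_to_scipy_approx(self):
        rng = np.random.default_rng(7)
        d = rng.normal(size=60) + 0.3
        res = wilcoxon_signed_rank(d)
        ref = stats.wilcoxon(d, method="approx", correction=True)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)


@pytest.fixture(scope="module")
def two_domain_scores():
    return run_cross_domain(
        domains=[DOMAINS["identity"], DOMAINS["bright_blur"]],
        seeds=[0],
        n_train_per_class=8,
        n_test_per_class=3,
        collect_decisions=True,
    )


class TestRunCrossDomain:
    def test_two_domains_give_two_ordered_pairs(self, two_domain_scores):
        scores, _ = two_domain_scores
        pairs = set(map(tuple, scores[["source", "target"]].drop_duplicates().values))
        assert pairs == {("identity", "bright_blur"), ("bright_blur", "identity")}

    def test_all_methods_and_metrics_present(self, two_domain_scores):
        scores, _ = two_domain_scores
        assert set(scores["method"]) == set(ALL_METHODS)
        assert set(scores["metric"]) == {"accuracy", "precision", "recall", "f1"}

    def test_determinism(self):
        kwargs = dict(
            domains=[DOMAINS["identity"], DOMAINS["stain_shift"]],
            seeds=[3],
            n_train_per_class=6,
            n_test_per_class=2,
        )
        a = run_cross_domain(**kwargs)
        b = run_cross_domain(**kwargs)
        pd.testing.assert_frame_equal(a, b)

    def test_fewer_than_two_domains_rejected(self):
        with pytest.raises(InvalidArgumentError):
            run_cross_domain(domains=[DOMAINS["identity"]])

    def test_unknown_method_rejected(self):
        with pytest.raises(InvalidArgumentError):
            run_cross_domain(
                domains=[DOMAINS["identity"], DOMAINS["stain_shift"]],
                methods=["baseline", "magic"],
            )

    def test_four_domains_give_twelve_pairs(self):
        # structural check only: count pairs without running inference
        assert len(list(itertools.permutations(DOMAINS.values(), 2))) == 12


class TestAblationGrid:
    def _synthetic_scores(self, offset_by_method):
        rows = []
        rng = np.random.default_rng(0)
        base = {}
        for s, t in [("a", "b"), ("b", "a")]:
            for metric in ("accuracy", "precision", "recall", "f1"):
                base[(s, t, metric)] = float(rng.uniform(50, 90))
        for method in ALL_METHODS:
            for (s, t, metric), v in base.items():
                rows.append(
                    {
                        "seed": 0,
                        "source": s,
                        "target": t,
                        "method": method,
                        "metric": metric,
                        "value": v + offset_by_method.get(method, 0.0),
                    }
                )
        return pd.DataFrame(rows)

    def test_grid_has_exactly_8_cells(self):
        cells = ablation_grid(self._synthetic_scores({}))
        assert len(cells) == 8
        assert {c.method for c in cells} == set(VARIANT_METHODS)

    def test_identical_scores_give_zero_diff_no_significance(self):
        cells = ablation_grid(self._synthetic_scores({}))
        for c in cells:
            assert c.mean_diff == 0.0
            assert c.p_value == 1.0

    def test_constant_shift_mean_diff(self):
        cells = ablation_grid(
            self._synthetic_scores({"tta_foods_soft_weighted": 1.0})
        )
        cell = next(c for c in cells if c.method == "tta_foods_soft_weighted")
        assert cell.mean_diff == pytest.approx(1.0)
        # 8 paired diffs all positive: p = 2/2^8 * ... checked via oracle
        assert cell.p_value == pytest.approx(
            exact_wilcoxon_enumeration(np.ones(8)), abs=1e-12
        )

    def test_spec_hand_example(self):
        base = np.array([1.0, 2, 3, 4, 5])
        meth = np.array([2.0, 3, 4, 5, 6])
        diffs = meth - base
        res = wilcoxon_signed_rank(diffs)
        assert float(diffs.mean()) == 1.0
        assert res.statistic == 15.0
        assert res.p_value == pytest.approx(exact_wilcoxon_enumeration(diffs), abs=1e-12)

    def test_missing_variant_rejected(self):
        scores = self._synthetic_scores({})
        scores = scores[scores["method"] != "tta_foods_hard_uniform"]
        with pytest.raises(InvalidArgumentError):
            ablation_grid(scores)

    def test_ablation_table_shape(self):
        table = ablation_table(ablation_grid(self._synthetic_scores({})))
        assert list(table.columns) == ["method", "foods", "voting", "weights", "diff", "p_value"]
        assert len(table) == 8


class TestReductionProperties:
    def test_nofoods_soft_uniform_equals_plain_tta_averaging(self, two_domain_scores):
        scores, _ = two_domain_scores
        # independently recompute plain averaging for one pair
        from ttafoods import (
            apply_tta,
            batch_probabilities,
            build_default_augmentations,
            extract_layer_features,
            fit_foods,
            generate_dataset,
            make_toy_adapter,
        )
        from ttafoods.evaluate import weighted_metrics as wm

        train = generate_dataset(8, DOMAINS["identity"], 64, seed=0)
        test = generate_dataset(3, DOMAINS["bright_blur"], 64, seed=10_000)
        adapter = make_toy_adapter(train)
        augset = build_default_augmentations(64)
        y_pred = [
            int(
                batch_probabilities(adapter, apply_tta(img, augset))
                .mean(axis=0)
                .argmax()
            )
            for img in test.images
        ]
        expected = wm(test.labels, y_pred, 5).accuracy
        got = scores[
            (scores.method == "tta_nofoods_soft_uniform")
            & (scores.source == "identity")
            & (scores.target == "bright_blur")
            & (scores.metric == "accuracy")
        ].value.iloc[0]
        assert got == pytest.approx(expected)

    def test_baseline_equals_single_image_inference(self, two_domain_scores):
        scores, _ = two_domain_scores
        from ttafoods import generate_dataset, make_toy_adapter
        from ttafoods.evaluate import weighted_metrics as wm

        train = generate_dataset(8, DOMAINS["bright_blur"], 64, seed=0)
        test = generate_dataset(3, DOMAINS["identity"], 64, seed=10_000)
        adapter = make_toy_adapter(train)
        y_pred = [int(adapter.probabilities(img).argmax()) for img in test.images]
        expected = wm(test.labels, y_pred, 5).accuracy
        got = scores[
            (scores.method == "baseline")
            & (scores.source == "bright_blur")
            & (scores.target == "identity")
            & (scores.metric == "accuracy")
        ].value.iloc[0]
        assert got == pytest.approx(expected)


class TestExportDistanceDistributions:
    def test_summary_matches_order_statistics_oracle(self, two_domain_scores):
        _, decisions = two_domain_scores
        tidy, summary = export_distance_distributions(decisions)
        # the force-retained original (sample_index 0) is excluded
        assert len(tidy) == len(decisions[decisions["sample_index"] > 0])
        for _, row in summary.iterrows():
            mask = (
                (tidy["target"] == row["target"])
                & (tidy["tag"] == row["tag"])
                & (tidy["retained"] == row["retained"])
            )
            vals = tidy.loc[mask, "normalized_distance"].to_numpy()
            vals = vals[np.isfinite(vals)]
            assert row["median"] == pytest.approx(float(np.percentile(vals, 50)))
            assert row["q1"] == pytest.approx(float(np.percentile(vals, 25)))
            assert row["q3"] == pytest.approx(float(np.percentile(vals, 75)))

    def test_kept_groups_bounded_by_one(self, two_domain_scores):
        _, decisions = two_domain_scores
        _, summary = export_distance_distributions(decisions)
        kept = summary[summary["retained"]]
        assert (kept["max"] <= 1.0 + 1e-12).all()

    def test_discarded_samples_have_a_layer_above_one(self, two_domain_scores):
        _, decisions = two_domain_scores
        discarded = decisions[~decisions["retained"]]
        if len(discarded):
            per_sample_max = discarded.groupby(
                ["seed", "source", "target", "image_index", "sample_index"]
            )["normalized_distance"].max()
            assert (per_sample_max > 1.0).all()

    def test_empty_rejected(self):
        with pytest.raises(InvalidArgumentError):
            export_distance_distributions(pd.DataFrame())


def test_parse_method_roundtrip():
    for m in VARIANT_METHODS:
        spec = parse_method(m)
        assert not spec["baseline"]
    assert parse_method("baseline") == {"baseline": True}
    with pytest.raises(InvalidArgumentError):
        parse_method("tta_soft")
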