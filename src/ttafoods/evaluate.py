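"""Evaluation machinery: weighted metrics, the cross-domain benchmark runner,
the 8-row ablation grid with a Wilcoxon signed-rank test, and exports of
threshold-normalized distance distributions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import precision_recall_fscore_support

from .augment import AugmentationSet, apply_tta, build_default_augmentations
from .errors import InvalidArgumentError
from .features import ClassifierAdapter, batch_probabilities, extract_layer_features
from .fixtures import DomainSpec, SyntheticDataset, generate_dataset, make_toy_adapter
from .foods import (
    DEFAULT_EPSILON,
    DEFAULT_K,
    DEFAULT_PERCENTILE,
    FilterDecision,
    FoodsModel,
    filter_and_weight,
    fit_foods,
    unfiltered_weight,
)

__all__ = [
    "MetricsReport",
    "AblationCell",
    "weighted_metrics",
    "wilcoxon_signed_rank",
    "run_cross_domain",
    "ablation_grid",
    "export_distance_distributions",
    "ALL_METHODS",
    "VARIANT_METHODS",
    "METRIC_NAMES",
]

METRIC_NAMES = ("accuracy", "precision", "recall", "f1")

#: "baseline" plus the 8 ablation variants (filter on/off × voting × weights).
VARIANT_METHODS: tuple[str, ...] = tuple(
    f"tta_{'foods' if f else 'nofoods'}_{v}_{w}"
    for f, v, w in itertools.product((False, True), ("hard", "soft"), ("uniform", "weighted"))
)
ALL_METHODS: tuple[str, ...] = ("baseline",) + VARIANT_METHODS

#: The full proposed method.
FULL_METHOD = "tta_foods_soft_weighted"


def parse_method(method: str) -> dict:
    """Decode a method name into its component flags."""
    if method == "baseline":
        return {"baseline": True}
    parts = method.split("_")
    if len(parts) != 4 or parts[0] != "tta" or parts[1] not in ("foods", "nofoods") \
            or parts[2] not in ("hard", "soft") or parts[3] not in ("uniform", "weighted"):
        raise InvalidArgumentError(f"unknown method name {method!r}")
    return {
        "baseline": False,
        "use_foods": parts[1] == "foods",
        "voting": parts[2],
        "weights": parts[3],
    }


# ---------------------------------------------------------------------------
# Metrics


@dataclass
class MetricsReport:
    """Weighted-average accuracy/precision/recall/F1 as percentages."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    per_class: dict[int, dict[str, float]]

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }


def weighted_metrics(
    y_true: Sequence[int], y_pred: Sequence[int], n_classes: int
) -> MetricsReport:
    """Per-class P/R/F1 aggregated with class support as weights, in percent.

    Classes with an empty denominator (never predicted / no support) score 0.
    """
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise InvalidArgumentError("y_true and y_pred must be equal-length and non-empty")
    if y_true.min() < 0 or y_true.max() >= n_classes or y_pred.min() < 0 \
            or y_pred.max() >= n_classes:
        raise InvalidArgumentError("labels out of range")
    labels = np.arange(n_classes)
    p, r, f, support = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, zero_division=0
    )
    accuracy = float((y_true == y_pred).mean()) * 100.0
    total = support.sum()
    return MetricsReport(
        accuracy=accuracy,
        precision=float((p * support).sum() / total) * 100.0,
        recall=float((r * support).sum() / total) * 100.0,
        f1=float((f * support).sum() / total) * 100.0,
        per_class={
            int(c): {
                "precision": float(p[c]) * 100.0,
                "recall": float(r[c]) * 100.0,
                "f1": float(f[c]) * 100.0,
                "support": int(support[c]),
            }
            for c in labels
        },
    )


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test (exact for n ≤ 25, normal approximation above)


@dataclass
class WilcoxonResult:
    statistic: float  # W+ = sum of ranks of positive differences
    p_value: float
    n: int  # non-zero differences used


def wilcoxon_signed_rank(diffs: Sequence[float]) -> WilcoxonResult:
    """Two-sided signed-rank test on paired differences.

    Zero differences are dropped. For n ≤ 25 the exact null distribution of
    W+ is computed by dynamic programming over (doubled, integer) ranks,
    which matches exhaustive sign enumeration; larger n uses the normal
    approximation with tie and continuity corrections.
    """
    d = np.asarray(diffs, dtype=np.float64)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return WilcoxonResult(statistic=0.0, p_value=1.0, n=0)
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= 25:
        # doubled ranks are integers even with midrank ties
        r2 = np.rint(2 * ranks).astype(np.int64)
        total = int(r2.sum())
        counts = np.zeros(total + 1)
        counts[0] = 1.0
        for r in r2:
            counts[r:] += counts[: total + 1 - r]
        counts /= counts.sum()
        w2 = int(round(2 * w_plus))
        p_le = counts[: w2 + 1].sum()
        p_ge = counts[w2:].sum()
        p = min(1.0, 2.0 * min(p_le, p_ge))
    else:
        mean = n * (n + 1) / 4.0
        tie_term = 0.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = float(((tie_counts**3 - tie_counts)).sum()) / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        if var <= 0:
            return WilcoxonResult(statistic=w_plus, p_value=1.0, n=n)
        z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / np.sqrt(var)
        p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return WilcoxonResult(statistic=w_plus, p_value=float(p), n=n)


# ---------------------------------------------------------------------------
# Inference variants over precomputed per-image TTA state


def _labels_for_method(
    method: str,
    per_image: Sequence[tuple[list[FilterDecision], np.ndarray]],
    epsilon: float,
) -> np.ndarray:
    """Final labels for one method, reusing cached decisions/probabilities."""
    spec = parse_method(method)
    labels = np.empty(len(per_image), dtype=np.int64)
    for i, (decisions, probs) in enumerate(per_image):
        if spec["baseline"]:
            labels[i] = int(np.argmax(probs[0]))
            continue
        n = len(decisions)
        retained = (
            np.array([d.retained for d in decisions])
            if spec["use_foods"]
            else np.ones(n, dtype=bool)
        )
        if spec["weights"] == "weighted":
            w = np.array(
                [
                    (d.weight if spec["use_foods"] else unfiltered_weight(d, epsilon))
                    for d in decisions
                ]
            )
            w = np.where(retained, w, 0.0)
        else:
            w = retained.astype(np.float64)
        if w.sum() == 0:  # everything filtered: fall back to the original
            w = np.zeros(n)
            w[0] = 1.0
        if spec["voting"] == "soft":
            fused = (w[:, None] * probs).sum(axis=0)
            labels[i] = int(np.argmax(fused))
        else:
            votes = np.argmax(probs, axis=1)
            score = np.zeros(probs.shape[1])
            np.add.at(score, votes, w)
            labels[i] = int(np.argmax(score))
    return labels


# ---------------------------------------------------------------------------
# Cross-domain benchmark


def run_cross_domain(
    adapter_factory: Callable[[SyntheticDataset], ClassifierAdapter] | None = None,
    domains: Sequence[DomainSpec] = (),
    methods: Sequence[str] = ALL_METHODS,
    seeds: Sequence[int] = (0,),
    *,
    n_train_per_class: int = 20,
    n_test_per_class: int = 6,
    image_size: int = 64,
    k: int = DEFAULT_K,
    percentile: float = DEFAULT_PERCENTILE,
    epsilon: float = DEFAULT_EPSILON,
    augset: AugmentationSet | None = None,
    collect_decisions: bool = False,
):
    """Evaluate every method on every ordered (source, target) domain pair.

    For each pair the adapter and the OOD filter are fitted on the source
    domain and evaluated on the target domain. Returns a long-format score
    table (seed, source, target, method, metric, value); with
    ``collect_decisions=True`` also returns the tidy per-sample normalized
    distance log of the fitted filter on target TTA images.
    """
    if len(domains) < 2:
        raise InvalidArgumentError("need at least 2 domains")
    for m in methods:
        parse_method(m)
    if adapter_factory is None:
        adapter_factory = make_toy_adapter
    if augset is None:
        augset = build_default_augmentations(image_size)

    score_rows: list[dict] = []
    decision_rows: list[dict] = []
    for seed in seeds:
        for source, target in itertools.permutations(domains, 2):
            train = generate_dataset(n_train_per_class, source, image_size, seed=seed)
            # distinct seed offset so test cells differ from training cells
            test = generate_dataset(
                n_test_per_class, target, image_size, seed=seed + 10_000
            )
            adapter = adapter_factory(train)
            train_feats = extract_layer_features(adapter, train.images)
            model = fit_foods(train_feats, k=k, percentile=percentile, epsilon=epsilon)

            per_image: list[tuple[list[FilterDecision], np.ndarray]] = []
            for img_idx, img in enumerate(test.images):
                versions = apply_tta(img, augset)
                feats = extract_layer_features(adapter, versions)
                decisions = filter_and_weight(model, feats)
                probs = batch_probabilities(adapter, versions)
                per_image.append((decisions, probs))
                if collect_decisions:
                    for d in decisions:
                        for tag, nd in d.per_layer_normalized.items():
                            decision_rows.append(
                                {
                                    "seed": seed,
                                    "source": source.name,
                                    "target": target.name,
                                    "image_index": img_idx,
                                    "sample_index": d.sample_index,
                                    "tag": tag,
                                    "normalized_distance": nd,
                                    "retained": d.retained,
                                }
                            )

            for method in methods:
                y_pred = _labels_for_method(method, per_image, epsilon)
                report = weighted_metrics(
                    test.labels, y_pred, n_classes=adapter.n_classes
                )
                for metric, value in report.as_dict().items():
                    score_rows.append(
                        {
                            "seed": seed,
                            "source": source.name,
                            "target": target.name,
                            "method": method,
                            "metric": metric,
                            "value": value,
                        }
                    )
    scores = pd.DataFrame.from_records(score_rows)
    if collect_decisions:
        return scores, pd.DataFrame.from_records(decision_rows)
    return scores


# ---------------------------------------------------------------------------
# Ablation grid


@dataclass
class AblationCell:
    """One ablation configuration compared pairwise against the baseline."""

    method: str
    use_foods: bool
    voting: str
    weights: str
    baseline_scores: np.ndarray
    method_scores: np.ndarray
    mean_diff: float
    p_value: float

    def __post_init__(self) -> None:
        if self.baseline_scores.shape != self.method_scores.shape \
                or self.baseline_scores.size < 1:
            raise InvalidArgumentError("scores must be paired and non-empty")


def ablation_grid(scores: pd.DataFrame) -> list[AblationCell]:
    """Build the 8-cell grid of paired comparisons against the baseline.

    Pairs are formed over every (seed, source, target, metric) combination;
    the mean paired difference and the two-sided signed-rank p-value are
    reported per variant.
    """
    keys = ["seed", "source", "target", "metric"]
    present = set(scores["method"].unique())
    missing = set(ALL_METHODS) - present
    if missing:
        raise InvalidArgumentError(f"score table missing methods: {sorted(missing)}")
    base = scores[scores["method"] == "baseline"].set_index(keys)["value"]
    cells: list[AblationCell] = []
    for method in VARIANT_METHODS:
        spec = parse_method(method)
        var = scores[scores["method"] == method].set_index(keys)["value"]
        joined = pd.concat({"baseline": base, "method": var}, axis=1).dropna()
        diffs = (joined["method"] - joined["baseline"]).to_numpy()
        wil = wilcoxon_signed_rank(diffs)
        cells.append(
            AblationCell(
                method=method,
                use_foods=spec["use_foods"],
                voting=spec["voting"],
                weights=spec["weights"],
                baseline_scores=joined["baseline"].to_numpy(),
                method_scores=joined["method"].to_numpy(),
                mean_diff=float(diffs.mean()),
                p_value=wil.p_value,
            )
        )
    return cells


def ablation_table(cells: Sequence[AblationCell]) -> pd.DataFrame:
    """Flatten ablation cells into a display table (one row per variant)."""
    return pd.DataFrame.from_records(
        [
            {
                "method": c.method,
                "foods": c.use_foods,
                "voting": c.voting,
                "weights": c.weights,
                "diff": c.mean_diff,
                "p_value": c.p_value,
            }
            for c in cells
        ]
    )


# ---------------------------------------------------------------------------
# Distance-distribution export


def export_distance_distributions(
    decision_log: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy records plus a five-number summary per (domain, layer, retained).

    The summary quartiles use linear-interpolation order statistics on the
    threshold-normalized distances.
    """
    if decision_log is None or len(decision_log) == 0:
        raise InvalidArgumentError("decision log must be non-empty")
    domain_col = "target" if "target" in decision_log.columns else "domain"
    tidy = decision_log.copy()
    if "sample_index" in tidy.columns:
        # the original (index 0) is force-retained regardless of distance and
        # is not an augmented sample; the distributions describe TTA images
        tidy = tidy[tidy["sample_index"] > 0].reset_index(drop=True)
    groups = []
    for (dom, tag, kept), g in tidy.groupby([domain_col, "tag", "retained"]):
        vals = g["normalized_distance"].to_numpy()
        finite = vals[np.isfinite(vals)]
        if finite.size == 0:
            finite = np.array([np.nan])
        groups.append(
            {
                domain_col: dom,
                "tag": tag,
                "retained": kept,
                "count": int(vals.size),
                "min": float(np.min(finite)),
                "q1": float(np.percentile(finite, 25)),
                "median": float(np.percentile(finite, 50)),
                "q3": float(np.percentile(finite, 75)),
                "max": float(np.max(finite)),
            }
        )
    return tidy, pd.DataFrame.from_records(groups)
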