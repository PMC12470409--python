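"""k-NN feature-space OOD filtering and inverse-distance weighting.

Fitting: for each layer, every training sample's average Euclidean distance
to its k nearest training neighbours (self excluded) is computed, and a
high percentile (default 95) of those distances becomes that layer's
threshold tau.

Test time: a sample is retained only if its average k-NN distance is at or
below tau on *all* layers; retained samples get a weight inversely
proportional to their mean threshold-normalized distance, discarded samples
get weight 0. The original (index 0) image is never filtered.

Neighbour search is exact (full sort) for bit-reproducibility.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .errors import DataError, FitError, InvalidArgumentError
from .features import LAYER_TAGS, LayerFeatureMatrix

__all__ = [
    "LayerFeatureIndex",
    "FoodsModel",
    "FilterDecision",
    "avg_knn_distance",
    "fit_foods",
    "filter_and_weight",
    "normalized_distance_table",
    "DEFAULT_K",
    "DEFAULT_PERCENTILE",
    "DEFAULT_EPSILON",
]

DEFAULT_K = 5
DEFAULT_PERCENTILE = 95.0
DEFAULT_EPSILON = 1e-3


@dataclass
class LayerFeatureIndex:
    """Per-layer OOD state: training features, k, and the distance threshold."""

    tag: str
    train_matrix: np.ndarray
    k: int
    tau: float

    def __post_init__(self) -> None:
        self.train_matrix = np.asarray(self.train_matrix, dtype=np.float64)
        if self.train_matrix.ndim != 2:
            raise InvalidArgumentError(
                f"layer {self.tag!r}: train matrix must be 2-D, got shape "
                f"{self.train_matrix.shape}"
            )
        n = self.train_matrix.shape[0]
        if not (1 <= self.k <= n - 1):
            raise InvalidArgumentError(
                f"layer {self.tag!r}: k={self.k} must be in [1, n_train-1]={n - 1}"
            )
        if not np.isfinite(self.tau) and self.tau != np.inf:
            raise InvalidArgumentError(f"layer {self.tag!r}: tau must be ≥ 0 or +inf")
        if self.tau < 0:
            raise InvalidArgumentError(f"layer {self.tag!r}: tau must be ≥ 0")

    @property
    def n_train(self) -> int:
        return self.train_matrix.shape[0]


def avg_knn_distance(
    index: LayerFeatureIndex, query: np.ndarray, exclude_self: bool = False
) -> float:
    """Mean Euclidean distance from *query* to its k nearest training rows.

    With ``exclude_self=True`` the query must be one of the training rows and
    its own row (the first exactly matching one) is excluded from the
    neighbour pool. Neighbour ties share equal distances, so they cannot
    affect the mean.
    """
    query = np.asarray(query, dtype=np.float64).ravel()
    if query.shape[0] != index.train_matrix.shape[1]:
        raise InvalidArgumentError(
            f"query length {query.shape[0]} != feature dimension "
            f"{index.train_matrix.shape[1]}"
        )
    dists = np.linalg.norm(index.train_matrix - query[None, :], axis=1)
    if exclude_self:
        matches = np.flatnonzero(np.all(index.train_matrix == query[None, :], axis=1))
        if matches.size == 0:
            raise InvalidArgumentError(
                "exclude_self=True but the query is not a training row"
            )
        dists = np.delete(dists, matches[0])
    if index.k > dists.shape[0]:
        raise InvalidArgumentError(
            f"k={index.k} exceeds available neighbours ({dists.shape[0]})"
        )
    dists.sort()
    return float(dists[: index.k].mean())


def _train_self_distances(matrix: np.ndarray, k: int) -> np.ndarray:
    """Average self-excluded k-NN distance for every training row."""
    d = cdist(matrix, matrix)
    np.fill_diagonal(d, np.inf)
    d.sort(axis=1)
    return d[:, :k].mean(axis=1)


@dataclass
class FoodsModel:
    """Full filter state: one fitted index per layer plus shared settings."""

    indices: dict[str, LayerFeatureIndex]
    percentile: float = DEFAULT_PERCENTILE
    epsilon: float = DEFAULT_EPSILON

    def __post_init__(self) -> None:
        if set(self.indices) != set(LAYER_TAGS):
            raise InvalidArgumentError(
                f"expected exactly the layer tags {LAYER_TAGS}, got "
                f"{sorted(self.indices)}"
            )
        ks = {ix.k for ix in self.indices.values()}
        if len(ks) != 1:
            raise InvalidArgumentError(f"all layers must share k, got {sorted(ks)}")
        if not (0 < self.percentile <= 100):
            raise InvalidArgumentError("percentile must be in (0, 100]")
        if self.epsilon <= 0:
            raise InvalidArgumentError("epsilon must be > 0")

    @property
    def k(self) -> int:
        return next(iter(self.indices.values())).k

    @property
    def tags(self) -> tuple[str, ...]:
        return tuple(t for t in LAYER_TAGS if t in self.indices)

    def save(self, path: str | Path) -> None:
        """Serialize to a single ``.npz`` (arrays + JSON header)."""
        path = Path(path)
        header = {
            "percentile": self.percentile,
            "epsilon": self.epsilon,
            "k": self.k,
            "tau": {t: self.indices[t].tau for t in self.tags},
            "tags": list(self.tags),
        }
        arrays = {f"train_{t}": self.indices[t].train_matrix for t in self.tags}
        np.savez(path, header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "FoodsModel":
        with np.load(Path(path)) as data:
            header = json.loads(bytes(data["header"]).decode())
            indices = {
                t: LayerFeatureIndex(
                    tag=t,
                    train_matrix=data[f"train_{t}"],
                    k=int(header["k"]),
                    tau=float(header["tau"][t]),
                )
                for t in header["tags"]
            }
        return cls(indices=indices, percentile=float(header["percentile"]),
                   epsilon=float(header["epsilon"]))


def fit_foods(
    train_features: Mapping[str, LayerFeatureMatrix],
    k: int = DEFAULT_K,
    percentile: float = DEFAULT_PERCENTILE,
    epsilon: float = DEFAULT_EPSILON,
) -> FoodsModel:
    """Fit the per-layer indices and thresholds on training features.

    tau per layer is the linear-interpolation percentile of the training
    rows' self-excluded average k-NN distances.
    """
    if set(train_features) != set(LAYER_TAGS):
        raise InvalidArgumentError(
            f"train_features must contain exactly the tags {LAYER_TAGS}, got "
            f"{sorted(train_features)}"
        )
    sizes = {t: m.n_samples for t, m in train_features.items()}
    if len(set(sizes.values())) != 1:
        raise InvalidArgumentError(f"layers disagree on sample count: {sizes}")
    ids = {m.sample_ids for m in train_features.values()}
    if len(ids) != 1:
        raise InvalidArgumentError("layers disagree on sample order (sample_ids differ)")
    indices: dict[str, LayerFeatureIndex] = {}
    for tag, lfm in train_features.items():
        n = lfm.n_samples
        if n <= k:
            raise FitError(
                f"layer {tag!r}: need at least k+1={k + 1} training samples, got {n}"
            )
        self_d = _train_self_distances(lfm.matrix, k)
        tau = float(np.percentile(self_d, percentile))
        indices[tag] = LayerFeatureIndex(tag=tag, train_matrix=lfm.matrix, k=k, tau=tau)
    return FoodsModel(indices=indices, percentile=float(percentile), epsilon=epsilon)


@dataclass
class FilterDecision:
    """Per-sample outcome: distances, retention flag and fusion weight."""

    sample_index: int
    per_layer_distance: dict[str, float]
    per_layer_normalized: dict[str, float]
    retained: bool
    weight: float

    @property
    def mean_normalized(self) -> float:
        return float(np.mean(list(self.per_layer_normalized.values())))


def _normalize(d: float, tau: float) -> float:
    # tau = 0 means the layer collapsed to duplicates: only exact matches
    # count as in-distribution.
    if tau == 0.0:
        return 0.0 if d == 0.0 else np.inf
    return d / tau


def unfiltered_weight(decision: FilterDecision, epsilon: float) -> float:
    """Inverse-distance weight ignoring the retention flag (ablation use)."""
    dbar = decision.mean_normalized
    if not np.isfinite(dbar):
        return epsilon
    return 1.0 / max(dbar, epsilon)


def filter_and_weight(
    model: FoodsModel,
    tta_features: Mapping[str, LayerFeatureMatrix],
) -> list[FilterDecision]:
    """Decide retention and weight for every row of a TTA feature batch.

    Row 0 is the original image and is always retained. A row is retained
    iff its average k-NN distance is ≤ tau on every layer; retained rows
    get weight 1 / max(mean normalized distance, epsilon), discarded rows
    get weight 0.
    """
    if set(tta_features) != set(model.indices):
        raise InvalidArgumentError(
            f"feature tags {sorted(tta_features)} do not match fitted tags "
            f"{sorted(model.indices)}"
        )
    counts = {t: m.n_samples for t, m in tta_features.items()}
    if len(set(counts.values())) != 1:
        raise InvalidArgumentError(f"layers disagree on row count: {counts}")
    n = next(iter(counts.values()))

    # Exact distances per layer for all rows at once.
    per_layer: dict[str, np.ndarray] = {}
    for tag, lfm in tta_features.items():
        ix = model.indices[tag]
        if lfm.n_features != ix.train_matrix.shape[1]:
            raise InvalidArgumentError(
                f"layer {tag!r}: query dimension {lfm.n_features} != trained "
                f"dimension {ix.train_matrix.shape[1]}"
            )
        d = cdist(lfm.matrix, ix.train_matrix)
        d.sort(axis=1)
        per_layer[tag] = d[:, : ix.k].mean(axis=1)

    decisions: list[FilterDecision] = []
    for i in range(n):
        dist = {t: float(per_layer[t][i]) for t in model.tags}
        norm = {t: _normalize(dist[t], model.indices[t].tau) for t in model.tags}
        within = all(dist[t] <= model.indices[t].tau for t in model.tags)
        retained = within or i == 0
        if retained:
            dbar = float(np.mean(list(norm.values())))
            # dbar can be inf only for the force-retained original under a
            # collapsed (tau=0) layer; fall back to the smallest weight.
            weight = 1.0 / max(dbar, model.epsilon) if np.isfinite(dbar) else model.epsilon
        else:
            weight = 0.0
        decisions.append(
            FilterDecision(
                sample_index=i,
                per_layer_distance=dist,
                per_layer_normalized=norm,
                retained=retained,
                weight=weight,
            )
        )
    return decisions


def normalized_distance_table(decisions: Sequence[FilterDecision]):
    """Tidy records (sample_index, tag, normalized_distance, retained).

    Returns a pandas DataFrame with one row per (sample, layer).
    """
    import pandas as pd

    if len(decisions) == 0:
        raise InvalidArgumentError("decisions must be non-empty")
    records = [
        {
            "sample_index": d.sample_index,
            "tag": tag,
            "normalized_distance": d.per_layer_normalized[tag],
            "retained": d.retained,
        }
        for d in decisions
        for tag in d.per_layer_normalized
    ]
    return pd.DataFrame.from_records(records)
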