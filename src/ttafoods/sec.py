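"""Weighted soft-vote fusion of per-sample class probabilities.

The fused vector is sum_i w_i * p_i divided by the total number of test-time
versions |M| (not by the weight sum), and the label is its argmax with ties
broken toward the lowest class index. Neither the division nor any positive
rescaling of the weights can change the label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .augment import AugmentationSet, apply_tta
from .errors import InvalidArgumentError
from .features import ClassifierAdapter, batch_probabilities, extract_layer_features
from .foods import FilterDecision, FoodsModel, filter_and_weight

__all__ = ["SecPrediction", "sec_fuse", "predict_pipeline"]


@dataclass
class SecPrediction:
    """Fusion output: accumulated probability vector and the final label."""

    fused: np.ndarray
    label: int
    n_contributing: int
    weights_used: np.ndarray
    decisions: list[FilterDecision] | None = None

    @property
    def normalized(self) -> np.ndarray:
        """Display-only copy of ``fused`` rescaled to sum to 1."""
        total = self.fused.sum()
        return self.fused / total if total > 0 else self.fused.copy()


def sec_fuse(
    probabilities: np.ndarray,
    weights: np.ndarray,
    n_versions: int | None = None,
) -> SecPrediction:
    """Fuse row-stochastic probability rows with non-negative weights.

    ``n_versions`` is the |M| divisor; it defaults to the number of rows and
    lets callers that pre-drop zero-weight rows keep the original divisor.
    """
    probabilities = np.asarray(probabilities, dtype=np.float64)
    weights = np.asarray(weights, dtype=np.float64)
    if probabilities.ndim != 2:
        raise InvalidArgumentError(
            f"probabilities must be 2-D, got shape {probabilities.shape}"
        )
    if weights.ndim != 1 or weights.shape[0] != probabilities.shape[0]:
        raise InvalidArgumentError(
            f"weights shape {weights.shape} does not match "
            f"{probabilities.shape[0]} probability rows"
        )
    if probabilities.shape[0] < 1:
        raise InvalidArgumentError("need at least one probability row")
    if np.any(weights < 0):
        raise InvalidArgumentError("weights must be non-negative")
    if not np.any(weights > 0):
        raise InvalidArgumentError(
            "all weights are zero; apply the original-only fallback before fusing"
        )
    if np.any(probabilities < 0) or np.any(
        np.abs(probabilities.sum(axis=1) - 1.0) > 1e-6
    ):
        raise InvalidArgumentError("probability rows must each sum to 1 and be ≥ 0")
    if n_versions is None:
        n_versions = probabilities.shape[0]
    fused = (weights[:, None] * probabilities).sum(axis=0) / n_versions
    label = int(np.argmax(fused))  # np.argmax returns the lowest tied index
    return SecPrediction(
        fused=fused,
        label=label,
        n_contributing=int(np.count_nonzero(weights)),
        weights_used=weights.copy(),
    )


def predict_pipeline(
    adapter: ClassifierAdapter,
    model: FoodsModel,
    augset: AugmentationSet,
    image: np.ndarray,
    use_filter: bool = True,
    uniform_weights: bool = False,
) -> SecPrediction:
    """Full inference: TTA → feature extraction → filter/weight → fusion.

    ``use_filter=False`` retains every augmented sample; ``uniform_weights``
    replaces the inverse-distance weights of retained samples with 1. With an
    empty augmentation set the result reduces to the adapter's own
    prediction. If every augmented sample is discarded, the original alone
    determines the output (it is never filtered).
    """
    versions = apply_tta(image, augset)
    feats = extract_layer_features(adapter, versions, tags=model.tags)
    decisions = filter_and_weight(model, feats)

    weights = np.array([d.weight for d in decisions], dtype=np.float64)
    if not use_filter:
        from .foods import unfiltered_weight

        weights = np.array(
            [unfiltered_weight(d, model.epsilon) for d in decisions], dtype=np.float64
        )
    if uniform_weights:
        weights = (weights > 0).astype(np.float64)

    contributing = np.flatnonzero(weights > 0)
    probs = batch_probabilities(adapter, [versions[i] for i in contributing])
    pred = sec_fuse(probs, weights[contributing], n_versions=len(versions))

    full_weights = np.zeros(len(versions))
    full_weights[contributing] = weights[contributing]
    pred.weights_used = full_weights
    pred.decisions = decisions
    return pred
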