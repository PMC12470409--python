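"""Classifier-adapter contract and multi-layer feature extraction.

An adapter wraps any classifier that can expose (a) class probabilities and
(b) three tagged intermediate representations — "low", "mid" and "high".
The OOD filter consumes per-layer feature matrices built here.
"""

from __future__ import annotations

import abc
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import DataError, InvalidArgumentError

__all__ = [
    "LAYER_TAGS",
    "ClassifierAdapter",
    "LayerFeatureMatrix",
    "global_average_pool",
    "extract_layer_features",
    "batch_probabilities",
]

#: Canonical ordered layer tags every adapter must expose.
LAYER_TAGS: tuple[str, str, str] = ("low", "mid", "high")


class ClassifierAdapter(abc.ABC):
    """Contract for a classifier usable by the filtering/fusion pipeline.

    Implementations must be deterministic at inference time: the same image
    must always yield the same probabilities and the same features.
    """

    layer_tags: tuple[str, ...] = LAYER_TAGS

    @property
    @abc.abstractmethod
    def n_classes(self) -> int:
        """Number of output classes."""

    @abc.abstractmethod
    def probabilities(self, image: np.ndarray) -> np.ndarray:
        """Class-probability vector of length ``n_classes`` (sums to 1)."""

    @abc.abstractmethod
    def features(self, image: np.ndarray) -> Mapping[str, np.ndarray]:
        """Mapping layer tag → feature array (vector or spatial map)."""


@dataclass
class LayerFeatureMatrix:
    """Feature matrix for one layer: one row per sample, rows ID-aligned."""

    tag: str
    matrix: np.ndarray
    sample_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise InvalidArgumentError(
                f"layer {self.tag!r}: expected a 2-D matrix, got shape {self.matrix.shape}"
            )
        if not self.sample_ids:
            self.sample_ids = tuple(str(i) for i in range(self.matrix.shape[0]))
        if len(self.sample_ids) != self.matrix.shape[0]:
            raise InvalidArgumentError(
                f"layer {self.tag!r}: {len(self.sample_ids)} sample ids for "
                f"{self.matrix.shape[0]} rows"
            )
        if not np.all(np.isfinite(self.matrix)):
            bad = int(np.flatnonzero(~np.isfinite(self.matrix).all(axis=1))[0])
            raise DataError(
                f"layer {self.tag!r}: non-finite feature values in row "
                f"{bad} (sample {self.sample_ids[bad]!r})"
            )

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]


def global_average_pool(feature: np.ndarray) -> np.ndarray:
    """Reduce a spatial feature map to a vector.

    1-D inputs pass through unchanged; for N-D inputs the last axis is
    treated as channels and all leading (spatial) axes are averaged out.
    """
    feature = np.asarray(feature, dtype=np.float64)
    if feature.ndim <= 1:
        return feature.ravel()
    return feature.reshape(-1, feature.shape[-1]).mean(axis=0)


def extract_layer_features(
    adapter: ClassifierAdapter,
    images: Sequence[np.ndarray],
    tags: Sequence[str] | None = None,
    sample_ids: Sequence[str] | None = None,
) -> dict[str, LayerFeatureMatrix]:
    """Extract pooled feature vectors per layer for a list of images.

    Returns one :class:`LayerFeatureMatrix` per tag with one row per image,
    image order preserved. Spatial feature maps are reduced to vectors by
    global average pooling.
    """
    if len(images) == 0:
        raise InvalidArgumentError("images must be non-empty")
    if tags is None:
        tags = adapter.layer_tags
    unknown = set(tags) - set(adapter.layer_tags)
    if unknown:
        raise InvalidArgumentError(
            f"tags {sorted(unknown)} not exposed by adapter (has {adapter.layer_tags})"
        )
    if sample_ids is None:
        sample_ids = tuple(str(i) for i in range(len(images)))
    rows: dict[str, list[np.ndarray]] = {t: [] for t in tags}
    for i, image in enumerate(images):
        feats = adapter.features(image)
        for t in tags:
            vec = global_average_pool(feats[t])
            if not np.all(np.isfinite(vec)):
                raise DataError(
                    f"adapter returned non-finite {t!r} features for image "
                    f"{sample_ids[i]!r}"
                )
            rows[t].append(vec)
    return {
        t: LayerFeatureMatrix(tag=t, matrix=np.vstack(rows[t]), sample_ids=tuple(sample_ids))
        for t in tags
    }


def batch_probabilities(
    adapter: ClassifierAdapter, images: Sequence[np.ndarray]
) -> np.ndarray:
    """Stack adapter class probabilities into an ``n_images × n_classes`` matrix."""
    if len(images) == 0:
        raise InvalidArgumentError("images must be non-empty")
    rows = []
    for i, image in enumerate(images):
        p = np.asarray(adapter.probabilities(image), dtype=np.float64)
        if not np.all(np.isfinite(p)):
            raise DataError(f"adapter returned non-finite probabilities for image {i}")
        if p.ndim != 1 or p.shape[0] != adapter.n_classes:
            raise DataError(
                f"adapter returned probability vector of shape {p.shape} for image {i}; "
                f"expected ({adapter.n_classes},)"
            )
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-6:
            raise DataError(
                f"adapter probabilities for image {i} are not a distribution "
                f"(sum={p.sum():.8f})"
            )
        rows.append(p)
    return np.vstack(rows)
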