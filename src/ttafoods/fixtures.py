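"""Synthetic 5-class cell-like image generator and a deterministic toy classifier.

The five class recipes (round nucleus, tri-lobed nucleus, kidney-shaped
nucleus, bi-lobed with pale granules, dense dark granules) are non-biological
stand-ins chosen only to be visually separable. Acquisition-domain shift is
emulated by a fixed corruption chain applied after rendering:

    background tint → hue shift → brightness gain → Gaussian blur → noise

with clipping to [0, 1] after each step that can leave the range. Everything
is a pure function of (parameters, seed): same inputs, bit-identical images.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage
from skimage import color as skcolor
from skimage import transform as sktransform

from .errors import FitError, InvalidArgumentError
from .features import LAYER_TAGS, ClassifierAdapter

__all__ = [
    "DomainSpec",
    "SyntheticDataset",
    "CLASS_NAMES",
    "DOMAINS",
    "generate_dataset",
    "apply_domain",
    "ToyAdapter",
    "make_toy_adapter",
]

#: Class names, lexicographically sorted so that sorted-directory loading
#: reproduces the label indices.
CLASS_NAMES: tuple[str, ...] = (
    "a_round",
    "b_trilobed",
    "c_kidney",
    "d_granular",
    "e_dense",
)


@dataclass(frozen=True)
class DomainSpec:
    """Acquisition-domain parameters; the defaults are the identity domain."""

    name: str = "identity"
    hue_shift: float = 0.0  # degrees on the color wheel
    brightness_gain: float = 1.0
    blur_sigma: float = 0.0  # pixels
    background_tint: tuple[float, float, float] = (1.0, 1.0, 1.0)
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.brightness_gain <= 0:
            raise InvalidArgumentError("brightness_gain must be > 0")
        if self.blur_sigma < 0:
            raise InvalidArgumentError("blur_sigma must be ≥ 0")
        if self.noise_sd < 0:
            raise InvalidArgumentError("noise_sd must be ≥ 0")


#: Named domains used by the CLI and the cross-domain benchmark.
DOMAINS: dict[str, DomainSpec] = {
    "identity": DomainSpec(),
    "stain_shift": DomainSpec(
        name="stain_shift", hue_shift=5.0, background_tint=(0.99, 0.97, 1.0)
    ),
    "bright_blur": DomainSpec(name="bright_blur", brightness_gain=1.07, blur_sigma=0.5),
    "noisy_dark": DomainSpec(
        name="noisy_dark",
        brightness_gain=0.96,
        noise_sd=0.008,
        background_tint=(1.0, 0.99, 0.98),
    ),
}


@dataclass
class SyntheticDataset:
    """A rendered dataset: images in [0,1], integer labels 0..4."""

    images: list[np.ndarray]
    labels: np.ndarray
    domain: str
    seed: int
    class_names: tuple[str, ...] = CLASS_NAMES

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.images) != len(self.labels):
            raise InvalidArgumentError("images and labels must align")

    def __len__(self) -> int:
        return len(self.images)


# ---------------------------------------------------------------------------
# Rendering


def _disk(yy: np.ndarray, xx: np.ndarray, cy: float, cx: float, ry: float,
          rx: float, angle: float = 0.0) -> np.ndarray:
    """Soft-edged elliptical mask on the [-1, 1]² grid."""
    ca, sa = np.cos(angle), np.sin(angle)
    u = (xx - cx) * ca + (yy - cy) * sa
    v = -(xx - cx) * sa + (yy - cy) * ca
    r = (u / rx) ** 2 + (v / ry) ** 2
    return np.clip(1.5 - 1.5 * r, 0.0, 1.0) ** 0.7


def _paint(img: np.ndarray, mask: np.ndarray, rgb: Sequence[float]) -> None:
    for c in range(3):
        img[..., c] = img[..., c] * (1 - mask) + rgb[c] * mask


def _render_cell(class_idx: int, size: int, rng: np.random.Generator) -> np.ndarray:
    """Render one clean (identity-domain) cell image."""
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    yy = yy / (size - 1) * 2 - 1
    xx = xx / (size - 1) * 2 - 1

    img = np.full((size, size, 3), rng.uniform(0.88, 0.96))
    cy, cx = rng.uniform(-0.12, 0.12, size=2)
    scale = rng.uniform(0.8, 1.2)
    theta = rng.uniform(0, 2 * np.pi)

    cyto_rgb = np.array((0.82, 0.76, 0.88)) + rng.uniform(-0.05, 0.05, size=3)
    nuc_rgb = np.array((0.42, 0.28, 0.58)) + rng.uniform(-0.06, 0.06, size=3)

    # cytoplasm body shared by all recipes
    _paint(img, _disk(yy, xx, cy, cx, 0.72 * scale, 0.68 * scale, theta), cyto_rgb)

    if class_idx == 0:  # single large round nucleus
        _paint(img, _disk(yy, xx, cy, cx, 0.48 * scale, 0.46 * scale, theta), nuc_rgb)
    elif class_idx == 1:  # three small lobes
        for j in range(3):
            a = theta + j * 2 * np.pi / 3
            _paint(
                img,
                _disk(yy, xx, cy + 0.26 * scale * np.sin(a),
                      cx + 0.26 * scale * np.cos(a), 0.2 * scale, 0.17 * scale, a),
                nuc_rgb,
            )
    elif class_idx == 2:  # kidney: large ellipse with a bite taken out
        body = _disk(yy, xx, cy, cx, 0.52 * scale, 0.5 * scale, theta)
        bite = _disk(yy, xx, cy + 0.3 * scale * np.sin(theta),
                     cx + 0.3 * scale * np.cos(theta), 0.3 * scale, 0.3 * scale, 0.0)
        _paint(img, np.clip(body - bite, 0.0, 1.0), nuc_rgb)
    elif class_idx == 3:  # two lobes plus pale reddish granules
        for j in range(2):
            a = theta + j * np.pi
            _paint(
                img,
                _disk(yy, xx, cy + 0.2 * scale * np.sin(a),
                      cx + 0.2 * scale * np.cos(a), 0.26 * scale, 0.2 * scale, a),
                nuc_rgb,
            )
        for _ in range(35):
            gy, gx = rng.uniform(-0.55, 0.55, size=2)
            _paint(img, _disk(yy, xx, cy + gy * scale, cx + gx * scale,
                              0.045, 0.045), (0.85, 0.45, 0.45))
    else:  # class 4: medium nucleus buried under dense dark granules
        _paint(img, _disk(yy, xx, cy, cx, 0.4 * scale, 0.38 * scale, theta), nuc_rgb)
        for _ in range(60):
            gy, gx = rng.uniform(-0.5, 0.5, size=2)
            _paint(img, _disk(yy, xx, cy + gy * scale, cx + gx * scale,
                              0.05, 0.05), (0.22, 0.16, 0.4))
    return np.clip(img, 0.0, 1.0)


def apply_domain(
    image: np.ndarray,
    domain: DomainSpec,
    rng: np.random.Generator | None = None,
    clip: bool = True,
) -> np.ndarray:
    """Apply the corruption chain tint → hue → brightness → blur → noise.

    ``clip=False`` skips range clipping (used to verify the multiplicative
    steps on the raw render); noise requires ``rng`` when noise_sd > 0.
    """
    out = np.asarray(image, dtype=np.float64).copy()
    tint = np.asarray(domain.background_tint, dtype=np.float64)
    out = out * tint[None, None, :]
    if clip:
        out = np.clip(out, 0.0, 1.0)
    if domain.hue_shift != 0.0:
        hsv = skcolor.rgb2hsv(np.clip(out, 0.0, 1.0))
        hsv[..., 0] = np.mod(hsv[..., 0] + domain.hue_shift / 360.0, 1.0)
        out = skcolor.hsv2rgb(hsv)
    out = out * domain.brightness_gain
    if clip:
        out = np.clip(out, 0.0, 1.0)
    if domain.blur_sigma > 0:
        out = ndimage.gaussian_filter(
            out, sigma=(domain.blur_sigma, domain.blur_sigma, 0.0)
        )
    if domain.noise_sd > 0:
        if rng is None:
            raise InvalidArgumentError("noise_sd > 0 requires an rng")
        out = out + rng.normal(0.0, domain.noise_sd, size=out.shape)
        if clip:
            out = np.clip(out, 0.0, 1.0)
    return out


def generate_dataset(
    n_per_class: int,
    domain: DomainSpec,
    image_size: int = 64,
    seed: int = 0,
) -> SyntheticDataset:
    """Render ``5 * n_per_class`` images under the given domain.

    Per-image randomness is derived from ``(seed, class, index)`` so the
    clean render of image j of class c is identical across domains for the
    same seed — domains differ only by the corruption chain.
    """
    if n_per_class < 1:
        raise InvalidArgumentError("n_per_class must be ≥ 1")
    if image_size < 32:
        raise InvalidArgumentError("image_size must be ≥ 32")
    images: list[np.ndarray] = []
    labels: list[int] = []
    for c in range(len(CLASS_NAMES)):
        for j in range(n_per_class):
            render_rng = np.random.default_rng([seed, c, j, 0])
            noise_rng = np.random.default_rng([seed, c, j, 1])
            clean = _render_cell(c, image_size, render_rng)
            images.append(apply_domain(clean, domain, rng=noise_rng))
            labels.append(c)
    return SyntheticDataset(
        images=images, labels=np.asarray(labels), domain=domain.name, seed=seed
    )


# ---------------------------------------------------------------------------
# Toy classifier adapter


def _gray(image: np.ndarray) -> np.ndarray:
    return image @ np.array([0.2125, 0.7154, 0.0721])


class ToyAdapter(ClassifierAdapter):
    """Nearest-centroid classifier over hand-crafted multi-scale features.

    Layers: "low" = 8×8 downsampled grayscale flatten (64-d), "mid" =
    per-channel 16-bin histograms (48-d), "high" = 10 shape/intensity
    moments of the thresholded foreground. Probabilities are a softmax over
    negative distances to per-class centroids in standardized feature space.
    Fully deterministic.
    """

    layer_tags = LAYER_TAGS

    def __init__(
        self,
        centroids: np.ndarray,
        feat_mean: np.ndarray,
        feat_std: np.ndarray,
        class_names: tuple[str, ...] = CLASS_NAMES,
    ) -> None:
        self.centroids = np.asarray(centroids, dtype=np.float64)
        self.feat_mean = np.asarray(feat_mean, dtype=np.float64)
        self.feat_std = np.asarray(feat_std, dtype=np.float64)
        self.class_names = tuple(class_names)

    @property
    def n_classes(self) -> int:
        return self.centroids.shape[0]

    # -- feature definitions -------------------------------------------------

    @staticmethod
    def _features_low(image: np.ndarray) -> np.ndarray:
        g = _gray(image)
        small = sktransform.resize(
            g, (8, 8), order=1, mode="reflect", anti_aliasing=False,
            preserve_range=True,
        )
        return small.ravel()

    @staticmethod
    def _features_mid(image: np.ndarray) -> np.ndarray:
        hists = []
        for c in range(3):
            h, _ = np.histogram(image[..., c], bins=16, range=(0.0, 1.0))
            hists.append(h / image[..., c].size)
        return np.concatenate(hists)

    @staticmethod
    def _features_high(image: np.ndarray) -> np.ndarray:
        g = _gray(image)
        thr = g.mean() - 0.5 * g.std()
        fg = g < thr  # cells are darker than background
        n = fg.sum()
        if n == 0:
            return np.zeros(10)
        h, w = g.shape
        yy, xx = np.mgrid[0:h, 0:w]
        cy = yy[fg].mean() / h
        cx = xx[fg].mean() / w
        dy = (yy[fg] / h) - cy
        dx = (xx[fg] / w) - cx
        sat = image.max(axis=2) - image.min(axis=2)
        return np.array(
            [
                n / g.size,                # foreground fraction
                cy,
                cx,
                (dy * dy).mean(),          # normalized central moments
                (dx * dx).mean(),
                (dy * dx).mean(),
                g[fg].mean(),
                g[fg].std(),
                g.mean(),
                sat[fg].mean(),
            ]
        )

    def features(self, image: np.ndarray) -> dict[str, np.ndarray]:
        image = np.asarray(image, dtype=np.float64)
        return {
            "low": self._features_low(image),
            "mid": self._features_mid(image),
            "high": self._features_high(image),
        }

    def _concat(self, image: np.ndarray) -> np.ndarray:
        f = self.features(image)
        return np.concatenate([f[t] for t in self.layer_tags])

    def probabilities(self, image: np.ndarray) -> np.ndarray:
        z = (self._concat(image) - self.feat_mean) / self.feat_std
        d = np.linalg.norm(self.centroids - z[None, :], axis=1)
        logits = -d
        logits = logits - logits.max()
        e = np.exp(logits)
        return e / e.sum()


def make_toy_adapter(train: SyntheticDataset) -> ToyAdapter:
    """Fit the nearest-centroid toy adapter on a training dataset."""
    if len(train) == 0:
        raise FitError("training dataset is empty")
    present = set(int(c) for c in np.unique(train.labels))
    wanted = set(range(len(CLASS_NAMES)))
    if present != wanted:
        raise FitError(f"all 5 classes required; missing {sorted(wanted - present)}")
    probe = ToyAdapter(
        centroids=np.zeros((1, 1)), feat_mean=np.zeros(1), feat_std=np.ones(1)
    )
    feats = np.vstack([probe._concat(img) for img in train.images])
    mean = feats.mean(axis=0)
    std = np.maximum(feats.std(axis=0), 1e-8)
    z = (feats - mean) / std
    centroids = np.vstack(
        [z[train.labels == c].mean(axis=0) for c in range(len(CLASS_NAMES))]
    )
    return ToyAdapter(
        centroids=centroids, feat_mean=mean, feat_std=std,
        class_names=train.class_names,
    )
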