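"""Deterministic test-time augmentation.

Every transform is a pure function of its input image: same image in, same
image out, bit for bit. Images are H×W×3 float arrays in [0, 1] and every
transform returns an image of the same shape (crops are resized back,
rotations do not expand).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import ndimage
from skimage import color as skcolor
from skimage import transform as sktransform

from .errors import InvalidArgumentError

__all__ = [
    "AugmentationTransform",
    "AugmentationSet",
    "build_default_augmentations",
    "apply_tta",
    "DEFAULT_CROP_MARGINS",
    "DEFAULT_ROTATION_ANGLES",
]

#: Crop margins (pixels removed per side) for the 7 default center crops:
#: seven integers evenly spread over [5, 20].
DEFAULT_CROP_MARGINS: tuple[int, ...] = (5, 8, 10, 13, 15, 18, 20)

#: Default rotation angles in degrees (positive = counter-clockwise).
DEFAULT_ROTATION_ANGLES: tuple[float, ...] = (5.0, 10.0, 20.0)

#: Default Gaussian blur sigma; truncate=2.0 gives an effective 5×5 kernel.
DEFAULT_BLUR_SIGMA = 1.0

#: Default deterministic color-jitter factors.
DEFAULT_JITTER = {"brightness": 1.1, "contrast": 0.9, "saturation": 1.1, "hue": 0.02}


def _check_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 3 or image.shape[2] != 3:
        raise InvalidArgumentError(
            f"expected an H×W×3 image, got array of shape {image.shape}"
        )
    return image


def _center_crop(image: np.ndarray, margin: int) -> np.ndarray:
    h, w = image.shape[:2]
    if 2 * margin >= min(h, w):
        raise InvalidArgumentError(
            f"crop margin {margin} too large for image of size {h}×{w}"
        )
    cropped = image[margin : h - margin, margin : w - margin]
    out = sktransform.resize(
        cropped, (h, w), order=1, mode="reflect", anti_aliasing=False,
        preserve_range=True,
    )
    return np.clip(out, 0.0, 1.0)


def _hflip(image: np.ndarray) -> np.ndarray:
    return image[:, ::-1].copy()


def _vflip(image: np.ndarray) -> np.ndarray:
    return image[::-1, :].copy()


def _rotate(image: np.ndarray, angle: float) -> np.ndarray:
    out = sktransform.rotate(
        image, angle, resize=False, order=1, mode="reflect", preserve_range=True
    )
    return np.clip(out, 0.0, 1.0)


def _gaussian_blur(image: np.ndarray, sigma: float) -> np.ndarray:
    if sigma <= 0:
        return image.copy()
    out = ndimage.gaussian_filter(image, sigma=(sigma, sigma, 0.0), truncate=2.0)
    return np.clip(out, 0.0, 1.0)


def _color_jitter(
    image: np.ndarray,
    brightness: float = 1.0,
    contrast: float = 1.0,
    saturation: float = 1.0,
    hue: float = 0.0,
) -> np.ndarray:
    out = np.clip(image * brightness, 0.0, 1.0)
    mean = out.mean()
    out = np.clip(mean + (out - mean) * contrast, 0.0, 1.0)
    gray = out @ np.array([0.2125, 0.7154, 0.0721])
    out = np.clip(gray[..., None] + (out - gray[..., None]) * saturation, 0.0, 1.0)
    if hue != 0.0:
        hsv = skcolor.rgb2hsv(out)
        hsv[..., 0] = np.mod(hsv[..., 0] + hue, 1.0)
        out = np.clip(skcolor.hsv2rgb(hsv), 0.0, 1.0)
    return out


_KINDS: Mapping[str, Callable[..., np.ndarray]] = {
    "center_crop": lambda img, margin: _center_crop(img, int(margin)),
    "hflip": lambda img: _hflip(img),
    "vflip": lambda img: _vflip(img),
    "rotate": lambda img, angle: _rotate(img, float(angle)),
    "gaussian_blur": lambda img, sigma: _gaussian_blur(img, float(sigma)),
    "color_jitter": lambda img, **kw: _color_jitter(img, **kw),
}


@dataclass(frozen=True)
class AugmentationTransform:
    """A named, parameterised, deterministic image transform."""

    name: str
    kind: str
    params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise InvalidArgumentError(
                f"unknown transform kind {self.kind!r}; "
                f"expected one of {sorted(_KINDS)}"
            )

    def __call__(self, image: np.ndarray) -> np.ndarray:
        image = _check_image(image)
        return _KINDS[self.kind](image, **dict(self.params))

    def to_config(self) -> dict:
        return {"name": self.name, "kind": self.kind, "params": dict(self.params)}

    @classmethod
    def from_config(cls, cfg: Mapping) -> "AugmentationTransform":
        return cls(name=cfg["name"], kind=cfg["kind"], params=dict(cfg.get("params", {})))


@dataclass(frozen=True)
class AugmentationSet:
    """An ordered collection of uniquely named transforms.

    Order matters: downstream fusion weights are index-aligned with the
    test-time image list this set produces.
    """

    transforms: tuple[AugmentationTransform, ...] = ()

    def __post_init__(self) -> None:
        names = [t.name for t in self.transforms]
        if len(set(names)) != len(names):
            raise InvalidArgumentError(f"duplicate transform names in {names}")
        object.__setattr__(self, "transforms", tuple(self.transforms))

    def __len__(self) -> int:
        return len(self.transforms)

    def __iter__(self):
        return iter(self.transforms)

    def to_config(self) -> list[dict]:
        return [t.to_config() for t in self.transforms]

    @classmethod
    def from_config(cls, cfg: Sequence[Mapping]) -> "AugmentationSet":
        return cls(tuple(AugmentationTransform.from_config(c) for c in cfg))


def build_default_augmentations(input_size: int = 64) -> AugmentationSet:
    """Build the default 14-transform set.

    7 center crops (margins 5..20 px per side, resized back), horizontal and
    vertical flips, rotations by 5/10/20 degrees, one Gaussian blur and one
    deterministic color jitter — in that order.
    """
    if input_size <= 2 * max(DEFAULT_CROP_MARGINS):
        raise InvalidArgumentError(
            f"input_size {input_size} too small for the largest default crop "
            f"margin {max(DEFAULT_CROP_MARGINS)}"
        )
    transforms: list[AugmentationTransform] = []
    for m in DEFAULT_CROP_MARGINS:
        transforms.append(
            AugmentationTransform(f"center_crop_{m}", "center_crop", {"margin": m})
        )
    transforms.append(AugmentationTransform("hflip", "hflip"))
    transforms.append(AugmentationTransform("vflip", "vflip"))
    for a in DEFAULT_ROTATION_ANGLES:
        transforms.append(
            AugmentationTransform(f"rotate_{a:g}", "rotate", {"angle": a})
        )
    transforms.append(
        AugmentationTransform("gaussian_blur", "gaussian_blur", {"sigma": DEFAULT_BLUR_SIGMA})
    )
    transforms.append(
        AugmentationTransform("color_jitter", "color_jitter", dict(DEFAULT_JITTER))
    )
    return AugmentationSet(tuple(transforms))


def apply_tta(image: np.ndarray, augset: AugmentationSet) -> list[np.ndarray]:
    """Return ``[original, t1(image), t2(image), ...]`` in set order.

    The output has length ``len(augset) + 1`` and index 0 is a bit-identical
    copy of the input.
    """
    image = _check_image(image)
    return [image.copy()] + [t(image) for t in augset]
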