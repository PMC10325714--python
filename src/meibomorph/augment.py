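"""Random augmentation policy for gland-segmentation training data.

A policy draws N of the 11 registered transforms (without replacement)
and gives each an integer magnitude M in 1..10.  Geometric transforms
(crop, horizontal flip, cutout, x/y translation, rotation, x-shear) are
applied with identical parameters to the image and its mask — the mask by
nearest neighbour, so it stays binary.  Photometric transforms
(equalization, contrast, brightness, sharpness) touch the image only.
Output dimensions are always preserved; pixels leaving the canvas are
filled with 0 (image) / background (mask).

Each transform maps M linearly onto its documented parameter range, so
M=1 is the smallest nonzero effect and M=10 the full range (e.g. rotation
spans +/-30 degrees: M=10 -> 30 deg, M=1 -> 3 deg).  Where a transform
has a direction (rotation sign, translation sign, darken vs brighten) the
direction is drawn from the seeded generator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from PIL import Image, ImageEnhance
from skimage import exposure, transform

__all__ = [
    "AugmentError",
    "AugPolicy",
    "REGISTRY",
    "GEOMETRIC",
    "PHOTOMETRIC",
    "sample_policy",
    "apply_policy",
    "apply_transform",
]


class AugmentError(ValueError):
    """Raised for invalid policies or unregistered transforms."""


# Per-magnitude-unit parameter scales (the "linear map" constants).
ROTATE_DEG_PER_M = 3.0       # M=10 -> 30 degrees
TRANSLATE_FRAC_PER_M = 0.03  # of the image dimension; M=10 -> 30%
SHEAR_PER_M = 0.03           # shear factor; M=10 -> 0.3
CROP_FRAC_PER_M = 0.02       # margin per side; M=10 -> 20% per side
CUTOUT_FRAC_PER_M = 0.04     # square side vs min(dims); M=10 -> 40%
EQUALIZE_BLEND_PER_M = 0.1   # blend weight towards equalized; M=10 -> 1.0
ENHANCE_PER_M = 0.08         # contrast/brightness factor 1 +/- 0.08*M
SHARPNESS_PER_M = 0.19       # sharpness factor 1 + 0.19*M


def _check_pair(image: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape != mask.shape:
        raise AugmentError("image and mask dims must match")
    return image, mask > 0


def _cast_back(img_float: np.ndarray, dtype) -> np.ndarray:
    if np.issubdtype(dtype, np.integer):
        return np.rint(img_float).astype(dtype)
    return img_float.astype(dtype)


def _warp_pair(image, mask, tform):
    img = transform.warp(
        image.astype(float), tform, order=1, mode="constant", cval=0.0, preserve_range=True
    )
    msk = transform.warp(
        mask.astype(float), tform, order=0, mode="constant", cval=0.0, preserve_range=True
    )
    return _cast_back(img, image.dtype), msk > 0.5


def rotate_pair(image: np.ndarray, mask: np.ndarray, angle_deg: float):
    """Rotate image (bilinear) and mask (nearest) about the center."""
    img = transform.rotate(
        image.astype(float), angle_deg, order=1, mode="constant", cval=0.0, preserve_range=True
    )
    msk = transform.rotate(
        mask.astype(float), angle_deg, order=0, mode="constant", cval=0.0, preserve_range=True
    )
    return _cast_back(img, image.dtype), msk > 0.5


def _op_crop(image, mask, m, rng):
    h, w = image.shape
    mh = int(round(CROP_FRAC_PER_M * m * h))
    mw = int(round(CROP_FRAC_PER_M * m * w))
    out_i = np.zeros_like(image)
    out_m = np.zeros_like(mask)
    if h - 2 * mh > 0 and w - 2 * mw > 0:
        out_i[mh : h - mh, mw : w - mw] = image[mh : h - mh, mw : w - mw]
        out_m[mh : h - mh, mw : w - mw] = mask[mh : h - mh, mw : w - mw]
    return out_i, out_m


def _op_hflip(image, mask, m, rng):
    return np.fliplr(image), np.fliplr(mask)


def _op_cutout(image, mask, m, rng):
    h, w = image.shape
    side = int(round(CUTOUT_FRAC_PER_M * m * min(h, w)))
    r0 = int(rng.integers(0, max(1, h - side)))
    c0 = int(rng.integers(0, max(1, w - side)))
    out_i = image.copy()
    out_m = mask.copy()
    out_i[r0 : r0 + side, c0 : c0 + side] = 0
    out_m[r0 : r0 + side, c0 : c0 + side] = False
    return out_i, out_m


def _shift(arr, dr, dc, fill):
    out = np.full_like(arr, fill)
    h, w = arr.shape
    rs, re = max(0, dr), min(h, h + dr)
    cs, ce = max(0, dc), min(w, w + dc)
    out[rs:re, cs:ce] = arr[rs - dr : re - dr, cs - dc : ce - dc]
    return out


def _op_translate_x(image, mask, m, rng):
    w = image.shape[1]
    d = int(round(TRANSLATE_FRAC_PER_M * m * w)) * (1 if rng.integers(2) else -1)
    return _shift(image, 0, d, 0), _shift(mask, 0, d, False)


def _op_translate_y(image, mask, m, rng):
    h = image.shape[0]
    d = int(round(TRANSLATE_FRAC_PER_M * m * h)) * (1 if rng.integers(2) else -1)
    return _shift(image, d, 0, 0), _shift(mask, d, 0, False)


def _op_rotate(image, mask, m, rng):
    sign = 1.0 if rng.integers(2) else -1.0
    return rotate_pair(image, mask, sign * ROTATE_DEG_PER_M * m)


def _op_shear_x(image, mask, m, rng):
    s = SHEAR_PER_M * m * (1.0 if rng.integers(2) else -1.0)
    h, w = image.shape
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    shear = transform.AffineTransform(matrix=np.array([[1.0, s, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]))
    tform = (
        transform.AffineTransform(translation=-center)
        + shear
        + transform.AffineTransform(translation=center)
    )
    return _warp_pair(image, mask, tform.inverse)


def _op_equalize(image, mask, m, rng):
    eq = exposure.equalize_hist(image) * 255.0
    alpha = EQUALIZE_BLEND_PER_M * m
    out = (1.0 - alpha) * image.astype(float) + alpha * eq
    return np.clip(out, 0, 255).astype(image.dtype), mask


def _enhance(image, enhancer_cls, factor):
    pil = Image.fromarray(image.astype(np.uint8))
    out = enhancer_cls(pil).enhance(factor)
    return np.asarray(out, dtype=image.dtype)


def _op_contrast(image, mask, m, rng):
    f = 1.0 + ENHANCE_PER_M * m
    if not rng.integers(2):
        f = 1.0 / f
    return _enhance(image, ImageEnhance.Contrast, f), mask


def _op_brightness(image, mask, m, rng):
    f = 1.0 + ENHANCE_PER_M * m
    if not rng.integers(2):
        f = 1.0 / f
    return _enhance(image, ImageEnhance.Brightness, f), mask


def _op_sharpness(image, mask, m, rng):
    return _enhance(image, ImageEnhance.Sharpness, 1.0 + SHARPNESS_PER_M * m), mask


GEOMETRIC = ("crop", "horizontal_flip", "cutout", "translate_x", "translate_y", "rotate", "shear_x")
PHOTOMETRIC = ("equalize", "contrast", "brightness", "sharpness")

#: The 11-transform registry: name -> (function, is_geometric).
REGISTRY = {
    "crop": (_op_crop, True),
    "horizontal_flip": (_op_hflip, True),
    "cutout": (_op_cutout, True),
    "translate_x": (_op_translate_x, True),
    "translate_y": (_op_translate_y, True),
    "rotate": (_op_rotate, True),
    "shear_x": (_op_shear_x, True),
    "equalize": (_op_equalize, False),
    "contrast": (_op_contrast, False),
    "brightness": (_op_brightness, False),
    "sharpness": (_op_sharpness, False),
}


@dataclass
class AugPolicy:
    """Ordered list of (transform name, magnitude 1..10) pairs."""

    ops: list[tuple[str, int]]

    def __post_init__(self) -> None:
        for name, m in self.ops:
            if name not in REGISTRY:
                raise AugmentError(f"unregistered transform {name!r}")
            if not 1 <= int(m) <= 10:
                raise AugmentError(f"magnitude {m} outside 1..10")
        self.ops = [(name, int(m)) for name, m in self.ops]

    @property
    def N(self) -> int:
        return len(self.ops)

    def to_json(self) -> str:
        return json.dumps({"ops": self.ops})

    @classmethod
    def from_json(cls, text: str) -> "AugPolicy":
        payload = json.loads(text)
        return cls(ops=[tuple(op) for op in payload["ops"]])


def sample_policy(seed: int, N: int = 2, registry=None) -> AugPolicy:
    """Sample a policy: N distinct transforms, each with magnitude in 1..10.

    Transforms are drawn uniformly without replacement from the registry,
    magnitudes uniformly per op; deterministic given the seed.
    """
    names = sorted(registry if registry is not None else REGISTRY)
    if not 0 <= N <= len(names):
        raise AugmentError(f"N must be in 0..{len(names)}, got {N}")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(names, size=N, replace=False)
    mags = rng.integers(1, 11, size=N)
    return AugPolicy(ops=[(str(nm), int(m)) for nm, m in zip(chosen, mags)])


def apply_transform(name: str, image: np.ndarray, mask: np.ndarray, magnitude: int, rng: np.random.Generator):
    """Apply one registered transform; photometric ops leave the mask untouched."""
    if name not in REGISTRY:
        raise AugmentError(f"unregistered transform {name!r}")
    fn, geometric = REGISTRY[name]
    image, mask = _check_pair(image, mask)
    if geometric:
        return fn(image, mask, magnitude, rng)
    out_i, _ = fn(image, mask, magnitude, rng)
    return out_i, mask


def apply_policy(image: np.ndarray, mask: np.ndarray, policy: AugPolicy, seed: int):
    """Apply a policy's ops in order; (seed, policy) fully determine the output."""
    image, mask = _check_pair(image, mask)
    rng = np.random.default_rng(seed)
    for name, m in policy.ops:
        image, mask = apply_transform(name, image, mask, m, rng)
    return image, mask
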