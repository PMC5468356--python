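"""Patch cropping around seed points and dataset splitting.

A patch is the classifier's unit of input: a fixed 71x71 RGB crop
centered on a nucleus seed point. 71 is odd, so the centroid sits on an
exact center pixel at index (35, 35). Splits are stratified by class;
grouping by source image (all patches of one image in one fold) is
available to avoid leakage between folds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import (
    GroupShuffleSplit,
    StratifiedGroupKFold,
    StratifiedKFold,
    train_test_split,
)

from .seeds import SeedPoint

log = logging.getLogger(__name__)

PATCH_SIZE = 71  # spatial side of the classifier input


@dataclass
class Patch:
    """One labeled crop: pixels (size, size, 3) uint8, its class label,
    the source image id and the seed it was cropped around."""

    pixels: np.ndarray
    label: str
    source_image_id: str = ""
    seed: SeedPoint | None = None


@dataclass
class SplitPlan:
    """Train/validation fractions, fold count and batch size."""

    train_fraction: float = 0.7
    val_fraction: float = 0.3
    k_folds: int = 5
    batch_size: int = 128
    rng_seed: int = 0

    def __post_init__(self):
        if not (0 < self.train_fraction < 1 and 0 < self.val_fraction < 1):
            raise ValueError("fractions must lie in (0, 1)")
        if self.train_fraction + self.val_fraction > 1 + 1e-12:
            raise ValueError("train_fraction + val_fraction must be <= 1")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def crop_patch(
    image: np.ndarray,
    seed: SeedPoint,
    size: int = PATCH_SIZE,
    boundary: str = "reflect",
    constant_value: int = 0,
) -> Patch | None:
    """Crop a ``size`` x ``size`` patch centered on a seed point.

    The seed maps to patch index (size//2, size//2). Out-of-bounds
    regions are filled per ``boundary``: ``reflect`` mirrors image
    content, ``constant`` pads with ``constant_value``, ``skip`` returns
    None (patch omitted) when the crop exceeds the image.
    """
    H, W = image.shape[:2]
    if not (0 <= seed.row < H and 0 <= seed.col < W):
        raise ValueError(f"seed ({seed.row}, {seed.col}) outside image {H}x{W}")
    half = size // 2
    r0, r1 = seed.row - half, seed.row - half + size
    c0, c1 = seed.col - half, seed.col - half + size
    if r0 >= 0 and c0 >= 0 and r1 <= H and c1 <= W:
        block = image[r0:r1, c0:c1]
    elif boundary == "skip":
        log.info(
            "skipping seed (%d, %d): %dx%d patch exceeds image bounds",
            seed.row, seed.col, size, size,
        )
        return None
    else:
        if boundary == "reflect":
            if size > min(H, W):
                log.warning("patch size %d exceeds image extent; reflection tiles", size)
            mode, kw = "reflect", {}
        elif boundary == "constant":
            mode, kw = "constant", {"constant_values": constant_value}
        else:
            raise ValueError(f"unknown boundary policy {boundary!r}")
        pad = ((max(0, -r0), max(0, r1 - H)), (max(0, -c0), max(0, c1 - W)), (0, 0))
        padded = np.pad(image, pad, mode=mode, **kw)
        block = padded[r0 + pad[0][0] : r0 + pad[0][0] + size,
                       c0 + pad[1][0] : c0 + pad[1][0] + size]
    return Patch(pixels=np.ascontiguousarray(block), label=seed.klass, seed=seed)


def crop_patches(
    image: np.ndarray,
    seeds: list[SeedPoint],
    size: int = PATCH_SIZE,
    boundary: str = "reflect",
    image_id: str = "",
) -> list[Patch]:
    """Crop one patch per seed, dropping seeds the boundary policy skips."""
    out = []
    for s in seeds:
        p = crop_patch(image, s, size=size, boundary=boundary)
        if p is not None:
            p.source_image_id = image_id
            out.append(p)
    return out


def _labels_groups(patches):
    y = np.array([p.label for p in patches])
    groups = np.array([p.source_image_id for p in patches])
    return y, groups


def build_splits(patches: list[Patch], plan: SplitPlan, grouped: bool = False):
    """Stratified train/validation split.

    Returns (train_patches, val_patches). ``grouped=True`` keeps all
    patches of one source image on the same side of the split.
    """
    y, groups = _labels_groups(patches)
    if len(np.unique(y)) < 2:
        raise ValueError("stratified splitting needs both classes present")
    idx = np.arange(len(patches))
    if grouped:
        gss = GroupShuffleSplit(
            n_splits=1, train_size=plan.train_fraction, random_state=plan.rng_seed
        )
        tr, va = next(gss.split(idx, y, groups))
    else:
        tr, va = train_test_split(
            idx,
            train_size=plan.train_fraction,
            test_size=plan.val_fraction,
            stratify=y,
            random_state=plan.rng_seed,
        )
    return [patches[i] for i in tr], [patches[i] for i in va]


def build_folds(patches: list[Patch], plan: SplitPlan, grouped: bool = False):
    """Stratified k-fold partition: k disjoint, exhaustive folds, each
    holding ~1/k of the patches with class proportions preserved."""
    y, groups = _labels_groups(patches)
    if len(np.unique(y)) < 2:
        raise ValueError("stratified folding needs both classes present")
    if len(patches) < plan.k_folds:
        raise ValueError("fewer patches than folds")
    idx = np.arange(len(patches))
    if grouped:
        skf = StratifiedGroupKFold(
            n_splits=plan.k_folds, shuffle=True, random_state=plan.rng_seed
        )
        splits = skf.split(idx, y, groups)
    else:
        skf = StratifiedKFold(
            n_splits=plan.k_folds, shuffle=True, random_state=plan.rng_seed
        )
        splits = skf.split(idx, y)
    return [[patches[i] for i in test] for _, test in splits]


def patches_to_arrays(patches: list[Patch], class_order=("immunopositive", "immunonegative")):
    """Stack patches into (N, 3, H, W) float64 in [0, 1] plus integer
    labels indexing ``class_order`` (immunopositive = 0)."""
    X = np.stack([p.pixels for p in patches]).astype(np.float64) / 255.0
    X = X.transpose(0, 3, 1, 2)
    lut = {k: i for i, k in enumerate(class_order)}
    y = np.array([lut[p.label] for p in patches], dtype=np.int64)
    return X, y
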