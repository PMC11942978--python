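"""Dataset split and augmentation bookkeeping.

The detection-model workflow splits the available frames 60/20/20 into
train/validation/test and expands the training set with k photometric
variants per image (brightness, exposure, blur — all geometry-preserving,
so masks carry over unchanged).  The counting rule is: train and
validation take the floor of their fractions, the remainder goes to test;
with k = 5 this reproduces the usual bookkeeping (397 originals ->
238 train -> 1190 extra -> 1428 augmented training images; 92 -> 330;
305 -> 1098).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .errors import InvalidParamsError

__all__ = ["SplitPlan", "plan_split", "augment_image", "AUGMENT_LIMITS"]

#: magnitude limits of the photometric transforms
AUGMENT_LIMITS = {"brightness": 0.25, "exposure": 0.10, "blur": 2.0}


@dataclass(frozen=True)
class SplitPlan:
    n_total: int
    train_frac: float
    val_frac: float
    test_frac: float
    n_train: int
    n_val: int
    n_test: int
    augment_k: int
    n_extra: int            # augment_k * n_train
    n_train_augmented: int  # n_train * (augment_k + 1)
    train_idx: tuple[int, ...] = field(repr=False, default=())
    val_idx: tuple[int, ...] = field(repr=False, default=())
    test_idx: tuple[int, ...] = field(repr=False, default=())

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "fractions": [self.train_frac, self.val_frac, self.test_frac],
            "n_train": self.n_train,
            "n_val": self.n_val,
            "n_test": self.n_test,
            "augment_k": self.augment_k,
            "n_extra": self.n_extra,
            "n_train_augmented": self.n_train_augmented,
            "train_idx": list(self.train_idx),
            "val_idx": list(self.val_idx),
            "test_idx": list(self.test_idx),
        }


def plan_split(
    n_total: int,
    fracs: tuple[float, float, float] = (0.6, 0.2, 0.2),
    augment_k: int = 5,
    seed: int = 0,
) -> SplitPlan:
    """Deterministic train/val/test split plan with augmentation counts.

    ``n_train = floor(train_frac * n)``, ``n_val = floor(val_frac * n)``,
    the remainder is the test set.  Membership is a seeded permutation of
    ``0..n-1``.
    """
    if n_total < 1:
        raise InvalidParamsError(f"n_total must be >= 1, got {n_total}")
    if augment_k < 0:
        raise InvalidParamsError(f"augment_k must be >= 0, got {augment_k}")
    tf, vf, sf = fracs
    if min(tf, vf, sf) <= 0:
        raise InvalidParamsError(f"fractions must be positive, got {fracs}")
    if abs(tf + vf + sf - 1.0) > 1e-9:
        raise InvalidParamsError(f"fractions must sum to 1, got {fracs}")

    n_train = math.floor(tf * n_total)
    n_val = math.floor(vf * n_total)
    n_test = n_total - n_train - n_val

    perm = np.random.default_rng(seed).permutation(n_total)
    return SplitPlan(
        n_total=n_total,
        train_frac=tf,
        val_frac=vf,
        test_frac=sf,
        n_train=n_train,
        n_val=n_val,
        n_test=n_test,
        augment_k=augment_k,
        n_extra=augment_k * n_train,
        n_train_augmented=n_train * (augment_k + 1),
        train_idx=tuple(int(i) for i in perm[:n_train]),
        val_idx=tuple(int(i) for i in perm[n_train : n_train + n_val]),
        test_idx=tuple(int(i) for i in perm[n_train + n_val :]),
    )


def augment_image(
    image: np.ndarray, transform: str, magnitude: float, seed: int = 0
) -> np.ndarray:
    """Apply one photometric augmentation, deterministically.

    * ``brightness``: multiplicative gain ``1 + m``, |m| <= 0.25.
    * ``exposure``: gamma-style adjustment ``out = 255 * (in/255)^(1/(1+m))``,
      |m| <= 0.10 (positive m brightens mid-tones).
    * ``blur``: Gaussian blur with sigma = m, 0 <= m <= 2 px.

    Output is clipped to [0, 255]; masks are unaffected by design (all
    transforms are geometric identities).
    """
    arr = np.asarray(image, dtype=np.float64)
    if transform not in AUGMENT_LIMITS:
        raise InvalidParamsError(f"unknown transform {transform!r}")
    limit = AUGMENT_LIMITS[transform]
    if transform == "blur":
        if not 0 <= magnitude <= limit:
            raise InvalidParamsError(f"blur sigma must be in [0, {limit}], got {magnitude}")
        out = ndi.gaussian_filter(arr, magnitude) if magnitude > 0 else arr
    elif transform == "brightness":
        if abs(magnitude) > limit:
            raise InvalidParamsError(f"|brightness| must be <= {limit}, got {magnitude}")
        out = arr * (1.0 + magnitude)
    else:  # exposure
        if abs(magnitude) > limit:
            raise InvalidParamsError(f"|exposure| must be <= {limit}, got {magnitude}")
        out = 255.0 * np.power(np.clip(arr, 0, 255) / 255.0, 1.0 / (1.0 + magnitude))
    return np.clip(np.round(out), 0, 255).astype(np.uint8)
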