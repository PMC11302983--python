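"""Synthetic task generators and optional IDX image loading.

The classification generator emulates the statistics of greyscale digit
images that matter for energy-efficient synapse experiments: features are
non-negative, bounded in [0, 1], carry learnable class structure, and —
crucially — have per-feature mean activation ("input rate") spanning
orders of magnitude.  The rate heterogeneity is planted explicitly so that
downstream diagnostics can recover it.

The quadratic toys expose a loss with a known diagonal Hessian, used as
the analytic testbed for noise-allocation theory.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "Dataset",
    "QuadraticToy",
    "make_classification_task",
    "make_quadratic_toy",
    "load_idx_images",
]


@dataclass
class Dataset:
    """A split classification dataset with features in [0, 1].

    ``rate_scale`` stores the planted per-feature rate multiplier when the
    dataset was produced by :func:`make_classification_task`; it is the
    ground truth against which recovered input rates can be compared.
    """

    features: np.ndarray  # (n_samples, n_features), float64 in [0, 1]
    labels: np.ndarray  # (n_samples,), int
    split: np.ndarray  # (n_samples,), '<U5' tags: train / val / test
    n_classes: int
    rate_scale: np.ndarray | None = None

    def subset(self, tag: str) -> tuple[np.ndarray, np.ndarray]:
        mask = self.split == tag
        return self.features[mask], self.labels[mask]

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def save_npz(self, path: str | Path) -> None:
        arrays = dict(
            features=self.features,
            labels=self.labels,
            split=self.split,
            n_classes=np.asarray(self.n_classes),
        )
        if self.rate_scale is not None:
            arrays["rate_scale"] = self.rate_scale
        np.savez(path, **arrays)

    @classmethod
    def load_npz(cls, path: str | Path) -> "Dataset":
        with np.load(path, allow_pickle=False) as f:
            return cls(
                features=f["features"],
                labels=f["labels"],
                split=f["split"],
                n_classes=int(f["n_classes"]),
                rate_scale=f["rate_scale"] if "rate_scale" in f else None,
            )


@dataclass
class QuadraticToy:
    """Diagonal quadratic loss L(w) = sum_i h_i (w_i - w*_i)^2 / 2.

    ``h`` is exactly the diagonal of the Hessian of the loss; the loss
    vanishes at ``w_star``.
    """

    h: np.ndarray
    w_star: np.ndarray
    seed: int = 0

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        self.w_star = np.asarray(self.w_star, dtype=float)
        if self.h.shape != self.w_star.shape:
            raise ValueError("h_values and w_star must have the same shape")
        if np.any(self.h <= 0):
            raise ValueError("curvatures h must all be positive")

    def loss(self, w: np.ndarray) -> float:
        d = np.asarray(w, dtype=float) - self.w_star
        return float(0.5 * np.sum(self.h * d * d))

    def gradient(self, w: np.ndarray) -> np.ndarray:
        return self.h * (np.asarray(w, dtype=float) - self.w_star)

    @property
    def n_synapses(self) -> int:
        return self.h.size


def make_quadratic_toy(h_values, w_star, seed: int = 0) -> QuadraticToy:
    """Build a quadratic toy problem with Hessian diagonal ``h_values``."""
    return QuadraticToy(np.asarray(h_values, float), np.asarray(w_star, float), seed)


def _assign_splits(n: int, fractions: tuple[float, float, float], rng) -> np.ndarray:
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    tags = np.array(
        ["train"] * n_train + ["val"] * n_val + ["test"] * (n - n_train - n_val)
    )
    rng.shuffle(tags)
    return tags


def make_classification_task(
    n_classes: int = 4,
    n_features: int = 100,
    n_samples: int = 4000,
    rate_heterogeneity: float = 3.0,
    seed: int = 0,
    *,
    template_sd: float = 0.35,
    noise_sd: float = 0.15,
    splits: tuple[float, float, float] = (0.8, 0.1, 0.1),
) -> Dataset:
    """Generate a bounded, rate-heterogeneous multi-class task.

    Each class has a Gaussian template over features; samples are the
    template plus Gaussian noise, clipped to [0, 1], then multiplied by a
    per-feature rate scale drawn log-uniformly from
    ``[10**-rate_heterogeneity, 1]``.  With the default heterogeneity of 3
    the per-feature mean activations span roughly three orders of
    magnitude, mirroring the highly uneven per-pixel firing rates of digit
    images.  Deterministic given ``seed``.
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if n_features < 2:
        raise ValueError("n_features must be >= 2")
    if n_samples < n_classes:
        raise ValueError("n_samples must be >= n_classes")
    if rate_heterogeneity < 0:
        raise ValueError("rate_heterogeneity must be >= 0")
    if abs(sum(splits) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")

    rng = np.random.default_rng(seed)
    # class templates centred at 0.5 per feature (deviations sum to zero
    # across classes), so absent rate scaling every column has the same
    # mean activation up to sampling error
    dev = rng.normal(0.0, template_sd, size=(n_classes, n_features))
    templates = 0.5 + dev - dev.mean(axis=0)
    rate_scale = 10.0 ** rng.uniform(-rate_heterogeneity, 0.0, size=n_features)

    labels = rng.integers(0, n_classes, size=n_samples)
    raw = templates[labels] + rng.normal(0.0, noise_sd, size=(n_samples, n_features))
    features = np.clip(raw, 0.0, 1.0) * rate_scale

    split = _assign_splits(n_samples, splits, rng)
    return Dataset(features, labels.astype(np.int64), split, n_classes, rate_scale)


_IDX_DTYPES = {0x08: np.uint8, 0x09: np.int8, 0x0B: ">i2", 0x0C: ">i4", 0x0D: ">f4", 0x0E: ">f8"}


class IdxFormatError(ValueError):
    """Raised on malformed IDX image/label files."""


def _read_idx(path: str | Path) -> np.ndarray:
    data = Path(path).read_bytes()
    if len(data) < 4:
        raise IdxFormatError(f"{path}: truncated IDX header")
    zeros, dtype_code, ndim = data[0] << 8 | data[1], data[2], data[3]
    if zeros != 0 or dtype_code not in _IDX_DTYPES:
        raise IdxFormatError(f"{path}: bad IDX magic number {data[:4].hex()}")
    header_len = 4 + 4 * ndim
    if len(data) < header_len:
        raise IdxFormatError(f"{path}: truncated IDX dimension header")
    dims = struct.unpack(f">{ndim}i", data[4:header_len])
    arr = np.frombuffer(data, dtype=_IDX_DTYPES[dtype_code], offset=header_len)
    expected = int(np.prod(dims)) if ndim else 0
    if arr.size != expected:
        raise IdxFormatError(
            f"{path}: payload has {arr.size} items, header promises {expected}"
        )
    return arr.reshape(dims)


def load_idx_images(
    images_path: str | Path,
    labels_path: str | Path,
    *,
    splits: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> Dataset:
    """Read an IDX image/label pair (the on-disk format of the MNIST files).

    Pixels are rescaled from [0, 255] to [0, 1]; images are flattened to
    one feature per pixel.  Optional — no test or experiment requires
    external data.
    """
    images = _read_idx(images_path)
    labels = _read_idx(labels_path)
    if images.ndim != 3:
        raise IdxFormatError(f"{images_path}: expected 3-D image tensor, got {images.ndim}-D")
    if labels.ndim != 1:
        raise IdxFormatError(f"{labels_path}: expected 1-D label vector, got {labels.ndim}-D")
    if images.shape[0] != labels.shape[0]:
        raise IdxFormatError(
            f"image count {images.shape[0]} != label count {labels.shape[0]}"
        )
    features = images.reshape(images.shape[0], -1).astype(np.float64) / 255.0
    labels = labels.astype(np.int64)
    rng = np.random.default_rng(seed)
    split = _assign_splits(images.shape[0], splits, rng)
    return Dataset(features, labels, split, int(labels.max()) + 1 if labels.size else 0)
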