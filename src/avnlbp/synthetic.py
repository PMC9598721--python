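"""Labeled synthetic texture databases for exercising the full pipeline.

Real medical texture archives cannot be redistributed, so the generator
emulates the statistical structure the retrieval stack actually consumes:
multiple classes with class-distinct second-order spatial statistics.  Two
texture families are provided:

* ``gratings`` — sinusoidal gratings with a per-class orientation and
  spatial frequency, random phase per image, and a smooth random
  luminance field on top (so images within a class vary);
* ``grf`` — Gaussian random fields with a per-class autocorrelation length
  (white noise smoothed by a Gaussian kernel).

Both families are strongly discriminable by LBP-type histograms at high
SNR, and additive Gaussian noise at a configurable SNR exercises the
descriptors' noise behaviour.  Generation is fully deterministic given the
spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from avnlbp.descriptors import add_gaussian_noise

__all__ = ["SyntheticSpec", "generate", "split_dataset", "save_dataset",
           "load_dataset"]


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic texture database.

    Per-class texture parameters must be pairwise distinct; defaults give
    ``n_classes`` gratings with orientations evenly spaced over 180 deg at
    ~0.15 cycles/pixel, the regime where LBP-type codes separate classes
    cleanly.  ``snr_db=None`` (or ``inf``) means clean images.
    """

    n_classes: int = 3
    images_per_class: int = 10
    image_size: int = 64
    family: str = "gratings"
    orientations_deg: list[float] | None = None
    frequencies: list[float] | None = None
    corr_lengths: list[float] | None = None
    snr_db: float | None = None
    seed: int = 0

    def class_params(self) -> list[tuple]:
        if self.family == "gratings":
            orients = (self.orientations_deg
                       if self.orientations_deg is not None
                       else [180.0 * c / self.n_classes for c in range(self.n_classes)])
            freqs = (self.frequencies
                     if self.frequencies is not None
                     else [0.15 + 0.02 * (c % 3) for c in range(self.n_classes)])
            params = list(zip(orients, freqs))
        elif self.family == "grf":
            lengths = (self.corr_lengths
                       if self.corr_lengths is not None
                       else [1.0 * 2 ** c for c in range(self.n_classes)])
            params = [(l,) for l in lengths]
        else:
            raise ValueError(f"unknown texture family {self.family!r}")
        if len(params) != self.n_classes:
            raise ValueError(
                f"{len(params)} parameter sets for {self.n_classes} classes")
        if len(set(params)) != self.n_classes:
            raise ValueError("class texture parameters must be pairwise distinct")
        return params


def _grating(size: int, orientation_deg: float, frequency: float,
             phase: float, rng) -> np.ndarray:
    rows, cols = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    theta = np.deg2rad(orientation_deg)
    carrier = np.sin(2.0 * np.pi * frequency * (cols * np.cos(theta)
                                                + rows * np.sin(theta)) + phase)
    # smooth luminance field: within-class variability without destroying
    # the oriented structure
    lum = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (size, size)), sigma=8.0)
    lum *= 10.0 / max(lum.std(), 1e-9)
    return 128.0 + 55.0 * carrier + lum


def _random_field(size: int, corr_length: float, rng) -> np.ndarray:
    raw = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (size, size)),
                                  sigma=corr_length, mode="wrap")
    raw = (raw - raw.mean()) / max(raw.std(), 1e-9)
    return 128.0 + 40.0 * raw


def generate(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """Generate the database: returns ``(images, labels)`` with images a
    uint8 array of shape ``(n_classes * images_per_class, size, size)``.

    Deterministic given ``spec.seed``; per-image streams are derived from
    (seed, class, image index) so datasets are reproducible element-wise.
    """
    params = spec.class_params()
    images, labels = [], []
    for c in range(spec.n_classes):
        for j in range(spec.images_per_class):
            rng = np.random.default_rng([spec.seed, c, j])
            if spec.family == "gratings":
                orient, freq = params[c]
                img = _grating(spec.image_size, orient, freq,
                               rng.uniform(0.0, 2.0 * np.pi), rng)
            else:
                img = _random_field(spec.image_size, params[c][0], rng)
            img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
            if spec.snr_db is not None and np.isfinite(spec.snr_db):
                img = add_gaussian_noise(img, spec.snr_db, rng)
            images.append(img)
            labels.append(c)
    return np.stack(images), np.array(labels, dtype=np.intp)


@dataclass
class DatasetSplit:
    """Stratified train/test/validation index lists."""

    train: np.ndarray
    test: np.ndarray
    validation: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"train": self.train, "test": self.test,
                "validation": self.validation}


def split_dataset(labels, fractions=(0.4, 0.3, 0.3), seed: int = 0) -> DatasetSplit:
    """Stratified train/test/validation split.

    Within every class, a seeded shuffle is partitioned by the requested
    fractions using largest-remainder rounding with the earlier partitions
    (train first) taking the remainders, so 10 images at (0.4, 0.3, 0.3)
    split 4/3/3.  The three parts are disjoint and jointly exhaustive.
    """
    fractions = np.asarray(fractions, dtype=np.float64)
    if fractions.size != 3 or fractions.min() < 0 or abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError(f"fractions must be 3 non-negative values summing to 1, "
                         f"got {fractions}")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    parts: list[list[int]] = [[], [], []]
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < 3:
            raise ValueError(f"class {cls!r} has {len(idx)} images; need >= 3 "
                             "to populate all three partitions")
        idx = rng.permutation(idx)
        exact = fractions * len(idx)
        sizes = np.floor(exact).astype(int)
        remainder = len(idx) - sizes.sum()
        # largest remainder, ties to the earlier (train-first) partition
        order = np.argsort(-(exact - sizes), kind="stable")
        for k in order[:remainder]:
            sizes[k] += 1
        bounds = np.cumsum(sizes)
        parts[0].extend(idx[:bounds[0]])
        parts[1].extend(idx[bounds[0]:bounds[1]])
        parts[2].extend(idx[bounds[1]:bounds[2]])
    return DatasetSplit(*(np.array(sorted(p), dtype=np.intp) for p in parts))


def save_dataset(images: np.ndarray, labels: np.ndarray, outdir) -> Path:
    """Write a ``class_<c>/img_<j>.png`` tree plus a manifest CSV; returns
    the manifest path."""
    import imageio.v3 as iio

    outdir = Path(outdir)
    rows = []
    counters: dict[int, int] = {}
    for img, label in zip(images, labels):
        j = counters.get(int(label), 0)
        counters[int(label)] = j + 1
        rel = Path(f"class_{label}") / f"img_{j}.png"
        (outdir / rel.parent).mkdir(parents=True, exist_ok=True)
        iio.imwrite(outdir / rel, img.astype(np.uint8))
        rows.append({"path": str(rel), "label": int(label)})
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_dataset(manifest) -> tuple[list[np.ndarray], np.ndarray, list[str]]:
    """Read a manifest CSV back into (images, labels, paths); color images
    are converted to grayscale by luminance."""
    import imageio.v3 as iio

    manifest = Path(manifest)
    frame = pd.read_csv(manifest)
    images, paths = [], []
    for rel in frame["path"]:
        img = np.asarray(iio.imread(manifest.parent / rel))
        if img.ndim == 3:  # luminance conversion for color inputs
            img = (0.2126 * img[..., 0] + 0.7152 * img[..., 1]
                   + 0.0722 * img[..., 2])
            img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
        images.append(img)
        paths.append(str(rel))
    return images, frame["label"].to_numpy(), paths
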