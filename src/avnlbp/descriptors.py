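"""Local binary pattern descriptors: classic LBP and sector-averaged AvN-LBP.

The classic LBP code of a pixel thresholds its ``p`` circular neighbours at
radius ``R`` against the centre intensity and reads the results as a binary
number.  AvN-LBP replaces the individual neighbour samples by the mean
intensity of each of ``p`` angular sectors of the surrounding
``(2R+1) x (2R+1)`` window, and thresholds the sector means against their own
arithmetic mean.  Averaging over sectors makes the code far less sensitive to
per-pixel noise, and thresholding at the neighbourhood mean makes it exactly
invariant to additive grey-level shifts.

Geometric conventions (fixed so codes are reproducible):

* sector / sample ``n = 0`` starts at angle 0 deg on the +x (column) axis,
  angles increase counter-clockwise (row offsets point *down* the image, so
  the angle of an offset ``(di, dj)`` is ``atan2(-di, dj)``);
* sectors are half-open bins ``[n*theta, (n+1)*theta)`` with
  ``theta = 360/p``; offsets lying exactly on a bin boundary belong to the
  sector whose lower bound is their angle;
* sector membership is defined over the full square ring
  ``0 < max(|di|, |dj|) <= R`` (for ``R=3, p=8`` this gives exactly 6 offsets
  per sector);
* bit ``n`` of a code carries weight ``2**n``.

The classic-LBP step function thresholds at 1 (``S(x)=1`` iff ``x >= 1``,
strict inequality on integer images); pass ``threshold=0`` for the
conventional ``x >= 0`` variant.  The AvN-LBP step thresholds at 0.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "build_sector_partition",
    "sector_means",
    "avn_lbp_code",
    "lbp_code",
    "lbp_code_from_neighbors",
    "code_map",
    "descriptor_histogram",
    "add_gaussian_noise",
    "LBPHistogram",
]

_ANGLE_TOL = 1e-6  # degrees; lattice angles are either exact or >1 deg away


def _as_gray_image(image) -> np.ndarray:
    """Validate and return a 2-D grayscale image as a float array."""
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError("empty image")
    if np.issubdtype(arr.dtype, np.floating) and not np.isfinite(arr).all():
        raise ValueError("image contains non-finite intensities")
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("intensities must lie in [0, 255]")
    return arr.astype(np.float64, copy=False)


def _check_window(image: np.ndarray, radius: int) -> None:
    n_rows, n_cols = image.shape
    if n_rows < 2 * radius + 1 or n_cols < 2 * radius + 1:
        raise ValueError(
            f"image of shape {image.shape} too small for window radius {radius}: "
            f"need at least {2 * radius + 1} pixels per side"
        )


def build_sector_partition(p: int = 8, radius: int = 3) -> list[np.ndarray]:
    """Partition the square ring of offsets around a pixel into ``p`` sectors.

    Every offset ``(di, dj)`` with ``0 < max(|di|, |dj|) <= radius`` is
    assigned to sector ``floor(angle / theta)`` where ``theta = 360/p`` and
    the angle is measured counter-clockwise from the +x axis in [0, 360).

    Returns a list of ``p`` integer arrays of shape ``(m_n, 2)`` holding the
    (row, col) offsets of each sector.  Sectors are pairwise disjoint and
    jointly cover all ``(2*radius+1)**2 - 1`` ring offsets; for the default
    ``p=8, radius=3`` every sector holds exactly 6 offsets.
    """
    if p < 2:
        raise ValueError(f"need at least 2 sectors, got p={p}")
    if radius < 1:
        raise ValueError(f"window radius must be >= 1, got {radius}")
    theta = 360.0 / p
    sectors: list[list[tuple[int, int]]] = [[] for _ in range(p)]
    for di in range(-radius, radius + 1):
        for dj in range(-radius, radius + 1):
            if di == 0 and dj == 0:
                continue
            angle = math.degrees(math.atan2(-di, dj)) % 360.0
            n = int((angle + _ANGLE_TOL) // theta) % p
            sectors[n].append((di, dj))
    return [np.array(s, dtype=np.intp) for s in sectors]


def sector_means(
    image, center: tuple[int, int], partition: list[np.ndarray]
) -> tuple[np.ndarray, float]:
    """Mean intensity of each angular sector around ``center``.

    Returns ``(means, mu)`` where ``means[n]`` is the arithmetic mean of the
    intensities at the sector-``n`` offsets and ``mu`` is the mean of the
    ``p`` sector means.  The window must lie fully inside the image.
    """
    img = _as_gray_image(image)
    i, j = center
    radius = int(max(np.abs(off).max() for off in partition))
    _check_window(img, radius)
    if not (radius <= i < img.shape[0] - radius and radius <= j < img.shape[1] - radius):
        raise ValueError(
            f"center {center} closer than {radius} pixels to the image border"
        )
    means = np.empty(len(partition))
    for n, offsets in enumerate(partition):
        if len(offsets) == 0:
            raise ValueError(f"sector {n} is empty; invalid partition")
        means[n] = img[i + offsets[:, 0], j + offsets[:, 1]].mean()
    return means, float(means.mean())


def avn_lbp_code(means, mu: float | None = None) -> int:
    """AvN-LBP code from ``p`` sector means.

    Bit ``n`` is set iff ``means[n] - mu >= 0`` where ``mu`` defaults to the
    arithmetic mean of the sector means; the code is ``sum 2**n`` over set
    bits.  A flat neighbourhood (all means equal) therefore yields
    ``2**p - 1``.
    """
    m = np.asarray(means, dtype=np.float64)
    if mu is None:
        mu = float(m.mean())
    bits = m - mu >= 0.0
    return int(bits @ (1 << np.arange(m.size, dtype=np.int64)))


def lbp_code_from_neighbors(center_value: float, neighbors, threshold: float = 1.0) -> int:
    """Classic-LBP bit accumulation: bit ``n`` set iff
    ``neighbors[n] - center_value >= threshold``."""
    nb = np.asarray(neighbors, dtype=np.float64)
    bits = nb - float(center_value) >= threshold
    return int(bits @ (1 << np.arange(nb.size, dtype=np.int64)))


def _circle_offsets(p: int, radius: float) -> np.ndarray:
    """(row, col) offsets of the p circle samples, n=0 at 0 deg, CCW.

    Offsets within 1e-9 of an integer are snapped so that on-lattice samples
    are read exactly rather than through bilinear interpolation.
    """
    angles = 2.0 * np.pi * np.arange(p) / p
    d_col = radius * np.cos(angles)
    d_row = -radius * np.sin(angles)
    for arr in (d_col, d_row):
        near = np.abs(arr - np.round(arr)) < 1e-9
        arr[near] = np.round(arr[near])
    return np.stack([d_row, d_col], axis=1)


def lbp_code(image, center: tuple[int, int], p: int = 8, radius: int = 3,
             threshold: float = 1.0) -> int:
    """Classic LBP code of one pixel.

    Neighbours are sampled on the circle of the given radius in the order
    ``n = 0..p-1`` (start angle 0 deg, counter-clockwise), bilinearly
    interpolated at non-integer positions.  ``center`` must be at least
    ``radius`` pixels from every border.
    """
    img = _as_gray_image(image)
    r_int = int(math.ceil(radius))
    _check_window(img, r_int)
    i, j = center
    if not (r_int <= i < img.shape[0] - r_int and r_int <= j < img.shape[1] - r_int):
        raise ValueError(
            f"center {center} closer than {r_int} pixels to the image border"
        )
    offsets = _circle_offsets(p, radius)
    coords = offsets + np.array([i, j], dtype=np.float64)
    samples = ndimage.map_coordinates(img, coords.T, order=1, mode="nearest")
    return lbp_code_from_neighbors(img[i, j], samples, threshold)


def _classic_code_map(img: np.ndarray, p: int, radius: int, threshold: float) -> np.ndarray:
    r_int = int(math.ceil(radius))
    n_rows, n_cols = img.shape
    rows = np.arange(r_int, n_rows - r_int)
    cols = np.arange(r_int, n_cols - r_int)
    grid_r, grid_c = np.meshgrid(rows, cols, indexing="ij")
    center = img[r_int:n_rows - r_int, r_int:n_cols - r_int]
    codes = np.zeros(center.shape, dtype=np.int64)
    for n, (d_row, d_col) in enumerate(_circle_offsets(p, radius)):
        sample = ndimage.map_coordinates(
            img,
            [grid_r.ravel() + d_row, grid_c.ravel() + d_col],
            order=1,
            mode="nearest",
        ).reshape(center.shape)
        codes += ((sample - center) >= threshold).astype(np.int64) << n
    return codes


def _avn_code_map(img: np.ndarray, p: int, radius: int) -> np.ndarray:
    # Integer-exact evaluation: bit n tests mean_n >= mu, i.e.
    # S_n/C_n >= (1/p) sum_m S_m/C_m with integer sector sums S and counts
    # C.  Scaling by L = lcm(C) turns this into p*S_n*(L/C_n) >= sum_m
    # S_m*(L/C_m), all in int64, so codes are exact and grey-shift
    # invariance holds to the bit.
    partition = build_sector_partition(p, radius)
    size = 2 * radius + 1
    int_img = np.rint(img).astype(np.int64)
    counts = np.array([len(s) for s in partition], dtype=np.int64)
    lcm = np.lcm.reduce(counts)
    scaled = np.empty((p,) + img.shape, dtype=np.int64)
    for n, offsets in enumerate(partition):
        kernel = np.zeros((size, size), dtype=np.int64)
        kernel[offsets[:, 0] + radius, offsets[:, 1] + radius] = 1
        sums = ndimage.correlate(int_img, kernel, mode="constant")
        scaled[n] = sums * (lcm // counts[n])
    total = scaled.sum(axis=0)
    weights = (1 << np.arange(p, dtype=np.int64)).reshape(-1, 1, 1)
    codes = ((p * scaled >= total).astype(np.int64) * weights).sum(axis=0)
    return codes[radius:img.shape[0] - radius, radius:img.shape[1] - radius]


def code_map(image, p: int = 8, radius: int = 3, variant: str = "avn",
             threshold: float = 1.0) -> np.ndarray:
    """Per-pixel code map over the interior where the full window fits.

    Returns an integer array of shape ``(N - 2R, M - 2R)``.  Border pixels
    are skipped rather than padded: padding would fabricate intensities and
    distort the histogram.
    """
    img = _as_gray_image(image)
    _check_window(img, radius)
    if variant == "avn":
        return _avn_code_map(img, p, radius)
    if variant == "classic":
        return _classic_code_map(img, p, radius, threshold)
    raise ValueError(f"unknown variant {variant!r}; use 'avn' or 'classic'")


def descriptor_histogram(image, p: int = 8, radius: int = 3, variant: str = "avn",
                         threshold: float = 1.0) -> np.ndarray:
    """Code histogram of an image: ``counts[k]`` = number of interior pixels
    with code ``k``; length exactly ``2**p`` and total ``(N-2R)(M-2R)``."""
    codes = code_map(image, p=p, radius=radius, variant=variant, threshold=threshold)
    return np.bincount(codes.ravel(), minlength=1 << p).astype(np.int64)


def add_gaussian_noise(image, snr_db: float, rng, var_floor: float = 1.0) -> np.ndarray:
    """Corrupt an image with additive zero-mean Gaussian noise at a given SNR.

    The noise variance is ``var(image) / 10**(snr_db / 10)``; the noisy image
    is rounded and clipped back to [0, 255].  ``snr_db = inf`` is the no-noise
    sentinel and returns an unchanged copy.  For a constant image (zero
    variance) the signal variance is taken as ``var_floor``.

    Parameters
    ----------
    rng : numpy.random.Generator or int seed
        Source of randomness; same seed, same output.
    """
    img = _as_gray_image(image)
    if not (np.isfinite(snr_db) or snr_db == np.inf):
        raise ValueError(f"snr_db must be finite or +inf, got {snr_db}")
    original = np.asarray(image)
    if snr_db == np.inf:
        return original.copy()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    signal_var = img.var()
    if signal_var == 0.0:
        signal_var = var_floor
    noise_sd = math.sqrt(signal_var / 10.0 ** (snr_db / 10.0))
    noisy = img + rng.normal(0.0, noise_sd, size=img.shape)
    noisy = np.clip(np.rint(noisy), 0, 255)
    dtype = original.dtype if np.issubdtype(original.dtype, np.integer) else np.uint8
    return noisy.astype(dtype)


class LBPHistogram(TransformerMixin, BaseEstimator):
    """Transform grayscale images into LBP / AvN-LBP code histograms.

    Parameters
    ----------
    p : int, default=8
        Number of circle samples (classic) or angular sectors (AvN);
        histogram length is ``2**p``.
    radius : int, default=3
        Window radius in pixels.
    variant : {'avn', 'classic'}, default='avn'
        Descriptor flavour.
    threshold : float, default=1.0
        Classic-LBP step threshold (``S(x)=1`` iff ``x >= threshold``);
        ignored by the AvN variant.
    normalize : {'max', None}, default='max'
        'max' scales every histogram into [0, 1] by its largest count, the
        scaling expected by the unit-interval classifiers downstream; None
        returns raw counts.

    Examples
    --------
    >>> import numpy as np
    >>> rng = np.random.default_rng(0)
    >>> images = rng.integers(0, 256, size=(3, 16, 16))
    >>> LBPHistogram(p=8, radius=3).fit_transform(images).shape
    (3, 256)
    """

    def __init__(self, p: int = 8, radius: int = 3, variant: str = "avn",
                 threshold: float = 1.0, normalize: str | None = "max"):
        self.p = p
        self.radius = radius
        self.variant = variant
        self.threshold = threshold
        self.normalize = normalize

    def fit(self, X, y=None):
        """No-op fit (the descriptor is stateless); validates parameters."""
        if self.variant not in ("avn", "classic"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.normalize not in ("max", None):
            raise ValueError(f"unknown normalize {self.normalize!r}")
        self.n_bins_ = 1 << self.p
        return self

    def transform(self, X) -> np.ndarray:
        """Compute one histogram per image.

        ``X`` is an iterable of 2-D arrays (or a 3-D stack); returns a float
        array of shape ``(n_images, 2**p)``.
        """
        check_is_fitted(self)
        rows = []
        for image in X:
            h = descriptor_histogram(
                image, p=self.p, radius=self.radius,
                variant=self.variant, threshold=self.threshold,
            ).astype(np.float64)
            if self.normalize == "max":
                h /= max(h.max(), 1.0)
            rows.append(h)
        if not rows:
            raise ValueError("no images to transform")
        return np.stack(rows)
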