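"""Preprocessing steps feeding the factorization: centering, normalization,
log transform, and sliding-window FFT feature stacks.

Centering and interval normalization store enough state to be inverted
exactly; the sliding FFT turns a single 2-D image into a non-negative
feature matrix (one FFT-magnitude column per window position) suitable for
NMF-based phase segmentation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PreprocessRecord",
    "SlidingFFTStack",
    "mean_center",
    "uncenter",
    "normalize",
    "denormalize",
    "window_origins",
    "sliding_fft",
]


class DegenerateScaleError(ValueError):
    """Interval normalization of a constant matrix has no well-defined scale."""


@dataclass
class PreprocessRecord:
    """Ordered log of applied steps with the parameters needed to invert them."""

    steps: list[tuple[str, dict]] = field(default_factory=list)
    mu: np.ndarray | None = None
    scale: dict = field(default_factory=dict)


def mean_center(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Subtract each feature's mean across samples.

    Rows are features; ``mu[i]`` is the mean of row ``i`` and every row of
    the result has mean zero.  Returns ``(Xc, mu)``.
    """
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=1)
    return X - mu[:, None], mu


def uncenter(Xc: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Invert :func:`mean_center`."""
    return np.asarray(Xc, dtype=float) + np.asarray(mu, dtype=float)[:, None]


def normalize(X: np.ndarray, mode: str = "unit_interval") -> tuple[np.ndarray, PreprocessRecord]:
    """Rescale or transform the matrix prior to factorization.

    Modes
    -----
    ``unit_interval``
        Affine map of the global range onto [0, 1].
    ``symmetric_interval``
        Affine map of the global range onto [-1, 1].
    ``log``
        Element-wise ``log(1 + x)``; the +1 offset admits zero counts, so
        mass-spectral channels with no hits map to exactly 0.  Requires
        ``X >= 0``.
    """
    X = np.asarray(X, dtype=float)
    rec = PreprocessRecord()
    if mode == "log":
        if np.any(X < 0):
            raise ValueError("log normalization requires a non-negative matrix")
        rec.steps.append(("log", {"offset": 1.0}))
        return np.log1p(X), rec

    lo, hi = float(X.min()), float(X.max())
    if hi == lo:
        raise DegenerateScaleError("constant matrix: interval normalization is undefined")
    if mode == "unit_interval":
        out = (X - lo) / (hi - lo)
        rec.scale = {"lo": lo, "hi": hi, "target": (0.0, 1.0)}
    elif mode == "symmetric_interval":
        out = 2.0 * (X - lo) / (hi - lo) - 1.0
        rec.scale = {"lo": lo, "hi": hi, "target": (-1.0, 1.0)}
    else:
        raise ValueError(f"unknown normalization mode: {mode!r}")
    rec.steps.append((mode, dict(rec.scale)))
    return out, rec


def denormalize(Xn: np.ndarray, record: PreprocessRecord) -> np.ndarray:
    """Invert :func:`normalize` from its record (interval and log modes)."""
    Xn = np.asarray(Xn, dtype=float)
    name, params = record.steps[-1]
    if name == "log":
        return np.expm1(Xn)
    lo, hi = params["lo"], params["hi"]
    a, b = params["target"]
    return (Xn - a) / (b - a) * (hi - lo) + lo


@dataclass
class SlidingFFTStack:
    """Stack of FFT-magnitude feature vectors from a scanned window.

    ``features`` has shape ``(p, nw)`` with ``p = window_size**2`` frequency
    bins (fftshift-centered, flattened) and one column per window position.
    ``window_origins`` lists top-left corners ``(y, x)`` in raster order, so
    ``nw = (floor((H - w)/s) + 1) * (floor((W - w)/s) + 1)``.
    """

    features: np.ndarray
    window_size: int
    step: int
    window_origins: list[tuple[int, int]]
    image_shape: tuple[int, int]

    @property
    def n_windows(self) -> int:
        return self.features.shape[1]

    @property
    def window_grid_shape(self) -> tuple[int, int]:
        ys = {o[0] for o in self.window_origins}
        xs = {o[1] for o in self.window_origins}
        return (len(ys), len(xs))


def window_origins(H: int, W: int, window: int, step: int) -> list[tuple[int, int]]:
    """Top-left corners of every full window, anchored at (0, 0), advancing by ``step``.

    Trailing pixels not covered by a full window are dropped — no padding.
    """
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    if window > H or window > W:
        raise ValueError(f"window {window} larger than image {H} x {W}")
    ys = range(0, H - window + 1, step)
    xs = range(0, W - window + 1, step)
    return [(y, x) for y in ys for x in xs]


def sliding_fft(
    image: np.ndarray,
    window: int,
    step: int,
    dtype: type = np.float64,
) -> SlidingFFTStack:
    """Scan a ``window x window`` patch across the image and stack FFT magnitudes.

    For each window position the centered 2-D FFT magnitude of the patch is
    computed and flattened into a feature column.  Magnitude (not power, not
    the complex transform) keeps the features non-negative, as NMF requires;
    the zero-frequency bin is retained.  The resulting ``(p, nw)`` matrix is
    a drop-in input for the factorization solvers: on atomically resolved
    images, NMF on this stack separates local structure factors (endmembers)
    from their loading maps over the window grid.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("sliding_fft expects a single 2-D grayscale image")
    H, W = image.shape
    origins = window_origins(H, W, window, step)
    p = window * window
    features = np.empty((p, len(origins)), dtype=dtype)
    for j, (y, x) in enumerate(origins):
        patch = image[y : y + window, x : x + window]
        mag = np.abs(np.fft.fftshift(np.fft.fft2(patch)))
        features[:, j] = mag.reshape(-1)
    return SlidingFFTStack(
        features=features,
        window_size=window,
        step=step,
        window_origins=origins,
        image_shape=(H, W),
    )
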