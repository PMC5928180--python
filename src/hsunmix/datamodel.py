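"""Core containers for gridded hyperspectral data and its matrix form.

A hyperspectral dataset is a cube ``(ny, nx, m)``: a spectrum of ``m``
channels at each of ``ny * nx`` pixels.  Factorization operates on the
matrix form ``X`` of shape ``(m, n)`` with ``n = ny * nx`` — rows are
spectral channels (features), columns are pixels (samples).  A 128 x 128
image with 1535 mass channels therefore becomes a 1535 x 16384 matrix.

Raster convention
-----------------
One global convention is used for every reshape in the package: row-major
flattening with ``y`` as the slow axis, so pixel ``(y, x)`` maps to column
``y * nx + x``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

__all__ = [
    "HyperspectralCube",
    "DataMatrix",
    "AbundanceMapStack",
    "RASTER_ORDER",
    "cube_to_matrix",
    "matrix_to_cube",
    "abundances_to_maps",
    "flatten_grid",
    "unflatten_grid",
]

#: The single raster convention used by every reshape in the package.
RASTER_ORDER = "row-major, y slow / x fast"


class InvalidInputError(ValueError):
    """Raised when a container violates its structural contract."""


def _as_float_array(values: Any, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise InvalidInputError(f"{name} is empty")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"{name} contains non-finite entries")
    return arr


def flatten_grid(field_2d: np.ndarray) -> np.ndarray:
    """Flatten a ``(ny, nx)`` field to length ``ny*nx`` under the package raster order."""
    return np.asarray(field_2d).reshape(-1)


def unflatten_grid(vec: np.ndarray, grid_shape: tuple[int, int]) -> np.ndarray:
    """Inverse of :func:`flatten_grid`."""
    ny, nx = grid_shape
    vec = np.asarray(vec)
    if vec.size != ny * nx:
        raise InvalidInputError(
            f"cannot reshape {vec.size} values onto a {ny} x {nx} grid"
        )
    return vec.reshape(ny, nx)


@dataclass
class HyperspectralCube:
    """Gridded spectra: ``values[y, x, c]`` with a physical coordinate per channel.

    Parameters
    ----------
    values
        Array of shape ``(ny, nx, m)``.  Non-negative for count-like
        modalities (mass spectrometry, EELS); real-valued in general.
    channel_axis
        Ordered physical coordinate per channel (mass-to-charge u, energy
        eV, bias V, momentum transfer 1/A) or unitless labels.  Strictly
        monotonic when numeric.
    meta
        Free-form provenance strings.
    """

    values: np.ndarray
    channel_axis: np.ndarray | Sequence[Any] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = _as_float_array(self.values, "cube values")
        if self.values.ndim != 3:
            raise InvalidInputError(
                f"cube must be (ny, nx, channels), got ndim={self.values.ndim}"
            )
        ny, nx, m = self.values.shape
        if ny < 1 or nx < 1 or m < 1:
            raise InvalidInputError("cube dimensions must all be >= 1")
        if self.channel_axis is None:
            self.channel_axis = np.arange(m, dtype=float)
        else:
            self.channel_axis = np.asarray(self.channel_axis)
            if len(self.channel_axis) != m:
                raise InvalidInputError(
                    f"channel_axis length {len(self.channel_axis)} != channel count {m}"
                )
            if np.issubdtype(self.channel_axis.dtype, np.number):
                diffs = np.diff(self.channel_axis.astype(float))
                if len(diffs) and not (np.all(diffs > 0) or np.all(diffs < 0)):
                    raise InvalidInputError("numeric channel_axis must be strictly monotonic")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.values.shape[:2]

    @property
    def n_channels(self) -> int:
        return self.values.shape[2]

    @property
    def n_pixels(self) -> int:
        ny, nx = self.grid_shape
        return ny * nx


@dataclass
class DataMatrix:
    """Matrix form ``X`` of a cube: ``m`` channels x ``n`` pixels, with grid mapping.

    Column ``j`` is the full spectrum of pixel ``j`` under :data:`RASTER_ORDER`.
    """

    X: np.ndarray
    grid_shape: tuple[int, int]
    channel_axis: np.ndarray | Sequence[Any] | None = None
    pixel_order: str = RASTER_ORDER
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = _as_float_array(self.X, "data matrix")
        if self.X.ndim != 2:
            raise InvalidInputError("X must be 2-D (channels x pixels)")
        ny, nx = self.grid_shape
        self.grid_shape = (int(ny), int(nx))
        if ny < 1 or nx < 1:
            raise InvalidInputError("grid_shape components must be >= 1")
        if ny * nx != self.X.shape[1]:
            raise InvalidInputError(
                f"grid {ny} x {nx} does not match {self.X.shape[1]} pixels"
            )
        if self.channel_axis is None:
            self.channel_axis = np.arange(self.X.shape[0], dtype=float)
        else:
            self.channel_axis = np.asarray(self.channel_axis)
            if len(self.channel_axis) != self.X.shape[0]:
                raise InvalidInputError("channel_axis length != channel count")

    @property
    def n_channels(self) -> int:
        return self.X.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.X.shape[1]


@dataclass
class AbundanceMapStack:
    """Per-endmember abundance fields on the pixel grid: ``maps[i]`` is ``(ny, nx)``."""

    maps: np.ndarray
    endmember_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 3:
            raise InvalidInputError("maps must be (k, ny, nx)")
        if not self.endmember_ids:
            self.endmember_ids = [f"endmember_{i + 1}" for i in range(self.maps.shape[0])]
        if len(self.endmember_ids) != self.maps.shape[0]:
            raise InvalidInputError("endmember_ids length != number of maps")

    @property
    def k(self) -> int:
        return self.maps.shape[0]


def cube_to_matrix(cube: HyperspectralCube) -> DataMatrix:
    """Reshape a cube to its ``m x n`` matrix form.

    Column ``j = y * nx + x`` holds the spectrum at pixel ``(y, x)``.
    A 128 x 128 x 1535 cube yields a 1535 x 16384 matrix.
    """
    ny, nx, m = cube.values.shape
    X = cube.values.reshape(ny * nx, m).T
    return DataMatrix(
        X=X,
        grid_shape=(ny, nx),
        channel_axis=cube.channel_axis,
        meta=dict(cube.meta),
    )


def matrix_to_cube(dm: DataMatrix) -> HyperspectralCube:
    """Exact inverse of :func:`cube_to_matrix`."""
    ny, nx = dm.grid_shape
    values = dm.X.T.reshape(ny, nx, dm.n_channels)
    return HyperspectralCube(values=values, channel_axis=dm.channel_axis, meta=dict(dm.meta))


def abundances_to_maps(
    V: np.ndarray,
    grid_shape: tuple[int, int],
    endmember_ids: list[str] | None = None,
) -> AbundanceMapStack:
    """Render an abundance matrix ``V (k, n)`` as ``k`` maps on the pixel grid."""
    V = np.asarray(V, dtype=float)
    if V.ndim == 1:
        V = V[None, :]
    ny, nx = grid_shape
    if V.shape[1] != ny * nx:
        raise InvalidInputError(
            f"abundance matrix has {V.shape[1]} pixels, grid is {ny} x {nx}"
        )
    maps = V.reshape(V.shape[0], ny, nx)
    return AbundanceMapStack(maps=maps, endmember_ids=endmember_ids or [])
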