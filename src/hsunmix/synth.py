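"""Synthetic hyperspectral cubes with known ground truth.

The generator realizes the linear mixing model behind every solver in the
package: the measured spectrum at pixel ``x`` is
``S(x, R) = sum_i a_i(x) w_i(R) + N`` — a non-negative superposition of
``k`` endmember spectra ``w_i`` weighted by spatial abundance fields
``a_i``, plus noise.  Endmembers are sums of Gaussian peaks over the
channel axis (the visual motif of classical mass spectra); abundance
fields are smooth seeded random blobs with controllable sparsity and
optional per-pixel simplex normalization; noise is additive Gaussian at a
chosen SNR or Poisson counting noise.

Defaults (32 x 32 grid, 200 channels, k = 3, 30 dB SNR, seeds 0-4) are the
frozen verification conditions for the recovery contracts.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.optimize import linear_sum_assignment

from .datamodel import HyperspectralCube
from .factorize import FactorModel, reconstruct

__all__ = [
    "GroundTruth",
    "make_endmembers",
    "make_abundances",
    "make_cube",
    "default_ground_truth",
    "recovery_report",
    "RecoveryReport",
    "DEFAULTS",
]

#: Frozen default generation conditions used by the verification suite.
DEFAULTS = {
    "grid_shape": (32, 32),
    "m": 200,
    "k": 3,
    "snr_db": 30.0,
    "seeds": (0, 1, 2, 3, 4),
    "peaks_per_spectrum": 6,
    "smoothness_scale": 4.0,
    "sparsity": 0.1,
}


@dataclass
class GroundTruth:
    """True factors and generation parameters behind a synthetic cube."""

    endmembers_true: np.ndarray  # (m, k), non-negative
    abundances_true: np.ndarray  # (k, n), non-negative
    grid_shape: tuple[int, int]
    noise_model: str = "gaussian"  # "gaussian" | "poisson" | "none"
    noise_param: float = 0.0  # sigma for gaussian, scale for poisson
    seed: int = 0
    sum_to_one: bool = False
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.endmembers_true < 0) or np.any(self.abundances_true < 0):
            raise ValueError("ground-truth factors must be non-negative")
        ny, nx = self.grid_shape
        if self.abundances_true.shape[1] != ny * nx:
            raise ValueError("abundance pixel count does not match the grid")
        if self.sum_to_one:
            sums = self.abundances_true.sum(axis=0)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("sum_to_one ground truth must have simplex columns")

    @property
    def k(self) -> int:
        return self.endmembers_true.shape[1]

    @property
    def noiseless_matrix(self) -> np.ndarray:
        return self.endmembers_true @ self.abundances_true


def make_endmembers(
    k: int,
    m: int,
    peaks_per_spectrum: int = 6,
    seed: int = 0,
    max_pairwise_cosine: float = 0.9,
    baseline: float = 0.02,
    max_attempts: int = 100,
) -> np.ndarray:
    """Draw ``k`` non-negative peak-shaped spectra of length ``m``.

    Each spectrum is a sum of Gaussian peaks at seeded random channel
    positions (widths 1-4 % of the axis, heights 0.3-1) on a small smooth
    baseline.  The draw is resampled until all pairwise cosines are at most
    ``max_pairwise_cosine`` so that recovery is well-posed; an error is
    raised if that fails within ``max_attempts``.
    """
    if k < 1 or m < 1:
        raise ValueError("k and m must be >= 1")
    if peaks_per_spectrum < 1 and baseline <= 0:
        raise ValueError("degenerate endmembers: no peaks and no baseline")
    rng = np.random.default_rng(seed)
    channels = np.arange(m)
    for _ in range(max_attempts):
        U = np.zeros((m, k))
        for i in range(k):
            for _ in range(peaks_per_spectrum):
                center = rng.uniform(0, m - 1)
                width = rng.uniform(0.01, 0.04) * m
                height = rng.uniform(0.3, 1.0)
                U[:, i] += height * np.exp(-0.5 * ((channels - center) / width) ** 2)
            if baseline > 0:
                U[:, i] += baseline * (1.0 + np.sin(rng.uniform(0, 2 * np.pi) + channels * rng.uniform(0.005, 0.02))) / 2.0
        norms = np.linalg.norm(U, axis=0)
        if np.any(norms == 0):
            raise ValueError("degenerate endmembers: a spectrum is identically zero")
        Un = U / norms
        G = Un.T @ Un
        off = G[~np.eye(k, dtype=bool)]
        if k == 1 or (off.size and off.max() <= max_pairwise_cosine):
            return U
    raise RuntimeError(
        f"could not draw {k} endmembers with pairwise cosine <= {max_pairwise_cosine} "
        f"in {max_attempts} attempts"
    )


def make_abundances(
    grid_shape: tuple[int, int],
    k: int,
    smoothness_scale: float = 4.0,
    sparsity: float = 0.1,
    sum_to_one: bool = False,
    seed: int = 0,
) -> np.ndarray:
    """Smooth, optionally sparse abundance fields on the pixel grid.

    Each of the ``k`` fields is a smoothed seeded Gaussian random field
    (length scale ``smoothness_scale`` pixels), exponentiated to be
    positive.  A ``sparsity`` fraction of pixels is made single-endmember
    dominant (all but the strongest component zeroed), emulating the low
    probability of several phases coexisting in one pixel.  With
    ``sum_to_one`` each pixel column is normalized onto the simplex.
    Returns ``V (k, n)`` flattened in the package raster order.
    """
    ny, nx = grid_shape
    if k < 1 or ny < 1 or nx < 1:
        raise ValueError("k and grid dimensions must be >= 1")
    if not 0 <= sparsity <= 1:
        raise ValueError("sparsity must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    fields = np.empty((k, ny, nx))
    for i in range(k):
        white = rng.normal(size=(ny, nx))
        smooth = gaussian_filter(white, sigma=smoothness_scale, mode="reflect")
        sd = smooth.std()
        if sd > 0:
            smooth = (smooth - smooth.mean()) / sd  # standardize: comparable
        fields[i] = np.exp(smooth)  # log-normal fields, positive by construction
    V = fields.reshape(k, ny * nx)
    if sparsity > 0 and k > 1:
        n = ny * nx
        n_sparse = int(round(sparsity * n))
        chosen = rng.choice(n, size=n_sparse, replace=False)
        dominant = np.argmax(V[:, chosen], axis=0)
        mask = np.zeros((k, n_sparse), dtype=bool)
        mask[dominant, np.arange(n_sparse)] = True
        V[:, chosen] = np.where(mask, V[:, chosen], 0.0)
    if sum_to_one:
        sums = V.sum(axis=0)
        sums[sums == 0] = 1.0
        V = V / sums[None, :]
    return V


def make_cube(gt: GroundTruth) -> HyperspectralCube:
    """Mix the ground-truth factors into a cube and add the configured noise.

    Gaussian noise may push entries negative; those are clipped at zero and
    the clipped fraction is logged in ``cube.meta['clip_fraction']``.
    Poisson mode draws counts with mean ``scale * (U V)``.
    """
    clean = gt.noiseless_matrix
    ny, nx = gt.grid_shape
    m = clean.shape[0]
    rng = np.random.default_rng(gt.seed)
    clip_fraction = 0.0
    if gt.noise_model == "none" or gt.noise_param == 0.0:
        noisy = clean.copy()
    elif gt.noise_model == "gaussian":
        noisy = clean + rng.normal(scale=gt.noise_param, size=clean.shape)
        neg = noisy < 0
        clip_fraction = float(neg.mean())
        noisy[neg] = 0.0
    elif gt.noise_model == "poisson":
        noisy = rng.poisson(gt.noise_param * clean).astype(float)
    else:
        raise ValueError(f"unknown noise model {gt.noise_model!r}")
    values = noisy.T.reshape(ny, nx, m)
    meta = {
        "synthetic": True,
        "noise_model": gt.noise_model,
        "noise_param": gt.noise_param,
        "seed": gt.seed,
        "clip_fraction": clip_fraction,
    }
    if clip_fraction > 0:
        warnings.warn(
            f"gaussian noise clipped at zero in {clip_fraction:.2%} of entries",
            RuntimeWarning,
        )
    return HyperspectralCube(values=values, meta=meta)


def sigma_for_snr(clean: np.ndarray, snr_db: float) -> float:
    """Gaussian noise level giving the requested signal-to-noise ratio in dB."""
    power = float(np.mean(clean**2))
    return float(np.sqrt(power / 10.0 ** (snr_db / 10.0)))


def default_ground_truth(seed: int = 0, sum_to_one: bool = False, noise_model: str = "gaussian") -> GroundTruth:
    """Ground truth under the frozen default conditions (see :data:`DEFAULTS`)."""
    d = DEFAULTS
    U = make_endmembers(d["k"], d["m"], d["peaks_per_spectrum"], seed=seed)
    V = make_abundances(
        d["grid_shape"], d["k"], d["smoothness_scale"], d["sparsity"],
        sum_to_one=sum_to_one, seed=seed + 1000,
    )
    clean = U @ V
    if noise_model == "gaussian":
        noise_param = sigma_for_snr(clean, d["snr_db"])
    elif noise_model == "poisson":
        noise_param = 50.0
    else:
        noise_param = 0.0
    return GroundTruth(
        endmembers_true=U,
        abundances_true=V,
        grid_shape=d["grid_shape"],
        noise_model=noise_model,
        noise_param=noise_param,
        seed=seed,
        sum_to_one=sum_to_one,
        params=dict(d),
    )


@dataclass
class RecoveryReport:
    """Matched comparison of a fitted model against generator ground truth."""

    permutation: np.ndarray  # recovered component matched to true component i
    cosines: np.ndarray  # per true component, after matching
    mean_cosine: float
    abundance_rmse: float
    reconstruction_error: float  # relative Frobenius error vs the noiseless matrix


def _cosine_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    An = A / np.maximum(np.linalg.norm(A, axis=0, keepdims=True), 1e-300)
    Bn = B / np.maximum(np.linalg.norm(B, axis=0, keepdims=True), 1e-300)
    return An.T @ Bn


def match_components(U_true: np.ndarray, U_est: np.ndarray, brute_force: bool = False) -> np.ndarray:
    """Permutation matching estimated to true endmembers by total cosine.

    Solved as an optimal assignment (Hungarian); ``brute_force`` enumerates
    all permutations instead, for cross-checking on small k.
    """
    C = _cosine_matrix(U_true, U_est)
    if brute_force:
        k = C.shape[0]
        best, best_perm = -np.inf, None
        for perm in itertools.permutations(range(k)):
            total = sum(C[i, perm[i]] for i in range(k))
            if total > best:
                best, best_perm = total, perm
        return np.asarray(best_perm)
    _, cols = linear_sum_assignment(-C)
    return cols


def recovery_report(model: FactorModel, gt: GroundTruth) -> RecoveryReport:
    """Score a fitted model against the ground truth it was generated from.

    Components are matched by maximizing total endmember cosine over
    permutations; abundances are compared after matching and per-component
    least-squares positive rescaling, so the report is invariant to the
    factorization's inherent permutation and scale ambiguity.
    """
    if model.k != gt.k:
        raise ValueError("model and ground truth have different component counts")
    perm = match_components(gt.endmembers_true, model.U)
    U_m = model.U[:, perm]
    V_m = model.V[perm, :]
    V_ref = gt.abundances_true
    C = _cosine_matrix(gt.endmembers_true, U_m)
    cosines = np.diag(C)
    # per-component optimal positive scale for the abundance comparison
    rmse_num = 0.0
    for i in range(gt.k):
        v_est, v_true = V_m[i], V_ref[i]
        denom = float(v_est @ v_est)
        s = float(v_est @ v_true) / denom if denom > 0 else 0.0
        s = max(s, 0.0)
        rmse_num += float(np.sum((s * v_est - v_true) ** 2))
    rmse = float(np.sqrt(rmse_num / gt.abundances_true.size))
    clean = gt.noiseless_matrix
    R = reconstruct(model)
    rec_err = float(np.linalg.norm(clean - R) / max(np.linalg.norm(clean), 1e-300))
    return RecoveryReport(
        permutation=perm,
        cosines=cosines,
        mean_cosine=float(cosines.mean()),
        abundance_rmse=rmse,
        reconstruction_error=rec_err,
    )
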