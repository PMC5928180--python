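"""Rank-selection diagnostics: how many endmembers does the data support?

Three complementary criteria are computed over a scan of candidate ranks:

* **Consensus dispersion** — NMF is rerun from many seeded random starts;
  each run labels every pixel by its dominant endmember, runs are averaged
  into a consensus co-clustering matrix, and the dispersion coefficient
  ``rho = (1/n^2) sum_ij 4 (Cbar_ij - 1/2)^2`` in [0, 1] measures how
  crisp the consensus is (1 = every restart clusters pixels identically).
* **Elbow** — the rank where the reconstruction-error curve has maximal
  discrete curvature (law of diminishing returns).
* **Component-similarity saturation** — the first rank at which two fitted
  endmembers become nearly collinear, signalling that extra components
  only duplicate existing ones.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .factorize import FactorModel, UnmixingConfig, nmf, reconstruct

__all__ = [
    "RankScanResult",
    "dispersion_from_consensus",
    "connectivity_matrix",
    "dispersion_coefficient",
    "elbow_k",
    "component_similarity_saturation",
    "scan_k",
]


def connectivity_matrix(V: np.ndarray) -> np.ndarray:
    """Pixel co-clustering indicator from dominant endmembers.

    ``C_ij = 1`` iff pixels i and j share the same dominant endmember
    (argmax over abundance rows; ties broken toward the lowest index).
    """
    labels = np.argmax(np.asarray(V), axis=0)
    return (labels[:, None] == labels[None, :]).astype(float)


def dispersion_from_consensus(consensus: np.ndarray) -> float:
    """Dispersion ``rho = (1/n^2) sum 4 (Cbar - 1/2)^2`` of a consensus matrix.

    1 when every entry is 0 or 1 (perfectly reproducible clustering),
    0 when every entry is 1/2 (coin-flip consensus).
    """
    C = np.asarray(consensus, dtype=float)
    return float(np.mean(4.0 * (C - 0.5) ** 2))


def dispersion_coefficient(
    X,
    k: int,
    n_restarts: int = 20,
    seed: int = 0,
    config: Optional[UnmixingConfig] = None,
) -> float:
    """Consensus-dispersion statistic of NMF restart stability at rank ``k``.

    Runs NMF from ``n_restarts`` seeded random starts, builds each run's
    connectivity matrix, averages them, and returns the dispersion of the
    consensus.
    """
    if n_restarts < 2:
        raise ValueError("need at least 2 restarts for a consensus")
    base = config if config is not None else UnmixingConfig(k=k, max_iter=200)
    n = X.X.shape[1] if hasattr(X, "X") else np.asarray(X).shape[1]
    if k >= n:
        raise ValueError("k must be smaller than the number of pixels")
    consensus = np.zeros((n, n))
    for r in range(n_restarts):
        cfg = replace(base, k=k, seed=seed + r, init="random")
        model = nmf(X, cfg)
        consensus += connectivity_matrix(model.V)
    consensus /= n_restarts
    return dispersion_from_consensus(consensus)


def elbow_k(k_values: Sequence[int], errors: Sequence[float]) -> int:
    """Rank at the elbow of the reconstruction-error curve.

    Returns the ``k`` maximizing the discrete second difference
    ``e[i-1] - 2 e[i] + e[i+1]`` (ties -> smallest k).  A strictly linear
    decay has no elbow; the smallest ``k`` is returned with a warning.
    """
    k_values = list(k_values)
    errors = np.asarray(errors, dtype=float)
    if len(k_values) != len(errors) or len(k_values) < 3:
        raise ValueError("need errors for at least 3 aligned k values")
    curv = errors[:-2] - 2.0 * errors[1:-1] + errors[2:]
    if np.allclose(curv, 0.0):
        warnings.warn("error curve has no elbow (zero curvature); returning smallest k")
        return k_values[0]
    return k_values[1 + int(np.argmax(curv))]


def component_similarity_saturation(
    U_by_k: "dict[int, np.ndarray]",
    threshold: float = 0.95,
) -> tuple[int, bool]:
    """First rank whose endmember set contains two nearly collinear columns.

    Scans ranks in ascending order; returns ``(k, True)`` at the first
    ``k`` where the maximum pairwise cosine among columns of ``U`` reaches
    ``threshold``.  If no rank saturates, returns the largest scanned rank
    with ``False``.
    """
    if not U_by_k:
        raise ValueError("no fitted components supplied")
    ks = sorted(U_by_k)
    for k in ks:
        if max_pairwise_cosine(U_by_k[k]) >= threshold:
            return k, True
    return ks[-1], False


def max_pairwise_cosine(U: np.ndarray) -> float:
    """Largest cosine between distinct columns (0 for a single column)."""
    U = np.asarray(U, dtype=float)
    k = U.shape[1]
    if k < 2:
        return 0.0
    Un = U / np.maximum(np.linalg.norm(U, axis=0, keepdims=True), 1e-300)
    G = Un.T @ Un
    return float(G[~np.eye(k, dtype=bool)].max())


@dataclass
class RankScanResult:
    """Aligned diagnostics over a scanned range of ranks."""

    k_values: list[int]
    reconstruction_errors: np.ndarray
    dispersion_coefficients: np.ndarray
    max_component_similarities: np.ndarray
    chosen_k: int
    criterion: str
    saturation_k: Optional[int] = None
    models: dict = field(default_factory=dict, repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.k_values,
                "reconstruction_error": self.reconstruction_errors,
                "dispersion_coefficient": self.dispersion_coefficients,
                "max_component_similarity": self.max_component_similarities,
            }
        )

    def to_json(self) -> str:
        payload = {
            "k_values": self.k_values,
            "reconstruction_errors": list(map(float, self.reconstruction_errors)),
            "dispersion_coefficients": list(map(float, self.dispersion_coefficients)),
            "max_component_similarities": list(map(float, self.max_component_similarities)),
            "chosen_k": self.chosen_k,
            "criterion": self.criterion,
            "saturation_k": self.saturation_k,
        }
        return json.dumps(payload, indent=2)


def scan_k(
    X,
    k_range: Sequence[int],
    config: Optional[UnmixingConfig] = None,
    n_restarts: int = 10,
    seed: int = 0,
    saturation_threshold: float = 0.95,
) -> RankScanResult:
    """Run all three rank diagnostics over ``k_range``.

    For each rank: a seeded NMF fit (reconstruction error, endmember
    similarity) and a restart consensus (dispersion).  ``chosen_k`` follows
    the elbow criterion when three or more ranks are scanned (dispersion
    and saturation are reported alongside for the analyst); with fewer
    ranks the values are passed through and the best-error rank returned.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("empty k range")
    arr = X.X if hasattr(X, "X") else np.asarray(X)
    norm_X = float(np.linalg.norm(arr))
    n = arr.shape[1]
    errors, dispersions, sims = [], [], []
    U_by_k: dict[int, np.ndarray] = {}
    models: dict[int, FactorModel] = {}
    for k in ks:
        # one restart ensemble per rank serves both the consensus (all runs)
        # and the error curve (best run), so the curve is seed-best
        consensus = np.zeros((n, n))
        best_model, best_err = None, np.inf
        for r in range(max(n_restarts, 1)):
            cfg = (
                replace(config, k=k, seed=seed + r)
                if config is not None
                else UnmixingConfig(k=k, seed=seed + r, max_iter=300)
            )
            model = nmf(X, cfg)
            consensus += connectivity_matrix(model.V)
            err = float(np.linalg.norm(arr - reconstruct(model))) / max(norm_X, 1e-300)
            if err < best_err:
                best_model, best_err = model, err
        consensus /= max(n_restarts, 1)
        models[k] = best_model
        errors.append(best_err)
        sims.append(max_pairwise_cosine(best_model.U))
        U_by_k[k] = best_model.U
        dispersions.append(dispersion_from_consensus(consensus))
    sat_k, saturated = component_similarity_saturation(U_by_k, saturation_threshold)
    if len(ks) >= 3:
        chosen = elbow_k(ks, errors)
        criterion = "elbow"
    else:
        chosen = ks[int(np.argmin(errors))]
        criterion = "min-error (range too short for an elbow)"
    return RankScanResult(
        k_values=ks,
        reconstruction_errors=np.asarray(errors),
        dispersion_coefficients=np.asarray(dispersions),
        max_component_similarities=np.asarray(sims),
        chosen_k=chosen,
        criterion=criterion,
        saturation_k=sat_k if saturated else None,
        models=models,
    )
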