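"""Weighted nestedness as the spectral radius of a bipartite matrix.

A rectangular non-negative matrix B is embedded as the off-diagonal blocks
of the symmetric matrix [[0, B], [B^T, 0]]; the largest eigenvalue of that
embedding equals the largest singular value of B. Among matrices with the
same total weight, the spectral radius is maximised when weight concentrates
into a nested pattern, so rho serves as a weighted nestedness statistic that
is invariant to row/column permutation.

Significance is assessed against counterpart networks in which every CCI
layer is curveball-shuffled; the statistic matrix (e.g. the realized-niche
matrix R_c^a) is rebuilt per replicate, recomputing P_c from the shuffled
layers, and the one-tailed p-value is the fraction of null rho strictly
exceeding the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import MultilayerNetwork
from .niche import niche_table
from .nullmodels import empirical_pvalue, shuffle_network

__all__ = [
    "spectral_radius",
    "nestedness_test",
    "NestednessResult",
    "realized_niche_matrix",
    "specialization_matrix",
]


def spectral_radius(matrix) -> float:
    """Largest singular value of a non-negative rectangular matrix.

    Equals the largest eigenvalue of the symmetric bipartite embedding
    [[0, B], [B^T, 0]]. All-zero matrices have rho = 0.
    """
    B = np.asarray(matrix, dtype=float)
    if B.size == 0:
        return 0.0
    if not np.all(np.isfinite(B)):
        raise ValueError("spectral_radius requires finite entries")
    if np.any(B < 0):
        raise ValueError("spectral_radius requires non-negative entries")
    if not B.any():
        return 0.0
    return float(np.linalg.svd(B, compute_uv=False)[0])


def realized_niche_matrix(net: MultilayerNetwork) -> np.ndarray:
    """Chaperone × layer R_c^a matrix; isolated chaperones contribute zeros."""
    tab = niche_table(net)
    M = tab.realized_niche_matrix().reindex(index=net.chaperone_ids, columns=net.layer_ids)
    return np.nan_to_num(M.to_numpy(dtype=float), nan=0.0)


def specialization_matrix(net: MultilayerNetwork) -> np.ndarray:
    """Chaperone × layer S_c^a matrix."""
    tab = niche_table(net)
    M = tab.specialization_matrix().reindex(index=net.chaperone_ids, columns=net.layer_ids)
    return M.to_numpy(dtype=float)


@dataclass
class NestednessResult:
    rho_observed: float
    null_samples: np.ndarray
    p_value: float
    n_shuffles: int

    @property
    def significant(self) -> bool:
        return self.p_value <= 0.05


def nestedness_test(
    net: MultilayerNetwork,
    statistic_matrix_builder=realized_niche_matrix,
    n_shuffles: int = 1000,
    n_trades: int | None = None,
    seed=None,
) -> NestednessResult:
    """One-tailed nestedness significance against layer-shuffled counterparts.

    ``statistic_matrix_builder`` maps a network to the weighted matrix whose
    spectral radius is the statistic (default: the realized-niche matrix;
    P_c is recomputed for every shuffled replicate). p-value uses strict
    inequality: ties count toward non-significance.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    observed_matrix = np.asarray(statistic_matrix_builder(net), dtype=float)
    if not np.all(np.isfinite(observed_matrix)):
        raise ValueError("statistic matrix builder returned non-finite values")
    rho_obs = spectral_radius(observed_matrix)
    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffles)
    for s in range(n_shuffles):
        shuffled = shuffle_network(net, n_trades=n_trades, seed=rng)
        m = np.asarray(statistic_matrix_builder(shuffled), dtype=float)
        if not np.all(np.isfinite(m)):
            raise ValueError("statistic matrix builder returned non-finite values on a shuffle")
        null[s] = spectral_radius(m)
    return NestednessResult(
        rho_observed=rho_obs,
        null_samples=null,
        p_value=empirical_pvalue(rho_obs, null),
        n_shuffles=n_shuffles,
    )
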