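"""Niche statistics for multilayer chaperone-client networks.

For chaperone *c* with L_c^a links in layer (environment) *a*:

* P_c  — number of distinct clients across all layers (union size);
* S_c  = P_c / n_clients — specialization (generalist vs specialist);
* S_c^a = L_c^a / n_clients — environment-specific specialization;
* R_c^a = L_c^a / P_c — realized niche, the fraction of a chaperone's
  potential clients it actually services in one environment.

Similarity measures are Jaccard indices over client sets: J_c^{ab}
(same chaperone, two layers; its median over layer pairs is the partner
fidelity J_c) and J_xy^a (two chaperones inside one layer; low values mean
niche separation, high values redundancy).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import ExpressionMatrix, MultilayerNetwork

__all__ = [
    "NicheTable",
    "SimilarityTable",
    "niche_table",
    "partner_fidelity",
    "within_layer_overlap",
    "layer_similarity",
    "spearman_with_bonferroni",
    "expression_summary",
]


@dataclass
class NicheTable:
    """Per-chaperone niche statistics.

    ``per_chaperone`` columns: P_c, S_c. ``per_layer`` columns: one row per
    (chaperone, layer) with L_ca, S_ca, R_ca. Chaperones with P_c = 0 have
    NaN ratio fields and are listed in ``isolated``.
    """

    per_chaperone: pd.DataFrame
    per_layer: pd.DataFrame
    isolated: list[str]

    def realized_niche_matrix(self) -> pd.DataFrame:
        """Chaperone × layer matrix of R_ca (the weighted-nestedness input)."""
        return self.per_layer.pivot(index="chaperone", columns="layer", values="R_ca")

    def specialization_matrix(self) -> pd.DataFrame:
        """Chaperone × layer matrix of S_ca."""
        return self.per_layer.pivot(index="chaperone", columns="layer", values="S_ca")


@dataclass
class SimilarityTable:
    """Tidy Jaccard similarity tables.

    ``between_layers`` has one row per (chaperone, layer_a, layer_b) with
    J_c_ab; ``fidelity`` one row per chaperone with J_c (median over defined
    layer pairs); ``within_layer`` one row per (chaperone_x, chaperone_y,
    layer) with J_xy_a. Pairs of two empty client sets are undefined (NaN)
    and excluded from medians.
    """

    between_layers: pd.DataFrame | None = None
    fidelity: pd.DataFrame | None = None
    within_layer: pd.DataFrame | None = None


def _jaccard_from_counts(inter: np.ndarray, size_a: np.ndarray, size_b: np.ndarray) -> np.ndarray:
    union = size_a + size_b - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        j = np.where(union > 0, inter / np.where(union > 0, union, 1), np.nan)
    return j


def niche_table(net: MultilayerNetwork) -> NicheTable:
    """Compute P_c, S_c and the per-layer L_ca, S_ca, R_ca statistics."""
    A = net.incidence
    n_clients = net.n_clients
    L = A.sum(axis=1)  # chaperone × layer link counts
    union = (A.max(axis=2) > 0).sum(axis=1)  # P_c
    isolated = [c for c, p in zip(net.chaperone_ids, union) if p == 0]
    if isolated:
        warnings.warn(f"chaperones with no links in any layer: {isolated}", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        S_c = union / n_clients
        R = np.where(union[:, None] > 0, L / np.where(union[:, None] > 0, union[:, None], 1), np.nan)
    per_chap = pd.DataFrame(
        {"chaperone": net.chaperone_ids, "P_c": union, "S_c": S_c}
    )
    rows = []
    for i, c in enumerate(net.chaperone_ids):
        for a, lid in enumerate(net.layer_ids):
            rows.append(
                {
                    "chaperone": c,
                    "layer": lid,
                    "L_ca": int(L[i, a]),
                    "S_ca": L[i, a] / n_clients,
                    "R_ca": R[i, a],
                }
            )
    return NicheTable(per_chaperone=per_chap, per_layer=pd.DataFrame(rows), isolated=isolated)


def partner_fidelity(net: MultilayerNetwork) -> SimilarityTable:
    """J_c^{ab} for every chaperone × unordered layer pair, and J_c medians.

    With 15 chaperones and 12 layers this yields 66 layer pairs and 990
    J_c^{ab} values. Layer pairs where both client sets are empty are
    undefined and excluded from each chaperone's median.
    """
    if net.n_layers < 2:
        raise ValueError("partner_fidelity requires at least 2 layers")
    A = net.incidence
    rows = []
    for i, c in enumerate(net.chaperone_ids):
        M = A[i]  # clients × layers
        sizes = M.sum(axis=0)
        inter = M.T @ M  # layer × layer co-client counts
        for a in range(net.n_layers):
            for b in range(a + 1, net.n_layers):
                union = sizes[a] + sizes[b] - inter[a, b]
                j = inter[a, b] / union if union > 0 else np.nan
                rows.append(
                    {
                        "chaperone": c,
                        "layer_a": net.layer_ids[a],
                        "layer_b": net.layer_ids[b],
                        "J_c_ab": j,
                    }
                )
    between = pd.DataFrame(rows)
    fidelity = (
        between.groupby("chaperone", sort=False)["J_c_ab"]
        .median()  # NaN pairs excluded by pandas
        .rename("J_c")
        .reset_index()
    )
    return SimilarityTable(between_layers=between, fidelity=fidelity)


def within_layer_overlap(net: MultilayerNetwork) -> SimilarityTable:
    """J_xy^a for every unordered chaperone pair inside every layer.

    15 chaperones give 105 pairs per layer; 1260 values over 12 layers.
    """
    if net.n_chaperones < 2:
        raise ValueError("within_layer_overlap requires at least 2 chaperones")
    rows = []
    for a, lid in enumerate(net.layer_ids):
        M = net.incidence[:, :, a]
        sizes = M.sum(axis=1)
        inter = M @ M.T
        for x in range(net.n_chaperones):
            for y in range(x + 1, net.n_chaperones):
                union = sizes[x] + sizes[y] - inter[x, y]
                j = inter[x, y] / union if union > 0 else np.nan
                rows.append(
                    {
                        "chaperone_x": net.chaperone_ids[x],
                        "chaperone_y": net.chaperone_ids[y],
                        "layer": lid,
                        "J_xy_a": j,
                    }
                )
    return SimilarityTable(within_layer=pd.DataFrame(rows))


def layer_similarity(net: MultilayerNetwork) -> pd.DataFrame:
    """Layer × layer Jaccard similarity of whole edge sets ((chaperone, client) pairs)."""
    if net.n_layers < 2:
        raise ValueError("layer_similarity requires at least 2 layers")
    flat = net.incidence.reshape(-1, net.n_layers)
    sizes = flat.sum(axis=0)
    inter = flat.T @ flat
    sim = _jaccard_from_counts(inter, sizes[:, None], sizes[None, :])
    np.fill_diagonal(sim, 1.0)
    return pd.DataFrame(sim, index=net.layer_ids, columns=net.layer_ids)


def spearman_with_bonferroni(x_values, y_values, n_tests: int = 1):
    """Two-sided Spearman test with Bonferroni-corrected p = min(1, p * n_tests).

    Returns ``(rho, raw_p, corrected_p)``; rho is NaN for constant input.
    """
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("spearman_with_bonferroni requires equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("spearman: constant input vector, rho undefined", stacklevel=2)
        return float("nan"), float("nan"), float("nan")
    res = stats.spearmanr(x, y)
    corrected = min(1.0, float(res.pvalue) * n_tests)
    return float(res.statistic), float(res.pvalue), corrected


def expression_summary(expr_set, chaperone_ids) -> pd.DataFrame:
    """Per-chaperone, per-layer log10 of the median expression over samples.

    Zero medians cannot be log-transformed and are recorded as NaN.
    Returns a tidy frame with columns chaperone, layer, log10_median.
    """
    rows = []
    for expr in expr_set:
        if not isinstance(expr, ExpressionMatrix):
            raise TypeError("expression_summary expects ExpressionMatrix objects")
        idx = {g: i for i, g in enumerate(expr.gene_ids)}
        for c in chaperone_ids:
            if c not in idx:
                raise KeyError(f"chaperone {c!r} missing from expression matrix {expr.layer_id!r}")
            med = float(np.median(expr.values[idx[c]]))
            if med <= 0:
                warnings.warn(
                    f"chaperone {c!r} in layer {expr.layer_id!r}: zero median expression",
                    stacklevel=2,
                )
                val = float("nan")
            else:
                val = float(np.log10(med))
            rows.append({"chaperone": c, "layer": expr.layer_id, "log10_median": val})
    return pd.DataFrame(rows)
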