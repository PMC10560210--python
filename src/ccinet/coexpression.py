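"""Binary CCI layers from coexpression: Spearman + Bonferroni + bootstrap consensus.

A chaperone-client pair is an interaction candidate when its expression
profiles are significantly positively rank-correlated after Bonferroni
correction over all chaperone × client tests in the layer. To equalise
statistical power across environments with different cohort sizes, the
consensus procedure subsamples a fixed number of samples without
replacement many times and keeps a pair only if it is significant and
positive in at least a threshold fraction of attempts (the study defaults:
288 samples, 1000 attempts, 95%).

Spearman p-values use the t-distribution approximation (the same
large-sample form ``scipy.stats.spearmanr`` uses), computed vectorised over
the whole pair grid so the 1000-attempt bootstrap stays tractable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import ExpressionMatrix, MultilayerNetwork

__all__ = [
    "CorrelationResult",
    "correlate_layer",
    "bootstrap_consensus",
    "build_consensus_network",
    "consensus_edges",
]


@dataclass
class CorrelationResult:
    """Spearman rho/p grids over chaperones × clients, plus the thresholded calls."""

    chaperone_ids: list[str]
    client_ids: list[str]
    rho: np.ndarray
    pvalue: np.ndarray
    significant_positive: np.ndarray
    alpha: float
    n_tests: int


def _rank_rows(values: np.ndarray) -> np.ndarray:
    """Midrank-transform each row (ties share the average rank)."""
    return stats.rankdata(values, axis=1)


def _spearman_grid(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Spearman rho and two-sided p for every row of x against every row of y.

    x: (n_x, n_samples), y: (n_y, n_samples); returns (n_x, n_y) grids.
    Constant rows yield NaN.
    """
    n = x.shape[1]
    rx = _rank_rows(x)
    ry = _rank_rows(y)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean(axis=1, keepdims=True)
    sx = np.sqrt((rx**2).sum(axis=1))
    sy = np.sqrt((ry**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rx @ ry.T) / np.outer(sx, sy)
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)  # perfect monotone: t -> inf
    p = np.where(np.isnan(rho), np.nan, p)
    return rho, p


def correlate_layer(
    expr: ExpressionMatrix,
    chaperone_ids,
    client_ids,
    alpha: float = 0.05,
) -> CorrelationResult:
    """Spearman rho and Bonferroni-corrected significance for every pair.

    The correction family is all chaperone × client tests within the layer
    (m = 15 × 1142 = 17,130 at study scale). ``significant_positive`` marks
    pairs with rho > 0 and raw p < alpha / m. Pairs involving a
    constant-expression gene have undefined rho and are never significant.
    """
    chaperone_ids = list(chaperone_ids)
    client_ids = list(client_ids)
    if expr.n_samples < 3:
        raise ValueError("correlate_layer requires at least 3 samples")
    idx = {g: i for i, g in enumerate(expr.gene_ids)}
    missing = [g for g in chaperone_ids + client_ids if g not in idx]
    if missing:
        raise KeyError(f"genes missing from expression matrix: {missing[:5]}...")
    X = expr.values[[idx[g] for g in chaperone_ids]]
    Y = expr.values[[idx[g] for g in client_ids]]
    if np.any(np.ptp(X, axis=1) == 0) or np.any(np.ptp(Y, axis=1) == 0):
        warnings.warn("constant-expression gene(s): their pairs are non-significant", stacklevel=2)
    rho, p = _spearman_grid(X, Y)
    n_tests = len(chaperone_ids) * len(client_ids)
    sig = (rho > 0) & (p < alpha / n_tests)
    sig = np.where(np.isnan(rho), False, sig)
    return CorrelationResult(
        chaperone_ids=chaperone_ids,
        client_ids=client_ids,
        rho=rho,
        pvalue=p,
        significant_positive=sig.astype(np.int8),
        alpha=alpha,
        n_tests=n_tests,
    )


def consensus_edges(counts: np.ndarray, n_boot: int, consensus_threshold: float = 0.95) -> np.ndarray:
    """Edge iff called significant-positive in >= threshold of attempts.

    "At least": a pair hit in exactly ``threshold * n_boot`` attempts
    qualifies (950/1000 at 0.95 is an edge; 949/1000 is not).
    """
    return (np.asarray(counts) / n_boot >= consensus_threshold).astype(np.int8)


def bootstrap_consensus(
    expr: ExpressionMatrix,
    chaperone_ids,
    client_ids,
    n_subsample: int = 288,
    n_boot: int = 1000,
    consensus_threshold: float = 0.95,
    alpha: float = 0.05,
    seed=None,
) -> np.ndarray:
    """Sample-size-matched consensus incidence layer.

    Each attempt subsamples ``n_subsample`` samples without replacement and
    recomputes the Bonferroni-corrected significant-positive calls; a pair
    becomes an edge iff it is called in at least ``consensus_threshold`` of
    the attempts (0.95 exactly qualifies). Returns the binary
    chaperones × clients matrix.
    """
    if n_subsample > expr.n_samples:
        raise ValueError("n_subsample exceeds the number of samples")
    if n_subsample == expr.n_samples:
        warnings.warn("n_subsample equals the sample count: attempts are identical", stacklevel=2)
    rng = np.random.default_rng(seed)
    counts = np.zeros((len(list(chaperone_ids)), len(list(client_ids))), dtype=np.int32)
    chaperone_ids = list(chaperone_ids)
    client_ids = list(client_ids)
    for _ in range(n_boot):
        take = rng.choice(expr.n_samples, size=n_subsample, replace=False)
        sub = ExpressionMatrix(
            gene_ids=expr.gene_ids,
            sample_ids=[expr.sample_ids[t] for t in take],
            values=expr.values[:, take],
            layer_id=expr.layer_id,
        )
        res = correlate_layer(sub, chaperone_ids, client_ids, alpha=alpha)
        counts += res.significant_positive
    return consensus_edges(counts, n_boot, consensus_threshold)


def build_consensus_network(
    expr_set,
    chaperone_ids,
    client_ids,
    n_subsample: int | None = None,
    n_boot: int = 1000,
    consensus_threshold: float = 0.95,
    alpha: float = 0.05,
    seed=None,
) -> MultilayerNetwork:
    """Run the bootstrap consensus over every environment's expression matrix.

    ``n_subsample`` defaults to the smallest cohort size across layers, the
    study's power-matching rule. Per-layer RNG substreams spawn from one
    master seed, so layers can be rebuilt independently and reproducibly.
    """
    expr_set = list(expr_set)
    if n_subsample is None:
        n_subsample = min(e.n_samples for e in expr_set)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(expr_set))
    layers = []
    for expr, child in zip(expr_set, children):
        layers.append(
            bootstrap_consensus(
                expr,
                chaperone_ids,
                client_ids,
                n_subsample=n_subsample,
                n_boot=n_boot,
                consensus_threshold=consensus_threshold,
                alpha=alpha,
                seed=np.random.default_rng(child),
            )
        )
    incidence = np.stack(layers, axis=2)
    return MultilayerNetwork(
        chaperone_ids=list(chaperone_ids),
        client_ids=list(client_ids),
        layer_ids=[e.layer_id for e in expr_set],
        incidence=incidence,
    )
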