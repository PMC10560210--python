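"""Fixed-margin randomisation and permutation-test statistics.

The curveball algorithm randomises a binary matrix while preserving every
row and column sum exactly: it repeatedly picks two rows, pools the columns
held by exactly one of them, and deals that pool back at random keeping each
row's count. Margins are conserved by construction after every trade, which
makes the null highly conservative (degree sequences are never perturbed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import MultilayerNetwork

__all__ = [
    "curveball",
    "empirical_pvalue",
    "zscore",
    "shuffle_ensemble",
    "shuffle_network",
    "NullEnsemble",
]


def default_n_trades(n_rows: int) -> int:
    """Mixing heuristic: five trades per row."""
    return 5 * n_rows


def curveball(matrix: np.ndarray, n_trades: int | None = None, seed=None) -> np.ndarray:
    """Return a margin-preserving shuffle of a binary matrix.

    Each trade draws two distinct rows, finds the columns unique to each, and
    swaps a random subset between them (sizes preserved). ``n_trades``
    defaults to five times the row count. ``seed`` may be an int or a
    ``numpy.random.Generator``.
    """
    matrix = np.asarray(matrix)
    if not np.all(np.isin(matrix, [0, 1])):
        raise ValueError("curveball requires a binary matrix")
    n_rows = matrix.shape[0]
    if n_rows < 2:
        warnings.warn("curveball: fewer than 2 rows, returning matrix unchanged", stacklevel=2)
        return matrix.copy()
    rng = np.random.default_rng(seed)
    if n_trades is None:
        n_trades = default_n_trades(n_rows)
    # row-wise column sets; set ops dominate, cheap at CCI scale (15 rows)
    rows = [set(np.nonzero(matrix[i])[0].tolist()) for i in range(n_rows)]
    pairs = rng.integers(0, n_rows, size=(n_trades, 2))
    for a, b in pairs:
        if a == b:
            continue
        ra, rb = rows[a], rows[b]
        only_a = list(ra - rb)
        only_b = list(rb - ra)
        if not only_a or not only_b:
            continue
        pool = only_a + only_b
        rng.shuffle(pool)
        new_a = set(pool[: len(only_a)])
        new_b = set(pool[len(only_a):])
        rows[a] = (ra & rb) | new_a
        rows[b] = (ra & rb) | new_b
    out = np.zeros_like(matrix)
    for i, cols in enumerate(rows):
        out[i, list(cols)] = 1
    return out


def empirical_pvalue(observed: float, null_samples) -> float:
    """One-tailed permutation p: fraction of null samples strictly above observed.

    Ties count toward non-significance (strict inequality).
    """
    null_samples = np.asarray(null_samples, dtype=float)
    if null_samples.size == 0:
        raise ValueError("empirical_pvalue requires at least one null sample")
    return float(np.count_nonzero(null_samples > observed)) / null_samples.size


def zscore(observed: float, null_samples) -> float:
    """Standard score of the observed value against the null ensemble.

    Uses the sample (n-1) standard deviation. Significance at |z| > 1.96.
    Returns NaN (with a warning) when the null has zero spread.
    """
    null_samples = np.asarray(null_samples, dtype=float)
    if null_samples.size < 2:
        raise ValueError("zscore requires at least two null samples")
    sd = null_samples.std(ddof=1)
    if sd == 0:
        warnings.warn("zscore: null ensemble has zero SD, z undefined", stacklevel=2)
        return float("nan")
    return float((observed - null_samples.mean()) / sd)


def is_significant(z: float, threshold: float = 1.96) -> bool:
    return bool(np.isfinite(z) and abs(z) > threshold)


@dataclass
class NullEnsemble:
    """Curveball-shuffled network replicates plus optional derived statistics."""

    replicates: list[MultilayerNetwork]
    seed: int | None = None
    statistic_samples: dict[str, np.ndarray] | None = None

    def __len__(self) -> int:
        return len(self.replicates)

    def apply(self, statistic) -> np.ndarray:
        """Evaluate a scalar statistic on every replicate."""
        return np.asarray([statistic(rep) for rep in self.replicates], dtype=float)


def shuffle_network(net: MultilayerNetwork, n_trades: int | None = None, seed=None) -> MultilayerNetwork:
    """Shuffle every layer of a multilayer network independently."""
    rng = np.random.default_rng(seed)
    incidence = np.empty_like(net.incidence)
    for a in range(net.n_layers):
        incidence[:, :, a] = curveball(net.incidence[:, :, a], n_trades=n_trades, seed=rng)
    return MultilayerNetwork(
        chaperone_ids=list(net.chaperone_ids),
        client_ids=list(net.client_ids),
        layer_ids=list(net.layer_ids),
        incidence=incidence,
    )


def shuffle_ensemble(
    net: MultilayerNetwork,
    n_replicates: int = 1000,
    n_trades: int | None = None,
    seed=None,
) -> NullEnsemble:
    """Generate ``n_replicates`` independently shuffled counterpart networks."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    reps = [shuffle_network(net, n_trades=n_trades, seed=rng) for _ in range(n_replicates)]
    return NullEnsemble(replicates=reps, seed=seed if isinstance(seed, int) else None)
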