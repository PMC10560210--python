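"""Hold-out link prediction with the multilayer SBM, scored by AUC.

The hold-out unit is the adjacency *cell* (present and absent pairs alike):
the SBM likelihood ranges over all cells and ROC analysis needs negatives.
"5-fold with an 80% hold-out" is inverted cross-validation — the model is
fit on one fold (the visible 20%) and scored on the other four. Within-layer
prediction fits the focal layer alone; cross-layer prediction fits a
two-layer network of the focal layer's visible cells plus the complete
auxiliary layer, then scores the focal layer's masked cells by their fitted
expected-edge values M. K is fixed at 2, the BIC-selected group count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import MultilayerNetwork
from .sbm import expected_edges, fit_multitensor

__all__ = [
    "auc",
    "predict_within",
    "predict_cross",
    "prediction_grid",
    "PredictionResult",
]

# prediction needs score *rankings*, not a tightly converged likelihood, so
# the per-fold fits use fewer, looser EM runs than model selection does
DEFAULT_MODEL_PARAMS = {"K": 2, "n_restarts": 2, "max_iter": 150, "tolerance": 1e-3}


def auc(scores_for_positives, scores_for_negatives) -> float:
    """Probability a random positive outscores a random negative; ties count half."""
    pos = np.asarray(scores_for_positives, dtype=float)
    neg = np.asarray(scores_for_negatives, dtype=float)
    if pos.size == 0 or neg.size == 0:
        warnings.warn("auc: empty score group, undefined", stacklevel=2)
        return float("nan")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    return float((r_pos - pos.size * (pos.size + 1) / 2.0) / (pos.size * neg.size))


def _fold_masks(n_cells: int, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Partition cell indices into folds; fold f's array holds its cell indices."""
    perm = rng.permutation(n_cells)
    return [perm[f::n_folds] for f in range(n_folds)]


def _run_holdout(
    net: MultilayerNetwork,
    target_idx: int,
    layer_indices: list[int],
    model_params: dict,
    n_reps: int,
    n_folds: int,
    rng: np.random.Generator,
) -> float:
    """Mean AUC over reps × folds; in each fold one fifth of the target layer's
    cells is visible and the rest is masked out of the likelihood."""
    sub = net.subset_layers([net.layer_ids[i] for i in layer_indices])
    t = layer_indices.index(target_idx)
    A_target = net.incidence[:, :, target_idx]
    n_cells = A_target.size
    aucs = []
    for _ in range(n_reps):
        folds = _fold_masks(n_cells, n_folds, rng)
        for visible_cells in folds:
            mask = np.ones_like(sub.incidence, dtype=bool)
            tmask = np.zeros(n_cells, dtype=bool)
            tmask[visible_cells] = True
            mask[:, :, t] = tmask.reshape(A_target.shape)
            model = fit_multitensor(sub, mask=mask, seed=rng, **model_params)
            M = expected_edges(model)[:, :, t]
            heldout = ~mask[:, :, t]
            scores = M[heldout]
            labels = A_target[heldout]
            if labels.sum() == 0 or labels.sum() == labels.size:
                warnings.warn("fold without both classes among masked cells, skipped", stacklevel=2)
                continue
            aucs.append(auc(scores[labels == 1], scores[labels == 0]))
    return float(np.mean(aucs)) if aucs else float("nan")


def predict_within(
    net: MultilayerNetwork,
    target_layer: str,
    model_params: dict | None = None,
    n_reps: int = 20,
    n_folds: int = 5,
    seed=None,
) -> float:
    """Mean AUC for recovering a layer's masked cells from its visible 20%."""
    params = dict(DEFAULT_MODEL_PARAMS, **(model_params or {}))
    rng = np.random.default_rng(seed)
    ti = net.layer_ids.index(target_layer)
    return _run_holdout(net, ti, [ti], params, n_reps, n_folds, rng)


def predict_cross(
    net: MultilayerNetwork,
    target_layer: str,
    auxiliary_layer: str,
    model_params: dict | None = None,
    n_reps: int = 20,
    n_folds: int = 5,
    seed=None,
) -> float:
    """Mean AUC for a layer's masked cells given its visible 20% plus a full
    auxiliary layer (a two-layer fit)."""
    if target_layer == auxiliary_layer:
        raise ValueError("target and auxiliary layers must differ")
    params = dict(DEFAULT_MODEL_PARAMS, **(model_params or {}))
    rng = np.random.default_rng(seed)
    ti = net.layer_ids.index(target_layer)
    ai = net.layer_ids.index(auxiliary_layer)
    return _run_holdout(net, ti, [ti, ai], params, n_reps, n_folds, rng)


@dataclass
class PredictionResult:
    """Layer × layer AUC grid; rows are the predicted layer, columns the helper."""

    auc_matrix: pd.DataFrame
    n_repetitions: int
    n_folds: int
    per_cell: dict = field(default_factory=dict)

    @property
    def within_values(self) -> np.ndarray:
        return np.diag(self.auc_matrix.to_numpy())

    @property
    def cross_values(self) -> np.ndarray:
        m = self.auc_matrix.to_numpy()
        return m[~np.eye(m.shape[0], dtype=bool)]


def prediction_grid(
    net: MultilayerNetwork,
    model_params: dict | None = None,
    n_reps: int = 20,
    n_folds: int = 5,
    seed=None,
) -> PredictionResult:
    """Full grid: diagonal from within-layer, off-diagonal from cross-layer prediction."""
    if net.n_layers < 2:
        raise ValueError("prediction_grid requires at least 2 layers")
    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(net.n_layers * net.n_layers))
    L = net.n_layers
    out = np.full((L, L), np.nan)
    for i, target in enumerate(net.layer_ids):
        for j, aux in enumerate(net.layer_ids):
            child = next(children)
            if i == j:
                out[i, j] = predict_within(
                    net, target, model_params, n_reps, n_folds, seed=np.random.default_rng(child)
                )
            else:
                out[i, j] = predict_cross(
                    net, target, aux, model_params, n_reps, n_folds, seed=np.random.default_rng(child)
                )
    return PredictionResult(
        auc_matrix=pd.DataFrame(out, index=net.layer_ids, columns=net.layer_ids),
        n_repetitions=n_reps,
        n_folds=n_folds,
    )
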