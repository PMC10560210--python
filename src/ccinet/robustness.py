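"""Co-extinction robustness of CCI layers to sequential chaperone removal.

Chaperones are removed one at a time; a client goes co-extinct when its last
connected chaperone is removed. The extinction curve tracks the fraction of
initially-connected clients still connected after each removal, sampled at
k/N for k = 0..N, and the robustness score T is the trapezoidal area under
it (T near 1: the network tolerates removals; near 0: immediate collapse).

Four removal orders mirror attack-tolerance analysis: (1) most-to-least
connected; (2)/(3) most-to-least connected within one SBM module then the
other; (4) uniformly random, the benchmark. Degrees are the static initial
degrees; ties break by identifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MultilayerNetwork
from .niche import NicheTable, spearman_with_bonferroni

__all__ = [
    "ExtinctionCurve",
    "removal_order",
    "simulate_extinctions",
    "robustness_T",
    "robustness_suite",
    "correlate_T_with_niche",
    "SCENARIOS",
]

SCENARIOS = ("degree", "module_first_A", "module_first_B", "random")


@dataclass
class ExtinctionCurve:
    scenario: str
    removal_order: list[str]
    x: np.ndarray  # fraction of chaperones removed, 0..1
    y: np.ndarray  # fraction of initially-connected clients surviving
    T: float | None = None


def _degree_sorted(chaperone_ids, degrees, subset=None):
    """Identifiers sorted by descending degree, ties by identifier."""
    items = [
        (c, d) for c, d in zip(chaperone_ids, degrees) if subset is None or c in subset
    ]
    return [c for c, _ in sorted(items, key=lambda cd: (-cd[1], cd[0]))]


def _module_sets(chaperone_ids, group_labels):
    """Modules ordered by descending size, ties by lowest member identifier."""
    labels = np.asarray(group_labels)
    groups = {}
    for c, g in zip(chaperone_ids, labels):
        groups.setdefault(int(g), []).append(c)
    ordered = sorted(groups.values(), key=lambda members: (-len(members), min(members)))
    return ordered


def removal_order(
    layer: np.ndarray,
    chaperone_ids,
    scenario: str,
    group_labels=None,
    seed=None,
) -> list[str]:
    """Chaperone removal sequence for one scenario.

    ``layer`` is the chaperone × client incidence of one environment;
    degrees are its row sums. Modular scenarios walk module A (or B) in
    degree order, then the other module; they require SBM hard labels.
    """
    chaperone_ids = list(chaperone_ids)
    degrees = np.asarray(layer).sum(axis=1)
    if scenario == "degree":
        return _degree_sorted(chaperone_ids, degrees)
    if scenario in ("module_first_A", "module_first_B"):
        if group_labels is None:
            raise ValueError(f"scenario {scenario!r} requires SBM group labels")
        modules = _module_sets(chaperone_ids, group_labels)
        if scenario == "module_first_B":
            modules = list(reversed(modules))
        order: list[str] = []
        for members in modules:
            order.extend(_degree_sorted(chaperone_ids, degrees, subset=set(members)))
        return order
    if scenario == "random":
        rng = np.random.default_rng(seed)
        return [chaperone_ids[i] for i in rng.permutation(len(chaperone_ids))]
    raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")


def simulate_extinctions(layer: np.ndarray, chaperone_ids, order, scenario: str = "") -> ExtinctionCurve:
    """Sequential removal along ``order``; returns the extinction curve.

    y(k/N) is the number of clients with >= 1 remaining link divided by the
    number of clients with >= 1 link initially; y is non-increasing and
    y(1) = 0.
    """
    layer = np.asarray(layer)
    chaperone_ids = list(chaperone_ids)
    if sorted(order) != sorted(chaperone_ids):
        raise ValueError("order must be a permutation of the chaperones")
    if not layer.any():
        raise ValueError("layer has no links; nothing to collapse")
    n = len(chaperone_ids)
    idx = {c: i for i, c in enumerate(chaperone_ids)}
    support = layer.sum(axis=0).astype(int)  # remaining chaperones per client
    initially_connected = int(np.count_nonzero(support))
    y = np.empty(n + 1)
    y[0] = 1.0
    for k, c in enumerate(order, start=1):
        support = support - layer[idx[c]]
        y[k] = np.count_nonzero(support) / initially_connected
    x = np.arange(n + 1) / n
    return ExtinctionCurve(scenario=scenario, removal_order=list(order), x=x, y=y)


def robustness_T(curve: ExtinctionCurve) -> float:
    """Trapezoidal area under the extinction curve on its k/N grid."""
    return float(np.trapezoid(curve.y, curve.x))


def robustness_suite(
    net: MultilayerNetwork,
    group_labels,
    n_random_reps: int = 100,
    seed=None,
) -> pd.DataFrame:
    """T for every layer × scenario; the random scenario averages replicates.

    Returns a tidy frame with columns layer, scenario, T, T_sd (SD only for
    the random scenario).
    """
    if n_random_reps < 1:
        raise ValueError("n_random_reps must be >= 1")
    ss = np.random.SeedSequence(seed)
    layer_seeds = ss.spawn(net.n_layers)
    rows = []
    for a, lid in enumerate(net.layer_ids):
        layer = net.incidence[:, :, a]
        for scenario in ("degree", "module_first_A", "module_first_B"):
            order = removal_order(layer, net.chaperone_ids, scenario, group_labels=group_labels)
            T = robustness_T(simulate_extinctions(layer, net.chaperone_ids, order, scenario))
            rows.append({"layer": lid, "scenario": scenario, "T": T, "T_sd": np.nan})
        rng = np.random.default_rng(layer_seeds[a])
        Ts = []
        for _ in range(n_random_reps):
            order = removal_order(layer, net.chaperone_ids, "random", seed=rng)
            Ts.append(robustness_T(simulate_extinctions(layer, net.chaperone_ids, order, "random")))
        Ts = np.asarray(Ts)
        rows.append(
            {
                "layer": lid,
                "scenario": "random",
                "T": float(Ts.mean()),
                "T_sd": float(Ts.std(ddof=1)) if len(Ts) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def correlate_T_with_niche(T_table: pd.DataFrame, niche: NicheTable) -> pd.DataFrame:
    """Per-scenario two-tailed Spearman of layer-mean realized niche vs T.

    A positive correlation means environments letting chaperones realise
    more of their potential clients are also more robust to removal.
    """
    mean_R = niche.per_layer.groupby("layer", sort=False)["R_ca"].mean()
    layers = list(mean_R.index)
    if len(layers) < 3:
        raise ValueError("correlate_T_with_niche requires at least 3 layers")
    rows = []
    for scenario, sub in T_table.groupby("scenario", sort=False):
        t_by_layer = sub.set_index("layer")["T"].reindex(layers)
        rho, p_raw, _ = spearman_with_bonferroni(mean_R.to_numpy(), t_by_layer.to_numpy(), n_tests=1)
        rows.append({"scenario": scenario, "rho": rho, "p": p_raw})
    return pd.DataFrame(rows)
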