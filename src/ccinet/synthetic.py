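"""Synthetic inputs with the statistical structure the analysis assumes.

Three generators:

* :func:`generate_sbm_multilayer` plants an overlapping block structure and
  draws each edge Bernoulli(min(1, M)) from the bilinear expected-edge form,
  emulating multilayer CCI networks (small chaperone set, large client set,
  shared node identities across layers).
* :func:`generate_expression` builds FPKM-like expression matrices whose
  pairwise rank correlations encode a planted network: each chaperone gets a
  latent per-sample signal, linked clients are noisy monotone transforms of
  it, and the noise is calibrated so linked pairs reach a target Spearman
  correlation.
* :func:`generate_nested_matrix` / :func:`generate_nested_multilayer` build
  perfectly nested weight patterns, and a multilayer network whose
  realized-niche matrix carries that pattern, for nestedness testing.

All generators are deterministic given a seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import ExpressionMatrix, MultilayerNetwork

__all__ = [
    "PlantedTruth",
    "generate_sbm_multilayer",
    "generate_expression",
    "generate_nested_matrix",
    "generate_nested_multilayer",
]

logger = logging.getLogger(__name__)


@dataclass
class PlantedTruth:
    """Ground-truth parameters behind a generated network."""

    true_memberships_u: np.ndarray  # chaperones × K, rows sum to 1
    true_memberships_v: np.ndarray  # clients × K, rows sum to 1
    true_affinities_w: np.ndarray  # K × K × L, >= 0
    planted_network: MultilayerNetwork

    @property
    def hard_labels_u(self) -> np.ndarray:
        return np.argmax(self.true_memberships_u, axis=1)

    @property
    def hard_labels_v(self) -> np.ndarray:
        return np.argmax(self.true_memberships_v, axis=1)


def _ids(prefix: str, n: int) -> list[str]:
    width = len(str(n - 1)) if n > 1 else 1
    return [f"{prefix}{i:0{width}d}" for i in range(n)]


def generate_sbm_multilayer(
    n_chaperones: int = 15,
    n_clients: int = 1000,
    n_layers: int = 12,
    K: int = 2,
    affinity_contrast: float = 10.0,
    membership_concentration: float = 0.05,
    seed=None,
    mean_density: float = 0.2,
    share_affinities: bool = True,
    affinity_layer_noise: float = 0.0,
) -> tuple[MultilayerNetwork, PlantedTruth]:
    """Draw a multilayer bipartite network from a planted mixed-membership SBM.

    Memberships come from a symmetric Dirichlet(``membership_concentration``);
    small concentrations give near-hard group assignments. Affinities put a
    within-group rate ``contrast`` times the between-group rate, scaled so the
    expected edge density is ``mean_density``. With ``share_affinities`` every
    layer reuses the same affinity matrix (high cross-layer link fidelity);
    otherwise each layer perturbs it by a lognormal factor of spread
    ``affinity_layer_noise`` (or resamples when noise is large). Edges are
    Bernoulli(min(1, M)); any clipping is counted and logged.
    """
    if min(n_chaperones, n_clients, n_layers) < 1:
        raise ValueError("network dimensions must be >= 1")
    if K < 1:
        raise ValueError("K must be >= 1")
    if affinity_contrast < 1:
        raise ValueError("affinity_contrast must be >= 1")
    rng = np.random.default_rng(seed)
    alpha = np.full(K, membership_concentration)
    u = rng.dirichlet(alpha, size=n_chaperones)
    v = rng.dirichlet(alpha, size=n_clients)

    # Solve the within rate so that the average expected edge equals
    # mean_density for balanced memberships: the same-group pair mass is
    # roughly 1/K, rest is between-group at rate within/contrast.
    between_frac = 1.0 - 1.0 / K
    within = mean_density / (1.0 / K + between_frac / affinity_contrast)
    base = np.full((K, K), within / affinity_contrast)
    np.fill_diagonal(base, within)
    w = np.empty((K, K, n_layers))
    for a in range(n_layers):
        if share_affinities or affinity_layer_noise == 0.0:
            w[:, :, a] = base
        else:
            w[:, :, a] = base * rng.lognormal(0.0, affinity_layer_noise, size=(K, K))

    M = np.einsum("ik,jl,kla->ija", u, v, w, optimize=True)
    clipped = int(np.count_nonzero(M > 1.0))
    if clipped:
        logger.info("generate_sbm_multilayer: clipped %d expected-edge values above 1", clipped)
    P = np.minimum(M, 1.0)
    incidence = (rng.random(P.shape) < P).astype(np.int8)

    net = MultilayerNetwork(
        chaperone_ids=_ids("chap", n_chaperones),
        client_ids=_ids("cli", n_clients),
        layer_ids=_ids("env", n_layers),
        incidence=incidence,
    )
    truth = PlantedTruth(
        true_memberships_u=u,
        true_memberships_v=v,
        true_affinities_w=w,
        planted_network=net,
    )
    return net, truth


def generate_expression(
    planted_network: MultilayerNetwork,
    n_samples_per_layer: int = 300,
    signal_rho: float = 0.9,
    noise_sd: float = 1.0,
    seed=None,
) -> list[ExpressionMatrix]:
    """Expression matrices whose rank correlations encode a planted network.

    Per layer, chaperone c gets a latent standard-normal per-sample signal
    z_c; its observed expression is exp(z_c) (monotone, so Spearman against
    the latent is preserved; exp gives FPKM-like positive skew). A client
    linked to chaperones C is a * sum_{c in C} z_c + noise_sd * eps with
    ``a`` calibrated so a singly-linked pair has Spearman correlation
    ``signal_rho`` (via the bivariate-normal identity
    rho_s = (6/pi) arcsin(r/2)). Clients linked to several chaperones use
    the summed signal, a documented behaviour, so their per-chaperone
    correlation is somewhat below the target. Unlinked clients are
    independent noise.
    """
    if not (0 < signal_rho < 1):
        raise ValueError("signal_rho must be in (0, 1)")
    if n_samples_per_layer < 10:
        raise ValueError("n_samples_per_layer must be >= 10")
    rng = np.random.default_rng(seed)
    # target Pearson correlation on the latent normal scale
    r = 2.0 * np.sin(np.pi * signal_rho / 6.0)
    a = noise_sd * r / np.sqrt(1.0 - r * r)
    out: list[ExpressionMatrix] = []
    gene_ids = list(planted_network.chaperone_ids) + list(planted_network.client_ids)
    for li, lid in enumerate(planted_network.layer_ids):
        A = planted_network.incidence[:, :, li]
        z = rng.standard_normal((planted_network.n_chaperones, n_samples_per_layer))
        eps = rng.standard_normal((planted_network.n_clients, n_samples_per_layer))
        # normalise summed signals to unit variance so calibration holds per link
        deg = A.sum(axis=0)
        signal = A.T @ z
        scale = np.sqrt(np.maximum(deg, 1))[:, None]
        client_latent = a * signal / scale + noise_sd * eps
        values = np.vstack([np.exp(z), np.exp(client_latent)])
        out.append(
            ExpressionMatrix(
                gene_ids=gene_ids,
                sample_ids=[f"{lid}_s{t}" for t in range(n_samples_per_layer)],
                values=values,
                layer_id=lid,
            )
        )
    return out


def generate_nested_matrix(n_rows: int, n_cols: int, fill: float = 1.0) -> np.ndarray:
    """Perfectly nested weighted matrix: each row's support contains the next's.

    Row i occupies a prefix of the columns whose length shrinks with i
    (longest prefix has length ``round(fill * n_cols)``); weights decay
    smoothly toward the lower-right so the pattern is nested across rows and
    columns alike. ``fill=1`` with square shape gives the dense staircase
    covering the upper-left triangle and above.
    """
    if not (0 < fill <= 1):
        raise ValueError("fill must be in (0, 1]")
    M = np.zeros((n_rows, n_cols))
    max_len = max(1, round(fill * n_cols))
    for i in range(n_rows):
        length = max(1, round(max_len * (n_rows - i) / n_rows))
        cols = np.arange(length)
        M[i, cols] = (n_rows - i) / n_rows * (n_cols - cols) / n_cols
    return M


def generate_nested_multilayer(
    n_chaperones: int = 15,
    n_clients: int = 400,
    n_layers: int = 8,
    fill: float = 1.0,
    pool_fraction: float = 0.5,
    seed=0,
) -> MultilayerNetwork:
    """Multilayer network whose realized-niche matrix carries a nested pattern.

    Each chaperone gets a fixed random pool of potential clients
    (``pool_fraction`` of all clients); in layer a it realises a random
    subset of that pool of size L_ca = round(f_ca * pool), with the f
    fractions from :func:`generate_nested_matrix` (chaperones × layers).
    The union P_c stays close to the pool size, so R_ca = L_ca / P_c
    inherits the nested weight pattern. Curveball shuffling preserves every
    L_ca but scatters clients over the whole client set, inflating P_c and
    shrinking R row-wise — exactly the contrast the nestedness test detects.
    Realised subsets are drawn independently per layer so layers are not
    themselves nested and the fixed-margin null class is non-trivial.
    """
    if not (0 < pool_fraction <= 1):
        raise ValueError("pool_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    f = generate_nested_matrix(n_chaperones, n_layers, fill=fill)
    pool_size = max(2, round(pool_fraction * n_clients))
    incidence = np.zeros((n_chaperones, n_clients, n_layers), dtype=np.int8)
    for i in range(n_chaperones):
        pool = rng.choice(n_clients, size=pool_size, replace=False)
        for a in range(n_layers):
            L = max(1, round(f[i, a] * pool_size))
            chosen = rng.choice(pool, size=L, replace=False)
            incidence[i, chosen, a] = 1
    return MultilayerNetwork(
        chaperone_ids=_ids("chap", n_chaperones),
        client_ids=_ids("cli", n_clients),
        layer_ids=_ids("env", n_layers),
        incidence=incidence,
    )
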