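"""Multilayer mixed-membership stochastic block model for bipartite networks.

Each chaperone i carries an outgoing membership vector u_i over K groups,
each client j an incoming vector v_j, and each layer a a K × K affinity
matrix w^(a). The expected number of edges from i to j in layer a is the
bilinear form

    M_ij^(a) = sum_{k,l} u_ik * v_jl * w_kl^(a),

and the binary adjacency is treated as Poisson counts with mean M, giving
the log-likelihood sum_{a,i,j} [A_ij^(a) log M_ij^(a) - M_ij^(a)] (constant
terms dropped). Directing links from chaperones to clients realises the
bipartite constraint: within-set link probabilities are structurally zero.

Fitting is by multiplicative expectation-maximisation block updates (the
same fixed-point form as KL non-negative tensor factorisation), which never
decrease the likelihood. An optional boolean mask restricts the likelihood
to a subset of adjacency cells, which is what hold-out link prediction
needs: masked cells contribute nothing to the fit, and their fitted M is
the prediction score.

Model selection over K uses BIC = -2 logL + p log n with p =
K (n_chaperones + n_clients) + K^2 L free parameters and n the number of
observed adjacency cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import MultilayerNetwork

__all__ = [
    "MembershipModel",
    "expected_edges",
    "fit_multitensor",
    "select_K",
    "hard_assignments",
    "coassignment_agreement",
]

_EPS = 1e-12


@dataclass
class MembershipModel:
    """Fitted mixed-membership parameters for one K."""

    u: np.ndarray  # chaperones × K
    v: np.ndarray  # clients × K
    w: np.ndarray  # K × K × layers
    K: int
    log_likelihood: float
    BIC: float
    n_restarts: int
    converged: bool
    chaperone_ids: list[str] = field(default_factory=list)
    client_ids: list[str] = field(default_factory=list)
    layer_ids: list[str] = field(default_factory=list)
    loglik_trace: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "log_likelihood": self.log_likelihood,
            "BIC": self.BIC,
            "converged": self.converged,
            "n_restarts": self.n_restarts,
            "u": self.u.tolist(),
            "v": self.v.tolist(),
            "w": self.w.tolist(),
            "chaperone_ids": self.chaperone_ids,
            "client_ids": self.client_ids,
            "layer_ids": self.layer_ids,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MembershipModel":
        return cls(
            u=np.asarray(d["u"], dtype=float),
            v=np.asarray(d["v"], dtype=float),
            w=np.asarray(d["w"], dtype=float),
            K=int(d["K"]),
            log_likelihood=float(d["log_likelihood"]),
            BIC=float(d["BIC"]),
            n_restarts=int(d.get("n_restarts", 0)),
            converged=bool(d.get("converged", True)),
            chaperone_ids=list(d.get("chaperone_ids", [])),
            client_ids=list(d.get("client_ids", [])),
            layer_ids=list(d.get("layer_ids", [])),
        )


def expected_edges(model: MembershipModel) -> np.ndarray:
    """Expected-edge tensor M (chaperones × clients × layers) from the bilinear form."""
    return _expected(model.u, model.v, model.w)


def _expected(u: np.ndarray, v: np.ndarray, w: np.ndarray) -> np.ndarray:
    # M[i,j,a] = sum_kl u[i,k] v[j,l] w[k,l,a]
    return np.einsum("ik,jl,kla->ija", u, v, w, optimize=True)


def _loglik(A: np.ndarray, M: np.ndarray, mask: np.ndarray | None) -> float:
    Mc = np.maximum(M, _EPS)
    ll = A * np.log(Mc) - M
    if mask is not None:
        ll = ll * mask
    return float(ll.sum())


def _em_run(
    A: np.ndarray,
    K: int,
    mask: np.ndarray | None,
    rng: np.random.Generator,
    tolerance: float,
    max_iter: int,
    check_every: int,
):
    n_i, n_j, n_l = A.shape
    u = rng.uniform(0.1, 1.0, size=(n_i, K))
    v = rng.uniform(0.1, 1.0, size=(n_j, K))
    w = rng.uniform(0.1, 1.0, size=(K, K, n_l))
    Am = A * mask if mask is not None else A
    trace = []
    converged = False
    last_ll = -np.inf
    for it in range(max_iter):
        # --- update u ---
        M = np.maximum(_expected(u, v, w), _EPS)
        R = Am / M
        num = u * np.einsum("ija,jl,kla->ik", R, v, w, optimize=True)
        if mask is None:
            den = np.einsum("jl,kla->ka", v, w, optimize=True).sum(axis=1)[None, :]
        else:
            den = np.einsum("ija,jl,kla->ik", mask, v, w, optimize=True)
        u = num / np.maximum(den, _EPS)
        # --- update v ---
        M = np.maximum(_expected(u, v, w), _EPS)
        R = Am / M
        num = v * np.einsum("ija,ik,kla->jl", R, u, w, optimize=True)
        if mask is None:
            den = np.einsum("ik,kla->la", u, w, optimize=True).sum(axis=1)[None, :]
        else:
            den = np.einsum("ija,ik,kla->jl", mask, u, w, optimize=True)
        v = num / np.maximum(den, _EPS)
        # --- update w ---
        M = np.maximum(_expected(u, v, w), _EPS)
        R = Am / M
        num = w * np.einsum("ija,ik,jl->kla", R, u, v, optimize=True)
        if mask is None:
            den = (u.sum(axis=0)[:, None] * v.sum(axis=0)[None, :])[:, :, None]
            den = np.broadcast_to(den, w.shape)
        else:
            den = np.einsum("ija,ik,jl->kla", mask, u, v, optimize=True)
        w = num / np.maximum(den, _EPS)

        if (it + 1) % check_every == 0 or it == max_iter - 1:
            ll = _loglik(A, _expected(u, v, w), mask)
            trace.append(ll)
            if np.isfinite(last_ll) and abs(ll - last_ll) < tolerance:
                converged = True
                break
            last_ll = ll
    final_ll = _loglik(A, _expected(u, v, w), mask)
    return u, v, w, final_ll, converged, np.asarray(trace)


def fit_multitensor(
    net: MultilayerNetwork,
    K: int,
    n_restarts: int = 10,
    tolerance: float = 1e-6,
    max_iter: int = 500,
    seed=None,
    mask: np.ndarray | None = None,
    check_every: int = 10,
) -> MembershipModel:
    """Fit the K-group multilayer mixed-membership SBM by EM.

    Keeps the best of ``n_restarts`` random initialisations; convergence is
    declared when the log-likelihood improves by less than ``tolerance``
    between checks (every ``check_every`` iterations). ``mask`` is an
    optional boolean tensor the shape of the adjacency selecting the cells
    the likelihood sees (hold-out support).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    A = np.asarray(net.incidence, dtype=float)
    if A.size == 0 or not A.any():
        raise ValueError("cannot fit an SBM to an empty network")
    if mask is not None:
        mask = np.asarray(mask, dtype=float)
        if mask.shape != A.shape:
            raise ValueError("mask shape must match incidence shape")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        u, v, w, ll, conv, trace = _em_run(A, K, mask, rng, tolerance, max_iter, check_every)
        if best is None or ll > best[3]:
            best = (u, v, w, ll, conv, trace)
    u, v, w, ll, conv, trace = best
    if not conv:
        warnings.warn(f"EM did not converge within {max_iter} iterations (K={K})", stacklevel=2)
    n_obs = int(mask.sum()) if mask is not None else A.size
    p = K * (net.n_chaperones + net.n_clients) + K * K * net.n_layers
    bic = -2.0 * ll + p * np.log(n_obs)
    return MembershipModel(
        u=u,
        v=v,
        w=w,
        K=K,
        log_likelihood=ll,
        BIC=float(bic),
        n_restarts=n_restarts,
        converged=conv,
        chaperone_ids=list(net.chaperone_ids),
        client_ids=list(net.client_ids),
        layer_ids=list(net.layer_ids),
        loglik_trace=trace,
    )


def select_K(
    net: MultilayerNetwork,
    K_min: int = 2,
    K_max: int = 15,
    seed=None,
    **fit_params,
):
    """Fit every K in [K_min, K_max] and return (lowest-BIC model, BIC trace).

    The trace is a list of (K, BIC, log_likelihood) tuples in K order.
    """
    if K_min > K_max:
        raise ValueError("K_min must be <= K_max")
    rng = np.random.default_rng(seed)
    trace = []
    best = None
    for K in range(K_min, K_max + 1):
        model = fit_multitensor(net, K, seed=rng, **fit_params)
        trace.append((K, model.BIC, model.log_likelihood))
        if best is None or model.BIC < best.BIC:
            best = model
    return best, trace


def hard_assignments(model: MembershipModel, side: str = "chaperones") -> np.ndarray:
    """Single-group labels: argmax of the normalised membership vector.

    Ties break toward the lowest group index; all-zero rows get label -1
    with a warning.
    """
    m = model.u if side == "chaperones" else model.v
    totals = m.sum(axis=1)
    labels = np.argmax(m, axis=1)
    dead = totals <= 0
    if dead.any():
        warnings.warn(f"{int(dead.sum())} node(s) have all-zero membership, left unassigned", stacklevel=2)
        labels = labels.copy()
        labels[dead] = -1
    return labels


def coassignment_agreement(labels_a, labels_b) -> float:
    """Fraction of node pairs on which two hard partitions agree.

    A pair agrees when both partitions place it in the same group or both
    place it in different groups; invariant to label permutation.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length label vectors of length >= 2")
    same_a = a[:, None] == a[None, :]
    same_b = b[:, None] == b[None, :]
    iu = np.triu_indices(a.size, k=1)
    return float(np.mean(same_a[iu] == same_b[iu]))
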