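"""Independent brute-force oracles used across the test suite.

These implement the defining summations literally on a general graph
container (networkx), independent of the package's vectorized paths.
"""

from __future__ import annotations

import numpy as np
import networkx as nx


def graph_from_Z(Z: np.ndarray) -> nx.Graph:
    """Weighted undirected graph with node 0 = ego, 1..n = alters."""
    G = nx.Graph()
    n1 = Z.shape[0]
    G.add_nodes_from(range(n1))
    for i in range(n1):
        for j in range(i + 1, n1):
            if Z[i, j] > 0:
                G.add_edge(i, j, weight=float(Z[i, j]))
    return G


def _z(G: nx.Graph, i: int, j: int) -> float:
    return G.edges[i, j]["weight"] if G.has_edge(i, j) else 0.0


def _p(G: nx.Graph, i: int, j: int) -> float:
    total = sum(_z(G, i, k) for k in G.nodes if k != i)
    return _z(G, i, j) / total if total > 0 else 0.0


def effective_size_oracle(Z: np.ndarray) -> float:
    """Literal Burt effective-size summation over (j, q) pairs."""
    G = graph_from_Z(Z)
    ego = 0
    alters = [v for v in G.nodes if v != ego]
    es = 0.0
    for j in alters:
        m_max = max(_z(G, j, k) for k in G.nodes if k != j)
        redundancy = 0.0
        for q in alters:
            if q == j:
                continue
            m_jq = _z(G, j, q) / m_max if m_max > 0 else 0.0
            redundancy += _p(G, ego, q) * m_jq
        es += 1.0 - redundancy
    return es


def constraint_raw_oracle(Z: np.ndarray) -> float:
    """Literal Burt aggregate constraint: sum_j (p_ij + sum_q p_iq p_qj)^2."""
    G = graph_from_Z(Z)
    ego = 0
    alters = [v for v in G.nodes if v != ego]
    total = 0.0
    for j in alters:
        indirect = sum(_p(G, ego, q) * _p(G, q, j) for q in alters if q != j)
        total += (_p(G, ego, j) + indirect) ** 2
    return total


def constraint_rescaled_oracle(Z: np.ndarray) -> float:
    n = Z.shape[0] - 1
    if n == 1:
        return 1.0
    c = constraint_raw_oracle(Z)
    empty = np.zeros_like(Z)
    empty[0, 1:] = empty[1:, 0] = 1.0
    full = np.ones_like(Z) - np.eye(Z.shape[0])
    lo = constraint_raw_oracle(empty)
    hi = constraint_raw_oracle(full)
    return float(np.clip((c - lo) / (hi - lo), 0.0, 1.0))


def hierarchy_oracle(Z: np.ndarray) -> float:
    """Coleman-Theil concentration of the dyadic constraints."""
    G = graph_from_Z(Z)
    ego = 0
    alters = [v for v in G.nodes if v != ego]
    n = len(alters)
    if n < 2:
        return 0.0
    cs = []
    for j in alters:
        indirect = sum(_p(G, ego, q) * _p(G, q, j) for q in alters if q != j)
        cs.append((_p(G, ego, j) + indirect) ** 2)
    mean_c = sum(cs) / n
    if mean_c <= 0:
        return 0.0
    num = sum((c / mean_c) * np.log(c / mean_c) if c > 0 else 0.0 for c in cs)
    return float(num / (n * np.log(n)))


def density_oracle(Z: np.ndarray) -> float:
    n = Z.shape[0] - 1
    if n < 2:
        return 0.0
    pairs = [(j, k) for j in range(1, n + 1) for k in range(j + 1, n + 1)]
    return float(sum(Z[j, k] for j, k in pairs) / len(pairs))


def iqv_pair_counting_oracle(labels: list, k: int) -> float:
    """Fraction of unordered pairs in different categories, normalized by
    the (fractional) even-split maximum of the same fraction."""
    n = len(labels)
    unlike = sum(1 for i in range(n) for j in range(i + 1, n) if labels[i] != labels[j])
    max_unlike = (1.0 - 1.0 / k) * n * n / 2.0
    return unlike / max_unlike


def random_ego_Z(rng: np.random.Generator, n_max: int = 8) -> np.ndarray:
    """Random ego-network tie matrix with the package's weight alphabet."""
    n = int(rng.integers(1, n_max + 1))
    Z = np.zeros((n + 1, n + 1))
    Z[0, 1:] = Z[1:, 0] = 1.0
    weights = np.array([0.0, 0.0, 0.25, 0.5, 1.0])
    for j in range(1, n + 1):
        for q in range(j + 1, n + 1):
            Z[j, q] = Z[q, j] = weights[rng.integers(len(weights))]
    return Z


def glmm_loglike_grid_oracle(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    beta: np.ndarray,
    sigma: float,
    half_width: float = 8.0,
    n_grid: int = 20001,
) -> float:
    """Random-intercept logistic marginal log-likelihood by dense
    trapezoidal integration over the random effect."""
    from scipy.special import expit

    total = 0.0
    u = np.linspace(-half_width * sigma, half_width * sigma, n_grid)
    phi = np.exp(-(u**2) / (2 * sigma**2)) / (sigma * np.sqrt(2 * np.pi))
    for g in np.unique(groups):
        idx = groups == g
        eta = X[idx] @ beta
        # log integrand per grid point, summed over the group's observations
        ll = np.zeros_like(u)
        for e, yy in zip(eta, y[idx]):
            p = expit(e + u)
            ll += yy * np.log(p) + (1 - yy) * np.log1p(-p)
        m = ll.max()
        total += m + np.log(np.trapezoid(np.exp(ll - m) * phi, u))
    return float(total)
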