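"""Structural ego-network variables: degree, density, effective size,
efficiency, constraint and hierarchy (Burt's structural-hole measures),
plus the PCA-based reduction of the variable set.

All measures are computed on the weighted ego network whose alters are the
respondent's household members and whose alter-alter tie weights are
normalized kinship relatedness.  Conventions for the degenerate one-alter
network: effective size 1, constraint 1 (the single alter absorbs the whole
network), hierarchy 0, density 0.

The constraint reported alongside Burt's raw aggregate is an affine
per-degree rescaling chosen so the two boundary networks pin the endpoints:
0 when no alter pair is tied and 1 for the complete weight-1 kin clique.
Raw Burt constraint does not have that range (an empty alter graph of n
alters gives 1/n and small complete cliques exceed 1), so the rescaling

    C' = (C - C_empty(n)) / (C_complete(n) - C_empty(n)),   clamped to [0, 1]

with ``C_empty(n) = 1/n`` and ``C_complete(n) = (2n-1)^2 / n^3`` is the
minimal transform with the documented 0/1 endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .kinship import EgoNetwork

__all__ = [
    "StructuralMetrics",
    "degree",
    "density",
    "effective_size",
    "efficiency",
    "constraint_raw",
    "constraint",
    "dyadic_constraints",
    "hierarchy",
    "classify_effective_size",
    "compute_structural_metrics",
    "structural_table",
    "PCAReduction",
    "reduce_structural_set",
]

#: Effective-size cutoff separating "low" from "high" (the cohort median).
ES_CUTOFF_DEFAULT = 3.0

#: Canonical structural variable order (also the PCA tie-break order).
STRUCTURAL_VARIABLES = (
    "degree",
    "density",
    "effective_size",
    "efficiency",
    "constraint",
    "hierarchy",
)


@dataclass(frozen=True)
class StructuralMetrics:
    degree: int
    density: float
    effective_size: float
    efficiency: float
    constraint_raw: float
    constraint: float
    hierarchy: float
    es_class: str  # low | high


def _proportions(Z: np.ndarray) -> np.ndarray:
    """Row-normalized tie strengths p_ij = z_ij / sum_k z_ik."""
    sums = Z.sum(axis=1, keepdims=True)
    sums[sums == 0] = 1.0
    return Z / sums


def degree(net: EgoNetwork) -> int:
    """Number of alters (household members the respondent lives with)."""
    return net.n_alters


def density(net: EgoNetwork) -> float:
    """Mean alter-alter tie weight over the n(n-1)/2 unordered pairs; 0 for n=1."""
    n = net.n_alters
    if n < 2:
        return 0.0
    A = net.alter_tie_matrix()
    return float(A[np.triu_indices(n, k=1)].mean())


def effective_size(net: EgoNetwork) -> float:
    """Burt effective size: the count of non-redundant alters.

    ES = sum_j [ 1 - sum_{q != i,j} p_iq * m_jq ]  with i the ego,
    p_iq the ego's proportional tie strength to q and m_jq alter j's tie
    to q scaled by j's strongest tie.  Ranges from 1 (complete kin clique)
    to n (no alter pair related).
    """
    n = net.n_alters
    Z = net.Z
    P = _proportions(Z)
    maxes = Z[1:, :].max(axis=1)
    maxes[maxes == 0] = 1.0
    M = Z[1:, :] / maxes[:, None]  # m_j. rows, columns indexed like Z
    es = 0.0
    for j in range(1, n + 1):
        redundancy = 0.0
        for q in range(1, n + 1):
            if q == j:
                continue
            redundancy += P[0, q] * M[j - 1, q]
        es += 1.0 - redundancy
    # the summation is bounded by [1, n] exactly; clamp away float noise
    return float(min(max(es, 1.0), float(n)))


def efficiency(net: EgoNetwork) -> float:
    """Effective size per alter: ES / degree, in (0, 1]."""
    return effective_size(net) / degree(net)


def dyadic_constraints(net: EgoNetwork) -> np.ndarray:
    """Burt dyadic constraint c_ij of the ego on each alter j.

    c_ij = (p_ij + sum_{q != i,j} p_iq p_qj)^2 ; aggregate constraint is the
    sum over alters.
    """
    n = net.n_alters
    P = _proportions(net.Z)
    c = np.empty(n)
    for j in range(1, n + 1):
        indirect = sum(P[0, q] * P[q, j] for q in range(1, n + 1) if q != j)
        c[j - 1] = (P[0, j] + indirect) ** 2
    return c


def constraint_raw(net: EgoNetwork) -> float:
    """Burt aggregate constraint C = sum_j c_ij (unrescaled)."""
    return float(dyadic_constraints(net).sum())


def _constraint_bounds(n: int) -> tuple[float, float]:
    """Aggregate constraint of the empty and complete same-degree networks."""
    c_empty = 1.0 / n
    c_complete = (2 * n - 1) ** 2 / n**3
    return c_empty, c_complete


def constraint(net: EgoNetwork) -> float:
    """Constraint rescaled to [0, 1]: 0 when no alters are related, 1 for
    the complete kin clique (e.g. a nuclear family), clamped in between."""
    n = net.n_alters
    if n == 1:
        return 1.0
    c = constraint_raw(net)
    lo, hi = _constraint_bounds(n)
    return float(np.clip((c - lo) / (hi - lo), 0.0, 1.0))


def hierarchy(net: EgoNetwork) -> float:
    """Coleman-Theil concentration of the dyadic constraints.

    0 when constraint is spread evenly over alters, approaching 1 when it
    concentrates on a single alter.  Defined as 0 for degree-1 networks.
    """
    n = net.n_alters
    if n < 2:
        return 0.0
    c = dyadic_constraints(net)
    total = c.sum()
    if total <= 0:
        return 0.0
    ratios = c / (total / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(ratios > 0, ratios * np.log(ratios), 0.0)
    return float(terms.sum() / (n * np.log(n)))


def classify_effective_size(es: float, cutoff: float = ES_CUTOFF_DEFAULT) -> str:
    """Dichotomize effective size: 'high' above the cutoff (default 3, the
    cohort median), 'low' at or below it."""
    if es < 1:
        raise ValueError(f"effective size {es} below its lower bound of 1")
    return "high" if es > cutoff else "low"


def compute_structural_metrics(net: EgoNetwork, es_cutoff: float = ES_CUTOFF_DEFAULT) -> StructuralMetrics:
    es = effective_size(net)
    d = degree(net)
    return StructuralMetrics(
        degree=d,
        density=density(net),
        effective_size=es,
        efficiency=es / d,
        constraint_raw=constraint_raw(net),
        constraint=constraint(net),
        hierarchy=hierarchy(net),
        es_class=classify_effective_size(es, cutoff=es_cutoff),
    )


def structural_table(networks: Iterable[tuple[str, EgoNetwork]], es_cutoff: float = ES_CUTOFF_DEFAULT) -> pd.DataFrame:
    """Per-household structural metrics as a tidy table.

    ``networks`` yields (household_id, EgoNetwork) pairs.
    """
    rows = []
    for hid, net in networks:
        m = compute_structural_metrics(net, es_cutoff=es_cutoff)
        rows.append({"household_id": hid, **m.__dict__})
    return pd.DataFrame(rows)


@dataclass
class PCAReduction:
    """Loadings-based reduction of the correlated structural variable set."""

    variables: list[str]
    eigenvalues: np.ndarray
    loadings: pd.DataFrame  # variables x components
    retained: list[str]
    dropped_constant: list[str]


def reduce_structural_set(
    table: pd.DataFrame,
    variables: Sequence[str] = STRUCTURAL_VARIABLES,
    kaiser_threshold: float = 1.0,
    fallback: Sequence[str] = ("degree", "effective_size", "constraint"),
) -> PCAReduction:
    """Pick a representative subset of the structural variables by PCA.

    Columns are standardized and the correlation matrix eigendecomposed.
    For each leading component (eigenvalue > ``kaiser_threshold``) the
    variable with the largest absolute loading is retained, deduplicated in
    component order with ties broken by the canonical variable order.  When
    no component clears the threshold (near-identity correlation), the
    conventional trio ``fallback`` is returned.
    """
    variables = [v for v in variables if v in table.columns]
    if len(variables) < 3:
        raise ValueError("need at least three structural metric columns")
    if len(table) < 10:
        raise ValueError("need at least 10 rows for a stable correlation matrix")

    X = table[variables].to_numpy(dtype=float)
    stds = X.std(axis=0, ddof=1)
    dropped = [v for v, s in zip(variables, stds) if s == 0 or not np.isfinite(s)]
    kept = [v for v in variables if v not in dropped]
    X = table[kept].to_numpy(dtype=float)
    corr = np.corrcoef(X, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    # loadings: correlations between variables and components
    loadings = eigvecs * np.sqrt(np.maximum(eigvals, 0.0))
    loadings_df = pd.DataFrame(
        loadings, index=kept, columns=[f"PC{i + 1}" for i in range(len(kept))]
    )

    leading = [i for i, ev in enumerate(eigvals) if ev > kaiser_threshold + 1e-9]
    if not leading:
        retained = [v for v in fallback if v in kept]
    else:
        retained = []
        for i in leading:
            col = np.abs(loadings[:, i])
            # deterministic tie-break: first variable in canonical order at the max
            best = max(range(len(kept)), key=lambda j: (col[j], -j))
            if kept[best] not in retained:
                retained.append(kept[best])
    return PCAReduction(
        variables=kept,
        eigenvalues=eigvals,
        loadings=loadings_df,
        retained=retained,
        dropped_constant=dropped,
    )
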