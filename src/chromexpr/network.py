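"""Redundancy quantification and partial-correlation network inference.

Marginal Pearson correlations within/between factor classes expose
statistical redundancy; the cross-model correlation (TF-only vs HM-only
out-of-fold predictions) quantifies how interchangeable the two classes are
for predicting expression. The interaction network conditions that away:
edges are partial correlations from a Schäfer–Strimmer shrinkage estimate of
the correlation matrix (analytic optimal intensity toward the identity),
ranked by magnitude, with the top-k kept. Robustness is assessed by
re-inferring the network on leave-genes-out resamples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import AssociationMatrix
from .core import log_expression
from .errors import AlignmentError, DegenerateSampleError, EstimationError, SizingError, UndefinedCorrelationError
from .models import ModelReport

SHRINKAGE_FLOOR = 1e-3
EXPRESSION_NODE = "expression"


@dataclass
class CorrelationMatrix:
    labels: list
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class NetworkReport:
    """Top partial-correlation edges among factors and expression."""

    nodes: list
    edges: list  # (node_a, node_b, pcor, rank, sign) with rank 1 = strongest
    n_edges_selected: int
    shrinkage_intensity: float
    pcor: pd.DataFrame

    def edge_set(self) -> set:
        return {frozenset((a, b)) for a, b, *_ in self.edges}


def correlation_heatmap(assoc: AssociationMatrix) -> CorrelationMatrix:
    """Pairwise Pearson correlations of the logged association columns."""
    X = assoc.logged
    if len(X) < 3:
        raise DegenerateSampleError("need >= 3 genes")
    const = [c for c in X.columns if X[c].nunique() == 1]
    if const:
        raise UndefinedCorrelationError(f"constant columns: {const}")
    return CorrelationMatrix(list(X.columns), X.corr().to_numpy())


def cross_model_pcc(report_a: ModelReport, report_b: ModelReport) -> float:
    """Pearson correlation between two models' out-of-fold predictions."""
    a, b = report_a.predictions_oof, report_b.predictions_oof
    if a.shape != b.shape:
        raise AlignmentError(f"prediction lengths differ: {a.shape} vs {b.shape}")
    return float(np.corrcoef(a, b)[0, 1])


def attach_expression(assoc: AssociationMatrix, genes: pd.DataFrame,
                      pseudocount: float = 1.0) -> pd.DataFrame:
    """Logged features plus a log2(RPKM + sigma) column as the expression node."""
    if list(genes["id"]) != list(assoc.gene_ids):
        raise AlignmentError("gene order of table and association matrix differ")
    data = assoc.logged.copy()
    data[EXPRESSION_NODE] = log_expression(genes, pseudocount)
    return data


def shrunk_correlation(X: np.ndarray) -> tuple:
    """(R_shrunk, lambda): Schäfer–Strimmer shrinkage toward the identity.

    lambda* = sum_{i<j} Var(r_ij) / sum_{i<j} r_ij^2, estimated from the
    standardized data, clipped to [SHRINKAGE_FLOOR, 1].
    """
    n, p = X.shape
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    R = (Z.T @ Z) / (n - 1)
    # Var(r_ij) ~ n/(n-1)^3 * sum_k (z_ki z_kj - mean)^2
    W = np.einsum("ki,kj->ij", Z ** 2, Z ** 2) - n * (R * (n - 1) / n) ** 2
    var_r = n / (n - 1.0) ** 3 * W
    off = ~np.eye(p, dtype=bool)
    denom = float(np.sum(R[off] ** 2))
    lam = float(np.sum(var_r[off]) / denom) if denom > 0 else 1.0
    lam = float(np.clip(lam, SHRINKAGE_FLOOR, 1.0))
    R_sh = (1.0 - lam) * R
    np.fill_diagonal(R_sh, 1.0)
    return R_sh, lam


def partial_correlations(data: pd.DataFrame) -> tuple:
    """(pcor DataFrame, shrinkage intensity) from the shrunk correlation's
    inverse, scaled to unit diagonal."""
    X = data.to_numpy(dtype=float)
    if np.any(X.std(axis=0) == 0):
        bad = [c for c in data.columns if data[c].nunique() == 1]
        raise UndefinedCorrelationError(f"constant columns: {bad}")
    R_sh, lam = shrunk_correlation(X)
    try:
        omega = np.linalg.inv(R_sh)
    except np.linalg.LinAlgError as exc:
        raise EstimationError(
            "shrunk correlation matrix singular; raise the shrinkage floor"
        ) from exc
    d = np.sqrt(np.diag(omega))
    pcor = -omega / np.outer(d, d)
    np.fill_diagonal(pcor, 1.0)
    pcor = (pcor + pcor.T) / 2.0
    return pd.DataFrame(pcor, index=data.columns, columns=data.columns), lam


def partial_correlation_network(data: pd.DataFrame, n_edges: int = 60) -> NetworkReport:
    """Top-``n_edges`` partial-correlation edges, ranked by |pcor|.

    ``data`` is genes x variables (association columns, typically plus an
    expression column). Ties are broken by the lexicographic label pair; a
    negative partial correlation is flagged with sign -1 (dashed edge in the
    conventional visualization).
    """
    n, p = data.shape
    if n <= p:
        warnings.warn(
            f"n_genes ({n}) <= n_variables ({p}); estimates will be heavily shrunk",
            stacklevel=2,
        )
    pcor, lam = partial_correlations(data)
    labels = list(data.columns)
    pairs = []
    for i in range(p):
        for j in range(i + 1, p):
            a, b = sorted((labels[i], labels[j]))
            pairs.append((a, b, float(pcor.iloc[i, j])))
    pairs.sort(key=lambda t: (-abs(t[2]), t[0], t[1]))
    max_pairs = len(pairs)
    if n_edges > max_pairs:
        warnings.warn(
            f"requested {n_edges} edges but only {max_pairs} pairs exist", stacklevel=2
        )
    kept = pairs[: min(n_edges, max_pairs)]
    edges = [
        (a, b, r, rank + 1, 1 if r >= 0 else -1) for rank, (a, b, r) in enumerate(kept)
    ]
    return NetworkReport(
        nodes=labels,
        edges=edges,
        n_edges_selected=len(edges),
        shrinkage_intensity=lam,
        pcor=pcor,
    )


@dataclass
class RobustnessReport:
    edge_frequency: dict  # frozenset({a, b}) -> fraction of reps selected
    jaccard: np.ndarray  # per-rep Jaccard similarity to the full-data edge set
    full_network: NetworkReport

    @property
    def mean_jaccard(self) -> float:
        return float(np.mean(self.jaccard))


def network_robustness(data: pd.DataFrame, n_edges: int = 60, n_reps: int = 50,
                       n_remove: int = 200, seed: int = 0) -> RobustnessReport:
    """Leave-genes-out stability of the inferred edge set.

    Each rep removes ``n_remove`` random genes, re-infers the network and
    compares its edge set to the full-data network by Jaccard similarity.
    """
    n, p = data.shape
    if n <= n_remove + p:
        raise SizingError(f"need n_genes > n_remove + n_variables ({n_remove + p})")
    full = partial_correlation_network(data, n_edges=n_edges)
    full_edges = full.edge_set()
    rng = np.random.default_rng(seed)
    counts: dict = {}
    jac = np.empty(n_reps)
    for rep in range(n_reps):
        if n_remove:
            drop = rng.choice(n, size=n_remove, replace=False)
            sub = data.drop(data.index[drop])
        else:
            sub = data
        net = partial_correlation_network(sub, n_edges=n_edges)
        edges = net.edge_set()
        for e in edges:
            counts[e] = counts.get(e, 0) + 1
        jac[rep] = len(edges & full_edges) / len(edges | full_edges)
    return RobustnessReport(
        edge_frequency={e: c / n_reps for e, c in counts.items()},
        jaccard=jac,
        full_network=full,
    )
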