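"""Signed weighted co-expression network construction.

Implements the standard signed WGCNA chain: Pearson correlation ->
signed similarity s = (1 + r) / 2 -> soft-threshold power adjacency
a = s^beta -> signed topological overlap (TOM) -> thresholded edge
export.  The soft-threshold power is chosen by the scale-free topology
criterion: the smallest beta whose log-log degree-distribution fit
reaches a target R^2 (default 0.5).

The TOM of a gene pair combines their direct adjacency with the weight
of their shared neighbourhood:

    TOM_ij = (a_ij + sum_{u != i,j} a_iu a_uj) / (min(k_i, k_j) + 1 - a_ij)

with connectivity k_i = sum_{u != i} a_ui.  Pairs whose TOM reaches the
export cutoff become edges; the edge carries the TOM weight and the sign
of the underlying correlation.  Genes with no surviving edge are not part
of the exported network.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .preprocess import ExpressionMatrix, ValidationError

logger = logging.getLogger("salinet")

DEFAULT_BETA_GRID = tuple(range(1, 31))  # includes 22, the classic signed-network choice
DEFAULT_TOM_CUTOFF = 0.4
DEFAULT_R2_TARGET = 0.5


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson correlation over genes, with the sample count kept
    for downstream differential-correlation testing."""

    gene_ids: list[str]
    values: np.ndarray
    n_samples: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.gene_ids)


@dataclass
class SimilarityMatrix:
    gene_ids: list[str]
    values: np.ndarray  # (1 + r) / 2, in [0, 1]


@dataclass
class AdjacencyMatrix:
    gene_ids: list[str]
    values: np.ndarray  # s**beta with zero diagonal
    beta: int


@dataclass
class TomMatrix:
    gene_ids: list[str]
    values: np.ndarray  # signed TOM, diagonal 1
    beta: int


@dataclass
class SoftThresholdReport:
    """Per-candidate scale-free fit and the selected power."""

    betas: list[int]
    r_squared: list[float]       # signed: negated when the log-log slope is positive
    mean_connectivity: list[float]
    selected_beta: int
    target_reached: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beta": self.betas,
                "signed_r2": self.r_squared,
                "mean_connectivity": self.mean_connectivity,
                "selected": [b == self.selected_beta for b in self.betas],
            }
        )


def correlation_matrix(matrix: ExpressionMatrix) -> CorrelationMatrix:
    """Pearson correlation between all gene pairs of one group.

    Constant gene rows have no defined correlation and are dropped with a
    warning before computing.
    """
    if matrix.n_samples < 3:
        raise ValidationError("need at least 3 samples for correlation")
    vals = matrix.data.to_numpy(dtype=float)
    sd = vals.std(axis=1)
    const = sd == 0
    if const.any():
        dropped = [matrix.gene_ids[i] for i in np.flatnonzero(const)]
        warnings.warn(f"dropping {len(dropped)} constant gene(s): {dropped[:5]}",
                      stacklevel=2)
        vals = vals[~const]
    genes = [g for g, c in zip(matrix.gene_ids, const) if not c]
    r = np.atleast_2d(np.corrcoef(vals))
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)  # enforce exact symmetry and bounds
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(genes, r, matrix.n_samples)


def signed_similarity(r: CorrelationMatrix | np.ndarray | float):
    """Signed similarity s = (1 + r) / 2.

    Maps r = -1 to 0 (strong negative correlation treated as unconnected),
    r = 0 to 0.5, and r = 1 to 1.
    """
    if isinstance(r, CorrelationMatrix):
        return SimilarityMatrix(r.gene_ids, (1.0 + r.values) / 2.0)
    arr = np.asarray(r, dtype=float)
    if np.any(arr < -1.0) or np.any(arr > 1.0):
        raise ValidationError("correlation outside [-1, 1]")
    out = (1.0 + arr) / 2.0
    return float(out) if np.isscalar(r) or arr.ndim == 0 else out


def soft_adjacency(s: SimilarityMatrix, beta: int) -> AdjacencyMatrix:
    """Raise similarity to the soft-threshold power; zero the diagonal."""
    if beta < 1:
        raise ValidationError("beta must be a positive integer")
    a = np.power(s.values, beta)
    np.fill_diagonal(a, 0.0)
    return AdjacencyMatrix(s.gene_ids, a, int(beta))


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log-log degree-distribution fit.

    Connectivities are binned into ``n_bins`` equal-width bins; empty bins
    are dropped; log10(frequency) is regressed on log10(mean k per bin).
    The R^2 is negated when the slope is positive (scale-free topology
    requires a decreasing fit).  Degenerate inputs give 0.
    """
    k = k[k > 0]
    if k.size == 0 or np.ptp(k) == 0:
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        sel = which == b
        if not sel.any():
            continue
        xs.append(np.log10(k[sel].mean()))
        ys.append(np.log10(sel.mean()))
    if len(xs) < 2:
        return 0.0
    x = np.asarray(xs)
    y = np.asarray(ys)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    slope, _ = np.polyfit(x, y, 1)
    r2 = float(np.corrcoef(x, y)[0, 1] ** 2)
    return -r2 if slope > 0 else r2


def pick_soft_threshold(
    s: SimilarityMatrix,
    candidates: tuple[int, ...] = DEFAULT_BETA_GRID,
    r2_target: float = DEFAULT_R2_TARGET,
) -> SoftThresholdReport:
    """Scan candidate powers and select the smallest reaching the R^2 target.

    For each beta the soft connectivities k_i are computed and their
    distribution's signed scale-free fit R^2 is measured.  If no candidate
    reaches the target, the beta with the maximal signed R^2 is selected
    and a warning is logged.
    """
    if not candidates:
        raise ValidationError("candidate beta list is empty")
    r2s: list[float] = []
    mean_k: list[float] = []
    for beta in candidates:
        a = soft_adjacency(s, beta)
        k = a.values.sum(axis=0)
        if np.all(k == 0):
            raise ValidationError("all genes isolated; cannot assess scale-free fit")
        r2s.append(_scale_free_fit(k))
        mean_k.append(float(k.mean()))
    selected = None
    for beta, r2 in zip(candidates, r2s):
        if r2 >= r2_target:
            selected = beta
            break
    reached = selected is not None
    if not reached:
        selected = candidates[int(np.argmax(r2s))]
        warnings.warn(
            f"no candidate beta reached signed R^2 >= {r2_target}; "
            f"selected beta={selected} with R^2={max(r2s):.3f}",
            stacklevel=2,
        )
    logger.info("pick_soft_threshold: selected beta=%d (target reached: %s)",
                selected, reached)
    return SoftThresholdReport(list(candidates), r2s, mean_k, int(selected), reached)


def signed_tom(a: AdjacencyMatrix) -> TomMatrix:
    """Signed topological overlap matrix.

    TOM_ij = (a_ij + sum_{u != i,j} a_iu a_uj) / (min(k_i, k_j) + 1 - a_ij)
    for i != j; the diagonal is 1 by convention.  With a zero-diagonal
    adjacency the matrix product A @ A already excludes the u = i and
    u = j self terms.
    """
    A = a.values
    if not np.allclose(A, A.T):
        raise ValidationError("adjacency must be symmetric")
    if np.any(np.diag(A) != 0):
        raise ValidationError("adjacency diagonal must be zero")
    k = A.sum(axis=0)
    shared = A @ A
    numer = A + shared
    denom = np.minimum.outer(k, k) + 1.0 - A
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = np.where(denom > 1e-12, numer / denom, 0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return TomMatrix(a.gene_ids, tom, a.beta)


def export_edges(
    tom: TomMatrix,
    cor: CorrelationMatrix,
    cutoff: float = DEFAULT_TOM_CUTOFF,
) -> nx.Graph:
    """Threshold the TOM into an undirected gene network.

    An edge (i, j) exists iff TOM_ij >= cutoff; its ``weight`` is the TOM
    value and its ``sign`` ('+' or '-') is the sign of the underlying
    Pearson correlation.  Genes with no surviving edge are excluded from
    the node set, so every node in the returned graph has degree >= 1.
    """
    if cutoff < 0.0:
        raise ValidationError("cutoff must be nonnegative")
    if tom.gene_ids != cor.gene_ids:
        raise ValidationError("TOM and correlation gene sets differ")
    genes = tom.gene_ids
    iu, ju = np.triu_indices(len(genes), k=1)
    w = tom.values[iu, ju]
    keep = w >= cutoff
    net = nx.Graph()
    for i, j, weight in zip(iu[keep], ju[keep], w[keep]):
        sign = "+" if cor.values[i, j] >= 0 else "-"
        net.add_edge(genes[i], genes[j], weight=float(weight), sign=sign)
    logger.info("export_edges: %d nodes, %d edges at cutoff %.2f",
                net.number_of_nodes(), net.number_of_edges(), cutoff)
    return net


def build_network(
    matrix: ExpressionMatrix,
    beta: int | None = None,
    tom_cutoff: float = DEFAULT_TOM_CUTOFF,
    r2_target: float = DEFAULT_R2_TARGET,
    beta_grid: tuple[int, ...] = DEFAULT_BETA_GRID,
) -> tuple[nx.Graph, SoftThresholdReport | None, CorrelationMatrix]:
    """Convenience chain: correlation -> similarity -> (beta) -> TOM -> edges.

    With ``beta=None`` the power is chosen by :func:`pick_soft_threshold`;
    an explicit beta bypasses selection.
    """
    cor = correlation_matrix(matrix)
    sim = signed_similarity(cor)
    report = None
    if beta is None:
        report = pick_soft_threshold(sim, beta_grid, r2_target)
        beta = report.selected_beta
    adj = soft_adjacency(sim, beta)
    tom = signed_tom(adj)
    net = export_edges(tom, cor, tom_cutoff)
    return net, report, cor
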