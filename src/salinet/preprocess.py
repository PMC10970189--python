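"""Expression-matrix preparation for two-condition co-expression analysis.

The pipeline order is fixed: probe averaging -> dataset merging by gene
intersection -> per-sample 0-100 rescaling -> low-expression filtering ->
hierarchical-clustering outlier removal.  Each step operates on an
:class:`ExpressionMatrix` (genes x samples, nonnegative values) tagged with
the condition group it belongs to ("sensitive" or "tolerant").
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

logger = logging.getLogger("salinet")

GROUPS = ("sensitive", "tolerant")


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression values for one condition group.

    Parameters
    ----------
    data
        DataFrame with gene IDs as index and sample IDs as columns.
        Values must be nonnegative reals.
    group
        Condition label, one of ``"sensitive"`` or ``"tolerant"``.
    """

    data: pd.DataFrame
    group: str = "sensitive"

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"group must be one of {GROUPS}, got {self.group!r}")
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.copy(), self.group)


@dataclass(frozen=True)
class FilterPolicy:
    """Low-expression filter: keep genes expressed above a floor in enough samples.

    Defaults follow the convention of filtering genes on a 0-100 rescaled
    scale: a gene is kept iff its value exceeds ``expression_floor`` in at
    least ``min_fraction_expressed`` of samples (boundary inclusive).
    """

    expression_floor: float = 1.0
    min_fraction_expressed: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_fraction_expressed <= 1.0:
            raise ValidationError("min_fraction_expressed must be in [0, 1]")


def average_probes(matrix: ExpressionMatrix, probe_map: pd.DataFrame) -> ExpressionMatrix:
    """Collapse probe-level rows to gene-level rows by arithmetic mean.

    ``probe_map`` is a two-column table (probe, gene).  Rows of ``matrix``
    not present in the map are assumed to already be gene identifiers and
    pass through unchanged.  A probe mapping to more than one gene is an
    error (ambiguous map).
    """
    pm = probe_map.iloc[:, :2].copy()
    pm.columns = ["probe", "gene"]
    multi = pm.groupby("probe")["gene"].nunique()
    ambiguous = multi[multi > 1]
    if len(ambiguous):
        raise ValidationError(
            f"probes map to multiple genes: {sorted(ambiguous.index)[:5]}"
        )
    probe_to_gene = dict(zip(pm["probe"], pm["gene"]))
    target = [probe_to_gene.get(rid, rid) for rid in matrix.data.index]
    collapsed = matrix.data.groupby(pd.Index(target, name=matrix.data.index.name)).mean()
    # groupby sorts; restore first-appearance order of target genes
    order = list(dict.fromkeys(target))
    collapsed = collapsed.loc[order]
    if collapsed.index.has_duplicates:
        raise ValidationError("duplicate gene IDs remain after probe averaging")
    return ExpressionMatrix(collapsed, matrix.group)


def merge_datasets(matrices: list[ExpressionMatrix]) -> ExpressionMatrix:
    """Merge datasets of one group: intersect genes, concatenate samples.

    Gene order follows the first input; sample IDs are prefixed with a
    dataset index (``d0.``, ``d1.``, ...) so they stay unique.
    """
    if not matrices:
        raise ValidationError("need at least one matrix to merge")
    groups = {m.group for m in matrices}
    if len(groups) > 1:
        raise ValidationError(f"cannot merge across groups: {sorted(groups)}")
    common = set(matrices[0].data.index)
    for m in matrices[1:]:
        common &= set(m.data.index)
    if not common:
        raise ValidationError("gene intersection across datasets is empty")
    genes = [g for g in matrices[0].data.index if g in common]
    parts = []
    for i, m in enumerate(matrices):
        part = m.data.loc[genes]
        part = part.rename(columns={c: f"d{i}.{c}" for c in part.columns})
        parts.append(part)
    merged = pd.concat(parts, axis=1)
    return ExpressionMatrix(merged, matrices[0].group)


def rescale_samples(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Rescale each sample (column) linearly to the range [0, 100].

    Applies (x - min x) / (max x - min x) * 100 per column, so every
    column attains 0 at its minimum and 100 at its maximum.
    """
    vals = matrix.data.to_numpy(dtype=float)
    lo = vals.min(axis=0)
    hi = vals.max(axis=0)
    flat = np.isclose(hi, lo)
    if flat.any():
        bad = [matrix.sample_ids[i] for i in np.flatnonzero(flat)]
        raise ValidationError(f"constant sample column(s), cannot rescale: {bad[:5]}")
    scaled = (vals - lo) / (hi - lo) * 100.0
    return ExpressionMatrix(
        pd.DataFrame(scaled, index=matrix.data.index, columns=matrix.data.columns),
        matrix.group,
    )


def filter_low_expression(
    matrix: ExpressionMatrix, policy: FilterPolicy = FilterPolicy()
) -> ExpressionMatrix:
    """Drop genes not expressed above the floor in enough samples.

    A gene is kept iff ``count(value > expression_floor) / n_samples >=
    min_fraction_expressed``.  Exactly hitting the fraction keeps the gene.
    Row order is preserved.
    """
    vals = matrix.data.to_numpy(dtype=float)
    frac = (vals > policy.expression_floor).mean(axis=1)
    keep = frac >= policy.min_fraction_expressed
    kept = matrix.data.loc[keep]
    logger.info(
        "filter_low_expression: kept %d of %d genes (floor=%g, min_frac=%g)",
        kept.shape[0], matrix.n_genes,
        policy.expression_floor, policy.min_fraction_expressed,
    )
    return ExpressionMatrix(kept, matrix.group)


def detect_outlier_samples(
    matrix: ExpressionMatrix, cut_height: float | None = None
) -> tuple[list[str], list[str]]:
    """Flag outlier samples by average-linkage hierarchical clustering.

    Samples are clustered on Euclidean distance over their gene vectors;
    the dendrogram is cut at ``cut_height`` and every sample outside the
    largest cluster is removed.  The automatic cut is a robust upper fence
    on the merge heights, median + 7 x (p80 - median): the 80th percentile
    stays inside the normal bulk even when a handful of outliers inflate
    the top merges, so the fence lands in the gap between ordinary and
    outlier joins on both raw and per-sample-rescaled data.

    Returns ``(kept_sample_ids, removed_sample_ids)``.
    """
    if matrix.n_samples < 3:
        raise ValidationError("need at least 3 samples for outlier detection")
    X = matrix.data.to_numpy(dtype=float).T  # samples x genes
    dist = pdist(X, metric="euclidean")
    Z = linkage(dist, method="average")
    if cut_height is None:
        med = float(np.median(Z[:, 2]))
        p80 = float(np.quantile(Z[:, 2], 0.8))
        cut_height = med + 7.0 * (p80 - med) if med > 0 else np.inf
    labels = fcluster(Z, t=cut_height, criterion="distance")
    # keep the largest cluster; ties broken by lowest label for determinism
    sizes = pd.Series(labels).value_counts()
    biggest = sizes[sizes == sizes.max()].index.min()
    samples = matrix.sample_ids
    kept = [s for s, lab in zip(samples, labels) if lab == biggest]
    removed = [s for s, lab in zip(samples, labels) if lab != biggest]
    if len(removed) > matrix.n_samples / 2:
        warnings.warn(
            f"outlier cut at height {cut_height:.3g} removes "
            f"{len(removed)}/{matrix.n_samples} samples; proceeding",
            stacklevel=2,
        )
    logger.info("detect_outlier_samples: removed %d of %d samples", len(removed), matrix.n_samples)
    return kept, removed


def drop_samples(matrix: ExpressionMatrix, sample_ids: list[str]) -> ExpressionMatrix:
    """Return a copy of ``matrix`` without the listed samples."""
    keep = [s for s in matrix.sample_ids if s not in set(sample_ids)]
    return ExpressionMatrix(matrix.data[keep], matrix.group)
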