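"""Differential correlation between two condition groups (Fisher z screen).

For every unordered gene pair over the shared gene universe the Pearson
correlation is computed separately in the sensitive and tolerant groups
and the equality of the two population correlations is tested with
Fisher's z:

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3))

with a two-sided standard-normal p-value.  Multiple testing is controlled
by Benjamini-Hochberg (default) or by an empirical-null local false
discovery rate estimated from the z histogram by central matching.
Selected pairs must change correlation by at least ``min_abs_delta``
(default 0.7, inclusive) AND pass the FDR cut (default 0.05) — the
magnitude condition exists to exclude differences between two weak
correlations (e.g. 0 vs 0.6) however significant.

The sign convention: delta_r = r_sensitive - r_tolerant, so a negative
delta means the pair is more strongly correlated in the tolerant group.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import ExpressionMatrix, ValidationError

logger = logging.getLogger("salinet")

_R_EPS = 1e-7


@dataclass(frozen=True)
class SelectionPolicy:
    """Thresholds of the differential-pair screen (both boundaries inclusive)."""

    min_abs_delta: float = 0.7
    max_fdr: float = 0.05
    fdr_method: str = "bh"

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_abs_delta <= 2.0:
            raise ValidationError("min_abs_delta must be in [0, 2]")
        if not 0.0 <= self.max_fdr <= 1.0:
            raise ValidationError("max_fdr must be in [0, 1]")
        if self.fdr_method not in ("bh", "local"):
            raise ValidationError("fdr_method must be 'bh' or 'local'")


def fisher_z(r):
    """Variance-stabilizing transform z = atanh(r) = 0.5*ln((1+r)/(1-r)).

    |r| is clamped to 1 - 1e-7 first so r = +/-1 stays finite.  Odd in r;
    accepts scalars or arrays.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) > 1.0):
        raise ValidationError("correlation outside [-1, 1]")
    clamped = np.clip(arr, -1.0 + _R_EPS, 1.0 - _R_EPS)
    out = np.arctanh(clamped)
    return float(out) if np.ndim(r) == 0 else out


def differential_correlation_test(r1, n1: int, r2, n2: int):
    """Fisher z-test of H0: the two population correlations are equal.

    Returns (z_stat, p_value); vectorized over r1/r2 arrays.  Requires at
    least 4 samples per group.
    """
    if n1 <= 3 or n2 <= 3:
        raise ValidationError("Fisher z-test requires n > 3 in each group")
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (np.asarray(fisher_z(r1)) - np.asarray(fisher_z(r2))) / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    if np.ndim(r1) == 0 and np.ndim(r2) == 0:
        return float(z), float(p)
    return z, p


def screen_all_pairs(
    mat_sensitive: ExpressionMatrix,
    mat_tolerant: ExpressionMatrix,
    gene_universe: list[str] | None = None,
) -> pd.DataFrame:
    """Fisher z-test for every unordered gene pair over the shared genes.

    ``gene_universe`` defaults to the intersection of the two matrices'
    genes (order of the sensitive matrix).  Genes constant in either group
    have undefined correlations; their pairs are dropped with a warning.

    Returns a DataFrame with one row per pair: gene_i, gene_j,
    r_sensitive, r_tolerant, n_sensitive, n_tolerant, z_stat, p_value,
    delta_r.
    """
    if gene_universe is None:
        shared = set(mat_sensitive.gene_ids) & set(mat_tolerant.gene_ids)
        gene_universe = [g for g in mat_sensitive.gene_ids if g in shared]
    else:
        for m in (mat_sensitive, mat_tolerant):
            missing = set(gene_universe) - set(m.gene_ids)
            if missing:
                raise ValidationError(f"universe genes missing from {m.group}: "
                                      f"{sorted(missing)[:5]}")
    if len(gene_universe) < 2:
        raise ValidationError("gene universe must contain at least 2 genes")

    xa = mat_sensitive.data.loc[gene_universe].to_numpy(dtype=float)
    xb = mat_tolerant.data.loc[gene_universe].to_numpy(dtype=float)
    const = (xa.std(axis=1) == 0) | (xb.std(axis=1) == 0)
    if const.any():
        dropped = [g for g, c in zip(gene_universe, const) if c]
        warnings.warn(
            f"dropping {len(dropped)} gene(s) constant in one group: {dropped[:5]}",
            stacklevel=2,
        )
        gene_universe = [g for g, c in zip(gene_universe, const) if not c]
        xa, xb = xa[~const], xb[~const]
    n1, n2 = xa.shape[1], xb.shape[1]
    ra = np.clip(np.corrcoef(xa), -1.0, 1.0)
    rb = np.clip(np.corrcoef(xb), -1.0, 1.0)
    iu, ju = np.triu_indices(len(gene_universe), k=1)
    r1 = ra[iu, ju]
    r2 = rb[iu, ju]
    z, p = differential_correlation_test(r1, n1, r2, n2)
    genes = np.asarray(gene_universe)
    records = pd.DataFrame(
        {
            "gene_i": genes[iu],
            "gene_j": genes[ju],
            "r_sensitive": r1,
            "r_tolerant": r2,
            "n_sensitive": n1,
            "n_tolerant": n2,
            "z_stat": z,
            "p_value": p,
            "delta_r": r1 - r2,
        }
    )
    logger.info("screen_all_pairs: %d pairs over %d genes", len(records), len(genes))
    return records


def _local_fdr(z: np.ndarray) -> np.ndarray:
    """Efron-style empirical-null local fdr via central matching.

    The marginal density f(z) is a Poisson-regression (polynomial) fit to
    the z histogram; the null N(mu0, sigma0) is fit to the central mass by
    a quadratic fit of log f around its peak; pi0 matches the densities at
    the mode.  Returns min(1, pi0 * f0(z) / f(z)).
    """
    z = np.asarray(z, dtype=float)
    n = z.size
    n_bins = max(20, min(120, int(np.sqrt(n))))
    counts, edges = np.histogram(z, bins=n_bins)
    mids = (edges[:-1] + edges[1:]) / 2.0
    width = edges[1] - edges[0]
    # polynomial Poisson-style fit of log density (weighted LS on log counts)
    pos = counts > 0
    deg = min(6, max(2, pos.sum() - 2))
    logc = np.log(counts[pos].astype(float))
    coefs = np.polyfit(mids[pos], logc, deg, w=np.sqrt(counts[pos]))
    logf_hat = np.polyval(coefs, mids)
    f_hat = np.exp(logf_hat) / (n * width)  # density estimate at bin mids

    # central matching: quadratic fit of log f around the empirical mode
    mode = mids[np.argmax(logf_hat)]
    central = np.abs(mids - mode) <= max(1.0, 2.0 * z.std() / 2.0)
    if central.sum() < 3:
        central = np.ones_like(mids, dtype=bool)
    qa, qb, qc = np.polyfit(mids[central], logf_hat[central], 2)
    if qa >= 0:  # no central peak; fall back to moments
        mu0, sigma0 = float(np.median(z)), float(z.std())
    else:
        mu0 = -qb / (2.0 * qa)
        sigma0 = float(np.sqrt(-1.0 / (2.0 * qa)))
    f0_mode = stats.norm.pdf(mode, mu0, sigma0)
    f_mode = np.exp(np.polyval(coefs, mode)) / (n * width)
    pi0 = min(1.0, f_mode / f0_mode) if f0_mode > 0 else 1.0

    f_z = np.exp(np.polyval(coefs, z)) / (n * width)
    f_z = np.maximum(f_z, 1e-300)
    fdr = pi0 * stats.norm.pdf(z, mu0, sigma0) / f_z
    return np.minimum(fdr, 1.0)


def adjust_fdr(records: pd.DataFrame, method: str = "bh") -> pd.DataFrame:
    """Fill the ``fdr`` column across all tested pairs.

    ``bh`` is the Benjamini-Hochberg step-up over p-values; ``local`` is
    the empirical-null local fdr computed from the z statistics.
    """
    out = records.copy()
    if len(out) == 0:
        out["fdr"] = pd.Series(dtype=float)
        return out
    if method == "bh":
        out["fdr"] = multipletests(out["p_value"].to_numpy(), method="fdr_bh")[1]
    elif method == "local":
        out["fdr"] = _local_fdr(out["z_stat"].to_numpy())
    else:
        raise ValidationError("method must be 'bh' or 'local'")
    return out


def select_significant_pairs(
    records: pd.DataFrame, policy: SelectionPolicy = SelectionPolicy()
) -> pd.DataFrame:
    """Keep pairs with |delta_r| >= min_abs_delta and fdr <= max_fdr."""
    if "fdr" not in records.columns:
        raise ValidationError("run adjust_fdr before selection")
    keep = (records["delta_r"].abs() >= policy.min_abs_delta) & (
        records["fdr"] <= policy.max_fdr
    )
    selected = records.loc[keep].reset_index(drop=True)
    logger.info("select_significant_pairs: %d of %d pairs selected",
                len(selected), len(records))
    return selected
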