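"""GO enrichment, marker-interval mapping and TF-centred differential modules.

Enrichment is a one-sided Fisher exact (hypergeometric upper tail) test of
over-representation of each GO term in a study gene set against a
background universe, with Benjamini-Hochberg FDR across tested terms.
The annotation is consumed as a flat gene->term table; no propagation up
the ontology DAG is performed.

Interval mapping assigns a gene (represented by its start coordinate,
1-based) to every marker interval that contains it, both interval ends
inclusive — membership is locus-level, as in meta-QTL candidate screens.

Transcription factors are the high-centrality genes annotated to any of
the four transcription-activity GO terms; a TF's differential module is
the set of its partners among the selected differential-correlation
pairs, each labelled with the sign of delta_r (positive: correlation
higher in the sensitive group).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import ValidationError
from .synthetic_data import TF_GO_TERMS

logger = logging.getLogger("salinet")


@dataclass
class TfModule:
    """A focal TF and its significantly rewired partners."""

    tf: str
    partners: pd.DataFrame = field(default_factory=pd.DataFrame)
    # partners columns: partner, delta_r, sign, fdr

    @property
    def n_partners(self) -> int:
        return len(self.partners)


def _annotation_frame(annotation: pd.DataFrame) -> pd.DataFrame:
    ann = annotation.iloc[:, :2].copy()
    ann.columns = ["gene", "term"]
    return ann.drop_duplicates()


def go_enrichment(
    study_set,
    annotation: pd.DataFrame,
    background: set[str] | None = None,
    max_p: float = 0.05,
    max_fdr: float = 0.05,
) -> pd.DataFrame:
    """Over-representation test of GO terms in a study gene set.

    Per term with at least one study gene, the hypergeometric upper-tail
    p-value of the 2x2 table (k study genes with the term, n study genes,
    K background genes with the term, N background genes) is computed; BH
    FDR is applied across tested terms; terms with p <= max_p and
    fdr <= max_fdr are returned sorted by p.

    ``background`` defaults to all genes in the annotation table.
    """
    study = set(study_set)
    if not study:
        raise ValidationError("study set is empty")
    ann = _annotation_frame(annotation)
    if background is None:
        background = set(ann["gene"])
    if not study <= background:
        study = study & background
        if not study:
            raise ValidationError("no study gene is in the background universe")
    ann = ann[ann["gene"].isin(background)]
    N = len(background)
    n = len(study)
    by_term = ann.groupby("term")["gene"].apply(set)
    rows = []
    for term, genes in by_term.items():
        k = len(genes & study)
        if k == 0:
            continue
        K = len(genes)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, n, K, N, p))
    if not rows:
        return pd.DataFrame(columns=["term", "k", "n", "K", "N", "p_value", "fdr"])
    res = pd.DataFrame(rows, columns=["term", "k", "n", "K", "N", "p_value"])
    res["fdr"] = multipletests(res["p_value"].to_numpy(), method="fdr_bh")[1]
    res = res[(res["p_value"] <= max_p) & (res["fdr"] <= max_fdr)]
    return res.sort_values(["p_value", "term"], ignore_index=True)


def map_genes_to_intervals(
    gene_positions: pd.DataFrame, intervals: pd.DataFrame
) -> pd.DataFrame:
    """Assign genes to the marker intervals containing their position.

    ``gene_positions``: columns (gene, chrom, pos); ``intervals``: columns
    (chrom, start, end, name), 1-based inclusive on both ends.  Returns one
    row per (gene, interval) hit: gene, chrom, pos, interval, start, end.
    """
    gp = gene_positions.iloc[:, :3].copy()
    gp.columns = ["gene", "chrom", "pos"]
    cols = ["gene", "chrom", "pos", "interval", "start", "end"]
    if intervals is None or len(intervals) == 0:
        return pd.DataFrame(columns=cols)
    iv = intervals.iloc[:, :4].copy()
    iv.columns = ["chrom", "start", "end", "name"]
    if (iv["start"] > iv["end"]).any():
        raise ValidationError("interval with start > end")
    merged = gp.merge(iv, on="chrom", how="inner")
    hit = merged[(merged["pos"] >= merged["start"]) & (merged["pos"] <= merged["end"])]
    out = hit.rename(columns={"name": "interval"})[cols]
    return out.sort_values(["gene", "interval"], ignore_index=True)


def select_transcription_factors(
    high_centrality_genes,
    annotation: pd.DataFrame,
    tf_terms=TF_GO_TERMS,
) -> set[str]:
    """High-centrality genes annotated to at least one transcription GO term."""
    ann = _annotation_frame(annotation)
    tf_annotated = set(ann.loc[ann["term"].isin(set(tf_terms)), "gene"])
    return set(high_centrality_genes) & tf_annotated


def build_tf_modules(tf_set, selected_pairs: pd.DataFrame) -> list[TfModule]:
    """Group the selected differential pairs into TF-centred modules.

    For each TF involved in at least one selected pair, the module lists
    its partners with delta_r, the sign label (positive: r_sensitive >
    r_tolerant; negative: r_sensitive < r_tolerant) and the pair's fdr.
    TFs with no selected pair are omitted.
    """
    modules: list[TfModule] = []
    for tf in sorted(set(tf_set)):
        mask_i = selected_pairs["gene_i"] == tf
        mask_j = selected_pairs["gene_j"] == tf
        if not (mask_i.any() or mask_j.any()):
            continue
        sub = selected_pairs[mask_i | mask_j]
        partners = np.where(sub["gene_i"] == tf, sub["gene_j"], sub["gene_i"])
        part = pd.DataFrame(
            {
                "partner": partners,
                "delta_r": sub["delta_r"].to_numpy(),
                "sign": np.where(sub["delta_r"] >= 0, "positive", "negative"),
                "fdr": sub["fdr"].to_numpy(),
            }
        ).sort_values("partner", ignore_index=True)
        modules.append(TfModule(tf=tf, partners=part))
    logger.info("build_tf_modules: %d TF modules", len(modules))
    return modules


def tf_modules_table(modules: list[TfModule]) -> pd.DataFrame:
    """Flatten TF modules into a (tf, partner, delta_r, sign, fdr) edge list."""
    if not modules:
        return pd.DataFrame(columns=["tf", "partner", "delta_r", "sign", "fdr"])
    frames = []
    for m in modules:
        part = m.partners.copy()
        part.insert(0, "tf", m.tf)
        frames.append(part)
    return pd.concat(frames, ignore_index=True)
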