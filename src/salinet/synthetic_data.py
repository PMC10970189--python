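"""Two-group synthetic expression data with planted co-expression structure.

The generator emulates the statistical structure a dual-condition weighted
co-expression pipeline assumes: two groups of samples (default 72 and 96)
over a shared gene universe containing

* block-correlated modules driven by latent factors,
* hub genes loading on a global factor shared by all module factors,
* planted gene pairs whose correlation differs between the groups by a
  controlled amount (the differential-correlation truth),
* optional duplicate probe rows and shifted outlier samples, and
* fixture GO annotations / marker intervals with known enrichment truth.

The model is a Gaussian latent factor model.  A module gene is
``l * f_m + noise_sd * sqrt(1 - l^2) * eps`` where the loading ``l``
grades from module core to periphery (the convention of WGCNA's own
expression simulator), centred so the mean pairwise within-module
correlation is ``within_module_cor`` at ``noise_sd = 1``; as
``noise_sd -> 0`` all within-module correlations tend to 1.  The graded
membership is what gives the networks the heavy-tailed connectivity
distribution real co-expression data shows.  Latents are mapped to nonnegative
expression by the affine transform ``50 + 10 z`` (clipped at zero), which
preserves Pearson correlations exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .preprocess import ValidationError

# four transcription-activity GO identifiers used for TF selection downstream
TF_GO_TERMS = ("GO:0006350", "GO:0030528", "GO:0006351", "GO:0006366")

# fixed construction constants (latent scale)
_EXPR_OFFSET = 50.0
_EXPR_SCALE = 10.0
_GLOBAL_RHO = 0.3        # share of each module factor's variance from the global factor
_HUB_LOADING = 0.95      # hub genes' squared loading on the global factor
_PROBE_NOISE_SD = 0.1    # latent-scale noise between duplicate probes
_OUTLIER_SHIFT = 8.0     # latent-scale mean shift of planted outlier samples
_R_CLAMP = 0.99


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the two-group expression simulation.

    Defaults emulate the study scale at desk size: 300 genes, 72 and 96
    samples per group (post-outlier counts), six 30-gene modules with
    within-module correlation 0.95, ten hubs, ten planted differential
    pairs with |delta r| = 0.9.
    """

    n_genes: int = 300
    n_samples_per_group: tuple[int, int] = (72, 96)
    n_modules: int = 6
    module_size: int = 30
    within_module_cor: float = 0.95
    n_hub_genes: int = 10
    n_diff_pairs: int = 10
    planted_delta: float = 0.9
    noise_sd: float = 1.0
    n_duplicate_probes: int = 10
    n_outlier_samples: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.n_modules * self.module_size > self.n_genes:
            raise ValidationError("n_modules * module_size exceeds n_genes")
        if not 0.0 < self.within_module_cor < 1.0:
            raise ValidationError("within_module_cor must be in (0, 1)")
        if not 0.0 < self.planted_delta <= 2.0:
            raise ValidationError("planted_delta must be in (0, 2]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be nonnegative")
        free = self.n_genes - self.n_modules * self.module_size - self.n_hub_genes
        if 2 * self.n_diff_pairs > free:
            raise ValidationError(
                "not enough genes outside module blocks and hubs for planted pairs"
            )


@dataclass
class SimOutput:
    """Simulated matrices plus the truth tables the tests check against."""

    expr_a: pd.DataFrame                 # sensitive group, genes x samples
    expr_b: pd.DataFrame                 # tolerant group
    module_membership: pd.DataFrame      # gene, module
    hub_genes: list[str]
    planted_pairs: pd.DataFrame          # gene_i, gene_j, r_a, r_b
    probe_map: pd.DataFrame | None = None
    outlier_samples: list[str] = field(default_factory=list)
    go_annotation: pd.DataFrame | None = None
    marker_intervals: pd.DataFrame | None = None
    gene_positions: pd.DataFrame | None = None
    tf_genes: list[str] = field(default_factory=list)
    enriched_term: str | None = None


def _clamp_r(r: float) -> float:
    return float(np.clip(r, -_R_CLAMP, _R_CLAMP))


def planted_correlations(planted_delta: float) -> tuple[float, float]:
    """Target correlations (r_A, r_B) for a planted pair, centred on 0.45."""
    r_a = _clamp_r(0.45 + planted_delta / 2.0)
    r_b = _clamp_r(r_a - planted_delta)
    return r_a, r_b


_PERIPHERY_COR = 0.35    # weakest graded module membership (squared loading)
_BG_COR_MAX = 0.30       # upper bound of background genes' diffuse membership


def _structural_loadings(
    cfg: SimConfig,
    rng: np.random.Generator,
    module_of: dict[str, int],
    gene_ids: list[str],
    hubs: list[str],
    pair_genes: set[str],
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene factor assignment and loading, drawn once and shared by
    both groups so every non-planted pair has equal population correlation.

    Module genes grade from a core at ``within_module_cor`` (squared
    loading, slightly inflated at the top) down to a periphery floor;
    background genes get a weak diffuse membership to a round-robin
    factor.  Hubs and planted-pair genes are handled separately
    (factor index -1).
    """
    n = cfg.n_genes
    factor_idx = np.full(n, -1, dtype=int)
    loading = np.zeros(n)
    c_hi = min(cfg.within_module_cor + 0.045, 0.995)
    c_lo = min(_PERIPHERY_COR, cfg.within_module_cor)
    grades = np.sqrt(np.linspace(c_hi, c_lo, max(cfg.module_size, 1)))
    counter = [0] * max(cfg.n_modules, 1)
    hubset = set(hubs)
    for gi, gene in enumerate(gene_ids):
        if gene in module_of:
            m = module_of[gene]
            factor_idx[gi] = m
            loading[gi] = grades[counter[m]]
            counter[m] += 1
        elif gene in hubset or gene in pair_genes:
            continue
        elif cfg.n_modules > 0:
            factor_idx[gi] = gi % cfg.n_modules
            loading[gi] = np.sqrt(rng.uniform(0.0, _BG_COR_MAX))
    return factor_idx, loading


def _simulate_group(
    cfg: SimConfig,
    rng: np.random.Generator,
    n_samples: int,
    planted_r: float,
    gene_ids: list[str],
    factor_idx: np.ndarray,
    loading: np.ndarray,
    hubs: list[str],
    pairs: list[tuple[str, str]],
) -> pd.DataFrame:
    n = cfg.n_genes
    Z = np.empty((n, n_samples))
    g_factor = rng.standard_normal(n_samples)
    mod_factors = []
    for _ in range(max(cfg.n_modules, 1)):
        u = rng.standard_normal(n_samples)
        f = np.sqrt(_GLOBAL_RHO) * g_factor + np.sqrt(1.0 - _GLOBAL_RHO) * u
        mod_factors.append(f)

    ns = cfg.noise_sd
    idx = {g: i for i, g in enumerate(gene_ids)}
    in_pair = {g for p in pairs for g in p}
    hubset = set(hubs)

    for gi, gene in enumerate(gene_ids):
        if gene in hubset:
            Z[gi] = (
                np.sqrt(_HUB_LOADING) * g_factor
                + ns * np.sqrt(1.0 - _HUB_LOADING) * rng.standard_normal(n_samples)
            )
        elif gene in in_pair:
            Z[gi] = np.nan  # filled below, pairwise
        elif factor_idx[gi] >= 0:
            f = mod_factors[factor_idx[gi]]
            l = loading[gi]
            Z[gi] = l * f + ns * np.sqrt(1.0 - l * l) * rng.standard_normal(n_samples)
        else:
            Z[gi] = ns * rng.standard_normal(n_samples)

    r = planted_r
    for ga, gb in pairs:
        w = rng.standard_normal(n_samples)
        e = rng.standard_normal(n_samples)
        Z[idx[ga]] = w
        Z[idx[gb]] = r * w + ns * np.sqrt(max(0.0, 1.0 - r * r)) * e

    X = np.clip(_EXPR_OFFSET + _EXPR_SCALE * Z, 0.0, None)
    cols = [f"s{j+1}" for j in range(n_samples)]
    return pd.DataFrame(X, index=gene_ids, columns=cols)


def simulate_two_group_expression(config: SimConfig = SimConfig()) -> SimOutput:
    """Generate the two-group expression matrices and their truth tables.

    The same seed always yields bit-identical output.  Group A
    ("sensitive") planted pairs have correlation ``r_A``; group B
    ("tolerant") has ``r_A - planted_delta`` (clamped to [-0.99, 0.99]).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    gene_ids = [f"g{i:04d}" for i in range(config.n_genes)]
    module_of: dict[str, int] = {}
    pos = 0
    for m in range(config.n_modules):
        for g in gene_ids[pos : pos + config.module_size]:
            module_of[g] = m
        pos += config.module_size
    hubs = gene_ids[pos : pos + config.n_hub_genes]
    pos += config.n_hub_genes
    pair_genes = gene_ids[pos : pos + 2 * config.n_diff_pairs]
    pairs = [
        (pair_genes[2 * i], pair_genes[2 * i + 1]) for i in range(config.n_diff_pairs)
    ]

    r_a, r_b = planted_correlations(config.planted_delta)
    n_a, n_b = config.n_samples_per_group
    factor_idx, loading = _structural_loadings(
        config, rng, module_of, gene_ids, hubs, set(pair_genes)
    )
    expr_a = _simulate_group(config, rng, n_a, r_a, gene_ids, factor_idx, loading,
                             hubs, pairs)
    expr_b = _simulate_group(config, rng, n_b, r_b, gene_ids, factor_idx, loading,
                             hubs, pairs)
    expr_a.columns = [f"sen.{c}" for c in expr_a.columns]
    expr_b.columns = [f"tol.{c}" for c in expr_b.columns]

    membership = pd.DataFrame(
        {"gene": list(module_of), "module": [module_of[g] for g in module_of]}
    )
    planted = pd.DataFrame(
        [(a, b, r_a, r_b) for a, b in pairs],
        columns=["gene_i", "gene_j", "r_a", "r_b"],
    )
    return SimOutput(
        expr_a=expr_a,
        expr_b=expr_b,
        module_membership=membership,
        hub_genes=list(hubs),
        planted_pairs=planted,
    )


def corrupt_with_probes_and_outliers(sim: SimOutput, config: SimConfig) -> SimOutput:
    """Add duplicate probe rows and shifted outlier samples to both groups.

    The first ``n_duplicate_probes`` genes are replaced by two probe rows
    ``<gene>_p1`` / ``<gene>_p2`` carrying independent probe-level noise;
    ``n_outlier_samples`` extra samples per group are drawn with a large
    per-gene shift of random sign (8 latent SDs, pattern independent per
    outlier) so average-linkage clustering separates them even after any
    per-sample affine rescaling.
    Returns a new SimOutput with the probe map and outlier truth recorded;
    with both counts zero the expression tables are returned unchanged.
    """
    if config.n_duplicate_probes == 0 and config.n_outlier_samples == 0:
        return replace(sim, probe_map=pd.DataFrame(columns=["probe", "gene"]),
                       outlier_samples=[])
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    genes = list(sim.expr_a.index)
    if config.n_duplicate_probes > len(genes):
        raise ValidationError("n_duplicate_probes exceeds number of genes")
    dup = genes[: config.n_duplicate_probes]

    def _probe_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
        rows, index, mapping = [], [], []
        for g in df.index:
            if g in dup:
                base = df.loc[g].to_numpy()
                for suffix in ("_p1", "_p2"):
                    noise = _EXPR_SCALE * _PROBE_NOISE_SD * rng.standard_normal(len(base))
                    rows.append(np.clip(base + noise, 0.0, None))
                    index.append(f"{g}{suffix}")
                    mapping.append((f"{g}{suffix}", g))
            else:
                rows.append(df.loc[g].to_numpy())
                index.append(g)
        return pd.DataFrame(rows, index=index, columns=df.columns), mapping

    expr_a, map_a = _probe_rows(sim.expr_a)
    expr_b, _ = _probe_rows(sim.expr_b)

    outliers: list[str] = []
    if config.n_outlier_samples:
        if config.n_outlier_samples > min(sim.expr_a.shape[1], sim.expr_b.shape[1]):
            raise ValidationError("n_outlier_samples exceeds available samples")
        for tag, df_name in (("sen", "expr_a"), ("tol", "expr_b")):
            df = expr_a if df_name == "expr_a" else expr_b
            n_genes_now = df.shape[0]
            signs = rng.choice([-1.0, 1.0], size=(n_genes_now, config.n_outlier_samples))
            extra = np.clip(
                _EXPR_OFFSET
                + _EXPR_SCALE
                * (rng.standard_normal((n_genes_now, config.n_outlier_samples))
                   + _OUTLIER_SHIFT * signs),
                0.0,
                None,
            )
            names = [f"{tag}.out{j+1}" for j in range(config.n_outlier_samples)]
            extra_df = pd.DataFrame(extra, index=df.index, columns=names)
            joined = pd.concat([df, extra_df], axis=1)
            if df_name == "expr_a":
                expr_a = joined
            else:
                expr_b = joined
            outliers.extend(names)

    probe_map = pd.DataFrame(map_a, columns=["probe", "gene"])
    return replace(
        sim, expr_a=expr_a, expr_b=expr_b, probe_map=probe_map, outlier_samples=outliers
    )


def generate_fixture_annotations(
    sim: SimOutput, n_terms: int = 12, n_intervals: int = 5, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Build GO annotation, marker intervals and gene positions for a sim.

    One synthetic term (``GO:SYN0000``) is deliberately enriched in the hub
    genes; the four transcription-activity GO IDs are attached to a known
    TF subset (hubs at even positions plus a few module genes).  Genes are
    laid out on 12 chromosomes at 10-kb spacing; intervals each span a
    known run of genes on one chromosome.  Results are also stored on
    ``sim`` (go_annotation, marker_intervals, gene_positions, tf_genes,
    enriched_term).
    """
    if n_terms < 1:
        raise ValidationError("n_terms must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    genes = [g for g in sim.expr_a.index if not g.endswith(("_p1", "_p2"))]
    if not genes:
        genes = list(sim.expr_a.index)

    records: list[tuple[str, str]] = []
    enriched = "GO:SYN0000"
    for g in sim.hub_genes:
        records.append((g, enriched))
    n_extra = max(1, len(genes) // 50)
    non_hub = [g for g in genes if g not in set(sim.hub_genes)]
    for g in rng.choice(non_hub, size=min(n_extra, len(non_hub)), replace=False):
        records.append((str(g), enriched))

    for t in range(1, n_terms):
        term = f"GO:SYN{t:04d}"
        size = int(rng.integers(5, max(6, len(genes) // 10)))
        for g in rng.choice(genes, size=min(size, len(genes)), replace=False):
            records.append((str(g), term))

    # transcription-activity terms on a known TF subset: alternate hubs,
    # a few module-core genes, and the first gene of every planted pair
    # (whose dyadic network components make them high-closeness)
    planted_tfs = list(sim.planted_pairs["gene_i"]) if len(sim.planted_pairs) else []
    tf_genes = sorted(
        set(sim.hub_genes[::2])
        | set(genes[: max(3, len(genes) // 60)])
        | set(planted_tfs)
    )
    for g in tf_genes:
        for term in TF_GO_TERMS[: 1 + int(rng.integers(0, len(TF_GO_TERMS)))]:
            records.append((g, term))
    go_annotation = (
        pd.DataFrame(records, columns=["gene", "term"])
        .drop_duplicates()
        .sort_values(["gene", "term"], ignore_index=True)
    )

    chroms = [f"chr{(i % 12) + 1}" for i in range(len(genes))]
    positions = [10_000 * (i // 12 + 1) for i in range(len(genes))]
    gene_positions = pd.DataFrame(
        {"gene": genes, "chrom": chroms, "pos": positions}
    )

    intervals = []
    for k in range(n_intervals):
        chrom = f"chr{(k % 12) + 1}"
        on_chrom = gene_positions[gene_positions["chrom"] == chrom]
        if on_chrom.empty:
            continue
        start_idx = int(rng.integers(0, max(1, len(on_chrom) - 3)))
        span = on_chrom.iloc[start_idx : start_idx + 4]
        intervals.append(
            (chrom, int(span["pos"].min()) - 500, int(span["pos"].max()) + 500,
             f"mqtl{k+1}")
        )
    marker_intervals = pd.DataFrame(
        intervals, columns=["chrom", "start", "end", "name"]
    )

    sim.go_annotation = go_annotation
    sim.marker_intervals = marker_intervals
    sim.gene_positions = gene_positions
    sim.tf_genes = tf_genes
    sim.enriched_term = enriched
    return go_annotation, marker_intervals, gene_positions
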