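"""Single-cell RNA-seq gene sets, transcriptional noise, and gating.

Stage- and cell-type-specific gene sets are called by a two-sample test
on per-cell normalized expression with Benjamini-Hochberg adjustment
plus expression-fraction filters: a member gene must be upregulated in
the target cells with adjusted p < 0.005, expressed in more than 20% of
the target cells (pct.1 > 0.2) and in fewer than 40% of the background
cells (pct.2 < 0.4). All three inequalities are strict.

Transcriptional noise of a stage is the distribution of cell-to-cell
distances d = sqrt((1 - rho) / 2) over the stage's 500 most variable
genes, rho being the pairwise Spearman correlation; a transcriptionally
homogeneous stage (e.g. the germline-competent formative epiblast)
scores low.

PGC-like cells are gated as (Dppa3 > 0.1 OR Prdm1 > 1) AND Klf4 < 1 on
normalized expression, i.e. germ-cell markers on, naive marker off.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = {"padj": 0.005, "pct1_min": 0.2, "pct2_max": 0.4}


def normalize_counts(counts: pd.DataFrame, scale: float = 1e4,
                     log1p: bool = False) -> pd.DataFrame:
    """Scale each cell (column) to `scale` total counts; optional log1p."""
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("cells with zero total counts cannot be normalized")
    norm = counts / totals * scale
    return np.log1p(norm) if log1p else norm


def _validate_matrix(counts: pd.DataFrame) -> None:
    if counts.index.duplicated().any():
        raise ValueError("duplicate gene ids")
    if counts.columns.duplicated().any():
        raise ValueError("duplicate cell ids")
    vals = counts.to_numpy()
    if (vals < 0).any():
        raise ValueError("negative counts")


@dataclass
class GeneSetResult:
    name: str
    table: pd.DataFrame  # per gene: padj, pct1, pct2, log2fc, member
    members: list[str] = field(default_factory=list)


def wilcoxon_rank_sum_test(target: np.ndarray, background: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value for one gene (default DE test)."""
    return float(
        stats.mannwhitneyu(target, background, alternative="two-sided").pvalue
    )


def define_gene_set(counts: pd.DataFrame, target_cells, background_cells,
                    thresholds: dict | None = None, name: str = "gene_set",
                    test=wilcoxon_rank_sum_test) -> GeneSetResult:
    """Call genes upregulated in target cells vs background.

    The per-gene two-sample `test` is pluggable and runs on per-cell
    normalized expression (counts per 10k); p-values are BH-adjusted.
    pct.1 / pct.2 are the fractions of target / background cells with a
    nonzero raw count.
    """
    _validate_matrix(counts)
    thr = {**DEFAULT_THRESHOLDS, **(thresholds or {})}
    target_cells = list(target_cells)
    background_cells = list(background_cells)
    if not target_cells or not background_cells:
        raise ValueError("target and background cell sets must be non-empty")
    if set(target_cells) & set(background_cells):
        raise ValueError("target and background cell sets overlap")
    for cid in target_cells + background_cells:
        if cid not in counts.columns:
            raise ValueError(f"cell {cid!r} not in matrix")

    norm = normalize_counts(counts)
    tgt_n = norm[target_cells].to_numpy()
    bgd_n = norm[background_cells].to_numpy()
    tgt_raw = counts[target_cells].to_numpy()
    bgd_raw = counts[background_cells].to_numpy()

    pct1 = (tgt_raw > 0).mean(axis=1)
    pct2 = (bgd_raw > 0).mean(axis=1)
    eps = 1e-9
    log2fc = np.log2((tgt_n.mean(axis=1) + eps) / (bgd_n.mean(axis=1) + eps))
    pvals = np.array([test(tgt_n[i], bgd_n[i]) for i in range(len(counts))])
    padj = multipletests(pvals, method="fdr_bh")[1]

    member = (
        (padj < thr["padj"]) & (pct1 > thr["pct1_min"]) & (pct2 < thr["pct2_max"])
        & (log2fc > 0)
    )
    table = pd.DataFrame(
        {"padj": padj, "pct1": pct1, "pct2": pct2, "log2fc": log2fc,
         "member": member},
        index=counts.index,
    )
    return GeneSetResult(name=name, table=table,
                         members=list(counts.index[member]))


@dataclass
class NoiseResult:
    stage: str
    distances: np.ndarray          # condensed upper-triangle pair distances
    cell_ids: list[str]
    variable_genes: list[str]
    n_excluded_pairs: int = 0

    @property
    def median(self) -> float:
        return float(np.median(self.distances))


def transcriptional_noise(counts: pd.DataFrame, meta: pd.DataFrame, stage: str,
                          n_variable_genes: int = 500) -> NoiseResult:
    """Cell-to-cell distance d = sqrt((1 - rho)/2) within one stage.

    Variable genes are ranked by dispersion (variance/mean) of per-cell
    normalized counts within the stage; rho is the pairwise Spearman
    correlation over those genes. Pairs involving a constant expression
    vector have undefined rho and are excluded with a warning.
    """
    cells = meta.index[meta["stage"] == stage]
    if len(cells) < 3:
        raise ValueError(f"stage {stage!r} has fewer than 3 cells")
    norm = normalize_counts(counts[cells])
    mean = norm.mean(axis=1)
    var = norm.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        dispersion = np.where(mean > 0, var / mean, 0.0)
    nonzero_var = int((var > 0).sum())
    if nonzero_var < n_variable_genes:
        raise ValueError(
            f"only {nonzero_var} genes with nonzero variance in stage {stage!r}; "
            f"need {n_variable_genes}"
        )
    order = np.argsort(-dispersion, kind="stable")[:n_variable_genes]
    genes = list(counts.index[order])
    sub = norm.iloc[order].to_numpy()

    with warnings.catch_warnings():
        # constant columns yield NaN correlations; handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        rho = stats.spearmanr(sub).statistic  # cells x cells over gene axis
    rho = np.atleast_2d(rho)
    const = sub.std(axis=0) == 0
    n_cells = sub.shape[1]
    dists, excluded = [], 0
    for i in range(n_cells):
        for j in range(i + 1, n_cells):
            if const[i] or const[j] or not np.isfinite(rho[i, j]):
                excluded += 1
                continue
            dists.append(np.sqrt((1.0 - np.clip(rho[i, j], -1.0, 1.0)) / 2.0))
    if excluded:
        warnings.warn(
            f"{excluded} cell pair(s) with constant expression excluded from "
            f"noise in stage {stage!r}"
        )
    return NoiseResult(stage=stage, distances=np.asarray(dists),
                       cell_ids=list(cells), variable_genes=genes,
                       n_excluded_pairs=excluded)


def gate_pgclc_cells(counts: pd.DataFrame,
                     dppa3: str = "Dppa3", prdm1: str = "Prdm1",
                     klf4: str = "Klf4",
                     thresholds: tuple[float, float, float] = (0.1, 1.0, 1.0),
                     normalized: pd.DataFrame | None = None) -> list[str]:
    """Gate PGC-like cells: (Dppa3 > 0.1 OR Prdm1 > 1) AND Klf4 < 1.

    Precedence: the naive marker Klf4 vetoes unconditionally — a cell
    with Klf4 >= 1 is never gated in. Expression is per-cell normalized
    (counts per 10k) unless a pre-normalized frame is supplied.
    """
    for gene in (dppa3, prdm1, klf4):
        if gene not in counts.index:
            raise ValueError(f"gating gene {gene!r} missing from matrix")
    expr = normalized if normalized is not None else normalize_counts(counts)
    t_dppa3, t_prdm1, t_klf4 = thresholds
    keep = (
        ((expr.loc[dppa3] > t_dppa3) | (expr.loc[prdm1] > t_prdm1))
        & (expr.loc[klf4] < t_klf4)
    )
    return list(expr.columns[keep])


def cluster_cells(embedding: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """K-means on a low-dimensional embedding (the embedding is an input).

    10 restarts, best inertia, deterministic for a fixed seed.
    """
    embedding = np.asarray(embedding, float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(embedding):
        raise ValueError("k exceeds the number of cells")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    return km.fit_predict(embedding)


@dataclass
class ClusterAnnotation:
    cluster: object               # whatever label type the caller used
    label: str                    # tissue name or 'undefined'
    pvalues: dict[str, float]     # BH-adjusted, per candidate tissue


def annotate_clusters(counts: pd.DataFrame, labels: np.ndarray,
                      marker_sets: dict[str, list[str]],
                      de_padj: float = 0.05, floor: float = 0.05
                      ) -> list[ClusterAnnotation]:
    """Annotate clusters by marker-set enrichment.

    Marker sets are expected pre-filtered to log2FC > 2.5 by the caller.
    Per cluster, upregulated genes (cluster vs rest, rank test, BH
    padj < de_padj, positive fold change) are tested for enrichment in
    each tissue's marker list with a one-sided hypergeometric test; the
    tissue with the most significant BH-adjusted enrichment wins, and
    clusters with no tissue below the significance floor are 'undefined'.
    """
    if not marker_sets:
        raise ValueError("no marker sets supplied")
    if any(len(v) == 0 for v in marker_sets.values()):
        raise ValueError("empty marker set")
    labels = np.asarray(labels)
    universe = set(counts.index)
    out = []
    for cl in sorted(set(labels.tolist())):
        in_cells = list(counts.columns[labels == cl])
        out_cells = list(counts.columns[labels != cl])
        de = define_gene_set(
            counts, in_cells, out_cells,
            thresholds={"padj": de_padj, "pct1_min": 0.0, "pct2_max": 1.0},
            name=f"cluster_{cl}",
        )
        up = set(de.members)
        tissues = sorted(marker_sets)
        pvals = []
        for tissue in tissues:
            markers = set(marker_sets[tissue]) & universe
            overlap = len(up & markers)
            pvals.append(
                float(stats.hypergeom.sf(overlap - 1, len(universe),
                                         len(markers), len(up)))
                if markers else 1.0
            )
        padj = multipletests(pvals, method="fdr_bh")[1]
        best = int(np.argmin(padj))
        label = tissues[best] if padj[best] < floor else "undefined"
        out.append(ClusterAnnotation(cluster=cl, label=label,
                                     pvalues=dict(zip(tissues, map(float, padj)))))
    return out


def cluster_fraction(labels, target) -> float:
    """Percent of entries labeled `target`, to one decimal.

    Used e.g. for the share of cells falling in the PGC-like cluster of
    an embryoid body, or the share of genes in a set with a given flag.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label vector")
    return round(float((labels == target).mean() * 100.0), 1)


def mean_gene_set_expression(expr: pd.DataFrame, gene_set) -> pd.Series:
    """Per-cell arithmetic mean of the gene set's expression values.

    `expr` may be raw UMI counts or normalized values; the caller picks
    the scale.
    """
    present = [g for g in gene_set if g in expr.index]
    if not present:
        raise ValueError("gene set does not intersect the matrix genes")
    return expr.loc[present].mean(axis=0)
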