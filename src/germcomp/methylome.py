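"""Single-cell CpG methylation filtering and heterogeneity.

Per-cell methylomes are sparse maps from CpG site to (methylated reads,
total reads). Sites are kept at a coverage of 3-100 reads (inclusive);
cells are kept when they cover strictly more than 100 distinct CpG
sites within the region set of interest. Epigenetic heterogeneity of a
cell population is the mean of pairwise dissimilarities: for each pair
of cells, the mean absolute difference of per-site methylation rates
over the CpGs covered in both cells, reported on a 0-100 percent scale.
For binary single-cell calls this equals the fraction of discordant
shared sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GenomicInterval

logger = logging.getLogger(__name__)


@dataclass
class CellMethylome:
    """CpG calls for one cell: a (chrom, pos)-indexed frame of m and t."""

    cell_id: str
    stage: str
    calls: pd.DataFrame  # columns chrom, pos, meth_count, total_count

    def __post_init__(self) -> None:
        c = self.calls
        if ((c["meth_count"] < 0) | (c["meth_count"] > c["total_count"])).any():
            raise ValueError(f"cell {self.cell_id}: need 0 <= m <= t at every site")

    def rates(self) -> pd.Series:
        """Per-site methylation rate m/t indexed by (chrom, pos)."""
        idx = pd.MultiIndex.from_frame(self.calls[["chrom", "pos"]])
        return pd.Series(
            self.calls["meth_count"].to_numpy()
            / self.calls["total_count"].to_numpy(),
            index=idx,
        )


def filter_cpg_sites(methylome: CellMethylome, min_cov: int = 3,
                     max_cov: int = 100) -> CellMethylome:
    """Keep sites with min_cov <= total reads <= max_cov (both inclusive)."""
    keep = methylome.calls["total_count"].between(min_cov, max_cov)
    return CellMethylome(methylome.cell_id, methylome.stage,
                         methylome.calls[keep].reset_index(drop=True))


def _sites_in_regions(calls: pd.DataFrame, regions) -> pd.Series:
    """Boolean mask of call rows whose CpG lies inside any region."""
    mask = np.zeros(len(calls), dtype=bool)
    chroms = calls["chrom"].to_numpy()
    pos = calls["pos"].to_numpy()
    for region in regions:
        mask |= (chroms == region.chrom) & (pos >= region.start) & (pos < region.end)
    return pd.Series(mask, index=calls.index)


def region_methylation(methylome: CellMethylome, regions) -> pd.Series:
    """Mean methylation rate (percent) of covered CpGs per region.

    Regions with no covered site get NaN (undefined), never 0.
    """
    out = {}
    for i, region in enumerate(regions):
        key = region.name or f"{region.chrom}:{region.start}-{region.end}"
        inside = _sites_in_regions(methylome.calls, [region])
        sub = methylome.calls[inside]
        if len(sub):
            out[key] = float(
                (sub["meth_count"] / sub["total_count"]).mean() * 100.0
            )
        else:
            out[key] = np.nan
    return pd.Series(out)


def filter_cells_by_region_coverage(cells, regions, min_sites: int = 100
                                    ) -> list[CellMethylome]:
    """Keep cells covering strictly more than min_sites CpGs in the regions."""
    kept = []
    for cell in cells:
        inside = _sites_in_regions(cell.calls, regions)
        n = cell.calls[inside][["chrom", "pos"]].drop_duplicates().shape[0]
        if n > min_sites:
            kept.append(cell)
    return kept


@dataclass
class MethDissimilarityMatrix:
    cell_ids: list[str]
    matrix: np.ndarray        # percent scale; NaN where no shared site
    shared: np.ndarray        # shared-CpG counts per pair
    low_confidence: np.ndarray = field(default=None)  # shared < floor

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.cell_ids,
                            columns=self.cell_ids)


def pairwise_dissimilarity(cells, regions, low_conf_floor: int = 5
                           ) -> MethDissimilarityMatrix:
    """Mean |rate_i - rate_j| over shared CpGs, per cell pair, x100.

    Only CpGs inside the region set and covered in both cells count.
    Pairs with zero shared sites are undefined (NaN) and logged; pairs
    with fewer than low_conf_floor shared sites are flagged
    low-confidence but still reported.
    """
    if not regions:
        raise ValueError("region set is empty")
    n = len(cells)
    rate_maps = []
    for cell in cells:
        inside = _sites_in_regions(cell.calls, regions)
        sub = cell.calls[inside]
        idx = pd.MultiIndex.from_frame(sub[["chrom", "pos"]])
        rate_maps.append(pd.Series(
            sub["meth_count"].to_numpy() / sub["total_count"].to_numpy(),
            index=idx,
        ))

    matrix = np.zeros((n, n))
    shared = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            common = rate_maps[i].index.intersection(rate_maps[j].index)
            shared[i, j] = shared[j, i] = len(common)
            if len(common) == 0:
                matrix[i, j] = matrix[j, i] = np.nan
                logger.warning(
                    "no shared CpGs between %s and %s; pair undefined",
                    cells[i].cell_id, cells[j].cell_id,
                )
                continue
            diff = np.abs(
                rate_maps[i].loc[common].to_numpy()
                - rate_maps[j].loc[common].to_numpy()
            )
            matrix[i, j] = matrix[j, i] = float(diff.mean() * 100.0)
    low = (shared < low_conf_floor) & ~np.eye(n, dtype=bool)
    return MethDissimilarityMatrix(
        cell_ids=[c.cell_id for c in cells], matrix=matrix, shared=shared,
        low_confidence=low,
    )


def stage_heterogeneity(dissim: MethDissimilarityMatrix,
                        stages: dict[str, str]) -> pd.Series:
    """Mean within-stage pairwise dissimilarity (defined entries only)."""
    labels = np.array([stages[c] for c in dissim.cell_ids])
    out = {}
    for stage in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == stage)
        if len(idx) < 2:
            raise ValueError(f"stage {stage!r} has fewer than 2 cells")
        vals = [
            dissim.matrix[i, j]
            for k, i in enumerate(idx) for j in idx[k + 1:]
            if np.isfinite(dissim.matrix[i, j])
        ]
        out[stage] = float(np.mean(vals)) if vals else np.nan
    return pd.Series(out)


def allele_methylation_summary(allele_matrix: np.ndarray
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Summarize a reads x CpGs matrix of calls (1 meth, 0 unmeth, NaN missing).

    Returns (per-CpG percent methylated over non-missing reads, per-read
    mean methylation over non-missing CpGs). All-missing columns/rows
    yield NaN.
    """
    m = np.asarray(allele_matrix, float)
    if m.ndim != 2 or m.shape[0] < 1:
        raise ValueError("need a reads x CpGs matrix with at least one read")
    valid = ~np.isnan(m)
    n_col, n_row = valid.sum(axis=0), valid.sum(axis=1)
    col_sum, row_sum = np.nansum(m, axis=0), np.nansum(m, axis=1)
    per_cpg = np.where(n_col > 0, col_sum / np.maximum(n_col, 1) * 100.0, np.nan)
    per_read = np.where(n_row > 0, row_sum / np.maximum(n_row, 1), np.nan)
    return per_cpg, per_read
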