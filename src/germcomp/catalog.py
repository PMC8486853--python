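"""Enhancer catalog construction.

Distal H3K27ac peaks are turned into an enhancer set in four steps:
replicate peaks merged when closer than a gap threshold, promoter and
blacklist regions subtracted, distal peaks linked to target genes via
chromatin-interaction anchor pairs, and (for stage enhancer sets without
interaction data) proximal assignment to the nearest gene-set TSS.

Defaults: 1 kb merge gap, TSS +/- 2 kb promoters, anchors within 1 kb of
a peak and 3 kb of a TSS, proximal assignment within 500 kb but at least
3.5 kb from any TSS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import groupby

from .core import GeneModel, GenomicInterval


@dataclass
class EnhancerRecord:
    """An enhancer interval plus the genes it is linked to."""

    interval: GenomicInterval
    genes: list[str] = field(default_factory=list)
    source: str = "interaction-linked"  # or "proximal"
    group: str | None = None  # filled in by chromatin_signal.classify_groups


def merge_peaks(peak_lists, gap_bp: int = 1000) -> list[GenomicInterval]:
    """Fuse peaks across replicate lists when separated by <= gap_bp.

    The union of all inputs is merged transitively: any two intervals
    that overlap or whose nearest edges are at most gap_bp apart end up
    in the same output interval. Output is sorted and pairwise farther
    than gap_bp apart.
    """
    if gap_bp < 0:
        raise ValueError("gap_bp must be >= 0")
    pooled = sorted(
        (iv for lst in peak_lists for iv in lst),
        key=lambda iv: (iv.chrom, iv.start, iv.end),
    )
    merged: list[GenomicInterval] = []
    for chrom, group in groupby(pooled, key=lambda iv: iv.chrom):
        cur_start = cur_end = None
        for iv in group:
            if cur_start is None:
                cur_start, cur_end = iv.start, iv.end
            elif iv.start - cur_end <= gap_bp:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        if cur_start is not None:
            merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


def promoter_regions(genes: list[GeneModel], flank: int = 2000,
                     chrom_lengths: dict[str, int] | None = None
                     ) -> list[GenomicInterval]:
    """TSS +/- flank windows, clipped at chromosome bounds when known."""
    out = []
    for g in genes:
        start = max(0, g.tss - flank)
        end = g.tss + flank
        if chrom_lengths is not None:
            end = min(end, chrom_lengths[g.chrom])
        if end > start:
            out.append(GenomicInterval(g.chrom, start, end))
    return out


def subtract_regions(intervals, masks) -> list[GenomicInterval]:
    """Remove every base covered by a mask region; drop emptied intervals."""
    mask_sorted = sorted(masks, key=lambda iv: (iv.chrom, iv.start, iv.end))
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for m in mask_sorted:
        by_chrom.setdefault(m.chrom, []).append(m)

    out: list[GenomicInterval] = []
    for iv in intervals:
        pieces = [(iv.start, iv.end)]
        for m in by_chrom.get(iv.chrom, ()):
            if m.start >= iv.end:
                break
            nxt = []
            for s, e in pieces:
                if m.end <= s or m.start >= e:
                    nxt.append((s, e))
                    continue
                if m.start > s:
                    nxt.append((s, m.start))
                if m.end < e:
                    nxt.append((m.end, e))
            pieces = nxt
            if not pieces:
                break
        out.extend(
            GenomicInterval(iv.chrom, s, e, name=iv.name) for s, e in pieces
        )
    return out


def _tss_distance(anchor: GenomicInterval, gene: GeneModel) -> float:
    return anchor.distance_to_point(gene.chrom, gene.tss)


def link_enhancers(peaks, interactions, genes: list[GeneModel],
                   gene_set: set[str], peak_dist: int = 1000,
                   tss_dist: int = 3000) -> list[EnhancerRecord]:
    """Link peaks to gene-set genes via interaction anchor pairs.

    A (peak, gene) link is emitted when one anchor of an interaction
    lies within peak_dist of the peak and the other anchor lies within
    tss_dist of the gene's TSS; both anchor orderings are tried.
    Distances are nearest-edge gaps (0 when overlapping). One record per
    peak aggregates all linked genes.
    """
    by_id = {g.gene_id: g for g in genes}
    missing = gene_set - set(by_id)
    if missing:
        raise ValueError(f"gene_set members without gene model: {sorted(missing)}")
    targets = [by_id[g] for g in sorted(gene_set)]

    links: dict[GenomicInterval, set[str]] = {}
    for pair in interactions:
        a1, a2 = pair[0], pair[1]
        for pa, ga in ((a1, a2), (a2, a1)):
            near_peaks = [p for p in peaks if pa.distance_to(p) <= peak_dist]
            if not near_peaks:
                continue
            near_genes = [g for g in targets if _tss_distance(ga, g) <= tss_dist]
            for p in near_peaks:
                for g in near_genes:
                    links.setdefault(p, set()).add(g.gene_id)

    return [
        EnhancerRecord(interval=p, genes=sorted(gs), source="interaction-linked")
        for p, gs in sorted(links.items())
    ]


def assign_proximal(peaks, genes: list[GeneModel], gene_set: set[str],
                    max_dist: int = 500_000, min_tss_dist: int = 3500
                    ) -> list[EnhancerRecord]:
    """Assign distal peaks to the nearest gene-set TSS.

    Keeps peaks within max_dist of some gene-set TSS and farther than
    min_tss_dist from the TSS of *any* gene (too-promoter-proximal peaks
    are dropped). Nearest gene ties break to the lexicographically
    smallest gene id.
    """
    by_id = {g.gene_id: g for g in genes}
    missing = gene_set - set(by_id)
    if missing:
        raise ValueError(f"gene_set members without gene model: {sorted(missing)}")
    targets = [by_id[g] for g in sorted(gene_set)]

    out: list[EnhancerRecord] = []
    for p in peaks:
        if min((_tss_distance(p, g) for g in genes), default=float("inf")) <= min_tss_dist:
            continue
        best = min(
            ((_tss_distance(p, g), g.gene_id) for g in targets),
            default=(float("inf"), ""),
        )
        if best[0] <= max_dist:
            out.append(EnhancerRecord(interval=p, genes=[best[1]], source="proximal"))
    return out


def enhancers_per_gene(records: list[EnhancerRecord]) -> float:
    """Enhancer records per distinct linked gene, to one decimal."""
    if not records:
        raise ValueError("no enhancer records")
    genes = {g for r in records for g in r.genes}
    if not genes:
        raise ValueError("no linked genes")
    return round(len(records) / len(genes), 1)
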