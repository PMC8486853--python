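"""Readers and writers for the plain-text genomic formats the pipeline uses.

BED/bedGraph/BEDPE are 0-based half-open. All tables go through pandas;
these helpers only fix column names and types.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import GeneModel, GenomicInterval, SignalTrack


# ---------------------------------------------------------------- BED / BEDPE

def read_bed(path) -> list[GenomicInterval]:
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            name = parts[3] if len(parts) > 3 else None
            out.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2]), name=name))
    return out


def write_bed(intervals, path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None:
                cols.append(iv.name)
            fh.write("\t".join(cols) + "\n")


def read_bedpe(path) -> list[tuple[GenomicInterval, GenomicInterval, str]]:
    """Return (anchor1, anchor2, name) triples; name '.' if absent."""
    pairs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            p = line.split("\t")
            a1 = GenomicInterval(p[0], int(p[1]), int(p[2]))
            a2 = GenomicInterval(p[3], int(p[4]), int(p[5]))
            name = p[6] if len(p) > 6 else "."
            pairs.append((a1, a2, name))
    return pairs


def write_bedpe(pairs, path) -> None:
    with open(path, "w") as fh:
        for a1, a2, name in pairs:
            fh.write(
                "\t".join(
                    [a1.chrom, str(a1.start), str(a1.end),
                     a2.chrom, str(a2.start), str(a2.end), name]
                )
                + "\n"
            )


# ------------------------------------------------------------------ bedGraph

def write_bedgraph(track: SignalTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom, vec in track.data.items():
            bs = track.bin_size
            for i, v in enumerate(vec):
                fh.write(f"{chrom}\t{i * bs}\t{(i + 1) * bs}\t{v:.6g}\n")


def read_bedgraph(path, bin_size: int, chrom_lengths: dict[str, int],
                  mark: str = "", stage: str = "", replicate: int = 0,
                  norm: str = "raw") -> SignalTrack:
    """Load a bedGraph whose records are aligned to a fixed bin grid."""
    data = {c: np.zeros(-(-length // bin_size)) for c, length in chrom_lengths.items()}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start, end, value = line.split("\t")
            start, end = int(start), int(end)
            if chrom not in data:
                raise ValueError(f"bedGraph chromosome {chrom!r} not in genome")
            if start % bin_size or (end - start) != bin_size:
                raise ValueError(
                    f"bedGraph record {chrom}:{start}-{end} not aligned to "
                    f"{bin_size} bp bins"
                )
            data[chrom][start // bin_size] = float(value)
    return SignalTrack(bin_size=bin_size, data=data, norm=norm,
                       mark=mark, stage=stage, replicate=replicate)


# ----------------------------------------------------------------- gene table

GENE_COLUMNS = ["gene_id", "name", "chrom", "tss", "strand"]


def write_gene_table(genes: list[GeneModel], path) -> None:
    df = pd.DataFrame(
        [(g.gene_id, g.name, g.chrom, g.tss, g.strand) for g in genes],
        columns=GENE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_gene_table(path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t")
    return [
        GeneModel(str(r.gene_id), str(r.name), str(r.chrom), int(r.tss), str(r.strand))
        for r in df.itertuples(index=False)
    ]


# ----------------------------------------------------------------- UMI matrix

def write_umi_matrix(counts: pd.DataFrame, meta: pd.DataFrame,
                     counts_path, meta_path) -> None:
    """counts: genes x cells integer DataFrame; meta indexed by cell_id."""
    counts.to_csv(counts_path, sep="\t")
    meta.to_csv(meta_path, sep="\t")


def read_umi_matrix(counts_path, meta_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return counts, meta


# ----------------------------------------------------- per-cell methylation

METH_COLUMNS = ["chrom", "pos", "meth_count", "total_count"]


def write_methylation_calls(calls: pd.DataFrame, path) -> None:
    calls[METH_COLUMNS].to_csv(path, sep="\t", index=False)


def read_methylation_calls(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(METH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"methylation file {path} missing columns {sorted(missing)}")
    return df[METH_COLUMNS].copy()
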