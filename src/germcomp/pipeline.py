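"""End-to-end orchestration of the synthetic demo pipeline.

Stages: synthetic-data generation -> scRNA-seq gene sets / noise /
gating / clustering -> enhancer catalog -> chromatin quantification and
Group I/II classification -> methylome heterogeneity. Every stage reads
and writes plain-text files under the run directory; all randomness
flows from the single master seed in the config; reruns with the same
config and seed produce byte-identical analysis outputs (the run
manifest additionally records wall-clock timestamps).
"""

from __future__ import annotations

import dataclasses
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import catalog, io as gio, methylome as meth, scrna, signal as csig
from .synthetic import SimulationConfig, generate_dataset, write_dataset

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Every tunable threshold, at the study defaults."""

    seed: int = 0
    # enhancer catalog
    gap: int = 1000
    promoter_flank: int = 2000
    peak_dist: int = 1000
    tss_dist: int = 3000
    max_dist: int = 500_000
    min_tss_dist: int = 3500
    # chromatin signal
    flank: int = 1000
    ratio_threshold: float = 1.2
    min_replicates: int = 2
    pseudocount: float = 0.01
    n_boot: int = 1000
    # gene sets / noise / gating
    padj: float = 0.005
    pct1_min: float = 0.2
    pct2_max: float = 0.4
    gate_dppa3: float = 0.1
    gate_prdm1: float = 1.0
    gate_klf4: float = 1.0
    n_variable_genes: int = 500
    k_eb: int = 4
    # methylome
    cpg_min_cov: int = 3
    cpg_max_cov: int = 100
    min_sites: int = 100
    # synthetic-data generation
    simulate: bool = True
    sim: dict = field(default_factory=dict)  # overrides for SimulationConfig

    def validate(self) -> None:
        positive = ["gap", "promoter_flank", "peak_dist", "tss_dist",
                    "max_dist", "min_tss_dist", "flank", "ratio_threshold",
                    "min_replicates", "n_boot", "padj", "pct1_min",
                    "pct2_max", "n_variable_genes", "k_eb", "cpg_min_cov",
                    "cpg_max_cov", "min_sites"]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name!r} must be positive")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def simulation_config(self) -> SimulationConfig:
        return SimulationConfig(seed=self.seed, **self.sim)


def _log_stage(stage: str, t0: float, **counts) -> dict:
    rec = {"stage": stage, "seconds": round(time.perf_counter() - t0, 3), **counts}
    logger.info("stage %s done: %s", stage, rec)
    return rec


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run all stages; return the run manifest (also written as YAML)."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage_logs = []
    outputs: dict[str, str] = {}

    # ------------------------------------------------------------ simulate
    t0 = time.perf_counter()
    try:
        if not config.simulate:
            raise StageError("simulate", "only synthetic-input runs are supported "
                             "by run_pipeline; invoke stage commands directly "
                             "for external data")
        ds = generate_dataset(config.simulation_config())
        write_dataset(ds, outdir / "data")
        outputs["data"] = "data"
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("simulate", str(exc)) from exc
    stage_logs.append(_log_stage(
        "simulate", t0,
        n_enhancers=len(ds.genome.enhancers), n_cells=ds.umi.counts.shape[1],
        n_methylomes=len(ds.methylomes),
    ))

    # ------------------------------------------------------------ genesets
    t0 = time.perf_counter()
    try:
        meta = ds.umi.meta
        eb = meta[meta["stage"] == "d4EB"]
        target = list(eb.index[eb["cluster"] == "PGCLC"])
        background = list(eb.index[eb["cluster"] != "PGCLC"])
        gs = scrna.define_gene_set(
            ds.umi.counts, target, background,
            thresholds={"padj": config.padj, "pct1_min": config.pct1_min,
                        "pct2_max": config.pct2_max},
            name="PGCLC",
        )
        gs.table.to_csv(outdir / "pgclc_gene_set.tsv", sep="\t")
        outputs["gene_set"] = "pgclc_gene_set.tsv"
    except Exception as exc:  # noqa: BLE001
        raise StageError("genesets", str(exc)) from exc
    stage_logs.append(_log_stage("genesets", t0, n_members=len(gs.members)))

    # --------------------------------------------------------------- noise
    t0 = time.perf_counter()
    try:
        noise_rows = []
        for stage in sorted(ds.config.stage_cells):
            res = scrna.transcriptional_noise(
                ds.umi.counts, meta, stage,
                n_variable_genes=config.n_variable_genes,
            )
            noise_rows.append((stage, res.median, len(res.distances)))
        noise_df = pd.DataFrame(noise_rows,
                                columns=["stage", "median_noise", "n_pairs"])
        noise_df.to_csv(outdir / "transcriptional_noise.tsv", sep="\t",
                        index=False)
        outputs["noise"] = "transcriptional_noise.tsv"
    except Exception as exc:  # noqa: BLE001
        raise StageError("noise", str(exc)) from exc
    stage_logs.append(_log_stage("noise", t0, n_stages=len(noise_rows)))

    # ---------------------------------------------------------------- gate
    t0 = time.perf_counter()
    try:
        gated = scrna.gate_pgclc_cells(
            ds.umi.counts,
            thresholds=(config.gate_dppa3, config.gate_prdm1, config.gate_klf4),
        )
        pd.Series(gated, name="cell_id").to_csv(
            outdir / "gated_cells.tsv", sep="\t", index=False)
        outputs["gated_cells"] = "gated_cells.tsv"
    except Exception as exc:  # noqa: BLE001
        raise StageError("gate", str(exc)) from exc
    stage_logs.append(_log_stage("gate", t0, n_gated=len(gated)))

    # ------------------------------------------------------------ clusters
    t0 = time.perf_counter()
    try:
        emb = ds.umi.embedding
        labels = scrna.cluster_cells(emb.to_numpy(), k=config.k_eb,
                                     seed=config.seed)
        marker_sets = dict(ds.umi.tissue_markers)
        marker_sets["PGCLC"] = ds.umi.marker_genes
        ann = scrna.annotate_clusters(ds.umi.counts[emb.index], labels,
                                      marker_sets)
        pd.DataFrame(
            [(a.cluster, a.label) for a in ann], columns=["cluster", "label"]
        ).to_csv(outdir / "eb_clusters.tsv", sep="\t", index=False)
        outputs["eb_clusters"] = "eb_clusters.tsv"
    except Exception as exc:  # noqa: BLE001
        raise StageError("clusters", str(exc)) from exc
    stage_logs.append(_log_stage("clusters", t0, k=config.k_eb))

    # ------------------------------------------------------------- catalog
    t0 = time.perf_counter()
    peaks_path = outdir / "data" / "peaks.bed"
    try:
        if not peaks_path.exists():
            raise StageError("catalog", f"missing peak file: {peaks_path}")
        peaks = gio.read_bed(peaks_path)
        merged = catalog.merge_peaks([peaks], gap_bp=config.gap)
        promoters = catalog.promoter_regions(
            ds.genome.genes, flank=config.promoter_flank,
            chrom_lengths=ds.genome.chrom_lengths)
        distal = catalog.subtract_regions(merged, promoters)
        records = catalog.link_enhancers(
            distal, [(a1, a2) for a1, a2, _ in ds.interactions],
            ds.genome.genes, ds.genome.gene_set(),
            peak_dist=config.peak_dist, tss_dist=config.tss_dist)
        rows = [
            (r.interval.chrom, r.interval.start, r.interval.end,
             ",".join(r.genes), r.source)
            for r in records
        ]
        pd.DataFrame(rows, columns=["chrom", "start", "end", "genes", "source"]
                     ).to_csv(outdir / "enhancers.tsv", sep="\t", index=False)
        outputs["enhancers"] = "enhancers.tsv"
        epg = catalog.enhancers_per_gene(records)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("catalog", str(exc)) from exc
    stage_logs.append(_log_stage("catalog", t0, n_peaks=len(peaks),
                                 n_enhancers=len(records),
                                 enhancers_per_gene=epg))

    # ------------------------------------------- quantify/classify/effects
    t0 = time.perf_counter()
    try:
        linked = [r.interval for r in records]
        norm_tracks = {
            key: csig.rpgc_normalize(tr) for key, tr in ds.tracks.items()
        }
        window_means = {}
        for rep in range(1, ds.config.n_replicates + 1):
            epilc = csig.window_signal(
                norm_tracks[("H3K4me1", "EpiLC", rep)], linked,
                flank=config.flank)
            episc = csig.window_signal(
                norm_tracks[("H3K4me1", "EpiSC", rep)], linked,
                flank=config.flank)
            window_means[rep] = (epilc, episc)
        cls = csig.classify_groups(
            window_means, threshold=config.ratio_threshold,
            min_replicates=config.min_replicates,
            pseudocount=config.pseudocount)
        cls_df = pd.DataFrame(
            cls.ratios, columns=[f"ratio_rep{r}" for r in sorted(window_means)])
        cls_df.insert(0, "enhancer",
                      [f"{iv.chrom}:{iv.start}-{iv.end}" for iv in linked])
        cls_df["group"] = cls.labels
        cls_df.to_csv(outdir / "enhancer_groups.tsv", sep="\t", index=False)
        outputs["enhancer_groups"] = "enhancer_groups.tsv"

        group1 = [iv for iv, lab in zip(linked, cls.labels) if lab == "Group I"]
        rep1_epilc, rep1_episc = window_means[1]
        g1_mask = cls.labels == "Group I"
        eff = csig.paired_effect_size(
            rep1_episc[g1_mask], rep1_epilc[g1_mask],
            n_boot=config.n_boot, seed=config.seed)
        pd.DataFrame(
            [("H3K4me1", "EpiSC-vs-EpiLC", eff.z, eff.n, eff.r,
              eff.ci_low, eff.ci_high)],
            columns=["mark", "comparison", "z", "n", "r", "ci_low", "ci_high"],
        ).to_csv(outdir / "effect_sizes.tsv", sep="\t", index=False)
        outputs["effect_sizes"] = "effect_sizes.tsv"

        rho, _, _ = csig.flank_methylation_correlation(
            ds.meth_track, norm_tracks[("H3K4me1", "EpiLC", 1)], group1)
    except Exception as exc:  # noqa: BLE001
        raise StageError("classify", str(exc)) from exc
    stage_logs.append(_log_stage(
        "classify", t0, n_group1=int(g1_mask.sum()),
        n_group2=int((~g1_mask).sum()), effect_r=round(eff.r, 3),
        flank_meth_rho=round(rho, 3)))

    # ------------------------------------------------------------ methylome
    t0 = time.perf_counter()
    try:
        regions = ds.genome.enhancer_intervals(("I", "II"))
        cells = [meth.filter_cpg_sites(c, config.cpg_min_cov,
                                       config.cpg_max_cov)
                 for c in ds.methylomes]
        kept = meth.filter_cells_by_region_coverage(
            cells, regions, min_sites=config.min_sites)
        dissim = meth.pairwise_dissimilarity(kept, regions)
        dissim.to_frame().to_csv(outdir / "dissimilarity.tsv", sep="\t")
        het = meth.stage_heterogeneity(
            dissim, {c.cell_id: c.stage for c in kept})
        het.rename("mean_dissimilarity_pct").to_csv(
            outdir / "stage_heterogeneity.tsv", sep="\t")
        outputs["dissimilarity"] = "dissimilarity.tsv"
        outputs["stage_heterogeneity"] = "stage_heterogeneity.tsv"
    except Exception as exc:  # noqa: BLE001
        raise StageError("methylome", str(exc)) from exc
    stage_logs.append(_log_stage("methylome", t0, n_cells_kept=len(kept)))

    from . import __version__
    manifest = {
        "config": dataclasses.asdict(config),
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "outputs": outputs,
        "stages": stage_logs,
    }
    for rel in outputs.values():
        p = outdir / rel
        if not p.exists() or (p.is_file() and p.stat().st_size == 0):
            raise StageError("manifest", f"declared output missing/empty: {p}")
    with open(outdir / "run_manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest


def validate_inputs(data_dir) -> dict:
    """Schema checks on a generated data directory; never raises on content.

    Returns {'violations': [{'path':..., 'line':..., 'message':...}, ...]}.
    """
    data_dir = Path(data_dir)
    violations: list[dict] = []

    def add(path, line, message):
        violations.append({"path": str(path), "line": line, "message": message})

    for bed in sorted(data_dir.glob("*.bed")):
        prev: tuple | None = None
        with open(bed) as fh:
            for ln, raw in enumerate(fh, 1):
                parts = raw.rstrip("\n").split("\t")
                try:
                    start, end = int(parts[1]), int(parts[2])
                except (IndexError, ValueError):
                    add(bed, ln, "malformed BED line")
                    continue
                if start < 0 or start >= end:
                    add(bed, ln, f"invalid interval {start}-{end}")
                key = (parts[0], start, end)
                if prev is not None and key < prev:
                    add(bed, ln, "file not coordinate-sorted")
                prev = key

    for bedpe in sorted(data_dir.glob("*.bedpe")):
        with open(bedpe) as fh:
            for ln, raw in enumerate(fh, 1):
                p = raw.rstrip("\n").split("\t")
                try:
                    coords = [int(p[1]), int(p[2]), int(p[4]), int(p[5])]
                except (IndexError, ValueError):
                    add(bedpe, ln, "malformed BEDPE line")
                    continue
                if coords[0] >= coords[1] or coords[2] >= coords[3]:
                    add(bedpe, ln, "invalid anchor interval")

    counts_path = data_dir / "umi_counts.tsv"
    if counts_path.exists():
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        vals = counts.to_numpy()
        if (vals < 0).any():
            add(counts_path, None, "negative counts")
        if not np.allclose(vals, np.round(vals)):
            add(counts_path, None, "non-integral counts")

    for mf in sorted(data_dir.glob("methylomes/*.tsv")):
        df = pd.read_csv(mf, sep="\t")
        bad = df.index[df["meth_count"] > df["total_count"]]
        for i in bad:
            add(mf, int(i) + 2, "meth_count exceeds total_count")

    return {"violations": violations, "n_files_checked": True}
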