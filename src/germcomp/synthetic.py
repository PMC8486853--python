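"""Synthetic data with planted ground truth for the whole pipeline.

The generator emulates the shapes of the study inputs on a toy genome
(default two 1 Mb chromosomes, 100 bp bins): multi-replicate H3K4me1
tracks in EpiLC and EpiSC with a planted subset of enhancers whose
EpiLC signal is a configured fold above EpiSC (class I; class II equal
means), chromatin-interaction anchor pairs linking true enhancers to
their target-gene TSSs plus decoy pairs violating the distance rules,
stage-labeled UMI count matrices with a rare PGC-like cluster and
planted marker genes, and stage-labeled sparse single-cell methylomes
whose cell-to-cell variance is set per stage by a beta-distribution
concentration.

Everything is driven by a single master seed; each generator draws from
an independent substream (seed plus a fixed stream offset) so adding a
replicate or stage does not perturb the others. Replicate noise on the
signal tracks is multiplicative lognormal, which keeps coverage
positive and makes windowed-ratio tails analytically tractable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as gio
from .core import GeneModel, GenomicInterval, SignalTrack

# fixed stream ids so each generator has an independent substream
_STREAM_GENOME = 1
_STREAM_TRACKS = 2
_STREAM_INTERACTIONS = 3
_STREAM_UMI = 4
_STREAM_METH = 5
_STREAM_METHTRACK = 6
_STREAM_INTENSITY = 7


def _rng(seed: int, stream: int, *extra: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream, *extra])


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with the study defaults."""

    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 1_000_000, "chr2": 1_000_000}
    )
    bin_size: int = 100
    n_genes: int = 50

    # enhancer truth classes
    n_class1: int = 40
    n_class2: int = 40
    n_decoy: int = 20
    enhancer_width: int = 600
    min_enhancer_gap: int = 3000
    min_tss_gap: int = 3500

    # signal tracks
    class1_fold: float = 2.0
    class2_fold: float = 1.0
    track_lognorm_sd: float = 0.1
    background_level: float = 0.2
    enhancer_level: float = 3.0
    n_replicates: int = 3
    signal_flank: int = 1000  # fold applied across midpoint +/- this

    # interactions
    n_decoy_pairs: int = 40
    anchor_width: int = 500

    # UMI matrices
    n_null_genes: int = 550
    n_markers: int = 20
    marker_fold: float = 4.0
    base_expression: float = 2.0
    stage_cells: dict[str, int] = field(
        default_factory=lambda: {"ESC": 100, "EpiLC": 100, "EpiSC": 100}
    )
    stage_dispersion: dict[str, float] = field(
        default_factory=lambda: {"ESC": 0.6, "EpiLC": 0.1, "EpiSC": 0.6}
    )
    eb_clusters: dict[str, int] = field(
        default_factory=lambda: {
            "PGCLC": 23, "ExEctoderm": 70, "ExMesoderm": 70, "Endothelial": 37,
        }
    )
    eb_dispersion: float = 0.4

    # single-cell methylomes
    meth_stages: dict[str, float] = field(
        # stage -> beta concentration; smaller = more heterogeneous
        default_factory=lambda: {"E4.5": 8.0, "E5.5": 2.0, "E6.5": 50.0}
    )
    meth_cells_per_stage: int = 12
    cpgs_per_enhancer: int = 10
    site_coverage_prob: float = 0.6
    mean_read_depth: float = 12.0

    def validate(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        if any(l <= 0 for l in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be positive")
        if any(l % self.bin_size for l in self.chrom_lengths.values()):
            raise ValueError("bin size must divide every chromosome length")
        if self.class1_fold <= 1.2:
            raise ValueError(
                "class-I fold must exceed the 1.2 classification threshold"
            )


@dataclass(frozen=True)
class EnhancerTruth:
    interval: GenomicInterval
    klass: str                 # 'I', 'II' or 'decoy'
    target_gene: str | None    # None for decoys


@dataclass
class SyntheticGenome:
    chrom_lengths: dict[str, int]
    genes: list[GeneModel]
    enhancers: list[EnhancerTruth]

    def enhancer_intervals(self, classes=("I", "II")) -> list[GenomicInterval]:
        return [e.interval for e in self.enhancers if e.klass in classes]

    def gene_set(self) -> set[str]:
        return {e.target_gene for e in self.enhancers if e.target_gene}


def gen_genome(config: SimulationConfig) -> SyntheticGenome:
    """Place genes and disjoint enhancers on the toy genome.

    Enhancers are kept >= min_tss_gap from every TSS (so the
    promoter-proximity rules downstream are exercised non-trivially)
    and >= min_enhancer_gap apart (so +/- 1 kb windows never bleed into
    a neighboring enhancer).
    """
    config.validate()
    rng = _rng(config.seed, _STREAM_GENOME)
    chroms = sorted(config.chrom_lengths)
    total_len = sum(config.chrom_lengths.values())
    n_enh = config.n_class1 + config.n_class2 + config.n_decoy
    footprint = config.enhancer_width + config.min_enhancer_gap
    if n_enh * footprint > total_len:
        raise ValueError(
            f"{n_enh} enhancers with a {footprint} bp footprint cannot fit "
            f"disjointly in {total_len} bp"
        )

    genes: list[GeneModel] = []
    for i in range(config.n_genes):
        chrom = chroms[i % len(chroms)]
        margin = config.min_tss_gap + 1
        tss = int(rng.integers(margin, config.chrom_lengths[chrom] - margin))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"gene{i:04d}", f"Gene{i:04d}", chrom, tss, strand))

    placed: list[GenomicInterval] = []
    attempts = 0
    while len(placed) < n_enh:
        attempts += 1
        if attempts > n_enh * 2000:
            raise ValueError("could not place enhancers under the distance rules")
        chrom = chroms[int(rng.integers(len(chroms)))]
        clen = config.chrom_lengths[chrom]
        # margin leaves room for signal windows and upstream anchors
        lo = max(config.signal_flank + config.bin_size, 2000)
        hi = clen - config.enhancer_width - lo
        if hi <= lo:
            continue
        start = int(rng.integers(lo, hi))
        cand = GenomicInterval(chrom, start, start + config.enhancer_width)
        if any(
            cand.distance_to_point(g.chrom, g.tss) <= config.min_tss_gap
            for g in genes
        ):
            continue
        if any(cand.distance_to(p) < config.min_enhancer_gap for p in placed):
            continue
        placed.append(cand)

    placed.sort()
    order = rng.permutation(n_enh)
    classes = (["I"] * config.n_class1 + ["II"] * config.n_class2
               + ["decoy"] * config.n_decoy)
    enhancers = []
    gene_ids = [g.gene_id for g in genes]
    for idx, klass in zip(order, classes):
        target = None
        if klass != "decoy":
            # prefer a same-chromosome target so interaction anchors are local
            same = [g for g in genes if g.chrom == placed[idx].chrom]
            target = same[int(rng.integers(len(same)))].gene_id if same else (
                gene_ids[int(rng.integers(len(gene_ids)))]
            )
        enhancers.append(EnhancerTruth(placed[idx], klass, target))
    enhancers.sort(key=lambda e: e.interval)
    return SyntheticGenome(dict(config.chrom_lengths), genes, enhancers)


def _enhancer_intensities(genome: SyntheticGenome, config: SimulationConfig
                          ) -> np.ndarray:
    """Per-enhancer lognormal intensity factors, shared across stages and
    replicates (so stage ratios are unaffected) and with the methylation
    track (so methylation can be planted inversely to H3K4me1)."""
    rng = _rng(config.seed, _STREAM_INTENSITY)
    return np.exp(rng.normal(0.0, 0.5, size=len(genome.enhancers)))


def gen_signal_tracks(genome: SyntheticGenome, config: SimulationConfig
                      ) -> dict[tuple[str, str, int], SignalTrack]:
    """Raw H3K4me1 tracks per (stage, replicate) with planted folds.

    The stage fold (class I: class1_fold in EpiLC, class II / decoy:
    class2_fold) is applied across each enhancer's midpoint
    +/- signal_flank so that windowed EpiLC/EpiSC ratios equal the fold
    exactly in the zero-noise limit. Noise is multiplicative lognormal
    per bin, independent across replicates.
    """
    bs = config.bin_size
    means: dict[str, dict[str, np.ndarray]] = {}
    for stage in ("EpiLC", "EpiSC"):
        means[stage] = {
            c: np.full(l // bs, config.background_level, dtype=float)
            for c, l in genome.chrom_lengths.items()
        }
    intensities = _enhancer_intensities(genome, config)
    for enh, intensity in zip(genome.enhancers, intensities):
        iv = enh.interval
        mid = iv.midpoint
        lo = max(0, mid - config.signal_flank)
        hi = min(genome.chrom_lengths[iv.chrom], mid + config.signal_flank)
        b0, b1 = lo // bs, -(-hi // bs)
        fold = config.class1_fold if enh.klass == "I" else config.class2_fold
        level = config.enhancer_level * intensity
        means["EpiSC"][iv.chrom][b0:b1] = level
        means["EpiLC"][iv.chrom][b0:b1] = level * fold

    tracks: dict[tuple[str, str, int], SignalTrack] = {}
    for si, stage in enumerate(("EpiLC", "EpiSC")):
        for rep in range(1, config.n_replicates + 1):
            rng = _rng(config.seed, _STREAM_TRACKS, si, rep)
            data = {}
            for chrom, mu in means[stage].items():
                if config.track_lognorm_sd > 0:
                    noise = np.exp(
                        rng.normal(0.0, config.track_lognorm_sd, size=mu.shape)
                    )
                    data[chrom] = mu * noise
                else:
                    data[chrom] = mu.copy()
            tracks[("H3K4me1", stage, rep)] = SignalTrack(
                bin_size=bs, data=data, norm="raw",
                mark="H3K4me1", stage=stage, replicate=rep,
            )
    return tracks


def gen_methylation_track(genome: SyntheticGenome, config: SimulationConfig
                          ) -> SignalTrack:
    """Percent-mCpG track anti-correlated with H3K4me1 around enhancers.

    Background is highly methylated; bins inside the planted H3K4me1
    domains are hypomethylated in proportion to the stage fold, with
    additive noise. Used by the demo pipeline for the flanking-bin
    methylation-H3K4me1 correlation.
    """
    rng = _rng(config.seed, _STREAM_METHTRACK)
    bs = config.bin_size
    data = {
        c: np.full(l // bs, 80.0) for c, l in genome.chrom_lengths.items()
    }
    intensities = _enhancer_intensities(genome, config)
    for enh, intensity in zip(genome.enhancers, intensities):
        iv = enh.interval
        mid = iv.midpoint
        lo = max(0, mid - config.signal_flank)
        hi = min(genome.chrom_lengths[iv.chrom], mid + config.signal_flank)
        b0, b1 = lo // bs, -(-hi // bs)
        fold = config.class1_fold if enh.klass == "I" else config.class2_fold
        # more H3K4me1 -> less methylation
        data[iv.chrom][b0:b1] = 80.0 / (
            1.0 + config.enhancer_level * intensity * fold / 2.0
        )
    for chrom, v in data.items():
        v += rng.normal(0.0, 2.0, size=v.shape)
        np.clip(v, 0.0, 100.0, out=v)
    return SignalTrack(bin_size=bs, data=data, norm="raw", mark="mCpG",
                       stage="EpiLC", replicate=1)


def gen_interactions(genome: SyntheticGenome, config: SimulationConfig
                     ) -> list[tuple[GenomicInterval, GenomicInterval, str]]:
    """Anchor pairs: one true pair per class I/II enhancer plus decoys.

    True pairs place one anchor within 1 kb of the enhancer and the
    partner within 3 kb of the target TSS. Decoy pairs violate at least
    one of the two distance rules by a wide margin.
    """
    rng = _rng(config.seed, _STREAM_INTERACTIONS)
    aw = config.anchor_width
    genes = {g.gene_id: g for g in genome.genes}
    true_enh = [e for e in genome.enhancers if e.klass != "decoy"]
    pairs = []
    for enh in true_enh:
        iv = enh.interval
        gap = int(rng.integers(0, 900))  # nearest-edge gap <= 1 kb
        a1 = GenomicInterval(iv.chrom, max(0, iv.start - gap - aw),
                             max(aw, iv.start - gap))
        g = genes[enh.target_gene]
        tgap = int(rng.integers(0, 2800))  # anchor edge <= 3 kb from TSS
        a2 = GenomicInterval(g.chrom, g.tss + tgap + 1, g.tss + tgap + 1 + aw)
        pairs.append((a1, a2, f"true:{enh.target_gene}"))

    all_enh = [e.interval for e in genome.enhancers]
    tss_list = [(g.chrom, g.tss) for g in genome.genes]
    n_made = 0
    while n_made < config.n_decoy_pairs:
        chrom = str(rng.choice(sorted(genome.chrom_lengths)))
        clen = genome.chrom_lengths[chrom]
        s1 = int(rng.integers(0, clen - aw))
        a1 = GenomicInterval(chrom, s1, s1 + aw)
        # a1 violates the 1 kb peak rule AND the 3 kb TSS rule by a wide
        # margin, so the pair fails under either anchor ordering
        if any(a1.distance_to(e) <= 2000 for e in all_enh):
            continue
        if any(a1.distance_to_point(c, t) <= 4000 for c, t in tss_list):
            continue
        s2 = int(rng.integers(0, clen - aw))
        a2 = GenomicInterval(chrom, s2, s2 + aw)
        pairs.append((a1, a2, "decoy"))
        n_made += 1
    return pairs


@dataclass
class UMIDataset:
    counts: pd.DataFrame       # genes x cells
    meta: pd.DataFrame         # index cell_id; columns stage, cluster
    embedding: pd.DataFrame    # EB cells x (x, y)
    marker_genes: list[str]    # planted PGC-like markers
    tissue_markers: dict[str, list[str]]


def _nb_draws(rng: np.random.Generator, mu: np.ndarray, dispersion: float,
              size) -> np.ndarray:
    """Negative binomial with var = mu + dispersion * mu^2 (Poisson at 0)."""
    mu = np.broadcast_to(mu, size)
    if dispersion <= 0:
        return rng.poisson(mu)
    n = 1.0 / dispersion
    p = n / (n + mu)
    return rng.negative_binomial(n, np.broadcast_to(p, size))


def gen_umi_matrix(config: SimulationConfig) -> UMIDataset:
    """Stage-labeled UMI counts with a rare PGC-like cluster.

    Pluripotent stages (ESC / EpiLC / EpiSC) differ only in negative
    binomial dispersion — EpiLC is generated with the lowest dispersion
    so the transcriptional-noise statistic ranks it lowest by
    construction. A d4 embryoid-body stage carries truth clusters; the
    rare PGC-like cluster over-expresses the planted marker genes and
    the gating genes (Dppa3, Prdm1 on; Klf4 off), while each
    extraembryonic-like cluster over-expresses its own tissue markers.
    """
    rng = _rng(config.seed, _STREAM_UMI)
    gating = ["Dppa3", "Prdm1", "Klf4"]
    markers = [f"pgclc_mk{i:02d}" for i in range(1, config.n_markers + 1)]
    tissues = [t for t in config.eb_clusters if t != "PGCLC"]
    tissue_markers = {
        t: [f"{t.lower()}_mk{i:02d}" for i in range(1, 11)] for t in tissues
    }
    null_genes = [f"null{i:04d}" for i in range(config.n_null_genes)]
    genes = (gating + markers
             + [g for t in tissues for g in tissue_markers[t]] + null_genes)

    base = rng.gamma(2.0, config.base_expression / 2.0, size=len(genes))
    base = pd.Series(base, index=genes).clip(lower=0.05)
    # marker genes are nearly silent outside their own population, as real
    # lineage markers are; otherwise the pct.2 < 0.4 filter would never pass
    all_markers = markers + [g for t in tissues for g in tissue_markers[t]]
    base[all_markers] = rng.uniform(0.2, 0.35, size=len(all_markers))
    # gating genes get stable moderate baselines so thresholds are meaningful
    base[["Dppa3", "Prdm1", "Klf4"]] = 0.05  # off unless boosted per group

    blocks = []
    metas = []
    for stage, n_cells in config.stage_cells.items():
        mu = base.copy()
        if stage == "ESC":
            mu["Klf4"] = 5.0  # naive marker on in ESC
        disp = config.stage_dispersion[stage]
        counts = _nb_draws(rng, mu.to_numpy()[:, None], disp,
                           (len(genes), n_cells))
        blocks.append(counts)
        metas.extend((f"{stage}_{i:04d}", stage, stage) for i in range(n_cells))

    emb_rows = []
    centers = {name: (8.0 * i, 8.0 * (i % 2))
               for i, name in enumerate(sorted(config.eb_clusters))}
    for cluster, n_cells in config.eb_clusters.items():
        mu = base.copy()
        if cluster == "PGCLC":
            mu[markers] = base[markers] * config.marker_fold
            mu["Dppa3"] = 4.0
            mu["Prdm1"] = 4.0
        else:
            mu[tissue_markers[cluster]] = (
                base[tissue_markers[cluster]] * 8.0  # log2FC > 2.5 planted
            )
        counts = _nb_draws(rng, mu.to_numpy()[:, None], config.eb_dispersion,
                           (len(genes), n_cells))
        blocks.append(counts)
        cx, cy = centers[cluster]
        for i in range(n_cells):
            cid = f"d4EB_{cluster}_{i:04d}"
            metas.append((cid, "d4EB", cluster))
            emb_rows.append((cid, cx + rng.normal(0, 0.6),
                             cy + rng.normal(0, 0.6)))

    counts = pd.DataFrame(np.hstack(blocks), index=genes,
                          columns=[m[0] for m in metas])
    meta = pd.DataFrame(
        {"stage": [m[1] for m in metas], "cluster": [m[2] for m in metas]},
        index=pd.Index([m[0] for m in metas], name="cell_id"),
    )
    embedding = pd.DataFrame(
        [(r[1], r[2]) for r in emb_rows], columns=["x", "y"],
        index=pd.Index([r[0] for r in emb_rows], name="cell_id"),
    )
    return UMIDataset(counts=counts, meta=meta, embedding=embedding,
                      marker_genes=markers, tissue_markers=tissue_markers)


def gen_marker_matrix(config: SimulationConfig, n_target: int = 100,
                      n_background: int = 100
                      ) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Two-population matrix for marker-recovery benchmarking.

    n_markers genes are expressed at marker_fold times their (low)
    baseline in the target population; the null genes are exchangeable
    between populations. Returns (counts, target cell ids, marker ids).
    """
    rng = _rng(config.seed, _STREAM_UMI, 1)
    markers = [f"mk{i:02d}" for i in range(1, config.n_markers + 1)]
    null_genes = [f"null{i:04d}" for i in range(config.n_null_genes)]
    genes = markers + null_genes
    base = pd.Series(
        rng.gamma(2.0, config.base_expression / 2.0, size=len(genes)),
        index=genes,
    ).clip(lower=0.05)
    base[markers] = rng.uniform(0.2, 0.35, size=len(markers))

    mu_t = base.copy()
    mu_t[markers] = base[markers] * config.marker_fold
    disp = config.eb_dispersion
    tgt = _nb_draws(rng, mu_t.to_numpy()[:, None], disp, (len(genes), n_target))
    bgd = _nb_draws(rng, base.to_numpy()[:, None], disp,
                    (len(genes), n_background))
    cells = ([f"target_{i:04d}" for i in range(n_target)]
             + [f"bgd_{i:04d}" for i in range(n_background)])
    counts = pd.DataFrame(np.hstack([tgt, bgd]), index=genes, columns=cells)
    return counts, cells[:n_target], markers


def gen_methylomes(genome: SyntheticGenome, config: SimulationConfig) -> list:
    """Sparse per-cell methylomes with stage-dependent heterogeneity.

    CpG sites are fixed per enhancer (shared across cells). Per cell
    and enhancer, a methylation level is drawn from Beta(c/2, c/2)
    where c is the stage concentration, so the cross-cell variance is
    0.25 / (c + 1): small c plants a heterogeneous stage. Site coverage
    is Bernoulli dropout; read counts are 1 + Poisson(mean_read_depth)
    and methylated reads binomial given the level.
    """
    from .methylome import CellMethylome  # local import avoids a cycle

    site_rng = _rng(config.seed, _STREAM_METH, 0)
    enh_sites = []
    for enh in genome.enhancers:
        if enh.klass == "decoy":
            continue
        iv = enh.interval
        pos = np.sort(site_rng.choice(
            np.arange(iv.start, iv.end), size=config.cpgs_per_enhancer,
            replace=False,
        ))
        enh_sites.append((iv.chrom, pos))

    cells = []
    for si, (stage, conc) in enumerate(sorted(config.meth_stages.items())):
        a = conc / 2.0
        for ci in range(config.meth_cells_per_stage):
            rng = _rng(config.seed, _STREAM_METH, 1 + si, ci)
            rows = []
            for chrom, positions in enh_sites:
                level = rng.beta(a, a)
                for p in positions:
                    if rng.random() > config.site_coverage_prob:
                        continue
                    t = 1 + int(rng.poisson(config.mean_read_depth))
                    m = int(rng.binomial(t, level))
                    rows.append((chrom, int(p), m, t))
            calls = pd.DataFrame(rows, columns=gio.METH_COLUMNS)
            cells.append(CellMethylome(f"{stage}_cell{ci:03d}", stage, calls))
    return cells


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    genome: SyntheticGenome
    tracks: dict
    meth_track: SignalTrack
    interactions: list
    umi: UMIDataset
    methylomes: list


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    genome = gen_genome(config)
    return SyntheticDataset(
        config=config,
        genome=genome,
        tracks=gen_signal_tracks(genome, config),
        meth_track=gen_methylation_track(genome, config),
        interactions=gen_interactions(genome, config),
        umi=gen_umi_matrix(config),
        methylomes=gen_methylomes(genome, config),
    )


def write_dataset(ds: SyntheticDataset, outdir) -> dict:
    """Serialize every generated input plus truth tables; return the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, object] = {}

    gio.write_gene_table(ds.genome.genes, outdir / "genes.tsv")
    paths["genes"] = "genes.tsv"

    truth = [
        GenomicInterval(e.interval.chrom, e.interval.start, e.interval.end,
                        name=f"{e.klass}|{e.target_gene or '.'}")
        for e in ds.genome.enhancers
    ]
    gio.write_bed(truth, outdir / "enhancer_truth.bed")
    paths["enhancer_truth"] = "enhancer_truth.bed"

    peaks = [e.interval for e in ds.genome.enhancers]
    gio.write_bed(peaks, outdir / "peaks.bed")
    paths["peaks"] = "peaks.bed"

    track_paths = {}
    for (mark, stage, rep), track in ds.tracks.items():
        name = f"{mark}_{stage}_rep{rep}.bedGraph"
        gio.write_bedgraph(track, outdir / name)
        track_paths[f"{mark}/{stage}/rep{rep}"] = name
    paths["tracks"] = track_paths
    gio.write_bedgraph(ds.meth_track, outdir / "mCpG_EpiLC.bedGraph")
    paths["meth_track"] = "mCpG_EpiLC.bedGraph"

    gio.write_bedpe(ds.interactions, outdir / "interactions.bedpe")
    paths["interactions"] = "interactions.bedpe"

    gio.write_umi_matrix(ds.umi.counts, ds.umi.meta,
                         outdir / "umi_counts.tsv", outdir / "cell_meta.tsv")
    ds.umi.embedding.to_csv(outdir / "embedding.tsv", sep="\t")
    paths["umi_counts"] = "umi_counts.tsv"
    paths["cell_meta"] = "cell_meta.tsv"
    paths["embedding"] = "embedding.tsv"

    meth_dir = outdir / "methylomes"
    meth_dir.mkdir(exist_ok=True)
    meth_files = {}
    for cell in ds.methylomes:
        name = f"methylomes/{cell.cell_id}.tsv"
        gio.write_methylation_calls(cell.calls, outdir / name)
        meth_files[cell.cell_id] = {"path": name, "stage": cell.stage}
    paths["methylomes"] = meth_files

    manifest = {
        "seed": ds.config.seed,
        "chrom_lengths": dict(ds.config.chrom_lengths),
        "bin_size": ds.config.bin_size,
        "paths": paths,
        "truth": {
            "n_class1": ds.config.n_class1,
            "n_class2": ds.config.n_class2,
            "n_decoy": ds.config.n_decoy,
            "class1_fold": ds.config.class1_fold,
            "marker_genes": ds.umi.marker_genes,
            "meth_stage_concentration": dict(ds.config.meth_stages),
        },
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest
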