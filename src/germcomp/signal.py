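"""Chromatin-signal quantification and enhancer group classification.

Tracks are normalized to 1x coverage (RPGC: reads per genomic content,
i.e. genome-wide base-weighted mean coverage of 1). Marks are quantified
as the mean signal in a window around each region's midpoint (default
+/- 1 kb). Enhancers are split into Group I (EpiLC/EpiSC H3K4me1 ratio
> 1.2 in at least two of three replicates, i.e. partially decommissioned
with H3K4me1 retained in the germline-competent state) and Group II
(all others). Paired differences between stages are summarized by the
Wilcoxon signed-rank effect size r = z / sqrt(n) with a percentile
bootstrap confidence interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import RAW, RPGC, GenomicInterval, SignalTrack


def rpgc_normalize(track: SignalTrack, effective_genome_size: int | None = None
                   ) -> SignalTrack:
    """Scale all bins by one factor so the genome-wide mean coverage is 1.

    effective_genome_size defaults to the track's own genome span; when
    given, the mean is computed over that many bases instead (mimicking
    an effective-size correction). Idempotent and scale invariant.
    """
    total = sum(float(v.sum()) * track.bin_size for v in track.data.values())
    span = sum(len(v) * track.bin_size for v in track.data.values())
    genome = effective_genome_size if effective_genome_size else span
    mean = total / genome
    if mean == 0:
        raise ValueError("cannot RPGC-normalize an all-zero track")
    out = track.copy_with(norm=RPGC)
    for v in out.data.values():
        v /= mean
    return out


def window_signal(track: SignalTrack, regions, flank: int = 1000,
                  anchor: str = "center") -> np.ndarray:
    """Mean signal in [anchor - flank, anchor + flank) per region.

    anchor='center' uses the region midpoint; anchor='start' the
    interval start (e.g. a TSS supplied as a 1 bp interval). Windows are
    clipped at chromosome bounds; partial bins contribute proportionally
    to their overlap.
    """
    means = np.empty(len(regions))
    for i, region in enumerate(regions):
        if region.chrom not in track.data:
            raise ValueError(f"region chromosome {region.chrom!r} not in track")
        vec = track.data[region.chrom]
        clen = len(vec) * track.bin_size
        if anchor == "center":
            a = region.midpoint
        elif anchor == "start":
            a = region.start
        else:
            raise ValueError(f"unknown anchor {anchor!r}")
        means[i] = _window_mean(vec, track.bin_size, max(0, a - flank),
                                min(clen, a + flank))
    return means


def _window_mean(vec: np.ndarray, bin_size: int, start: int, end: int) -> float:
    """Per-base mean of a binned vector over [start, end)."""
    if end <= start:
        return float("nan")
    first, last = start // bin_size, (end - 1) // bin_size
    idx = np.arange(first, last + 1)
    overlap = (
        np.minimum((idx + 1) * bin_size, end) - np.maximum(idx * bin_size, start)
    ).astype(float)
    return float(np.dot(vec[first:last + 1], overlap) / (end - start))


@dataclass
class GroupClassification:
    """Per-enhancer replicate ratios and the Group I/II call."""

    ratios: np.ndarray        # enhancers x replicates
    n_above: np.ndarray       # replicates with ratio > threshold
    labels: np.ndarray        # 'Group I' / 'Group II'
    threshold: float
    min_replicates: int


def classify_groups(window_means: dict[int, tuple[np.ndarray, np.ndarray]],
                    threshold: float = 1.2, min_replicates: int = 2,
                    pseudocount: float = 0.01) -> GroupClassification:
    """Classify enhancers by replicate-consistent stage ratios.

    window_means maps replicate -> (epilc, episc) arrays of per-enhancer
    window means. The ratio (epilc + eps) / (episc + eps) must exceed
    the threshold (strict) in at least min_replicates replicates for
    Group I; everything else is Group II.
    """
    reps = sorted(window_means)
    if not reps:
        raise ValueError("no replicate data")
    n = len(window_means[reps[0]][0])
    ratios = np.empty((n, len(reps)))
    for j, rep in enumerate(reps):
        epilc, episc = window_means[rep]
        if len(epilc) != n or len(episc) != n:
            raise ValueError("replicates disagree on the number of enhancers")
        ratios[:, j] = (np.asarray(epilc) + pseudocount) / (np.asarray(episc) + pseudocount)
    n_above = (ratios > threshold).sum(axis=1)
    labels = np.where(n_above >= min_replicates, "Group I", "Group II")
    return GroupClassification(ratios=ratios, n_above=n_above, labels=labels,
                               threshold=threshold, min_replicates=min_replicates)


@dataclass
class EffectSizeResult:
    z: float
    n: int
    r: float
    ci_low: float
    ci_high: float


def _signed_rank_z(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Wilcoxon signed-rank z (normal approximation, tie-corrected).

    Zero differences are dropped; no continuity correction. The sign of
    z indicates the direction y vs x (positive when y > x overall).
    """
    d = np.asarray(y, float) - np.asarray(x, float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 0.0, 0
    ranks = stats.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    mu = n * (n + 1) / 4.0
    # exact null variance with midranks: sum(r_i^2) / 4
    sigma2 = float((ranks ** 2).sum()) / 4.0
    if sigma2 == 0:
        return 0.0, n
    return float((w_plus - mu) / np.sqrt(sigma2)), n


def paired_effect_size(x, y, n_boot: int = 1000, seed: int = 0) -> EffectSizeResult:
    """Effect size r = z / sqrt(n) of the paired signed-rank test.

    n is the number of nonzero-difference pairs. The 0.95 confidence
    interval is a percentile bootstrap over resampled pairs. When all
    differences are zero the result degenerates to r = 0 with CI [0, 0]
    (a warning is emitted rather than an exception so that pipelines
    survive constant inputs).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("x and y must be paired (equal length)")
    if len(x) < 10:
        raise ValueError("need at least 10 pairs")
    z, n = _signed_rank_z(x, y)
    if n == 0:
        warnings.warn("all paired differences are zero; effect size degenerates to 0")
        return EffectSizeResult(z=0.0, n=0, r=0.0, ci_low=0.0, ci_high=0.0)
    r = z / np.sqrt(n)

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    m = len(x)
    for b in range(n_boot):
        idx = rng.integers(0, m, size=m)
        zb, nb = _signed_rank_z(x[idx], y[idx])
        boots[b] = zb / np.sqrt(nb) if nb else 0.0
    ci_low, ci_high = np.percentile(boots, [2.5, 97.5])
    # percentile CIs from small resamples can exclude the point estimate
    ci_low, ci_high = min(ci_low, r), max(ci_high, r)
    return EffectSizeResult(z=z, n=n, r=float(r),
                            ci_low=float(ci_low), ci_high=float(ci_high))


def flank_methylation_correlation(meth_track: SignalTrack,
                                  h3k4me1_track: SignalTrack,
                                  enhancers, bin: int = 500
                                  ) -> tuple[float, np.ndarray, np.ndarray]:
    """Spearman rho of methylation vs H3K4me1 in enhancer flanks.

    For each enhancer, both signals are averaged over one `bin`-bp
    window immediately upstream and one immediately downstream of the
    interval (the two bin means pooled by averaging), and rho is
    computed across enhancers between the two pooled means. Returns
    (rho, per-enhancer methylation means, per-enhancer H3K4me1 means).
    """
    meth_means = np.empty(len(enhancers))
    k4_means = np.empty(len(enhancers))
    for i, enh in enumerate(enhancers):
        vals = []
        for track, store in ((meth_track, meth_means), (h3k4me1_track, k4_means)):
            if enh.chrom not in track.data:
                raise ValueError(f"chromosome {enh.chrom!r} missing from track")
            vec = track.data[enh.chrom]
            clen = len(vec) * track.bin_size
            up = _window_mean(vec, track.bin_size,
                              max(0, enh.start - bin), min(clen, enh.start))
            down = _window_mean(vec, track.bin_size,
                                max(0, enh.end), min(clen, enh.end + bin))
            both = [v for v in (up, down) if np.isfinite(v)]
            store[i] = np.mean(both) if both else np.nan
    ok = np.isfinite(meth_means) & np.isfinite(k4_means)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 enhancers with both signals defined")
    rho = stats.spearmanr(meth_means[ok], k4_means[ok]).statistic
    return float(rho), meth_means, k4_means
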