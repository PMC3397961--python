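"""Input-controlled ChIP-seq peak filtering and peak-to-gene association.

Peaks are detected from a coverage track, height-thresholded via an
analytic Poisson false-discovery model, and then filtered against an
input-control track with two local criteria computed in a +/-400 bp
window around the summit: a Poisson-based local z-score and a
ChIP/control fold change.  Passing peaks are associated to genes through
regulatory domains (a strand-aware basal promoter interval extended
toward neighbouring genes up to a distance cap) and intersected with
differential-expression calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import poisson

from valvetag import defaults


@dataclass
class Peak:
    chrom: str
    start: int           # 0-based half-open
    end: int
    summit: int          # leftmost position of the maximum
    height: float

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError("peak start must be < end")
        if not self.start <= self.summit < self.end:
            raise ValueError("summit must lie inside the peak")


@dataclass
class FilterThresholds:
    h_min: float = defaults.PEAK_H_MIN
    h_high: float = defaults.PEAK_H_HIGH
    z_min: float = defaults.PEAK_Z_MIN
    fold_min: float = defaults.PEAK_FOLD_MIN
    window: int = defaults.PEAK_WINDOW


@dataclass
class FilteredPeak:
    peak: Peak
    control_mean: float      # lambda: scaled mean control coverage in window
    control_max: float       # c_max: scaled max control coverage in window
    local_z: float
    control_fold: float
    passes_height: bool
    passes_z: bool
    passes_fold: bool
    high_confidence: bool
    thresholds: FilterThresholds
    associated_genes: list[str] = field(default_factory=list)

    @property
    def passes(self) -> bool:
        return self.passes_height and self.passes_z and self.passes_fold


def find_peaks(coverage: dict[str, np.ndarray], min_height: float) -> list[Peak]:
    """Detect peaks as maximal contiguous regions of elevated coverage.

    A region is any maximal run of bases with coverage >= max(1,
    min_height/2); its height is the maximum coverage and its summit the
    leftmost maximal base.  Only regions with height >= min_height are
    returned.
    """
    peaks: list[Peak] = []
    floor = max(1.0, min_height / 2.0)
    for chrom in sorted(coverage):
        cov = np.asarray(coverage[chrom], dtype=float)
        above = cov >= floor
        if not above.any():
            continue
        padded = np.concatenate(([False], above, [False]))
        d = np.diff(padded.astype(np.int8))
        run_starts = np.flatnonzero(d == 1)
        run_ends = np.flatnonzero(d == -1)
        for s, e in zip(run_starts, run_ends):
            h = cov[s:e].max()
            if h >= min_height:
                summit = int(s + int(np.argmax(cov[s:e])))
                peaks.append(Peak(chrom, int(s), int(e), summit, float(h)))
    return peaks


def fdr_height_threshold(
    peaks: list[Peak],
    n_reads: int,
    read_len: int,
    genome_len: int,
    fdr: float = defaults.PEAK_FDR,
) -> int:
    """Minimum peak height at a target false-discovery rate.

    Under a uniform-placement model the background per-base coverage is
    Poisson with rate lambda = n_reads x read_len / genome_len.  The
    threshold is the smallest height h for which

        genome_len x P(Poisson(lambda) >= h) / #{peaks with height >= h}

    drops to or below ``fdr``.  An analytic stand-in for a Monte-Carlo
    peak-calling FDR; with fdr >= 1 no filtering is demanded and h = 1.
    """
    if genome_len <= 0:
        raise ValueError("genome_len must be > 0")
    lam = n_reads * read_len / genome_len
    if lam <= 0:
        raise ValueError("background rate must be > 0")
    if fdr >= 1:
        return 1
    heights = np.array([p.height for p in peaks])
    h_max = int(heights.max()) + 2 if len(heights) else int(poisson.isf(1e-12, lam)) + 2
    for h in range(1, h_max + 1):
        expected = genome_len * poisson.sf(h - 1, lam)
        observed = int((heights >= h).sum()) if len(heights) else 0
        if expected / max(observed, 1) <= fdr:
            return h
    return h_max


def local_control_stats(
    peak: Peak,
    control: dict[str, np.ndarray],
    depth_chip: float,
    depth_control: float,
    window: int = defaults.PEAK_WINDOW,
) -> tuple[float, float]:
    """Scaled control coverage statistics in [summit-W, summit+W].

    Returns (lambda, c_max): the mean and max control coverage in the
    window, scaled by r = depth_chip/depth_control so control and ChIP
    are on the same depth scale.  Bases beyond the track are zero.
    """
    cov = control.get(peak.chrom)
    r = depth_chip / depth_control
    lo = peak.summit - window
    hi = peak.summit + window + 1
    if cov is None or len(cov) == 0:
        return 0.0, 0.0
    n = hi - lo
    seg = cov[max(lo, 0):min(hi, len(cov))]
    total = float(seg.sum())
    cmax = float(seg.max()) if len(seg) else 0.0
    return r * total / n, r * cmax


def local_zscore(height: float, lam: float) -> float:
    """Poisson-based local z with a +1 variance guard: (h - lam)/sqrt(lam + 1)."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    return (height - lam) / np.sqrt(lam + 1.0)


def filter_peaks(
    peaks: list[Peak],
    control: dict[str, np.ndarray],
    depth_chip: float,
    depth_control: float,
    thresholds: FilterThresholds | None = None,
) -> list[FilteredPeak]:
    """Apply the height / local-z / control-fold criteria to each peak.

    control_fold = height / max(c_max, 1); a peak passes iff height >=
    h_min AND z > z_min AND fold > fold_min; passing peaks with height
    >= h_high are flagged high-confidence.
    """
    th = thresholds or FilterThresholds()
    out = []
    for p in peaks:
        lam, cmax = local_control_stats(p, control, depth_chip, depth_control, th.window)
        z = local_zscore(p.height, lam)
        fold = p.height / max(cmax, 1.0)
        passes_h = p.height >= th.h_min
        passes_z = z > th.z_min
        passes_f = fold > th.fold_min
        out.append(FilteredPeak(
            peak=p, control_mean=lam, control_max=cmax, local_z=z,
            control_fold=fold, passes_height=passes_h, passes_z=passes_z,
            passes_fold=passes_f,
            high_confidence=passes_h and passes_z and passes_f and p.height >= th.h_high,
            thresholds=th,
        ))
    return out


def build_regulatory_domains(
    annotation: pd.DataFrame,
    chrom_lengths: dict[str, int],
    basal_upstream: int = defaults.BASAL_UPSTREAM,
    basal_downstream: int = defaults.BASAL_DOWNSTREAM,
    max_extension: int = defaults.MAX_EXTENSION,
) -> pd.DataFrame:
    """Basal-plus-extension regulatory domains per gene.

    The basal domain is strand-aware: [TSS-5000, TSS+1000) on the plus
    strand, reflected on the minus strand.  Each side then extends to
    the nearer of ``max_extension`` from the TSS or the adjacent gene's
    basal boundary, clipped at chromosome ends; a gene's extended domain
    always contains its basal domain.
    """
    rows = []
    for chrom, sub in annotation.groupby("chrom", sort=True):
        L = int(chrom_lengths[chrom])
        sub = sub.sort_values("tss")
        tss = sub["tss"].to_numpy()
        plus = (sub["strand"] == "+").to_numpy()
        b_start = np.where(plus, tss - basal_upstream, tss - basal_downstream)
        b_end = np.where(plus, tss + basal_downstream, tss + basal_upstream)
        b_start = np.clip(b_start, 0, L)
        b_end = np.clip(b_end, 0, L)
        for i in range(len(sub)):
            left_limit = 0
            right_limit = L
            others_end = np.delete(b_end, i)
            others_start = np.delete(b_start, i)
            left_cand = others_end[others_end <= b_start[i]]
            if len(left_cand):
                left_limit = int(left_cand.max())
            right_cand = others_start[others_start >= b_end[i]]
            if len(right_cand):
                right_limit = int(right_cand.min())
            e_start = max(left_limit, int(tss[i]) - max_extension, 0)
            e_end = min(right_limit, int(tss[i]) + max_extension, L)
            e_start = min(e_start, int(b_start[i]))
            e_end = max(e_end, int(b_end[i]))
            rows.append({
                "gene_id": sub["gene_id"].iloc[i], "chrom": chrom,
                "basal_start": int(b_start[i]), "basal_end": int(b_end[i]),
                "ext_start": e_start, "ext_end": e_end,
            })
    return pd.DataFrame(rows)


def associate_peaks(
    peaks: list[Peak] | list[FilteredPeak], domains: pd.DataFrame
) -> tuple[list[list[str]], dict[str, list[int]]]:
    """Associate each peak with every gene whose extended domain it overlaps.

    Returns (genes per peak in input order, gene -> peak indices); gene
    lists are sorted for determinism.  FilteredPeak inputs also get
    their ``associated_genes`` field filled.
    """
    per_peak: list[list[str]] = []
    gene_to_peaks: dict[str, list[int]] = {}
    by_chrom = {c: sub for c, sub in domains.groupby("chrom")}
    for i, p in enumerate(peaks):
        pk = p.peak if isinstance(p, FilteredPeak) else p
        sub = by_chrom.get(pk.chrom)
        genes: list[str] = []
        if sub is not None:
            hit = (sub["ext_start"] < pk.end) & (sub["ext_end"] > pk.start)
            genes = sorted(sub.loc[hit, "gene_id"])
        per_peak.append(genes)
        if isinstance(p, FilteredPeak):
            p.associated_genes = genes
        for g in genes:
            gene_to_peaks.setdefault(g, []).append(i)
    return per_peak, gene_to_peaks


def intersect_with_de(
    bound_genes,
    de_results: pd.DataFrame,
    alpha: float = defaults.ALPHA,
) -> pd.DataFrame:
    """Partition genes with binding evidence by DE direction at p < alpha.

    ``de_results`` is a call_enrichment frame (indexed by gene, with
    fold_change and p_value); the returned frame lists each bound,
    differentially expressed gene with its direction (down = FC < 1).
    """
    bound = [g for g in sorted(set(bound_genes)) if g in de_results.index]
    sub = de_results.loc[bound]
    sig = sub[sub["p_value"] < alpha].copy()
    sig["direction"] = np.where(sig["fold_change"] < 1, "down", "up")
    return sig[["fold_change", "p_value", "direction"]].sort_index()


def peaks_to_bed(peaks: list[FilteredPeak]) -> pd.DataFrame:
    """BED6-shaped frame: name = comma-joined associated genes, score = height."""
    return pd.DataFrame([
        {"chrom": f.peak.chrom, "start": f.peak.start, "end": f.peak.end,
         "name": ",".join(f.associated_genes) or ".",
         "score": f.peak.height, "strand": "."}
        for f in peaks
    ])
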