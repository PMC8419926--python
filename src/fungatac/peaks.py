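"""Accessible-region detection and comparison.

Peaks are called with a local-Poisson sliding-window scan on insertion
events: each 200 bp window is tested against the most conservative of
the genome-wide rate and the 5 kb / 10 kb local rates (the classic
local-lambda guard against copy-number and domain effects), p-values
are BH-corrected across windows, and significant windows are merged.
Differential accessibility between conditions is a count-based
negative-binomial Wald test with a common method-of-moments dispersion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome import GeneAnnotation
from .insertions import InsertionTrack


def _window_sums(counts: np.ndarray, window: int, starts: np.ndarray) -> np.ndarray:
    cum = np.concatenate([[0], np.cumsum(counts, dtype=np.int64)])
    ends = np.minimum(starts + window, counts.size)
    return cum[ends] - cum[starts]


def call_peaks(
    track: InsertionTrack,
    window: int = 200,
    step: int = 50,
    min_qvalue: float = 0.05,
    merge_gap: int = 100,
    min_length: int = 100,
    local_windows: tuple[int, ...] = (5000, 10000),
    summit_smooth: int = 50,
) -> pd.DataFrame:
    """Call accessible regions from combined-strand insertion counts.

    Returns a DataFrame with chrom/start/end/summit/enrichment/p/q,
    intervals 0-based half-open and non-overlapping. Peaks shorter than
    ``min_length`` are discarded. Empty tracks yield an empty frame.
    """
    total = track.total_events
    genome_bp = sum(a.size for a in track.plus.values())
    cols = ["chrom", "start", "end", "summit", "enrichment", "p", "q", "name"]
    if total == 0 or genome_bp == 0:
        return pd.DataFrame(columns=cols)
    genome_rate = total / genome_bp

    per_chrom = []
    for chrom in track.chrom_names:
        counts = track.combined(chrom).astype(np.int64)
        n = counts.size
        starts = np.arange(0, max(n - window + 1, 1), step)
        obs = _window_sums(counts, window, starts)
        lam = np.full(starts.size, genome_rate * window)
        for lw in local_windows:
            centers = starts + window // 2
            lo = np.maximum(centers - lw // 2, 0)
            span_starts = np.minimum(lo, np.maximum(n - lw, 0))
            local = _window_sums(counts, lw, span_starts)
            lam = np.maximum(lam, local / lw * window)
        p = stats.poisson.sf(obs - 1, lam)
        per_chrom.append((chrom, starts, obs, lam, p))

    all_p = np.concatenate([p for *_, p in per_chrom])
    _, all_q, *_ = multipletests(all_p, method="fdr_bh")
    offset = 0
    peaks = []
    for chrom, starts, obs, lam, p in per_chrom:
        q = all_q[offset:offset + starts.size]
        offset += starts.size
        sig = q < min_qvalue
        if not sig.any():
            continue
        counts = track.combined(chrom).astype(np.float64)
        peaks.extend(_merge_windows(chrom, starts[sig], obs[sig], lam[sig], p[sig],
                                    q[sig], counts, window, merge_gap, min_length,
                                    summit_smooth, genome_rate))
    df = pd.DataFrame(peaks, columns=cols[:-1])
    df["name"] = [f"peak_{i + 1}" for i in range(len(df))]
    return df


def _merge_windows(chrom, starts, obs, lam, p, q, counts, window, merge_gap,
                   min_length, summit_smooth, genome_rate):
    order = np.argsort(starts)
    starts, obs, lam, p, q = starts[order], obs[order], lam[order], p[order], q[order]
    smooth = np.convolve(counts, np.ones(summit_smooth) / summit_smooth, mode="same")
    out = []
    i = 0
    while i < starts.size:
        j = i
        end = starts[i] + window
        while j + 1 < starts.size and starts[j + 1] <= end + merge_gap:
            j += 1
            end = max(end, starts[j] + window)
        lo, hi = int(starts[i]), int(min(end, counts.size))
        if hi - lo >= min_length:
            summit = lo + int(np.argmax(smooth[lo:hi]))
            local_rate = max(lam[i:j + 1].max() / window, genome_rate)
            enrich = counts[lo:hi].sum() / (local_rate * (hi - lo))
            out.append((chrom, lo, hi, summit, float(enrich),
                        float(p[i:j + 1].min()), float(q[i:j + 1].min())))
        i = j + 1
    return out


# ---------------------------------------------------------------------------
# annotation

CATEGORY_PRECEDENCE = ("promoter", "TTS", "exon", "intron", "intergenic")


@dataclass(frozen=True)
class FeatureAnnotation:
    peak_id: str
    category: str
    nearest_gene: str | None
    distance_to_tss: int | None


def annotate_peak(
    summit: int,
    chrom: str,
    genes: list[GeneAnnotation],
    promoter_bp: int = 1000,
    tts_bp: int = 300,
    peak_id: str = ".",
) -> FeatureAnnotation:
    """Assign one category to a peak by its summit, with precedence
    promoter > TTS > exon > intron > intergenic; the nearest gene is
    the one minimizing |summit - TSS|, with the signed distance
    negative upstream of the gene."""
    chrom_genes = [g for g in genes if g.chrom == chrom]
    category = "intergenic"
    found = {c: False for c in CATEGORY_PRECEDENCE}
    for g in chrom_genes:
        if g.strand == "+":
            if g.tss - promoter_bp <= summit < g.tss:
                found["promoter"] = True
            if g.tts - tts_bp <= summit <= g.tts + tts_bp:
                found["TTS"] = True
        else:
            if g.tss < summit <= g.tss + promoter_bp:
                found["promoter"] = True
            if g.tts - tts_bp <= summit <= g.tts + tts_bp:
                found["TTS"] = True
        if g.start <= summit < g.end:
            in_exon = any(s <= summit < e for s, e in (g.exons or ((g.start, g.end),)))
            found["exon" if in_exon else "intron"] = True
    for cat in CATEGORY_PRECEDENCE[:-1]:
        if found[cat]:
            category = cat
            break
    nearest, dist = None, None
    if chrom_genes:
        deltas = [(abs(summit - g.tss), g) for g in chrom_genes]
        _, g = min(deltas, key=lambda t: t[0])
        nearest = g.gene_id
        signed = summit - g.tss
        dist = int(signed if g.strand == "+" else -signed)
    return FeatureAnnotation(peak_id=peak_id, category=category,
                             nearest_gene=nearest, distance_to_tss=dist)


def annotate_peaks(peaks: pd.DataFrame, genes, promoter_bp: int = 1000,
                   tts_bp: int = 300) -> pd.DataFrame:
    anns = [
        annotate_peak(int(r["summit"]), r["chrom"], genes, promoter_bp, tts_bp,
                      peak_id=str(r.get("name", i)))
        for i, r in peaks.iterrows()
    ]
    return pd.DataFrame([a.__dict__ for a in anns])


# ---------------------------------------------------------------------------
# set comparisons


@dataclass(frozen=True)
class VennSummary:
    n_a: int
    n_b: int
    common_a: int
    common_b: int
    a_specific: int
    b_specific: int

    @property
    def symmetric(self) -> bool:
        return self.common_a == self.common_b


def _overlaps_any(peaks: pd.DataFrame, others: pd.DataFrame, min_overlap_bp: int) -> np.ndarray:
    hit = np.zeros(len(peaks), dtype=bool)
    for chrom, sub in others.groupby("chrom"):
        sel = (peaks["chrom"] == chrom).to_numpy()
        if not sel.any():
            continue
        o_starts = sub["start"].to_numpy()
        o_ends = sub["end"].to_numpy()
        order = np.argsort(o_starts, kind="stable")
        o_starts, o_ends = o_starts[order], o_ends[order]
        p_starts = peaks.loc[sel, "start"].to_numpy()
        p_ends = peaks.loc[sel, "end"].to_numpy()
        if min_overlap_bp <= 1:
            # overlap exists iff some interval starting before the peak end
            # extends past the peak start: prefix running max of ends
            run_max = np.maximum.accumulate(o_ends)
            j0 = np.searchsorted(o_starts, p_ends, side="left")
            ok = (j0 > 0) & (run_max[np.maximum(j0 - 1, 0)] > p_starts)
        else:
            max_len = int((o_ends - o_starts).max()) if o_starts.size else 0
            ok = np.zeros(p_starts.size, dtype=bool)
            for i, (ps, pe) in enumerate(zip(p_starts, p_ends)):
                j_hi = np.searchsorted(o_starts, pe - min_overlap_bp, side="right")
                j_lo = np.searchsorted(o_starts, ps - max_len, side="left")
                ov = (np.minimum(pe, o_ends[j_lo:j_hi])
                      - np.maximum(ps, o_starts[j_lo:j_hi]))
                ok[i] = bool((ov >= min_overlap_bp).any())
        hit[np.nonzero(sel)[0]] = ok
    return hit


def overlap_sets(peaks_a: pd.DataFrame, peaks_b: pd.DataFrame,
                 min_overlap_bp: int = 1) -> VennSummary:
    """Venn summary of two peak sets. A peak is common when it overlaps
    any peak of the other set by >= ``min_overlap_bp``; common counts
    are reported on each side separately since they can differ."""
    common_a = int(_overlaps_any(peaks_a, peaks_b, min_overlap_bp).sum())
    common_b = int(_overlaps_any(peaks_b, peaks_a, min_overlap_bp).sum())
    return VennSummary(
        n_a=len(peaks_a), n_b=len(peaks_b),
        common_a=common_a, common_b=common_b,
        a_specific=len(peaks_a) - common_a, b_specific=len(peaks_b) - common_b)


def chip_atac_overlap(chip_peaks: pd.DataFrame, atac_peaks: pd.DataFrame,
                      min_overlap_bp: int = 1) -> dict:
    """Fraction of ChIP peaks recovered by ATAC accessibility, as a
    percentage rounded to 2 decimals."""
    n_chip = len(chip_peaks)
    if n_chip == 0:
        raise ValueError("empty ChIP peak set")
    n_overlap = int(_overlaps_any(chip_peaks, atac_peaks, min_overlap_bp).sum())
    return {"n_chip": n_chip, "n_overlapping": n_overlap,
            "percentage": round(100.0 * n_overlap / n_chip, 2)}


def consensus_peaks(peak_sets: list[pd.DataFrame], merge_gap: int = 0) -> pd.DataFrame:
    """Union of per-sample peaks, merged; the consensus set for
    differential testing."""
    frames = [p[["chrom", "start", "end"]] for p in peak_sets if len(p)]
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end", "name"])
    allp = pd.concat(frames).sort_values(["chrom", "start"]).reset_index(drop=True)
    rows = []
    for chrom, sub in allp.groupby("chrom", sort=True):
        cur_s, cur_e = None, None
        for s, e in zip(sub["start"], sub["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e + merge_gap:
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            rows.append((chrom, cur_s, cur_e))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["name"] = [f"consensus_{i + 1}" for i in range(len(df))]
    return df


def count_matrix(consensus: pd.DataFrame, tracks: dict[str, InsertionTrack]) -> pd.DataFrame:
    """Insertion events per consensus peak per sample."""
    out = {}
    for sample, track in tracks.items():
        vals = []
        for _, r in consensus.iterrows():
            vals.append(int(track.combined(r["chrom"])[r["start"]:r["end"]].sum()))
        out[sample] = vals
    return pd.DataFrame(out, index=consensus["name"].to_numpy())


# ---------------------------------------------------------------------------
# differential accessibility


def estimate_common_dispersion(norm_counts: np.ndarray, groups: list[np.ndarray]) -> float:
    """Method-of-moments NB dispersion pooled across peaks: the common
    alpha solves sum(s^2 - m) = alpha * sum(m^2) over within-group
    peak-level moments (ratio of sums, which unlike a median of 1-df
    per-peak estimates is not biased toward zero). Floored at 0
    (0 = Poisson)."""
    num = 0.0
    den = 0.0
    for idx in groups:
        if idx.size < 2:
            continue
        sub = norm_counts[:, idx]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        ok = m > 0
        num += float((v[ok] - m[ok]).sum())
        den += float((m[ok] ** 2).sum())
    if den <= 0:
        return 0.0
    return float(max(num / den, 0.0))


def differential_accessibility(
    counts: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-peak differential accessibility between two sample groups.

    Counts are normalized to counts-per-mean-library (library-size
    scaling), log2FC uses a pseudocount, and each peak gets a two-sided
    Wald test of the group-mean difference under a negative binomial
    with common method-of-moments dispersion (Poisson when the estimate
    is <= 0); BH correction gives the FDR.
    """
    missing = [s for s in group_a + group_b if s not in counts.columns]
    if missing:
        raise KeyError(f"samples absent from count matrix: {missing}")
    mat = counts[group_a + group_b].to_numpy(dtype=float)
    libsize = mat.sum(axis=0)
    if (libsize == 0).any():
        raise ValueError("a sample has zero total counts")
    norm = mat / libsize * libsize.mean()

    ia = np.arange(len(group_a))
    ib = np.arange(len(group_a), len(group_a) + len(group_b))
    alpha = estimate_common_dispersion(norm, [ia, ib]) \
        if (len(group_a) >= 2 or len(group_b) >= 2) else 0.0

    mean_a = norm[:, ia].mean(axis=1)
    mean_b = norm[:, ib].mean(axis=1)
    log2fc = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))

    pooled = norm.mean(axis=1)
    var1 = pooled + alpha * pooled ** 2  # per-observation NB variance at pooled mean
    se = np.sqrt(var1 * (1.0 / len(group_a) + 1.0 / len(group_b)))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, (mean_a - mean_b) / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    _, fdr, *_ = multipletests(p, method="fdr_bh")

    out = pd.DataFrame({
        "mean_a": mean_a, "mean_b": mean_b, "log2FC": log2fc,
        "p": p, "FDR": fdr,
    }, index=counts.index)
    out.attrs["dispersion"] = alpha
    return out
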