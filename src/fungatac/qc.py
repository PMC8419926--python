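"""Library-quality diagnostics: fragment-length periodicity, TSS
enrichment matrices and between-sample correlation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .insertions import FragmentSet, InsertionTrack

MAX_HIST_LENGTH = 1000


def length_histogram(fragments: FragmentSet) -> np.ndarray:
    """Counts indexed by fragment length 1..1000 bp (index 0 unused;
    lengths above 1000 pool into the last bin). Sums to the fragment
    count."""
    counts = np.zeros(MAX_HIST_LENGTH + 1, dtype=np.int64)
    lengths = np.clip(fragments.lengths, 1, MAX_HIST_LENGTH).astype(np.int64)
    np.add.at(counts, lengths, 1)
    return counts


@dataclass
class PeriodEstimate:
    period: int | None
    confidence: float
    reliable: bool


def estimate_period(
    histogram: np.ndarray,
    search_range: tuple[int, int] = (120, 300),
    detrend_window: int = 301,
    min_fragments: int = 100,
    min_length: int = 100,
    confidence_floor: float = 1.2,
) -> PeriodEstimate:
    """Dominant fragment-length period via autocorrelation.

    Lengths below ``min_length`` (the nucleosome-free class) are
    excluded first: periodicity is a property of the nucleosomal
    ladder, and the large sub-100 bp mode otherwise contaminates the
    autocorrelation through its cross-term with the mononucleosome
    peak. The remaining histogram is detrended by subtracting a
    ``detrend_window``-bin moving average (removing the exponential
    decay of the size distribution); the period is the lag of maximal
    autocorrelation within ``search_range``. Confidence is the
    prominence ratio of that peak over the mean absolute
    autocorrelation in the range; a degenerate histogram
    (< ``min_fragments`` fragments) yields ``period=None``.

    Invariant to rescaling of the histogram.
    """
    h = np.asarray(histogram, dtype=float).copy()
    if h.sum() < min_fragments:
        return PeriodEstimate(period=None, confidence=0.0, reliable=False)
    h[:min_length] = 0.0
    kernel = np.ones(detrend_window) / detrend_window
    trend = np.convolve(h, kernel, mode="same")
    x = h - trend
    x = x - x.mean()
    ac = np.correlate(x, x, mode="full")[x.size - 1:]
    if ac[0] <= 0:
        return PeriodEstimate(period=None, confidence=0.0, reliable=False)
    ac = ac / ac[0]
    lo, hi = search_range
    hi = min(hi, ac.size - 1)
    lags = np.arange(lo, hi + 1)
    window = ac[lo:hi + 1]
    best = int(lags[np.argmax(window)])
    baseline = np.mean(np.abs(window))
    confidence = float(window.max() / baseline) if baseline > 0 else 0.0
    return PeriodEstimate(period=best, confidence=confidence,
                          reliable=bool(confidence >= confidence_floor and window.max() > 0))


def tss_matrix(
    track: InsertionTrack,
    genes,
    flank: int = 1000,
    bin_width: int = 10,
    chrom_lengths: dict[str, int] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-gene insertion counts around the TSS, gene-strand oriented.

    Rows are usable genes (TSS +- flank inside the chromosome), columns
    are offset bins from -flank to +flank; negative offsets are upstream
    for both strands. To restrict to a fragment size class, build the
    track from class-filtered fragments first. Returns the matrix and
    the mean profile (column means). Insertions in the flanks of two
    genes count in both rows.
    """
    if not genes:
        raise ValueError("annotation is empty")
    if chrom_lengths is None:
        chrom_lengths = {c: len(a) for c, a in track.plus.items()}
    n_bins = 2 * flank // bin_width
    edges = np.arange(-flank, flank + 1, bin_width)
    rows, index = [], []
    for g in genes:
        t = g.tss
        if t - flank < 0 or t + flank >= chrom_lengths[g.chrom]:
            continue
        window = track.combined(g.chrom)[t - flank: t + flank + 1].astype(np.int64)
        if g.strand == "-":
            window = window[::-1]
        binned = np.add.reduceat(window[:2 * flank], np.arange(0, 2 * flank, bin_width))
        rows.append(binned)
        index.append(g.gene_id)
    if not rows:
        mat = pd.DataFrame(np.empty((0, n_bins), dtype=np.int64), columns=edges[:-1])
        return mat, mat.mean()
    mat = pd.DataFrame(np.vstack(rows), index=index, columns=edges[:-1])
    return mat, mat.mean()


def sample_correlation(
    tracks: list[InsertionTrack],
    bin_size: int = 1000,
    method: str = "spearman",
    labels: list[str] | None = None,
) -> pd.DataFrame:
    """Correlation matrix of binned genome-wide insertion counts.

    Spearman by default, so the result is invariant under any strictly
    monotone transform of the counts. Requires >= 2 samples on the same
    genome.
    """
    if len(tracks) < 2:
        raise ValueError("need at least two samples")
    ref = {c: a.size for c, a in tracks[0].plus.items()}
    for t in tracks[1:]:
        if {c: a.size for c, a in t.plus.items()} != ref:
            raise ValueError("tracks are on mismatched genomes")
    cols = {}
    labels = labels or [f"sample{i + 1}" for i in range(len(tracks))]
    for lab, t in zip(labels, tracks):
        parts = []
        for c in t.chrom_names:
            comb = t.combined(c)
            n_bins = comb.size // bin_size
            parts.append(comb[:n_bins * bin_size].reshape(n_bins, bin_size).sum(axis=1))
        cols[lab] = np.concatenate(parts)
    return pd.DataFrame(cols).corr(method=method)
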