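"""IUPAC consensus motif scanning, footprint enrichment and
expression integration.

Motifs are matched exactly under IUPAC degeneracy (zero mismatches) on
both strands, which is how short fungal TF consensi such as PrtT's
CCGHCGG or AmyR's CGG-N8-MGG are used in practice; no PWM log-odds
scoring is involved.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K", "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

_GAP_RE = re.compile(r"-?N(\d+)-?")
_PAREN_RE = re.compile(r"\(([ACGT/]+)\)")

_PAREN_TO_IUPAC = {
    frozenset("AC"): "M", frozenset("AG"): "R", frozenset("AT"): "W",
    frozenset("CG"): "S", frozenset("CT"): "Y", frozenset("GT"): "K",
    frozenset("ACG"): "V", frozenset("ACT"): "H", frozenset("AGT"): "D",
    frozenset("CGT"): "B", frozenset("ACGT"): "N",
}


def expand_consensus(consensus: str) -> str:
    """Normalize a consensus string to plain IUPAC letters.

    Supports fixed-length gap notation (``CGG-N8-MGG`` -> ``CGGNNNNNNNNMGG``)
    and slash alternatives (``CGGN8(C/A)GG`` -> ``CGGNNNNNNNNMGG``).
    """
    s = consensus.upper().strip()
    s = _PAREN_RE.sub(lambda m: _PAREN_TO_IUPAC[frozenset(m.group(1).split("/"))], s)
    s = _GAP_RE.sub(lambda m: "N" * int(m.group(1)), s)
    bad = set(s) - set(IUPAC_SETS)
    if bad:
        raise ValueError(f"consensus {consensus!r}: non-IUPAC characters {sorted(bad)}")
    if len(s) < 5:
        raise ValueError(f"consensus {consensus!r}: motifs must be >= 5 bp")
    return s


def reverse_complement_consensus(consensus: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(consensus))


@dataclass(frozen=True)
class MotifModel:
    """A named IUPAC consensus motif."""

    motif_id: str
    consensus: str

    @classmethod
    def from_string(cls, motif_id: str, consensus: str) -> "MotifModel":
        return cls(motif_id, expand_consensus(consensus))

    @classmethod
    def from_pcm(cls, motif_id: str, counts: np.ndarray,
                 min_frequency: float = 0.25) -> "MotifModel":
        """Collapse a position-count matrix (4 x L, rows A/C/G/T) to an
        IUPAC consensus: at each position, every base with relative
        frequency >= ``min_frequency`` enters the degeneracy set."""
        counts = np.asarray(counts, dtype=float)
        if counts.shape[0] != 4:
            raise ValueError("position-count matrix must be 4 x L (rows A, C, G, T)")
        letters = "ACGT"
        cols = []
        for j in range(counts.shape[1]):
            col = counts[:, j]
            total = col.sum()
            kept = frozenset(letters[i] for i in range(4)
                             if total > 0 and col[i] / total >= min_frequency)
            if not kept:
                kept = frozenset(letters[int(np.argmax(col))])
            cols.append(_PAREN_TO_IUPAC.get(kept, next(iter(kept)) if len(kept) == 1 else "N"))
        return cls(motif_id, expand_consensus("".join(cols)) if len(cols) >= 5
                   else "".join(cols))

    def __len__(self) -> int:
        return len(self.consensus)

    @property
    def is_palindromic(self) -> bool:
        return self.consensus == reverse_complement_consensus(self.consensus)


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    return arr


def _match_positions(seq_codes: np.ndarray, consensus: str) -> np.ndarray:
    """Start positions of exact IUPAC matches, via per-position boolean
    lookup tables combined across the motif."""
    L = len(consensus)
    n = seq_codes.size
    if n < L:
        return np.array([], dtype=np.int64)
    ok = np.ones(n - L + 1, dtype=bool)
    for j, c in enumerate(consensus):
        table = np.zeros(256, dtype=bool)
        for b in IUPAC_SETS[c]:
            table[ord(b)] = True
        ok &= table[seq_codes[j:n - L + 1 + j]]
    return np.nonzero(ok)[0].astype(np.int64)


def scan_motif(
    sequences: dict[str, str],
    motif: MotifModel,
    intervals: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """All exact IUPAC matches of ``motif`` on both strands.

    Returns BED6-like rows (chrom, start, end, name, score, strand).
    A site matching on both strands (palindrome) is reported once, on +.
    If ``intervals`` (chrom/start/end) is given, only matches fully
    inside an interval are returned.
    """
    fwd = motif.consensus
    rev = reverse_complement_consensus(fwd)
    rows = []
    for chrom, seq in sequences.items():
        codes = _encode(seq)
        plus = _match_positions(codes, fwd)
        minus = _match_positions(codes, rev)
        minus = np.setdiff1d(minus, plus, assume_unique=False)  # palindrome rule
        for pos_arr, strand in ((plus, "+"), (minus, "-")):
            for p in pos_arr:
                rows.append((chrom, int(p), int(p) + len(fwd), motif.motif_id, 0, strand))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
    if intervals is not None and len(df):
        keep = np.zeros(len(df), dtype=bool)
        for chrom, sub in intervals.groupby("chrom"):
            sel = df["chrom"] == chrom
            if not sel.any():
                continue
            starts = np.sort(sub["start"].to_numpy())
            ends = sub["end"].to_numpy()[np.argsort(sub["start"].to_numpy())]
            i = np.searchsorted(starts, df.loc[sel, "start"].to_numpy(), side="right") - 1
            ok = (i >= 0) & (df.loc[sel, "end"].to_numpy() <= np.where(i >= 0, ends[i], 0))
            keep[np.nonzero(sel.to_numpy())[0]] = ok
        df = df[keep]
    return df.sort_values(["chrom", "start", "strand"]).reset_index(drop=True)


def _interval_hit_flags(intervals: pd.DataFrame, instances: pd.DataFrame) -> np.ndarray:
    flags = np.zeros(len(intervals), dtype=bool)
    for idx, (_, iv) in enumerate(intervals.iterrows()):
        sub = instances[(instances["chrom"] == iv["chrom"])
                        & (instances["start"] < iv["end"])
                        & (instances["end"] > iv["start"])]
        flags[idx] = len(sub) > 0
    return flags


@dataclass
class EnrichmentResult:
    motif_id: str
    hits_target: int
    hits_background: int
    n_target: int
    n_background: int
    fold_enrichment: float
    p_value: float
    passes: bool
    degenerate: bool = False


def motif_enrichment(
    target_intervals: pd.DataFrame,
    background_intervals: pd.DataFrame,
    motif: MotifModel,
    sequences: dict[str, str],
    fold_threshold: float = 5.0,
    p_threshold: float = 1.0e-12,
) -> EnrichmentResult:
    """Interval-level motif enrichment of targets over background.

    Fold enrichment compares hit densities (motif sites per bp);
    significance is a hypergeometric upper tail on interval-level
    hit/no-hit counts, which is exact for the sampling scheme. The
    ``passes`` flag applies the >5-fold, P < 1e-12 rule.
    """
    if len(background_intervals) == 0:
        raise ValueError("background interval set is empty")
    instances = scan_motif(sequences, motif)
    t_flags = _interval_hit_flags(target_intervals, instances)
    b_flags = _interval_hit_flags(background_intervals, instances)

    t_bp = int((target_intervals["end"] - target_intervals["start"]).sum())
    b_bp = int((background_intervals["end"] - background_intervals["start"]).sum())
    t_sites = _count_sites(target_intervals, instances)
    b_sites = _count_sites(background_intervals, instances)

    degenerate = (t_sites + b_sites) == 0
    if degenerate or t_bp == 0 or b_bp == 0 or b_sites == 0:
        fold = 0.0 if (degenerate or t_sites == 0) else np.inf
    else:
        fold = (t_sites / t_bp) / (b_sites / b_bp)

    N = len(target_intervals) + len(background_intervals)
    K = int(t_flags.sum() + b_flags.sum())
    n = len(target_intervals)
    k = int(t_flags.sum())
    p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0

    return EnrichmentResult(
        motif_id=motif.motif_id, hits_target=k, hits_background=int(b_flags.sum()),
        n_target=n, n_background=len(background_intervals),
        fold_enrichment=float(fold), p_value=p,
        passes=bool(np.isfinite(fold) and fold > fold_threshold and p < p_threshold
                    and not degenerate),
        degenerate=degenerate)


def _count_sites(intervals: pd.DataFrame, instances: pd.DataFrame) -> int:
    total = 0
    for _, iv in intervals.iterrows():
        total += int(((instances["chrom"] == iv["chrom"])
                      & (instances["start"] < iv["end"])
                      & (instances["end"] > iv["start"])).sum())
    return total


def instances_to_targets(
    instances: pd.DataFrame,
    genes,
    promoter_bp: int = 1000,
) -> pd.DataFrame:
    """Assign motif instances to genes whose promoter they occupy.

    An instance is assigned to gene G when its midpoint lies within
    ``promoter_bp`` upstream of G's TSS on G's strand. An instance
    between two divergent genes can be assigned to both.
    """
    rows = []
    for _, inst in instances.iterrows():
        mid = (int(inst["start"]) + int(inst["end"])) // 2
        for g in genes:
            if g.chrom != inst["chrom"]:
                continue
            if g.strand == "+":
                in_prom = g.tss - promoter_bp <= mid < g.tss
            else:
                in_prom = g.tss < mid <= g.tss + promoter_bp
            if in_prom:
                rows.append((inst["chrom"], int(inst["start"]), int(inst["end"]),
                             inst.get("name", "."), g.gene_id))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "motif_id", "gene_id"])


DEG_LOG2FC = 1.0
DEG_PVALUE = 0.05


def deg_flags(expression: pd.DataFrame, direction: str | None = None) -> pd.Series:
    """Differential-expression call: |log2FC| >= 1 and P < 0.05,
    optionally restricted to one direction of change."""
    lfc = expression["log2FC"]
    sig = (lfc.abs() >= DEG_LOG2FC) & (expression["p"] < DEG_PVALUE)
    if direction == "up":
        sig &= lfc > 0
    elif direction == "down":
        sig &= lfc < 0
    elif direction is not None:
        raise ValueError("direction must be 'up', 'down' or None")
    return sig


def integrate_expression(
    target_genes, expression: pd.DataFrame, direction: str = "down",
) -> dict:
    """Overlap of motif target genes with DEGs, with a hypergeometric
    overlap P against the universe of genes in the expression table."""
    universe = set(expression["gene_id"])
    targets = set(target_genes) & universe
    degs = set(expression.loc[deg_flags(expression, direction), "gene_id"])
    overlap = targets & degs
    N, K, n, k = len(universe), len(degs), len(targets), len(overlap)
    p = float(stats.hypergeom.sf(k - 1, N, K, n)) if n and K else 1.0
    return {"n_targets": n, "n_degs": K, "overlap": k, "universe": N, "p_value": p,
            "overlap_genes": sorted(overlap)}


def load_known_motifs(path=None) -> list[MotifModel]:
    """Shipped known Aspergillus TF motifs (tab-separated id/consensus
    file; lines starting with ``#`` are comments)."""
    from pathlib import Path

    if path is None:
        path = Path(__file__).parent / "data" / "known_motifs.txt"
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        motif_id, consensus = line.split("\t")[:2]
        out.append(MotifModel.from_string(motif_id, consensus))
    return out
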