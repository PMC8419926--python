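"""Readers and writers for the interchange formats the pipeline touches.

Everything is 0-based half-open in memory; GFF3's 1-based inclusive
coordinates are converted at this boundary. Writers emit records in a
deterministic order (natural chromosome order, then start) so reruns
are byte-identical.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GeneAnnotation

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]
NARROWPEAK_COLUMNS = BED6_COLUMNS + ["signalValue", "pValue", "qValue", "summitOffset"]


def natural_chrom_key(chrom: str):
    return [int(t) if t.isdigit() else t for t in re.split(r"(\d+)", chrom)]


def _sort_records(df: pd.DataFrame) -> pd.DataFrame:
    key = df["chrom"].map(lambda c: tuple(natural_chrom_key(str(c))))
    order = np.lexsort((df["start"].to_numpy(), key.to_numpy()))
    return df.iloc[order].reset_index(drop=True)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path, width: int = 60) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    seqio_write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(path) -> list[GeneAnnotation]:
    """Parse gene/mRNA/exon features into annotations, converting
    1-based inclusive coordinates to 0-based half-open."""
    import gffutils

    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        if len(line.split("\t")) != 9:
            raise ValueError(f"{path}: malformed GFF3 line {lineno} "
                             f"({len(line.split(chr(9)))} columns, expected 9)")
    try:
        db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                                keep_order=True, merge_strategy="create_unique")
    except Exception as exc:
        raise ValueError(f"{path}: malformed GFF3 ({exc})") from exc
    genes = []
    for g in db.features_of_type("gene", order_by="start"):
        exons = []
        for ex in db.children(g, featuretype="exon", order_by="start"):
            exons.append((ex.start - 1, ex.end))
        genes.append(GeneAnnotation(
            gene_id=g.id, chrom=g.seqid, start=g.start - 1, end=g.end,
            strand=g.strand, exons=tuple(exons)))
    return genes


def write_gff3(genes: list[GeneAnnotation], path) -> None:
    lines = ["##gff-version 3"]
    for g in sorted(genes, key=lambda g: (natural_chrom_key(g.chrom), g.start)):
        lines.append("\t".join([
            g.chrom, "fungatac", "gene", str(g.start + 1), str(g.end), ".",
            g.strand, ".", f"ID={g.gene_id}"]))
        lines.append("\t".join([
            g.chrom, "fungatac", "mRNA", str(g.start + 1), str(g.end), ".",
            g.strand, ".", f"ID={g.gene_id}.t1;Parent={g.gene_id}"]))
        for i, (s, e) in enumerate(g.exons or ((g.start, g.end),), start=1):
            lines.append("\t".join([
                g.chrom, "fungatac", "exon", str(s + 1), str(e), ".",
                g.strand, ".", f"ID={g.gene_id}.exon{i};Parent={g.gene_id}.t1"]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# BED dialects


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=BED6_COLUMNS, dtype={0: str, 3: str, 5: str})
    if (df["start"] >= df["end"]).any():
        raise ValueError(f"{path}: BED records must satisfy start < end")
    return df


def write_bed(records: pd.DataFrame, path) -> None:
    df = records.copy()
    for col, default in (("name", "."), ("score", 0), ("strand", ".")):
        if col not in df.columns:
            df[col] = default
    df = _sort_records(df[BED6_COLUMNS])
    df.to_csv(path, sep="\t", header=False, index=False)


def read_bedpe(path):
    from .insertions import fragments_from_alignments

    return fragments_from_alignments(path)


def write_bedpe(fragments, path) -> None:
    """Fragments as BEDPE, each template written as its two 1 bp outer
    mates (lossless for the (chrom, start, end) triple)."""
    df = fragments.df
    out = pd.DataFrame({
        "chrom1": df["chrom"], "start1": df["start"], "end1": df["start"] + 1,
        "chrom2": df["chrom"], "start2": df["end"] - 1, "end2": df["end"],
        "name": [f"frag{i + 1}" for i in range(len(df))],
        "score": ".", "strand1": "+", "strand2": "-",
    })
    out.to_csv(path, sep="\t", header=False, index=False)


def read_narrowpeak(path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t", header=None, comment="#")
    if raw.shape[1] != 10:
        raise ValueError(f"{path}: narrowPeak requires 10 columns, found {raw.shape[1]}")
    df = raw.set_axis(NARROWPEAK_COLUMNS, axis=1)
    df["chrom"] = df["chrom"].astype(str)
    bad = (df["summitOffset"] < -1) | (df["summitOffset"] >= df["end"] - df["start"])
    if bad.any():
        raise ValueError(f"{path}: summit offset outside peak (use -1 for none)")
    return df


def write_narrowpeak(peaks: pd.DataFrame, path) -> None:
    """Peak calls as ENCODE narrowPeak (BED6+4; summit offset in
    column 10, -1 when absent)."""
    df = peaks.copy()
    with np.errstate(divide="ignore"):
        df["pValue"] = np.where(df["p"] > 0, -np.log10(df["p"]), 999.0)
        df["qValue"] = np.where(df["q"] > 0, -np.log10(df["q"]), 999.0)
    out = pd.DataFrame({
        "chrom": df["chrom"], "start": df["start"], "end": df["end"],
        "name": df.get("name", "."), "score": np.minimum(
            (10 * df["qValue"]).round().astype(int), 1000),
        "strand": ".", "signalValue": df["enrichment"].round(5),
        "pValue": df["pValue"].round(5), "qValue": df["qValue"].round(5),
        "summitOffset": (df["summit"] - df["start"]).astype(int),
    })
    out = _sort_records(out)
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# tracks


def write_bedgraph_pair(track, out_prefix) -> tuple[str, str]:
    """Per-strand bedGraph pair for an insertion track (sparse: only
    nonzero bases)."""
    paths = []
    for strand, arrays in (("plus", track.plus), ("minus", track.minus)):
        path = Path(f"{out_prefix}.{strand}.bedGraph")
        lines = []
        for chrom in sorted(arrays, key=natural_chrom_key):
            arr = arrays[chrom]
            nz = np.nonzero(arr)[0]
            for pos in nz:
                lines.append(f"{chrom}\t{pos}\t{pos + 1}\t{arr[pos]}")
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
        paths.append(str(path))
    return tuple(paths)


def read_expression_table(path) -> pd.DataFrame:
    """Gene expression TSV with columns gene_id, log2FC, p."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "log2FC", "p"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expression table needs columns {sorted(required)}")
    return df
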