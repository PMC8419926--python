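"""Genome and annotation containers shared across the pipeline.

All coordinates are 0-based half-open internally; 1-based inclusive
coordinates appear only at the GFF3 boundary (see :mod:`fungatac.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class GeneAnnotation:
    """A protein-coding gene with exon structure.

    ``tss``/``tts`` are derived from the interval and strand: on the +
    strand the TSS is ``start`` and the TTS is ``end - 1``; on the -
    strand they swap, so ``tss > tts`` there.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -, got {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})")
        prev_end = -1
        for s, e in self.exons:
            if s < prev_end:
                raise ValueError(f"gene {self.gene_id}: exons must be sorted, non-overlapping")
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"gene {self.gene_id}: exon [{s}, {e}) outside gene body")
            prev_end = e

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    def introns(self) -> tuple[tuple[int, int], ...]:
        out = []
        for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if s2 > e1:
                out.append((e1, s2))
        return tuple(out)


@dataclass(frozen=True)
class PlantedMotif:
    """A motif instance written into a synthetic genome sequence."""

    motif_id: str
    consensus: str
    chrom: str
    start: int
    end: int
    strand: str


@dataclass
class GenomeModel:
    """A genome sequence plus gene annotation (and, for synthetic
    genomes, the motif instances planted into the sequence)."""

    sequences: dict[str, str]
    genes: list[GeneAnnotation] = field(default_factory=list)
    planted_motifs: list[PlantedMotif] = field(default_factory=list)

    def __post_init__(self) -> None:
        for g in self.genes:
            if g.chrom not in self.sequences:
                raise ValueError(f"gene {g.gene_id} on unknown chromosome {g.chrom}")
            if g.end > len(self.sequences[g.chrom]):
                raise ValueError(f"gene {g.gene_id} extends past end of {g.chrom}")

    @property
    def chrom_names(self) -> list[str]:
        return list(self.sequences)

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def genes_on(self, chrom: str) -> list[GeneAnnotation]:
        return [g for g in self.genes if g.chrom == chrom]
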