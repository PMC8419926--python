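"""Synthetic fungal ATAC-seq data with planted ground truth.

The generator emulates the statistical structure a fungal ATAC-seq
library shows after alignment, at the level the downstream stages
consume (deduplicated fragments; no base-call or aligner error model):

* a fragment-length mixture with a sub-100 bp nucleosome-free class and
  a decaying nucleosomal ladder at multiples of ~200 bp;
* nucleosome-free regions (NFRs) at promoters (TSS +- 150 bp) enriched
  for short-fragment insertions, with nucleosomes on a jittered 200 bp
  lattice elsewhere;
* bound TF footprints that locally deplete insertions and, crucially,
  bias the strand of flanking insertions: cuts 5' of a bound motif are
  preferentially read out on the + strand and cuts 3' on the - strand,
  with odds ``exp(kappa)``. Naked DNA and TF-deleted conditions lack
  this coupling, which is the signal the asymmetry module tests.

Every sampled quantity flows from one seeded NumPy generator, so a
(config, seed) pair reproduces byte-identical fixtures.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import GeneAnnotation, GenomeModel, PlantedMotif
from .insertions import FragmentSet
from .motifs import IUPAC_SETS, expand_consensus

CONDITION_WT = "WT"
CONDITION_NAKED = "naked"
TF_DELETED_PREFIX = "TF-deleted:"

NUCLEOSOME_HALF = 73  # bp protected either side of a dyad


@dataclass(frozen=True)
class FootprintSpec:
    """One planted TF: its motif, instance count, occupancy and the
    strength ``kappa`` of the strand-orientation bias at bound sites."""

    motif_id: str
    consensus: str
    n_instances: int
    occupancy: float = 0.9
    kappa: float = 2.0
    skew: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy must lie in [0, 1], got {self.occupancy}")
        if self.kappa < 0:
            raise ValueError(f"kappa must be >= 0, got {self.kappa}")
        if not 0.0 <= self.skew <= 1.0:
            raise ValueError(f"skew must lie in [0, 1], got {self.skew}")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated library.

    Fragment lengths follow
    ``nfr_fraction * TruncExp(scale=sub_length_scale, <100)`` plus a
    nucleosomal ladder ``sum_k w_k * Normal(k*nucleosome_period,
    mono_length_sd*sqrt(k))`` for k = 1..3.
    """

    n_fragments: int = 100_000
    nfr_fraction: float = 0.4
    nucleosome_period: int = 200
    mono_length_mean: float = 200.0
    mono_length_sd: float = 20.0
    sub_length_scale: float = 40.0
    ladder_weights: tuple[float, ...] = (0.55, 0.30, 0.15)
    footprint_spec: tuple[FootprintSpec, ...] = ()
    background_insertion_rate: float = 1.0
    nfr_enrichment: float = 8.0
    nfr_halfwidth: int = 150
    mono_nfr_depletion: float = 0.2
    nucleosome_protection: float = 0.2
    nucleosome_jitter_sd: float = 10.0
    footprint_pad: int = 4
    pad_kappa_scale: float = 3.0
    edge_boost: float = 4.0
    edge_width: int = 6
    asym_flank: int = 100
    duplication_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("background_insertion_rate", "nfr_enrichment", "duplication_rate",
                     "sub_length_scale", "mono_length_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.nfr_fraction <= 1:
            raise ValueError("nfr_fraction must lie in [0, 1]")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a simulated library."""

    condition: str
    planted_footprints: list[dict] = field(default_factory=list)
    nucleosome_dyads: dict[str, np.ndarray] = field(default_factory=dict)

    def footprint_frame(self) -> pd.DataFrame:
        cols = ["chrom", "start", "end", "motif_id", "strand", "bound"]
        return pd.DataFrame(self.planted_footprints, columns=cols)


# ---------------------------------------------------------------------------
# genome construction


def _sample_iupac(consensus: str, rng: np.random.Generator) -> str:
    return "".join(rng.choice(sorted(IUPAC_SETS[c])) for c in consensus)


_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def make_genome(
    n_chrom: int,
    lengths: list[int],
    n_genes: int,
    seed: int,
    motifs: list[tuple[str, str, int]] | None = None,
    gene_length_range: tuple[int, int] = (500, 1500),
    nfr_halfwidth: int = 150,
    max_retries: int = 50,
) -> GenomeModel:
    """Random genome with non-overlapping genes and motif instances
    planted in promoter NFRs.

    ``motifs`` is a list of ``(motif_id, consensus, n_instances)``; by
    default one instance of the PrtT-type consensus CCGHCGG is planted
    in every gene's promoter. Base composition is i.i.d. uniform except
    at planted instances. Raises if gene placement is infeasible after
    bounded retries.
    """
    if len(lengths) != n_chrom:
        raise ValueError("lengths must have one entry per chromosome")
    if any(ln < 10_000 for ln in lengths):
        raise ValueError("chromosomes must be >= 10 kb")
    rng = np.random.default_rng(seed)
    names = [f"chr{i + 1}" for i in range(n_chrom)]
    seqs = {n: rng.choice(list("ACGT"), size=ln) for n, ln in zip(names, lengths)}

    genes = _place_genes(names, lengths, n_genes, rng, gene_length_range, max_retries)

    if motifs is None:
        motifs = [("prtT", "CCGHCGG", n_genes)]
    planted = _plant_motifs(seqs, genes, motifs, rng, nfr_halfwidth)

    sequences = {n: "".join(s) for n, s in seqs.items()}
    return GenomeModel(sequences=sequences, genes=genes, planted_motifs=planted)


def _place_genes(names, lengths, n_genes, rng, length_range, max_retries):
    if n_genes == 0:
        return []
    total = sum(lengths)
    per_chrom = [int(round(n_genes * ln / total)) for ln in lengths]
    while sum(per_chrom) != n_genes:  # rounding drift
        i = int(np.argmax(lengths)) if sum(per_chrom) < n_genes else int(np.argmin(per_chrom))
        per_chrom[i] += 1 if sum(per_chrom) < n_genes else -1

    margin = 1000  # room for promoter NFR and chromosome ends
    genes: list[GeneAnnotation] = []
    gid = 0
    for name, ln, k in zip(names, lengths, per_chrom):
        if k == 0:
            continue
        span = ln - 2 * margin
        slot = span / k
        if slot < length_range[1] + 50:
            raise ValueError(
                f"cannot place {k} non-overlapping genes on {name} ({ln} bp)")
        for j in range(k):
            for attempt in range(max_retries):
                glen = int(rng.integers(length_range[0], length_range[1] + 1))
                lo = margin + int(j * slot)
                hi = margin + int((j + 1) * slot) - glen
                if hi <= lo:
                    continue
                start = int(rng.integers(lo, hi))
                end = start + glen
                strand = "+" if rng.random() < 0.5 else "-"
                exons = _split_exons(start, end, rng)
                genes.append(GeneAnnotation(
                    gene_id=f"gene{gid:05d}", chrom=name, start=start, end=end,
                    strand=strand, exons=exons))
                gid += 1
                break
            else:
                raise ValueError(f"gene placement failed on {name} after {max_retries} tries")
    return genes


def _split_exons(start, end, rng):
    n_exons = int(rng.integers(1, 4))
    glen = end - start
    if n_exons == 1 or glen < 300:
        return ((start, end),)
    intron = 60
    usable = glen - intron * (n_exons - 1)
    if usable < n_exons * 50:
        return ((start, end),)
    cuts = np.sort(rng.choice(np.arange(1, usable // 50), size=n_exons - 1, replace=False)) * 50
    exon_lens = np.diff(np.concatenate([[0], cuts, [usable]]))
    exons = []
    pos = start
    for el in exon_lens:
        exons.append((pos, pos + int(el)))
        pos += int(el) + intron
    exons[-1] = (exons[-1][0], end)
    return tuple(exons)


def promoter_nfr(gene: GeneAnnotation, halfwidth: int, chrom_len: int) -> tuple[int, int]:
    """TSS +- halfwidth, clipped to the chromosome."""
    t = gene.tss
    return max(0, t - halfwidth), min(chrom_len, t + halfwidth + 1)


def _plant_motifs(seqs, genes, motifs, rng, nfr_halfwidth):
    total_wanted = sum(n for _, _, n in motifs)
    if total_wanted > len(genes):
        raise ValueError(
            f"{total_wanted} motif instances requested but only {len(genes)} promoters")
    order = rng.permutation(len(genes))
    planted: list[PlantedMotif] = []
    cursor = 0
    for motif_id, consensus, n_inst in motifs:
        consensus = expand_consensus(consensus)
        for _ in range(n_inst):
            g = genes[order[cursor]]
            cursor += 1
            chrom_len = len(seqs[g.chrom])
            lo, hi = promoter_nfr(g, nfr_halfwidth, chrom_len)
            center = (lo + hi) // 2 + int(rng.integers(-20, 21))
            start = center - len(consensus) // 2
            end = start + len(consensus)
            start = max(0, min(start, chrom_len - len(consensus)))
            end = start + len(consensus)
            strand = "+" if rng.random() < 0.5 else "-"
            site = _sample_iupac(consensus, rng)
            written = site if strand == "+" else _revcomp(site)
            seqs[g.chrom][start:end] = list(written)
            planted.append(PlantedMotif(motif_id, consensus, g.chrom, start, end, strand))
    return planted


# ---------------------------------------------------------------------------
# condition simulation


def _condition_rng(seed: int, condition: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(condition.encode()) & 0x7FFFFFFF])


def _parse_condition(condition: str) -> tuple[str, str | None]:
    if condition == CONDITION_WT:
        return "WT", None
    if condition == CONDITION_NAKED:
        return "naked", None
    if condition.startswith(TF_DELETED_PREFIX):
        return "TF-deleted", condition[len(TF_DELETED_PREFIX):]
    raise ValueError(
        f"unknown condition {condition!r}; expected 'WT', 'naked' or 'TF-deleted:<motif>'")


def _sample_lengths(classes, config, rng):
    """Fragment lengths given per-fragment class index (0 = NFR,
    k = 1..K nucleosomal)."""
    n = len(classes)
    lengths = np.empty(n, dtype=np.int64)
    is_nfr = classes == 0
    m = int(is_nfr.sum())
    if m:
        sub = rng.exponential(config.sub_length_scale, size=m)
        while True:  # truncate to [10, 100)
            bad = (sub >= 100) | (sub < 10)
            if not bad.any():
                break
            sub[bad] = rng.exponential(config.sub_length_scale, size=int(bad.sum()))
        lengths[is_nfr] = sub.astype(np.int64)
    for k in range(1, len(config.ladder_weights) + 1):
        sel = classes == k
        m = int(sel.sum())
        if m:
            mean = config.mono_length_mean + (k - 1) * config.nucleosome_period
            sd = config.mono_length_sd * np.sqrt(k)
            lengths[sel] = np.clip(rng.normal(mean, sd, size=m), 50, None).astype(np.int64)
    return lengths


def simulate_condition(
    genome: GenomeModel,
    config: SimulationConfig,
    condition: str = CONDITION_WT,
) -> tuple[FragmentSet, SyntheticTruth]:
    """Simulate one library under WT, ``TF-deleted:<motif>`` or naked DNA.

    Returns raw (pre-deduplication) fragments and the ground truth:
    planted footprint intervals with bound flags and nucleosome dyads.
    """
    kind, deleted_motif = _parse_condition(condition)
    rng = _condition_rng(config.seed, condition)
    chrom_lengths = genome.chrom_lengths
    names = genome.chrom_names

    truth = SyntheticTruth(condition=condition)

    # nucleosome dyads: jittered lattice outside promoter NFRs (chromatin only)
    nfr_windows: dict[str, list[tuple[int, int]]] = {c: [] for c in names}
    for g in genome.genes:
        nfr_windows[g.chrom].append(promoter_nfr(g, config.nfr_halfwidth, chrom_lengths[g.chrom]))
    if kind != "naked":
        for c in names:
            lattice = np.arange(config.nucleosome_period, chrom_lengths[c] - NUCLEOSOME_HALF,
                                config.nucleosome_period, dtype=np.int64)
            lattice = lattice + rng.normal(0, config.nucleosome_jitter_sd,
                                           size=lattice.size).astype(np.int64)
            keep = np.ones(lattice.size, dtype=bool)
            for lo, hi in nfr_windows[c]:
                keep &= (lattice + NUCLEOSOME_HALF < lo) | (lattice - NUCLEOSOME_HALF >= hi)
            truth.nucleosome_dyads[c] = lattice[keep]
    else:
        truth.nucleosome_dyads = {c: np.array([], dtype=np.int64) for c in names}

    # occupancy, bound states and footprint intervals
    occ_by_motif = {fs.motif_id: fs for fs in config.footprint_spec}
    bound_mask = {c: np.zeros(chrom_lengths[c], dtype=bool) for c in names}
    instance_rows = []
    for pm in genome.planted_motifs:
        fs = occ_by_motif.get(pm.motif_id)
        occupancy = 0.0 if fs is None else fs.occupancy
        if kind == "naked" or (kind == "TF-deleted" and pm.motif_id == deleted_motif):
            occupancy = 0.0
        bound = bool(rng.random() < occupancy)
        # The protected interval is offset to the motif's 5' side, scaled
        # by kappa: TF/DNA complexes are structurally one-sided, and this
        # motif-oriented offset is what makes bound-site strand profiles
        # mirror-asymmetric while controls stay symmetric.
        kappa = 0.0 if fs is None else fs.kappa
        pad5 = config.footprint_pad + int(round(config.pad_kappa_scale * kappa))
        pad3 = config.footprint_pad
        lo_pad, hi_pad = (pad5, pad3) if pm.strand == "+" else (pad3, pad5)
        fp_lo = max(0, pm.start - lo_pad)
        fp_hi = min(chrom_lengths[pm.chrom], pm.end + hi_pad)
        if bound:
            bound_mask[pm.chrom][fp_lo:fp_hi] = True
        instance_rows.append(dict(chrom=pm.chrom, start=fp_lo, end=fp_hi,
                                  motif_id=pm.motif_id, strand=pm.strand, bound=bound,
                                  occupancy=occupancy,
                                  kappa=0.0 if fs is None else fs.kappa,
                                  skew=0.0 if fs is None else fs.skew))
    truth.planted_footprints = [
        {k: r[k] for k in ("chrom", "start", "end", "motif_id", "strand", "bound")}
        for r in instance_rows]

    weights = _insertion_landscapes(genome, config, kind, nfr_windows, truth, instance_rows)
    frag_df = _sample_fragments(genome, config, kind, rng, weights, bound_mask,
                                instance_rows, nfr_windows)

    if config.duplication_rate > 0:
        n_dup = int(round(config.duplication_rate * len(frag_df)))
        if n_dup:
            idx = rng.integers(0, len(frag_df), size=n_dup)
            keep = rng.integers(0, len(frag_df), size=len(frag_df) - n_dup)
            frag_df = pd.concat([frag_df.iloc[keep], frag_df.iloc[idx]],
                                ignore_index=True)

    return FragmentSet(frag_df.reset_index(drop=True)), truth


def _insertion_landscapes(genome, config, kind, nfr_windows, truth, instance_rows):
    """Two per-chromosome insertion-weight landscapes: one for NFR-class
    fragments, one for nucleosomal-class fragments."""
    chrom_lengths = genome.chrom_lengths
    w_nfr, w_nuc = {}, {}
    for c, ln in chrom_lengths.items():
        base = np.full(ln, config.background_insertion_rate, dtype=np.float64)
        if kind == "naked":
            w_nfr[c] = base
            w_nuc[c] = base
            continue
        nfr = base.copy()
        nuc = base.copy()
        for lo, hi in nfr_windows[c]:
            nfr[lo:hi] *= config.nfr_enrichment
            nuc[lo:hi] *= config.mono_nfr_depletion
        for dyad in truth.nucleosome_dyads[c]:
            lo = max(0, int(dyad) - NUCLEOSOME_HALF)
            hi = min(ln, int(dyad) + NUCLEOSOME_HALF + 1)
            nfr[lo:hi] *= config.nucleosome_protection
        w_nfr[c] = nfr
        w_nuc[c] = nuc
    # occupancy-weighted suppression inside bound footprints, with the
    # displaced transposase activity concentrated in short bands at the
    # footprint edges (the elevated flanking activity of protected sites)
    for r in instance_rows:
        if r["bound"]:
            residual = 1.0 - r["occupancy"]
            for w in (w_nfr, w_nuc):
                arr = w[r["chrom"]]
                lo_b = max(0, r["start"] - config.edge_width)
                hi_b = min(arr.size, r["end"] + config.edge_width)
                arr[lo_b:r["start"]] *= config.edge_boost
                arr[r["end"]:hi_b] *= config.edge_boost
                arr[r["start"]:r["end"]] *= residual
    return {"nfr": w_nfr, "nuc": w_nuc}


def _sample_fragments(genome, config, kind, rng, weights, bound_mask,
                      instance_rows, nfr_windows):
    chrom_lengths = genome.chrom_lengths
    names = genome.chrom_names
    ladder = np.asarray(config.ladder_weights, dtype=float)
    ladder = ladder / ladder.sum()

    # per-instance oriented centres for the strand-bias lookup
    asym = {c: np.zeros(chrom_lengths[c], dtype=np.float64) for c in names}
    if kind != "naked":
        for r in instance_rows:
            if not r["bound"] or r["kappa"] <= 0:
                continue
            center = (r["start"] + r["end"]) // 2
            lo = max(0, center - config.asym_flank)
            hi = min(chrom_lengths[r["chrom"]], center + config.asym_flank + 1)
            # Motif-oriented, per-flank strand bias. In the motif frame the
            # 5' flank prefers the motif-frame + strand with odds exp(kappa)
            # and the 3' flank the - strand with the attenuated odds
            # exp(kappa * skew). Equal strengths on both flanks would make
            # the expected profiles exactly mirror-symmetric (f+(x) =
            # f-(-x), indistinguishable from naked DNA by the asymmetry
            # statistic), so the default skew of 0 biases the 5' flank only,
            # emulating the structurally one-sided TF/Tn5 contact geometry.
            s = 1.0 if r["strand"] == "+" else -1.0
            offs = (np.arange(lo, hi) - center) * s
            kappa3 = r["kappa"] * r["skew"]
            # logit a with P(genomic + strand) = 1 / (1 + exp(a))
            asym[r["chrom"]][lo:hi] = s * (-r["kappa"] * (offs < 0)
                                           + kappa3 * (offs > 0))

    # class first (so nfr_fraction is the *global* short-fragment share),
    # then chromosome by that class's landscape mass
    n_nfr_total = int(rng.binomial(config.n_fragments, config.nfr_fraction))
    frames = []
    for class_kind, n_cls in (("nfr", n_nfr_total),
                              ("nuc", config.n_fragments - n_nfr_total)):
        if n_cls == 0:
            continue
        w = weights[class_kind]
        mass = np.array([w[c].sum() for c in names])
        n_per_chrom = rng.multinomial(n_cls, mass / mass.sum())
        for c, n_c in zip(names, n_per_chrom):
            if n_c == 0:
                continue
            frames.append(_sample_chrom(c, int(n_c), chrom_lengths[c], config,
                                        class_kind, rng, w[c], asym[c],
                                        bound_mask[c], ladder))
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    return pd.concat(frames, ignore_index=True)


def _sample_chrom(chrom, n, chrom_len, config, class_kind, rng, w, asym,
                  bound_mask, ladder):
    out_start = np.empty(0, dtype=np.int64)
    out_end = np.empty(0, dtype=np.int64)
    need = n
    cdf = np.cumsum(w / w.sum())
    for _ in range(100):  # rejection sampling tops up to the exact count
        m = int(need * 1.1) + 16
        cut = np.searchsorted(cdf, rng.random(m)).astype(np.int64)
        np.clip(cut, 0, chrom_len - 1, out=cut)

        if class_kind == "nfr":
            classes = np.zeros(m, dtype=np.int64)
        else:
            classes = rng.choice(np.arange(1, ladder.size + 1), size=m, p=ladder)
        lengths = _sample_lengths(classes, config, rng)

        # orientation: is this cut the + (left) end of its fragment?
        p_plus = 1.0 / (1.0 + np.exp(asym[cut]))
        cut_is_plus = rng.random(m) < p_plus

        # partner-end protection: a bound footprint blocks the second cut too
        for _retry in range(3):
            partner = np.where(cut_is_plus, cut + lengths - 11, cut - lengths + 11)
            inb = (partner >= 0) & (partner < chrom_len)
            blocked = np.zeros(m, dtype=bool)
            blocked[inb] = bound_mask[partner[inb]]
            if not blocked.any():
                break
            lengths[blocked] = _sample_lengths(classes[blocked], config, rng)

        # track-space cut -> fragment coordinates (undoing the +5/-5 shift)
        start = np.where(cut_is_plus, cut - 5, cut - lengths + 6)
        end = start + lengths
        ok = (start >= 0) & (end <= chrom_len) & (lengths > 0)
        start, end = start[ok], end[ok]
        take = min(need, start.size)
        out_start = np.concatenate([out_start, start[:take]])
        out_end = np.concatenate([out_end, end[:take]])
        need -= take
        if need == 0:
            break
    else:
        raise RuntimeError(f"fragment sampling failed to converge on {chrom}")
    return pd.DataFrame({"chrom": chrom, "start": out_start, "end": out_end})


# ---------------------------------------------------------------------------
# fixture export


def write_fixtures(genome: GenomeModel, fragments: FragmentSet,
                   truth: SyntheticTruth, out_dir) -> dict[str, str]:
    """Write FASTA / GFF3 / BEDPE / truth BED / truth JSON for a
    simulated condition; all files round-trip through :mod:`fungatac.io`."""
    import json
    from pathlib import Path

    from . import io as fio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "genome.fa",
        "gff3": out / "genes.gff3",
        "bedpe": out / "fragments.bedpe",
        "truth_bed": out / "truth_footprints.bed",
        "truth_json": out / "truth.json",
    }
    try:
        fio.write_fasta(genome.sequences, paths["fasta"])
        fio.write_gff3(genome.genes, paths["gff3"])
        fio.write_bedpe(fragments, paths["bedpe"])
        fp = truth.footprint_frame()
        bed = pd.DataFrame({
            "chrom": fp["chrom"], "start": fp["start"], "end": fp["end"],
            "name": fp["motif_id"],
            "score": fp["bound"].astype(int), "strand": fp["strand"]})
        fio.write_bed(bed, paths["truth_bed"])
        meta = {
            "condition": truth.condition,
            "n_fragments": len(fragments),
            "n_planted": len(truth.planted_footprints),
            "n_bound": int(sum(r["bound"] for r in truth.planted_footprints)),
            "nucleosome_dyads": {c: np.asarray(d).tolist()
                                 for c, d in truth.nucleosome_dyads.items()},
        }
        paths["truth_json"].write_text(json.dumps(meta, indent=1))
    except OSError as exc:
        raise OSError(f"failed writing fixtures under {out}: {exc}") from exc
    return {k: str(v) for k, v in paths.items()}
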