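"""End-to-end pipeline driver with provenance tracking.

``run_pipeline`` executes insertions -> qc -> peaks -> footprints ->
asymmetry -> motifs on a simulated or user-supplied dataset, writing
each stage's outputs plus a JSON provenance record (parameters, input
hashes, seed). Reruns with the same config are idempotent.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from . import asymmetry as asym_mod
from . import footprints as fp_mod
from . import insertions as ins_mod
from . import motifs as motif_mod
from . import peaks as peak_mod
from . import qc as qc_mod

logger = logging.getLogger(__name__)

KNOWN_KEYS = {
    "genome", "annotation", "fragments", "motifs", "expression", "out_dir",
    "seed", "verbosity", "shift_plus", "shift_minus", "min_mapq",
    "peak_window", "peak_step", "peak_min_qvalue", "peak_merge_gap",
    "footprint_shoulder", "footprint_threshold", "footprint_fdr_mode",
    "asym_flank", "n_perm", "promoter_bp", "tts_bp",
}


@dataclass
class RunConfig:
    genome: str
    annotation: str
    fragments: str
    out_dir: str
    motifs: str | None = None
    expression: str | None = None
    seed: int = 0
    verbosity: str = "INFO"
    shift_plus: int = ins_mod.DEFAULT_SHIFT_PLUS
    shift_minus: int = ins_mod.DEFAULT_SHIFT_MINUS
    min_mapq: int = ins_mod.DEFAULT_MIN_MAPQ
    peak_window: int = 200
    peak_step: int = 50
    peak_min_qvalue: float = 0.05
    peak_merge_gap: int = 100
    footprint_shoulder: int = 35
    footprint_threshold: float = -10.0
    footprint_fdr_mode: bool = True
    asym_flank: int = asym_mod.DEFAULT_FLANK
    n_perm: int = 1000
    promoter_bp: int = 1000
    tts_bp: int = 300

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _stage_seed(seed: int, stage: str) -> int:
    import zlib

    return int(np.random.SeedSequence([seed, zlib.crc32(stage.encode()) & 0x7FFFFFFF])
               .generate_state(1)[0] % (2 ** 31))


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage; halts with the stage name on failure."""
    logging.basicConfig(level=getattr(logging, config.verbosity, logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance: dict = {
        "config": asdict(config),
        "inputs": {k: _sha256(getattr(config, k))
                   for k in ("genome", "annotation", "fragments")
                   if getattr(config, k)},
        "stages": {},
    }
    stage = "setup"
    try:
        sequences = fio.read_fasta(config.genome)
        genes = fio.read_gff3(config.annotation)
        chrom_lengths = {c: len(s) for c, s in sequences.items()}

        stage = "insertions"
        raw = ins_mod.fragments_from_alignments(config.fragments, config.min_mapq)
        frags = ins_mod.deduplicate(raw)
        frags = ins_mod.classify_fragments(frags)
        events, dropped = ins_mod.insertion_events(
            frags, chrom_lengths, config.shift_plus, config.shift_minus)
        track = ins_mod.build_track(events, chrom_lengths, dropped=dropped)
        fio.write_bedgraph_pair(track, out / "insertions")
        provenance["stages"][stage] = {
            "fragments_in": len(raw), "fragments_dedup": len(frags),
            "events": int(len(events)), "events_dropped": dropped,
            "class_counts": {k: int(v) for k, v in frags.class_counts().items()}}
        logger.info("insertions: %d fragments -> %d events (%d dropped)",
                    len(frags), len(events), dropped)

        stage = "qc"
        hist = qc_mod.length_histogram(frags)
        pd.DataFrame({"length": np.arange(hist.size), "count": hist}).to_csv(
            out / "fragment_lengths.tsv", sep="\t", index=False)
        period = qc_mod.estimate_period(hist)
        _, profile = qc_mod.tss_matrix(track, genes)
        profile.to_csv(out / "tss_profile.tsv", sep="\t", header=["mean_insertions"])
        provenance["stages"][stage] = {
            "period": period.period, "period_confidence": period.confidence,
            "period_reliable": period.reliable}

        stage = "peaks"
        peaks = peak_mod.call_peaks(
            track, window=config.peak_window, step=config.peak_step,
            min_qvalue=config.peak_min_qvalue, merge_gap=config.peak_merge_gap)
        fio.write_narrowpeak(peaks, out / "peaks.narrowPeak")
        ann = peak_mod.annotate_peaks(peaks, genes, config.promoter_bp, config.tts_bp)
        ann.to_csv(out / "peak_annotation.tsv", sep="\t", index=False)
        provenance["stages"][stage] = {
            "n_peaks": len(peaks),
            "categories": ann["category"].value_counts().to_dict() if len(ann) else {}}
        logger.info("peaks: %d accessible regions", len(peaks))

        stage = "footprints"
        params = fp_mod.FootprintParams(
            shoulder=config.footprint_shoulder,
            score_threshold=config.footprint_threshold,
            fdr_mode=config.footprint_fdr_mode)
        fps = fp_mod.detect_footprints(track, peaks, params,
                                       seed=_stage_seed(config.seed, stage))
        fps.to_csv(out / "footprints.tsv", sep="\t", index=False)
        if len(fps):
            bed = fps.rename(columns={"parent_peak": "name"})[
                ["chrom", "start", "end", "name"]].copy()
            bed["score"] = np.clip((-10 * fps["score"]).round(), 0, 1000).astype(int)
            bed["strand"] = "."
            fio.write_bed(bed, out / "footprints.bed")
        provenance["stages"][stage] = {
            "n_footprints": len(fps), "threshold": float(fps.attrs["threshold"])}
        logger.info("footprints: %d at threshold %.2f",
                    len(fps), fps.attrs["threshold"])

        stage = "asymmetry"
        motif_models = (motif_mod.load_known_motifs(config.motifs)
                        if config.motifs else motif_mod.load_known_motifs())
        asym_records = {}
        fp_extended = fp_mod.extend_footprints(fps, chrom_lengths) if len(fps) else fps
        for motif in motif_models:
            inst = motif_mod.scan_motif(sequences, motif, intervals=fp_extended
                                        if len(fp_extended) else None)
            if len(inst) < 10:
                continue
            prof = asym_mod.strand_profiles(track, inst, config.asym_flank,
                                            motif_id=motif.motif_id)
            res = asym_mod.permutation_test(
                prof, n_perm=config.n_perm,
                seed=_stage_seed(config.seed, f"asym:{motif.motif_id}"))
            asym_records[motif.motif_id] = {
                "n_instances": prof.n_instances, "S": res.s_obs,
                "p_perm": res.p_perm, "call": res.call}
            pd.DataFrame({"offset": prof.offsets, "f_plus": prof.f_plus,
                          "f_minus": prof.f_minus}).to_csv(
                out / f"asymmetry_{motif.motif_id}.tsv", sep="\t", index=False)
        (out / "asymmetry.json").write_text(json.dumps(asym_records, indent=1))
        provenance["stages"][stage] = asym_records

        stage = "motifs"
        motif_stage: dict = {}
        if len(fps):
            targets_all = {}
            for motif in motif_models:
                inst = motif_mod.scan_motif(sequences, motif, intervals=fp_extended)
                targets = motif_mod.instances_to_targets(inst, genes, config.promoter_bp)
                targets_all[motif.motif_id] = sorted(set(targets["gene_id"]))
            (out / "motif_targets.json").write_text(json.dumps(targets_all, indent=1))
            motif_stage["n_target_genes"] = {k: len(v) for k, v in targets_all.items()}
            if config.expression:
                expr = fio.read_expression_table(config.expression)
                integration = {
                    mid: motif_mod.integrate_expression(genes_, expr, "down")
                    for mid, genes_ in targets_all.items()}
                (out / "expression_integration.json").write_text(
                    json.dumps(integration, indent=1, default=str))
                motif_stage["integration"] = {
                    k: v["overlap"] for k, v in integration.items()}
        provenance["stages"][stage] = motif_stage
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "provenance.json").write_text(json.dumps(provenance, indent=1, default=str))
    return out
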