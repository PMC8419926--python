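# fungatac

Chromatin-accessibility and transcription-factor footprint analysis for
fungal ATAC-seq, built around one question: **which insertion-depleted
sites are real protein/DNA contacts?** In compact genomes like
*Aspergillus niger*, the Tn5 transposase has sequence preferences that
carve "pseudo footprints" into naked DNA; the discriminating signal of a
genuinely bound site is a *strand-asymmetric* Tn5 integration pattern
around the motif, absent from naked genomic DNA and from strains in
which the corresponding TF has been deleted.

The package is for computational biologists who have aligned paired-end
ATAC-seq fragments (BAM or BEDPE), a genome (FASTA) and an annotation
(GFF3), and want a transparent, fully in-repo re-implementation of the
analysis chain — no MACS2/pyDNase/DiffBind binaries — plus a seeded
simulator that generates libraries with planted ground truth so every
stage can be validated.

## The analysis chain

1. **Insertion tracks** (`fungatac.insertions`). Fragments are
   deduplicated at template level; each yields two single-base cut
   events, shifted +5 (on +) and −5 (on −) to correct for the 9 bp
   duplication Tn5 introduces. Fragments are size-classified:
   < 100 bp nucleosome-free (NFR), 180–247 bp mononucleosomal,
   > 247 bp oligonucleosomal.
2. **QC** (`fungatac.qc`). Fragment-length spectrum with nucleosomal
   periodicity estimation (autocorrelation of the detrended histogram),
   TSS-centred insertion matrices per size class, Spearman correlation
   of binned genome-wide counts between samples.
3. **Peaks** (`fungatac.peaks`). A local-Poisson sliding-window scan:
   each 200 bp window is tested against
   λ = w·max(genome-wide rate, 5 kb rate, 10 kb rate), BH-corrected,
   and significant windows are merged. Peaks are annotated
   promoter > TTS > exon > intron > intergenic by summit position, and
   peak sets can be compared (Venn, ChIP/ATAC overlap). Differential
   accessibility between conditions uses a negative-binomial Wald test
   with a pooled method-of-moments dispersion and BH FDR.
4. **Footprints** (`fungatac.footprints`). A Wellington-style,
   strand-aware depletion test inside peaks: for a candidate footprint
   window FP with shoulders of 35 bp,
   `p_fwd = P(X ≤ x_FP,+)` under `Binom(n_+ in US∪FP, |FP|/(|FP|+|US|))`
   (and mirrored for − strand cuts against the downstream shoulder);
   the score is `log10 max(p_fwd, p_rev)`, so both strands must be
   depleted. The score threshold is depth-dependent; an empirical-FDR
   mode calibrates it on strand-and-position-shuffled tracks.
5. **Asymmetry** (`fungatac.asymmetry`) — the core criterion. Around
   motif instances the per-strand insertion profiles f₊(x), f₋(x) are
   aggregated motif-oriented; the mirror-asymmetry statistic

       S = ½ Σₓ |g₊(x) − g₋(−x)|,   gₛ = fₛ / Σ fₛ,

   is the total-variation distance between the + profile and the
   mirrored − profile: 0 under the reverse-complement symmetry that
   holds for naked DNA, elevated at bound sites. Significance comes
   from a per-instance orientation-flip permutation test, and a site is
   called *bound* only if it also exceeds the control condition
   (TF-deleted or naked DNA).
6. **Motifs** (`fungatac.motifs`). Exact IUPAC consensus scanning on
   both strands (gapped spellings such as the AmyR site CGG-N8-MGG are
   supported), interval-level hypergeometric enrichment with the
   > 5-fold, P < 1e−12 rule, promoter assignment of instances, and
   intersection with differential-expression tables
   (DEG = |log2FC| ≥ 1, P < 0.05).
7. **Simulator** (`fungatac.synthetic`). Generates genomes, gene
   annotations and fragment libraries with the statistical structure
   the analysis assumes — ~200 bp fragment-length periodicity,
   promoter NFRs enriched for short fragments, nucleosomes on a
   jittered lattice, and planted TF footprints whose occupancy and
   strand-bias strength κ are configurable — together with the ground
   truth needed to score recovery. Conditions: `WT`, `TF-deleted:<motif>`,
   `naked`.

## Worked example

```python
import pandas as pd
from fungatac.synthetic import (FootprintSpec, SimulationConfig, make_genome,
                                simulate_condition)
from fungatac.insertions import track_from_fragments
from fungatac.peaks import call_peaks
from fungatac.footprints import FootprintParams, detect_footprints
from fungatac.asymmetry import strand_profiles, permutation_test
from fungatac.qc import estimate_period, length_histogram

genome = make_genome(2, [250_000, 250_000], 400, seed=1,
                     gene_length_range=(400, 900),
                     motifs=[("prtT", "CCGHCGG", 300), ("decoy", "CCGHCGG", 100)])
config = SimulationConfig(
    n_fragments=100_000, seed=1,
    footprint_spec=(FootprintSpec("prtT", "CCGHCGG", 300, occupancy=0.9, kappa=2.0),))

wt, truth = simulate_condition(genome, config, "WT")
naked, _ = simulate_condition(genome, config, "naked")
track = track_from_fragments(wt, genome.chrom_lengths)
track_naked = track_from_fragments(naked, genome.chrom_lengths)

period = estimate_period(length_histogram(wt))
print(f"fragment-length period: {period.period} bp (confidence {period.confidence:.2f})")

peaks = call_peaks(track)
print(f"accessible regions: {len(peaks)} (naked DNA: {len(call_peaks(track_naked))})")

fps = detect_footprints(track, peaks, FootprintParams(fdr_mode=True), seed=1)
print(f"footprints: {len(fps)} at calibrated threshold {fps.attrs['threshold']:.2f}")

instances = pd.DataFrame([{"chrom": m.chrom, "start": m.start, "end": m.end,
                           "strand": m.strand}
                          for m in genome.planted_motifs if m.motif_id == "prtT"])
profile = strand_profiles(track, instances, flank=100)
control = strand_profiles(track_naked, instances, flank=100)
result = permutation_test(profile, n_perm=999, seed=1, control=control)
print(f"mirror asymmetry S = {result.s_obs:.3f}, permutation p = {result.p_perm:.4f},"
      f" call: {result.call}")
```

Output:

```
fragment-length period: 201 bp (confidence 1.82)
accessible regions: 350 (naked DNA: 0)
footprints: 248 at calibrated threshold -2.19
mirror asymmetry S = 0.154, permutation p = 0.0010, call: bound
```

Reading it: the simulated chromatin library shows the expected
~200 bp nucleosomal ladder; 350 accessible regions are called where the
matched naked-DNA library yields none; 248 footprints survive the
shuffle-calibrated score threshold; and around the planted TF motifs
the strand profiles are mirror-asymmetric (S = 0.154) far beyond what
orientation-flipping permutations produce, while the naked control
stays symmetric — the site set is called bound.

The same chain is available from the shell:

```bash
fatac simulate --out fix --seed 9
fatac peaks --alignments fix/fragments.bedpe --genome fix/genome.fa --out peaks.narrowPeak
fatac footprints --alignments fix/fragments.bedpe --genome fix/genome.fa \
      --peaks peaks.narrowPeak --out footprints.tsv
fatac motifs scan --genome fix/genome.fa --intervals fix/truth_footprints.bed --out motifs.bed
fatac asymmetry --alignments fix/fragments.bedpe --genome fix/genome.fa \
      --motif-bed motifs.bed --out asymmetry.json
```

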