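# Methods

This note documents the models and procedures the package implements,
the defaults that matter, what the simulator does and does not emulate,
and the numerical choices made where the design was open.

## Tn5 insertion events

A paired-end template [start, end) records two transposition cuts. Tn5
acts as a dimer making staggered cuts 9 bp apart, so the observed
alignment ends are offset from the insertion centre; the package shifts
+-strand coordinates by +5 and −-strand coordinates by −5, taking the
−-strand cut at the last covered base (`end − 1`) before shifting. The
ENCODE +4/−5 variant is available via `shift_plus`/`shift_minus`.
Deduplication collapses exact (chrom, start, end) triples — template
level, strand-free. Events shifted outside a chromosome are dropped and
counted, preserving the audit identity
`2·|fragments| = |events| + |dropped|`. Fragment size classes follow
the standard convention: < 100 bp nucleosome-free, 180–247 bp
mononucleosomal, > 247 bp oligonucleosomal; lengths in [100, 180) are
ambiguous and excluded from class-specific analyses.

## Fragment-length periodicity

The period estimator autocorrelates the detrended length histogram
(301-bin moving-average detrend) and reports the lag of maximal
autocorrelation in [120, 300] bp. Lengths below 100 bp are excluded
first: periodicity is a property of the nucleosomal ladder, and the
large sub-nucleosomal mode otherwise contaminates the autocorrelation
through its cross-term with the mononucleosome peak (empirically a
~20 bp downward bias). Confidence is the ratio of the peak to the mean
absolute autocorrelation in the search range; histograms under 100
fragments return an undefined period.

## Peak calling

Insertion counts (both strands) are summed in 200 bp windows every
50 bp. Each window is tested with a Poisson upper tail against
λ = w · max(genome-wide rate, 5 kb local rate, 10 kb local rate) — the
local-λ guard makes the caller robust to broad accessibility domains
and copy-number structure. Window p-values are BH-corrected genome-wide;
windows with q < 0.05 are merged across gaps ≤ 100 bp, peaks shorter
than 100 bp are discarded, and the summit is the maximum of the 50 bp
smoothed insertion density. Calling is translation-invariant by
construction.

Peak categories are assigned by summit with precedence
promoter (1 kb upstream of a TSS) > TTS (±300 bp) > exon > intron >
intergenic; promoter-first matches the promoter-centric structure of
compact fungal genomes, and the TTS half-width is a documented default
where no published value exists. Venn comparisons report the common
count on each side separately, because "overlaps ≥ 1 peak of the other
set" is not symmetric; the two counts are equal in the printed worked
example but need not be in general.

## Differential accessibility

Counts per consensus peak (union of per-sample peaks, merged) are
library-size normalized. The per-peak two-sided test is a Wald z on the
difference of group means under a negative-binomial variance
μ + αμ² evaluated at the pooled mean, with the common dispersion α
estimated by the pooled moment ratio Σ(s² − m)/Σ(m²) across peaks
(within groups). The ratio-of-sums form matters: a median of per-peak
1-degree-of-freedom moment estimates is biased toward zero (the median
of χ²₁ is 0.455) and inflates the type-I error several-fold. α ≤ 0
falls back to Poisson. log2 fold changes use a pseudocount of 1; BH
gives the FDR. With two replicates per group this calibrates to the
nominal level on NB-simulated nulls and recovers ≥ 80% of planted
4-fold changes at FDR < 0.05 (see `scripts/acceptance.py`).

## Footprint detection

For a candidate footprint FP of size s (odd, default 11–31) centred in
a peak, with 35 bp shoulders US (upstream) and DS (downstream):

    p_fwd = P(X ≤ x⁺_FP),  X ~ Binom(n⁺_{US∪FP}, s/(s+35))
    p_rev = P(X ≤ x⁻_FP),  X ~ Binom(n⁻_{FP∪DS}, s/(s+35))
    score = log10 max(p_fwd, p_rev)

The max combination demands depletion on *both* strands — conservative
by construction. The binomial tail is the default; the cited
beta-binomial variant is not reproducible without a dispersion
parameterization, so reproducibility won the trade. Every base of every
peak is scored at every size (footprint windows must lie inside the
peak; shoulders may extend beyond it but not past the chromosome);
the best (most negative) score per position is kept and footprints are
selected greedily in ascending score order, ties broken by smaller
size then leftmost, yielding pairwise non-overlapping calls.

The score threshold is depth-dependent, as in any Wellington-family
tool: the library default of −10 suits deeply sequenced genomes, while
desk-scale simulations operate around −2 to −3. The FDR mode calibrates
the threshold on strand-and-position-shuffled tracks (events within
each peak redistributed uniformly over positions and strands),
choosing the loosest threshold at which the mean shuffled yield over 5
independent shuffles is ≤ 1% of the real yield; averaging matters
because single-shuffle yields at the chosen threshold are small Poisson
counts. Specificity against naked DNA is evaluated at the same
threshold, averaged over replicate naked libraries for the same reason.

## Mirror-asymmetry criterion

Around motif instances (profiles are anchored on the *motif scan*
coordinates — anchoring on padded footprint intervals would re-centre
any one-sided protection and cancel the signal), per-strand insertion
profiles are aggregated motif-oriented over offsets x ∈ [−F, F]
(F = 100): a −-strand instance contributes with offsets negated and
strand labels swapped. With each strand profile normalized to a
distribution, the statistic

    S = ½ Σₓ |g₊(x) − g₋(−x)|

is the total-variation distance between the + profile and the mirrored
− profile, bounded in [0, 1], scale-free, and exactly 0 under the
reverse-complement symmetry f₊(x) = f₋(−x) that holds in expectation
for naked DNA. Each strand is normalized separately — this is what
makes the disjoint-support extreme reach S = 1 and keeps S a pure shape
statistic. An all-zero profile raises an explicit undefined-statistic
error; a profile with one silent strand returns S = 1.

The null flips each instance's orientation independently with
probability ½ (offset negation + strand swap), preserving every
instance's total signal and positional clustering while destroying only
the strand/orientation coupling; p = (1 + #{S_null ≥ S_obs})/(n_perm+1)
with n_perm ≥ 100 enforced. A site set is called *bound* only when
p < 0.05 **and** S_obs exceeds the 95th bootstrap percentile of every
supplied control condition (TF-deleted, naked DNA) — mirroring the
three-way experimental comparison; controls that disagree yield
*indeterminate*. Condition contrasts come with instance-level bootstrap
CIs (1000 resamples, seeded). Motif-body offsets are included in S by
default (the published profiles span the motif); excluding them is a
flag.

## Motif scanning and integration

Matching is exact IUPAC set membership on both strands, zero
mismatches; gapped spellings (CGG-N8-MGG) and slash alternatives
((C/A)) are normalized first. A site matching both strands is reported
once, on + — note this palindrome rule means reverse-complement
consensus matches can appear at sites the forward spelling rejects
(CCGHCGG rejects CCGGCGG forward, but the reverse-complement consensus
CCGDCGG accepts it). Enrichment is interval-level (hit/no-hit) with a
hypergeometric upper tail — exact for the sampling scheme — with hit
*density* (sites per bp) for the fold, and the > 5-fold, P < 1e−12
passing rule. Site-count enrichment is deliberately not the default
because multiple sites per interval break the hypergeometric model.
Instances map to a gene when their midpoint lies within 1 kb upstream
of its TSS, gene-strand aware; divergent promoters can claim an
instance for both genes. Expression integration flags DEGs at
|log2FC| ≥ 1 and P < 0.05, split by direction, and tests target/DEG
overlap hypergeometrically against the expression-table universe.

## The simulator

The generator emulates, at the level the analysis consumes
(deduplicated aligned fragments; no base-call errors, no aligner, no
PCR-duplicate structure beyond an optional duplication rate, no
organellar contamination):

* **Genome**: i.i.d. uniform base composition; non-overlapping genes
  with 1–3 exons on slot-partitioned chromosomes; motif instances
  written into promoter NFRs (one per selected gene, random strand),
  sampled from their IUPAC sets.
* **Fragment lengths**: `nfr_fraction`·TruncExp(scale 40, in [10, 100))
  plus a nucleosomal ladder Σₖ wₖ·Normal(k·200, 20√k), k = 1..3 with
  weights (0.55, 0.30, 0.15) — the decaying multi-modal spectrum of a
  chromatin library. `nfr_fraction` is the *global* short-fragment
  share (class is drawn first, then position).
* **Positions**: class-specific insertion landscapes. Sub-nucleosomal
  cuts are enriched 8× in promoter NFRs (TSS ± 150 bp) and suppressed
  5× inside nucleosome cores (dyads on a 200 bp lattice, 10 bp jitter,
  excluded from NFRs); nucleosomal-class cuts are depleted 5× in NFRs.
  Naked DNA is uniform for both classes. One cut is sampled from the
  landscape; the fragment extends left or right of it, and the partner
  cut is re-drawn (up to 3 times) if it lands in a protected footprint.
  Rejection sampling tops libraries up to the exact fragment count.
* **Bound footprints**: each planted instance is bound with probability
  `occupancy`; bound intervals suppress insertions to (1 − occupancy)
  of their landscape weight. Two further features make bound sites
  realistic and detectable:
  (a) *one-sided protection* — the protected interval extends
  `pad + 3κ` bp on the motif's 5′ side but only `pad` bp on its 3′ side
  (TF/DNA complexes are structurally asymmetric), and
  (b) *edge-displaced activity* — 6 bp bands at the footprint edges
  carry 4× elevated insertion weight (the flanking hyperactivity of
  protected sites).
  In addition, cuts within 100 bp of a bound motif are assigned to the
  + strand with odds exp(κ) on the 5′ flank (attenuated by a
  configurable skew, default 0, on the 3′ flank), applied in the
  genomic frame, where the 5′→+/3′→− pattern is reverse-complement
  invariant.

  A design note on why (a) and (b) exist: a *symmetric* positional
  strand bias (equal odds on both flanks) leaves the expected profiles
  exactly mirror-symmetric — f₊(x) = f₋(−x) — so the S statistic
  provably cannot distinguish it from naked DNA; moreover paired-end
  fragments conserve strand totals locally (each biased cut's mate
  refills the opposite strand nearby), which empirically flattens even
  large per-cut biases. Mirror asymmetry at bound sites must therefore
  come from motif-*oriented* structural asymmetry, which (a) and (b)
  provide; the per-cut strand bias contributes the strand-shoulder
  signal the footprint detector exploits.
* **Conditions**: `TF-deleted:<motif>` forces that motif's occupancy
  to 0 (all else identical to WT); `naked` removes nucleosomes,
  binding, and landscape structure entirely and has, by construction,
  zero bound sites.
* **Determinism**: all randomness flows from one seeded NumPy
  generator; the condition label is folded into the seed stream, so a
  (config, seed) pair reproduces byte-identical fixtures.

What passing tests on this simulator do **not** show about real data:
Tn5 hexamer sequence preference (the package's asymmetry criterion is
precisely the tool meant to separate such pseudo-footprints from
binding, but the generator does not plant sequence-driven bias), GC
and mappability structure, chromatin heterogeneity across cell
populations, and organellar or duplicated-read contamination.

## Study conditions used by tests and the acceptance script

Chosen once, as a desk-scale model of a compact fungal genome: two
250 kb chromosomes, 400 genes (gene bodies 400–900 bp), one planted
PrtT-type CCGHCGG instance per promoter — 300 with a bound TF
(occupancy 0.9, κ = 2) and 100 unbound decoys; libraries of 1e5
fragments (2e5 insertion events), `nfr_fraction` 0.4, NFR enrichment
8×. Calibration studies use 100 replicate datasets at reduced depth
(2e4-fragment naked libraries for permutation type-I error; 2000-peak,
2 vs 2 count matrices for the differential test). These sizes keep the
full suite and the acceptance run in the minutes range on one CPU
while leaving every recovery margin interpretable.

## Known limitations

* The binomial footprint score ignores overdispersion of cut counts;
  the beta-binomial option estimates dispersion from shoulder
  variability but is off by default for reproducibility reasons — at
  desk-scale depth the binomial calibrates well against shuffled
  tracks.
* `sample_correlation` operates on binned totals only; no
  library-complexity or saturation diagnostics.
* The peak caller has no control-subtraction mode (input libraries)
  and no fragment-pileup mode; insertion midpoints are the signal.
* IUPAC consensus scanning has no mismatch tolerance or PWM scoring;
  for the short, high-information fungal motifs involved this is the
  intended behaviour, not a restriction to be lifted lightly.
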