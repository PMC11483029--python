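# Methods

## Model and scope

The package analyses the downstream consequences of branchpoint competition:
a repressive RNA-binding protein (QKI-like, binding ACUAA with a UAAY
half-site) and the branchpoint-recognition factor SF1/BBP contend for intron
branchpoint sequences. Four analysis stages are covered — intron-retention
quantification from class-labeled counts, two-contrast dPSI co-regulation,
3′ss-proximal motif grammar, and RNA-affinity-chromatography (RAC)
proteomics enrichment. Upstream tools (aligners, pseudo-aligners, PSI
callers, DESeq2-style dispersion modeling, MS search engines, SEA/rMAPS2)
are deliberately out of scope: their *output tables* are the inputs, and
only the filtering/statistical logic applied to those tables is implemented
here.

## Coordinate and sequence conventions

Internal intervals are 0-based half-open; GFF3 is converted from/to 1-based
inclusive, BED is native. All sequences and motifs are normalized to the
DNA alphabet (U→T, uppercase) on ingest; RNA input is accepted everywhere.
For an intron on the minus strand, the 3′ss-adjacent base is the interval
`start`; windows are always returned 5′→3′ in transcript orientation.

**Window convention.** `WindowSpec(a, b)` denotes the half-open
transcript-oriented slice `intron[len-a : len-b]`, so its length is `a − b`.
The yeast-style window is `(80, 0)` — the last 80 intron nucleotides
including the base adjacent to the 3′ss — and the human-style window
default is `(63, 20)` (43 nt ending 20 nt upstream of the 3′ss), with
`(60, 20)` available since both spans appear in common usage. The
half-open reading was chosen over the inclusive one because it makes the
80-nt window exactly 80 nt and keeps slice arithmetic trivial; the
difference is a single boundary base and does not affect any enrichment
logic. Windows never extend past the intron 5′ end (clamp policy
"truncate" keeps the available sequence; "skip" drops the intron with a
report) and never cross into exons.

## Motif scanning

Patterns combine IUPAC codes and bracket classes (`ACT[ACTG]AG`), compiled
to per-position allowed-base sets and executed as a regex lookahead so that
**overlapping matches are all reported**. This is load-bearing: a
tandem-embedded dual site such as `TACTAACTAAC` contains two ACUAA cores at
offsets 1 and 5, and a scanner that consumes matched text would count one.
`N` in a sequence matches nothing. The dual-core classifier calls a window
dual when ≥ 2 core occurrences exist (independent or tandem-embedded), and
the 2×2 chi-squared enrichment test exposes its contingency table rather
than just the p-value, since the underlying counts are the scientific
object. QRE calls pair a core with a half-site within ≤ 20 nt (nearest
pattern edges, either side); half-sites lying fully inside a core hit are
excluded as non-independent. The positional map is a simplified coverage
profile (fraction of sequences with a fully contained hit per sliding
window, two-proportion chi-squared against the background set); it is a
validation tool for synthetic data, not a reimplementation of rMAPS2's
background model.

## Statistics

`stats_core` implements the exact semantics the filters rely on, with
p-values from scipy reference distributions:

* **Student t** — pooled-variance unpaired two-sided by default (the
  typical choice for 3 vs 3 replicate designs); Welch available. Both
  samples constant: p = 1 if means equal, else p = 0 with a warning.
* **Mann-Whitney U** — midrank U; exact two-sided p by full enumeration of
  all C(n₁+n₂, n₁) rank assignments when n₁+n₂ ≤ 12 (exact under ties,
  conditional on the tie pattern), otherwise normal approximation with tie
  and continuity corrections. The approximation agrees with enumeration to
  < 0.02 in tests.
* **Chi-squared 2×2** — the closed form N(ad−bc)²/((a+b)(c+d)(a+c)(b+d)),
  df = 1, uncorrected by default (Yates optional, never increases the
  statistic); zero margins are errors.
* No multiple-testing correction in the per-intron splicing test: the
  analysis uses raw P < 0.1 cutoffs by design. Benjamini-Hochberg is
  available behind a flag in the proteomics differential analysis.

## Splicing quantification

Percent unspliced is computed per gene from its unspliced and spliced rows
(summed over multiple transcript rows of the same class if present);
0/(0+0) is undefined and excludes the gene for that comparison rather than
being imputed. The expression filter is base mean > 100 (strict) on raw
unspliced+spliced counts over all analyzed samples — no library-size
normalization, since the cutoff is a detectability floor, not an abundance
estimate; a size-factor option could be added behind the same interface.
Significance is p < 0.1 (strict) on the per-replicate percent-unspliced
values; direction is the sign of Δ%unspliced (induced − control). The
class-abundance summary excludes transcripts below 0.2 TPM in all samples
and compares per-class log2FC distributions (pseudocount 0.01) by
Mann-Whitney U. One documented ambiguity: the abundance analysis cutoff is
implemented as P < 0.1 (the significance reading); the opposite direction
is configurable. The ΔΔCt calculator is literal: ΔCt = Ct_target −
Ct_reference, relative abundance 2^(−ΔCt), normalized to the
reference-group mean (so that group averages exactly 1).

## Co-regulation rules

All printed cutoffs are strict inequalities: single-contrast significance
is |dPSI| > 10 AND MVdPSI95 > 0; co-regulated events need |dPSI| > 10 in
*either* contrast AND MVdPSI95 > 0 in *both*; control events need base
mean > 100, |dPSI| < 1 in both and MVdPSI95 exactly 0 in both. Boundary
values (|dPSI| = 10, MV = 0, |dPSI| = 1) are therefore excluded, and this
is tested. An event with dPSI exactly 0 in a co-regulated pair receives no
quadrant and is reported separately, since the sign-pair mapping is
undefined there. Control sampling is uniform without replacement from the
eligible set, seeded; if fewer than n are eligible all are returned with a
warning.

## RAC proteomics

Background correction is (NSC_substrate − NSC_APT)/NSC_NE per protein;
proteins with zero or missing nuclear-extract (NE) values are excluded with
a reason because the correction is undefined for them. The tally over a
protein set (e.g. E-complex/17S U2 members) first restricts to members
with a positive corrected value in ≥ 1 substrate, then counts signs per
substrate; zeros are counted as neither and reported, so
n_pos + n_neg + n_zero equals the number of included members. Row Z-scores
use the population SD; constant rows become zero with a warning.
Hierarchical clustering is average-linkage on Euclidean distances with
rows/columns pre-sorted lexicographically by id, which makes the leaf
order a pure function of the values and resolves equal-height merges
deterministically. The replicate differential analysis replaces the
moderated (empirical-Bayes) statistics of limma-style pipelines with a
plain two-sample t-test on log2 values — the filter logic (|log2FC| > 0.2
strict / ≥ 0.7 with p < 0.01, missing or zero values excluded rather than
imputed) is the analysis content here, and a moderated test is out of
scope by design.

## Synthetic data: what it emulates, and what it does not

`SimulationConfig` defaults define the study conditions: 300 genes, 20%
intronless, 3 vs 3 replicates, negative-binomial counts
(var = m + 0.05·m²) around log-normal expression (μ = 6.5, σ = 0.8 on the
log scale — median ≈ 660 counts so ~99% of genes clear base mean > 100),
baseline unspliced fractions from Beta(2, 18) (mean 10%, typical of
efficiently spliced transcripts), and a planted 30-percentage-point
increase in unspliced fraction for affected genes under induction. Motif
classes {0, 1, ≥ 2 cores} have probabilities (0.55, 0.30, 0.15); the dual
class is tandem-embedded half the time. Affectedness is conditioned on
motif content (probability 0 / 0.5 / 1.0 by class), emulating dual-motif
introns being the most repression-sensitive; the coupling strengths are a
modeling choice, not a measured quantity. Windows are built by rejection
sampling: backgrounds are redrawn until they contain no accidental core,
the planted motifs are then written in, and the window is re-scanned and
accepted only if exactly the planted hits are found — so scanner tests
have clean ground truth.

dPSI tables plant quadrant events with |dPSI| in [12, 60] (noise re-clamped
above 11, keeping them confidently past the > 10 cutoff) and MVdPSI95 =
max(|dPSI| − 10, 0.5) > 0; null events have |dPSI| < 1 and MVdPSI95 = 0.
Default quadrant probabilities put ~43% of non-null events in the
"up in contrast A, down in contrast B" quadrant, mirroring the structure
the quadrant analysis is designed to detect. Spectral-count tables plant a
protein's substrate value at APT + fold·NE so its corrected enrichment is
~fold; the DIA-style generator plants log2 fold changes on replicate
columns with Gaussian log-scale noise and optional missingness.

All streams derive from one integer seed via `numpy.random.SeedSequence`
spawning, and fixed-seed runs are byte-identical.

**Limitations.** The simulator does not model read-level artifacts,
GC/codon composition, batch effects, library-size variation, multi-intron
genes, correlated gene expression, or DESeq2-style dispersion trends; one
contig per gene is a simplification. Passing tests therefore demonstrate
correctness of the analysis logic and its calibration under the assumed
noise model — not robustness to every property of real RNA-seq or DIA
data. The positional map and the plain t-test stand-ins are declared
simplifications of rMAPS2 and limma respectively.

## Problem sizes and numerical choices

The validation suite uses 1000 random 80-mers × 9 patterns for scanner
oracle equivalence, 500 random introns on both strands for window
extraction, full enumeration for all Mann-Whitney size pairs with
n₁+n₂ ≤ 10, 20 null simulations of 300 genes for type-I calibration
(flagged fraction expected in [0.06, 0.14] at p < 0.1), 5 simulations for
sensitivity (≥ 0.8 at a 30-point planted effect, direction ≥ 99% correct),
100 simulations of 40 vs 100 windows at 40% vs 6% dual-core prevalence for
enrichment power (≥ 0.9 at α = 0.05) plus 400 permuted-label null
simulations for size (5% ± 3 points), and 600-event noiseless dPSI tables
for exact quadrant recovery. These sizes give tight Monte-Carlo error at
interactive runtimes. Floating-point ties in the exact Mann-Whitney
enumeration are handled with a 1e-9 tolerance on the deviation
comparison; chi-squared inputs are validated for positive margins before
division.
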