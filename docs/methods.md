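# Methods

This note records the models, parameter choices and numerical conventions
behind the package, and what the synthetic study conditions do and do not
establish.

## Coordinates and gene models

All internal coordinates are 0-based half-open (BED convention); GFF3 is
converted on read. Protein-coding genes are extended to transcribed spans:
explicit `five_prime_UTR` / `three_prime_UTR` features are honoured, and
genes without them get the genome-wide mean UTR lengths for fission yeast,
293 bp (5′) and 430 bp (3′), strand-mirrored and clamped to the chromosome.
Dubious ORFs are dropped by a configurable attribute-keyword match
(default: any attribute containing "dubious"), since annotations flag them
inconsistently. IGRs are the complement of the union of transcribed spans on
chromosome arms (chromosome minus the centromere/telomere/rDNA mask);
overlapping genes leave no IGR, and an IGR missing a flanking gene on one
side is classed `edge` and excluded from orientation statistics. Orientation
is read off the flanking strands — (−,+) divergent, (+,−) convergent, equal
strands tandem — and the "second orientation" applies the same rule one gene
further out.

## Peak calling and site classification

The fold-enrichment (FE) track is the depth-normalized
(chip + 1)/(input + 1) ratio per 10 bp bin. A peak is a maximal run of bins
with FE at or above the threshold (6 for Orc4, 2 for Mcm2 — the enrichment
cutoffs of the upstream peak caller); runs narrower than 50 bp are discarded
as false positives; a run containing several local maxima stays one peak and
the summit is the center of the highest-FE bin, leftmost on ties (a
determinism requirement). Peaks overlapping the mask by ≥1 bp are removed.
An Orc peak overlapping a Mcm peak by ≥1 bp becomes an OM site; when several
Mcm peaks overlap one Orc peak, the largest-overlap one is paired (leftmost
on ties) — the pairing only affects summit-offset statistics, and
many-to-many overlaps are why per-protein overlap tallies need not sum to
the pair count.

## Sequence features

*AT content.* `at_profile` is a centered sliding-window mean (window
truncated at sequence ends; N counts as non-AT). `L_AT` counts positions in
the 1 kb analysis window whose centered 101 bp window has AT fraction
≥ 0.75; the 101 bp windows may reach into flanking sequence. Flank asymmetry
compares the AT fractions of [summit−500, −100) and [+100, +500).

*Melting energy.* ΔG_melt over a 200 bp window is the negated sum of the
199 dinucleotide stacking free energies, using the unified nearest-neighbour
ΔG°37 table (kcal/mol) as the default parameter set; any standard table
preserves the AT-vs-GC ordering the analysis relies on, and the parameter
map is overridable. Duplex-initiation terms are omitted because profiles are
only compared across equal-width windows. Windows containing N, or extending
past the sequence, are NaN.

*Motif scanning.* Sequences are scored on both strands with log2
likelihood-ratio PWM scores against a strand-symmetrized 0-order background
estimated from the scanned sequence (symmetrization makes the null
distribution shared by both strands). Scores are discretized to a 1e-3 bit
grid; the null distribution is computed exactly by dynamic programming over
the motif columns on that grid, so the reported score, p-value pair is
internally consistent (scores are therefore grid-rounded, within 1.5e-2 bits
of exact for a 15-mer). Positions whose window contains N are skipped.
Benjamini–Hochberg runs jointly over all scanned positions of all sequences
and strands; hits with q ≤ 0.05 are kept. Overlapping hits (≥1 bp shared;
bookended hits stay separate) are united into strand-less motif-union sites
carrying the best member score. `N_mt` counts union sites whose integer
midpoint falls in the closed window [anchor−r, anchor+r] (r = 250 bp for the
positioning analyses, the full 500 bp half-window for the classifier
feature, whose radius the source analyses leave unstated). The shipped 15 bp
A-rich PWM is synthetic — strong-A columns interleaved with A/T columns —
built only so the machinery can be exercised on generated genomes; real
analyses should supply discovered motifs in minimal MEME format.

*Transcription.* `L_ntx` is the longest contiguous run of positions with
per-base RNA-seq depth ≤ 1 inside the window, truncated at the window edges
("read count" is interpreted as per-base depth; a total-qualifying-bases
variant is exposed as an option). RPKM is reads / (exon kb × millions of
mapped reads).

*Copy number.* Per-100 bp sample/reference depth ratios (zero-reference
bins missing) are smoothed by LOESS with span 0.005 — local quadratic
regression with tricube weights over the `ceil(span·n)` nearest bins, no
robustness iterations, implemented directly because the available lowess
routines are degree-1 only — then scaled so the 25th percentile
(linear-interpolation quantile) equals 1.

## Feature table and datasets

Windows are 1000 bp, `[anchor−500, anchor+500)` (left-biased for odd
widths). Positives anchor on the Orc summits of intergenic OM sites;
negatives on the midpoints of IGRs containing no OM summit, shifted
minimally inward at chromosome ends. O-site IGRs are held out for
probability scoring by default (`policy="holdout"`); including them as
negatives is the other policy. The 13 default features extend the core trio
with AT-richness (window AT mean, max 101 bp AT, minimum ΔG_melt, longest
A/T run), motif signal (union-score sum, distance from window center to the
nearest union midpoint, capped at 500 when none), and IGR-context variables
(IGR length, minimum flanking-gene RPKM, divergent/convergent indicators,
zero outside IGRs); only the trio and the orientation pair are fixed by the
source analyses, the rest are natural members of the three characteristic
groups, and any named subset can be selected. The intragenic evaluation set
pairs positives with 5× controls drawn uniformly from unmasked arm positions
more than 1 kb from every OM/O interval, scored on the trio only.

## Classifier and evaluation

The SVM uses the RBF kernel in the kernlab parameterization
`k(x,z) = exp(-σ‖x−z‖²)` with σ = 0.01 and C = 10 — note this σ multiplies
the squared distance directly (scikit-learn's `gamma`), not the common
`1/(2σ²)` convention. Features are standardized with training-fold
statistics by default (exposed as a flag). Probabilistic outputs are a Platt
sigmoid `P = 1/(1+exp(Af+B))` fitted by maximum likelihood with the
prior-corrected targets on decision values from an inner 3-fold CV (the
inner-fold count is not determinable from the source; direct fitting is the
fallback for tiny classes). Evaluation is stratified 4-fold CV — fold class
counts within one sample of proportionality — repeated over 10 seeded
partitions; the report carries fold AUCs, round means, and a 10,000-resample
percentile-bootstrap 95% CI over the 10 round means. ROC-AUC is the
tie-corrected Mann–Whitney statistic; PR-AUC uses the continuous
interpolation that accrues true/false positives linearly between adjacent
thresholds (closed-form per segment), with a trapezoid option. The F-score
of a feature is [(x̄⁺−x̄)² + (x̄⁻−x̄)²] / (s²⁺ + s²⁻) with n−1 variances;
zero-variance features return inf/0 rather than failing. Held-out windows
are scored by the mean Platt probability across all CV-trained models.

## Monte Carlo nulls and bootstrap

Random-site nulls draw positions uniformly from unmasked arm sequence
(positions whose ±radius window would leave the arm are excluded) and
summarize per-draw fractions by the 95% percentile bootstrap. The
length-controlled IGR null cuts the pooled IGR length distribution at unique
decile quantiles (right-closed bins, so heavily tied lengths collapse into
one stratum instead of absorbing the tail); each target length draws a
not-yet-used IGR from its stratum, falling back to the globally
nearest-length unused IGR. Stratification granularity is a parameter.
Mann–Whitney tests are two-sided with tie correction (exact for tiny
untied samples).

## The synthetic genome

The generator emits the study conditions the tests and acceptance run use:
two chromosomes, ~2.76 Mb total, i.i.d. background sequence at AT 0.64
(fission-yeast-like), genes with log-normal transcribed lengths (median
300 bp — compressed relative to real genes so ~3,340 IGRs fit in a desk-scale
genome) and log-normal expression (median 8 RPKM, log-sd 1). IGR classes:
280 OM-like (log-normal length, median 1466 bp), 60 O-like (median 800 bp),
3000 background (median 277 bp, log-sd 0.8 so a realistic tail of long
motif-free IGRs keeps single-feature classifiers imperfect). OM IGRs carry
1–3 consensus motif plants at the Orc anchor, an AT segment of 180–400 bp at
0.88 AT centered on the Mcm anchor (offset from Orc: half near zero, half
uniform 100–500 bp, clamped to fit short IGRs), and no transcription across
the IGR; O IGRs carry motifs only; 10% of background IGRs get a decoy AT
segment (100–300 bp), and background motif instances are planted genome-wide
at 0.44/kb — chosen so roughly a fifth to a third of random ±250 bp windows
contain a motif, the regime in which motif count is informative but not
trivial. FE tracks put Gaussian bumps (Orc: median height 12, sd 200 bp;
Mcm: median height 5, sd 230 bp — calling widths on the same few-hundred-bp
scale as the observed peaks, with Mcm wide enough that OM peak pairs overlap
across the full offset range) on multiplicative log-normal noise (sd 0.15)
around FE = 1; RNA-seq coverage is per-base Poisson at RPKM × 0.5 inside
transcribed spans. Everything derives from one seed via spawned generators.

What the generator does **not** emulate — and what passing tests therefore
do not establish about real data: mapping and GC biases, nucleosome
structure, replicate variability, ncRNA transcription, degenerate motif
variants (plants are consensus at fidelity 1 by default), and the coupling
between gene orientation and IGR length that produces the divergent-IGR
preference in the real genome (strands are independent here, so the
orientation Monte Carlo is exercised mechanically but shows no divergent
enrichment). Absolute AUCs on synthetic data are higher than on real data;
the meaningful checks are orderings, calibrations and exact oracle
agreement, not the absolute numbers.

## Problem sizes and determinism

Default analysis/acceptance sizes: ~2.76 Mb genome, 3,340 windows, 10×4-fold
CV per feature subset, 400-rep Monte Carlo draws, 300–500 bootstrap
calibration simulations at 600–800 resamples — sized so the full study runs
in about a minute on one CPU while keeping every planted-effect estimate
stable. Every stage takes an explicit seed; the pipeline runner derives
per-stage seeds from a master seed by hashing the stage name, and reruns are
byte-identical.

## Known limitations

* The threshold-run peak caller implements the documented post-processing
  semantics, not the upstream caller's statistical model; FE thresholds
  stand in for its enrichment parameters.
* PWM hits carry grid-rounded scores (1e-3 bit resolution).
* The LOESS neighbourhood uses contiguous windows on sorted positions,
  which is exact for (near-)uniform genomic bins but would differ from true
  k-nearest-neighbour selection on highly irregular grids.
* `build_intragenic_dataset` rejection-samples controls; pathologically
  tight exclusion constraints raise rather than loop forever.
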