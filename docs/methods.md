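# Methods notes

This note records the models, parameter choices, numerical details and
known limitations of `chromdyn`, in the order the pipeline runs.

## Coordinates and intervals

All coordinates are 0-based half-open; BED is the native dialect and any
1-based input would have to be converted at its reader. The overlap engine
reports pairs whose overlap is at least `max(1 bp, fraction × query
length)` — the fraction is always relative to the **query** (first) set,
which is how the "at least 10% overlap" control-overlap criterion is read
throughout. Promoter windows are strand-symmetric (TSS ± 2 kb) and clipped
at chromosome ends; symmetric clipping is a choice, as only the window
width is conventionally specified. Unknown chromosomes are errors, never
silent drops.

## Contact matrices

Matrices store the upper triangle of the symmetric whole-genome matrix
(diagonal once). `build_matrix` conserves the input pair count exactly.
Balancing masks bins whose coverage z-score falls outside
[−1.24, 4] (the filter-threshold convention of matrix-correction tools;
configurable) plus zero-coverage bins, then applies iterative correction
(alternating row/column scaling by √(rowsum/target)) until all unmasked
row sums agree to 1e−7 relative; non-convergence raises with the iteration
count and residual. Balancing is idempotent up to the tolerance.

Note on usage: the synthetic generator plants no per-bin visibility bias,
so on simulated data balancing is at best a near-identity and at worst
harmful — with nearly homogeneous coverage the z-filter clips ordinary
sampling fluctuations, and forcing equal row sums on chromosome-edge bins
(which genuinely see fewer partners) inflates their near-diagonal pixels.
The recovery analyses therefore run on raw merged matrices; balancing is
exercised by its own contract tests and is there for data with real
visibility bias.

Matrix correlation is Pearson on log1p counts over the union of non-zero
bin-pairs, excluding bins masked in either matrix; the estimator behind
published whole-matrix correlations is typically unstated, so this
definition is documented rather than assumed comparable.

`expected_by_distance` averages over *all* unmasked bin-pairs at each
distance (zeros included), pooled across chromosomes.

## Compartments

Per chromosome: observed/expected by diagonal (zero-mean diagonals become
the neutral value 1), Pearson correlation matrix, leading eigenvector by
dense symmetric eigendecomposition. Bins with degenerate O/E rows and
chromosomes with < 20 usable bins are masked with a warning. The sign is
fixed so bins overlapping the supplied activity track average positive —
an explicit orientation input instead of sequence-based heuristics, which
keeps the operation data-only. A constant matrix yields all-masked output
rather than an arbitrary eigenvector.

## TAD segmentation

The TAD-separation score per bin is the minimum over window sizes
{5, 10, 20} bins of log2(diamond mean / chromosome mean diamond), where
the diamond at bin i is the w×w block of contacts bridging i. Boundaries
are strict local minima that (i) drop ≥ δ = 0.1 below both flanking maxima
within the largest window and (ii) show significantly depleted
cross-boundary contacts versus the two flanking within-domain diamonds
(one-sided Mann–Whitney at 0.05, BH-corrected across candidates). This is
the insulation-family statistic; the published tool's internal multi-window
p-value machinery is not replicated, only its interface thresholds
(δ, comparison p, FDR correction). Domains are the intervals between
consecutive detected boundaries. Boundary colocalization uses a ± one-bin
(50 kb at compartment resolution, 10 kb at matrix resolution) default
tolerance, reported in both directions, because "proximal" is not
conventionally quantified.

## Loop calling and APA

Per-distance z-scores use the stratum mean and *population* sd over all
unmasked pixels of that distance, zeros included; strata with < 10 pixels
or beyond the maximum depth are undefined. Strata whose sd is zero up to
float tolerance (relative 1e−9) give z = 0 rather than noise-driven ±1.
Called pixels (z ≥ 6, span ≤ 1 Mb midpoint-to-midpoint) merge by
8-neighbourhood connectivity to the maximum-z pixel — the merge rule is a
design choice, as upstream tools leave it unspecified. APA sums 21×21
(±100 kb at 10-kb bins) submatrices centred on loop pixels, skipping loops
within 300 kb of the diagonal or too close to a matrix edge, and scales by
the mean of the aggregate's four corner pixels; a uniform matrix scores
exactly 1. The centre score on planted data runs slightly above the
planted enrichment (≈ 5.5 for 5×) because the near-diagonal corner sits on
a higher decay background than the far corner — a property of the
statistic, not an error.

## Capture interaction scoring

The score is −log10 of the NB upper-tail probability of the observed
count under a background mean `s_b · f(d)`: `f` is the pooled decay
profile (50 log-spaced distance bins, mean count per bin, linear
interpolation in log-distance) and `s_b` is the bait's observed/expected
total. The dispersion is pooled method-of-moments. Because genuinely
interacting pairs would contaminate all three estimates, the fit is
iterative: pairs significant at the working threshold (p < 0.01) are set
aside and the background refitted (first pass with a prior dispersion of
0.1 so enrichment cannot inflate it); a final pass relaxes the exclusion
to p < 1e−4 so that on null data essentially no tail mass is trimmed —
trimming at 1% leaves the mean and dispersion biased low and the scores
anti-conservative. The uncertainty of the per-bait scaling is propagated
as extra dispersion (Var(ŝ)/s² ≈ Σ(μ+αμ²)/(Σμ)² per bait). The full
capture-calling model of the field (Delaporte background, multi-window
p-value weighting) is deliberately not reimplemented; the score-≥ 5
convention is kept and the null calibration (P(score ≥ 5) ≤ 1.2e−5 per
pair) is enforced by simulation in the test suite. Cross-condition
interaction identity is exact fragment-pair identity.

## Differential testing

`nb_count_test` scales counts to a common library size (total-count; TMM
is out of scope), pools normalised counts per condition, and computes the
doubly conditional exact NB p-value of the observed split of the pooled
total, with a common method-of-moments dispersion floored at 0.01 — with
two replicates per condition a per-unit dispersion is not estimable.
Distributions are memoised per pooled total, making 10⁴ units fast.
Direction thresholds are per unit type: interactions p < 0.001; peaks
FDR < 0.05 and FC > 1.5; genes FDR < 0.05 and FC > 1.2. log2FC uses a 0.5
pseudo-count on normalised condition means. Total-count normalisation has
the usual composition bias: if a large, one-sided fraction of units truly
changes, the factors absorb part of the signal; the power contracts are
therefore stated for depth-matched libraries (`normalize=False`) or for
effects embedded among a majority of null units, and the FPR contract for
a pure null — both hold empirically (FPR ≈ 6e−4 at nominal 1e−3).

Classification: rewired takes precedence over preformed-activated when
both fire (the categories are exclusive by construction — "not
significantly different but ..."). When opposing differential peaks
overlap one distal end, the peak with the larger |log2FC| decides the
condition. Every interaction must carry a differential record; a missing
record is an error so that partial testing cannot silently bias class
counts.

## Association statistics

Mann–Whitney: midrank U; exact enumeration of all C(n, n₁) assignments
when n₁+n₂ ≤ 8 with two-sided p = 2·min(P(U ≤ u), P(U ≥ u)) capped at 1;
otherwise normal approximation with tie and continuity corrections. Tests
are two-sided throughout (the sidedness of published box-plot annotations
is typically unstated).

TPM bins read "0–1" as (0,1] and "1–10" as (1,10], with TPM = 0 its own
bin. Gene loop-count strata are {none; 1; 2–5; >5} crossed with
with/without ≥ 1 acetylated distal end.

The shuffle test places size-matched intervals uniformly within the
universe (per unique length, universe intervals weighted by the number of
feasible start positions), resolving self-overlaps by re-placing the
violators — a bounded-bias approximation to exact uniform non-overlapping
placement, acceptable at the occupancies used. Empirical p is the add-one
estimator (r+1)/(n+1), never zero. Null p-values are approximately uniform
provided the overlap count has reasonable resolution; with coarse counts
(few query intervals) the p distribution is atomic, which is a property of
any count-based permutation test.

Nearest-TSS assignment measures the gap between the site interval and the
TSS point (0 if inside), assigns within ± 50 kb, and breaks exact ties by
the lexicographically smaller gene id for determinism.

Energy expenditure is the fixed linear calorimetry formula; weight
normalisation of cage data is not modelled, as no formula for it is
conventionally stated.

## Synthetic data

Defaults are the desk-scale study conditions: 2 chromosomes × 20 Mb, 10-kb
matrix bins, HindIII-like fragments (exponential lengths, mean 4 kb, floor
200 bp), 2,500 genes on a ≥ 10-kb spaced grid, ~2,000 baits (fragments
containing TSSs), ~5,000 planted capture interactions over 45,000
background pairs, 2 Hi-C/capture replicates, 3 ChIP replicates, 5 RNA
replicates per condition (matching the per-assay design of such studies),
NB dispersion 0.05 for matrix/peak/expression counts, 5 × 10⁶ pairs per
Hi-C replicate.

Generator design decisions worth knowing:

- **Capture dispersion 0.02** (not 0.05): deep capture libraries are
  highly concordant between biological replicates, and the stated
  stability property of preformed interactions (|log2FC| < 0.5 in ≥ 90% of
  cases) is unattainable at dispersion 0.05 with two replicates — the
  sampling sd of log2FC alone is ≈ 0.37.
- **Loops are intra-compartment**: both anchors sit inside one compartment
  block, ≥ 8 bins from its edges, as regulatory promoter–enhancer loops
  are. Loops planted across compartment contexts are suppressed by the
  cross-compartment factor and cannot carry their nominal enrichment.
- **TAD suppression is short-range** (≤ 300 kb): insulation windows never
  look further than 200 kb, and restricting the cross-boundary factor to
  this range keeps the planted loop pixels (350–950 kb spans) on a
  homogeneous background so a 5× enrichment means what it says.
- **Compartment blocks are 2 Mb**, a multiple of the 400-kb domain size,
  so block edges coincide with planted boundaries and create no unplanted
  insulation minima.
- **Planted distal ends are unique** across planted interactions: shared
  distal fragments would let one interaction's acetylation peak bleed into
  another's classification ("clean planting").
- **Planted counts are large** (base 120 at the 50-kb reference distance,
  8× capture enrichment, 4× rewired fold change), keeping the weakest
  planted interaction near 50 counts per replicate — the clean-effect
  regime the classification accuracy contract assumes.
- **TPM is scaled against the simulated library depth** (3 × 10⁶ reads,
  the transcriptome-scale depth prorated to a 2,500-gene genome); a strict
  within-sample per-million renormalisation over so few genes would
  inflate values ~14× and detach them from the absolute TPM bin edges.
- **Expression follows the planted classes**: genes contacting an
  acetylated (preformed) enhancer are boosted 3× in both conditions, and
  the 2× DE fold change sits on top in the condition the gene's dominant
  loop class points to. Genes in the TPM = 0 tier stay at zero and can
  never be recovered as DEGs — DE power statements apply to expressed
  genes.
- Contact replicate noise is gamma-weighted multinomial (NB-like) so each
  replicate's matrix total equals its library size exactly; pair tables
  are only materialised on request, deep simulations return binned
  matrices directly.

What the generator does **not** emulate: trans contacts, per-bin
visibility bias (hence the raw-matrix analyses above), restriction-site
sequence realism, fragment-level digestion noise, mappability, replicate
batch effects, and the real genome's gene-density and compartment
irregularity. Passing recovery tests therefore demonstrate the
correctness and calibration of the statistics under the planted model,
not performance on real libraries.

## Problem sizes

The bundled analyses run on the desk-scale defaults above: whole test
suite ≈ 1 minute, acceptance script ≈ 30 s on one CPU. The calibration
checks use 10⁴ null units (count test) and ≈ 10⁶ null bait–fragment pairs
(capture score), the scales at which their bounds are stated.

## Known limitations

- The exact NB test rounds pooled normalised counts to integers; with
  strongly unequal library sizes this discards sub-integer information.
- Insulation significance uses the smallest window's diamond only.
- The shuffle placement's resample-on-collision scheme is biased at high
  universe occupancy (> ~50%); it errors out rather than degrade silently.
- `matched_control_annotation_overlap` recomputes overlap per control via
  the interval tree; for very large annotation collections a sweep-line
  batch implementation would be preferable.
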