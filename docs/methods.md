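# Methods

## The matrix sequence–activity model

Origin activity is modeled as additive over positions: a 4 × L matrix θ
assigns one real parameter per base per position, and a sequence's
activity is the sum of the parameters of its bases (L = 50 by default,
spanning the A and B1 elements of the assayed ARS; the offset of that
window within the 150-bp construct is configurable, default position 1).
Two transformations of θ leave all activity *rank orders* unchanged:
adding a constant to the four entries of any column, and multiplying θ
by a positive scalar. Rank-based inference (IM, below) additionally
cannot distinguish θ from −θ. This gauge freedom is removed before any
comparison by centering each column to zero sum, rescaling to unit
Frobenius norm (`normalize_motif`), and sign-aligning ensembles to a
deterministic reference. Degenerate motifs (all columns constant) are
rejected rather than mapped to zero, because a silent zero would
corrupt ensemble averages and PCA downstream.

Ambiguous bases (N etc.) are rejected at encoding with the offending
position named: the model assigns them no parameters, and the
generators never produce them.

## ER inference

The enrichment-ratio motif is θ_bl = log2(f_sel/f_lib) where f is the
read-count-weighted fraction of base b at position l in each sample,
computed with a pseudocount of 1 (per base; +4 in the denominator), so
every parameter is finite even when a base is absent from a sample. ER
is the field's standard estimator; its weakness is that any monotone
distortion of the selection scale — saturation, differing numbers of
growth cycles, amplification bias — changes the estimate. Under a
cubic sharpening of the selection weights the raw ER matrix steepens
roughly threefold; unit-norm gauge fixing hides a pure scale change,
but composition with sampling noise and saturation still biases the
direction, which is what the IM comparison quantifies.

## IM inference

IM seeks θ maximizing the mutual information I(θ) between predicted
activity and sample identity. The activity distributions are estimated
rank-based: the combined samples' activities are sorted (ties broken by
stable input order, for determinism; exact ties are rare at 15%
mutagenesis), replaced by ranks and assigned to B equipopulated bins
(bin = rank·B/n, populations differing by at most one). Equipopulation
weights *distinct variants*; a switch (`weight_by="reads"`) equalizes
combined read mass instead, since either reading of "equipopulated" is
defensible. Each sample's read counts are histogrammed over bins and
smoothed with a discrete Gaussian kernel (σ in bins; the kernel is
truncated at the histogram edges and column-renormalized, so mass is
conserved by construction and each p(a|sample) sums to 1). Sample
weights are read-count fractions, p(sample) = N_sample/N. With two
samples 0 ≤ I ≤ H(sample) ≤ 1 bit; zero-probability bins contribute
zero. Defaults B = 1000, σ = 20.

Because only ranks enter, I(θ) is *exactly* invariant under strictly
increasing transformations of the activity scale — the property that
removes systematic experiment-to-experiment variation ER is sensitive
to. I is also exactly invariant under the gauge group (per-column
shifts, positive scaling, negation), which is why endpoints must be
gauge-fixed and sign-aligned before averaging.

### Monte Carlo optimization

θ is sampled with stationary weight 2^(N·I(θ)) by Metropolis Monte
Carlo: chains start at i.i.d. standard-normal parameters, each step
perturbs one uniformly chosen entry by a centered Gaussian and accepts
with probability min(1, 2^(N·ΔI)) (evaluated in log space to avoid
overflow; N = 0 degenerates to a pure random walk with acceptance 1).
The reported motif is the entry-wise mean of the normalized,
sign-aligned endpoints of 5 independent 25,000-step chains (no burn-in:
endpoints only), re-normalized. Sign alignment uses the inner product
with the ER motif of the same table — a deterministic reference that is
always available; a zero inner product falls back to the first
endpoint. The entry-wise standard deviation across endpoints is
reported as a dispersion diagnostic.

The proposal scale default is 0.3: the initialization is unit-scale
standard normal, and single-coordinate steps must traverse roughly that
scale within the per-coordinate share of the step budget (25,000 steps
/ 200 coordinates ≈ 125 proposals each at L = 50). Measured at
desk scale (2,000 variants, 10^5 reads/sample, B = 200, 5,000 steps),
0.3 brings every chain's final I within 1% of I(θ_true), whereas
scales ≲ 0.1 leave chains visibly unconverged within the same budget.
With realistic N (~10^5–10^6) the acceptance rule is effectively
greedy — declines beyond ~1/N bits are essentially never accepted —
which is intended: the target distribution is extremely peaked, and
run-to-run endpoint spread plus the 5-run average stand in for
uncertainty.

## Motif comparison

Normalized motifs are unrolled base-major into 4L-vectors.
`motif_similarity` is the Pearson correlation after sign alignment
(vectors are column-centered, so this equals cosine similarity); an
independent random motif pair at L = 50 has |r| < 0.3 with probability
> 0.99. PCA (scikit-learn, on mean-centered vectors without further
scaling — the inputs are already unit-norm) reports per-motif component
coordinates and explained-variance fractions; component signs follow
the largest-|loading|-positive convention so results are reproducible
under reordering. A variance-free ensemble yields all-zero coordinates
and zero explained variance rather than an error.

## Genome tracks

Tracks are per-chromosome float arrays (0-based positions). Smoothing
is a centered moving average; even widths are incremented to the next
odd integer, and windows are truncated at chromosome ends (mean over
available positions) to avoid zero-padding artifacts — so constant
tracks are exact fixed points and interior totals are preserved only in
the per-position mean sense. Normalization divides the whole profile
(all chromosomes) by the nearest-rank 99.5th percentile of per-position
coverage — "the value bounding 99.5% of positions" — recorded in the
provenance chain; it is scale-equivariant by construction. Peak height
is the maximum normalized value within ±2,500 bp (configurable) of an
annotated origin; an apex rather than an area readout, chosen because
it is robust to peak-width differences between strains. bedGraph and
fixedStep wiggle are supported as text I/O.

## Dinucleotide ANOVA

Each annotated ACS contributes the dinucleotide at motif positions
29–30 of its strand-corrected aligned sequence (minus-strand
annotations are reverse-complemented first; pre-aligned sequences or an
explicit offset are the input contract). Dinucleotide groups with ≤ 3
members are removed (kept iff ≥ 4) and reported. The test is a one-way
fixed-effects ANOVA (scipy) on log10 peak heights — log applied exactly
once at entry; non-positive heights are excluded with a logged warning.
Stars follow *p* < 0.05 / 0.01 / 0.001. Outliers are retained (an
exclusion flag exists). All-constant groups with equal means give an
undefined F, reported as NaN rather than an exception. Box-plot
summaries (min, quartiles, median, max) accompany the test.

## Synthetic data

The generator mirrors the assay's design parameters. Libraries:
150-bp wild type, each position independently substituted with
probability 0.15, substitutions drawn uniformly from the three non-WT
bases ("15% substitution rate" = 15% observed mismatches; a flag
switches to the uniform-over-four convention, ≈ 11.25% observed).
Library counts are multinomial over the drawn pool at 10^5 reads;
selected counts are multinomial with weights g(exp(a_true)) × library
fraction, where exp(·) is a log-linear fitness link (the simplest
strictly increasing choice) and g an optional monotone distortion used
to probe IM's rank invariance (g(x) = x³ in the tests). Decreasing g
is rejected.

The wild type is a *synthetic* ARS-like sequence (fixed filler bases
with a planted TTTTATGTTTA A element at window positions 18–28, AG at
29–30, and a short B1-like block at 38–41), and the default ground
truth assigns weight 1.0 to the consensus base over the A element and
the dinucleotide and 0.5 over the B1 block — about 16 informative
positions with unit effects, a strong, element-structured specificity
of the kind plasmid-retention selection imposes. Desk-scale defaults
(2,000 distinct variants, 10^5 reads/sample, B = 200 and 5,000-step
chains in the tests) keep a full inference run under ~10 s on one CPU;
the full-size defaults (B = 1000, 25,000 steps) are what the CLI uses.

Genome fixtures plant Gaussian-shaped peaks (s.d. 2 kb) on a flat
baseline across 2 × 500-kb chromosomes, apex heights lognormal
(σ = 0.15 in log10) around dinucleotide-specific medians, with matched
strand-aware ACS annotations; overlapping placements are rejected. The
ANOVA power scenario suppresses the AG median 3-fold with n = 40 ACSs
per group.

What the generator does *not* emulate: sequencing error, PCR
amplification bias, paired-end structure, chromatin or replication-
timing context, and the genomic ACS catalog itself. Passing tests
therefore demonstrate correctness of the estimators and their stated
invariances under the assumed sampling model, not robustness to every
artifact of real libraries.

## Numerical choices and limitations

Normalization invariants are checked at 1e-9 (double-precision
accumulation over 4 × 50 entries); oracle agreements are asserted at
1e-12. MI is computed with explicit zero-term handling, never via
log of zero. The Metropolis ΔI acceptance is computed as
log2(u) < N·ΔI. Equipopulated binning with fewer distinct variants
than bins reduces B with a logged warning. The IM estimator's absolute
I value depends on B and σ (smoothing biases I downward; few variants
per bin bias it upward), so I values should only be compared at fixed
binning settings; the motif estimate itself is insensitive to moderate
changes. IM assumes a strictly monotone selection link — it cannot
detect non-monotone activity–fitness relations — and the additive model
ignores epistasis between positions by construction.
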