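# oriselect

Sequence determinants of DNA replication origin activity, from massively
parallel origin selection (MPOS) assays and genome-wide replication
profiles.

In *Saccharomyces cerevisiae*, replication origins are specified by DNA
sequence: an ARS (autonomously replicating sequence) containing the ACS
(ARS consensus sequence) read out by the origin recognition complex
(ORC). An MPOS assay mutagenizes a 150-bp ARS at a 15% per-nucleotide
substitution rate, propagates the plasmid library through selection in
yeast, and sequences the library and the selected pool. `oriselect`
turns those data into quantitative sequence–activity motifs, compares
motifs across strains, and tests whether genome-wide origin firing
strength depends on specific motif positions.

## The models

**Matrix (additive) sequence–activity model.** The activity of a
sequence *s* of length *L* is

    a(s) = Σ_b Σ_l θ_bl s_bl ,

with *s_bl* the one-hot indicator of base *b* at position *l* and θ a
4 × *L* parameter matrix. Motifs are gauge-fixed (columns centered to
zero sum, unit Frobenius norm) before comparison, logo rendering or PCA.

**ER inference** estimates θ as the log2 enrichment of base frequencies
in the selected vs the library sample (pseudocount 1). It is simple but
biased by any monotone distortion of the selection scale.

**IM inference** finds θ maximizing the mutual information between
predicted activity and sample identity,

    I(θ) = Σ_sample p(sample) Σ_a p(a|sample) log2 [ p(a|sample) / p(a) ] ,

where activity distributions are estimated by rank-transforming the
combined activities, binning into equipopulated bins (default 1000) and
Gaussian-smoothing the per-sample read histograms (default σ = 20 bins).
Because only ranks enter, the estimate is exactly invariant under any
strictly increasing distortion of the activity scale. The optimum is
found by Metropolis Monte Carlo with stationary weight 2^(N·I(θ)) (N =
total reads), averaging the normalized, sign-aligned endpoints of five
independent 25,000-step chains.

**Genome tracks and the dinucleotide ANOVA.** Coverage profiles are
smoothed with a uniform kernel (5,000 bp for replication profiles,
300 bp for ChIP), normalized by the coverage value bounding 99.5% of
positions, and read out as peak heights at annotated origins. Origins
are grouped by the dinucleotide at motif positions 29–30 of their
aligned ACS, rare dinucleotides (≤ 3 occurrences) removed, and a
one-way ANOVA run on log10 peak heights.

A synthetic-data module generates every input — mutagenized libraries,
selection with optional monotone distortion, toy genomes with planted
origin peaks — from a known ground truth, so the whole pipeline is
testable end to end.

## Worked example

```python
import oriselect as o

scenario = o.SelectionScenario()              # 2,000 variants, 10^5 reads/sample
table = o.simulate_mpos(scenario, seed=1)     # library + selected counts
model = o.OriginSelectionModel(table)         # windows to the 50-bp motif frame
cfg = o.MCConfig(steps=5000, runs=5, n_bins=200, sigma=20, seed=42)
result = model.fit(method="im", config=cfg)
print(result.summary())
print("similarity to planted truth:",
      round(o.motif_similarity(result.motif, scenario.truth_motif.normalize()), 3))
```

prints

```
Origin selection motif fit
============================================================
method:              IM
motif length L:      50
distinct variants:   2000
total reads N:       200000
mutual information:  0.1628 bits
MC runs x steps:     5 x 5000
bins / sigma:        200 / 20

strongest positions (|theta| of top base):
  position  20: T +0.243
  position  19: T +0.238
  position  25: T +0.238
  position  22: A +0.238
  position  27: T +0.236
  position  30: G +0.234
  position  21: T +0.233
  position  18: T +0.232
  position  26: T +0.228
  position  28: A +0.226

similarity to planted truth: 0.989
```

The mutual information (0.16 bits) measures how well predicted activity
separates library from selected reads; the strongest parameters sit on
the planted T-rich A element and the position 29–30 dinucleotide, and
the fitted motif correlates 0.989 with the ground truth after gauge
fixing. `result.plot_logo()` renders the parameter logo;
`o.pca_motifs([...])` compares motifs across strains/replicates.

A `oriselect` command-line tool exposes the same stages (`demux`,
`collapse`, `window`, `infer`, `smooth`, `normalize`, `peaks`, `anova`,
`simulate-mpos`, `simulate-genome`).

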