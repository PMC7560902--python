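"""Synthetic MPOS libraries and genome fixtures with known ground truth.

Everything the pipeline consumes can be generated here with the
statistical structure the analysis assumes, so every stage is testable
end-to-end without external data:

* variant libraries — 150-bp ARS-like sequences mutagenized at a 15%
  per-nucleotide substitution rate (each position independently replaced
  by one of the three non-wild-type bases), with library read counts
  drawn multinomially at a chosen depth;
* selection — selected-sample read counts drawn multinomially with
  per-variant weights ``g(exp(a_true))`` where ``a_true`` is the
  ground-truth matrix-model activity and ``g`` an optional strictly
  increasing distortion (identity by default; nonlinear choices emulate
  the systematic scale distortions that bias ER but not IM inference);
* genome fixtures — toy chromosomes with planted Gaussian-shaped origin
  peaks whose apex heights are lognormal with dinucleotide-specific
  medians, plus matched ACS annotations, for the track-processing and
  ANOVA stages.

All generators are pure functions of (scenario, seed).

The wild-type reference is a *synthetic* ARS-like sequence (built in
:func:`_build_synthetic_wt`), not a genomic ARS: it carries a T-rich
11-nt A-element block, the A/G dinucleotide at motif positions 29-30 and
a short B1-like block inside the default 50-bp analysis window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .motif import (
    BASES,
    Motif,
    reverse_complement,
    sequence_to_indices,
    sequences_to_indices,
)
from .mpos_io import VariantCountTable
from .tracks import GenomeTrack

#: 1-based coordinates of the planted motif elements inside the 50-bp window
A_ELEMENT = (18, 28)   # 11-nt T-rich A element, weight 1.0
DINUCLEOTIDE = (29, 30)  # the Orc4-read dinucleotide, weight 1.0
B1_ELEMENT = (38, 41)  # short B1-like block, weight 0.5


def _build_synthetic_wt(length: int = 150, seed: int = 20201014) -> str:
    """Deterministically build the synthetic ARS-like wild-type sequence.

    Filler bases come from a fixed internal RNG; the A element
    (TTTTATGTTTA), the AG dinucleotide at 29-30 and a B1-like AACA block
    are overwritten at their window coordinates.  Synthetic stand-in:
    this is not a genomic ARS sequence.
    """
    rng = np.random.default_rng(seed)
    seq = list("".join(BASES[i] for i in rng.integers(0, 4, size=length)))
    seq[A_ELEMENT[0] - 1 : A_ELEMENT[1]] = "TTTTATGTTTA"
    seq[DINUCLEOTIDE[0] - 1 : DINUCLEOTIDE[1]] = "AG"
    seq[B1_ELEMENT[0] - 1 : B1_ELEMENT[1]] = "AACA"
    return "".join(seq)


SYNTHETIC_ARS_WT = _build_synthetic_wt()


def default_truth_motif(wt: str = SYNTHETIC_ARS_WT, window_start: int = 1,
                        window_length: int = 50) -> Motif:
    """Ground-truth matrix model used by the default selection scenario.

    Consensus-matching parameters: weight 1.0 over the A element and the
    29-30 dinucleotide, 0.5 over the B1 block, 0 elsewhere — a strong,
    element-structured specificity of the kind plasmid-retention
    selection imposes on an origin.
    """
    window = wt[window_start - 1 : window_start - 1 + window_length]
    idx = sequence_to_indices(window)
    theta = np.zeros((4, window_length))
    for (lo, hi), w in ((A_ELEMENT, 1.0), (DINUCLEOTIDE, 1.0), (B1_ELEMENT, 0.5)):
        for pos in range(lo, hi + 1):
            theta[idx[pos - 1], pos - 1] = w
    return Motif(theta=theta, label="ground truth")


@dataclass(frozen=True)
class SelectionScenario:
    """Generative model of one MPOS experiment.

    Defaults are the desk-scale study conditions: 150-bp wild type,
    15% per-nucleotide substitution rate, 2,000 distinct variants,
    10^5 reads per sample, log-linear (exponential) selection link.
    ``distortion`` is an optional strictly increasing function applied
    to the exponential selection weight; ``include_silent`` switches the
    mutagenesis convention from "15% chance of a non-WT base" to
    "15% chance of a uniform draw over all four bases".
    """

    wt: str = SYNTHETIC_ARS_WT
    rate: float = 0.15
    n_variants: int = 2000
    depth: int = 100_000
    window_start: int = 1
    window_length: int = 50
    truth: Motif | None = None
    distortion: object = None  # callable or None (identity)
    include_silent: bool = False

    def __post_init__(self):
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError("substitution rate must be in [0, 1]")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.n_variants < 1:
            raise ValueError("need at least one variant")

    @property
    def truth_motif(self) -> Motif:
        if self.truth is not None:
            return self.truth
        return default_truth_motif(self.wt, self.window_start, self.window_length)

    def window_of(self, sequence: str) -> str:
        lo = self.window_start - 1
        return sequence[lo : lo + self.window_length]


def make_variant_library(scenario: SelectionScenario, seed: int | None = None):
    """Draw the mutagenized variant pool and multinomial library counts.

    Each position of each variant is independently substituted with
    probability ``scenario.rate``; a substitution draws uniformly from
    the three non-wild-type bases (or all four when ``include_silent``).
    Duplicate draws are collapsed, so the returned variants are distinct.

    Returns (variants, library_counts) as a list of strings and an
    aligned integer array.
    """
    rng = np.random.default_rng(seed)
    wt_idx = sequence_to_indices(scenario.wt)
    n, L = scenario.n_variants, len(scenario.wt)
    mutate = rng.random((n, L)) < scenario.rate
    if scenario.include_silent:
        drawn = rng.integers(0, 4, size=(n, L), dtype=np.uint8)
    else:
        offset = rng.integers(1, 4, size=(n, L), dtype=np.uint8)
        drawn = (wt_idx[None, :] + offset) % 4
    idx = np.where(mutate, drawn, wt_idx[None, :])
    lut = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    seqs = [bytes(lut[row]).decode() for row in idx]

    # multinomial depth over the drawn pool, then aggregate duplicates
    pool_counts = rng.multinomial(scenario.depth, np.full(n, 1.0 / n))
    agg: dict[str, int] = {}
    for s, c in zip(seqs, pool_counts):
        agg[s] = agg.get(s, 0) + int(c)
    variants = sorted(agg)
    counts = np.array([agg[v] for v in variants], dtype=np.int64)
    keep = counts > 0
    return [v for v, k in zip(variants, keep) if k], counts[keep]


def simulate_selection(
    scenario: SelectionScenario,
    variants: list[str],
    library_counts: np.ndarray,
    seed: int | None = None,
) -> np.ndarray:
    """Multinomial selected-sample counts under the ground-truth model.

    Variant i is selected with weight g(exp(a_true_i)) times its library
    fraction, where g is the scenario's monotone distortion (identity if
    None); counts are multinomial at the scenario depth.
    """
    rng = np.random.default_rng(seed)
    truth = scenario.truth_motif
    windows = [scenario.window_of(v) for v in variants]
    a = truth.activities(windows)
    w0 = np.exp(a - a.max())  # stable; overall scale is irrelevant
    if scenario.distortion is not None:
        w = np.asarray(scenario.distortion(w0), dtype=float)
        order = np.argsort(w0, kind="stable")
        if (np.diff(w[order]) < -1e-12).any():
            raise ValueError("distortion must be increasing in activity")
    else:
        w = w0
    probs = w * (library_counts / library_counts.sum())
    total = probs.sum()
    if total == 0:
        raise ValueError("all selection weights are zero")
    return rng.multinomial(scenario.depth, probs / total)


def simulate_mpos(scenario: SelectionScenario, seed: int | None = None) -> VariantCountTable:
    """Full experiment: library draw + selection, as a count table.

    The table holds full-length sequences; apply ``.window()`` with the
    scenario's window to reach the motif-inference coordinate frame.
    """
    ss = np.random.SeedSequence(seed)
    lib_seed, sel_seed = ss.generate_state(2)
    variants, lib = make_variant_library(scenario, seed=int(lib_seed))
    sel = simulate_selection(scenario, variants, lib, seed=int(sel_seed))
    frame = pd.DataFrame(
        {"sequence": variants, "library_count": lib, "selected_count": sel}
    )
    return VariantCountTable(frame=frame, wt=scenario.wt)


def mpos_reads(table: VariantCountTable, barcode_map: dict[str, str],
               seed: int | None = None) -> list[str]:
    """Expand a count table back into barcoded reads (shuffled).

    Inverse of demultiplex + collapse, for round-trip testing:
    ``barcode_map`` must contain 'library' and 'selected' entries.
    """
    rng = np.random.default_rng(seed)
    reads = []
    for sample, col in (("library", "library_count"), ("selected", "selected_count")):
        bc = barcode_map[sample]
        for seq, c in zip(table.frame["sequence"], table.frame[col]):
            reads.extend([bc + seq] * int(c))
    rng.shuffle(reads)
    return reads


# ---------------------------------------------------------------------
# genome fixtures
# ---------------------------------------------------------------------


def simulate_acs_heights(
    effect_map: dict[str, float],
    n_per_group: int = 40,
    sigma: float = 0.15,
    seed: int | None = None,
) -> dict[str, np.ndarray]:
    """Lognormal peak heights per dinucleotide group.

    log10(height) ~ Normal(log10(median), sigma) with the group median
    taken from ``effect_map``.
    """
    rng = np.random.default_rng(seed)
    return {
        dinuc: median * 10 ** (sigma * rng.standard_normal(n_per_group))
        for dinuc, median in effect_map.items()
    }


def _random_acs_sequence(rng, dinuc: str, length: int = 50) -> str:
    seq = list("".join(BASES[i] for i in rng.integers(0, 4, size=length)))
    seq[DINUCLEOTIDE[0] - 1 : DINUCLEOTIDE[1]] = dinuc
    return "".join(seq)


def make_genome_fixture(
    n_chrom: int = 2,
    chrom_length: int = 500_000,
    origins_per_chrom: int = 20,
    effect_map: dict[str, float] | None = None,
    noise_sigma: float = 0.15,
    peak_sd: float = 2000.0,
    baseline: float = 1.0,
    apex_scale: float = 100.0,
    seed: int | None = None,
):
    """Toy genome with planted origin peaks and matched ACS annotations.

    Peaks are Gaussian-shaped (s.d. ``peak_sd`` bp) on a flat baseline;
    apex heights are lognormal around ``apex_scale`` times the
    dinucleotide-specific median from ``effect_map`` (noise
    ``noise_sigma`` in log10 units; 0 disables noise).  Dinucleotides
    cycle through the effect map across origins.  Raises if planted
    origins would overlap (closer than 6 peak s.d.).

    Returns (track, acs_table) — the raw :class:`GenomeTrack` and a
    DataFrame with chrom/start/end/strand/sequence/apex/dinucleotide.
    """
    if effect_map is None:
        effect_map = {"AG": 1.0, "TG": 1.0, "AT": 1.0, "TT": 1.0, "GG": 1.0}
    rng = np.random.default_rng(seed)
    spacing = chrom_length / (origins_per_chrom + 1)
    if spacing < 6 * peak_sd:
        raise ValueError("planted origins would overlap: reduce origins or peak width")
    dinucs = list(effect_map)
    data = {}
    records = []
    k = 0
    for c in range(n_chrom):
        chrom = f"chr{'I' * (c + 1)}" if c < 3 else f"chr{c + 1}"
        values = np.full(chrom_length, float(baseline))
        x = np.arange(chrom_length, dtype=float)
        for j in range(origins_per_chrom):
            center = int((j + 1) * spacing + rng.integers(-int(peak_sd), int(peak_sd) + 1))
            dinuc = dinucs[k % len(dinucs)]
            k += 1
            median = effect_map[dinuc] * apex_scale
            apex = (
                median * 10 ** (noise_sigma * rng.standard_normal())
                if noise_sigma > 0 else median
            )
            lo = max(center - int(6 * peak_sd), 0)
            hi = min(center + int(6 * peak_sd), chrom_length)
            values[lo:hi] += apex * np.exp(
                -0.5 * ((x[lo:hi] - center) / peak_sd) ** 2
            )
            strand = "+" if rng.random() < 0.5 else "-"
            aligned = _random_acs_sequence(rng, dinuc)
            sequence = aligned if strand == "+" else reverse_complement(aligned)
            records.append(
                {
                    "chrom": chrom,
                    "start": center - 25,
                    "end": center + 25,
                    "strand": strand,
                    "sequence": sequence,
                    "dinucleotide": dinuc,
                    "apex": apex,
                }
            )
        data[chrom] = values
    track = GenomeTrack(data=data)
    return track, pd.DataFrame(records)


def write_genome_fixture(outdir, track: GenomeTrack, acs_table: pd.DataFrame) -> None:
    """Emit the fixture as bedGraph + TSV + BED + FASTA of ACS sequences."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    track.to_bedgraph(outdir / "coverage.bedgraph")
    acs_table.to_csv(outdir / "acs.tsv", sep="\t", index=False)
    with open(outdir / "acs.bed", "w") as fh:
        for i, row in acs_table.iterrows():
            fh.write(
                f"{row['chrom']}\t{row['start']}\t{row['end']}\tACS_{i}\t0\t{row['strand']}\n"
            )
    with open(outdir / "acs.fasta", "w") as fh:
        for i, row in acs_table.iterrows():
            fh.write(f">ACS_{i} {row['chrom']}:{row['start']}-{row['end']}\n")
            fh.write(row["sequence"] + "\n")
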