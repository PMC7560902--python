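"""Read handling and variant count tables for MPOS libraries.

The selection assay yields two sequenced samples per experiment: the
plasmid *library* before transformation and the *selected* pool after
propagation.  Reads carry inline sample barcodes at their 5' end.  This
module demultiplexes reads by exact barcode prefix, collapses identical
variant sequences into counts, and round-trips the resulting
:class:`VariantCountTable` through a 3-column TSV
(sequence, library_count, selected_count).

Reads are used single-end and as-is: no quality filtering or trimming
beyond the barcode, no alignment (variants are fixed-length synthesized
sequences under a substitution-only model).  Anything anomalous — wrong
length, non-ACGT characters, unmatched barcode — is discarded and
tallied, never silently dropped.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .motif import sequences_to_indices

logger = logging.getLogger(__name__)

SAMPLES = ("library", "selected")


@dataclass
class VariantCountTable:
    """Unique variant sequences with per-sample read counts.

    ``frame`` has columns ``sequence`` (fixed-length DNA strings, unique),
    ``library_count`` and ``selected_count`` (non-negative integers; a
    variant absent from one sample is recorded as 0).  ``wt`` is the
    reference wild-type sequence, if known.
    """

    frame: pd.DataFrame
    wt: str | None = None

    def __post_init__(self):
        f = self.frame
        for col in ("sequence", "library_count", "selected_count"):
            if col not in f.columns:
                raise ValueError(f"missing column {col!r}")
        if f["sequence"].duplicated().any():
            raise ValueError("duplicate sequences in count table")
        lengths = f["sequence"].str.len().unique()
        if len(lengths) > 1:
            raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
        if (f[["library_count", "selected_count"]].to_numpy() < 0).any():
            raise ValueError("negative counts")
        self.frame = f.reset_index(drop=True)

    # -- basic accessors ---------------------------------------------

    @property
    def sequence_length(self) -> int:
        return len(self.frame["sequence"].iloc[0])

    @property
    def n_variants(self) -> int:
        return len(self.frame)

    @property
    def counts(self) -> np.ndarray:
        """(2, n) float array of counts, rows ordered (library, selected)."""
        return self.frame[["library_count", "selected_count"]].to_numpy(float).T

    @property
    def total_reads(self) -> int:
        """N: read counts in library and selected samples combined."""
        return int(self.counts.sum())

    def indices(self) -> np.ndarray:
        """(n, L) base-index encoding of all variant sequences."""
        return sequences_to_indices(self.frame["sequence"].tolist())

    # -- construction -------------------------------------------------

    @classmethod
    def from_samples(cls, library: dict, selected: dict, wt: str | None = None):
        """Build from two {sequence: count} mappings."""
        seqs = sorted(set(library) | set(selected))
        frame = pd.DataFrame(
            {
                "sequence": seqs,
                "library_count": [int(library.get(s, 0)) for s in seqs],
                "selected_count": [int(selected.get(s, 0)) for s in seqs],
            }
        )
        return cls(frame=frame, wt=wt)

    # -- windowing -----------------------------------------------------

    def window(self, start: int, length: int = 50) -> "VariantCountTable":
        """Restrict sequences to the [start, start+length-1] window (1-based).

        Variants identical within the window are re-collapsed with summed
        counts; total counts are conserved exactly.
        """
        if start < 1 or start + length - 1 > self.sequence_length:
            raise ValueError(
                f"window [{start}, {start + length - 1}] outside sequence "
                f"bounds [1, {self.sequence_length}]"
            )
        sub = self.frame.copy()
        sub["sequence"] = sub["sequence"].str.slice(start - 1, start - 1 + length)
        collapsed = (
            sub.groupby("sequence", as_index=False, sort=True)[
                ["library_count", "selected_count"]
            ].sum()
        )
        wt = self.wt[start - 1 : start - 1 + length] if self.wt else None
        return VariantCountTable(frame=collapsed, wt=wt)

    # -- I/O ------------------------------------------------------------

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, wt: str | None = None) -> "VariantCountTable":
        frame = pd.read_csv(path, sep="\t", dtype={"sequence": str})
        return cls(frame=frame, wt=wt)


# ---------------------------------------------------------------------
# read processing
# ---------------------------------------------------------------------


def read_sequences(path, fmt: str | None = None) -> list[str]:
    """Load read sequences (uppercased strings) from FASTA or FASTQ."""
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = "fastq" if suffix in (".fastq", ".fq") else "fasta"
    return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), fmt)]


def demultiplex(reads, barcode_map: dict[str, str]):
    """Assign reads to samples by exact barcode prefix match.

    Parameters
    ----------
    reads : iterable of str
        Read sequences (barcode still attached at the 5' end).
    barcode_map : dict
        sample label -> barcode string; barcodes must be same-length and
        mutually distinct.

    Returns
    -------
    (assigned, tallies)
        ``assigned`` maps each sample label to the list of barcode-trimmed
        reads; ``tallies`` counts assigned reads per sample plus an
        ``"unassigned"`` entry.
    """
    if not barcode_map:
        raise ValueError("empty barcode map")
    lengths = {len(b) for b in barcode_map.values()}
    if len(lengths) != 1:
        raise ValueError("barcodes must all have the same length")
    if len(set(barcode_map.values())) != len(barcode_map):
        raise ValueError("duplicate barcodes in barcode map")
    blen = lengths.pop()
    lookup = {b: label for label, b in barcode_map.items()}
    assigned = {label: [] for label in barcode_map}
    tallies = Counter({label: 0 for label in barcode_map})
    tallies["unassigned"] = 0
    for read in reads:
        label = lookup.get(read[:blen])
        if label is None:
            tallies["unassigned"] += 1
        else:
            assigned[label].append(read[blen:])
            tallies[label] += 1
    return assigned, dict(tallies)


def collapse_counts(reads, expected_length: int):
    """Collapse identical reads into {sequence: count}.

    Reads of the wrong length or containing characters outside A/C/G/T
    are discarded and tallied; kept + discarded always equals the input
    size.

    Returns
    -------
    (counts, tallies)
        ``counts`` maps sequence -> summed count; ``tallies`` has keys
        ``kept``, ``discarded_length``, ``discarded_invalid``.
    """
    if expected_length <= 0:
        raise ValueError("expected_length must be positive")
    counts: Counter = Counter()
    tallies = {"kept": 0, "discarded_length": 0, "discarded_invalid": 0}
    valid = set("ACGT")
    for read in reads:
        if len(read) != expected_length:
            tallies["discarded_length"] += 1
            continue
        if not valid.issuperset(read):
            tallies["discarded_invalid"] += 1
            continue
        counts[read] += 1
        tallies["kept"] += 1
    if tallies["discarded_length"] or tallies["discarded_invalid"]:
        logger.info("collapse_counts tallies: %s", tallies)
    return dict(counts), tallies
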