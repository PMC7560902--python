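"""Additive sequence-activity (matrix) models of replication-origin activity.

A motif is a 4 x L matrix of real parameters theta.  The activity a
matrix model assigns to a DNA sequence ``s`` of length L is

    a(s) = sum_b sum_l theta[b, l] * s[b, l]

where ``s[b, l]`` is the one-hot indicator that base ``b`` (A, C, G or T)
occupies position ``l``.  The model is linear in theta and carries a gauge
freedom: adding a constant to all four parameters of one position shifts
every sequence's activity by that constant, and multiplying theta by a
positive scalar rescales all activities, so neither transformation changes
activity *rank order*.  :func:`normalize_motif` removes both degrees of
freedom by centering each column to zero sum and rescaling to unit
Frobenius norm, which makes motifs from different experiments directly
comparable (visually, via similarity scores, or by PCA).

Positions are 1-based (1..L) in every report and file this package emits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: tolerance for the normalized-motif invariant checks (double-precision
#: accumulation over a 4 x 50 matrix stays far below this)
NORM_TOL = 1e-9


class DegenerateMotifError(ValueError):
    """Raised when a motif has no non-gauge content (all columns constant)."""


def sequence_to_indices(sequence: str) -> np.ndarray:
    """Map an A/C/G/T string to an array of base indices (0..3).

    Raises ``ValueError`` naming the first offending 1-based position for
    any character outside the four canonical bases (ambiguity codes such
    as N included: the matrix model assigns them no parameters).
    """
    if not sequence:
        raise ValueError("empty sequence")
    idx = np.empty(len(sequence), dtype=np.uint8)
    for i, ch in enumerate(sequence):
        code = BASE_INDEX.get(ch)
        if code is None:
            raise ValueError(
                f"invalid base {ch!r} at position {i + 1}: only A/C/G/T allowed"
            )
        idx[i] = code
    return idx


def sequences_to_indices(sequences) -> np.ndarray:
    """Vectorized :func:`sequence_to_indices` for equal-length sequences."""
    if isinstance(sequences, str):
        raise TypeError(
            "pass a list of sequences; use sequence_to_indices for one string"
        )
    seqs = list(sequences)
    if not seqs:
        raise ValueError("no sequences")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
    joined = "".join(seqs)
    raw = np.frombuffer(joined.encode("ascii"), dtype=np.uint8)
    lut = np.full(256, 255, dtype=np.uint8)
    for b, i in BASE_INDEX.items():
        lut[ord(b)] = i
    idx = lut[raw]
    if (idx == 255).any():
        flat = int(np.argmax(idx == 255))
        n = lengths.pop()
        raise ValueError(
            f"invalid base {joined[flat]!r} at position {flat % n + 1} "
            f"of sequence {flat // n}"
        )
    return idx.reshape(len(seqs), -1)


@dataclass(frozen=True)
class OneHotSequence:
    """One-hot (indicator) encoding of a DNA sequence.

    ``matrix`` is 4 x L with rows ordered A, C, G, T; exactly one 1 per
    column.  ``sequence`` is the source string, recoverable from the
    matrix (the encoding is a bijection).
    """

    matrix: np.ndarray
    sequence: str

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def decode(self) -> str:
        """Recover the source string from the indicator matrix."""
        return "".join(BASES[i] for i in self.matrix.argmax(axis=0))


def encode(sequence: str) -> OneHotSequence:
    """Encode an A/C/G/T string as a 4 x L indicator matrix."""
    idx = sequence_to_indices(sequence)
    mat = np.zeros((4, len(sequence)), dtype=np.int8)
    mat[idx, np.arange(len(sequence))] = 1
    return OneHotSequence(matrix=mat, sequence=sequence)


@dataclass(frozen=True)
class Motif:
    """A 4 x L matrix sequence-activity model.

    Parameters
    ----------
    theta : ndarray, shape (4, L)
        Model parameters; rows ordered A, C, G, T.
    normalized : bool
        True when every column of theta sums to zero and the Frobenius
        norm is one (the canonical gauge produced by :meth:`normalize`).
    label : str, optional
        Free-text tag (e.g. strain / replicate / inference method).
    """

    theta: np.ndarray
    normalized: bool = False
    label: str | None = None

    def __post_init__(self):
        theta = np.asarray(self.theta, dtype=float)
        if theta.ndim != 2 or theta.shape[0] != 4:
            raise ValueError(f"theta must be 4 x L, got shape {theta.shape}")
        object.__setattr__(self, "theta", theta)
        if self.normalized:
            col = np.abs(theta.sum(axis=0)).max()
            norm = float((theta**2).sum())
            if col > NORM_TOL or abs(norm - 1.0) > NORM_TOL:
                raise ValueError(
                    "normalized flag set but columns do not sum to 0 / "
                    "Frobenius norm is not 1"
                )

    @property
    def length(self) -> int:
        return self.theta.shape[1]

    # -- activity -----------------------------------------------------

    def activity(self, seq) -> float:
        """Activity a(s) of one sequence (string or :class:`OneHotSequence`)."""
        if isinstance(seq, OneHotSequence):
            idx = seq.matrix.argmax(axis=0)
            n = seq.length
        else:
            idx = sequence_to_indices(seq)
            n = len(seq)
        if n != self.length:
            raise ValueError(f"sequence length {n} != motif length {self.length}")
        return float(self.theta[idx, np.arange(self.length)].sum())

    def activities(self, sequences) -> np.ndarray:
        """Vectorized activity for many equal-length sequences."""
        idx = sequences if isinstance(sequences, np.ndarray) else sequences_to_indices(sequences)
        if idx.shape[1] != self.length:
            raise ValueError(
                f"sequence length {idx.shape[1]} != motif length {self.length}"
            )
        return self.theta[idx, np.arange(self.length)].sum(axis=1)

    # -- gauge fixing -------------------------------------------------

    def normalize(self) -> "Motif":
        """Center each column to zero sum and rescale to unit Frobenius norm.

        Idempotent; raises :class:`DegenerateMotifError` when the motif
        has only gauge content (every column constant), because a silent
        zero return would poison downstream averaging and PCA.
        """
        centered = self.theta - self.theta.mean(axis=0, keepdims=True)
        c = float(np.sqrt((centered**2).sum()))
        if c == 0.0:
            raise DegenerateMotifError(
                "degenerate motif: all columns constant (C = 0)"
            )
        return Motif(theta=centered / c, normalized=True, label=self.label)

    # -- logo ---------------------------------------------------------

    def logo_matrix(self) -> pd.DataFrame:
        """Plotting-ready character-height table.

        One row per 1-based position, one column per base; the height of
        character b at position l is theta[b, l] exactly (negative values
        are drawn below the axis).
        """
        return pd.DataFrame(
            self.theta.T,
            index=pd.RangeIndex(1, self.length + 1, name="position"),
            columns=list(BASES),
        )

    def plot_logo(self, ax=None):
        """Render the parameter logo as stacked per-base bars.

        Positive parameters stack upward from zero, negative ones
        downward, so bar extent equals theta exactly.
        """
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(max(6, self.length / 5), 2.5))
        colors = {"A": "#109648", "C": "#255C99", "G": "#F7B32B", "T": "#D62839"}
        pos = np.arange(1, self.length + 1)
        up = np.zeros(self.length)
        down = np.zeros(self.length)
        for b in BASES:
            vals = self.theta[BASE_INDEX[b]]
            top = np.where(vals > 0, vals, 0.0)
            bot = np.where(vals < 0, vals, 0.0)
            ax.bar(pos, top, bottom=up, color=colors[b], width=0.85, label=b)
            ax.bar(pos, bot, bottom=down, color=colors[b], width=0.85)
            up += top
            down += bot
        ax.axhline(0.0, color="black", lw=0.8)
        ax.set_xlabel("position")
        ax.set_ylabel(r"$\theta$")
        ax.legend(ncol=4, fontsize=8, frameon=False)
        return ax

    # -- serialization ------------------------------------------------

    def to_tsv(self, path) -> None:
        """Write theta as TSV (4 rows A,C,G,T x L columns) + JSON sidecar."""
        path = Path(path)
        df = pd.DataFrame(
            self.theta,
            index=list(BASES),
            columns=[str(i) for i in range(1, self.length + 1)],
        )
        df.to_csv(path, sep="\t", index_label="base")
        meta = {"label": self.label, "L": self.length, "normalized": self.normalized}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_tsv(cls, path) -> "Motif":
        path = Path(path)
        df = pd.read_csv(path, sep="\t", index_col="base")
        theta = df.loc[list(BASES)].to_numpy(dtype=float)
        sidecar = path.with_suffix(path.suffix + ".json")
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls(
            theta=theta,
            normalized=bool(meta.get("normalized", False)),
            label=meta.get("label"),
        )

    def with_label(self, label: str) -> "Motif":
        return replace(self, label=label)


def normalize_motif(motif: Motif) -> Motif:
    """Module-level alias for :meth:`Motif.normalize`."""
    return motif.normalize()


def logo_matrix(motif: Motif) -> pd.DataFrame:
    """Module-level alias for :meth:`Motif.logo_matrix`."""
    return motif.logo_matrix()


def reverse_complement(sequence: str) -> str:
    """Reverse complement of an A/C/G/T string."""
    comp = str.maketrans("ACGT", "TGCA")
    return sequence.translate(comp)[::-1]
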