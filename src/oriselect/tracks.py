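"""Genome coverage track processing for replication-origin profiles.

Tracks are per-chromosome arrays of per-position, non-negative coverage
(read pileup) values.  The processing chain applied to replication
profiles and ChIP tracks is: (1) smoothing by convolution with a
uniform (boxcar) kernel — width 5000 bp for replication-origin profiles,
300 bp for ChIP — with the window truncated to the available positions
at chromosome ends; (2) cross-profile normalization by dividing the
whole profile by the coverage value bounding 99.5% of positions
(nearest-rank percentile); (3) peak-height readout as the maximum
normalized value within a flank of an annotated origin locus.

Coordinates are 0-based half-open internally; bedGraph and BED files are
read and written in their native conventions, fixedStep wiggle start
positions are 1-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class GenomeTrack:
    """Per-chromosome, per-position coverage with processing provenance."""

    data: dict[str, np.ndarray]
    provenance: tuple[str, ...] = ("raw",)

    def __post_init__(self):
        clean = {}
        for chrom, values in self.data.items():
            arr = np.asarray(values, dtype=float)
            if arr.ndim != 1:
                raise ValueError(f"{chrom}: track values must be 1-D")
            if (arr < 0).any():
                raise ValueError(f"{chrom}: negative coverage values")
            clean[chrom] = arr
        self.data = clean
        self.provenance = tuple(self.provenance)

    @property
    def chromosomes(self) -> list[str]:
        return list(self.data)

    def total_positions(self) -> int:
        return sum(len(v) for v in self.data.values())

    # -- smoothing ----------------------------------------------------

    def smooth(self, width: int) -> "GenomeTrack":
        """Uniform-kernel (moving-average) smoothing, width in bp.

        Even widths are incremented to the next odd integer so the
        window is symmetric.  At chromosome ends the window is truncated
        and the mean taken over the available positions, avoiding
        zero-padding artifacts.  Constant tracks are fixed points.
        """
        if width < 1:
            raise ValueError("width must be >= 1")
        if width % 2 == 0:
            width += 1
        half = width // 2
        out = {}
        for chrom, values in self.data.items():
            n = len(values)
            if width > n:
                raise ValueError(
                    f"kernel width {width} exceeds length of {chrom} ({n})"
                )
            cum = np.concatenate([[0.0], np.cumsum(values)])
            pos = np.arange(n)
            lo = np.maximum(pos - half, 0)
            hi = np.minimum(pos + half + 1, n)
            out[chrom] = (cum[hi] - cum[lo]) / (hi - lo)
        return GenomeTrack(
            data=out, provenance=self.provenance + (f"smoothed(width={width})",)
        )

    # -- normalization ------------------------------------------------

    def normalize(self, percentile: float = 99.5) -> "GenomeTrack":
        """Divide the whole profile by its nearest-rank 99.5th percentile.

        The divisor is the coverage value bounding ``percentile`` % of
        positions across *all* chromosomes of the profile, so relative
        peak heights are comparable between profiles.  The divisor is
        recorded in the provenance chain.
        """
        values = np.concatenate(list(self.data.values()))
        if values.size == 0 or not values.any():
            raise ValueError("cannot normalize an identically zero track")
        ordered = np.sort(values)
        rank = math.ceil(percentile / 100.0 * values.size)
        divisor = float(ordered[max(rank - 1, 0)])
        if divisor == 0.0:
            raise ValueError("normalization divisor is zero")
        out = {chrom: v / divisor for chrom, v in self.data.items()}
        return GenomeTrack(
            data=out,
            provenance=self.provenance + (f"normalized(divisor={divisor:g})",),
        )

    # -- peak readout -------------------------------------------------

    def peak_height_at(self, chrom: str, position: int, flank: int = 2500) -> float:
        """Maximum track value within ``position`` +/- ``flank`` bp."""
        if chrom not in self.data:
            raise ValueError(f"unknown chromosome {chrom!r}")
        values = self.data[chrom]
        if not 0 <= position < len(values):
            raise ValueError(
                f"position {position} outside {chrom} [0, {len(values)})"
            )
        if flank < 0:
            raise ValueError("flank must be >= 0")
        lo = max(position - flank, 0)
        hi = min(position + flank + 1, len(values))
        return float(values[lo:hi].max())

    # -- I/O ----------------------------------------------------------

    def to_bedgraph(self, path) -> None:
        """Write as bedGraph, merging runs of equal value."""
        with open(path, "w") as fh:
            for chrom, values in self.data.items():
                start = 0
                for i in range(1, len(values) + 1):
                    if i == len(values) or values[i] != values[start]:
                        fh.write(f"{chrom}\t{start}\t{i}\t{values[start]:g}\n")
                        start = i

    @classmethod
    def from_bedgraph(cls, path, chrom_sizes: dict[str, int] | None = None) -> "GenomeTrack":
        """Read a bedGraph text file; values apply to every covered position.

        Chromosome lengths default to the maximum end coordinate seen.
        """
        intervals: dict[str, list] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("track", "#", "browser")):
                    continue
                chrom, start, end, value = line.split()[:4]
                intervals.setdefault(chrom, []).append(
                    (int(start), int(end), float(value))
                )
        data = {}
        for chrom, ivals in intervals.items():
            n = chrom_sizes[chrom] if chrom_sizes else max(e for _, e, _ in ivals)
            arr = np.zeros(n)
            for start, end, value in ivals:
                arr[start:end] = value
            data[chrom] = arr
        return cls(data=data)

    def to_wiggle(self, path) -> None:
        """Write as fixedStep wiggle (step 1, 1-based starts)."""
        with open(path, "w") as fh:
            for chrom, values in self.data.items():
                fh.write(f"fixedStep chrom={chrom} start=1 step=1\n")
                fh.writelines(f"{v:g}\n" for v in values)

    @classmethod
    def from_wiggle(cls, path) -> "GenomeTrack":
        """Read a fixedStep wiggle file (step 1)."""
        data: dict[str, list[float]] = {}
        current = None
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("track", "#")):
                    continue
                if line.startswith("fixedStep"):
                    fields = dict(kv.split("=") for kv in line.split()[1:])
                    if fields.get("step", "1") != "1":
                        raise ValueError("only step=1 fixedStep wiggle supported")
                    current = fields["chrom"]
                    data.setdefault(current, [])
                else:
                    if current is None:
                        raise ValueError("wiggle data before fixedStep header")
                    data[current].append(float(line))
        return cls(data={c: np.asarray(v) for c, v in data.items()})


def read_bed_loci(path) -> list[tuple[str, int, int, str]]:
    """Read BED intervals as (chrom, start, end, strand) tuples."""
    loci = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            fields = line.split("\t")
            strand = fields[5] if len(fields) > 5 else "+"
            loci.append((fields[0], int(fields[1]), int(fields[2]), strand))
    return loci
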