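"""Genome-wide test for sequence dependence of origin firing strength.

Each annotated origin carries an aligned ACS (ARS consensus sequence)
match in the 50-position motif coordinate frame and a measured peak
height from the normalized replication profile.  The analysis asks
whether firing strength depends on the dinucleotide at motif positions
29-30 (the positions whose readout changes in Orc4 alpha-helix
mutants): origins are grouped by that dinucleotide, rare dinucleotide
groups (3 or fewer occurrences) are removed, and a one-way fixed-effects
ANOVA is run on log10 peak heights, with box-plot summary statistics
per group.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .motif import reverse_complement

logger = logging.getLogger(__name__)

#: 1-based motif positions whose dinucleotide is tested
DINUCLEOTIDE_POSITIONS = (29, 30)


@dataclass(frozen=True)
class AnnotatedACS:
    """One annotated ACS: location, strand, aligned sequence, peak height."""

    chrom: str
    start: int
    end: int
    strand: str
    sequence: str
    peak_height: float
    strain: str | None = None

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.peak_height < 0:
            raise ValueError("peak height must be >= 0")

    @property
    def dinucleotide(self) -> str:
        return extract_dinucleotide(self.sequence, self.strand)


def extract_dinucleotide(sequence: str, strand: str = "+") -> str:
    """Dinucleotide at motif positions 29-30 of the aligned ACS.

    Minus-strand annotations are reverse-complemented first so positions
    are always counted in motif orientation (1-based).
    """
    if strand == "-":
        sequence = reverse_complement(sequence)
    lo, hi = DINUCLEOTIDE_POSITIONS
    if len(sequence) < hi:
        raise ValueError(
            f"aligned sequence length {len(sequence)} < {hi}; cannot read "
            f"positions {lo}-{hi}"
        )
    return sequence[lo - 1 : hi]


def group_by_dinucleotide(records) -> dict[str, list]:
    """Group AnnotatedACS records (or a DataFrame) by the 29-30 dinucleotide."""
    groups: dict[str, list] = {}
    if isinstance(records, pd.DataFrame):
        for _, row in records.iterrows():
            dinuc = extract_dinucleotide(row["sequence"], row.get("strand", "+"))
            groups.setdefault(dinuc, []).append(float(row["peak_height"]))
    else:
        for rec in records:
            groups.setdefault(rec.dinucleotide, []).append(float(rec.peak_height))
    return groups


def filter_rare(groups: dict[str, list], min_count: int = 4):
    """Remove dinucleotide groups with fewer than ``min_count`` members.

    The default keeps groups of >= 4, i.e. removes dinucleotides that
    occur 3 or fewer times.  Returns (kept, removed_report) where
    ``removed_report`` maps each dropped dinucleotide to its member count.
    """
    kept = {k: v for k, v in groups.items() if len(v) >= min_count}
    removed = {k: len(v) for k, v in groups.items() if len(v) < min_count}
    if removed:
        logger.info("removed rare dinucleotide groups: %s", removed)
    if not kept:
        raise ValueError("all groups removed by rare-variant filter: nothing to test")
    return kept, removed


def significance_stars(p: float) -> str:
    """Star annotation: *** p<0.001, ** p<0.01, * p<0.05, else 'ns'."""
    if not np.isfinite(p):
        return "undefined"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class AnovaResult:
    """One-way ANOVA of log10 peak heights across dinucleotide groups."""

    f_stat: float
    p_value: float
    df_between: int
    df_within: int
    stars: str
    group_summary: pd.DataFrame
    n_excluded_zero: int = 0

    def summary(self) -> str:
        lines = [
            "One-way ANOVA: log10 peak height ~ dinucleotide at positions 29-30",
            f"  F({self.df_between}, {self.df_within}) = {self.f_stat:.4f}, "
            f"p = {self.p_value:.4g}  [{self.stars}]",
        ]
        if self.n_excluded_zero:
            lines.append(f"  ({self.n_excluded_zero} zero-height records excluded)")
        lines.append("")
        lines.append(self.group_summary.to_string())
        return "\n".join(lines)


def anova_peak_heights(
    groups: dict[str, list], log_transform: bool = True
) -> AnovaResult:
    """One-way fixed-effects ANOVA of (log10) peak heights across groups.

    ``log_transform`` applies log10 exactly once at entry; zero heights
    are excluded with a logged warning (log10 undefined).  Requires >= 2
    groups with >= 2 members each.  When every group is constant with
    equal means the F statistic is undefined and reported as NaN.
    Per-group summaries (min, quartiles, median, max) are box-plot ready.
    """
    n_excluded = 0
    arrays: dict[str, np.ndarray] = {}
    for name, values in groups.items():
        arr = np.asarray(values, dtype=float)
        if log_transform:
            zero = arr <= 0
            if zero.any():
                n_excluded += int(zero.sum())
                logger.warning(
                    "%d non-positive peak heights excluded from group %s",
                    int(zero.sum()), name,
                )
                arr = arr[~zero]
            arr = np.log10(arr)
        arrays[name] = arr
    if len(arrays) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    for name, arr in arrays.items():
        if len(arr) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 usable members")

    samples = list(arrays.values())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant-input -> NaN is the contract
        f_stat, p_value = stats.f_oneway(*samples)
    df_between = len(samples) - 1
    df_within = sum(len(a) for a in samples) - len(samples)

    rows = []
    for name in sorted(arrays):
        arr = arrays[name]
        rows.append(
            {
                "dinucleotide": name,
                "n": len(arr),
                "min": arr.min(),
                "q1": float(np.percentile(arr, 25)),
                "median": float(np.median(arr)),
                "q3": float(np.percentile(arr, 75)),
                "max": arr.max(),
            }
        )
    summary = pd.DataFrame(rows).set_index("dinucleotide")
    return AnovaResult(
        f_stat=float(f_stat),
        p_value=float(p_value),
        df_between=df_between,
        df_within=df_within,
        stars=significance_stars(float(p_value)),
        group_summary=summary,
        n_excluded_zero=n_excluded,
    )


def run_acs_analysis(
    records, min_count: int = 4, log_transform: bool = True
) -> AnovaResult:
    """Full pipeline: group by dinucleotide, drop rare groups, run ANOVA."""
    groups = group_by_dinucleotide(records)
    kept, _ = filter_rare(groups, min_count=min_count)
    return anova_peak_heights(kept, log_transform=log_transform)


def annotate_peak_heights(frame: pd.DataFrame, track, flank: int = 2500) -> pd.DataFrame:
    """Attach peak heights from a processed track to an ACS table.

    ``frame`` needs columns chrom/start/end; the peak is read at the
    interval midpoint +/- ``flank``.
    """
    out = frame.copy()
    heights = []
    for _, row in out.iterrows():
        mid = (int(row["start"]) + int(row["end"])) // 2
        heights.append(track.peak_height_at(row["chrom"], mid, flank=flank))
    out["peak_height"] = heights
    return out
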