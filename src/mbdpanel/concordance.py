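"""Agreement between two genome-wide methylation profiles.

Two views of concordance between, e.g., a tumor-tissue and a matched cfDNA
MBD-seq profile: (i) the fraction of each sample's methylation peaks that
overlap a peak of the other sample, and (ii) the Pearson correlation of
binned signal over the genome.  All coordinates are 0-based half-open (BED
convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import pearsonr

BED_COLUMNS = ["chrom", "start", "end"]


@dataclass
class IntervalSet:
    """Sorted, validated genomic intervals (0-based, half-open)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in BED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"interval table lacks columns {missing}")
        if (df["start"] >= df["end"]).any():
            bad = df.index[(df["start"] >= df["end"])][0]
            raise ValueError(f"interval with start >= end at row {bad}")
        if (df["start"] < 0).any():
            raise ValueError("negative interval start")
        self.df = (
            df.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.df)


def read_bed(path) -> IntervalSet:
    """Strictly parse a BED3+ file (tab-separated, no header)."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or start >= end:
                raise ValueError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            rec = {"chrom": fields[0], "start": start, "end": end}
            if len(fields) > 4:
                try:
                    rec["score"] = float(fields[4])
                except ValueError:
                    pass
            records.append(rec)
    df = pd.DataFrame(records)
    if df.empty:
        df = pd.DataFrame(columns=BED_COLUMNS)
    return IntervalSet(df)


def write_bed(intervals: IntervalSet | pd.DataFrame, path) -> None:
    df = intervals.df if isinstance(intervals, IntervalSet) else intervals
    df[BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


@dataclass
class ConcordanceReport:
    n_a: int
    n_b: int
    n_shared_a: int  # peaks of A overlapped by B
    n_shared_b: int
    overlap_pct_a: float
    overlap_pct_b: float
    pearson_r: float | None = None


def _as_df(x) -> pd.DataFrame:
    return x.df if isinstance(x, IntervalSet) else IntervalSet(pd.DataFrame(x)).df


def _count_shared(a: pd.DataFrame, b: pd.DataFrame, min_overlap_bp: int) -> int:
    shared = 0
    for chrom, sub_b in b.groupby("chrom"):
        tree = IntervalTree.from_tuples(zip(sub_b["start"], sub_b["end"]))
        sub_a = a[a["chrom"] == chrom]
        for start, end in zip(sub_a["start"], sub_a["end"]):
            hits = tree.overlap(start, end)
            if any(min(end, iv.end) - max(start, iv.begin) >= min_overlap_bp
                   for iv in hits):
                shared += 1
    return shared


def peak_overlap(a, b, min_overlap_bp: int = 1) -> ConcordanceReport:
    """Mutual peak-overlap fractions of two interval sets.

    A peak of one set counts as shared iff it intersects at least
    ``min_overlap_bp`` bases of any peak of the other set; percentages are
    shared peaks over the set's own size.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    da, db = _as_df(a), _as_df(b)
    n_shared_a = _count_shared(da, db, min_overlap_bp)
    n_shared_b = _count_shared(db, da, min_overlap_bp)
    return ConcordanceReport(
        n_a=len(da),
        n_b=len(db),
        n_shared_a=n_shared_a,
        n_shared_b=n_shared_b,
        overlap_pct_a=100.0 * n_shared_a / len(da) if len(da) else 0.0,
        overlap_pct_b=100.0 * n_shared_b / len(db) if len(db) else 0.0,
    )


def read_bedgraph(path) -> pd.DataFrame:
    """Parse a bedGraph file into (chrom, start, end, value)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "value"],
    )
    if (df["start"] >= df["end"]).any():
        raise ValueError(f"{path}: interval with start >= end")
    return df


def _bin_signal(signal: pd.DataFrame, bin_size: int) -> dict[tuple[str, int], float]:
    """Sum value x covered-bases of each interval into fixed-width bins."""
    out: dict[tuple[str, int], float] = {}
    for chrom, start, end, value in zip(
        signal["chrom"], signal["start"], signal["end"], signal["value"]
    ):
        b = int(start) // bin_size
        while b * bin_size < end:
            lo = max(start, b * bin_size)
            hi = min(end, (b + 1) * bin_size)
            key = (chrom, b)
            out[key] = out.get(key, 0.0) + float(value) * (hi - lo)
            b += 1
    return out


def binned_correlation(
    signal_a: pd.DataFrame, signal_b: pd.DataFrame, bin_size: int = 1000
) -> float:
    """Pearson r of the two signals summed over fixed-width genome bins.

    Bins with zero signal in both samples are excluded (they would inflate
    the correlation with empty genome).
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    binned_a = _bin_signal(signal_a, bin_size)
    binned_b = _bin_signal(signal_b, bin_size)
    keys = sorted(set(binned_a) | set(binned_b))
    va = np.array([binned_a.get(k, 0.0) for k in keys])
    vb = np.array([binned_b.get(k, 0.0) for k in keys])
    nonzero = (va != 0) | (vb != 0)
    va, vb = va[nonzero], vb[nonzero]
    if len(va) < 2:
        raise ValueError("fewer than 2 informative bins")
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise ValueError("constant binned signal; correlation undefined")
    return float(pearsonr(va, vb).statistic)
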