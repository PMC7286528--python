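"""Diagnostic rule over per-sample marker/KRAS calls and performance metrics.

The diagnostic criterion for pancreatic cancer is: KRAS mutation positive
and/or DNA methylation positive in at least one marker gene.  Sensitivity and
specificity are reported as integer percents (round half up), matching the
arithmetic used for the published counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RULES = ("methylation_only", "kras_only", "combined")

DEFAULT_MARKERS = ("ADAMTS2", "HOXA1", "PCDH10", "SEMA5A", "SPSB4")


def round_half_up_percent(numerator: float, denominator: float) -> int:
    """Integer percent with ties rounded up (e.g. 23/47 -> 49, 19/29 -> 66)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return int(math.floor(100.0 * numerator / denominator + 0.5))


def _wilson_ci(k: int, n: int, z: float = 1.959963984540054) -> tuple[float, float]:
    if n == 0:
        return (float("nan"), float("nan"))
    p = k / n
    denom = 1 + z**2 / n
    centre = (p + z**2 / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return (max(0.0, centre - half), min(1.0, centre + half))


@dataclass
class PerformanceReport:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity_pct: int | None  # absent when there are no cancers
    specificity_pct: int | None  # absent when there are no controls
    sensitivity_ci: tuple[float, float] | None = None  # Wilson 95%, informational
    specificity_ci: tuple[float, float] | None = None
    mean_methylated_markers: float | None = None  # over diagnosed-positive cancers
    sd_methylated_markers: float | None = None


def _marker_columns(table: pd.DataFrame, markers: Sequence[str] | None) -> list[str]:
    if markers is not None:
        missing = [m for m in markers if m not in table.columns]
        if missing:
            raise ValueError(f"markers missing from table: {missing}")
        return list(markers)
    reserved = {"kras", "truth"}
    cols = [c for c in table.columns if c not in reserved]
    if not cols:
        raise ValueError("call table has no marker columns")
    return cols


def classify(
    table: pd.DataFrame,
    rule: str = "combined",
    markers: Sequence[str] | None = None,
    strict_kras: bool = False,
) -> pd.Series:
    """Per-sample diagnosis under the chosen rule.

    ``table`` has one row per sample: boolean/0-1 marker columns, a ``kras``
    column (NaN = status unknown) and optionally ``truth``.  Rules:
    ``methylation_only`` (at least one marker positive), ``kras_only``, and
    ``combined`` (either).  Unknown KRAS counts as negative with a logged
    count; with ``strict_kras=True`` those samples are dropped instead.
    """
    if rule not in RULES:
        raise ValueError(f"rule must be one of {RULES}")
    cols = _marker_columns(table, markers)
    meth_pos = table[cols].fillna(False).astype(bool).any(axis=1)
    kras = table["kras"] if "kras" in table.columns else pd.Series(
        np.nan, index=table.index
    )
    n_unknown = int(kras.isna().sum())
    if n_unknown and rule != "methylation_only":
        if strict_kras:
            keep = kras.notna()
            table, meth_pos, kras = table[keep], meth_pos[keep], kras[keep]
            logger.info("excluded %d samples with unknown KRAS status", n_unknown)
        else:
            logger.info("%d samples with unknown KRAS treated as negative", n_unknown)
    kras_pos = kras.map(lambda v: bool(v) if pd.notna(v) else False)
    if rule == "methylation_only":
        return meth_pos
    if rule == "kras_only":
        return kras_pos
    return meth_pos | kras_pos


def performance(
    diagnoses: pd.Series,
    truth: pd.Series,
    marker_table: pd.DataFrame | None = None,
    markers: Sequence[str] | None = None,
) -> PerformanceReport:
    """Confusion counts and rounded percent sensitivity/specificity.

    ``truth`` holds "cancer" / "non-cancer" per sample.  When a class is
    absent, the corresponding metric is reported as None rather than zero.
    If ``marker_table`` is given, also summarizes the number of methylated
    markers per diagnosed-positive cancer case (mean +/- sd).
    """
    truth = truth.reindex(diagnoses.index)
    if truth.isna().any():
        raise ValueError("truth label missing for some samples")
    is_cancer = truth == "cancer"
    d = diagnoses.astype(bool)
    tp = int((d & is_cancer).sum())
    fn = int((~d & is_cancer).sum())
    fp = int((d & ~is_cancer).sum())
    tn = int((~d & ~is_cancer).sum())
    sens = round_half_up_percent(tp, tp + fn) if tp + fn > 0 else None
    spec = round_half_up_percent(tn, tn + fp) if tn + fp > 0 else None
    report = PerformanceReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity_pct=sens, specificity_pct=spec,
        sensitivity_ci=_wilson_ci(tp, tp + fn) if tp + fn > 0 else None,
        specificity_ci=_wilson_ci(tn, tn + fp) if tn + fp > 0 else None,
    )
    if marker_table is not None:
        cols = _marker_columns(marker_table, markers)
        pos_cancers = diagnoses.index[(d & is_cancer)]
        if len(pos_cancers):
            counts = (
                marker_table.loc[pos_cancers, cols].fillna(False).astype(bool).sum(axis=1)
            )
            report.mean_methylated_markers = float(counts.mean())
            report.sd_methylated_markers = float(counts.std(ddof=1)) if len(counts) > 1 else 0.0
    return report


@dataclass
class PairedConcordance:
    n_pairs: int
    n_tissue_positive: int
    n_cfdna_positive_given_tissue_positive: int
    concordance_pct: int | None


def paired_concordance(
    tissue_calls: pd.Series, cfdna_calls: pd.Series
) -> PairedConcordance:
    """Fraction of cfDNA-positive samples among tissue-positive pairs.

    Computed over samples present in both series; reported as an integer
    percent (round half up), None when no pair is tissue-positive.
    """
    common = tissue_calls.index.intersection(cfdna_calls.index)
    t = tissue_calls.loc[common].astype(bool)
    c = cfdna_calls.loc[common].astype(bool)
    n_tis = int(t.sum())
    n_both = int((t & c).sum())
    return PairedConcordance(
        n_pairs=len(common),
        n_tissue_positive=n_tis,
        n_cfdna_positive_given_tissue_positive=n_both,
        concordance_pct=round_half_up_percent(n_both, n_tis) if n_tis else None,
    )
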