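"""Probe-filtering cascade for pancreatic-cancer methylation marker discovery.

Starting from a 450K-style probe x sample matrix of beta-values, candidate
marker genes are selected by five successive filters:

1. drop technically unreliable probes (problematic, SNP-overlapping, chrX/Y);
2. keep probes hypermethylated in tumor vs normal pancreas (fold change of
   group mean beta > 1.15) and located in CpG islands;
3. drop probes methylated across many cancer types (mean beta > 0.2 in
   strictly more than 4 of the panel's cancer types, pancreas included);
4. drop probes methylated in normal whole blood (blood summary beta > 0.1),
   since leukocytes dominate cfDNA;
5. aggregate surviving probes to genes (per-sample gene beta = max over the
   gene's probes) and keep genes whose tumor methylation frequency exceeds
   10% of samples.

Surviving genes are then classified by cancer-type specificity and ranked.
All inequalities are strict, matching the "over" / "more than" semantics of
the thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SEX_CHROMOSOMES = {"chrX", "chrY", "X", "Y"}


@dataclass
class SelectionConfig:
    """Thresholds of the filtering cascade (all comparisons strict)."""

    fold_change_min: float = 1.15
    beta_methylated: float = 0.2
    beta_blood_max: float = 0.1
    pan_cancer_mean_beta: float = 0.2
    pan_cancer_max_types: int = 4
    gene_min_frequency: float = 10.0  # percent of tumor samples
    blood_aggregate: str = "mean"  # or "max": per-sample max across blood

    def __post_init__(self) -> None:
        if self.fold_change_min <= 1:
            raise ValueError("fold_change_min must exceed 1")
        for name in ("beta_methylated", "beta_blood_max", "pan_cancer_mean_beta"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0 <= self.gene_min_frequency <= 100:
            raise ValueError("gene_min_frequency is a percent")
        if self.blood_aggregate not in ("mean", "max"):
            raise ValueError("blood_aggregate must be 'mean' or 'max'")


@dataclass
class CascadeReport:
    """Per-stage surviving probe/gene counts and the final candidates."""

    stage_counts: dict[str, int]
    candidates: pd.DataFrame  # gene, n_types_methylated, specificity_class, rank
    surviving_probes: pd.Index
    gene_frequency: pd.Series


def _check_alignment(matrix: pd.DataFrame, annotation: pd.DataFrame) -> None:
    missing = matrix.index.difference(annotation.index)
    if len(missing):
        raise ValueError(f"probes without annotation: {list(missing[:5])}")


def filter_probes(matrix: pd.DataFrame, annotation: pd.DataFrame) -> pd.Index:
    """Drop problematic, SNP-overlapping and sex-chromosome probes."""
    _check_alignment(matrix, annotation)
    ann = annotation.loc[matrix.index]
    bad = (
        ann["problematic"].astype(bool)
        | ann["snp_overlap"].astype(bool)
        | ann["chromosome"].isin(SEX_CHROMOSOMES)
    )
    kept = matrix.index[~bad.to_numpy()]
    if len(kept) == 0:
        logger.warning("all %d probes removed by reliability filters", len(matrix))
    return kept


def _group_mean(matrix: pd.DataFrame) -> pd.Series:
    """Per-probe mean beta, ignoring missing values."""
    return matrix.mean(axis=1, skipna=True)


def _drop_all_missing(probes: pd.Index, *matrices: pd.DataFrame) -> pd.Index:
    """Drop probes with no observed value in any required group."""
    keep = np.ones(len(probes), dtype=bool)
    for m in matrices:
        keep &= m.loc[probes].notna().any(axis=1).to_numpy()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropping %d probes with all-missing beta in a group", n_dropped)
    return probes[keep]


def select_hypermethylated_probes(
    tumor: pd.DataFrame,
    normal: pd.DataFrame,
    annotation: pd.DataFrame,
    config: SelectionConfig | None = None,
    probes: pd.Index | None = None,
) -> pd.Index:
    """Keep CpG-island probes with tumor/normal mean-beta ratio above the
    fold-change threshold.

    A probe whose normal mean is exactly zero passes whenever its tumor mean
    is positive (the fold change is unbounded); such probes are counted in
    the log.
    """
    config = config or SelectionConfig()
    _check_alignment(tumor, annotation)
    if probes is None:
        probes = tumor.index
    probes = _drop_all_missing(probes, tumor, normal)
    t_mean = _group_mean(tumor.loc[probes])
    n_mean = _group_mean(normal.loc[probes])
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = t_mean / n_mean
    zero_norm = (n_mean == 0) & (t_mean > 0)
    if zero_norm.any():
        logger.info("%d probes with zero normal mean treated as passing", zero_norm.sum())
    passes_fc = (fold > config.fold_change_min) | zero_norm
    island = annotation.loc[probes, "cpg_island"].astype(bool)
    return probes[(passes_fc & island).to_numpy()]


def exclude_pan_cancer_probes(
    probes: pd.Index,
    cancer_matrices: Mapping[str, pd.DataFrame],
    config: SelectionConfig | None = None,
) -> pd.Index:
    """Drop probes whose mean beta exceeds the threshold in strictly more
    than ``pan_cancer_max_types`` cancer types.

    ``cancer_matrices`` maps cancer-type name to its beta matrix and must
    include the pancreatic cohort itself: the type count is over the whole
    panel, pancreas included.
    """
    config = config or SelectionConfig()
    n_meth = pd.Series(0, index=probes, dtype=int)
    for mat in cancer_matrices.values():
        n_meth += (_group_mean(mat.loc[probes]) > config.pan_cancer_mean_beta).astype(int)
    return probes[(n_meth <= config.pan_cancer_max_types).to_numpy()]


def exclude_blood_probes(
    probes: pd.Index,
    blood: pd.DataFrame,
    config: SelectionConfig | None = None,
) -> pd.Index:
    """Drop probes methylated in normal whole blood (summary beta strictly
    over the blood threshold; summary = mean across blood samples by default,
    per-sample max if ``blood_aggregate='max'``)."""
    config = config or SelectionConfig()
    probes = _drop_all_missing(probes, blood)
    sub = blood.loc[probes]
    summary = sub.max(axis=1, skipna=True) if config.blood_aggregate == "max" else _group_mean(sub)
    return probes[(summary <= config.beta_blood_max).to_numpy()]


def gene_beta(
    matrix: pd.DataFrame, annotation: pd.DataFrame, probes: pd.Index | None = None
) -> pd.DataFrame:
    """Per-sample gene-level beta: the maximum beta over each gene's probes."""
    if probes is None:
        probes = matrix.index
    _check_alignment(matrix.loc[probes], annotation)
    genes = annotation.loc[probes, "gene"]
    keep = genes.notna() & (genes != "")
    sub = matrix.loc[probes[keep.to_numpy()]]
    return sub.groupby(genes[keep.to_numpy()].to_numpy()).max()


def gene_frequency(
    matrix: pd.DataFrame,
    annotation: pd.DataFrame,
    config: SelectionConfig | None = None,
    probes: pd.Index | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Gene-level beta per sample and the methylation frequency per gene.

    A sample counts as methylated for a gene iff its gene-level beta strictly
    exceeds ``beta_methylated``; frequency is the percent of samples
    methylated.
    """
    config = config or SelectionConfig()
    gb = gene_beta(matrix, annotation, probes)
    freq = 100.0 * (gb > config.beta_methylated).mean(axis=1)
    freq.name = "methylation_frequency_pct"
    return gb, freq


def select_stable_genes(
    freq: pd.Series, config: SelectionConfig | None = None
) -> list[str]:
    """Genes whose tumor methylation frequency strictly exceeds the minimum."""
    config = config or SelectionConfig()
    return sorted(freq.index[freq > config.gene_min_frequency])


def classify_specificity(
    genes: Sequence[str],
    cancer_matrices: Mapping[str, pd.DataFrame],
    annotation: pd.DataFrame,
    pancreas_name: str,
    config: SelectionConfig | None = None,
    tumor_frequency: pd.Series | None = None,
) -> pd.DataFrame:
    """Classify candidate genes by how many cancer types they are methylated in.

    A gene is methylated in a cancer type iff the mean over samples of its
    gene-level beta in that type strictly exceeds ``beta_methylated``
    (mirroring the probe-level pan-cancer rule).  Classes: 1 = methylated in
    four types including pancreas, 2 = two or three types, 3 = pancreas only.
    Genes not methylated in pancreas or methylated in more than four types
    fall outside the classes and are dropped with a log message.  Within each
    class genes are ranked by tumor methylation frequency, then mean
    gene-level beta in pancreas (both descending), ties by gene symbol.
    """
    config = config or SelectionConfig()
    if pancreas_name not in cancer_matrices:
        raise ValueError(f"pancreas cohort {pancreas_name!r} missing from panel")
    genes = list(genes)
    per_type: dict[str, pd.Series] = {}
    for name, mat in cancer_matrices.items():
        gb = gene_beta(mat, annotation)
        per_type[name] = gb.reindex(genes).mean(axis=1, skipna=True)
    meth = pd.DataFrame(
        {name: s > config.beta_methylated for name, s in per_type.items()}
    ).fillna(False)
    n_types = meth.sum(axis=1).astype(int)
    in_pancreas = meth[pancreas_name]

    def _class(row_gene: str) -> int | None:
        n = n_types[row_gene]
        if not in_pancreas[row_gene] or n > 4:
            return None
        if n == 1:
            return 3
        if n in (2, 3):
            return 2
        return 1  # n == 4

    cls = pd.Series({g: _class(g) for g in genes})
    dropped = cls.index[cls.isna()]
    if len(dropped):
        logger.info("%d genes outside specificity classes dropped", len(dropped))
    out = pd.DataFrame(
        {
            "gene": genes,
            "n_types_methylated": n_types.reindex(genes).to_numpy(),
            "specificity_class": cls.reindex(genes).to_numpy(),
            "mean_beta_pancreas": per_type[pancreas_name].reindex(genes).to_numpy(),
        }
    ).dropna(subset=["specificity_class"])
    out["specificity_class"] = out["specificity_class"].astype(int)
    if tumor_frequency is not None:
        out["tumor_frequency_pct"] = tumor_frequency.reindex(out["gene"]).to_numpy()
    else:
        out["tumor_frequency_pct"] = np.nan
    out = out.sort_values(
        by=["specificity_class", "tumor_frequency_pct", "mean_beta_pancreas", "gene"],
        ascending=[True, False, False, True],
    ).reset_index(drop=True)
    out["rank_in_class"] = out.groupby("specificity_class").cumcount() + 1
    return out


def run_cascade(
    tumor: pd.DataFrame,
    normal: pd.DataFrame,
    blood: pd.DataFrame,
    other_cancers: Mapping[str, pd.DataFrame],
    annotation: pd.DataFrame,
    config: SelectionConfig | None = None,
    pancreas_name: str = "pancreas",
    exclude_genes: Sequence[str] = (),
) -> CascadeReport:
    """Run the five-stage filtering cascade and classify the survivors.

    ``exclude_genes`` removes genes for which an assay cannot be designed
    (a wet-lab constraint supplied by the user, not inferred from data).
    """
    config = config or SelectionConfig()
    if tumor.shape[1] == 0:
        raise ValueError("tumor cohort is empty")
    if normal.shape[1] == 0 or blood.shape[1] == 0:
        raise ValueError("normal and blood cohorts must be non-empty")

    counts: dict[str, int] = {"input_probes": len(tumor.index)}
    probes = filter_probes(tumor, annotation)
    counts["after_reliability_filter"] = len(probes)
    probes = select_hypermethylated_probes(tumor, normal, annotation, config, probes)
    counts["after_hypermethylation_filter"] = len(probes)
    panel = {pancreas_name: tumor, **other_cancers}
    probes = exclude_pan_cancer_probes(probes, panel, config)
    counts["after_pan_cancer_filter"] = len(probes)
    probes = exclude_blood_probes(probes, blood, config)
    counts["after_blood_filter"] = len(probes)

    _, freq = gene_frequency(tumor, annotation, config, probes)
    genes = select_stable_genes(freq, config)
    genes = [g for g in genes if g not in set(exclude_genes)]
    counts["stable_genes"] = len(genes)

    candidates = classify_specificity(
        genes, panel, annotation, pancreas_name, config, tumor_frequency=freq
    )
    counts["classified_candidates"] = len(candidates)
    return CascadeReport(
        stage_counts=counts,
        candidates=candidates,
        surviving_probes=probes,
        gene_frequency=freq,
    )
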