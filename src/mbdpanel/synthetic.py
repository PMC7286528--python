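"""Seeded generators for every input the pipeline consumes.

The generators emulate the study's data structures with known ground truth:

* 450K-style beta-value cohorts (pancreatic tumor, normal pancreas, normal
  whole blood, and a panel of other cancer types) with planted
  pancreas-specific hypermethylated genes, plus decoy genes shared across
  cancer types, pan-cancer genes, and blood-methylated genes, so every branch
  of the filtering cascade is exercised;
* methylated/unmethylated mixture series for MBD-ddPCR calibration
  (ratios 0-100% at a 1,000-copy total, Poisson counting noise);
* droplet wells under the standard partition-occupancy model;
* cfDNA cohorts where tumors shed each marker with a stated probability; and
* paired peak interval sets with a controlled overlap fraction.

Beta noise is a normal truncated to [0, 1] around the group mean (a beta
distribution is available via ``CohortSpec.noise_model``); the generative
model is a package choice, chosen to reproduce the decision logic rather
than any real cohort's variance structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .ddpcr import DEFAULT_DROPLET_VOLUME_NL, DropletWell, REFERENCE_CALIBRATIONS

logger = logging.getLogger(__name__)

DEFAULT_OTHER_CANCERS = [
    ("LUAD", 8),
    ("BLCA", 8),
    ("CRC", 8),
    ("BRCA", 8),
    ("KIRC", 8),
    ("LAML", 8),
    ("LUSC", 8),
    ("SKCM", 8),
    ("STAD", 8),
]

MIXTURE_RATIOS = (0.0, 0.1, 0.5, 1.0, 2.5, 5.0, 10.0, 25.0, 50.0, 100.0)


@dataclass
class CohortSpec:
    """Layout of a simulated methylation-array study.

    Sizes default to the study design: 37 pancreatic tumors, 3 normal
    pancreatic tissues, 95 normal whole-blood samples, and nine other cancer
    types.  ``n_planted_marker_genes`` pancreas-specific genes are the ground
    truth the cascade should recover; decoy genes shared with a few other
    cancer types, pan-cancer genes, and blood-methylated genes exercise the
    exclusion filters.
    """

    n_tumor: int = 37
    n_normal: int = 3
    n_blood: int = 95
    other_cancer_types: list[tuple[str, int]] = field(
        default_factory=lambda: list(DEFAULT_OTHER_CANCERS)
    )
    n_probes: int = 2000
    n_planted_marker_genes: int = 5
    probes_per_gene: int = 5
    beta_noise_sd: float = 0.05
    tumor_meth_beta_mean: float = 0.6
    background_beta_mean: float = 0.05
    seed: int = 0
    # decoy architecture
    n_shared_cancer_genes: int = 4  # methylated in pancreas + 1..3 other types
    n_pan_cancer_genes: int = 3  # methylated in pancreas + >=4 other types
    n_blood_positive_genes: int = 2  # methylated in tumor and in blood
    flagged_probe_fraction: float = 0.05
    island_background_fraction: float = 0.3
    noise_model: str = "truncnorm"  # or "beta"

    def __post_init__(self) -> None:
        for name in ("n_tumor", "n_normal", "n_blood", "n_probes",
                     "n_planted_marker_genes", "probes_per_gene"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("beta_noise_sd", "tumor_meth_beta_mean", "background_beta_mean"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.noise_model not in ("truncnorm", "beta"):
            raise ValueError("noise_model must be 'truncnorm' or 'beta'")
        n_special = (
            self.n_planted_marker_genes
            + self.n_shared_cancer_genes
            + self.n_pan_cancer_genes
            + self.n_blood_positive_genes
        )
        if n_special * self.probes_per_gene > self.n_probes:
            raise ValueError(
                "n_probes too small for the requested planted/decoy genes"
            )


@dataclass
class CohortResult:
    matrices: dict[str, pd.DataFrame]  # group -> probes x samples
    annotation: pd.DataFrame
    truth_markers: list[str]  # planted pancreas-specific genes
    truth_shared: list[str]
    truth_pan_cancer: list[str]
    truth_blood: list[str]


def _draw_beta(
    rng: np.random.Generator, mean: float, sd: float, size, model: str
) -> np.ndarray:
    """Draw beta-values around ``mean`` restricted to [0, 1]."""
    if sd == 0:
        return np.full(size, mean)
    if model == "beta":
        # method-of-moments beta; fall back to truncnorm if infeasible
        v = min(sd**2, mean * (1 - mean) * 0.99)
        k = mean * (1 - mean) / v - 1
        return rng.beta(max(mean * k, 1e-3), max((1 - mean) * k, 1e-3), size=size)
    from scipy.stats import truncnorm

    a, b = (0 - mean) / sd, (1 - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def truncated_beta_mean(mean: float, sd: float) -> float:
    """Expected value of the truncated-normal beta draw (for moment checks)."""
    if sd == 0:
        return mean
    from scipy.stats import truncnorm

    a, b = (0 - mean) / sd, (1 - mean) / sd
    return float(truncnorm.mean(a, b, loc=mean, scale=sd))


def simulate_beta_cohort(spec: CohortSpec) -> CohortResult:
    """Simulate beta matrices per group, a probe annotation, and the truth.

    Probes are grouped into consecutive genes of ``probes_per_gene`` probes.
    Planted marker genes are hypermethylated in pancreatic tumors only;
    shared decoys additionally in 1-3 other cancer types (drawn per gene),
    pan-cancer decoys in at least 4 other types, blood decoys in tumor and
    whole blood.  Reliability flags (SNP / problematic / sex chromosome) are
    assigned to a fraction of background probes only, so the planted truth
    survives stage 1 by construction.
    """
    rng = np.random.default_rng(spec.seed)
    n_genes = spec.n_probes // spec.probes_per_gene
    if spec.n_probes % spec.probes_per_gene:
        n_genes += 1
    gene_names = [f"G{i:05d}" for i in range(n_genes)]
    probe_ids = [f"cg{i:08d}" for i in range(spec.n_probes)]
    probe_gene = [gene_names[i // spec.probes_per_gene] for i in range(spec.n_probes)]

    # assign special roles to distinct genes (only genes with a full probe set)
    n_full = spec.n_probes // spec.probes_per_gene
    special = rng.choice(
        n_full,
        size=spec.n_planted_marker_genes
        + spec.n_shared_cancer_genes
        + spec.n_pan_cancer_genes
        + spec.n_blood_positive_genes,
        replace=False,
    )
    i0 = spec.n_planted_marker_genes
    i1 = i0 + spec.n_shared_cancer_genes
    i2 = i1 + spec.n_pan_cancer_genes
    markers = sorted(gene_names[i] for i in special[:i0])
    shared = sorted(gene_names[i] for i in special[i0:i1])
    pan = sorted(gene_names[i] for i in special[i1:i2])
    blood_genes = sorted(gene_names[i] for i in special[i2:])

    other_names = [name for name, _ in spec.other_cancer_types]
    shared_types: dict[str, list[str]] = {
        g: list(rng.choice(other_names, size=rng.integers(1, min(3, len(other_names)) + 1),
                           replace=False))
        for g in shared
    }
    pan_types: dict[str, list[str]] = {
        g: list(rng.choice(other_names, size=rng.integers(4, len(other_names) + 1),
                           replace=False))
        for g in pan
    }

    tumor_high = set(markers) | set(shared) | set(pan) | set(blood_genes)

    groups: list[tuple[str, int]] = [
        ("tumor", spec.n_tumor),
        ("normal_pancreas", spec.n_normal),
        ("normal_blood", spec.n_blood),
        *spec.other_cancer_types,
    ]

    def high_in(group: str, gene: str) -> bool:
        if group == "tumor":
            return gene in tumor_high
        if group == "normal_blood":
            return gene in blood_genes
        if group == "normal_pancreas":
            return False
        if gene in shared:
            return group in shared_types[gene]
        if gene in pan:
            return group in pan_types[gene]
        return False

    matrices: dict[str, pd.DataFrame] = {}
    probe_gene_arr = np.array(probe_gene)
    for group, n_samples in groups:
        mat = _draw_beta(
            rng, spec.background_beta_mean, spec.beta_noise_sd,
            (spec.n_probes, n_samples), spec.noise_model,
        )
        high_genes = {g for g in tumor_high if high_in(group, g)}
        if high_genes:
            mask = np.isin(probe_gene_arr, sorted(high_genes))
            mat[mask, :] = _draw_beta(
                rng, spec.tumor_meth_beta_mean, spec.beta_noise_sd,
                (int(mask.sum()), n_samples), spec.noise_model,
            )
        matrices[group] = pd.DataFrame(
            mat, index=probe_ids,
            columns=[f"{group}_{j:03d}" for j in range(n_samples)],
        )

    # annotation: planted/decoy probes are islands and never flagged
    special_probe = np.isin(probe_gene_arr, sorted(tumor_high))
    island = special_probe | (
        rng.random(spec.n_probes) < spec.island_background_fraction
    )
    snp = (~special_probe) & (rng.random(spec.n_probes) < spec.flagged_probe_fraction)
    problematic = (~special_probe) & (
        rng.random(spec.n_probes) < spec.flagged_probe_fraction
    )
    autosomes = [f"chr{c}" for c in range(1, 23)]
    chrom = rng.choice(autosomes, size=spec.n_probes)
    sex = (~special_probe) & (rng.random(spec.n_probes) < spec.flagged_probe_fraction)
    chrom[sex] = rng.choice(["chrX", "chrY"], size=int(sex.sum()))
    annotation = pd.DataFrame(
        {
            "chromosome": chrom,
            "gene": probe_gene,
            "cpg_island": island,
            "snp_overlap": snp,
            "problematic": problematic,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    return CohortResult(
        matrices=matrices,
        annotation=annotation,
        truth_markers=markers,
        truth_shared=shared,
        truth_pan_cancer=pan,
        truth_blood=blood_genes,
    )


@dataclass
class DdpcrSimSpec:
    """Design of a simulated MBD-ddPCR mixture series.

    Defaults follow the published calibration design: ratios 0-100% at a
    total input of 1,000 copies per gene.  ``true_slope``/``true_intercept``
    define the ground-truth response at the 1,000-copy reference total;
    expected copies scale linearly with ``total_copies / 1000``.
    """

    true_slope: float  # copies per % methylation
    true_intercept: float  # copies
    ratios: Sequence[float] = MIXTURE_RATIOS
    total_copies: int = 1000
    n_droplets: int = 20000
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL
    seed: int = 0
    noise: str = "poisson"  # or "none"

    def __post_init__(self) -> None:
        if any(not 0 <= r <= 100 for r in self.ratios):
            raise ValueError("ratios must lie in [0, 100]")
        if self.n_droplets <= 0:
            raise ValueError("n_droplets must be positive")
        if self.total_copies < 0:
            raise ValueError("total_copies must be >= 0")
        if self.noise not in ("poisson", "none"):
            raise ValueError("noise must be 'poisson' or 'none'")


def simulate_mixture_series(spec: DdpcrSimSpec) -> list[tuple[float, float]]:
    """(ratio, observed methylated copies) pairs for one calibration series.

    The expected response at ratio x is ``(a*x + b) * total_copies/1000``;
    realized copies are Poisson with that mean unless ``noise='none'``.
    Negative expected values are clamped to zero with a warning.
    """
    rng = np.random.default_rng(spec.seed)
    scale = spec.total_copies / 1000.0
    out: list[tuple[float, float]] = []
    for x in spec.ratios:
        mu = (spec.true_slope * x + spec.true_intercept) * scale
        if mu < 0:
            logger.warning("expected copies negative (%.3f) at x=%s; clamped", mu, x)
            mu = 0.0
        y = float(rng.poisson(mu)) if spec.noise == "poisson" else float(mu)
        out.append((float(x), y))
    return out


def simulate_droplet_well(
    copies: float,
    n_droplets: int = 20000,
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL,
    seed: int | np.random.Generator = 0,
    sample: str = "sim",
    assay: str = "sim",
) -> DropletWell:
    """Partition ``copies`` template molecules into droplets.

    Each droplet is positive independently with probability
    ``1 - exp(-copies / n_droplets)`` (Poisson occupancy).
    """
    if copies < 0:
        raise ValueError("copies must be >= 0")
    if n_droplets <= 0:
        raise ValueError("n_droplets must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = -np.expm1(-copies / n_droplets)
    positives = int(rng.binomial(n_droplets, p))
    return DropletWell(
        sample=sample,
        assay=assay,
        total_droplets=n_droplets,
        positive_droplets=positives,
        droplet_volume_nl=droplet_volume_nl,
    )


# copies used when decoding a boolean call into a well: positives are well
# above the 100-copy LoD and invert to a percent above every panel cutoff;
# negatives fall below the LoD.
_POSITIVE_COPIES = 2000.0
_NEGATIVE_COPIES = 10.0
_KRAS_WT_COPIES = 2000.0
_KRAS_MUT_COPIES = 100.0


@dataclass
class CfdnaCohort:
    marker_wells: dict[str, dict[str, DropletWell]]  # sample -> marker -> well
    kras_wells: dict[str, tuple[DropletWell, DropletWell]]  # (wt, mut)
    truth: pd.Series  # sample -> "cancer" | "non-cancer"
    call_matrix: pd.DataFrame  # boolean marker columns + kras, the ground truth


def simulate_cfdna_cohort(
    n_cancer: int = 47,
    n_normal: int = 14,
    marker_shed_prob: float = 0.2,
    kras_shed_prob: float = 0.49,
    seed: int = 0,
    normal_false_positive_rate: float = 0.02,
    markers: Sequence[str] = tuple(REFERENCE_CALIBRATIONS),
    call_matrix: pd.DataFrame | None = None,
) -> CfdnaCohort:
    """Simulate per-sample marker and KRAS droplet wells for a cfDNA cohort.

    Each cancer sample sheds detectable methylated DNA for each marker
    independently with ``marker_shed_prob`` and mutant KRAS with
    ``kras_shed_prob``; normal samples yield marker false positives at
    ``normal_false_positive_rate`` and never shed mutant KRAS.  Passing an
    explicit boolean ``call_matrix`` (marker columns plus ``kras`` and
    ``truth``) switches to deterministic mode: wells are generated so the
    quantification pipeline decodes exactly those calls.
    """
    rng = np.random.default_rng(seed)
    markers = list(markers)
    if call_matrix is None:
        samples = [f"PC{i:03d}" for i in range(n_cancer)] + [
            f"NV{i:03d}" for i in range(n_normal)
        ]
        truth = ["cancer"] * n_cancer + ["non-cancer"] * n_normal
        rows = {}
        for s, t in zip(samples, truth):
            p = marker_shed_prob if t == "cancer" else normal_false_positive_rate
            row = {m: bool(rng.random() < p) for m in markers}
            row["kras"] = bool(
                t == "cancer" and rng.random() < kras_shed_prob
            )
            row["truth"] = t
            rows[s] = row
        call_matrix = pd.DataFrame.from_dict(rows, orient="index")
    else:
        call_matrix = call_matrix.copy()
        missing = [c for c in markers + ["kras", "truth"] if c not in call_matrix]
        if missing:
            raise ValueError(f"call_matrix lacks columns: {missing}")

    marker_wells: dict[str, dict[str, DropletWell]] = {}
    kras_wells: dict[str, tuple[DropletWell, DropletWell]] = {}
    for s, row in call_matrix.iterrows():
        marker_wells[s] = {
            m: simulate_droplet_well(
                _POSITIVE_COPIES if bool(row[m]) else _NEGATIVE_COPIES,
                seed=rng, sample=str(s), assay=m,
            )
            for m in markers
        }
        mut = _KRAS_MUT_COPIES if bool(row["kras"]) else 0.0
        kras_wells[s] = (
            simulate_droplet_well(_KRAS_WT_COPIES, seed=rng, sample=str(s), assay="KRAS_wt"),
            simulate_droplet_well(mut, seed=rng, sample=str(s), assay="KRAS_mut"),
        )
    return CfdnaCohort(
        marker_wells=marker_wells,
        kras_wells=kras_wells,
        truth=call_matrix["truth"].copy(),
        call_matrix=call_matrix,
    )


def simulate_paired_peaks(
    n_peaks: int,
    shared_fraction: float,
    genome_length: int = 100_000_000,
    peak_width: int = 150,
    seed: int = 0,
    chrom: str = "chr1",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two peak sets (BED-style, 0-based half-open) with a known overlap.

    Peaks are placed on a non-overlapping grid of ``2 * n_peaks`` slots; set B
    reuses ``round(shared_fraction * n_peaks)`` of A's slots and fills the
    rest from slots disjoint from A, so the realized overlap fraction equals
    ``shared_fraction`` up to the rounding of that product.
    """
    if not 0 <= shared_fraction <= 1:
        raise ValueError("shared_fraction must lie in [0, 1]")
    n_slots = 2 * n_peaks
    stride = genome_length // (n_slots + 1)
    if stride <= peak_width:
        raise ValueError("genome_length too small for the requested peaks")
    rng = np.random.default_rng(seed)
    slots = rng.permutation(n_slots)
    a_slots = slots[:n_peaks]
    n_shared = int(round(shared_fraction * n_peaks))
    b_slots = np.concatenate([a_slots[:n_shared], slots[n_peaks : 2 * n_peaks - n_shared]])

    def to_df(slot_idx: np.ndarray) -> pd.DataFrame:
        starts = np.sort(slot_idx) * stride
        return pd.DataFrame(
            {"chrom": chrom, "start": starts, "end": starts + peak_width}
        )

    return to_df(a_slots), to_df(b_slots)
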