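"""Droplet digital PCR quantification and MBD-ddPCR calibration.

A ddPCR reaction partitions the template into ~20,000 droplets; the number of
template copies is inferred from the fraction of positive droplets under a
Poisson occupancy model.  For the MBD-ddPCR methylation assay, a per-gene
calibration line (fitted on methylated/unmethylated DNA mixtures of known
ratio) maps input percent methylation to observed methylated copies; inverting
it converts an observed copy number in a patient sample to percent
methylation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

#: Calibration lines (slope: copies per % methylation, intercept: copies)
#: published for the five-marker MBD-ddPCR panel at a 1,000-copy input.
REFERENCE_CALIBRATIONS: dict[str, tuple[float, float]] = {
    "ADAMTS2": (0.4548, 3.295),
    "HOXA1": (1.2164, 1.7287),
    "PCDH10": (1.4164, 5.1705),
    "SEMA5A": (0.6902, 3.9448),
    "SPSB4": (0.9506, 1.1368),
}

#: QX200 droplet volume convention, nanolitres.  Only affects the
#: copies-per-microlitre conversion, never per-well copy counts.
DEFAULT_DROPLET_VOLUME_NL = 0.85


@dataclass(frozen=True)
class DropletWell:
    """Raw droplet partition counts for one assay on one sample."""

    sample: str
    assay: str
    total_droplets: int
    positive_droplets: int
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL

    def __post_init__(self) -> None:
        if self.total_droplets <= 0:
            raise ValueError("total_droplets must be positive")
        if not 0 <= self.positive_droplets <= self.total_droplets:
            raise ValueError("positive_droplets must lie in [0, total_droplets]")


@dataclass
class CalibrationModel:
    """Linear map between input % methylation and observed ddPCR copies."""

    gene: str
    slope: float  # copies per % methylation
    intercept: float  # copies
    r_squared: float = float("nan")


@dataclass
class DdpcrConfig:
    """Detection limits for methylation and KRAS calls.

    ``methylation_copy_lod``: minimum methylated copies for a reliable
    MBD-ddPCR detection (calls require strictly more).
    ``kras_maf_llod``: lower limit of detection for the mutant allele
    frequency, percent (inclusive).
    """

    methylation_copy_lod: float = 100.0
    kras_maf_llod: float = 0.2

    def __post_init__(self) -> None:
        if self.methylation_copy_lod <= 0 or self.kras_maf_llod <= 0:
            raise ValueError("detection limits must be positive")


@dataclass
class KrasCall:
    sample: str
    wildtype_copies: float
    mutant_copies: float
    maf_percent: float
    positive: bool


def poisson_copies(well: DropletWell) -> tuple[float, float]:
    """Invert droplet counts to template copies.

    With ``p`` the positive fraction, the mean occupancy is
    ``lambda = -ln(1 - p)``; copies per well is ``lambda * total_droplets``.

    Returns ``(copies_per_well, copies_per_microlitre)``.  Saturated wells
    (every droplet positive) are rejected: the Poisson inversion diverges.
    """
    if well.positive_droplets == well.total_droplets:
        raise ValueError(
            f"well {well.sample}/{well.assay} is saturated "
            "(all droplets positive); copies not estimable"
        )
    lam = -math.log1p(-well.positive_droplets / well.total_droplets)
    copies_per_well = lam * well.total_droplets
    copies_per_ul = lam / (well.droplet_volume_nl * 1e-3)
    return copies_per_well, copies_per_ul


def merge_wells(wells: Sequence[DropletWell]) -> DropletWell:
    """Merge replicate wells of one (sample, assay) by summing droplets."""
    if not wells:
        raise ValueError("no wells to merge")
    keys = {(w.sample, w.assay) for w in wells}
    if len(keys) > 1:
        raise ValueError(f"cannot merge wells from different assays: {sorted(keys)}")
    return DropletWell(
        sample=wells[0].sample,
        assay=wells[0].assay,
        total_droplets=sum(w.total_droplets for w in wells),
        positive_droplets=sum(w.positive_droplets for w in wells),
        droplet_volume_nl=wells[0].droplet_volume_nl,
    )


def fit_calibration(
    points: Iterable[tuple[float, float]], gene: str = ""
) -> CalibrationModel:
    """Ordinary least squares of observed copies on input % methylation.

    ``points`` are (x, y) pairs with x in [0, 100] percent and y >= 0 copies;
    at least three distinct x values are required for a meaningful line.
    """
    pts = [(float(x), float(y)) for x, y in points]
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if len(np.unique(x)) < 3:
        raise ValueError("calibration requires at least 3 distinct mixture ratios")
    if np.ptp(y) == 0:
        # degenerate: a flat response carries no calibration information
        return CalibrationModel(gene=gene, slope=0.0, intercept=float(y[0]), r_squared=0.0)
    res = stats.linregress(x, y)
    return CalibrationModel(
        gene=gene,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def estimate_methylation(model: CalibrationModel, observed_copies: float) -> float:
    """Invert the calibration line: percent = (y - b) / a, clipped to [0, 100].

    A non-positive slope means the mixture series did not respond to input
    methylation and the calibration is not identifiable.
    """
    if model.slope <= 0:
        raise ValueError(f"calibration for {model.gene!r} has non-positive slope")
    pct = (observed_copies - model.intercept) / model.slope
    if pct < 0 or pct > 100:
        logger.debug(
            "estimate for %s clipped from %.3f%% to [0, 100]", model.gene, pct
        )
    return float(min(max(pct, 0.0), 100.0))


def call_methylation(
    model: CalibrationModel,
    well: DropletWell,
    cutoff: float,
    config: DdpcrConfig | None = None,
) -> bool:
    """Methylation-positive call for one marker on one sample.

    Positive iff estimated copies strictly exceed the copy LoD *and* the
    estimated percent methylation strictly exceeds the marker's panel cutoff.
    Both gates are required: the copy floor guards against quantifying below
    the assay's reliable range, the percent cutoff distinguishes tumor signal
    from background.
    """
    config = config or DdpcrConfig()
    copies, _ = poisson_copies(well)
    if copies <= config.methylation_copy_lod:
        return False
    return estimate_methylation(model, copies) > cutoff


def call_kras(
    wt_well: DropletWell,
    mut_well: DropletWell,
    config: DdpcrConfig | None = None,
) -> KrasCall:
    """Two-channel KRAS call from wild-type and mutant droplet counts.

    MAF = 100 * mutant / (mutant + wild-type) copies; positive iff the MAF
    reaches the lower limit of detection (inclusive) and at least one mutant
    copy was observed.
    """
    config = config or DdpcrConfig()
    wt, _ = poisson_copies(wt_well)
    mut, _ = poisson_copies(mut_well)
    total = wt + mut
    maf = 100.0 * mut / total if total > 0 else 0.0
    positive = mut > 0 and maf >= config.kras_maf_llod
    return KrasCall(
        sample=mut_well.sample,
        wildtype_copies=wt,
        mutant_copies=mut,
        maf_percent=maf,
        positive=positive,
    )
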