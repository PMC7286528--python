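"""Synthetic worked-example call tables.

The original per-sample call matrices are not public; these tables are
synthetic reconstructions that reproduce the published aggregate counts
exactly (which samples carry which marker is arbitrary, the margins are
not):

* validation cohort: 46 pancreatic cancers all methylation-positive in at
  least one marker, 43/46 KRAS-mutant (the 3 wild-type cases methylated),
  6 benign pancreatic disease samples all negative;
* TCGA-style cohort: 137 cancers of which 132 are methylation-positive
  (mean ~3.5 methylated markers among positives), 10 normals of which 1 is
  positive; KRAS mutant in 59, wild type in 36, unknown in 42, with every
  mutant case methylation-positive;
* cfDNA cohort: 47 cancers (23 methylation-positive, 23 KRAS-positive, 32
  positive under the combined rule) and 14 normal volunteers (2 marker
  false positives, no KRAS);
* paired FNA-cfDNA set: 29 pairs, every tissue sample positive, 19 cfDNA
  samples positive under the combined rule.

Tables are pandas DataFrames indexed by sample with boolean marker columns,
a ``kras`` column (NaN = unknown status) and a ``truth`` column.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .classify import DEFAULT_MARKERS

_MARKERS = list(DEFAULT_MARKERS)


def _rows_with_marker_count(n_rows: int, counts: list[int], start_offset: int = 0):
    """Deterministic marker patterns: row i gets counts[i] markers, chosen by
    cycling through the marker combinations of that size."""
    combos_by_k = {
        k: list(itertools.combinations(_MARKERS, k)) for k in range(0, 6)
    }
    rows = []
    for i, k in enumerate(counts):
        combo = combos_by_k[k][(i + start_offset) % len(combos_by_k[k])] if k else ()
        rows.append({m: m in combo for m in _MARKERS})
    return rows


def validation_tissue_calls() -> pd.DataFrame:
    """46 cancers (all methylated, 43 KRAS-mutant) + 6 benign controls."""
    counts = [1 + (i % 5) for i in range(46)]  # 1..5 markers per case
    rows = _rows_with_marker_count(46, counts)
    for i, row in enumerate(rows):
        row["kras"] = i >= 3  # first 3 cases are the KRAS wild-type ones
        row["truth"] = "cancer"
    for j in range(6):
        rows.append({**{m: False for m in _MARKERS}, "kras": False, "truth": "non-cancer"})
    idx = [f"V{i:03d}" for i in range(46)] + [f"B{j:03d}" for j in range(6)]
    return pd.DataFrame(rows, index=idx)


def tcga_calls() -> pd.DataFrame:
    """137 cancers (132 methylation-positive) + 10 normals (1 positive).

    The 132 positive cases carry 1-5 methylated markers with mean 3.5
    (12x1, 20x2, 30x3, 30x4, 40x5).  KRAS: 59 mutant (all among the
    methylation-positive cases), 36 wild type (including the two
    unmethylated wild-type cases), 42 unknown.
    """
    counts = [1] * 12 + [2] * 20 + [3] * 30 + [4] * 30 + [5] * 40 + [0] * 5
    rows = _rows_with_marker_count(137, counts)
    # KRAS status: mutants first (all methylation-positive), then wild type,
    # then unknown; the five unmethylated cases are 2 wild type + 3 unknown.
    kras: list[float | bool] = [True] * 59 + [False] * 34 + [np.nan] * 39
    kras += [False, False, np.nan, np.nan, np.nan]  # the 5 unmethylated cases
    for row, k in zip(rows, kras):
        row["kras"] = k
        row["truth"] = "cancer"
    for j in range(10):
        pos = j == 0  # one normal sample is methylation-positive
        rows.append(
            {**{m: (pos and m == "ADAMTS2") for m in _MARKERS},
             "kras": False, "truth": "non-cancer"}
        )
    idx = [f"TCGA{i:03d}" for i in range(137)] + [f"TN{j:03d}" for j in range(10)]
    return pd.DataFrame(rows, index=idx)


def cfdna_calls() -> pd.DataFrame:
    """cfDNA cohort: 47 cancers, 14 normal volunteers.

    Methylation-positive: cancers 0-22 (23 samples).  KRAS-positive: cancers
    9-31 (23 samples, 14 overlapping the methylated set), so the combined
    rule marks 32 cancers positive.  Two normals are marker false positives.
    SPSB4 is the least frequently positive marker, as observed in serum.
    """
    rows = []
    for i in range(47):
        meth = i < 23
        k = (1 + i % 4) if meth else 0  # SPSB4 (last combo element) rare
        row_markers = _rows_with_marker_count(1, [k])[0] if meth else {
            m: False for m in _MARKERS
        }
        rows.append({**row_markers, "kras": 9 <= i <= 31, "truth": "cancer"})
    for j in range(14):
        pos = j < 2
        rows.append(
            {**{m: (pos and m == ("PCDH10" if j == 0 else "SEMA5A")) for m in _MARKERS},
             "kras": False, "truth": "non-cancer"}
        )
    idx = [f"PC{i:03d}" for i in range(47)] + [f"NV{j:03d}" for j in range(14)]
    return pd.DataFrame(rows, index=idx)


def paired_fna_cfdna_calls() -> tuple[pd.DataFrame, pd.DataFrame]:
    """29 paired samples: tissue all positive, 19 cfDNA positive (combined)."""
    idx = [f"P{i:03d}" for i in range(29)]
    tissue = pd.DataFrame(
        _rows_with_marker_count(29, [2 + (i % 4) for i in range(29)]), index=idx
    )
    tissue["kras"] = True
    tissue["truth"] = "cancer"
    cf_rows = []
    for i in range(29):
        pos = i < 19
        meth = pos and i % 3 != 0  # some positives are KRAS-only
        k = (1 + i % 3) if meth else 0
        row = _rows_with_marker_count(1, [k], start_offset=i)[0]
        cf_rows.append({**row, "kras": pos and (i % 3 == 0 or i % 2 == 0),
                        "truth": "cancer"})
    cfdna = pd.DataFrame(cf_rows, index=idx)
    return tissue, cfdna
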