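"""TSV readers/writers for the pipeline's tabular formats.

Formats:

* beta matrix — TSV, first column ``probe_id``, remaining columns one per
  sample, values in [0, 1] or empty for missing;
* probe annotation — TSV with columns probe_id, chromosome, gene,
  cpg_island, snp_overlap, problematic;
* droplet wells — TSV with columns sample, assay, total_droplets,
  positive_droplets (optional droplet_volume_nl);
* call table — TSV with a sample column, 0/1 marker columns, kras
  (0/1/empty for unknown) and truth.
"""

from __future__ import annotations

import pandas as pd

from .ddpcr import DEFAULT_DROPLET_VOLUME_NL, DropletWell

ANNOTATION_COLUMNS = ["chromosome", "gene", "cpg_island", "snp_overlap", "problematic"]


def read_beta_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise ValueError(f"{path}: duplicate probe or sample identifiers")
    bad = ((df < 0) | (df > 1)).any().any()
    if bad:
        raise ValueError(f"{path}: beta-values outside [0, 1]")
    return df


def write_beta_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="probe_id")


def read_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: annotation lacks columns {missing}")
    for c in ("cpg_island", "snp_overlap", "problematic"):
        df[c] = df[c].astype(bool)
    df["gene"] = df["gene"].fillna("")
    return df


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, sep="\t", index_label="probe_id")


def read_wells(path) -> list[DropletWell]:
    df = pd.read_csv(path, sep="\t")
    wells = []
    for _, row in df.iterrows():
        wells.append(
            DropletWell(
                sample=str(row["sample"]),
                assay=str(row["assay"]),
                total_droplets=int(row["total_droplets"]),
                positive_droplets=int(row["positive_droplets"]),
                droplet_volume_nl=float(
                    row.get("droplet_volume_nl", DEFAULT_DROPLET_VOLUME_NL)
                ),
            )
        )
    return wells


def write_wells(wells, path) -> None:
    pd.DataFrame(
        [
            {
                "sample": w.sample,
                "assay": w.assay,
                "total_droplets": w.total_droplets,
                "positive_droplets": w.positive_droplets,
                "droplet_volume_nl": w.droplet_volume_nl,
            }
            for w in wells
        ]
    ).to_csv(path, sep="\t", index=False)


def read_call_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    for c in df.columns:
        if c in ("truth",):
            continue
        if c == "kras":
            df[c] = df[c].map({1: True, 0: False, 1.0: True, 0.0: False})
        else:
            df[c] = df[c].astype(bool)
    return df


def write_call_table(table: pd.DataFrame, path) -> None:
    out = table.copy()
    for c in out.columns:
        if c == "truth":
            continue
        out[c] = out[c].map(lambda v: "" if pd.isna(v) else int(bool(v)))
    out.to_csv(path, sep="\t", index_label="sample")
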