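"""Diagnostic performance on the worked-example call tables.

Builds the synthetic reconstructions of the study's call tables (validation
tissue cohort, TCGA-style cohort, cfDNA cohort, paired FNA-cfDNA set),
writes them as TSV under results/data/, applies the diagnostic rules and
reports sensitivity/specificity plus the paired tissue-cfDNA concordance.
Also runs the droplet-level round trip: the cfDNA call table is encoded
into simulated droplet wells, quantified back through the Poisson/
calibration pipeline, and the decoded calls are checked against the table.
Writes results/diagnostic_performance.json.
"""

import dataclasses
import json
from pathlib import Path

from mbdpanel import classify as clf
from mbdpanel import ddpcr, fixtures, io, roc, synthetic

ROOT = Path(__file__).resolve().parent.parent / "results"
DATA = ROOT / "data"


def report_dict(table, rule):
    r = clf.performance(clf.classify(table, rule), table["truth"], marker_table=table)
    return dataclasses.asdict(r)


def droplet_round_trip(table):
    """Encode calls as wells, decode via quantification; count mismatches."""
    cohort = synthetic.simulate_cfdna_cohort(call_matrix=table, seed=99)
    panel = roc.MarkerPanel()
    models = {
        g: ddpcr.CalibrationModel(g, *coef)
        for g, coef in ddpcr.REFERENCE_CALIBRATIONS.items()
    }
    mismatches = 0
    for sample, wells in cohort.marker_wells.items():
        for marker, well in wells.items():
            decoded = ddpcr.call_methylation(
                models[marker], well, panel.cutoffs[marker]
            )
            mismatches += decoded != bool(table.loc[sample, marker])
        wt, mut = cohort.kras_wells[sample]
        decoded_kras = ddpcr.call_kras(wt, mut).positive
        mismatches += decoded_kras != bool(table.loc[sample, "kras"])
    return mismatches


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    validation = fixtures.validation_tissue_calls()
    tcga = fixtures.tcga_calls()
    cfdna = fixtures.cfdna_calls()
    tissue, paired_cf = fixtures.paired_fna_cfdna_calls()
    for name, t in [("validation_calls", validation), ("tcga_calls", tcga),
                    ("cfdna_calls", cfdna), ("paired_tissue_calls", tissue),
                    ("paired_cfdna_calls", paired_cf)]:
        io.write_call_table(t, DATA / f"{name}.tsv")

    results = {
        "validation_methylation_only": report_dict(validation, "methylation_only"),
        "validation_kras_only": report_dict(validation, "kras_only"),
        "tcga_methylation_only": report_dict(tcga, "methylation_only"),
        "cfdna_methylation_only": report_dict(cfdna, "methylation_only"),
        "cfdna_kras_only": report_dict(cfdna, "kras_only"),
        "cfdna_combined": report_dict(cfdna, "combined"),
        "paired_concordance": dataclasses.asdict(clf.paired_concordance(
            clf.classify(tissue, "combined"), clf.classify(paired_cf, "combined")
        )),
    }

    print("cohort performance (sensitivity% / specificity%):")
    for key in ("validation_methylation_only", "tcga_methylation_only",
                "cfdna_methylation_only", "cfdna_combined"):
        r = results[key]
        print(f"  {key:30s} {r['sensitivity_pct']} / {r['specificity_pct']}")
    print(f"  validation KRAS frequency      "
          f"{results['validation_kras_only']['sensitivity_pct']}%")
    pc = results["paired_concordance"]
    print(f"  paired FNA-cfDNA positivity    "
          f"{pc['n_cfdna_positive_given_tissue_positive']}/{pc['n_tissue_positive']} "
          f"= {pc['concordance_pct']}%")
    tm = results["tcga_methylation_only"]
    print(f"  methylated markers per positive TCGA case: "
          f"{tm['mean_methylated_markers']:.1f} +/- {tm['sd_methylated_markers']:.1f}")

    mismatches = droplet_round_trip(cfdna)
    results["cfdna_droplet_round_trip_mismatches"] = mismatches
    print(f"droplet-level round trip of the cfDNA table: {mismatches} mismatched calls")

    (ROOT / "diagnostic_performance.json").write_text(json.dumps(results, indent=2))
    print(f"wrote {ROOT / 'diagnostic_performance.json'}")


if __name__ == "__main__":
    main()
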