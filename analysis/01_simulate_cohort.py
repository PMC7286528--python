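"""Simulate the methylation-array study inputs.

Generates a seeded beta-value cohort emulating the study design — 37
pancreatic tumors, 3 normal pancreatic tissues, 95 normal whole-blood
samples, and nine other cancer types — with five planted pancreas-specific
marker genes plus decoy genes (shared across a few cancer types, pan-cancer,
and blood-methylated), and writes the matrices, annotation and ground truth
under results/data/.
"""

import json
from pathlib import Path

from mbdpanel import io, synthetic

OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    spec = synthetic.CohortSpec(seed=20200610)
    result = synthetic.simulate_beta_cohort(spec)
    OUT.mkdir(parents=True, exist_ok=True)
    for group, mat in result.matrices.items():
        io.write_beta_matrix(mat, OUT / f"beta_{group}.tsv")
    io.write_annotation(result.annotation, OUT / "annotation.tsv")
    truth = {
        "markers": result.truth_markers,
        "shared": result.truth_shared,
        "pan_cancer": result.truth_pan_cancer,
        "blood": result.truth_blood,
    }
    (OUT / "truth.json").write_text(json.dumps(truth, indent=2))
    n_samples = sum(m.shape[1] for m in result.matrices.values())
    print(f"simulated {spec.n_probes} probes x {n_samples} samples "
          f"across {len(result.matrices)} groups")
    print(f"planted pancreas-specific markers: {', '.join(result.truth_markers)}")
    print(f"wrote inputs to {OUT}")


if __name__ == "__main__":
    main()
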