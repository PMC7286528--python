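import numpy as np
import pandas as pd
import pytest

from mbdpanel import synthetic


@pytest.fixture
def noiseless_cohort():
    """Small noiseless cohort where every planted signal is exact."""
    spec = synthetic.CohortSpec(
        n_tumor=8,
        n_normal=3,
        n_blood=10,
        other_cancer_types=[(n, 4) for n in
                            ["LUAD", "BLCA", "CRC", "BRCA", "KIRC",
                             "LAML", "LUSC", "SKCM", "STAD"]],
        n_probes=400,
        n_planted_marker_genes=5,
        probes_per_gene=4,
        beta_noise_sd=0.0,
        tumor_meth_beta_mean=0.8,
        background_beta_mean=0.05,
        seed=11,
    )
    return spec, synthetic.simulate_beta_cohort(spec)


@pytest.fixture
def toy_matrix_factory():
    """Random small beta matrices with annotation, for oracle comparisons."""

    def make(seed: int, n_probes: int = 40, n_samples: int = 6):
        rng = np.random.default_rng(seed)
        probes = [f"cg{i:05d}" for i in range(n_probes)]
        mat = pd.DataFrame(
            rng.random((n_probes, n_samples)),
            index=probes,
            columns=[f"s{j}" for j in range(n_samples)],
        )
        genes = [f"G{i // 4:03d}" for i in range(n_probes)]
        annotation = pd.DataFrame(
            {
                "chromosome": rng.choice(
                    ["chr1", "chr2", "chrX", "chrY"], size=n_probes,
                    p=[0.45, 0.45, 0.05, 0.05],
                ),
                "gene": genes,
                "cpg_island": rng.random(n_probes) < 0.6,
                "snp_overlap": rng.random(n_probes) < 0.1,
                "problematic": rng.random(n_probes) < 0.1,
            },
            index=pd.Index(probes, name="probe_id"),
        )
        return mat, annotation, rng

    return make
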