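"""Filtering cascade vs brute-force oracles, boundary semantics, truth recovery."""

import numpy as np
import pandas as pd
import pytest

from mbdpanel import selection
from mbdpanel.selection import SelectionConfig


def oracle_filter_probes(matrix, annotation):
    """Per-probe re-implementation of the reliability filter."""
    kept = []
    for p in matrix.index:
        row = annotation.loc[p]
        if row["problematic"] or row["snp_overlap"]:
            continue
        if row["chromosome"] in ("chrX", "chrY", "X", "Y"):
            continue
        kept.append(p)
    return kept


def oracle_hypermethylated(tumor, normal, annotation, cfg):
    kept = []
    for p in tumor.index:
        t = np.nanmean(tumor.loc[p].to_numpy(dtype=float))
        n = np.nanmean(normal.loc[p].to_numpy(dtype=float))
        if not annotation.loc[p, "cpg_island"]:
            continue
        if n == 0:
            if t > 0:
                kept.append(p)
            continue
        if t / n > cfg.fold_change_min:
            kept.append(p)
    return kept


def oracle_pan_cancer(probes, matrices, cfg):
    kept = []
    for p in probes:
        n = sum(
            np.nanmean(m.loc[p].to_numpy(dtype=float)) > cfg.pan_cancer_mean_beta
            for m in matrices.values()
        )
        if n <= cfg.pan_cancer_max_types:
            kept.append(p)
    return kept


def oracle_blood(probes, blood, cfg):
    return [
        p for p in probes
        if np.nanmean(blood.loc[p].to_numpy(dtype=float)) <= cfg.beta_blood_max
    ]


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
class TestOracleEquivalence:
    def test_filter_probes(self, toy_matrix_factory, seed):
        mat, ann, _ = toy_matrix_factory(seed)
        kept = selection.filter_probes(mat, ann)
        assert list(kept) == oracle_filter_probes(mat, ann)

    def test_hypermethylated(self, toy_matrix_factory, seed):
        cfg = SelectionConfig()
        tumor, ann, rng = toy_matrix_factory(seed)
        normal = pd.DataFrame(
            rng.random(tumor.shape), index=tumor.index, columns=[f"n{j}" for j in range(tumor.shape[1])]
        )
        kept = selection.select_hypermethylated_probes(tumor, normal, ann, cfg)
        assert list(kept) == oracle_hypermethylated(tumor, normal, ann, cfg)

    def test_pan_cancer(self, toy_matrix_factory, seed):
        cfg = SelectionConfig()
        mat, _, rng = toy_matrix_factory(seed)
        panel = {
            f"type{k}": pd.DataFrame(
                rng.random(mat.shape) * 0.4, index=mat.index, columns=mat.columns
            )
            for k in range(6)
        }
        kept = selection.exclude_pan_cancer_probes(mat.index, panel, cfg)
        assert list(kept) == oracle_pan_cancer(mat.index, panel, cfg)

    def test_blood(self, toy_matrix_factory, seed):
        cfg = SelectionConfig()
        mat, _, rng = toy_matrix_factory(seed)
        blood = pd.DataFrame(
            rng.random(mat.shape) * 0.25, index=mat.index, columns=mat.columns
        )
        kept = selection.exclude_blood_probes(mat.index, blood, cfg)
        assert list(kept) == oracle_blood(mat.index, blood, cfg)


def _const_matrix(values, columns=("s1", "s2")):
    """Probe x sample matrix where every sample shares the probe's value."""
    return pd.DataFrame({c: values for c in columns}, dtype=float)


def _island_annotation(index, gene="G1"):
    return pd.DataFrame(
        {
            "chromosome": "chr1",
            "gene": gene,
            "cpg_island": True,
            "snp_overlap": False,
            "problematic": False,
        },
        index=index,
    )


class TestBoundaryStrictness:
    def test_fold_change_exactly_at_threshold_dropped(self):
        tumor = _const_matrix(pd.Series({"p1": 0.23, "p2": 0.22}))
        normal = _const_matrix(pd.Series({"p1": 0.2, "p2": 0.2}))
        ann = _island_annotation(tumor.index)
        kept = selection.select_hypermethylated_probes(tumor, normal, ann)
        # p1: fold 1.15 exactly -> dropped; p2: 1.10 -> dropped
        assert list(kept) == []

    def test_fold_change_just_over_threshold_kept(self):
        tumor = _const_matrix(pd.Series({"p1": 0.8}))
        normal = _const_matrix(pd.Series({"p1": 0.05}))
        ann = _island_annotation(tumor.index)
        assert list(selection.select_hypermethylated_probes(tumor, normal, ann)) == ["p1"]

    def test_pan_cancer_exactly_four_types_kept(self):
        probes = pd.Index(["p1"])
        four = {f"t{k}": _const_matrix(pd.Series({"p1": 0.3})) for k in range(4)}
        five = {**four, "t5": _const_matrix(pd.Series({"p1": 0.3}))}
        assert list(selection.exclude_pan_cancer_probes(probes, four)) == ["p1"]
        assert list(selection.exclude_pan_cancer_probes(probes, five)) == []

    def test_blood_exactly_at_threshold_kept(self):
        blood = _const_matrix(pd.Series({"p1": 0.10, "p2": 0.15}))
        assert list(selection.exclude_blood_probes(blood.index, blood)) == ["p1"]

    def test_gene_frequency_strictly_over_ten_percent(self):
        freq = pd.Series({"A": 10.0, "B": 10.1, "C": 0.0})
        assert selection.select_stable_genes(freq) == ["B"]

    def test_beta_exactly_point_two_not_methylated(self):
        mat = _const_matrix(pd.Series({"p1": 0.2}))
        ann = _island_annotation(mat.index)
        _, freq = selection.gene_frequency(mat, ann)
        assert freq["G1"] == 0.0


class TestGeneAggregation:
    def test_gene_beta_is_max_over_probes(self):
        mat = pd.DataFrame({"s1": [0.1, 0.25]}, index=["p1", "p2"])
        ann = _island_annotation(mat.index)
        gb = selection.gene_beta(mat, ann)
        assert gb.loc["G1", "s1"] == 0.25

    def test_frequency_equals_hand_computation(self):
        # 3 genes x 4 samples; gene beta = max over 2 probes per gene
        rng = np.random.default_rng(12)
        mat = pd.DataFrame(
            rng.random((6, 4)), index=[f"p{i}" for i in range(6)],
            columns=list("abcd"),
        )
        ann = _island_annotation(mat.index)
        ann["gene"] = ["GA", "GA", "GB", "GB", "GC", "GC"]
        _, freq = selection.gene_frequency(mat, ann)
        for g in ("GA", "GB", "GC"):
            probes = ann.index[ann["gene"] == g]
            expected = 100.0 * np.mean(mat.loc[probes].max(axis=0) > 0.2)
            assert freq[g] == pytest.approx(expected)


class TestCascade:
    def test_noiseless_truth_recovery(self, noiseless_cohort):
        _, result = noiseless_cohort
        others = {
            k: v for k, v in result.matrices.items()
            if k not in ("tumor", "normal_pancreas", "normal_blood")
        }
        report = selection.run_cascade(
            result.matrices["tumor"], result.matrices["normal_pancreas"],
            result.matrices["normal_blood"], others, result.annotation,
        )
        recovered = sorted(
            report.candidates.query("specificity_class == 3")["gene"]
        )
        assert recovered == result.truth_markers
        # shared decoys land in classes 1-2, never class 3
        shared_rows = report.candidates[
            report.candidates["gene"].isin(result.truth_shared)
        ]
        assert set(shared_rows["specificity_class"]) <= {1, 2}
        # pan-cancer and blood decoys are filtered out entirely
        assert not set(result.truth_pan_cancer) & set(report.candidates["gene"])
        assert not set(result.truth_blood) & set(report.candidates["gene"])

    def test_stage_counts_non_increasing(self, noiseless_cohort):
        _, result = noiseless_cohort
        others = {
            k: v for k, v in result.matrices.items()
            if k not in ("tumor", "normal_pancreas", "normal_blood")
        }
        report = selection.run_cascade(
            result.matrices["tumor"], result.matrices["normal_pancreas"],
            result.matrices["normal_blood"], others, result.annotation,
        )
        probe_stages = [
            report.stage_counts[k] for k in (
                "input_probes", "after_reliability_filter",
                "after_hypermethylation_filter", "after_pan_cancer_filter",
                "after_blood_filter",
            )
        ]
        assert probe_stages == sorted(probe_stages, reverse=True)
        assert report.stage_counts["classified_candidates"] <= report.stage_counts["stable_genes"]

    def test_user_exclusion_list_removes_genes(self, noiseless_cohort):
        _, result = noiseless_cohort
        others = {
            k: v for k, v in result.matrices.items()
            if k not in ("tumor", "normal_pancreas", "normal_blood")
        }
        drop = result.truth_markers[0]
        report = selection.run_cascade(
            result.matrices["tumor"], result.matrices["normal_pancreas"],
            result.matrices["normal_blood"], others, result.annotation,
            exclude_genes=[drop],
        )
        assert drop not in set(report.candidates["gene"])

    def test_empty_tumor_cohort_rejected(self, noiseless_cohort):
        _, result = noiseless_cohort
        empty = result.matrices["tumor"].iloc[:, :0]
        with pytest.raises(ValueError, match="empty"):
            selection.run_cascade(
                empty, result.matrices["normal_pancreas"],
                result.matrices["normal_blood"], {}, result.annotation,
            )

    def test_probe_without_annotation_named_in_error(self, toy_matrix_factory):
        mat, ann, _ = toy_matrix_factory(0)
        with pytest.raises(ValueError, match="cg00000000"):
            selection.filter_probes(
                mat.rename(index={mat.index[0]: "cg00000000"}), ann
            )

    def test_all_flagged_probes_yield_empty_set(self, toy_matrix_factory, caplog):
        mat, ann, _ = toy_matrix_factory(0)
        ann["problematic"] = True
        with caplog.at_level("WARNING"):
            kept = selection.filter_probes(mat, ann)
        assert len(kept) == 0
        assert any("removed" in r.message for r in caplog.records)


def test_missing_values_excluded_from_means():
    tumor = pd.DataFrame({"s1": [0.8, np.nan], "s2": [np.nan, np.nan]},
                         index=["p1", "p2"], dtype=float)
    normal = pd.DataFrame({"n1": [0.05, 0.05]}, index=["p1", "p2"], dtype=float)
    ann = _island_annotation(tumor.index)
    kept = selection.select_hypermethylated_probes(tumor, normal, ann)
    # p1 passes on its single observed value; all-missing p2 is dropped
    assert list(kept) == ["p1"]
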