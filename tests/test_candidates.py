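"""Recurrence, filtering, expression association and FDR selection."""

import numpy as np
import pandas as pd
import pytest

from silopt import candidates as cand
from silopt.candidates import (
    adjust_and_select,
    cooccurrence_check,
    filter_candidates,
    find_recurrent,
    flag_splicing_overlap,
    run_candidate_screen,
)

# accessed via the module so pytest does not collect the library function
expression_association = cand.test_expression_association
from silopt.simulate import simulate_candidate_study


def mutation_rows(entries):
    rows = []
    for gene, sample, ct, pos, alt, score in entries:
        rows.append(
            {"gene": gene, "transcript_id": f"TX_{gene}", "cds_pos": pos,
             "ref_base": "C", "alt_base": alt, "sample_id": sample,
             "cancer_type": ct, "variant_class": "silent", "score": score}
        )
    return pd.DataFrame(rows)


class TestFindRecurrent:
    def test_three_distinct_samples_required(self):
        three = mutation_rows(
            [("G1", f"S{i}", "OV", 6, "T", -11.0) for i in range(3)]
        )
        two = mutation_rows(
            [("G2", f"S{i}", "OV", 9, "T", -11.0) for i in range(2)]
        )
        out = find_recurrent(pd.concat([three, two], ignore_index=True))
        assert list(out["gene"]) == ["G1"]
        assert out.iloc[0]["n_samples_total"] == 3

    def test_different_alt_alleles_are_distinct_keys(self):
        df = mutation_rows(
            [("G1", f"S{i}", "OV", 6, "T", -11.0) for i in range(2)]
            + [("G1", f"S{i}", "OV", 6, "A", 5.0) for i in range(2, 4)]
        )
        assert len(find_recurrent(df, min_samples=2)) == 2

    def test_pooled_vs_per_cancer_type(self):
        df = mutation_rows(
            [("G1", "S1", "OV", 6, "T", -11.0),
             ("G1", "S2", "OV", 6, "T", -11.0),
             ("G1", "S3", "BRCA", 6, "T", -11.0)]
        )
        assert len(find_recurrent(df)) == 1  # pooled: 3 samples
        assert len(find_recurrent(df, per_cancer_type=True)) == 0

    def test_duplicate_sample_rows_collapsed(self):
        df = mutation_rows(
            [("G1", "S1", "OV", 6, "T", -11.0)] * 3
            + [("G1", "S2", "OV", 6, "T", -11.0)]
        )
        out = find_recurrent(df, min_samples=2)
        assert out.iloc[0]["n_samples_total"] == 2


class TestFilterCandidates:
    @pytest.mark.parametrize(
        "score, kept", [(-11.4, True), (10.0, True), (9.9, False), (-10.0, True)]
    )
    def test_abs_score_boundary(self, score, kept):
        df = pd.DataFrame({"score": [score]})
        assert len(filter_candidates(df)) == (1 if kept else 0)

    def test_order_insensitive_with_recurrence(self):
        df = mutation_rows(
            [("G1", f"S{i}", "OV", 6, "T", -11.0) for i in range(3)]
            + [("G2", f"S{i}", "OV", 9, "T", -5.0) for i in range(3)]
            + [("G3", "S1", "OV", 3, "T", -20.0)]
        )
        a = filter_candidates(find_recurrent(df))
        b = find_recurrent(df[df["score"].abs() >= 10])
        assert sorted(a["gene"]) == sorted(b["gene"]) == ["G1"]


class TestSplicingFlag:
    INTERVALS = pd.DataFrame({"seq_id": ["TX1"], "start": [10], "end": [20]})

    @pytest.mark.parametrize(
        "pos, flagged",
        [(11, True), (20, True), (21, False), (10, False), (5, False)],
    )
    def test_half_open_convention(self, pos, flagged):
        # BED half-open [10, 20): 0-based 10..19 = 1-based 11..20
        df = pd.DataFrame({"transcript_id": ["TX1"], "cds_pos": [pos]})
        assert flag_splicing_overlap(df, self.INTERVALS).iloc[0] == flagged

    def test_empty_intervals(self):
        df = pd.DataFrame({"transcript_id": ["TX1"], "cds_pos": [11]})
        assert not flag_splicing_overlap(df, self.INTERVALS.iloc[:0]).any()


def expression_fixture(rng, n_samples=220, shift=0.0, n_mut=20, base=1.5):
    samples = [f"S{i}" for i in range(n_samples)]
    mutated = samples[:n_mut]
    log_tpm = rng.normal(base, 0.3, size=n_samples)
    log_tpm[:n_mut] += shift
    expr = pd.DataFrame([10.0 ** log_tpm], index=["G1"], columns=samples)
    return expr, {s: "OV" for s in samples}, mutated


class TestExpressionAssociation:
    def test_planted_downshift_detected(self, rng):
        expr, types, mutated = expression_fixture(rng, shift=-0.5)
        res = expression_association("G1", mutated, expr, types, "OV")
        assert res["p_value"] < 0.01
        assert res["direction"] == "down"
        assert res["n_mut"] == 20 and res["n_wt"] == 200

    def test_null_is_not_significant_at_fixed_seed(self):
        rng = np.random.default_rng(99)
        expr, types, mutated = expression_fixture(rng, shift=0.0)
        res = expression_association("G1", mutated, expr, types, "OV")
        assert res["p_value"] > 0.05

    def test_mean_tpm_boundary_passes_filter(self):
        samples = [f"S{i}" for i in range(10)]
        expr = pd.DataFrame([[10.0] * 10], index=["G1"], columns=samples)
        types = {s: "OV" for s in samples}
        res = expression_association(
            "G1", samples[:3], expr, types, "OV", pseudocount=0.0
        )
        assert res["mean_log_tpm"] == pytest.approx(1.0)
        assert res["expression_filter_passed"]

    def test_gene_absent_skipped_with_warning(self, rng):
        expr, types, mutated = expression_fixture(rng)
        with pytest.warns(UserWarning, match="G2"):
            assert expression_association("G2", mutated, expr, types, "OV") is None

    def test_too_few_mutated_samples_filtered(self, rng):
        expr, types, mutated = expression_fixture(rng)
        assert (
            expression_association("G1", mutated[:2], expr, types, "OV") is None
        )


class TestAdjustAndSelect:
    @staticmethod
    def results(p_values, cancer_type="OV"):
        return pd.DataFrame(
            {"gene": [f"G{i}" for i in range(len(p_values))],
             "cancer_type": cancer_type, "p_value": p_values,
             "expression_filter_passed": True}
        )

    def test_closed_form_example(self):
        out = adjust_and_select(self.results([0.001, 0.5]))
        assert out["fdr"].tolist() == pytest.approx([0.002, 0.5])
        assert out["passed"].tolist() == [True, False]

    def test_all_p_one_none_pass(self):
        out = adjust_and_select(self.results([1.0, 1.0, 1.0]))
        assert not out["passed"].any()

    def test_expression_filter_blocks_pass(self):
        res = self.results([0.001])
        res["expression_filter_passed"] = False
        assert not adjust_and_select(res)["passed"].any()

    def test_per_cancer_type_family(self):
        res = pd.concat(
            [self.results([0.01, 0.04], "OV"), self.results([0.03], "BRCA")],
            ignore_index=True,
        )
        out = adjust_and_select(res, family="per_cancer_type")
        brca = out[out["cancer_type"] == "BRCA"]
        assert brca["fdr"].iloc[0] == pytest.approx(0.03)

    def test_empty_input(self):
        out = adjust_and_select(self.results([]))
        assert out.empty


class TestCooccurrence:
    @staticmethod
    def cohort(missense_samples, nonsense_samples=()):
        rows = [
            {"gene": "G1", "transcript_id": "TX1", "cds_pos": 30, "ref_base": "G",
             "alt_base": "A", "sample_id": s, "variant_class": "missense"}
            for s in missense_samples
        ] + [
            {"gene": "G1", "transcript_id": "TX1", "cds_pos": 60, "ref_base": "C",
             "alt_base": "A", "sample_id": s, "variant_class": "nonsense"}
            for s in nonsense_samples
        ]
        return pd.DataFrame(rows)

    def test_all_samples_cooccur(self):
        flags = cooccurrence_check(["S1", "S2", "S3"], "G1",
                                   self.cohort(["S1", "S2", "S3"]))
        assert flags["all_cooccur"] and flags["recurrent_cooccur"]

    def test_one_sample_without_missense(self):
        flags = cooccurrence_check(["S1", "S2", "S3"], "G1",
                                   self.cohort(["S1", "S2"]))
        assert not flags["all_cooccur"]

    def test_cooccurring_but_not_recurrent(self):
        cohort = pd.concat(
            [self.cohort(["S1"]),
             self.cohort([]).assign()],
            ignore_index=True,
        )
        # three carriers, each with a *different* missense variant
        rows = [
            {"gene": "G1", "transcript_id": "TX1", "cds_pos": pos, "ref_base": "G",
             "alt_base": "A", "sample_id": s, "variant_class": "missense"}
            for pos, s in [(30, "S1"), (33, "S2"), (36, "S3")]
        ]
        flags = cooccurrence_check(["S1", "S2", "S3"], "G1", pd.DataFrame(rows))
        assert flags["all_cooccur"] and not flags["recurrent_cooccur"]


class TestEndToEndScreen:
    def test_recovers_planted_causal_genes(self):
        mutations, expr, types, truth = simulate_candidate_study(
            seed=123, n_genes=300, n_samples=200, n_causal=5,
            n_null_recurrent=50,
        )
        selected, funnel = run_candidate_screen(mutations, expr, types)
        causal = set(truth.loc[truth["causal"], "gene"])
        passed = set(selected.loc[selected["passed"], "gene"])
        assert len(passed & causal) >= 4  # sensitivity on one seed
        assert funnel["silent_scored"] >= funnel["recurrent_pooled"]
        assert funnel["expression_tested"] >= funnel["fdr_passed"]

    def test_zero_fdr_threshold_passes_nothing(self):
        mutations, expr, types, truth = simulate_candidate_study(
            seed=5, n_genes=100, n_samples=100, n_causal=3, n_null_recurrent=20
        )
        selected, funnel = run_candidate_screen(
            mutations, expr, types, fdr_threshold=0.0
        )
        assert funnel["fdr_passed"] == 0
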