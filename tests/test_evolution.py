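"""Timing labels, timing-stratified score contrasts, conservation controls."""

import numpy as np
import pandas as pd
import pytest

from silopt.evolution import (
    COARSE_TIMING,
    TIMING_CLASSES,
    TsvTrack,
    attach_timing,
    compare_conservation,
    compare_scores_by_timing,
    parse_timing_label,
    sample_cds_control,
)


class TestTimingLabels:
    @pytest.mark.parametrize(
        "raw, canonical, coarse",
        [
            ("clonal [early]", "early_clonal", "early"),
            ("clonal [late]", "late_clonal", "late"),
            ("clonal [NA]", "clonal_NA", "early"),
            ("subclonal", "subclonal", "late"),
        ],
    )
    def test_mutationtimer_strings(self, raw, canonical, coarse):
        assert parse_timing_label(raw) == canonical
        assert COARSE_TIMING[canonical] == coarse

    def test_coarse_mapping_total(self):
        assert set(COARSE_TIMING) == set(TIMING_CLASSES)
        assert set(COARSE_TIMING.values()) == {"early", "late"}

    def test_unknown_label_named_in_error(self):
        with pytest.raises(ValueError, match="wobbly"):
            parse_timing_label("wobbly")


def cohort_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["sample_id", "transcript_id", "cds_pos", "ref_base",
                 "alt_base", "score"],
    )


class TestAttachTiming:
    def test_matched_and_unmatched(self):
        mutations = cohort_frame(
            [["S1", "TX1", 6, "C", "T", -11.4], ["S2", "TX1", 9, "G", "A", 2.0]]
        )
        timing = pd.DataFrame(
            {"sample_id": ["S1"], "transcript_id": ["TX1"], "cds_pos": [6],
             "ref_base": ["C"], "alt_base": ["T"], "timing": ["subclonal"]}
        )
        out = attach_timing(mutations, timing)
        assert out.loc[0, "timing_raw"] == "subclonal"
        assert out.loc[0, "timing_coarse"] == "late"
        assert pd.isna(out.loc[1, "timing_raw"])

    def test_unknown_label_raises(self):
        mutations = cohort_frame([["S1", "TX1", 6, "C", "T", 0.0]])
        timing = pd.DataFrame(
            {"sample_id": ["S1"], "transcript_id": ["TX1"], "cds_pos": [6],
             "ref_base": ["C"], "alt_base": ["T"], "timing": ["bogus"]}
        )
        with pytest.raises(ValueError, match="bogus"):
            attach_timing(mutations, timing)


class TestCompareScoresByTiming:
    @staticmethod
    def frame(scores_by_class):
        rows = []
        for cls, scores in scores_by_class.items():
            for s in scores:
                rows.append({"timing_raw": cls, "score": s})
        return pd.DataFrame(rows)

    def test_identical_singletons_p_one(self):
        report = compare_scores_by_timing(
            self.frame({"early_clonal": [5.0], "subclonal": [5.0]})
        )
        assert report["contrasts"]["p_value"].iloc[0] == pytest.approx(1.0)

    def test_planted_subclonal_shift_recovered(self):
        rng = np.random.default_rng(3)
        scores = {
            cls: rng.normal(-3, 10, size=300) for cls in TIMING_CLASSES[:3]
        }
        scores["subclonal"] = rng.normal(2, 10, size=300)  # +5 shift
        report = compare_scores_by_timing(self.frame(scores))
        summary = report["summary"]
        for cls in TIMING_CLASSES[:3]:
            assert summary.loc["subclonal", "median"] > summary.loc[cls, "median"]
        sub = report["contrasts"]
        sub = sub[(sub["class_a"] == "subclonal") | (sub["class_b"] == "subclonal")]
        assert (sub["fdr"] < 0.05).all()

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            compare_scores_by_timing(self.frame({"subclonal": [1.0, 2.0]}))


class TestSampleCdsControl:
    LENGTHS = {f"TX{i}": 300 for i in range(10)}

    def test_deterministic_under_seed(self):
        a = sample_cds_control(self.LENGTHS, n=1000, seed=7)
        b = sample_cds_control(self.LENGTHS, n=1000, seed=7)
        pd.testing.assert_frame_equal(a.positions, b.positions)

    def test_positions_within_bounds(self):
        control = sample_cds_control({"TX1": 30}, n=10, seed=1)
        assert control.positions["pos"].between(1, 30).all()
        assert (control.positions["seq_id"] == "TX1").all()

    def test_uniform_over_equal_intervals(self):
        n = 100_000
        control = sample_cds_control(self.LENGTHS, n=n, seed=2)
        counts = control.positions["seq_id"].value_counts()
        expected = n / 10
        sd = np.sqrt(n * 0.1 * 0.9)
        assert (np.abs(counts - expected) < 4 * sd).all()
        from scipy.stats import chisquare

        stat, p = chisquare(counts.reindex(self.LENGTHS).to_numpy())
        assert p > 0.001

    def test_empty_intervals_error(self):
        with pytest.raises(ValueError):
            sample_cds_control({}, n=10, seed=0)


def make_mutations(rng, n=300):
    scores = rng.uniform(-30, 30, size=n)
    groups = np.where(scores < -10, "low", np.where(scores >= 10, "high", "mid"))
    return pd.DataFrame(
        {
            "transcript_id": "TX1",
            "cds_pos": np.arange(1, n + 1),
            "score": scores,
            "score_group": groups,
        }
    )


class TestCompareConservation:
    def test_planted_monotone_track_orders_groups(self, rng):
        mutations = make_mutations(rng)
        # conservation decreases with score: low-score group most conserved
        track_df = pd.DataFrame(
            {
                "seq_id": "TX1",
                "pos": mutations["cds_pos"],
                "value": 0.5 - 0.01 * mutations["score"],
            }
        )
        control = sample_cds_control({"TX1": 300}, n=500, seed=3)
        report = compare_conservation(mutations, control, TsvTrack(track_df))
        summary = report["summary"]
        assert summary.loc["low", "median"] > summary.loc["high", "median"]
        assert summary.loc["control", "median"] > summary.loc["high", "median"]
        assert (report["contrasts"]["p_value"] <= 1).all()

    def test_constant_track_all_p_one(self, rng):
        mutations = make_mutations(rng, n=100)
        track_df = pd.DataFrame(
            {"seq_id": "TX1", "pos": np.arange(1, 101), "value": 0.5}
        )
        control = sample_cds_control({"TX1": 100}, n=100, seed=4)
        report = compare_conservation(mutations, control, TsvTrack(track_df))
        assert np.allclose(report["contrasts"]["p_value"], 1.0)

    def test_track_missing_everywhere(self, rng):
        mutations = make_mutations(rng, n=50)
        track_df = pd.DataFrame({"seq_id": ["OTHER"], "pos": [1], "value": [0.5]})
        control = sample_cds_control({"TX1": 50}, n=20, seed=5)
        with pytest.warns(UserWarning):
            report = compare_conservation(mutations, control, TsvTrack(track_df))
        assert report["summary"].empty

    def test_missing_positions_counted_not_zeroed(self, rng):
        mutations = make_mutations(rng, n=50)
        track_df = pd.DataFrame(
            {"seq_id": "TX1", "pos": np.arange(1, 26), "value": 0.5}
        )
        control = sample_cds_control({"TX1": 50}, n=20, seed=6)
        report = compare_conservation(mutations, control, TsvTrack(track_df))
        assert sum(report["n_missing"].values()) > 0
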