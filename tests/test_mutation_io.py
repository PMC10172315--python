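"""MAF reading, codon-change resolution and allele-frequency strata."""

import numpy as np
import pandas as pd
import pytest

from silopt.io import (
    DataIntegrityError,
    MafFormatError,
    genomic_to_cds_pos,
    read_gtf_cds_intervals,
    read_maf,
    resolve_codon_change,
    resolve_cohort,
    stratify_by_af,
)

MAF_HEADER = (
    "Hugo_Symbol\tTumor_Sample_Barcode\tVariant_Classification\t"
    "Transcript_ID\tHGVSc\n"
)


def write_maf(tmp_path, rows, header=MAF_HEADER):
    path = tmp_path / "test.maf"
    path.write_text(header + "".join(rows))
    return path


class TestReadMaf:
    def test_keep_classes_filters(self, tmp_path):
        rows = [
            "G1\tS1\tSilent\tTX1\tc.6C>T\n",
            "G1\tS1\tMissense_Mutation\tTX1\tc.4G>A\n",
            "G1\tS1\tNonsense_Mutation\tTX1\tc.5G>A\n",
        ]
        path = write_maf(tmp_path, rows)
        out = read_maf(path, keep_classes={"silent"})
        assert len(out) == 1
        assert out.iloc[0]["variant_class"] == "silent"
        assert out.iloc[0]["cds_pos"] == 6
        assert (out.iloc[0]["ref_base"], out.iloc[0]["alt_base"]) == ("C", "T")
        assert len(read_maf(path)) == 3

    def test_empty_file_with_header(self, tmp_path):
        out = read_maf(write_maf(tmp_path, []))
        assert len(out) == 0

    def test_missing_mandatory_column(self, tmp_path):
        path = tmp_path / "bad.maf"
        path.write_text("Hugo_Symbol\tTumor_Sample_Barcode\tHGVSc\nG1\tS1\tc.6C>T\n")
        with pytest.raises(MafFormatError, match="Variant_Classification"):
            read_maf(path)

    def test_ambiguous_bases_and_unparseable_rows_dropped(self, tmp_path):
        rows = [
            "G1\tS1\tSilent\tTX1\tc.6C>N\n",
            "G1\tS2\tSilent\tTX1\tnot-hgvs\n",
            "G1\tS3\tSilent\tTX1\tc.6C>T\n",
        ]
        out = read_maf(write_maf(tmp_path, rows))
        assert list(out["sample_id"]) == ["S3"]

    def test_explicit_cds_columns(self, tmp_path):
        header = (
            "Hugo_Symbol\tTumor_Sample_Barcode\tVariant_Classification\t"
            "Transcript_ID\tCDS_Position\tReference_Allele\tTumor_Seq_Allele2\n"
        )
        path = write_maf(tmp_path, ["G1\tS1\tSilent\tTX1\t6\tC\tT\n"], header=header)
        out = read_maf(path)
        assert out.iloc[0]["cds_pos"] == 6

    def test_cancer_type_from_sample_map(self, tmp_path):
        path = write_maf(tmp_path, ["G1\tS1\tSilent\tTX1\tc.6C>T\n"])
        out = read_maf(path, sample_types={"S1": "OV"})
        assert out.iloc[0]["cancer_type"] == "OV"

    def test_round_trip_count_matches_simulator(self, small_cohort, tmp_path):
        path = tmp_path / "sim.maf"
        small_cohort["maf"].to_csv(path, sep="\t", index=False)
        out = read_maf(path)
        assert len(out) == len(small_cohort["truth"])


class TestResolveCodonChange:
    def test_mid_codon_substitution(self):
        change = resolve_codon_change("ATGGGCTAA", 6, "C", "T")
        assert (change.ref_codon, change.alt_codon) == ("GGC", "GGT")
        assert (change.codon_index, change.offset_in_codon) == (2, 3)
        assert not change.not_scoreable

    def test_first_base_boundary(self):
        change = resolve_codon_change("ATGGGCTAA", 1, "A", "G")
        assert (change.codon_index, change.offset_in_codon) == (1, 1)
        assert change.ref_codon == "ATG"
        assert change.alt_codon == "GTG"

    def test_reference_mismatch_carries_gene_and_position(self):
        with pytest.raises(DataIntegrityError, match="MYGENE.*6"):
            resolve_codon_change("ATGGGCTAA", 6, "A", "T", gene="MYGENE")

    def test_stop_codon_flagged_not_scoreable(self):
        change = resolve_codon_change("ATGGGCTAA", 8, "A", "G")  # TAA -> TGA
        assert change.not_scoreable

    def test_out_of_range_position(self):
        with pytest.raises(DataIntegrityError):
            resolve_codon_change("ATGGGCTAA", 10, "A", "G")

    def test_round_trip_recovers_planted_codon_pairs(self, small_cohort, tmp_path):
        """Simulator -> MAF -> reader -> resolution reproduces every
        planted codon pair."""
        truth = small_cohort["truth"]
        path = tmp_path / "sim.maf"
        small_cohort["maf"].to_csv(path, sep="\t", index=False)
        read = read_maf(path)
        resolved = resolve_cohort(read, small_cohort["cds"])
        key = ["sample_id", "transcript_id", "cds_pos", "ref_base", "alt_base"]
        merged = resolved.merge(
            truth[key + ["ref_codon", "alt_codon"]], on=key,
            suffixes=("", "_truth"),
        )
        assert len(merged) == len(truth)
        assert (merged["ref_codon"] == merged["ref_codon_truth"]).all()
        assert (merged["alt_codon"] == merged["alt_codon_truth"]).all()


class TestStratifyByAf:
    @pytest.mark.parametrize(
        "af, stratum", [(0.05, "high_af"), (0.01, "high_af"), (0.001, "low_af")]
    )
    def test_threshold_boundary(self, af, stratum):
        out = stratify_by_af(pd.DataFrame({"af": [af]}))
        assert out["af_stratum"].iloc[0] == stratum

    def test_partition_property(self, rng):
        df = pd.DataFrame({"af": rng.uniform(size=500)})
        out = stratify_by_af(df, threshold=0.3)
        n_high = (out["af_stratum"] == "high_af").sum()
        n_low = (out["af_stratum"] == "low_af").sum()
        assert n_high + n_low == len(df)
        assert (out.loc[out["af"] >= 0.3, "af_stratum"] == "high_af").all()

    def test_invalid_af_error(self):
        with pytest.raises(ValueError):
            stratify_by_af(pd.DataFrame({"af": [1.5]}))


class TestGenomicPath:
    GTF = (
        'chr1\tx\tCDS\t101\t106\t.\t+\t0\tgene_id "g1"; transcript_id "tp";\n'
        'chr1\tx\tCDS\t201\t206\t.\t+\t0\tgene_id "g1"; transcript_id "tp";\n'
        'chr1\tx\tCDS\t301\t306\t.\t-\t0\tgene_id "g2"; transcript_id "tm";\n'
        'chr1\tx\tCDS\t401\t406\t.\t-\t0\tgene_id "g2"; transcript_id "tm";\n'
    )

    def test_plus_strand_mapping(self, tmp_path):
        path = tmp_path / "a.gtf"
        path.write_text(self.GTF)
        iv = read_gtf_cds_intervals(path)
        assert genomic_to_cds_pos(iv, "tp", 101) == 1
        assert genomic_to_cds_pos(iv, "tp", 106) == 6
        assert genomic_to_cds_pos(iv, "tp", 201) == 7

    def test_minus_strand_mapping(self, tmp_path):
        path = tmp_path / "a.gtf"
        path.write_text(self.GTF)
        iv = read_gtf_cds_intervals(path)
        # translation starts at the highest genomic coordinate
        assert genomic_to_cds_pos(iv, "tm", 406) == 1
        assert genomic_to_cds_pos(iv, "tm", 401) == 6
        assert genomic_to_cds_pos(iv, "tm", 306) == 7

    def test_position_outside_cds(self, tmp_path):
        path = tmp_path / "a.gtf"
        path.write_text(self.GTF)
        iv = read_gtf_cds_intervals(path)
        with pytest.raises(ValueError):
            genomic_to_cds_pos(iv, "tp", 150)
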