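import json

import numpy as np
import pandas as pd
import pytest

from mrforge import (ConfigurationError, InputError, MREstimate,
                     map_positions_to_ids, read_report, read_summary_stats,
                     write_report)
from mrforge.sumstats_io import COLUMNS, SummaryStatsTable

from conftest import make_table

STD_MAP = {"snp_id": "variant_id", "chrom": "chromosome",
           "pos": "base_pair_location", "effect_allele": "effect_allele",
           "other_allele": "other_allele", "eaf": "effect_allele_frequency",
           "beta": "beta", "se": "standard_error", "pvalue": "p_value", "n": "n"}


def write_tsv(path, rows, header=None, sep="\t"):
    header = header or list(STD_MAP.values())
    lines = [sep.join(header)]
    lines += [sep.join(str(v) for v in row) for row in rows]
    path.write_text("\n".join(lines) + "\n")


GOOD_ROWS = [
    ["rs1", "1", 1000, "A", "G", 0.3, 0.1, 0.01, 1e-10, 50000],
    ["rs2", "2", 2000, "T", "C", 0.4, -0.05, 0.02, 0.012, 50000],
    ["rs3", "3", 3000, "G", "A", 0.1, 0.2, 0.05, 6.3e-5, 50000],
]


class TestReadSummaryStats:
    def test_well_formed_file_ingested_identically(self, tmp_path):
        f = tmp_path / "sumstats.tsv"
        write_tsv(f, GOOD_ROWS)
        t = read_summary_stats(f, STD_MAP, "quantitative")
        assert len(t) == 3
        assert list(t.df["snp_id"]) == ["rs1", "rs2", "rs3"]
        assert t.df["beta"].tolist() == [0.1, -0.05, 0.2]
        assert t.validation.n_dropped == 0

    @pytest.mark.parametrize("sep", ["\t", ",", " "])
    def test_delimiter_autodetected(self, tmp_path, sep):
        f = tmp_path / "x.txt"
        write_tsv(f, GOOD_ROWS, sep=sep)
        assert len(read_summary_stats(f, STD_MAP, "quantitative")) == 3

    @pytest.mark.parametrize("bad_row, reason", [
        (["rsX", "1", 500, "A", "G", 0.3, 0.1, 0.0, 1e-5, 1000], "nonpositive_se"),
        (["rsX", "1", 500, "A", "G", 0.3, 0.1, 0.01, 0.0, 1000], "pvalue_out_of_range"),
        (["rsX", "1", 500, "A", "G", 1.3, 0.1, 0.01, 1e-5, 1000], "eaf_out_of_range"),
        (["rsX", "1", 500, "A", "A", 0.3, 0.1, 0.01, 1e-5, 1000], "identical_alleles"),
        (["rsX", "1", 500, "A", "N", 0.3, 0.1, 0.01, 1e-5, 1000], "invalid_alleles"),
    ])
    def test_invalid_rows_dropped_and_counted(self, tmp_path, bad_row, reason):
        f = tmp_path / "x.tsv"
        write_tsv(f, GOOD_ROWS + [bad_row])
        t = read_summary_stats(f, STD_MAP, "quantitative")
        assert len(t) == 3
        assert t.validation.drop_counts == {reason: 1}

    def test_validation_never_alters_retained_values(self, tmp_path):
        f = tmp_path / "x.tsv"
        write_tsv(f, GOOD_ROWS + [["rsX", "1", 500, "A", "G", 0.3, 0.1, -1, 1e-5, 10]])
        t = read_summary_stats(f, STD_MAP, "quantitative")
        assert t.df["se"].tolist() == [0.01, 0.02, 0.05]

    def test_missing_required_column_is_configuration_error(self, tmp_path):
        f = tmp_path / "x.tsv"
        write_tsv(f, GOOD_ROWS)
        bad = {k: v for k, v in STD_MAP.items() if k != "beta"}
        with pytest.raises(ConfigurationError, match="beta"):
            read_summary_stats(f, bad, "quantitative")

    def test_mapped_column_absent_from_file_names_it(self, tmp_path):
        f = tmp_path / "x.tsv"
        write_tsv(f, GOOD_ROWS)
        bad = dict(STD_MAP, beta="effect_size")
        with pytest.raises(ConfigurationError, match="effect_size"):
            read_summary_stats(f, bad, "quantitative")

    def test_empty_file_is_input_error(self, tmp_path):
        f = tmp_path / "x.tsv"
        write_tsv(f, [])
        with pytest.raises((InputError, Exception)):
            read_summary_stats(f, STD_MAP, "quantitative")

    def test_truncated_pvalue_warns_but_keeps_row(self, tmp_path):
        # beta/se give z≈10 (p~1e-23) but the file says p=1e-300
        f = tmp_path / "x.tsv"
        write_tsv(f, [["rs1", "1", 1, "A", "G", 0.3, 0.1, 0.01, 0.9, 100]])
        t = read_summary_stats(f, STD_MAP, "quantitative")
        assert len(t) == 1
        assert t.validation.n_pvalue_inconsistent == 1

    def test_duplicate_ids_rejected_or_deduped_by_policy(self, tmp_path):
        rows = GOOD_ROWS + [["rs1", "1", 1000, "A", "G", 0.3, 0.5, 0.01, 1e-20, 500]]
        f = tmp_path / "x.tsv"
        write_tsv(f, rows)
        with pytest.raises(InputError, match="rs1"):
            read_summary_stats(f, STD_MAP, "quantitative")
        t = read_summary_stats(f, STD_MAP, "quantitative", dedup_policy="min_p")
        assert len(t) == 3
        assert t.df.loc[t.df.snp_id == "rs1", "beta"].item() == 0.5  # smaller p kept


class TestRoundTrip:
    def test_table_write_read_is_identity(self, tmp_path):
        t = make_table(beta=[0.123456789012, -1e-7], se=[0.01, 0.02],
                       pvalue=[1e-10, 0.5])
        f = tmp_path / "t.tsv"
        t.write(f)
        back = read_summary_stats(
            f, {c: c for c in COLUMNS}, "quantitative")
        for col in ("beta", "se", "pvalue", "eaf", "n"):
            np.testing.assert_allclose(back.df[col], t.df[col], rtol=1e-10)
        assert list(back.df["snp_id"]) == list(t.df["snp_id"])

    def test_estimates_round_trip_tsv_and_json(self, tmp_path):
        est = MREstimate("ivw_fixed", beta=-0.08338160893905101, se=0.0664,
                         ci_low=-0.2135, ci_high=0.0467, pvalue=0.186,
                         n_snps=150, or_scale=(0.92, 0.8078, 1.0478))
        write_report([est], tmp_path / "r.tsv", format="tsv")
        back = read_report(tmp_path / "r.tsv")
        assert np.isclose(back["beta"][0], est.beta, rtol=1e-10)
        assert np.isclose(back["or"][0], 0.92, rtol=1e-10)

        write_report([est], tmp_path / "r.json", format="json")
        objs = read_report(tmp_path / "r.json", format="json")
        assert len(objs) == 1 and objs[0]["method"] == "ivw_fixed"
        assert objs[0]["beta"] == est.beta

    def test_empty_results_error(self, tmp_path):
        with pytest.raises(InputError):
            write_report([], tmp_path / "r.tsv")


class TestMapPositionsToIds:
    def test_lookup_hit_miss_and_empty(self):
        t = make_table(snp_id=["x1", "x2"], chrom=["1", "1"], pos=[1000, 2000],
                       effect_allele=["A", "T"], other_allele=["G", "C"])
        lookup = {("1", 1000, "A", "G"): "rs111"}
        out = map_positions_to_ids(t, lookup)
        assert list(out.df["snp_id"]) == ["rs111", "1:2000:T:C"]
        allmiss = map_positions_to_ids(t, {})
        assert list(allmiss.df["snp_id"]) == ["1:1000:A:G", "1:2000:T:C"]

    def test_swapped_allele_key_still_hits(self):
        t = make_table(snp_id=["x1"], chrom=["1"], pos=[1000],
                       effect_allele=["A"], other_allele=["G"])
        out = map_positions_to_ids(t, {("1", 1000, "G", "A"): "rs9"})
        assert out.df["snp_id"].item() == "rs9"
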