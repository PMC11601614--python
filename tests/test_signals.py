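"""Signal-table loading, GenTrain filtering, whitelists and subsetting."""

import numpy as np
import pandas as pd
import pytest

from arraycnv.regions import RegionSpec
from arraycnv.signals import (
    SignalPanel,
    apply_gentrain_filter,
    read_signal_table,
    read_variant_whitelist,
    subset_panel,
)

from conftest import make_panel


class TestReadSignalTable:
    def test_identity_parse(self, tmp_path, signal_table_text):
        path = tmp_path / "toy.tsv"
        path.write_text(signal_table_text)
        panel = read_signal_table(path)
        assert len(panel) == 3
        assert panel.samples == ["A"]
        assert panel.load_report.raw_rows == 3
        assert panel.load_report.dropped_rows == 0
        rec = panel.records
        assert rec.loc[rec["snp_id"] == "rs2", "baf"].item() == pytest.approx(0.98)

    def test_out_of_range_baf_dropped_and_reported(self, tmp_path, signal_table_text):
        path = tmp_path / "bad.tsv"
        path.write_text(signal_table_text + "rs4\tchr1\t100400\tA\t1.2\t0.0\t0.9\n")
        panel = read_signal_table(path)
        assert len(panel) == 3
        assert panel.load_report.dropped_rows == 1
        assert panel.load_report.drop_reasons["baf_out_of_range"] == 1

    def test_unparseable_values_dropped_missing_kept(self, tmp_path):
        path = tmp_path / "mixed.tsv"
        path.write_text(
            "snpID\tchromosome\tposition\tsampleID\tBAF\tLRR\tGenTrain_Score\n"
            "rs1\tchr1\t100\tA\t0.5\t0.0\t0.9\n"
            "rs2\tchr1\t200\tA\t\t0.1\t0.9\n"      # missing BAF: kept as NaN
            "rs3\tchr1\t300\tA\toops\t0.1\t0.9\n"  # unparseable BAF: dropped
            "rs4\tchr1\t-5\tA\t0.5\t0.1\t0.9\n"    # invalid position: dropped
        )
        panel = read_signal_table(path)
        assert len(panel) == 2
        assert panel.load_report.parsed_rows + panel.load_report.dropped_rows == 4
        rec = panel.records
        assert np.isnan(rec.loc[rec["snp_id"] == "rs2", "baf"].item())

    def test_missing_lrr_column_is_fatal(self, tmp_path):
        path = tmp_path / "nolrr.tsv"
        path.write_text("snpID\tchromosome\tposition\tsampleID\tBAF\nrs1\tchr1\t1\tA\t0.5\n")
        with pytest.raises(ValueError, match="missing column: lrr"):
            read_signal_table(path)

    def test_empty_file_is_fatal(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("snpID\tchromosome\tposition\tsampleID\tBAF\tLRR\n")
        with pytest.raises(ValueError, match="empty"):
            read_signal_table(path)

    def test_comma_separator_autodetected(self, tmp_path, signal_table_text):
        path = tmp_path / "toy.csv"
        path.write_text(signal_table_text.replace("\t", ","))
        assert len(read_signal_table(path)) == 3


class TestGenTrainFilter:
    def test_below_cutoff_removed_at_cutoff_retained(self):
        panel = make_panel([100, 200, 300], ["A", "B"], gentrain=[0.15, 0.20, 0.9])
        out = apply_gentrain_filter(panel, cutoff=0.2)
        kept = set(out.records["snp_id"])
        assert kept == {"snp1", "snp2"}  # 0.15 removed, 0.20 (== cutoff) retained

    def test_removal_is_per_snp_across_samples(self):
        panel = make_panel([100, 200], ["A", "B"], gentrain=[0.1, 0.9])
        out = apply_gentrain_filter(panel)
        assert out.records.groupby("snp_id")["sample_id"].count().to_dict() == {"snp1": 2}

    def test_missing_score_retained(self):
        panel = make_panel([100, 200], ["A"], gentrain=[np.nan, 0.05])
        out = apply_gentrain_filter(panel, cutoff=0.2)
        assert set(out.records["snp_id"]) == {"snp0"}

    def test_cutoff_zero_is_identity(self):
        panel = make_panel([100, 200, 300], ["A"], gentrain=[0.0, 0.5, 1.0])
        assert apply_gentrain_filter(panel, cutoff=0.0) == panel

    def test_idempotent(self):
        panel = make_panel(np.arange(100, 1100, 100), ["A", "B"],
                           gentrain=np.linspace(0.05, 0.95, 10))
        once = apply_gentrain_filter(panel, cutoff=0.3)
        twice = apply_gentrain_filter(once, cutoff=0.3)
        assert once == twice

    @pytest.mark.parametrize("cutoff", [-0.1, 1.5])
    def test_cutoff_out_of_range(self, cutoff):
        panel = make_panel([100], ["A"])
        with pytest.raises(ValueError):
            apply_gentrain_filter(panel, cutoff=cutoff)


class TestVariantWhitelist:
    def test_bim_keys(self, tmp_path):
        path = tmp_path / "w.bim"
        path.write_text("6 rs1 0 161400000 A G\nchr6 rs2 0 161500000 T C\n")
        wl = read_variant_whitelist(path, "bim")
        assert "rs1" in wl and "rs2" in wl
        assert "6:161400000" in wl and "6:161500000" in wl  # chr prefix normalised

    def test_bim_wrong_column_count(self, tmp_path):
        path = tmp_path / "w.bim"
        path.write_text("6 rs1 0 161400000 A G\n6 rs2 0 161500000 T\n")
        with pytest.raises(ValueError, match=":2"):
            read_variant_whitelist(path, "bim")

    def test_pvar_meta_lines_ignored(self, tmp_path):
        path = tmp_path / "w.pvar"
        path.write_text(
            "##fileformat=PVARv1.0\n"
            "#CHROM\tPOS\tID\tREF\tALT\n"
            "6\t161400000\trs1\tA\tG\n"
        )
        wl = read_variant_whitelist(path, "pvar")
        assert wl.keys == frozenset({"rs1", "6:161400000"})

    def test_pvar_missing_header(self, tmp_path):
        path = tmp_path / "w.pvar"
        path.write_text("6\t161400000\trs1\tA\tG\n")
        with pytest.raises(ValueError):
            read_variant_whitelist(path, "pvar")


class TestSubsetPanel:
    def test_halfopen_boundaries(self, toy_region):
        # buffered interval is [90000, 210000)
        panel = make_panel([89_999, 90_000, 209_999, 210_000], ["A"])
        out = subset_panel(panel, toy_region)
        assert sorted(out.records["position"]) == [90_000, 209_999]

    def test_other_chromosome_dropped(self, toy_region):
        panel = make_panel([100_000, 150_000], ["A"], chromosome="chr2")
        with pytest.raises(ValueError, match="no SNPs"):
            subset_panel(panel, toy_region)

    def test_whitelist_halves_snp_count(self, toy_region, tmp_path):
        positions = np.arange(100_000, 100_010)
        panel = make_panel(positions, ["A", "B"])
        bim = tmp_path / "half.bim"
        bim.write_text(
            "".join(f"1 snp{i} 0 {100_000 + i} A G\n" for i in range(0, 10, 2))
        )
        wl = read_variant_whitelist(bim, "bim")
        out = subset_panel(panel, toy_region, wl)
        assert out.n_snps == panel.n_snps // 2

    def test_subset_is_idempotent(self, toy_region):
        panel = make_panel(np.arange(95_000, 205_000, 1_000), ["A", "B"])
        once = subset_panel(panel, toy_region)
        assert subset_panel(once, toy_region) == once


def test_panel_rejects_duplicate_records():
    df = pd.DataFrame(
        {
            "snp_id": ["rs1", "rs1"],
            "chromosome": "chr1",
            "position": [100, 100],
            "sample_id": ["A", "A"],
            "baf": 0.5,
            "lrr": 0.0,
            "gentrain": 0.9,
        }
    )
    with pytest.raises(ValueError, match="duplicate"):
        SignalPanel(df)
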