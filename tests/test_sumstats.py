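"""Summary-statistic parsing and cross-trait allele harmonization."""

import numpy as np
import pandas as pd
import pytest

from polarpleio import harmonize_and_merge, read_sumstats
from polarpleio.sumstats import TraitScan, read_panel_tsv, write_panel_tsv

from conftest import write_sumstats_file


def scan_from_rows(name, rows):
    df = pd.DataFrame(rows, columns=["id", "chrom", "pos", "ea", "oa", "z"])
    df["pos"] = df["pos"].astype(np.int64)
    return TraitScan(trait_name=name, df=df)


class TestRead:
    def test_z_from_beta_over_se(self, tmp_path):
        path = write_sumstats_file(
            tmp_path / "a.tsv", [("rs1", 1, 1000, "A", "G", 0.1, 0.05)]
        )
        scan = read_sumstats(path, trait_name="a")
        assert scan.df.loc[0, "z"] == pytest.approx(2.0)
        assert scan.df.loc[0, "ea"] == "A"

    def test_nonpositive_se_dropped_and_counted(self, tmp_path):
        path = write_sumstats_file(
            tmp_path / "a.tsv",
            [("rs1", 1, 1000, "A", "G", 0.1, 0.05), ("rs2", 1, 2000, "A", "G", 0.1, 0.0)],
        )
        scan = read_sumstats(path)
        assert len(scan) == 1
        assert scan.n_dropped["se_nonpositive"] == 1

    def test_z_column_passthrough(self, tmp_path):
        path = write_sumstats_file(
            tmp_path / "a.tsv",
            [("rs1", 1, 1000, "A", "G", -1.25)],
            header="snp chr pos ea oa z",
        )
        scan = read_sumstats(path)
        assert scan.df.loc[0, "z"] == -1.25

    def test_missing_mapped_column_named_in_error(self, tmp_path):
        path = write_sumstats_file(
            tmp_path / "a.tsv", [("rs1", 1, 1000, "A", "G", 0.1, 0.05)]
        )
        with pytest.raises(ValueError, match="rsid"):
            read_sumstats(path, column_map={"id": "rsid"})

    def test_zero_parseable_rows_is_hard_error(self, tmp_path):
        path = write_sumstats_file(
            tmp_path / "a.tsv", [("rs1", 1, 1000, "A", "G", 0.1, 0.0)]
        )
        with pytest.raises(ValueError, match="no parseable rows"):
            read_sumstats(path)

    def test_custom_column_names(self, tmp_path):
        path = write_sumstats_file(
            tmp_path / "a.tsv",
            [("rs1", 2, 500, "C", "T", 3.0)],
            header="rsid chrom bp a1 a2 zscore",
        )
        scan = read_sumstats(
            path,
            column_map={
                "id": "rsid", "chrom": "chrom", "pos": "bp",
                "effect_allele": "a1", "other_allele": "a2", "z": "zscore",
            },
        )
        assert scan.df.loc[0, "z"] == 3.0

    def test_duplicate_ids_keep_first(self, tmp_path):
        path = write_sumstats_file(
            tmp_path / "a.tsv",
            [("rs1", 1, 1000, "A", "G", 0.1, 0.05), ("rs1", 1, 1000, "A", "G", 0.2, 0.05)],
        )
        scan = read_sumstats(path)
        assert len(scan) == 1
        assert scan.df.loc[0, "z"] == pytest.approx(2.0)
        assert scan.n_dropped["duplicate_id"] == 1


class TestHarmonize:
    def test_swapped_alleles_flip_sign(self):
        a = scan_from_rows("a", [("rs1", "1", 1000, "A", "G", 2.0)])
        b = scan_from_rows("b", [("rs1", "1", 1000, "G", "A", 1.5)])
        panel = harmonize_and_merge([a, b])
        np.testing.assert_array_equal(panel.Z, [[2.0, -1.5]])

    def test_irreconcilable_alleles_dropped(self):
        a = scan_from_rows(
            "a", [("rs1", "1", 1000, "A", "G", 2.0), ("rs2", "1", 2000, "A", "G", 1.0)]
        )
        b = scan_from_rows(
            "b", [("rs1", "1", 1000, "A", "C", 1.5), ("rs2", "1", 2000, "A", "G", 0.5)]
        )
        panel = harmonize_and_merge([a, b])
        assert panel.variants["id"].tolist() == ["rs2"]

    def test_intersection_only(self):
        a = scan_from_rows(
            "a", [("rs1", "1", 1, "A", "G", 1.0), ("rs2", "1", 2, "A", "G", 2.0)]
        )
        b = scan_from_rows(
            "b", [("rs2", "1", 2, "A", "G", 3.0), ("rs3", "1", 3, "A", "G", 4.0)]
        )
        panel = harmonize_and_merge([a, b])
        assert panel.variants["id"].tolist() == ["rs2"]
        np.testing.assert_array_equal(panel.Z, [[2.0, 3.0]])

    def test_strand_flip_resolved_by_reverse_complement(self):
        a = scan_from_rows("a", [("rs1", "1", 1, "A", "G", 2.0)])
        b = scan_from_rows("b", [("rs1", "1", 1, "T", "C", 1.0)])  # other strand
        panel = harmonize_and_merge([a, b])
        np.testing.assert_array_equal(panel.Z, [[2.0, 1.0]])
        # swapped on the other strand flips the sign
        c = scan_from_rows("c", [("rs1", "1", 1, "C", "T", 1.0)])
        panel = harmonize_and_merge([a, c])
        np.testing.assert_array_equal(panel.Z, [[2.0, -1.0]])

    def test_palindromic_flagged_and_optionally_dropped(self):
        a = scan_from_rows(
            "a", [("rs1", "1", 1, "A", "T", 1.0), ("rs2", "1", 2, "A", "G", 2.0)]
        )
        b = scan_from_rows(
            "b", [("rs1", "1", 1, "A", "T", 1.0), ("rs2", "1", 2, "A", "G", 2.0)]
        )
        panel = harmonize_and_merge([a, b])
        assert panel.variants.set_index("id")["ambiguous"].to_dict() == {
            "rs1": True, "rs2": False,
        }
        panel = harmonize_and_merge([a, b], drop_ambiguous=True)
        assert panel.variants["id"].tolist() == ["rs2"]

    def test_empty_intersection_is_hard_error(self):
        a = scan_from_rows("a", [("rs1", "1", 1, "A", "G", 1.0)])
        b = scan_from_rows("b", [("rs2", "1", 2, "A", "G", 1.0)])
        with pytest.raises(ValueError, match="shared"):
            harmonize_and_merge([a, b])

    def test_needs_two_scans(self):
        a = scan_from_rows("a", [("rs1", "1", 1, "A", "G", 1.0)])
        with pytest.raises(ValueError):
            harmonize_and_merge([a])

    def test_merge_order_insensitive_up_to_orientation(self):
        rows_a = [("rs1", "1", 1, "A", "G", 2.0), ("rs2", "1", 2, "C", "T", -1.0)]
        rows_b = [("rs1", "1", 1, "G", "A", 0.5), ("rs2", "1", 2, "C", "T", 1.5)]
        a, b = scan_from_rows("a", rows_a), scan_from_rows("b", rows_b)
        ab = harmonize_and_merge([a, b])
        ba = harmonize_and_merge([b, a])
        # reorient ba to trait a's allele orientation and column order
        sign = np.where(
            ba.variants.set_index("id").loc[ab.variants["id"], "ea"].to_numpy()
            == ab.variants["ea"].to_numpy(),
            1.0,
            -1.0,
        )
        np.testing.assert_allclose(ba.Z[:, ::-1] * sign[:, None], ab.Z)

    def test_row_count_bounded_by_smallest_input(self):
        a = scan_from_rows("a", [(f"rs{i}", "1", i, "A", "G", 0.1) for i in range(1, 30)])
        b = scan_from_rows("b", [(f"rs{i}", "1", i, "A", "G", 0.1) for i in range(10, 50)])
        panel = harmonize_and_merge([a, b])
        assert panel.m <= min(len(a), len(b))


def test_panel_tsv_round_trip_bit_identical(tmp_path, rng):
    from polarpleio.sumstats import MultiTraitZPanel

    m = 50
    Z = rng.standard_normal((m, 3)) * 1.7
    panel = MultiTraitZPanel(
        variants=pd.DataFrame(
            {
                "id": [f"rs{i}" for i in range(m)],
                "chrom": "2",
                "pos": np.arange(1, m + 1),
                "ea": "A",
                "oa": "G",
                "ambiguous": False,
            }
        ),
        trait_names=["x", "y", "w"],
        Z=Z,
    )
    path = tmp_path / "panel.tsv"
    write_panel_tsv(panel, path)
    back = read_panel_tsv(path)
    np.testing.assert_array_equal(back.Z, Z)  # exact, not approx
    assert back.trait_names == ["x", "y", "w"]
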