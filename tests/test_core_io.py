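import io

import numpy as np
import pandas as pd
import pytest

from galldiv import (
    IncidenceMatrix,
    SiteHierarchy,
    aggregate_incidence,
    read_hierarchy,
    read_incidence,
    read_incidence_workbook,
    richness_summary,
    write_hierarchy,
    write_incidence,
)
from galldiv.core_io import HierarchyError, IncidenceFormatError

from conftest import matrix_from_sets, random_incidence


class TestReadIncidence:
    def test_long_layout_counts(self):
        m = read_incidence(io.StringIO("site,species\nP1,sp1\nP1,sp2\nP2,sp2\n"), layout="long")
        assert m.richness.tolist() == [2, 1]
        assert m.gamma == 2
        assert m.site_ids == ["P1", "P2"]

    def test_long_duplicate_occurrence_is_idempotent(self):
        once = read_incidence(io.StringIO("site,species\nP1,sp1\nP2,sp2\n"), layout="long")
        twice = read_incidence(
            io.StringIO("site,species\nP1,sp1\nP1,sp1\nP2,sp2\n"), layout="long"
        )
        pd.testing.assert_frame_equal(once.data, twice.data)

    def test_wide_non_binary_cell_reports_position(self):
        with pytest.raises(IncidenceFormatError, match="'2'.*'P2'.*'sp1'"):
            read_incidence(io.StringIO("site,sp1,sp2\nP1,1,0\nP2,2,1\n"), layout="wide")

    def test_duplicate_site_rows_rejected(self):
        with pytest.raises(IncidenceFormatError, match="duplicate site"):
            read_incidence(io.StringIO("site,sp1\nP1,1\nP1,1\n"), layout="wide")

    def test_empty_file_rejected(self):
        with pytest.raises(IncidenceFormatError, match="empty"):
            read_incidence(io.StringIO(""), layout="wide")

    def test_labels_are_whitespace_trimmed(self):
        m = read_incidence(io.StringIO("site,species\n P1 , sp1 \nP2,sp1\n"), layout="long")
        assert m.site_ids == ["P1", "P2"]
        assert m.species_ids == ["sp1"]

    def test_all_zero_species_dropped_at_read(self):
        m = read_incidence(io.StringIO("site,sp1,sp2\nP1,1,0\nP2,1,0\n"), layout="wide")
        assert m.species_ids == ["sp1"]

    @pytest.mark.parametrize("layout", ["wide", "long"])
    def test_round_trip(self, tmp_path, layout):
        rng = np.random.default_rng(0)
        m = random_incidence(rng, 7, 15)
        path = tmp_path / f"m_{layout}.csv"
        write_incidence(m, path, layout=layout)
        back = read_incidence(path, layout=layout)
        assert back.site_ids == m.site_ids
        assert sorted(back.species_ids) == sorted(m.species_ids)
        # long layout canonicalizes species order to first appearance in the
        # occurrence stream; contents are identical either way
        pd.testing.assert_frame_equal(back.data[m.species_ids], m.data)

    def test_tsv_round_trip(self, tmp_path):
        m = random_incidence(np.random.default_rng(1), 4, 6)
        path = tmp_path / "m.tsv"
        write_incidence(m, path, layout="wide")
        pd.testing.assert_frame_equal(read_incidence(path).data, m.data)

    def test_workbook_reader_with_column_mapping(self, tmp_path):
        # synthetic stand-in for a deposited supplementary workbook: extra
        # richness/coordinate columns around the occurrence block
        m = random_incidence(np.random.default_rng(2), 5, 8)
        df = m.data.copy()
        df.insert(0, "plot", df.index)
        df["latitude"] = np.linspace(-22, -18, 5)
        df["longitude"] = np.linspace(-45, -43, 5)
        path = tmp_path / "s1_like.xlsx"
        df.to_excel(path, index=False)
        back = read_incidence_workbook(
            path, site_col="plot", drop_cols=("latitude", "longitude")
        )
        pd.testing.assert_frame_equal(back.data, m.data)


class TestConstructionInvariants:
    def test_all_zero_species_forbidden(self):
        df = pd.DataFrame({"sp1": [1, 0], "sp2": [0, 0]}, index=["a", "b"])
        with pytest.raises(IncidenceFormatError, match="nowhere"):
            IncidenceMatrix(df)

    def test_empty_sites_flagged_not_rejected(self):
        df = pd.DataFrame({"sp1": [1, 0]}, index=["a", "b"])
        m = IncidenceMatrix(df)
        assert m.empty_sites == ["b"]
        assert m.drop_empty_sites().site_ids == ["a"]


class TestHierarchy:
    def test_read_and_units(self):
        h = read_hierarchy(
            io.StringIO(
                "site,plot,mountain,range\n"
                "P1,P1,M1,R1\nP2,P2,M1,R1\nP3,P3,M2,R1\nP4,P4,M2,R1\n"
            )
        )
        assert h.levels == ("plot", "mountain", "range")
        assert h.units("mountain") == ["M1", "M2"]
        assert h.members("mountain")["M2"] == ["P3", "P4"]

    def test_inconsistent_nesting_rejected(self):
        with pytest.raises(HierarchyError, match="M1.*more than one"):
            read_hierarchy(
                io.StringIO("site,plot,mountain,range\nP1,P1,M1,R1\nP2,P2,M1,R2\n")
            )

    def test_single_level_hierarchy_valid(self):
        h = read_hierarchy(io.StringIO("site,plot\nP1,P1\nP2,P2\n"))
        assert h.levels == ("plot",)

    def test_shared_lowest_level_unit_rejected(self):
        with pytest.raises(HierarchyError, match="one site per unit"):
            read_hierarchy(io.StringIO("site,plot\nP1,U1\nP2,U1\n"))

    def test_site_mismatch_detected_at_join(self, toy_partition):
        m, h = toy_partition
        with pytest.raises(HierarchyError, match="mismatch"):
            h.subset(["P1", "P2"]).validate_against(m)

    def test_round_trip(self, tmp_path, toy_partition):
        _, h = toy_partition
        path = tmp_path / "h.csv"
        write_hierarchy(h, path)
        back = read_hierarchy(path)
        assert back.levels == h.levels
        pd.testing.assert_frame_equal(back.assignment, h.assignment)


class TestAggregation:
    def test_union_within_mountain(self):
        m = matrix_from_sets({"P1": {"sp1", "sp2"}, "P2": {"sp2", "sp3"}})
        h = read_hierarchy(io.StringIO("site,plot,mountain\nP1,P1,M1\nP2,P2,M1\n"))
        agg = aggregate_incidence(m, h, "mountain")
        assert agg.site_ids == ["M1"]
        assert agg.site_set("M1") == {"sp1", "sp2", "sp3"}

    def test_lowest_level_is_identity(self, toy_partition):
        m, h = toy_partition
        agg = aggregate_incidence(m, h, "plot")
        pd.testing.assert_frame_equal(agg.data, m.data, check_names=False)

    def test_unknown_level_rejected(self, toy_partition):
        m, h = toy_partition
        with pytest.raises(HierarchyError, match="unknown level"):
            aggregate_incidence(m, h, "continent")

    def test_gamma_preserved_and_richness_monotone(self, small_sim):
        plants, _, h, _ = small_sim
        per_site_max = plants.richness.max()
        for level in h.levels:
            agg = aggregate_incidence(plants, h, level)
            assert agg.gamma == plants.gamma
            assert agg.richness.min() >= 0
            assert agg.richness.max() >= per_site_max  # unions never lose species


class TestRichnessSummary:
    def test_toy_counts(self):
        m = matrix_from_sets({"P1": {"sp1", "sp2"}, "P2": {"sp2"}})
        rs = richness_summary(m)
        assert rs.gamma == 2
        assert rs.mean_alpha == pytest.approx(1.5)

    def test_identical_sites_alpha_equals_gamma(self):
        m = matrix_from_sets({"P1": {"a", "b", "c"}, "P2": {"a", "b", "c"}})
        rs = richness_summary(m)
        assert rs.mean_alpha == rs.gamma == 3

    def test_mean_alpha_never_exceeds_gamma(self, study_sim):
        plants, galls, _, _ = study_sim
        for m in (plants, galls):
            rs = richness_summary(m)
            assert rs.mean_alpha <= rs.gamma <= m.n_species
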