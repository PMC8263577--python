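"""Specimen table: classification maps, validation and CSV round trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bonebed.specimens import (
    LENGTH_CLASSES,
    SpecimenRecord,
    SpecimenTable,
    assign_size_class,
    assign_skeletal_region,
    derive_length_class,
    element_vocabulary,
    read_specimen_table,
    write_specimen_table,
)


class TestSizeClasses:
    @pytest.mark.parametrize(
        "mass, group, expected",
        [
            (300, "herbivore", "3b"),
            (24.9, "herbivore", "0"),
            (125, "herbivore", "3a"),  # half-open convention at the boundary
            (25, "herbivore", "1"),
            (1000, "herbivore", "5"),
            (6, "carnivore", "small"),
            (40, "carnivore", "intermediate"),
            (180, "carnivore", "large"),
        ],
    )
    def test_mass_maps_to_expected_class(self, mass, group, expected):
        assert assign_size_class(mass, group) == expected

    @pytest.mark.parametrize("bad", [0, -5])
    def test_non_positive_mass_rejected(self, bad):
        with pytest.raises(ValueError):
            assign_size_class(bad)

    @given(st.floats(min_value=1e-6, max_value=1e6, allow_nan=False))
    @settings(max_examples=300, derandomize=True)
    def test_intervals_partition_positive_masses(self, mass):
        # exactly one class for any mass, for both trophic schemes
        assert assign_size_class(mass, "herbivore") in {"0", "1", "2", "3a", "3b", "4", "5"}
        assert assign_size_class(mass, "carnivore") in {"small", "intermediate", "large"}

    def test_adjacent_boundary_masses_change_class(self):
        for lo in (25, 50, 125, 250, 500, 1000):
            assert assign_size_class(lo - 1e-9) != assign_size_class(lo)


class TestSkeletalRegions:
    @pytest.mark.parametrize(
        "element, region, portion",
        [
            ("humerus", "upper appendicular", "anterior"),
            ("femur", "upper appendicular", "posterior"),
            ("scapula", "axial", "anterior"),
            ("pelvis", "axial", "posterior"),
            ("radius", "intermediate appendicular", "anterior"),
            ("tibia", "intermediate appendicular", "posterior"),
            ("metacarpal", "lower appendicular", "anterior"),
            ("metatarsal", "lower appendicular", "posterior"),
            ("tooth", "cranial", "n/a"),
            ("vertebra", "axial", "n/a"),
        ],
    )
    def test_printed_groupings(self, element, region, portion):
        assert assign_skeletal_region(element) == (region, portion)

    def test_map_total_over_vocabulary(self):
        for element in element_vocabulary().index:
            region, portion = assign_skeletal_region(element)
            assert region and portion

    def test_unknown_element_warns_not_drops(self):
        with pytest.warns(UserWarning):
            assert assign_skeletal_region("baculum") == ("unclassified", "n/a")


class TestLengthClasses:
    @pytest.mark.parametrize(
        "length, expected",
        [(2.9, "<3 cm"), (3.0, "<3 cm"), (5.0, "3.1-5 cm"), (7.0, "5.1-10 cm"),
         (10.0, "5.1-10 cm"), (10.1, ">10 cm")],
    )
    def test_examples(self, length, expected):
        assert derive_length_class(length) == expected

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            derive_length_class(0)


# ---------------------------------------------------------------------------
# I/O round trips
# ---------------------------------------------------------------------------

_sides = st.sampled_from(["left", "right", "axial", "unknown"])
_elements = st.sampled_from(["humerus", "tibia", "tooth", "rib", "indeterminate"])
_lengths = st.sampled_from([None, 1.2, 3.0, 4.4, 9.9, 15.0])


@st.composite
def records(draw, i):
    length = draw(_lengths)
    return SpecimenRecord(
        specimen_id=f"S{i:03d}",
        x=draw(st.one_of(st.none(), st.floats(0, 10, allow_nan=False))),
        y=draw(st.one_of(st.none(), st.floats(0, 10, allow_nan=False))),
        z=draw(st.floats(0, 100, allow_nan=False)),
        element=draw(_elements),
        side=draw(_sides),
        length_cm=length,
        length_class=derive_length_class(length) if length else "",
        trend_deg=draw(st.one_of(st.none(), st.floats(0, 359.9, allow_nan=False))),
        plunge_deg=draw(st.one_of(st.none(), st.floats(0, 90, allow_nan=False))),
        tm_pits=draw(st.integers(0, 3)),
        furrowing=draw(st.booleans()),
        taphotype=draw(st.sampled_from([None, 3, 15])),
    )


@st.composite
def tables(draw):
    n = draw(st.integers(1, 12))
    return SpecimenTable.from_records([draw(records(i)) for i in range(n)])


class TestRoundTrip:
    @given(table=tables())
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_write_read_identity(self, tmp_path_factory, table):
        path = tmp_path_factory.mktemp("io") / "t.csv"
        write_specimen_table(table, path)
        back = read_specimen_table(path)
        assert back.errors == []
        assert back.equals(table)

    def test_fifty_row_synthetic_round_trip(self, default_site, tmp_path):
        sub = SpecimenTable(default_site.df.head(50))
        path = tmp_path / "site.csv"
        write_specimen_table(sub, path)
        back = read_specimen_table(path)
        assert back.errors == []
        assert back.equals(sub)

    def test_minimal_csv_parses(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("specimen_id,x,y,z\nA,1.0,2.0,10\nB,2.0,3.0,20\n")
        t = read_specimen_table(p)
        assert len(t) == 2 and t.errors == []

    def test_out_of_range_trend_rejected_with_message(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("specimen_id,trend_deg\nA,361\nB,10\n")
        t = read_specimen_table(p)
        assert len(t) == 1
        assert any("trend out of range" in e for e in t.errors)

    def test_duplicate_id_hard_failure_names_rows(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text("specimen_id,z\nA,1\nA,2\n")
        with pytest.raises(ValueError, match="A"):
            read_specimen_table(p)

    def test_malformed_coordinate_reported(self, tmp_path):
        p = tmp_path / "mal.csv"
        p.write_text("specimen_id,x\nA,not-a-number\nB,1.5\n")
        t = read_specimen_table(p)
        assert len(t) == 1
        assert any("malformed x" in e for e in t.errors)
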