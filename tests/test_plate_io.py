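"""Gitter-table parsing, array maps and quartet assembly."""

import io
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from y1hscreen import (
    ArrayMap,
    ColonyRecord,
    Control,
    GitterDialect,
    assemble_quartets,
    read_gitter_table,
    write_gitter_table,
)
from y1hscreen.plate_io import (
    DialectConfigError,
    DuplicatePositionError,
    GitterParseError,
    read_well_mask,
    well_to_quartet,
)

HEADER = "row\tcol\tsize\tcircularity\tflags\n"


def make_table(rows):
    return HEADER + "".join(
        f"{r}\t{c}\t{s}\t{circ}\t{fl}\n" for r, c, s, circ, fl in rows
    )


class TestReadGitterTable:
    def test_zero_size_marks_colony_absent(self):
        table = make_table([(1, 1, 100, 0.9, "-"), (1, 2, 0, 0.0, "-"), (1, 3, 250, 0.8, "-")])
        recs = read_gitter_table(io.StringIO(table))
        assert len(recs) == 3
        assert recs[0].present and recs[0].pixel_area == 100
        assert not recs[1].present and recs[1].pixel_area == 0
        assert recs[2].present and recs[2].pixel_area == 250

    def test_noncircular_flag_clears_circular(self):
        table = make_table([(1, 1, 100, 0.3, "NC"), (1, 2, 90, 0.9, "-")])
        recs = read_gitter_table(io.StringIO(table))
        assert not recs[0].circular
        assert recs[1].circular

    def test_comment_lines_are_skipped(self):
        table = "# produced by scorer v1\n" + make_table([(2, 2, 10, 1.0, "-")])
        assert len(read_gitter_table(io.StringIO(table))) == 1

    def test_circularity_cutoff_dialect(self):
        dialect = GitterDialect(circularity_cutoff=0.5)
        table = make_table([(1, 1, 100, 0.3, "-"), (1, 2, 100, 0.7, "-")])
        recs = read_gitter_table(io.StringIO(table), dialect)
        assert [r.circular for r in recs] == [False, True]

    def test_duplicate_position_rejected(self):
        table = make_table([(1, 1, 10, 1.0, "-"), (1, 1, 20, 1.0, "-")])
        with pytest.raises(DuplicatePositionError):
            read_gitter_table(io.StringIO(table))

    def test_position_outside_grid_rejected(self):
        table = make_table([(33, 1, 10, 1.0, "-")])
        with pytest.raises(GitterParseError, match="outside"):
            read_gitter_table(io.StringIO(table))

    def test_malformed_line_reports_line_number(self):
        table = HEADER + "1\t1\tnot_a_number\t1.0\t-\n"
        with pytest.raises(GitterParseError, match="line 2"):
            read_gitter_table(io.StringIO(table))

    def test_unknown_dialect_column_is_config_error(self):
        dialect = GitterDialect(size_col="area_px")
        with pytest.raises(DialectConfigError):
            read_gitter_table(io.StringIO(make_table([(1, 1, 10, 1.0, "-")])), dialect)


class TestWriteGitterTable:
    def test_empty_record_list_gives_header_only(self):
        buf = io.StringIO()
        write_gitter_table([], buf)
        assert buf.getvalue().strip() == HEADER.strip()

    def test_full_plate_writes_1536_lines(self, full_plate_records):
        buf = io.StringIO()
        write_gitter_table(full_plate_records, buf)
        assert len(buf.getvalue().strip().split("\n")) == 1537

    @settings(max_examples=30, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.integers(1, 32),
                st.integers(1, 48),
                st.integers(0, 5000),
                st.booleans(),
            ),
            max_size=60,
            unique_by=lambda t: (t[0], t[1]),
        )
    )
    def test_round_trip_is_identity(self, rows):
        records = [
            ColonyRecord(r, c, s if s > 0 else 0, circ, s > 0)
            for r, c, s, circ in rows
        ]
        buf = io.StringIO()
        write_gitter_table(records, buf)
        buf.seek(0)
        assert read_gitter_table(buf) == records


class TestQuartetAssembly:
    def test_wells_partition_into_quartets(self):
        owners = {}
        for r in range(1, 33):
            for c in range(1, 49):
                owners.setdefault(well_to_quartet(r, c), []).append((r, c))
        assert len(owners) == 384
        assert all(len(w) == 4 for w in owners.values())
        assert sum(len(w) for w in owners.values()) == 1536

    def test_full_plate_yields_384_complete_quartets(
        self, full_plate_records, plate_meta, tiny_array
    ):
        quartets = assemble_quartets(full_plate_records, plate_meta, tiny_array)
        assert len(quartets) == 384
        assert all(q.n_present_circular == 4 for q in quartets)
        assert all(
            abs(v - math.log(148)) < 1e-12 for q in quartets for v in q.ln_areas
        )

    def test_absent_colony_drops_from_ln_areas(self, plate_meta, tiny_array):
        records = [
            ColonyRecord(1, 1, 148),
            ColonyRecord(1, 2, 148),
            ColonyRecord(2, 1, 148),
            ColonyRecord(2, 2, 0, True, False),
        ]
        quartets = assemble_quartets(records, plate_meta, tiny_array)
        q = quartets[0]
        assert q.n_present_circular == 3
        assert all(abs(v - 4.997) < 1e-3 for v in q.ln_areas)

    def test_noncircular_colony_is_screened_out(self, plate_meta, tiny_array):
        records = [
            ColonyRecord(1, 1, 148),
            ColonyRecord(1, 2, 148, circular=False),
            ColonyRecord(2, 1, 148),
            ColonyRecord(2, 2, 148),
        ]
        q = assemble_quartets(records, plate_meta, tiny_array)[0]
        assert q.n_present_circular == 3

    def test_missing_wells_count_as_absent(self, plate_meta, tiny_array):
        quartets = assemble_quartets([], plate_meta, tiny_array)
        assert len(quartets) == 384
        assert all(q.n_present_circular == 0 for q in quartets)

    def test_mask_forces_wells_absent(self, full_plate_records, plate_meta, tiny_array):
        mask = {(1, 1), (1, 2)}
        q = assemble_quartets(full_plate_records, plate_meta, tiny_array, mask=mask)[0]
        assert q.n_present_circular == 2

    def test_occupants_follow_array_map(self, full_plate_records, plate_meta, tiny_array):
        quartets = assemble_quartets(full_plate_records, plate_meta, tiny_array)
        by_pos = {(q.qrow, q.qcol): q.occupant for q in quartets}
        assert by_pos == dict(tiny_array.items())


class TestArrayMap:
    def test_must_cover_grid_exactly(self):
        with pytest.raises(ValueError, match="quartet grid"):
            ArrayMap("p1", {(1, 1): "TF0001"})

    def test_from_tf_list_places_controls(self):
        arr = ArrayMap.from_tf_list("p1", [f"T{i}" for i in range(360)], n_ad_only=8)
        occupants = [occ for _, occ in arr.items()]
        assert occupants.count(Control.AD_ONLY) == 8
        assert occupants.count(Control.EMPTY_NO_TF) == 384 - 360 - 8
        assert len(arr.tf_ids) == 360

    def test_too_many_tfs_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            ArrayMap.from_tf_list("p1", [f"T{i}" for i in range(385)])


def test_well_mask_reader(tmp_path):
    p = tmp_path / "mask.tsv"
    p.write_text("plate_id\twell_row\twell_col\nplate_x\t3\t4\nplate_x\t3\t5\n")
    mask = read_well_mask(p)
    assert mask == {"plate_x": {(3, 4), (3, 5)}}
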