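import csv

import pytest

from hsscreen.cassette import (
    Cassette,
    CompoundRecord,
    CompoundStatus,
    SchemaError,
    SurvivalEntry,
    ValidationError,
    WellObservation,
    filter_for_analysis,
    parse_status,
    read_plate_csv,
    read_survival_table,
    write_plate_csv,
    write_survival_table,
)


def write_rows(path, rows):
    with open(path, "w", newline="", encoding="utf-8") as handle:
        csv.writer(handle).writerows(rows)


class TestPlateCsv:
    def test_counts_preserved(self, tmp_path, plate_rows):
        path = tmp_path / "plate.csv"
        write_rows(path, plate_rows)
        cassette = read_plate_csv(path)
        assert cassette.mode == "raw-counts"
        assert len(cassette.compounds) == 1
        assert len(cassette.observations) == 9
        # conc_uM converted to molar
        assert {o.concentration for o in cassette.observations} == {1e-6, 1e-5, 1e-4}

    def test_alive_above_total_is_validation_error(self, tmp_path, plate_rows):
        plate_rows[3][5:7] = [25, 20]
        path = tmp_path / "plate.csv"
        write_rows(path, plate_rows)
        with pytest.raises(ValidationError, match="row 4"):
            read_plate_csv(path)

    def test_missing_column_is_schema_error(self, tmp_path, plate_rows):
        rows = [row[:-1] for row in plate_rows]
        path = tmp_path / "plate.csv"
        write_rows(path, rows)
        with pytest.raises(SchemaError, match="total"):
            read_plate_csv(path)

    def test_duplicate_well_rejected(self, tmp_path, plate_rows):
        path = tmp_path / "plate.csv"
        write_rows(path, plate_rows + [plate_rows[1]])
        with pytest.raises(ValidationError, match="duplicate"):
            read_plate_csv(path)

    def test_round_trip_identity(self, tmp_path, plate_rows):
        path = tmp_path / "plate.csv"
        write_rows(path, plate_rows)
        cassette = read_plate_csv(path)
        out = tmp_path / "out.csv"
        write_plate_csv(cassette, out)
        again = read_plate_csv(out)
        assert again == cassette


class TestSurvivalTable:
    @pytest.mark.parametrize(
        "token,expected",
        [
            ("L", CompoundStatus.LAUNCHED),
            ("T", CompoundStatus.TOOL),
            ("P", CompoundStatus.PRECLINICAL),
            ("C-I", CompoundStatus.CLINICAL_PHASE_1),
            ("C-II", CompoundStatus.CLINICAL_PHASE_2),
            ("C-III", CompoundStatus.CLINICAL_PHASE_3),
            ("W", CompoundStatus.WITHDRAWN),
            ("N/A", CompoundStatus.UNKNOWN),
            ("launched", CompoundStatus.LAUNCHED),
            ("gibberish", CompoundStatus.UNKNOWN),
        ],
    )
    def test_status_vocabulary(self, token, expected):
        assert parse_status(token) is expected

    def test_parse_complete_surface(self, tmp_path):
        rows = [["compound_id", "status", "conc_uM", "temp_C", "sn"]]
        for conc in (1, 10, 100):
            for temp in (38, 40):
                rows.append(["X1", "L", conc, temp, 1.1])
        path = tmp_path / "sn.csv"
        write_rows(path, rows)
        cassette = read_survival_table(path)
        assert cassette.mode == "pre-normalized"
        assert cassette.record("X1").status is CompoundStatus.LAUNCHED
        assert len(cassette.normalized) == 6
        assert cassette.incomplete_compounds() == ()

    def test_incomplete_surface_flagged_but_retained(self, tmp_path):
        rows = [["compound_id", "status", "conc_uM", "temp_C", "sn"]]
        for conc in (1, 10, 100):
            rows.append(["X1", "T", conc, 38, 0.9])
        path = tmp_path / "sn.csv"
        write_rows(path, rows)
        cassette = read_survival_table(path)
        assert cassette.incomplete_compounds() == ("X1",)
        assert len(cassette.normalized) == 3

    def test_negative_sn_rejected(self, tmp_path):
        rows = [
            ["compound_id", "status", "conc_uM", "temp_C", "sn"],
            ["X1", "L", 1, 38, -0.2],
        ]
        path = tmp_path / "sn.csv"
        write_rows(path, rows)
        with pytest.raises(ValidationError, match="negative"):
            read_survival_table(path)

    def test_round_trip_identity(self, tmp_path):
        cassette = Cassette(
            (CompoundRecord("X1", CompoundStatus.CLINICAL_PHASE_2),),
            normalized=tuple(
                SurvivalEntry("X1", c, t, 0.5 + c * 1e4 + t / 100)
                for c in (1e-6, 1e-5, 1e-4)
                for t in (38.0, 40.0)
            ),
        )
        path = tmp_path / "sn.csv"
        write_survival_table(cassette, path)
        assert read_survival_table(path) == cassette


class TestCassetteInvariants:
    def test_mixed_mode_rejected(self):
        with pytest.raises(ValidationError, match="never mixed"):
            Cassette(
                (CompoundRecord("A"),),
                observations=(WellObservation("A", 1e-6, 38.0, 5, 20),),
                normalized=(SurvivalEntry("A", 1e-6, 38.0, 1.0),),
            )

    def test_unresolved_compound_rejected(self):
        with pytest.raises(ValidationError, match="unknown compound"):
            Cassette(
                (CompoundRecord("A"),),
                observations=(WellObservation("B", 1e-6, 38.0, 5, 20),),
            )


class TestFilterForAnalysis:
    @staticmethod
    def cassette_of(statuses):
        return Cassette(
            tuple(CompoundRecord(f"c{i}", s) for i, s in enumerate(statuses))
        )

    def test_default_policy_drops_unknown_and_withdrawn(self):
        statuses = [CompoundStatus.LAUNCHED] * 69 + [
            CompoundStatus.UNKNOWN,
            CompoundStatus.WITHDRAWN,
            CompoundStatus.WITHDRAWN,
        ]
        cassette = self.cassette_of(statuses)
        kept = filter_for_analysis(cassette)
        assert len(kept.compounds) == 69
        # pure subset: surviving records unaltered
        assert set(kept.compounds) <= set(cassette.compounds)

    def test_keep_all_is_identity(self):
        cassette = self.cassette_of([CompoundStatus.UNKNOWN, CompoundStatus.TOOL])
        assert filter_for_analysis(cassette, "keep-all") == cassette

    def test_empty_result_is_error(self):
        cassette = self.cassette_of([CompoundStatus.WITHDRAWN] * 3)
        with pytest.raises(ValidationError, match="no analyzable compounds"):
            filter_for_analysis(cassette)
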