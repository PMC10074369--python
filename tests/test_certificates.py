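import pytest
from hypothesis import given, strategies as st

from multicause import (
    Certificate,
    CertificateError,
    age_group_label,
    fixture_mapping,
    read_certificates,
    resolve_record,
    resolve_records,
    table1_fixture,
    write_certificates,
)


def write_lines(path, lines):
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


class TestReadEntityAxis:
    def test_minimal_record(self, tmp_path):
        path = write_lines(
            tmp_path / "one.csv",
            ["id,sex,age,part,line,position,icd10,is_ucod", "1,,,1,1,1,A00,1"],
        )
        (cert,) = read_certificates(path, "entity_axis")
        assert cert.part1 == [["A00"]]
        assert cert.part2 == []
        assert cert.ucod == "A00"
        assert cert.ucod_position == (0, 0)

    def test_ucod_on_last_part1_line_with_part2(self, tmp_path):
        path = write_lines(
            tmp_path / "e.csv",
            [
                "id,sex,age,part,line,position,icd10,is_ucod",
                "7,F,81,1,1,1,J18,0",
                "7,F,81,1,2,1,I25,1",
                "7,F,81,2,1,1,E11,0",
                "7,F,81,2,1,2,F03,0",
            ],
        )
        (cert,) = read_certificates(path, "entity_axis")
        assert cert.ucod == "I25"
        assert cert.ucod_position == (1, 0)
        assert len(cert.part2) == 2
        assert cert.sex == "F" and cert.age_years == 81

    def test_malformed_code_names_row(self, tmp_path):
        path = write_lines(
            tmp_path / "bad.csv",
            ["id,sex,age,part,line,position,icd10,is_ucod", "1,,,1,1,1,NOTACODE,1"],
        )
        with pytest.raises(CertificateError, match="row 2"):
            read_certificates(path, "entity_axis")

    def test_duplicate_position_rejected(self, tmp_path):
        path = write_lines(
            tmp_path / "dup.csv",
            [
                "id,sex,age,part,line,position,icd10,is_ucod",
                "1,,,1,1,1,A00,1",
                "1,,,1,1,1,B00,0",
            ],
        )
        with pytest.raises(CertificateError, match="duplicate position"):
            read_certificates(path, "entity_axis")

    def test_missing_ucod_rejected(self, tmp_path):
        path = write_lines(
            tmp_path / "no_ucod.csv",
            ["id,sex,age,part,line,position,icd10,is_ucod", "1,,,1,1,1,A00,0"],
        )
        with pytest.raises(CertificateError, match="no UCoD"):
            read_certificates(path, "entity_axis")

    def test_ucod_in_part2_rejected(self, tmp_path):
        path = write_lines(
            tmp_path / "p2.csv",
            ["id,sex,age,part,line,position,icd10,is_ucod", "1,,,2,1,1,A00,1"],
        )
        with pytest.raises(CertificateError, match="Part II"):
            read_certificates(path, "entity_axis")


class TestReadRecordAxis:
    def test_duplicate_mentions_preserved_in_order(self, tmp_path):
        # UCoD first, remaining causes kept verbatim including repeats
        path = write_lines(
            tmp_path / "r.csv",
            ["id,sex,age,cause_1,cause_2,cause_3,cause_4", "8,,,C00,A00,C00,A00"],
        )
        (cert,) = read_certificates(path, "record_axis")
        assert cert.ucod == "C00"
        assert cert.part2 == ["A00", "C00", "A00"]
        assert cert.ucod_position is None

    def test_missing_ucod_rejected(self, tmp_path):
        path = write_lines(
            tmp_path / "r.csv", ["id,sex,age,cause_1,cause_2", "1,,,,"]
        )
        with pytest.raises(CertificateError, match="missing UCoD"):
            read_certificates(path, "record_axis")

    def test_duplicate_id_rejected(self, tmp_path):
        path = write_lines(
            tmp_path / "r.csv",
            ["id,sex,age,cause_1", "1,,,A00", "1,,,B00"],
        )
        with pytest.raises(CertificateError, match="duplicate"):
            read_certificates(path, "record_axis")


class TestRoundTrip:
    @pytest.mark.parametrize("dialect", ["entity_axis", "record_axis"])
    def test_write_read_write_is_byte_identical(self, tmp_path, dialect):
        certs = table1_fixture()
        first = tmp_path / "first.csv"
        second = tmp_path / "second.csv"
        write_certificates(certs, first, dialect)
        write_certificates(read_certificates(first, dialect), second, dialect)
        assert first.read_bytes() == second.read_bytes()

    def test_entity_roundtrip_preserves_structure(self, tmp_path):
        cert = Certificate(
            id="x",
            ucod="I25",
            part1=[["K70"], ["I21", "E11"], ["I25"]],
            part2=["F03"],
            ucod_position=(2, 0),
            sex="M",
            age_years=77,
        )
        path = tmp_path / "c.csv"
        write_certificates([cert], path, "entity_axis")
        (back,) = read_certificates(path, "entity_axis")
        assert back.part1 == cert.part1
        assert back.part2 == cert.part2
        assert back.ucod_position == cert.ucod_position
        assert back.sex == "M" and back.age_years == 77


class TestResolve:
    def test_duplicate_ccod_mentions_collapse(self, four_cat_mapping):
        # UCoD C with others A, C, A resolves to a single CCoD category A
        cert = table1_fixture()[7]
        rec = resolve_record(cert, four_cat_mapping)
        assert rec.ucod_cat == "C"
        assert rec.ccod_cats == frozenset({"A"})
        assert rec.n_ccod == 1

    def test_ucod_repeated_as_ccod_is_ignored(self, four_cat_mapping):
        cert = table1_fixture()[1]  # UCoD A, other cause A
        rec = resolve_record(cert, four_cat_mapping)
        assert rec.ucod_cat == "A"
        assert rec.ccod_cats == frozenset()
        assert rec.n_ccod == 0

    def test_part1_codes_above_ucod_are_ignored(self, four_cat_mapping):
        cert = Certificate(
            id="up",
            ucod="D00",
            part1=[["A00"], ["B00", "C00"], ["D00"]],
            part2=["B00"],
            ucod_position=(2, 0),
        )
        rec = resolve_record(cert, four_cat_mapping)
        assert rec.ccod_cats == frozenset({"B"})  # Part II only

    def test_codes_left_of_ucod_on_same_line_are_ignored(self, four_cat_mapping):
        cert = Certificate(
            id="line",
            ucod="B00",
            part1=[["A00", "B00", "C00"]],
            part2=[],
            ucod_position=(0, 1),
        )
        rec = resolve_record(cert, four_cat_mapping)
        assert rec.ccod_cats == frozenset({"C"})

    def test_part2_only_convention(self, four_cat_mapping):
        cert = Certificate(
            id="p2",
            ucod="A00",
            part1=[["A00", "B00"]],
            part2=["C00"],
            ucod_position=(0, 0),
        )
        rec = resolve_record(cert, four_cat_mapping, part2_only=True)
        assert rec.ccod_cats == frozenset({"C"})

    def test_adding_duplicate_mention_leaves_record_unchanged(self, four_cat_mapping):
        base = Certificate(
            id="d", ucod="A00", part1=[], part2=["B00", "C00"], ucod_position=None
        )
        extra = Certificate(
            id="d", ucod="A00", part1=[], part2=["B00", "C00", "B00"],
            ucod_position=None,
        )
        assert resolve_record(base, four_cat_mapping) == resolve_record(
            extra, four_cat_mapping
        )

    def test_strata_from_sex_and_age(self, four_cat_mapping):
        cert = Certificate(
            id="s", ucod="A00", part1=[], part2=[], ucod_position=None,
            sex="F", age_years=79,
        )
        rec = resolve_record(cert, four_cat_mapping)
        assert rec.strata == {"sex": "F", "age_group": "75-84"}

    def test_underage_records_excluded_with_count(self, four_cat_mapping, caplog):
        certs = [
            Certificate(id="young", ucod="A00", age_years=42),
            Certificate(id="old", ucod="A00", age_years=90),
        ]
        import logging

        with caplog.at_level(logging.INFO, logger="multicause.certificates"):
            recs = resolve_records(certs, four_cat_mapping)
        assert [r.id for r in recs] == ["old"]
        assert "excluded 1" in caplog.text


class TestAgeGroups:
    @pytest.mark.parametrize(
        "age, label",
        [(60, "60-74"), (74, "60-74"), (75, "75-84"), (84, "75-84"),
         (85, "85+"), (104, "85+"), (59, None)],
    )
    def test_default_breaks(self, age, label):
        assert age_group_label(age, (60, 75, 85)) == label


@given(
    ccods=st.lists(st.sampled_from(["A00", "B00", "C00", "D00"]), max_size=8),
    ucod=st.sampled_from(["A00", "B00", "C00", "D00"]),
)
def test_resolution_invariants_hold_for_arbitrary_records(ucod, ccods):
    """ucod_cat never among ccod_cats, and n_ccod counts unique categories."""
    mapping = fixture_mapping()
    cert = Certificate(id="h", ucod=ucod, part1=[], part2=ccods, ucod_position=None)
    rec = resolve_record(cert, mapping)
    assert rec.ucod_cat not in rec.ccod_cats
    assert rec.n_ccod == len(rec.ccod_cats)
    expected = {mapping.map_code(c) for c in ccods} - {mapping.map_code(ucod)}
    assert rec.ccod_cats == expected
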