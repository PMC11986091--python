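import re

import pytest
from hypothesis import given, settings, strategies as st

from atcmap import (
    VALID_FIRST_LETTERS,
    AtcCode,
    level_prefixes,
    load_atc_dictionary,
    load_atc_dictionary_yaml,
    load_rad,
    load_rad_yaml,
    match_pattern,
    validate_atc_code,
)
from atcmap.dictionaries import RadKind


class TestValidateAtcCode:
    @pytest.mark.parametrize(
        "code,valid,level",
        [
            ("L01BA01", True, 5),
            ("L01BA", True, 4),
            ("L01B", True, 3),
            ("L01", True, 2),
            ("L", True, 1),
            ("M01CX0", False, None),   # six characters: printed-truncation form
            ("Z99XX99", False, None),  # Z is not an anatomical group
            ("L01BA0", False, None),
            ("l01ba01", False, None),
            ("", False, None),
            ("A04AA01", True, 5),
        ],
    )
    def test_examples(self, code, valid, level):
        assert validate_atc_code(code) == (valid, level)

    def test_fourteen_first_letters(self):
        assert len(VALID_FIRST_LETTERS) == 14

    def test_level5_has_five_prefixes(self):
        assert level_prefixes("L01BA01") == {"L", "L01", "L01B", "L01BA", "L01BA01"}

    def test_prefixes_reject_partial_codes(self):
        with pytest.raises(ValueError):
            level_prefixes("L01BA")

    @given(st.text(alphabet="ABLZ019ab", max_size=8))
    @settings(max_examples=2000, derandomize=True)
    def test_agrees_with_regex_oracle(self, code):
        """Brute-force regex oracle over the five level shapes."""
        shapes = {
            1: r"[ABCDGHJLMNPRSV]",
            2: r"[ABCDGHJLMNPRSV]\d{2}",
            3: r"[ABCDGHJLMNPRSV]\d{2}[A-Z]",
            4: r"[ABCDGHJLMNPRSV]\d{2}[A-Z]{2}",
            5: r"[ABCDGHJLMNPRSV]\d{2}[A-Z]{2}\d{2}",
        }
        expected = next(
            (lvl for lvl, rx in shapes.items() if re.fullmatch(rx, code)), None
        )
        assert validate_atc_code(code) == (expected is not None, expected)

    def test_antineoplastic_flag(self):
        assert AtcCode("L01BA01").is_antineoplastic
        assert not AtcCode("A04AA01").is_antineoplastic


class TestMatchPattern:
    @pytest.mark.parametrize(
        "token,pattern,expected",
        [
            ("FLUOROURACIL", "FLUOROURACIL", True),
            ("MITOMYCIN", "MITOMYC*", True),
            ("MITOMYC", "MITOMYC*", True),   # '*' matches zero characters
            ("MITO", "MITOMYC*", False),
            ("CISPLATIN", "FLUOROURACIL", False),
            ("AB12CD", "AB*CD", True),
        ],
    )
    def test_examples(self, token, pattern, expected):
        assert match_pattern(token, pattern) is expected

    @given(
        st.text(alphabet="ABC12", max_size=8),
        st.text(alphabet="ABC12*", max_size=6),
    )
    @settings(max_examples=500, derandomize=True)
    def test_glob_agrees_with_regex_translation(self, token, pattern):
        rx = "".join("[A-Z0-9]*" if c == "*" else re.escape(c) for c in pattern)
        assert match_pattern(token, pattern) == bool(re.fullmatch(rx, token))


ATC_TSV = """# code\tname\tpattern
L01BA01\tMethotrexat\t
M01CX01\tMethotrexat\t
L01XA01\tCisplatin\tCis-platin
X99ZZ99\tPseudodrug\t
"""

RAD_TSV = """# key\tkind\tpayload
5-FU\tEXPANSION\tFluorouracil
Studie\tSTUDY\tStudie
TACE\tINFO\tTACE
Nodrug\tMEDICATION\tNodrug
"""


class TestLoaders:
    def test_atc_tsv(self, tmp_path):
        path = tmp_path / "atc.tsv"
        path.write_text(ATC_TSV, encoding="utf-8")
        atc = load_atc_dictionary(path)
        assert atc.lookup("METHOTREXAT") == {"L01BA01", "M01CX01"}
        # pattern column normalized with the input-text rules (hyphen fusion)
        assert atc.lookup("CISPLATIN") == {"L01XA01"}
        assert atc.name_of["L01BA01"] == "Methotrexat"
        assert any("X99ZZ99" in w for w in atc.warnings)  # kept, warned

    def test_atc_strict_mode_rejects_invalid(self, tmp_path):
        path = tmp_path / "atc.tsv"
        path.write_text(ATC_TSV, encoding="utf-8")
        with pytest.raises(ValueError, match="X99ZZ99"):
            load_atc_dictionary(path, strict=True)

    def test_atc_empty_file_with_header(self, tmp_path):
        path = tmp_path / "atc.tsv"
        path.write_text("# code\tname\tpattern\n", encoding="utf-8")
        atc = load_atc_dictionary(path)
        assert len(atc) == 0 and not atc.warnings

    def test_rad_tsv(self, tmp_path):
        path = tmp_path / "rad.tsv"
        path.write_text(RAD_TSV, encoding="utf-8")
        rad = load_rad(path)
        assert rad.get("5FU").names == ("FLUOROURACIL",)
        assert rad.get("STUDIE").kind is RadKind.STUDY
        assert rad.get("TACE").term == "TACE"
        assert rad.get("NODRUG").kind is RadKind.MEDICATION

    def test_rad_unknown_kind_is_hard_error(self, tmp_path):
        path = tmp_path / "rad.tsv"
        path.write_text("K\tBOGUS\tx\n", encoding="utf-8")
        with pytest.raises(ValueError, match="unknown RAD kind"):
            load_rad(path)

    def test_rad_empty_expansion_is_hard_error(self, tmp_path):
        path = tmp_path / "rad.tsv"
        path.write_text("K\tEXPANSION\t \n", encoding="utf-8")
        with pytest.raises(ValueError, match="empty EXPANSION"):
            load_rad(path)

    def test_rad_cross_check_warns_unresolvable(self, tmp_path, mini_atc):
        path = tmp_path / "rad.tsv"
        path.write_text("GHOST\tEXPANSION\tNosuchdrug\n", encoding="utf-8")
        rad = load_rad(path, atc=mini_atc)
        assert any("NOSUCHDRUG" in w for w in rad.warnings)

    def test_round_trip_idempotent(self, tmp_path, mini_atc, mini_rad):
        """Load → serialize → reload yields identical dictionaries."""
        a1, r1 = tmp_path / "a1.tsv", tmp_path / "r1.tsv"
        mini_atc.to_tsv(a1)
        mini_rad.to_tsv(r1)
        atc2, rad2 = load_atc_dictionary(a1), load_rad(r1)
        assert atc2.entries == mini_atc.entries
        assert rad2.entries == mini_rad.entries
        a2, r2 = tmp_path / "a2.tsv", tmp_path / "r2.tsv"
        atc2.to_tsv(a2)
        rad2.to_tsv(r2)
        assert a1.read_text() == a2.read_text()
        assert r1.read_text() == r2.read_text()

    def test_patterns_already_normalized(self, tmp_path, mini_atc):
        from atcmap import normalize_key

        for pattern in mini_atc.entries:
            assert normalize_key(pattern) == pattern


class TestYamlDialect:
    def test_atc_yaml(self, tmp_path):
        path = tmp_path / "atc.yaml"
        path.write_text(
            "L01BA01: [Methotrexat, MTX]\nM01CX01: Methotrexat\n", encoding="utf-8"
        )
        atc = load_atc_dictionary_yaml(path)
        assert atc.lookup("MTX") == {"L01BA01"}
        assert atc.lookup("METHOTREXAT") == {"L01BA01", "M01CX01"}

    def test_rad_yaml(self, tmp_path):
        path = tmp_path / "rad.yaml"
        path.write_text(
            "Fluorouracil: [5-FU]\n"
            "Fluorouracil;Calciumfolinat;Oxaliplatin: [FOLFOX]\n"
            "STUDY: [Studie]\n"
            "INFO: [TACE]\n",
            encoding="utf-8",
        )
        rad = load_rad_yaml(path)
        assert rad.get("5FU").names == ("FLUOROURACIL",)
        assert rad.get("FOLFOX").names == (
            "FLUOROURACIL", "CALCIUMFOLINAT", "OXALIPLATIN",
        )
        assert rad.get("STUDIE").kind is RadKind.STUDY
        assert rad.get("TACE").kind is RadKind.INFO
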