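"""Parsing, polymorphism resolution, transforms and dataset summaries."""

import math

import numpy as np
import pytest

import floramorph as fm
from floramorph.character_matrix import (
    Cell,
    CharacterDef,
    ConfigError,
    ValidationError,
    parse_cell,
    write_dataset,
)

from conftest import make_matrix


NUM = CharacterDef(id="petals", kind="numeric", module="perianth")
ORD = CharacterDef(
    id="fusion", kind="ordered_categorical", module="perianth",
    ordered_levels=("free", "basal", "full"),
)
CAT = CharacterDef(id="colour", kind="unordered_categorical", module="perianth")
BIN = CharacterDef(id="spur", kind="binary", module="perianth")


class TestCharacterDef:
    def test_ordered_levels_required_exactly_for_ordered(self):
        with pytest.raises(ConfigError):
            CharacterDef(id="x", kind="ordered_categorical", module="general")
        with pytest.raises(ConfigError):
            CharacterDef(id="x", kind="binary", module="general", ordered_levels=("a", "b"))

    def test_log_transform_numeric_only(self):
        with pytest.raises(ConfigError):
            CharacterDef(id="x", kind="binary", module="general", log_transform=True)


class TestParsing:
    @pytest.mark.parametrize(
        "token,cdef,expected",
        [
            ("5", NUM, Cell.single(5)),
            ("?", NUM, Cell.MISSING),
            ("", CAT, Cell.MISSING),
            ("4-6", NUM, Cell.poly_range(4, 6)),
            ("red|white", CAT, Cell.poly_set(["red", "white"])),
            ("free|full", ORD, Cell.poly_set(["free", "full"])),
            ("3|5", NUM, Cell.poly_set([3, 5])),
        ],
    )
    def test_tokens(self, token, cdef, expected):
        assert parse_cell(token, cdef) == expected

    def test_undeclared_ordered_state_rejected(self):
        with pytest.raises(ValidationError):
            parse_cell("half", ORD)

    def test_undeclared_binary_state_rejected(self):
        bin_lev = CharacterDef(
            id="spur2", kind="binary", module="perianth", levels=("absent", "present")
        )
        with pytest.raises(ValidationError):
            parse_cell("maybe", bin_lev)

    def test_polymorphic_range_needs_lo_lt_hi(self):
        with pytest.raises(ValidationError):
            Cell.poly_range(6, 4)


class TestLoadDataset:
    def _write(self, tmp_path, matrix_text):
        (tmp_path / "m.csv").write_text(matrix_text)
        (tmp_path / "chars.yaml").write_text(
            "characters:\n"
            "  - {id: petals, kind: numeric, module: perianth}\n"
            "  - id: fusion\n"
            "    kind: ordered_categorical\n"
            "    module: perianth\n"
            "    ordered_levels: [free, basal, full]\n"
        )
        (tmp_path / "meta.csv").write_text(
            "taxon,family,clade,is_fossil\nA,F1,C1,false\nB,F1,C1,false\nC,F2,C1,true\n"
        )
        return fm.load_dataset(
            tmp_path / "m.csv", tmp_path / "chars.yaml", tmp_path / "meta.csv"
        )

    def test_basic_parse(self, tmp_path):
        m = self._write(tmp_path, "taxon,petals,fusion\nA,5,free\nB,4-6,basal\nC,?,full\n")
        assert m.n_taxa == 3 and m.n_characters == 2
        assert m.cell("A", "petals") == Cell.single(5)
        assert m.cell("B", "petals") == Cell.poly_range(4, 6)
        assert m.cell("C", "petals").is_missing
        assert m.taxon_meta.loc["C", "is_fossil"]

    def test_unknown_column_is_config_error(self, tmp_path):
        with pytest.raises(ConfigError):
            self._write(tmp_path, "taxon,petals,fusion,extra\nA,5,free,1\nB,5,free,1\nC,5,free,1\n")

    def test_bad_state_reports_coordinates(self, tmp_path):
        with pytest.raises(ValidationError) as err:
            self._write(tmp_path, "taxon,petals,fusion\nA,5,wrong\nB,5,free\nC,5,free\n")
        assert "'A'" in str(err.value) and "fusion" in str(err.value)

    def test_duplicate_taxon_rejected(self, tmp_path):
        with pytest.raises(ValidationError):
            self._write(tmp_path, "taxon,petals,fusion\nA,5,free\nA,5,free\nC,5,free\n")


class TestRoundTrip:
    def test_write_then_reload_identical(self, tmp_path, small_synthetic):
        raw, _, _ = small_synthetic
        paths = [tmp_path / n for n in ("m.csv", "c.yaml", "t.csv", "f.csv")]
        write_dataset(raw, *paths)
        again = fm.load_dataset(*paths)
        assert again.taxa == raw.taxa
        assert again.characters == raw.characters
        assert (again.cells == raw.cells).all()
        assert again.taxon_meta.equals(raw.taxon_meta)


class TestResolvePolymorphisms:
    def test_range_resolves_inside_range(self):
        m = make_matrix(["A", "B"], [NUM], [[(4, 6)], [5]])
        for seed in range(10):
            r = fm.resolve_polymorphisms(m, seed=seed)
            assert r.cells[0, 0].value in (4, 5, 6)
        assert r.cells[1, 0] == Cell.single(5)

    def test_identity_without_polymorphisms_and_missing_untouched(self):
        m = make_matrix(["A", "B"], [NUM, CAT], [[4, "red"], [None, "white"]])
        r = fm.resolve_polymorphisms(m, seed=0)
        assert (r.cells == m.cells).all()
        assert r.cells[1, 0].is_missing

    def test_deterministic_given_seed(self):
        m = make_matrix(
            ["A", "B", "C"],
            [NUM, CAT],
            [[(2, 9), {"red", "white"}], [(1, 4), "red"], [3, {"red", "blue"}]],
        )
        r1 = fm.resolve_polymorphisms(m, seed=42)
        r2 = fm.resolve_polymorphisms(m, seed=42)
        assert (r1.cells == r2.cells).all()
        assert not any(c.is_polymorphic for c in r1.cells.flat)

    def test_uniform_over_range(self):
        m = make_matrix(["A"], [NUM], [[(4, 6)]])
        draws = [fm.resolve_polymorphisms(m, seed=s).cells[0, 0].value for s in range(300)]
        counts = {v: draws.count(v) for v in (4, 5, 6)}
        assert all(60 <= c <= 140 for c in counts.values()), counts


class TestApplyTransforms:
    LOGNUM = CharacterDef(id="stamens", kind="numeric", module="androecium", log_transform=True)

    def test_flagged_character_logged(self):
        m = make_matrix(["A", "B"], [self.LOGNUM, NUM], [[100, 5], [10, 7]])
        t = fm.apply_transforms(m)
        assert t.cells[0, 0].value == pytest.approx(math.log(100))
        assert t.cells[0, 1].value == 5  # unflagged untouched

    def test_non_positive_value_rejected(self):
        m = make_matrix(["A"], [self.LOGNUM], [[0]])
        with pytest.raises(ValidationError):
            fm.apply_transforms(m)

    def test_downstream_difference_is_log_base_invariant(self):
        # |log x - log y| / (log max - log min) identical for ln and log10
        vals = [3, 20, 400]
        ln = [math.log(v) for v in vals]
        l10 = [math.log10(v) for v in vals]
        d_ln = abs(ln[0] - ln[1]) / (max(ln) - min(ln))
        d_l10 = abs(l10[0] - l10[1]) / (max(l10) - min(l10))
        assert d_ln == pytest.approx(d_l10)


class TestSummarize:
    def test_missing_percentages(self):
        grid = [[1, "red", None, "x", 2] for _ in range(2)]
        chars = [
            NUM, CAT,
            CharacterDef(id="c3", kind="numeric", module="general"),
            BIN,
            CharacterDef(id="c5", kind="numeric", module="gynoecium"),
        ]
        grid[0][0] = None  # 3 missing of 10
        m = make_matrix(["A", "B"], chars, grid)
        s = fm.summarize_dataset(m)
        assert s.total_cells == 10
        assert s.missing_cells == 3
        assert s.missing_pct == pytest.approx(30.0)
        assert s.missing_pct_per_character["c3"] == pytest.approx(100.0)

    def test_no_missing_is_zero_pct(self):
        m = make_matrix(["A", "B"], [NUM], [[1], [2]])
        s = fm.summarize_dataset(m)
        assert s.missing_pct == 0.0 and s.scored_cells == 2
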