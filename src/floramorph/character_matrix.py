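"""Typed discrete character matrices: data model, file I/O, polymorphism
resolution and value transforms.

A character matrix records, for each taxon (row) and morphological character
(column), a single state, a missing entry, or a polymorphic entry (several
possible states, e.g. "4-6 petals").  Characters are typed: discrete numeric,
ordered categorical, unordered categorical, or binary, and each belongs to one
of four floral functional modules (general, perianth, androecium, gynoecium).

File dialect (common morphology-matrix conventions):

* matrix: delimited text (comma or tab), taxa as rows, first column ``taxon``,
  header row of character ids; missing token ``?``; polymorphic set separator
  ``|`` (e.g. ``red|white``); inclusive numeric range ``lo-hi`` (e.g. ``4-6``).
* character configuration: YAML listing per character its kind, module,
  ordered levels (ordered characters), optional declared levels (categorical
  validation) and log-transform flag.
* taxon metadata: delimited text with columns taxon, family, clade, is_fossil;
  family metadata with columns family, n_species, stem_age_ma.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

KINDS = ("numeric", "ordered_categorical", "unordered_categorical", "binary")
MODULES = ("general", "perianth", "androecium", "gynoecium")

MISSING_TOKEN = "?"
SET_SEPARATOR = "|"
RANGE_SEPARATOR = "-"


class ConfigError(ValueError):
    """Character configuration is inconsistent with the matrix."""


class ValidationError(ValueError):
    """A cell or metadata entry violates the declared character types."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CharacterDef:
    """Typed description of one character.

    Parameters
    ----------
    id
        Unique character label.
    kind
        One of ``numeric``, ``ordered_categorical``, ``unordered_categorical``,
        ``binary``.
    module
        Functional module: ``general``, ``perianth``, ``androecium`` or
        ``gynoecium``.
    ordered_levels
        Ordered list of state labels; required for (and restricted to)
        ordered-categorical characters.
    levels
        Optional declared state labels for unordered/binary characters, used
        for validation only.
    log_transform
        Natural-log transform flag; only allowed for numeric characters.
    """

    id: str
    kind: str
    module: str
    ordered_levels: tuple[str, ...] = ()
    levels: tuple[str, ...] = ()
    log_transform: bool = False

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ConfigError(f"character {self.id!r}: unknown kind {self.kind!r}")
        if self.module not in MODULES:
            raise ConfigError(f"character {self.id!r}: unknown module {self.module!r}")
        if (self.kind == "ordered_categorical") != bool(self.ordered_levels):
            raise ConfigError(
                f"character {self.id!r}: ordered_levels must be given exactly "
                "for ordered_categorical characters"
            )
        if self.log_transform and self.kind != "numeric":
            raise ConfigError(
                f"character {self.id!r}: log_transform requires a numeric character"
            )
        if self.levels and self.kind not in ("unordered_categorical", "binary"):
            raise ConfigError(
                f"character {self.id!r}: declared levels only apply to "
                "unordered/binary characters"
            )
        if self.kind == "binary" and self.levels and len(self.levels) != 2:
            raise ConfigError(f"character {self.id!r}: binary characters have 2 levels")
        object.__setattr__(self, "ordered_levels", tuple(self.ordered_levels))
        object.__setattr__(self, "levels", tuple(self.levels))


@dataclass(frozen=True)
class Cell:
    """One matrix entry: a single state, missing, or a polymorphism.

    ``states`` holds one state (single), none (missing), at least two distinct
    states (polymorphic set), or a ``(lo, hi)`` pair with ``lo < hi``
    interpreted as the inclusive integer range (polymorphic numeric range).
    """

    states: tuple = ()
    is_range: bool = False

    MISSING: "Cell" = None  # set below

    @staticmethod
    def single(value) -> "Cell":
        return Cell(states=(value,))

    @staticmethod
    def poly_set(values: Iterable) -> "Cell":
        vals = tuple(dict.fromkeys(values))  # dedupe, preserve order
        if len(vals) < 2:
            raise ValidationError("polymorphic sets need >= 2 distinct states")
        return Cell(states=vals)

    @staticmethod
    def poly_range(lo, hi) -> "Cell":
        if not lo < hi:
            raise ValidationError(f"polymorphic range needs lo < hi, got {lo}-{hi}")
        return Cell(states=(lo, hi), is_range=True)

    @property
    def is_missing(self) -> bool:
        return not self.states

    @property
    def is_polymorphic(self) -> bool:
        return self.is_range or len(self.states) > 1

    @property
    def value(self):
        """The single state; raises unless the cell is monomorphic."""
        if self.is_missing or self.is_polymorphic:
            raise ValidationError(f"cell {self!r} has no single value")
        return self.states[0]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        if self.is_missing:
            return "Cell(?)"
        if self.is_range:
            return f"Cell({self.states[0]}-{self.states[1]})"
        return f"Cell({'|'.join(map(str, self.states))})"


Cell.MISSING = Cell()


@dataclass
class CharacterMatrix:
    """A taxa x characters grid of :class:`Cell` plus taxon/family metadata.

    ``taxon_meta`` is indexed by taxon with columns ``family``, ``clade``,
    ``is_fossil``; ``family_meta`` is indexed by family with columns
    ``n_species`` and ``stem_age_ma`` (may be empty).
    """

    taxa: list[str]
    characters: list[CharacterDef]
    cells: np.ndarray  # object array, shape (n_taxa, n_characters)
    taxon_meta: pd.DataFrame
    family_meta: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["n_species", "stem_age_ma"])
    )

    def __post_init__(self) -> None:
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise ValidationError(f"duplicate taxon labels: {dupes}")
        ids = [c.id for c in self.characters]
        if len(set(ids)) != len(ids):
            raise ConfigError("duplicate character ids")
        if self.cells.shape != (len(self.taxa), len(self.characters)):
            raise ValidationError(
                f"cell grid shape {self.cells.shape} does not match "
                f"{len(self.taxa)} taxa x {len(self.characters)} characters"
            )
        meta = self.taxon_meta.copy()
        for col, default in (("family", None), ("clade", ""), ("is_fossil", False)):
            if col not in meta.columns:
                if default is None:
                    raise ValidationError("taxon metadata must assign every taxon a family")
                meta[col] = default
        missing = [t for t in self.taxa if t not in meta.index]
        if missing:
            raise ValidationError(f"taxa without metadata: {missing[:5]}")
        meta["is_fossil"] = meta["is_fossil"].astype(bool)
        self.taxon_meta = meta.loc[self.taxa]

    # -- convenience ----------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return len(self.characters)

    @property
    def character_ids(self) -> list[str]:
        return [c.id for c in self.characters]

    def character_index(self, char_id: str) -> int:
        try:
            return self.character_ids.index(char_id)
        except ValueError:
            raise ConfigError(f"unknown character id {char_id!r}") from None

    def module_characters(self, module: str) -> list[str]:
        if module not in MODULES:
            raise ConfigError(f"unknown module {module!r}")
        return [c.id for c in self.characters if c.module == module]

    def cell(self, taxon: str, char_id: str) -> Cell:
        return self.cells[self.taxa.index(taxon), self.character_index(char_id)]

    def has_polymorphisms(self) -> bool:
        return any(c.is_polymorphic for c in self.cells.flat)

    def subset_taxa(self, taxa: Sequence[str]) -> "CharacterMatrix":
        idx = [self.taxa.index(t) for t in taxa]
        return CharacterMatrix(
            taxa=list(taxa),
            characters=list(self.characters),
            cells=self.cells[idx, :].copy(),
            taxon_meta=self.taxon_meta.loc[list(taxa)].copy(),
            family_meta=self.family_meta.copy(),
        )

    def extant_taxa(self) -> list[str]:
        return [t for t in self.taxa if not self.taxon_meta.loc[t, "is_fossil"]]

    def fossil_taxa(self) -> list[str]:
        return [t for t in self.taxa if self.taxon_meta.loc[t, "is_fossil"]]

    def copy(self) -> "CharacterMatrix":
        return CharacterMatrix(
            taxa=list(self.taxa),
            characters=list(self.characters),
            cells=self.cells.copy(),
            taxon_meta=self.taxon_meta.copy(),
            family_meta=self.family_meta.copy(),
        )

    def groups(self, level: str) -> pd.Series:
        """Group label per taxon at ``level`` ('family' or 'clade')."""
        if level not in ("family", "clade"):
            raise ValidationError(f"grouping level must be family or clade, got {level!r}")
        return self.taxon_meta[level]


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------


def _parse_number(token: str):
    x = float(token)
    return int(x) if x == int(x) and "." not in token and "e" not in token.lower() else x


def parse_cell(token: str, cdef: CharacterDef) -> Cell:
    """Parse one matrix token according to the character's type."""
    token = str(token).strip()
    if token == "" or token == MISSING_TOKEN:
        return Cell.MISSING
    if SET_SEPARATOR in token:
        parts = [p.strip() for p in token.split(SET_SEPARATOR)]
        if cdef.kind == "numeric":
            return Cell.poly_set([_parse_number(p) for p in parts])
        for p in parts:
            _check_state(p, cdef)
        return Cell.poly_set(parts)
    if cdef.kind == "numeric":
        range_match = re.fullmatch(r"(\d+(?:\.\d+)?)-(\d+(?:\.\d+)?)", token)
        if range_match:
            return Cell.poly_range(
                _parse_number(range_match.group(1)), _parse_number(range_match.group(2))
            )
        try:
            return Cell.single(_parse_number(token))
        except ValueError:
            raise ValidationError(
                f"character {cdef.id!r}: cannot parse numeric token {token!r}"
            ) from None
    _check_state(token, cdef)
    return Cell.single(token)


def _check_state(state: str, cdef: CharacterDef) -> None:
    if cdef.kind == "ordered_categorical" and state not in cdef.ordered_levels:
        raise ValidationError(
            f"character {cdef.id!r}: state {state!r} not among ordered levels "
            f"{list(cdef.ordered_levels)}"
        )
    if cdef.kind in ("unordered_categorical", "binary") and cdef.levels and state not in cdef.levels:
        raise ValidationError(
            f"character {cdef.id!r}: state {state!r} not among declared levels "
            f"{list(cdef.levels)}"
        )


def format_cell(cell: Cell, cdef: CharacterDef) -> str:
    """Inverse of :func:`parse_cell` (used by the writer; round-trip safe)."""
    if cell.is_missing:
        return MISSING_TOKEN
    if cell.is_range:
        return f"{cell.states[0]}{RANGE_SEPARATOR}{cell.states[1]}"
    return SET_SEPARATOR.join(str(s) for s in cell.states)


def load_character_config(config_path: str | Path) -> list[CharacterDef]:
    with open(config_path) as fh:
        raw = yaml.safe_load(fh)
    entries = raw["characters"] if isinstance(raw, dict) else raw
    defs = []
    for entry in entries:
        defs.append(
            CharacterDef(
                id=str(entry["id"]),
                kind=entry["kind"],
                module=entry["module"],
                ordered_levels=tuple(map(str, entry.get("ordered_levels") or ())),
                levels=tuple(map(str, entry.get("levels") or ())),
                log_transform=bool(entry.get("log_transform", False)),
            )
        )
    return defs


def _read_delimited(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)


def load_dataset(
    matrix_path: str | Path,
    config_path: str | Path,
    meta_path: str | Path,
    family_meta_path: str | Path | None = None,
) -> CharacterMatrix:
    """Load a character matrix with its typed configuration and metadata.

    Raises :class:`ConfigError` for matrix columns absent from the config and
    :class:`ValidationError` for unparseable cells (reported with taxon and
    character coordinates) or duplicate taxa.
    """
    defs = load_character_config(config_path)
    by_id = {d.id: d for d in defs}
    table = _read_delimited(matrix_path)
    taxon_col = table.columns[0]
    char_cols = list(table.columns[1:])
    unknown = [c for c in char_cols if c not in by_id]
    if unknown:
        raise ConfigError(f"matrix columns missing from config: {unknown}")
    characters = [by_id[c] for c in char_cols]
    taxa = [str(t).strip() for t in table[taxon_col]]

    cells = np.empty((len(taxa), len(characters)), dtype=object)
    errors = []
    for j, cdef in enumerate(characters):
        col = table[cdef.id].tolist()
        for i, token in enumerate(col):
            try:
                cells[i, j] = parse_cell(token, cdef)
            except (ValidationError, ValueError) as exc:
                errors.append(f"  taxon {taxa[i]!r}, character {cdef.id!r}: {exc}")
    if errors:
        raise ValidationError("cell parse errors:\n" + "\n".join(errors[:20]))

    meta = _read_delimited(meta_path)
    meta = meta.set_index(meta.columns[0])
    if "is_fossil" in meta.columns:
        meta["is_fossil"] = meta["is_fossil"].astype(str).str.lower().isin(
            ("1", "true", "yes")
        )
    fam_meta = pd.DataFrame(columns=["n_species", "stem_age_ma"])
    if family_meta_path is not None:
        fam_meta = _read_delimited(family_meta_path).set_index("family")
        fam_meta = fam_meta.apply(pd.to_numeric, errors="coerce")
    return CharacterMatrix(
        taxa=taxa, characters=characters, cells=cells, taxon_meta=meta, family_meta=fam_meta
    )


def write_dataset(
    m: CharacterMatrix,
    matrix_path: str | Path,
    config_path: str | Path,
    meta_path: str | Path,
    family_meta_path: str | Path | None = None,
) -> None:
    """Write the matrix, character config and metadata in the read dialect."""
    rows = {}
    for j, cdef in enumerate(m.characters):
        rows[cdef.id] = [format_cell(m.cells[i, j], cdef) for i in range(m.n_taxa)]
    table = pd.DataFrame(rows, index=pd.Index(m.taxa, name="taxon"))
    table.to_csv(matrix_path)

    entries = []
    for cdef in m.characters:
        entry: dict = {"id": cdef.id, "kind": cdef.kind, "module": cdef.module}
        if cdef.ordered_levels:
            entry["ordered_levels"] = list(cdef.ordered_levels)
        if cdef.levels:
            entry["levels"] = list(cdef.levels)
        if cdef.log_transform:
            entry["log_transform"] = True
        entries.append(entry)
    with open(config_path, "w") as fh:
        yaml.safe_dump({"characters": entries}, fh, sort_keys=False)

    meta = m.taxon_meta.copy()
    meta.index.name = "taxon"
    meta.to_csv(meta_path)
    if family_meta_path is not None:
        fam = m.family_meta.copy()
        fam.index.name = "family"
        fam.to_csv(family_meta_path)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def resolve_polymorphisms(m: CharacterMatrix, seed: int) -> CharacterMatrix:
    """Replace every polymorphic cell by one state drawn uniformly.

    Numeric ranges are treated as the inclusive integer set {lo..hi} (organ
    counts are integers).  Missing and monomorphic cells are untouched; the
    result is deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    out = m.copy()
    for i in range(out.n_taxa):
        for j in range(out.n_characters):
            cell = out.cells[i, j]
            if not cell.is_polymorphic:
                continue
            if cell.is_range:
                lo, hi = cell.states
                if not (float(lo).is_integer() and float(hi).is_integer()):
                    raise ValidationError(
                        f"non-integer polymorphic range {lo}-{hi} for "
                        f"character {out.characters[j].id!r}"
                    )
                out.cells[i, j] = Cell.single(int(rng.integers(int(lo), int(hi) + 1)))
            else:
                out.cells[i, j] = Cell.single(
                    cell.states[int(rng.integers(len(cell.states)))]
                )
    return out


def apply_transforms(m: CharacterMatrix) -> CharacterMatrix:
    """Natural-log transform the flagged numeric characters.

    Tames heavy right tails (e.g. stamen and ovule counts spanning orders of
    magnitude) before range normalisation.  Downstream per-character
    differences are invariant to the log base, since the base cancels in
    |log x - log y| / (log max - log min).  Requires resolved cells and
    strictly positive values on flagged characters.
    """
    out = m.copy()
    for j, cdef in enumerate(out.characters):
        if not cdef.log_transform:
            continue
        for i in range(out.n_taxa):
            cell = out.cells[i, j]
            if cell.is_missing:
                continue
            if cell.is_polymorphic:
                raise ValidationError(
                    f"apply_transforms requires resolved cells; polymorphic cell at "
                    f"taxon {out.taxa[i]!r}, character {cdef.id!r}"
                )
            v = cell.value
            if not v > 0:
                raise ValidationError(
                    f"log transform of non-positive value {v!r} at taxon "
                    f"{out.taxa[i]!r}, character {cdef.id!r}"
                )
            out.cells[i, j] = Cell.single(math.log(v))
    return out


@dataclass
class DatasetSummary:
    """Cell bookkeeping: totals, missing and polymorphic counts/fractions."""

    n_taxa: int
    n_characters: int
    total_cells: int
    scored_cells: int
    missing_cells: int
    missing_pct: float
    polymorphic_cells: int
    polymorphic_pct: float
    missing_pct_per_taxon: pd.Series
    missing_pct_per_character: pd.Series

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "value": [
                    self.n_taxa,
                    self.n_characters,
                    self.total_cells,
                    self.scored_cells,
                    self.missing_cells,
                    self.missing_pct,
                    self.polymorphic_cells,
                    self.polymorphic_pct,
                ]
            },
            index=[
                "n_taxa",
                "n_characters",
                "total_cells",
                "scored_cells",
                "missing_cells",
                "missing_pct",
                "polymorphic_cells",
                "polymorphic_pct",
            ],
        )


def summarize_dataset(m: CharacterMatrix) -> DatasetSummary:
    """Count scored, missing and polymorphic cells, overall and marginally."""
    miss = np.array(
        [[cell.is_missing for cell in row] for row in m.cells], dtype=bool
    )
    poly = np.array(
        [[cell.is_polymorphic for cell in row] for row in m.cells], dtype=bool
    )
    total = m.n_taxa * m.n_characters
    n_miss = int(miss.sum())
    n_poly = int(poly.sum())
    return DatasetSummary(
        n_taxa=m.n_taxa,
        n_characters=m.n_characters,
        total_cells=total,
        scored_cells=total - n_miss,
        missing_cells=n_miss,
        missing_pct=100.0 * n_miss / total if total else 0.0,
        polymorphic_cells=n_poly,
        polymorphic_pct=100.0 * n_poly / total if total else 0.0,
        missing_pct_per_taxon=pd.Series(
            100.0 * miss.mean(axis=1), index=m.taxa, name="missing_pct"
        ),
        missing_pct_per_character=pd.Series(
            100.0 * miss.mean(axis=0), index=m.character_ids, name="missing_pct"
        ),
    )
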