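"""Mean character difference between taxa and per-character variation.

For two taxa A and B scored on N typed characters, the per-character
difference d_ABi is

* numeric: |x_A - x_B| divided by the observed range of the character in the
  dataset;
* ordered categorical: number of steps between the two states divided by the
  maximum observed step difference;
* binary / unordered categorical: 0 if the states are identical, 1 otherwise;
* if either cell is missing the character is dropped from the pair.

The mean character difference D_AB is the average of the applicable d_ABi,
over the N' <= N characters scored in both taxa.  D lies in [0, 1]; a pair
with N' = 0 is undefined and carried as NaN, never as zero.  Ranges and step
counts are recomputed from the observed, resolved, transformed matrix of each
analysis run, so a constant character contributes d = 0.

Dchar, the per-character mean of d_ABi over all scorable taxon pairs, ranks
characters by how much they vary across the dataset.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .character_matrix import Cell, CharacterDef, CharacterMatrix, ValidationError


class ArgumentError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Encoding: resolved typed cells -> float matrix + per-character scale
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EncodedMatrix:
    """Numeric view of a resolved matrix.

    ``values`` holds floats (NaN = missing): raw values for numeric
    characters, level indices for ordered characters, arbitrary category
    codes for unordered/binary ones.  ``scale`` is the observed range (or
    maximum step count); ``is_nominal`` marks characters compared by
    equality only.
    """

    taxa: tuple[str, ...]
    character_ids: tuple[str, ...]
    values: np.ndarray
    scale: np.ndarray
    is_nominal: np.ndarray


def encode_matrix(m: CharacterMatrix) -> EncodedMatrix:
    if m.has_polymorphisms():
        raise ValidationError(
            "matrix still contains polymorphic cells; resolve_polymorphisms first"
        )
    n, k = m.n_taxa, m.n_characters
    values = np.full((n, k), np.nan)
    scale = np.zeros(k)
    nominal = np.zeros(k, dtype=bool)
    for j, cdef in enumerate(m.characters):
        col = m.cells[:, j]
        if cdef.kind == "numeric":
            for i, cell in enumerate(col):
                if not cell.is_missing:
                    values[i, j] = float(cell.value)
        elif cdef.kind == "ordered_categorical":
            index = {lvl: float(r) for r, lvl in enumerate(cdef.ordered_levels)}
            for i, cell in enumerate(col):
                if not cell.is_missing:
                    values[i, j] = index[str(cell.value)]
        else:
            nominal[j] = True
            codes: dict[str, float] = {}
            for i, cell in enumerate(col):
                if not cell.is_missing:
                    state = str(cell.value)
                    values[i, j] = codes.setdefault(state, float(len(codes)))
        if not nominal[j]:
            colv = values[:, j]
            if np.isnan(colv).all():
                scale[j] = 0.0
            else:
                scale[j] = float(np.nanmax(colv) - np.nanmin(colv))
    return EncodedMatrix(
        taxa=tuple(m.taxa),
        character_ids=tuple(m.character_ids),
        values=values,
        scale=scale,
        is_nominal=nominal,
    )


def character_ranges(m: CharacterMatrix) -> pd.Series:
    """Observed range (numeric) or max step count (ordered) per character."""
    enc = encode_matrix(m)
    return pd.Series(enc.scale, index=list(enc.character_ids), name="scale")


# ---------------------------------------------------------------------------
# Single-cell operation
# ---------------------------------------------------------------------------


def pairwise_difference(
    a: Cell, b: Cell, cdef: CharacterDef, range_info: pd.Series | dict
) -> float | None:
    """d_ABi for one character; ``None`` when either cell is missing.

    ``range_info`` maps character id to observed range / max steps (see
    :func:`character_ranges`); ignored for nominal characters.
    """
    if a.is_missing or b.is_missing:
        return None
    if a.is_polymorphic or b.is_polymorphic:
        raise ValidationError("pairwise_difference requires resolved cells")
    if cdef.kind in ("binary", "unordered_categorical"):
        return 0.0 if _norm_state(a.value) == _norm_state(b.value) else 1.0
    if cdef.kind == "ordered_categorical":
        index = {lvl: r for r, lvl in enumerate(cdef.ordered_levels)}
        va, vb = index[str(a.value)], index[str(b.value)]
    else:
        va, vb = float(a.value), float(b.value)
    scale = float(range_info[cdef.id])
    diff = abs(va - vb)
    if diff == 0.0:
        return 0.0
    if scale <= 0.0:
        raise RuntimeError(
            f"character {cdef.id!r}: zero observed range but differing values "
            f"{a.value!r} vs {b.value!r} (internal error)"
        )
    return diff / scale


def _norm_state(s) -> str:
    return str(s).strip().lower()


# ---------------------------------------------------------------------------
# Matrix-level operations
# ---------------------------------------------------------------------------


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise mean character differences with N' bookkeeping.

    ``values[i, j]`` is D between taxa i and j (NaN where N' = 0);
    ``effective_n[i, j]`` counts the characters scored in both taxa.
    """

    taxa: list[str]
    values: np.ndarray
    effective_n: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if v.shape != (n, n):
            raise ValidationError("dissimilarity matrix shape mismatch")
        if not np.allclose(np.diag(v), 0.0, equal_nan=False):
            raise ValidationError("dissimilarity diagonal must be zero")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValidationError("dissimilarity matrix must be symmetric")
        with np.errstate(invalid="ignore"):
            if np.nanmin(v) < -1e-12 or np.nanmax(v) > 1 + 1e-12:
                raise ValidationError("dissimilarity values must lie in [0, 1]")
        self.values = v

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def condensed(self) -> np.ndarray:
        """Upper-triangle (i < j) values in scipy 'condensed' order."""
        iu = np.triu_indices(self.n_taxa, k=1)
        return self.values[iu]

    def has_undefined(self) -> bool:
        iu = np.triu_indices(self.n_taxa, k=1)
        return bool(np.isnan(self.values[iu]).any())

    def submatrix(self, taxa: Sequence[str]) -> "DissimilarityMatrix":
        idx = [self.taxa.index(t) for t in taxa]
        return DissimilarityMatrix(
            taxa=list(taxa),
            values=self.values[np.ix_(idx, idx)].copy(),
            effective_n=self.effective_n[np.ix_(idx, idx)].copy(),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.taxa, columns=self.taxa)

    def write(self, path: str | Path) -> None:
        df = self.to_dataframe()
        df.index.name = "taxon"
        df.to_csv(path)

    @staticmethod
    def read(path: str | Path) -> "DissimilarityMatrix":
        df = pd.read_csv(path, index_col=0)
        values = df.to_numpy(dtype=float)
        n_eff = np.full_like(values, -1, dtype=int)  # unknown after round-trip
        return DissimilarityMatrix(
            taxa=[str(t) for t in df.index], values=values, effective_n=n_eff
        )


def per_character_differences(
    m: CharacterMatrix, subset: Sequence[str] | None = None
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, str]]]:
    """Per-pair, per-character differences.

    Returns ``(d, applicable, pairs)`` where ``d`` has shape
    (n_pairs, n_characters_in_subset) with NaN where a character is missing in
    either taxon, ``applicable`` is the boolean complement of that mask, and
    ``pairs`` lists the (i < j) taxon label pairs in condensed order.

    This is the workhorse shared by the dissimilarity matrix, Dchar and the
    random-character-subset module test.
    """
    enc = encode_matrix(m)
    cols = _subset_columns(enc, subset)
    n = len(enc.taxa)
    iu, ju = np.triu_indices(n, k=1)
    d = np.empty((len(iu), len(cols)))
    for out_j, j in enumerate(cols):
        col = enc.values[:, j]
        diff = np.abs(col[iu] - col[ju])
        if enc.is_nominal[j]:
            with np.errstate(invalid="ignore"):
                dj = (diff > 0).astype(float)
            dj[np.isnan(diff)] = np.nan
        else:
            scale = enc.scale[j]
            if scale > 0:
                dj = diff / scale
            else:
                dj = np.where(np.isnan(diff), np.nan, 0.0)
        d[:, out_j] = dj
    pairs = [(enc.taxa[i], enc.taxa[j]) for i, j in zip(iu, ju)]
    return d, ~np.isnan(d), pairs


def _subset_columns(enc: EncodedMatrix, subset: Sequence[str] | None) -> list[int]:
    if subset is None:
        return list(range(len(enc.character_ids)))
    if len(subset) == 0:
        raise ArgumentError("character subset must be non-empty")
    index = {cid: j for j, cid in enumerate(enc.character_ids)}
    try:
        return [index[c] for c in subset]
    except KeyError as exc:
        raise ArgumentError(f"unknown character id {exc.args[0]!r}") from None


def mean_character_difference(
    a: str, b: str, m: CharacterMatrix
) -> tuple[float, int]:
    """(D, N') for one taxon pair; D is NaN when no shared character is scored."""
    d, applicable, pairs = per_character_differences(m)
    key = (a, b) if (a, b) in pairs else (b, a)
    try:
        row = pairs.index(key)
    except ValueError:
        if a == b:
            return 0.0, int(
                sum(
                    not m.cells[m.taxa.index(a), j].is_missing
                    for j in range(m.n_characters)
                )
            )
        raise ArgumentError(f"unknown taxon pair ({a!r}, {b!r})") from None
    n_eff = int(applicable[row].sum())
    if n_eff == 0:
        return float("nan"), 0
    return float(np.nanmean(d[row])), n_eff


def dissimilarity_matrix(
    m: CharacterMatrix, subset: Sequence[str] | None = None
) -> DissimilarityMatrix:
    """Mean character difference for every taxon pair.

    ``subset`` restricts the computation to the given character ids (used for
    the per-module morphospaces); ranges are still taken from the full matrix
    passed in, because encoding happens on ``m`` as given.
    """
    d, applicable, _ = per_character_differences(m, subset)
    n = m.n_taxa
    n_eff_cond = applicable.sum(axis=1)
    with np.errstate(invalid="ignore"):
        d_cond = np.where(
            n_eff_cond > 0,
            np.nansum(d, axis=1) / np.maximum(n_eff_cond, 1),
            np.nan,
        )
    values = np.zeros((n, n))
    n_eff = np.full((n, n), d.shape[1], dtype=int)
    iu, ju = np.triu_indices(n, k=1)
    values[iu, ju] = d_cond
    values[ju, iu] = d_cond
    n_eff[iu, ju] = n_eff_cond
    n_eff[ju, iu] = n_eff_cond
    return DissimilarityMatrix(taxa=list(m.taxa), values=values, effective_n=n_eff)


def character_variation(m: CharacterMatrix) -> pd.Series:
    """Dchar: mean d_ABi per character over all pairs where it is scored twice.

    NaN for characters scored in fewer than two taxa.
    """
    d, applicable, _ = per_character_differences(m)
    counts = applicable.sum(axis=0)
    with np.errstate(invalid="ignore"):
        dchar = np.where(counts > 0, np.nansum(d, axis=0) / np.maximum(counts, 1), np.nan)
    return pd.Series(dchar, index=m.character_ids, name="Dchar")
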