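import numpy as np
import pandas as pd
import pytest

from floramorph.character_matrix import Cell, CharacterDef, CharacterMatrix
from floramorph.dissimilarity import DissimilarityMatrix


def make_matrix(taxa, characters, grid, families=None, clades=None, fossils=None):
    """Build a CharacterMatrix from a grid of plain tokens.

    Grid entries: a value (state), None (missing), a set (polymorphic set) or
    a 2-tuple (polymorphic integer range).
    """
    cells = np.empty((len(taxa), len(characters)), dtype=object)
    for i, row in enumerate(grid):
        for j, entry in enumerate(row):
            if entry is None:
                cells[i, j] = Cell.MISSING
            elif isinstance(entry, set):
                cells[i, j] = Cell.poly_set(sorted(entry, key=str))
            elif isinstance(entry, tuple):
                cells[i, j] = Cell.poly_range(*entry)
            else:
                cells[i, j] = Cell.single(entry)
    meta = pd.DataFrame(
        {
            "family": families or ["FamA"] * len(taxa),
            "clade": clades or ["C1"] * len(taxa),
            "is_fossil": fossils or [False] * len(taxa),
        },
        index=pd.Index(taxa, name="taxon"),
    )
    return CharacterMatrix(
        taxa=list(taxa), characters=list(characters), cells=cells, taxon_meta=meta
    )


def dissim_from_square(values, taxa=None):
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    taxa = taxa or [f"t{i}" for i in range(n)]
    return DissimilarityMatrix(
        taxa=list(taxa), values=values, effective_n=np.full((n, n), 1, dtype=int)
    )


def random_mixed_matrix(rng, n_taxa=6, n_chars=5, missing_rate=0.15):
    """Random small mixed-type matrix for oracle-equivalence checks."""
    kinds = ["numeric", "ordered_categorical", "unordered_categorical", "binary"]
    characters = []
    grid_cols = []
    for j in range(n_chars):
        kind = kinds[j % len(kinds)]
        module = ["general", "perianth", "androecium", "gynoecium"][j % 4]
        if kind == "numeric":
            characters.append(CharacterDef(id=f"c{j}", kind=kind, module=module))
            col = [int(rng.integers(1, 12)) for _ in range(n_taxa)]
        elif kind == "ordered_categorical":
            levels = ("a", "b", "c", "d")
            characters.append(
                CharacterDef(id=f"c{j}", kind=kind, module=module, ordered_levels=levels)
            )
            col = [levels[int(rng.integers(4))] for _ in range(n_taxa)]
        else:
            levels = ("x", "y") if kind == "binary" else ("x", "y", "z")
            characters.append(CharacterDef(id=f"c{j}", kind=kind, module=module))
            col = [levels[int(rng.integers(len(levels)))] for _ in range(n_taxa)]
        col = [None if rng.random() < missing_rate else v for v in col]
        grid_cols.append(col)
    grid = [[grid_cols[j][i] for j in range(n_chars)] for i in range(n_taxa)]
    taxa = [f"t{i}" for i in range(n_taxa)]
    return make_matrix(taxa, characters, grid)


def naive_mean_character_difference(m, i, j):
    """Independent cell-by-cell evaluation of the dissimilarity rules.

    Recomputes observed ranges and step counts from scratch with plain
    loops; returns (D, N') or (nan, 0).
    """
    import math

    total, n_eff = 0.0, 0
    for k, cdef in enumerate(m.characters):
        a, b = m.cells[i, k], m.cells[j, k]
        if a.is_missing or b.is_missing:
            continue
        if cdef.kind in ("binary", "unordered_categorical"):
            d = 0.0 if str(a.value) == str(b.value) else 1.0
        elif cdef.kind == "ordered_categorical":
            idx = {s: r for r, s in enumerate(cdef.ordered_levels)}
            observed = [
                idx[str(m.cells[t, k].value)]
                for t in range(m.n_taxa)
                if not m.cells[t, k].is_missing
            ]
            max_steps = max(observed) - min(observed)
            steps = abs(idx[str(a.value)] - idx[str(b.value)])
            d = steps / max_steps if max_steps > 0 else 0.0
        else:
            observed = [
                float(m.cells[t, k].value)
                for t in range(m.n_taxa)
                if not m.cells[t, k].is_missing
            ]
            rng_ = max(observed) - min(observed)
            diff = abs(float(a.value) - float(b.value))
            d = diff / rng_ if rng_ > 0 else 0.0
        total += d
        n_eff += 1
    if n_eff == 0:
        return math.nan, 0
    return total / n_eff, n_eff


@pytest.fixture(scope="session")
def small_synthetic():
    """One resolved+transformed small synthetic dataset shared across tests."""
    import floramorph as fm

    cfg = fm.SimulationConfig.small(seed=11)
    m, truth = fm.generate_dataset(cfg)
    resolved = fm.prepare_matrix(m, seed=7)
    return m, resolved, truth
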