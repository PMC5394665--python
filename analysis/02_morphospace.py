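#!/usr/bin/env python
"""Build the floral morphospace: dissimilarity matrix + principal coordinates.

Resolves polymorphisms, log-transforms the heavy-tailed counts, computes the
mean character difference for every taxon pair (extant taxa), ordinates, and
reports how much of the dissimilarity structure low-dimensional plots retain.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import floramorph as fm
from floramorph.pipeline import child_seed

SEED = 20260926
ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "data" / "synthetic"
OUT = ROOT / "results"


def load_extant():
    if not (DATA / "matrix.csv").exists():
        sys.exit("run analysis/01_simulate_dataset.py first")
    m = fm.load_dataset(
        DATA / "matrix.csv", DATA / "characters.yaml", DATA / "taxa.csv",
        DATA / "families.csv",
    )
    extant = m.subset_taxa(m.extant_taxa())
    return m, fm.prepare_matrix(extant, seed=child_seed(SEED, "resolve"))


def main() -> None:
    OUT.mkdir(exist_ok=True)
    _, resolved = load_extant()
    d = fm.dissimilarity_matrix(resolved)
    d.write(OUT / "dissimilarity_matrix.csv")
    p = fm.pcoa(d)
    p.write(OUT / "pcoa_coordinates.csv", OUT / "pcoa_eigenvalues.csv")

    pct = 100 * p.variance_proportion
    print(f"dissimilarity matrix: {d.n_taxa} taxa, D in "
          f"[{d.condensed().min():.3f}, {d.condensed().max():.3f}]")
    print(f"PCoA: {p.n_axes} positive axes, negative eigenvalue mass "
          f"{p.negative_eigenvalue_mass:.2f}")
    print(f"axis variance: {pct[0]:.2f}%, {pct[1]:.2f}%, {pct[2]:.2f}% "
          f"(first three: {pct[:3].sum():.1f}%)")
    for k in (2, 3):
        r = fm.embedding_fidelity(d, p, k)
        print(f"embedding fidelity, {k} axes: Pearson r = {r:.2f}")
    print(f"wrote dissimilarity matrix and ordination to {OUT}")


if __name__ == "__main__":
    main()
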