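#!/usr/bin/env python
"""Do clades occupy distinct regions of the morphospace?

Overall PERMANOVA on the suprafamilial clades (10 000 permutations) plus
Bonferroni-corrected pairwise post hoc comparisons, presented as an
F-above / r2-below triangle table with 'n.s.' for indistinct pairs.
"""

import importlib.util
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import floramorph as fm
from floramorph.group_tests import posthoc_triangle_table
from floramorph.pipeline import child_seed

SEED = 20260926
ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"

spec = importlib.util.spec_from_file_location(
    "morphospace", Path(__file__).with_name("02_morphospace.py")
)
morphospace = importlib.util.module_from_spec(spec)
spec.loader.exec_module(morphospace)


def main() -> None:
    OUT.mkdir(exist_ok=True)
    _, resolved = morphospace.load_extant()
    d = fm.dissimilarity_matrix(resolved)
    clades = resolved.groups("clade")

    overall = fm.permanova(
        d, clades, n_perm=10_000, seed=child_seed(SEED, "permanova")
    )
    print(f"overall PERMANOVA (clades): F = {overall.statistic:.2f}, "
          f"r2 = {overall.effect_size:.2f}, p = {overall.p_value:.2g} "
          f"({overall.n_permutations} permutations)")

    posthoc = fm.permanova_posthoc(
        d, clades, n_perm=999, seed=child_seed(SEED, "posthoc")
    )
    posthoc.to_csv(OUT / "permanova_posthoc.csv", index=False)
    tri = posthoc_triangle_table(posthoc)
    tri.to_csv(OUT / "permanova_posthoc_table.csv")
    n_ns = int((posthoc["adjusted_p"] > 0.05).sum())
    print(f"post hoc: {len(posthoc)} clade pairs, {len(posthoc) - n_ns} "
          f"significantly separated after Bonferroni, {n_ns} n.s.")
    print(f"wrote post hoc tables to {OUT}")


if __name__ == "__main__":
    main()
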