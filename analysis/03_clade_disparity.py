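#!/usr/bin/env python
"""Per-family and per-clade disparity, and its correlates.

Computes mean pairwise dissimilarity, the range rarefied to 10 taxa, Foote
partial disparity per family/clade, and Spearman correlations of disparity
against family species richness and stem age.
"""

import importlib.util
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import numpy as np

import floramorph as fm
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
    p = fm.pcoa(d)

    for level in ("family", "clade"):
        table = fm.group_disparity_table(
            d, resolved.groups(level), p=p, n=10, reps=1000,
            seed=child_seed(SEED, f"disparity_{level}"),
        )
        table.to_csv(OUT / f"disparity_by_{level}.csv")
        most, least = table["mean_pairwise"].idxmax(), table["mean_pairwise"].idxmin()
        print(f"[{level}] most disparate: {most} "
              f"(D-bar = {table.loc[most, 'mean_pairwise']:.3f}, "
              f"R = {table.loc[most, 'range']:.3f}); least: {least} "
              f"(D-bar = {table.loc[least, 'mean_pairwise']:.3f})")
        top = table["pdiv_pct"].nlargest(4)
        print(f"[{level}] top partial-disparity groups: "
              + ", ".join(f"{g} {v:.1f}%" for g, v in top.items()))
        if level == "family":
            fam_table = table

    richness = np.log(resolved.family_meta["n_species"].astype(float))
    age = resolved.family_meta["stem_age_ma"].astype(float)
    rows = []
    for stat in ("mean_pairwise", "range", "pdiv"):
        for name, attr in (("log richness", richness), ("stem age", age)):
            res = fm.correlate_disparity(fam_table[stat], attr, method="spearman")
            rows.append((stat, name, res.statistic, res.p_value))
            print(f"Spearman {stat} vs {name}: rho = {res.statistic:.2f}, "
                  f"p = {res.p_value:.3g}")
    import pandas as pd

    pd.DataFrame(rows, columns=["statistic", "attribute", "rho", "p"]).to_csv(
        OUT / "disparity_correlations.csv", index=False
    )
    print(f"wrote disparity tables and correlations to {OUT}")


if __name__ == "__main__":
    main()
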