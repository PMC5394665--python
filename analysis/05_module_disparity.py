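#!/usr/bin/env python
"""How is floral disparity distributed among the functional modules?

Per-character variation (Dchar), Mantel tests of each module's dissimilarity
matrix against the whole-flower matrix, and the random-character-subset test
of whether the perianth, androecium and gynoecium are more or less variable
than same-size random character sets (1000 subsets, 97.5% criterion,
pseudo-p + 0.025 correction).
"""

import importlib.util
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import floramorph as fm
from floramorph.module_comparison import module_test_table
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

    dchar = fm.character_variation(resolved)
    dchar.to_csv(OUT / "character_variation.csv")
    print(f"Dchar: min {dchar.min():.3f} ({dchar.idxmin()}), "
          f"max {dchar.max():.3f} ({dchar.idxmax()}); "
          f"{(dchar <= 0.05).sum()} characters at Dchar <= 0.05, "
          f"{(dchar >= 0.5).sum()} at Dchar >= 0.5")

    results = []
    import pandas as pd

    mantel_rows = []
    for module in ("perianth", "androecium", "gynoecium"):
        chars = resolved.module_characters(module)
        dm = fm.dissimilarity_matrix(resolved, subset=chars)
        mres = fm.mantel(dm, d, n_perm=999, seed=child_seed(SEED, f"mantel_{module}"))
        mantel_rows.append(
            {"module": module, "r": mres.statistic, "p": mres.p_value,
             "n_pairs": mres.extra["n_pairs"]}
        )
        print(f"Mantel {module} ({len(chars)} characters, "
              f"{mres.extra['n_pairs']} taxon pairs): r = {mres.statistic:.2f}, "
              f"p = {mres.p_value:.3g}")
        t = fm.module_disparity_test(
            resolved, module, iterations=1000, seed=child_seed(SEED, f"module_{module}")
        )
        results.append(t)
        verdict = (
            f"significantly {'more' if t.tail == 'higher' else 'less'} variable"
            if t.significant
            else f"not significantly {'more' if t.tail == 'higher' else 'less'} variable"
        )
        print(f"module test {module}: observed D-bar = {t.observed:.3f}, "
              f"null mean = {t.null_mean:.3f}, pseudo-p = {t.pseudo_p:.3f} -> {verdict}")

    pd.DataFrame(mantel_rows).to_csv(OUT / "mantel_module_vs_total.csv", index=False)
    module_test_table(results).to_csv(OUT / "module_disparity_tests.csv")
    print(f"wrote module comparison tables to {OUT}")


if __name__ == "__main__":
    main()
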