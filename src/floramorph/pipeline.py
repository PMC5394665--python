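"""End-to-end orchestration: resolve -> transform -> dissimilarity -> PCoA ->
disparity/PDiv -> PERMANOVA/post hoc -> correlations -> Mantel -> module
tests -> optional fossil recomputation, with seeded reproducibility.

One global seed fans out deterministically to named per-stage child seeds, so
stages can be rerun independently yet reproducibly.  All tabular outputs are
delimited text; a run log records the seed and package versions.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .character_matrix import (
    CharacterMatrix,
    apply_transforms,
    load_dataset,
    resolve_polymorphisms,
    summarize_dataset,
)
from .dissimilarity import (
    DissimilarityMatrix,
    character_variation,
    dissimilarity_matrix,
)
from .disparity import group_disparity_table, partial_disparity
from .group_tests import (
    correlate_disparity,
    mantel,
    permanova,
    permanova_posthoc,
    posthoc_triangle_table,
)
from .module_comparison import module_disparity_test, module_test_table
from .ordination import PCoAResult, embedding_fidelity, pcoa

ANALYSIS_MODULES = ("perianth", "androecium", "gynoecium")


def child_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31, derived from the run seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Configuration of one full analysis run."""

    matrix_path: str | None = None
    config_path: str | None = None
    meta_path: str | None = None
    family_meta_path: str | None = None
    out_dir: str = "results"
    seed: int = 0
    n_permutations: int = 10_000
    posthoc_permutations: int = 10_000
    mantel_permutations: int = 999
    module_iterations: int = 1000
    rarefy_n: int = 10
    bootstrap_reps: int = 1000
    grouping: str = "clade"
    include_fossils: bool = False

    def __post_init__(self) -> None:
        if self.grouping not in ("family", "clade"):
            raise ValueError(f"grouping must be family or clade, got {self.grouping!r}")
        for count in (
            self.n_permutations,
            self.mantel_permutations,
            self.module_iterations,
            self.bootstrap_reps,
        ):
            if count < 1:
                raise ValueError("permutation/iteration counts must be positive")


@dataclass
class RunResult:
    """In-memory bundle of everything a run produced."""

    summary: pd.DataFrame
    dissimilarity: DissimilarityMatrix
    ordination: PCoAResult
    family_disparity: pd.DataFrame
    clade_disparity: pd.DataFrame
    permanova_overall: dict
    posthoc: pd.DataFrame
    correlations: pd.DataFrame
    dchar: pd.Series
    mantel_results: pd.DataFrame
    module_tests: pd.DataFrame
    fossil: dict = field(default_factory=dict)


def prepare_matrix(m: CharacterMatrix, seed: int) -> CharacterMatrix:
    """Resolve polymorphisms (seeded) and apply the log transforms."""
    return apply_transforms(resolve_polymorphisms(m, seed=seed))


def analyse_matrix(m: CharacterMatrix, cfg: RunConfig) -> RunResult:
    """Run every stage on an already-loaded (raw) character matrix.

    Extant taxa carry the main analysis; when ``cfg.include_fossils`` the
    morphospace and partial disparity are recomputed on the full taxon set
    (polymorphisms re-resolved and ranges recomputed over the enlarged set).
    """
    extant = m.subset_taxa(m.extant_taxa())
    resolved = prepare_matrix(extant, seed=child_seed(cfg.seed, "resolve"))
    summary = summarize_dataset(extant)

    d = dissimilarity_matrix(resolved)
    if d.has_undefined():
        bad = _undefined_taxa(d)
        raise RuntimeError(f"stage dissimilarity: undefined pairs involving taxa {bad}")
    ord_res = pcoa(d)

    families = resolved.groups("family")
    clades = resolved.groups("clade")
    fam_table = group_disparity_table(
        d, families, p=ord_res, n=cfg.rarefy_n, reps=cfg.bootstrap_reps,
        seed=child_seed(cfg.seed, "disparity_family"),
    )
    clade_table = group_disparity_table(
        d, clades, p=ord_res, n=cfg.rarefy_n, reps=cfg.bootstrap_reps,
        seed=child_seed(cfg.seed, "disparity_clade"),
    )

    grouping = families if cfg.grouping == "family" else clades
    overall = permanova(
        d, grouping, n_perm=cfg.n_permutations, seed=child_seed(cfg.seed, "permanova")
    )
    posthoc = permanova_posthoc(
        d, grouping, n_perm=cfg.posthoc_permutations,
        seed=child_seed(cfg.seed, "posthoc"),
    )

    correlations = _disparity_correlations(fam_table, resolved)
    dchar = character_variation(resolved)

    mantel_rows = []
    module_results = []
    for module in ANALYSIS_MODULES:
        chars = resolved.module_characters(module)
        dm = dissimilarity_matrix(resolved, subset=chars)
        res = mantel(
            dm, d, n_perm=cfg.mantel_permutations,
            seed=child_seed(cfg.seed, f"mantel_{module}"),
        )
        mantel_rows.append(
            {
                "module": module,
                "r": res.statistic,
                "p": res.p_value,
                "n_pairs": res.extra["n_pairs"],
                "n_permutations": res.n_permutations,
            }
        )
        module_results.append(
            module_disparity_test(
                resolved, module, iterations=cfg.module_iterations,
                seed=child_seed(cfg.seed, f"module_{module}"),
            )
        )

    fossil: dict = {}
    if cfg.include_fossils and m.fossil_taxa():
        fossil = _fossil_analysis(m, cfg)

    return RunResult(
        summary=summary.to_frame(),
        dissimilarity=d,
        ordination=ord_res,
        family_disparity=fam_table,
        clade_disparity=clade_table,
        permanova_overall={
            "F": overall.statistic,
            "r2": overall.effect_size,
            "p": overall.p_value,
            "n_permutations": overall.n_permutations,
        },
        posthoc=posthoc,
        correlations=correlations,
        dchar=dchar,
        mantel_results=pd.DataFrame(mantel_rows).set_index("module"),
        module_tests=module_test_table(module_results),
        fossil=fossil,
    )


def _undefined_taxa(d: DissimilarityMatrix) -> list[str]:
    und = np.isnan(d.values)
    np.fill_diagonal(und, False)
    return [t for t, n in zip(d.taxa, und.sum(axis=0)) if n > 0][:10]


def _disparity_correlations(
    fam_table: pd.DataFrame, m: CharacterMatrix
) -> pd.DataFrame:
    """Spearman correlations of family D-bar and R against log richness and
    stem age; families lacking metadata or statistics drop out pairwise."""
    rows = []
    meta = m.family_meta
    if meta.empty:
        return pd.DataFrame(
            columns=["statistic", "attribute", "rho", "p", "n"]
        ).set_index(["statistic", "attribute"])
    richness = np.log(meta["n_species"].astype(float))
    age = meta.get("stem_age_ma")
    for stat in ("mean_pairwise", "range", "pdiv"):
        x = fam_table[stat].reindex(meta.index)
        for attr_name, attr in (("log_richness", richness), ("stem_age_ma", age)):
            if attr is None:
                continue
            try:
                res = correlate_disparity(x, attr.astype(float), method="spearman")
            except Exception:
                continue
            rows.append(
                {
                    "statistic": stat,
                    "attribute": attr_name,
                    "rho": res.statistic,
                    "p": res.p_value,
                    "n": res.extra["n_groups"],
                }
            )
    return pd.DataFrame(rows).set_index(["statistic", "attribute"])


def _fossil_analysis(m: CharacterMatrix, cfg: RunConfig) -> dict:
    """Morphospace and partial disparity recomputed with fossils included."""
    resolved_all = prepare_matrix(m, seed=child_seed(cfg.seed, "resolve_fossil"))
    d_all = dissimilarity_matrix(resolved_all)
    ord_all = pcoa(d_all)
    groups = {
        str(g): [t for t in resolved_all.taxa if resolved_all.taxon_meta.loc[t, "family"] == g]
        for g in pd.unique(resolved_all.taxon_meta["family"])
    }
    pdiv = partial_disparity(ord_all, groups)
    fossil_families = set(
        resolved_all.taxon_meta.loc[resolved_all.fossil_taxa(), "family"]
    )
    fossil_pdiv_pct = float(pdiv.loc[sorted(fossil_families), "pdiv_pct"].sum())
    fossil_summary = summarize_dataset(m.subset_taxa(m.fossil_taxa()))
    return {
        "dissimilarity": d_all,
        "ordination": ord_all,
        "pdiv": pdiv,
        "fossil_pdiv_pct": fossil_pdiv_pct,
        "fossil_missing_pct": fossil_summary.missing_pct,
    }


def run_full_analysis(cfg: RunConfig, matrix: CharacterMatrix | None = None) -> RunResult:
    """Load (or accept) a dataset, run every stage, and write all outputs."""
    if matrix is None:
        if not (cfg.matrix_path and cfg.config_path and cfg.meta_path):
            raise ValueError("either a matrix or input paths must be provided")
        matrix = load_dataset(
            cfg.matrix_path, cfg.config_path, cfg.meta_path, cfg.family_meta_path
        )
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    result = analyse_matrix(matrix, cfg)

    result.summary.to_csv(out / "dataset_summary.csv")
    result.dissimilarity.write(out / "dissimilarity_matrix.csv")
    result.ordination.write(out / "pcoa_coordinates.csv", out / "pcoa_eigenvalues.csv")
    result.family_disparity.to_csv(out / "disparity_by_family.csv")
    result.clade_disparity.to_csv(out / "disparity_by_clade.csv")
    with open(out / "permanova_overall.json", "w") as fh:
        json.dump(result.permanova_overall, fh, indent=2)
    result.posthoc.to_csv(out / "permanova_posthoc.csv", index=False)
    posthoc_triangle_table(result.posthoc).to_csv(out / "permanova_posthoc_table.csv")
    result.correlations.to_csv(out / "disparity_correlations.csv")
    result.dchar.to_csv(out / "character_variation.csv")
    result.mantel_results.to_csv(out / "mantel_module_vs_total.csv")
    result.module_tests.to_csv(out / "module_disparity_tests.csv")
    if result.fossil:
        result.fossil["ordination"].write(
            out / "pcoa_coordinates_with_fossils.csv",
            out / "pcoa_eigenvalues_with_fossils.csv",
        )
        result.fossil["pdiv"].to_csv(out / "pdiv_with_fossils.csv")

    k3 = min(3, result.ordination.n_axes)
    log = {
        "seed": cfg.seed,
        "python": sys.version.split()[0],
        "floramorph": __version__,
        "numpy": np.__version__,
        "n_taxa": len(matrix.taxa),
        "n_characters": matrix.n_characters,
        "grouping": cfg.grouping,
        "include_fossils": cfg.include_fossils,
        "embedding_fidelity_r_3axes": embedding_fidelity(
            result.dissimilarity, result.ordination, k3
        ),
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2)
    return result
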