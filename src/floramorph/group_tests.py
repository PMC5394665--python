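"""Permutation tests of group separation and matrix/rank correlations.

PERMANOVA (npMANOVA) partitions the squared pairwise dissimilarities:

    SS_total   = (1/N) * sum_{i<j} d_ij^2
    SS_within  = sum_g (1/n_g) * sum_{i<j in g} d_ij^2
    SS_between = SS_total - SS_within
    F = [SS_between / (a - 1)] / [SS_within / (N - a)]

with a groups over N taxa; significance comes from permuting group labels.
The effect size r^2 = SS_between / SS_total is the fraction of dissimilarity
variance explained by the grouping.  Post hoc pairwise comparisons rerun the
two-group test per group pair with Bonferroni correction.

The Mantel test correlates two dissimilarity matrices over the same taxa
(Pearson, over unmasked i<j pairs) and permutes the taxon labels of one
matrix; pairs undefined in either matrix are masked in both, and masks travel
with the permuted matrix.

Permutation p-values use the (#more-extreme + 1) / (n_perm + 1) convention,
so p is never 0; both tests also support exhaustive enumeration of all
distinct label arrangements for small N, in which case p is exact (the
identity arrangement included, no +1 correction).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dissimilarity import ArgumentError, DissimilarityMatrix


@dataclass
class PermutationTestResult:
    """Outcome of one permutation (or classical) test."""

    statistic_name: str
    statistic: float
    p_value: float
    n_permutations: int
    effect_size: float = float("nan")  # r^2 where applicable
    adjusted_p: float = float("nan")
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


def _as_labels(d: DissimilarityMatrix, grouping) -> np.ndarray:
    if isinstance(grouping, pd.Series):
        return np.asarray([grouping[t] for t in d.taxa], dtype=object)
    if isinstance(grouping, dict):
        return np.asarray([grouping[t] for t in d.taxa], dtype=object)
    labels = np.asarray(grouping, dtype=object)
    if labels.shape[0] != d.n_taxa:
        raise ArgumentError("grouping length does not match the matrix")
    return labels


def permanova_statistic(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    """(pseudo-F, r^2) from a squared-dissimilarity matrix and group codes."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        members = np.flatnonzero(codes == g)
        ng = members.size
        if ng < 2:
            continue
        block = d2[np.ix_(members, members)]
        ss_within += block[np.triu_indices(ng, k=1)].sum() / ng
    ss_between = ss_total - ss_within
    r2 = ss_between / ss_total if ss_total > 0 else float("nan")
    if ss_within <= 0:
        return float("inf"), r2
    f = (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))
    return float(f), float(r2)


def permanova(
    d: DissimilarityMatrix,
    grouping,
    n_perm: int = 10_000,
    seed: int | None = None,
    exhaustive: bool = False,
) -> PermutationTestResult:
    """Permutational multivariate ANOVA on a dissimilarity matrix.

    ``grouping`` maps taxon -> label (Series/dict) or is a label sequence in
    matrix order.  ``exhaustive=True`` enumerates every distinct assignment of
    the label multiset (small N only) and returns the exact p.
    """
    labels = _as_labels(d, grouping)
    uniq, codes = np.unique(labels.astype(str), return_inverse=True)
    a = len(uniq)
    if a < 2:
        raise ArgumentError("PERMANOVA needs at least 2 groups")
    if np.max(np.bincount(codes)) < 2:
        raise ArgumentError("at least one group must have >= 2 taxa")
    if d.has_undefined():
        raise ArgumentError("undefined pairs among tested taxa")
    d2 = d.values**2
    f_obs, r2 = permanova_statistic(d2, codes, a)

    if exhaustive:
        count_ge = 0
        total = 0
        for perm in _multiset_permutations(codes):
            f_p, _ = permanova_statistic(d2, perm, a)
            total += 1
            if f_p >= f_obs - 1e-12:
                count_ge += 1
        p = count_ge / total
        n_used = total
    else:
        rng = np.random.default_rng(seed)
        count_ge = 0
        work = codes.copy()
        for _ in range(n_perm):
            rng.shuffle(work)
            f_p, _ = permanova_statistic(d2, work, a)
            if f_p >= f_obs - 1e-12:
                count_ge += 1
        p = (count_ge + 1) / (n_perm + 1)
        n_used = n_perm
    return PermutationTestResult(
        statistic_name="pseudo-F",
        statistic=f_obs,
        effect_size=r2,
        p_value=p,
        n_permutations=n_used,
        extra={"n_groups": a, "n_taxa": d.n_taxa},
    )


def _multiset_permutations(codes: np.ndarray):
    """All distinct arrangements of the code multiset, as int arrays."""
    seen = set()
    for perm in itertools.permutations(codes.tolist()):
        if perm in seen:
            continue
        seen.add(perm)
        yield np.asarray(perm)


def permanova_posthoc(
    d: DissimilarityMatrix,
    grouping,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Pairwise two-group PERMANOVAs with Bonferroni-adjusted p-values.

    Returns one row per group pair: F, r2, p, adjusted p (min(1, p * n_pairs)).
    """
    labels = _as_labels(d, grouping)
    uniq = sorted(set(labels.astype(str)))
    if len(uniq) < 3:
        raise ArgumentError("post hoc comparisons need >= 3 groups")
    pairs = list(itertools.combinations(uniq, 2))
    rng = np.random.default_rng(seed)
    rows = []
    for g1, g2 in pairs:
        keep = [t for t, lab in zip(d.taxa, labels.astype(str)) if lab in (g1, g2)]
        sub = d.submatrix(keep)
        sub_groups = pd.Series(
            [str(l) for l, t in zip(labels.astype(str), d.taxa) if t in set(keep)],
            index=keep,
        )
        res = permanova(sub, sub_groups, n_perm=n_perm, seed=int(rng.integers(2**31)))
        rows.append(
            {
                "group1": g1,
                "group2": g2,
                "F": res.statistic,
                "r2": res.effect_size,
                "p": res.p_value,
                "adjusted_p": min(1.0, res.p_value * len(pairs)),
            }
        )
    return pd.DataFrame(rows)


def posthoc_triangle_table(posthoc: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Square presentation of post hoc results: F above the diagonal, r^2
    below, 'n.s.' for pairs whose adjusted p exceeds ``alpha``."""
    groups = sorted(set(posthoc["group1"]) | set(posthoc["group2"]))
    out = pd.DataFrame("", index=groups, columns=groups)
    for _, row in posthoc.iterrows():
        g1, g2 = row["group1"], row["group2"]
        if row["adjusted_p"] <= alpha:
            out.loc[g1, g2] = f"{row['F']:.3f}"
            out.loc[g2, g1] = f"{row['r2']:.3f}"
        else:
            out.loc[g1, g2] = "n.s."
            out.loc[g2, g1] = "n.s."
    return out


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------


def _masked_pearson(x: np.ndarray, y: np.ndarray) -> float:
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 3:
        raise ArgumentError("fewer than 3 defined pairs for correlation")
    return float(np.corrcoef(x[ok], y[ok])[0, 1])


def mantel(
    d1: DissimilarityMatrix,
    d2: DissimilarityMatrix,
    n_perm: int = 999,
    seed: int | None = None,
    alternative: str = "greater",
    exhaustive: bool = False,
) -> PermutationTestResult:
    """Mantel correlation between two dissimilarity matrices.

    Pearson r over the i<j pairs defined in both matrices; the permutation
    null reorders the taxa of ``d2`` (values and undefined-pair mask move
    together).  One-sided ('greater'/'less') or 'two-sided' alternatives.
    """
    if list(d1.taxa) != list(d2.taxa):
        raise ArgumentError("Mantel test requires identical taxon ordering")
    n = d1.n_taxa
    if n < 3:
        raise ArgumentError("Mantel test needs at least 3 taxa")
    iu = np.triu_indices(n, k=1)
    x = d1.values[iu]
    B = d2.values
    r_obs = _masked_pearson(x, B[iu])

    def perm_r(order: np.ndarray) -> float:
        Bp = B[np.ix_(order, order)]
        return _masked_pearson(x, Bp[iu])

    if exhaustive:
        rs = np.array(
            [perm_r(np.asarray(perm)) for perm in itertools.permutations(range(n))]
        )
        p = _tail_fraction(rs, r_obs, alternative, exact=True)
        n_used = len(rs)
    else:
        rng = np.random.default_rng(seed)
        rs = np.empty(n_perm)
        for k in range(n_perm):
            rs[k] = perm_r(rng.permutation(n))
        p = _tail_fraction(rs, r_obs, alternative, exact=False)
        n_used = n_perm
    n_pairs = int((~np.isnan(x) & ~np.isnan(B[iu])).sum())
    return PermutationTestResult(
        statistic_name="Mantel r",
        statistic=r_obs,
        p_value=p,
        n_permutations=n_used,
        extra={"n_pairs": n_pairs, "alternative": alternative},
    )


def _tail_fraction(
    null: np.ndarray, obs: float, alternative: str, exact: bool
) -> float:
    eps = 1e-12
    if alternative == "greater":
        hits = np.sum(null >= obs - eps)
    elif alternative == "less":
        hits = np.sum(null <= obs + eps)
    elif alternative == "two-sided":
        hits = np.sum(np.abs(null) >= abs(obs) - eps)
    else:
        raise ArgumentError(f"unknown alternative {alternative!r}")
    if exact:
        return float(hits) / null.size
    return float(hits + 1) / (null.size + 1)


# ---------------------------------------------------------------------------
# Rank / linear correlations between group statistics and attributes
# ---------------------------------------------------------------------------


def correlate_disparity(
    x: pd.Series, y: pd.Series, method: str = "spearman"
) -> PermutationTestResult:
    """Spearman's rho (or Pearson's r) between paired per-group values.

    Groups with NaN in either series are dropped pairwise; classical
    two-sided p-value.
    """
    joined = pd.concat([x, y], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ArgumentError("need at least 3 paired groups")
    a, b = joined.iloc[:, 0].to_numpy(float), joined.iloc[:, 1].to_numpy(float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return PermutationTestResult(
            statistic_name=method, statistic=float("nan"), p_value=float("nan"),
            n_permutations=0, extra={"n_groups": len(joined)},
        )
    if method == "spearman":
        res = stats.spearmanr(a, b)
        stat, p = float(res.statistic), float(res.pvalue)
        name = "Spearman rho"
    elif method == "pearson":
        res = stats.pearsonr(a, b)
        stat, p = float(res.statistic), float(res.pvalue)
        name = "Pearson r"
    else:
        raise ArgumentError(f"unknown method {method!r}")
    return PermutationTestResult(
        statistic_name=name,
        statistic=stat,
        p_value=p,
        n_permutations=0,
        extra={"n_groups": len(joined)},
    )
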