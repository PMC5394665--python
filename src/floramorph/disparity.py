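"""Group-level disparity: mean pairwise dissimilarity, range (plain and
rarefied), bootstrap standard errors, and Foote partial disparity.

All distance-based statistics work directly on the dissimilarity matrix, not
on ordination scores.  The range R (maximum within-group D) grows with sample
size, so it is additionally rarefied: the mean of the maxima over repeated
subsamples of fixed size (default 10 taxa, the study's minimum workable group
size); groups at or below the rarefaction size keep their plain R.

Partial disparity (PDiv) decomposes total disparity additively over a
partition of the taxa: for each group, the summed squared distances of its
members to the grand centroid across all positive PCoA axes, divided by the
total number of taxa.  Group PDiv values sum exactly to the total.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dissimilarity import ArgumentError, DissimilarityMatrix
from .ordination import PCoAResult


@dataclass
class DisparityResult:
    """Disparity statistics for one group of taxa."""

    group: str
    n_taxa: int
    mean_pairwise: float
    mean_pairwise_se: float
    range: float
    rarefied_range: float
    rarefied_range_se: float
    partial_disparity: float = np.nan
    partial_disparity_pct: float = np.nan


def _within_values(d: DissimilarityMatrix, group: Sequence[str]) -> np.ndarray:
    idx = [d.taxa.index(t) for t in group]
    sub = d.values[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    vals = sub[iu]
    return vals[~np.isnan(vals)]


def mean_pairwise_disparity(d: DissimilarityMatrix, group: Sequence[str]) -> float:
    """Mean within-group pairwise D; NaN for groups of fewer than 2 taxa.

    Undefined pairs (no shared scored characters) are excluded from the mean.
    """
    if len(group) < 2:
        return float("nan")
    vals = _within_values(d, group)
    return float(vals.mean()) if vals.size else float("nan")


def range_disparity(d: DissimilarityMatrix, group: Sequence[str]) -> float:
    """R: maximum within-group pairwise D."""
    if len(group) < 2:
        return float("nan")
    vals = _within_values(d, group)
    return float(vals.max()) if vals.size else float("nan")


def rarefied_range_disparity(
    d: DissimilarityMatrix,
    group: Sequence[str],
    n: int = 10,
    reps: int = 1000,
    seed: int | None = None,
) -> tuple[float, float, float]:
    """(R, rarefied R, bootstrap s.e. of rarefied R) for one group.

    Rarefied R is the mean over ``reps`` subsamples (without replacement) of
    size ``n`` of the subsample maximum D; groups with <= n taxa return the
    plain R.  The bootstrap s.e. resamples taxa with replacement and
    recomputes the (rarefied) range each time.
    """
    if n < 2:
        raise ArgumentError("rarefaction size n must be >= 2")
    if len(group) < 2:
        return float("nan"), float("nan"), float("nan")
    rng = np.random.default_rng(seed)
    idx = np.array([d.taxa.index(t) for t in group])
    sub = d.values[np.ix_(idx, idx)]
    g = len(idx)

    r_plain = range_disparity(d, group)
    if g <= n:
        rarefied = r_plain
    else:
        maxima = np.empty(reps)
        for r in range(reps):
            pick = rng.choice(g, size=n, replace=False)
            block = sub[np.ix_(pick, pick)]
            maxima[r] = np.nanmax(block[np.triu_indices(n, k=1)])
        rarefied = float(maxima.mean())

    # bootstrap: resample taxa with replacement; self-pairs arising from
    # duplicated picks are not real taxon pairs and are excluded
    boots = np.empty(reps)
    tri_i, tri_j = np.triu_indices(g, k=1)
    for r in range(reps):
        pick = rng.choice(g, size=g, replace=True)
        if g <= n:
            vals = sub[pick[tri_i], pick[tri_j]]
            vals = vals[(pick[tri_i] != pick[tri_j]) & ~np.isnan(vals)]
            boots[r] = vals.max() if vals.size else np.nan
        else:
            sub_pick = pick[rng.choice(g, size=n, replace=False)]
            si, sj = np.triu_indices(n, k=1)
            vals = sub[sub_pick[si], sub_pick[sj]]
            vals = vals[(sub_pick[si] != sub_pick[sj]) & ~np.isnan(vals)]
            boots[r] = vals.max() if vals.size else np.nan
    se = float(np.nanstd(boots, ddof=1))
    return r_plain, float(rarefied), se


def bootstrap_se_mean_pairwise(
    d: DissimilarityMatrix, group: Sequence[str], reps: int = 1000, seed: int | None = None
) -> float:
    """Bootstrap s.e. of the within-group mean pairwise D (taxa resampled)."""
    if len(group) < 2:
        return float("nan")
    rng = np.random.default_rng(seed)
    idx = np.array([d.taxa.index(t) for t in group])
    sub = d.values[np.ix_(idx, idx)]
    g = len(idx)
    stats = np.empty(reps)
    for r in range(reps):
        pick = rng.choice(g, size=g, replace=True)
        block = sub[np.ix_(pick, pick)]
        # exclude self-pairs arising from duplicated picks: use off-diagonal of
        # distinct index pairs only
        tri_i, tri_j = np.triu_indices(g, k=1)
        vals = block[tri_i, tri_j]
        keep = pick[tri_i] != pick[tri_j]
        vals = vals[keep]
        vals = vals[~np.isnan(vals)]
        stats[r] = vals.mean() if vals.size else np.nan
    return float(np.nanstd(stats, ddof=1))


def partial_disparity(
    p: PCoAResult, groups: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Foote partial disparity per group over all positive PCoA axes.

    ``groups`` must partition the ordinated taxa.  Returns a DataFrame indexed
    by group with columns ``pdiv`` (sum of squared coordinates / N_total; the
    centroid is the origin after centring) and ``pdiv_pct``.
    """
    all_assigned = [t for members in groups.values() for t in members]
    if sorted(all_assigned) != sorted(p.taxa):
        raise ArgumentError("groups must form a partition of the ordinated taxa")
    n_total = len(p.taxa)
    sq = (p.coordinates**2).sum(axis=1)
    pos = {t: i for i, t in enumerate(p.taxa)}
    pdiv = {
        g: float(sq[[pos[t] for t in members]].sum()) / n_total
        for g, members in groups.items()
    }
    total = sum(pdiv.values())
    out = pd.DataFrame(
        {
            "pdiv": pd.Series(pdiv),
            "pdiv_pct": pd.Series(
                {g: 100.0 * v / total if total > 0 else np.nan for g, v in pdiv.items()}
            ),
        }
    )
    out.index.name = "group"
    return out


def total_disparity(p: PCoAResult) -> float:
    """Total disparity: mean squared distance of taxa to the grand centroid."""
    return float((p.coordinates**2).sum() / len(p.taxa))


def group_disparity_table(
    d: DissimilarityMatrix,
    grouping: pd.Series,
    p: PCoAResult | None = None,
    n: int = 10,
    reps: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-group disparity table: D-bar, R, rarefied R, bootstrap s.e.s, PDiv.

    ``grouping`` maps taxon -> group label for every taxon in ``d``.  When an
    ordination ``p`` over the same taxa is given, PDiv columns are included.
    """
    rng = np.random.default_rng(seed)
    groups = {
        str(g): [t for t in d.taxa if grouping[t] == g]
        for g in pd.unique(grouping.loc[d.taxa])
    }
    pdiv = None
    if p is not None:
        pdiv = partial_disparity(p, groups)
    rows = []
    for g, members in groups.items():
        child = int(rng.integers(2**31))
        r_plain, rarefied, r_se = rarefied_range_disparity(
            d, members, n=n, reps=reps, seed=child
        )
        rows.append(
            {
                "group": g,
                "n_taxa": len(members),
                "mean_pairwise": mean_pairwise_disparity(d, members),
                "mean_pairwise_se": bootstrap_se_mean_pairwise(
                    d, members, reps=reps, seed=child + 1
                ),
                "range": r_plain,
                "rarefied_range": rarefied,
                "rarefied_range_se": r_se,
                "pdiv": pdiv.loc[g, "pdiv"] if pdiv is not None else np.nan,
                "pdiv_pct": pdiv.loc[g, "pdiv_pct"] if pdiv is not None else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("group")
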