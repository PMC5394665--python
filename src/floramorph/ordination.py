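"""Principal coordinates analysis (PCoA) and embedding-fidelity diagnostics.

Classical metric scaling: the squared dissimilarity matrix is Gower
double-centred (B = -1/2 J D^2 J with J = I - 11'/n), eigendecomposed, and
taxa are placed at eigenvector * sqrt(eigenvalue) for each positive axis.
Mean-character-difference matrices are generally non-Euclidean, so some
eigenvalues are negative; those axes are dropped, their absolute mass is
reported, and axis variance proportions are taken over the sum of positive
eigenvalues (no Cailliez/Lingoes correction).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.spatial.distance import pdist
from scipy.stats import pearsonr

from .character_matrix import ValidationError
from .dissimilarity import ArgumentError, DissimilarityMatrix

_EIG_TOL = 1e-9  # relative threshold below which an eigenvalue counts as zero


@dataclass
class PCoAResult:
    """Coordinates (taxa x positive axes), eigenvalues and variance shares."""

    taxa: list[str]
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    variance_proportion: np.ndarray
    negative_eigenvalue_mass: float

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]

    def coordinates_frame(self) -> pd.DataFrame:
        cols = [f"axis{k + 1}" for k in range(self.n_axes)]
        return pd.DataFrame(self.coordinates, index=self.taxa, columns=cols)

    def eigenvalue_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "eigenvalue": self.eigenvalues,
                "variance_proportion": self.variance_proportion,
            },
            index=[f"axis{k + 1}" for k in range(self.n_axes)],
        )

    def write(self, coords_path: str | Path, eigen_path: str | Path) -> None:
        df = self.coordinates_frame()
        df.index.name = "taxon"
        df.to_csv(coords_path)
        ev = self.eigenvalue_table()
        ev.index.name = "axis"
        ev.to_csv(eigen_path)


def pcoa(d: DissimilarityMatrix) -> PCoAResult:
    """Principal coordinates of a complete dissimilarity matrix.

    The caller must remove taxa producing undefined pairs first.  Axes are
    ordered by decreasing eigenvalue; per-axis signs follow the convention
    that the largest-magnitude coordinate on each axis is positive.
    """
    if d.has_undefined():
        raise ValidationError(
            "dissimilarity matrix has undefined pairs; drop the offending taxa"
        )
    D = np.asarray(d.values, dtype=float)
    n = D.shape[0]
    if n < 2:
        raise ArgumentError("need at least 2 taxa for ordination")
    B = _double_center(D)
    eigvals, eigvecs = eigh(B)  # ascending
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    tol = _EIG_TOL * max(abs(eigvals[0]), 1.0)
    positive = eigvals > tol
    neg_mass = float(-eigvals[eigvals < -tol].sum())
    lam = eigvals[positive]
    coords = eigvecs[:, positive] * np.sqrt(lam)

    # sign convention: largest-|coordinate| positive per axis
    for k in range(coords.shape[1]):
        j = int(np.argmax(np.abs(coords[:, k])))
        if coords[j, k] < 0:
            coords[:, k] = -coords[:, k]

    total = float(lam.sum())
    return PCoAResult(
        taxa=list(d.taxa),
        coordinates=coords,
        eigenvalues=lam,
        variance_proportion=lam / total if total > 0 else np.zeros_like(lam),
        negative_eigenvalue_mass=neg_mass,
    )


def _double_center(D: np.ndarray) -> np.ndarray:
    A = -0.5 * D**2
    row = A.mean(axis=1, keepdims=True)
    col = A.mean(axis=0, keepdims=True)
    return A - row - col + A.mean()


def embedding_fidelity(d: DissimilarityMatrix, p: PCoAResult, k: int) -> float:
    """Pearson r between original D and Euclidean distances on the first k axes.

    Measures how faithfully a k-dimensional morphospace plot represents the
    full dissimilarity structure; non-decreasing in k.
    """
    if k < 1:
        raise ArgumentError("axis count k must be >= 1")
    if k > p.n_axes:
        raise ArgumentError(f"k={k} exceeds the {p.n_axes} positive axes")
    if list(d.taxa) != list(p.taxa):
        raise ArgumentError("dissimilarity matrix and ordination taxa differ")
    orig = d.condensed()
    embedded = pdist(p.coordinates[:, :k])
    return float(pearsonr(orig, embedded).statistic)
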