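"""Genomic relationship matrix (GRM) construction.

The GRM summarizes realized genomic similarity between genotypes from a
marker matrix.  The normalization used here is K = Z Z' / v, where Z is the
column-centered marker matrix and v = sum_j var(z_.j) with the
method-of-moments variance (denominator n).  Dividing by v makes the mean
of diag(K) exactly one, which fixes the scale of the genetic variance
parameter that multiplies K in the mixed models downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["MarkerMatrix", "RelationshipMatrix", "compute_grm"]


@dataclass
class MarkerMatrix:
    """Numeric marker codes, genotypes in rows and markers in columns."""

    values: np.ndarray
    genotype_ids: list[str]
    marker_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("marker values must be a 2-D matrix")
        n, m = self.values.shape
        if n < 2:
            raise ValueError("need at least 2 genotypes")
        if m < 1:
            raise ValueError("need at least 1 marker")
        self.genotype_ids = [str(g) for g in self.genotype_ids]
        self.marker_ids = [str(s) for s in self.marker_ids]
        if len(self.genotype_ids) != n:
            raise ValueError("genotype_ids length does not match row count")
        if len(self.marker_ids) != m:
            raise ValueError("marker_ids length does not match column count")

    @classmethod
    def from_array(
        cls,
        values: np.ndarray,
        genotype_ids: Sequence[str] | None = None,
        marker_ids: Sequence[str] | None = None,
    ) -> "MarkerMatrix":
        values = np.asarray(values, dtype=np.float64)
        n, m = values.shape
        gids = list(genotype_ids) if genotype_ids is not None else [
            f"G{i + 1}" for i in range(n)
        ]
        mids = list(marker_ids) if marker_ids is not None else [
            f"M{j + 1}" for j in range(m)
        ]
        return cls(values, gids, mids)


@dataclass
class RelationshipMatrix:
    """Symmetric n x n relationship matrix K with genotype labels."""

    values: np.ndarray
    genotype_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        K = self.values
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise ValueError("K must be square")
        scale = max(1.0, float(np.abs(K).max()))
        if np.abs(K - K.T).max() > 1e-8 * scale:
            raise ValueError("K must be symmetric")
        self.values = 0.5 * (K + K.T)
        self.genotype_ids = [str(g) for g in self.genotype_ids]
        if len(self.genotype_ids) != K.shape[0]:
            raise ValueError("genotype_ids length does not match K dimension")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def index_of(self, ids: Sequence[str]) -> np.ndarray:
        """Row indices of the given genotype labels (error on unknowns)."""
        lookup = {g: i for i, g in enumerate(self.genotype_ids)}
        missing = [g for g in ids if str(g) not in lookup]
        if missing:
            raise KeyError(f"genotype ids not present in K: {missing[:5]}")
        return np.array([lookup[str(g)] for g in ids], dtype=np.intp)


def compute_grm(
    markers: MarkerMatrix | np.ndarray,
    center: bool = True,
    impute: bool = False,
) -> RelationshipMatrix:
    """Build K = Z Z' / v from a marker matrix.

    Parameters
    ----------
    markers
        Marker codes, genotypes in rows.  A bare array is wrapped with
        generated labels.
    center
        Subtract column means before forming Z Z'.  Disable only when the
        input is already centered.
    impute
        Replace missing entries (NaN) by their column mean before centering.
        Off by default; with it off, missing values are an error.

    Notes
    -----
    v = sum_j var(z_.j) with variance denominator n (method of moments),
    which makes mean(diag(K)) = 1 an exact identity: sum_i K_ii =
    sum_ij z_ij^2 / v = n.
    """
    if not isinstance(markers, MarkerMatrix):
        markers = MarkerMatrix.from_array(np.asarray(markers))
    Z = markers.values.copy()
    n = Z.shape[0]

    if impute:
        col_mean = np.nanmean(Z, axis=0)
        # a column with no observed entries has no information to impute from
        if np.any(np.isnan(col_mean)):
            raise ValueError("marker column with all values missing")
        nan_r, nan_c = np.nonzero(np.isnan(Z))
        Z[nan_r, nan_c] = col_mean[nan_c]
    elif np.any(np.isnan(Z)):
        raise ValueError("marker matrix contains missing values (set impute=True)")

    if center:
        Z -= Z.mean(axis=0)

    # v = sum of column variances, denominator n
    v = float(np.sum(Z * Z) / n - np.sum(Z.mean(axis=0) ** 2))
    if v <= 0:
        raise ValueError("all markers have zero variance: degenerate input")
    K = (Z @ Z.T) / v
    return RelationshipMatrix(values=K, genotype_ids=markers.genotype_ids)
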