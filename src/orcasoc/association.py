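"""Pairwise association indices under the gambit of the group.

Every individual photographed in a group is assumed to be associating with
every other member of that group, so one daily encounter contributes one
joint sighting to each unordered pair it contains.  Association strength is
the simple ratio index

    SRI_ij = X_ij / (X_ij + Y_i + Y_j)

where X_ij counts the groups containing both i and j, and Y_i (Y_j) the
groups containing i (j) alone.  Since each retained individual appears in at
most one retained group per date, Y_i = n_i − X_ij and the denominator is
n_i + n_j − X_ij.  SRI ranges from 0 (never associated) to 1 (always
associated).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .encounters import EncounterRecord

__all__ = ["PairCounts", "AssociationMatrix", "pair_counts", "sri_matrix"]


class DataIntegrityError(ValueError):
    """Pair counts violate the one-group-per-day assumption."""


@dataclass
class PairCounts:
    """Joint and marginal daily-encounter counts for retained individuals.

    ``X[i, j]`` is the number of daily encounters containing both i and j
    (diagonal = marginal counts ``n``); symmetric by construction.
    """

    ids: list[str]
    X: np.ndarray  # (n, n) int, X[i,i] == n[i]
    n: np.ndarray  # (n,) int

    def validate(self) -> None:
        if not np.array_equal(self.X, self.X.T):
            raise DataIntegrityError("pair-count matrix not symmetric")
        if not np.array_equal(np.diag(self.X), self.n):
            raise DataIntegrityError("diagonal of X must equal marginal counts")
        pairwise_min = np.minimum.outer(self.n, self.n)
        if (self.X > pairwise_min).any():
            raise DataIntegrityError("X[i,j] exceeds min(n[i], n[j])")


@dataclass
class AssociationMatrix:
    """Symmetric simple-ratio-index matrix with the counts behind it."""

    ids: list[str]
    sri: np.ndarray  # (n, n) float in [0,1], diagonal fixed to 1
    counts: PairCounts

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.sri, index=self.ids, columns=self.ids)

    def to_edge_list(self) -> pd.DataFrame:
        """Long-format edge list of nonzero off-diagonal associations."""
        rows = []
        n = len(self.ids)
        for i in range(n):
            for j in range(i + 1, n):
                if self.sri[i, j] > 0:
                    rows.append(
                        {
                            "id_i": self.ids[i],
                            "id_j": self.ids[j],
                            "sri": self.sri[i, j],
                            "x": int(self.counts.X[i, j]),
                            "n_i": int(self.counts.n[i]),
                            "n_j": int(self.counts.n[j]),
                        }
                    )
        return pd.DataFrame(rows, columns=["id_i", "id_j", "sri", "x", "n_i", "n_j"])


def pair_counts(records: list[EncounterRecord], retained_ids: set[str]) -> PairCounts:
    """Count joint and marginal daily-encounter occurrences.

    Masked (excluded) individuals contribute nothing; every unordered pair
    co-occurring in a record increments X once per record.
    """
    ids = sorted(retained_ids)
    index = {ind: k for k, ind in enumerate(ids)}
    n_ids = len(ids)
    # incidence matrix: records x individuals
    B = np.zeros((len(records), n_ids), dtype=np.int64)
    for r, rec in enumerate(records):
        for ind in rec.individuals:
            k = index.get(ind)
            if k is not None:
                B[r, k] = 1
    X = B.T @ B
    n = np.diag(X).copy()
    pc = PairCounts(ids=ids, X=X, n=n)
    pc.validate()
    return pc


def sri_matrix(counts: PairCounts) -> AssociationMatrix:
    """Compute the simple ratio index from pair counts.

    SRI_ij = X_ij / (n_i + n_j − X_ij); the diagonal is set to 1 for
    clustering convenience and excluded from all statistics.
    """
    counts.validate()
    n_vec = counts.n.astype(float)
    X = counts.X.astype(float)
    denom = n_vec[:, None] + n_vec[None, :] - X
    off = ~np.eye(len(counts.ids), dtype=bool)
    if (denom[off] < X[off]).any():
        raise DataIntegrityError("negative Y: one-group-per-day assumption violated")
    with np.errstate(invalid="ignore", divide="ignore"):
        sri = np.where(denom > 0, X / np.where(denom > 0, denom, 1.0), 0.0)
    np.fill_diagonal(sri, 1.0)
    return AssociationMatrix(ids=counts.ids, sri=sri, counts=counts)
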