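"""mtDNA diversity statistics: pairwise-deletion distances, segregating
sites and Watterson's theta.

Pairwise deletion removes, for each sequence pair, every site where either
sequence is unassigned (N) or gapped before counting differences. Gaps are
treated identically to N throughout.

Watterson's estimator is computed as theta_w = K / (a_n * L) with a fixed
site constant L (default 16,595, the alignment length the diversity figures
here are calibrated to). Two harmonic-sum conventions are exposed:

* ``standard``:  a_n = sum_{i=1..n-1} 1/i   (the textbook estimator)
* ``inclusive``: a_n = sum_{i=1..n}   1/i

Both are reported because published mtDNA diversity values in this domain
are reproducible only under the inclusive convention, despite the standard
formula being the one usually written down; ``inclusive`` is the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import encode

__all__ = [
    "AlignmentMatrix",
    "DistanceMatrix",
    "DistanceSummary",
    "DiversityStats",
    "pairwise_differences",
    "distance_summary",
    "segregating_sites",
    "watterson_theta",
]


@dataclass
class AlignmentMatrix:
    """Equal-length aligned sequences over {A,C,G,T,N,-} with optional
    per-sequence group labels."""

    ids: list[str]
    rows: list[str]
    groups: dict = field(default_factory=dict)  # id -> group label

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows length mismatch")
        if len(self.rows) < 2:
            raise ValueError("alignment needs at least 2 sequences")
        L = len(self.rows[0])
        bad = [i for i, r in zip(self.ids, self.rows) if len(r) != L]
        if bad:
            raise ValueError(f"ragged alignment; offending sequences: {bad}")
        allowed = set("ACGTN-")
        for i, r in zip(self.ids, self.rows):
            extra = set(r) - allowed
            if extra:
                raise ValueError(f"sequence {i!r} has disallowed symbols {sorted(extra)}")

    @property
    def L(self) -> int:
        return len(self.rows[0])

    @property
    def n(self) -> int:
        return len(self.rows)

    def codes(self) -> np.ndarray:
        """(n, L) uint8 matrix; N and '-' both encode as 4 (missing)."""
        return np.stack([encode(r.replace("-", "N")) for r in self.rows])

    def members(self, group: str) -> list[str]:
        return [i for i in self.ids if self.groups.get(i) == group]


@dataclass
class DistanceMatrix:
    ids: list[str]
    diffs: np.ndarray  # pairwise mismatch counts
    compared: np.ndarray  # sites retained after pairwise deletion

    def __post_init__(self):
        d, c = np.asarray(self.diffs), np.asarray(self.compared)
        if d.shape != c.shape or d.shape[0] != d.shape[1]:
            raise ValueError("diffs/compared must be square and congruent")
        if (d > c).any():
            raise ValueError("diffs exceed compared sites")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.diffs, index=self.ids, columns=self.ids)

    def get(self, a: str, b: str) -> int:
        return int(self.diffs[self.ids.index(a), self.ids.index(b)])


def pairwise_differences(aln: AlignmentMatrix) -> DistanceMatrix:
    """Pairwise mismatch counts with pairwise deletion of unassigned sites."""
    m = aln.codes()
    n = aln.n
    valid = m < 4
    diffs = np.zeros((n, n), dtype=np.int64)
    compared = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        both = valid[i] & valid[i + 1 :]
        mism = both & (m[i] != m[i + 1 :])
        compared[i, i + 1 :] = both.sum(axis=1)
        diffs[i, i + 1 :] = mism.sum(axis=1)
    diffs += diffs.T
    compared += compared.T
    np.fill_diagonal(compared, valid.sum(axis=1))
    return DistanceMatrix(ids=list(aln.ids), diffs=diffs, compared=compared)


@dataclass
class DistanceSummary:
    focal: str
    group: str
    mean: float
    min: int
    max: int
    #: distance value -> number of pairs, for distance-spectrum plots
    frequency: pd.Series


def distance_summary(
    dm: DistanceMatrix, focal: str, group_ids: list[str], group_label: str = ""
) -> DistanceSummary:
    """Mean/min/max pairwise distance from a focal sequence to a group,
    plus the distance frequency spectrum."""
    if focal not in dm.ids:
        raise ValueError(f"focal id {focal!r} not in distance matrix")
    others = [g for g in group_ids if g != focal]
    if not others:
        raise ValueError("group is empty (excluding the focal sequence)")
    missing = [g for g in others if g not in dm.ids]
    if missing:
        raise ValueError(f"group members absent from matrix: {missing}")
    fi = dm.ids.index(focal)
    vals = np.array([dm.diffs[fi, dm.ids.index(g)] for g in others])
    freq = pd.Series(vals).value_counts().sort_index()
    freq.index.name = "distance"
    freq.name = "n_pairs"
    return DistanceSummary(
        focal=focal,
        group=group_label,
        mean=float(vals.mean()),
        min=int(vals.min()),
        max=int(vals.max()),
        frequency=freq,
    )


def segregating_sites(aln: AlignmentMatrix) -> int:
    """Number of columns with >= 2 distinct called bases (N/- excluded)."""
    m = aln.codes()
    present = np.stack([(m == b).any(axis=0) for b in range(4)])  # (4, L)
    return int((present.sum(axis=0) >= 2).sum())


def harmonic_sum(n: int, convention: str = "inclusive") -> float:
    if convention == "inclusive":
        top = n
    elif convention == "standard":
        top = n - 1
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return float(np.sum(1.0 / np.arange(1, top + 1)))


@dataclass
class DiversityStats:
    K: int
    n: int
    L: int
    convention: str
    a_n: float
    theta_w: float

    def as_dict(self) -> dict:
        return {
            "K": self.K,
            "n": self.n,
            "L": self.L,
            "convention": self.convention,
            "a_n": self.a_n,
            "theta_w": self.theta_w,
        }


def watterson_theta(
    K: int, n: int, L: int = 16595, convention: str = "inclusive"
) -> DiversityStats:
    """Watterson's per-site diversity theta_w = K / (a_n * L)."""
    if n < 2:
        raise ValueError("need at least 2 sequences")
    if L <= 0:
        raise ValueError("L must be positive")
    if K < 0:
        raise ValueError("K must be non-negative")
    a_n = harmonic_sum(n, convention)
    return DiversityStats(
        K=K, n=n, L=L, convention=convention, a_n=a_n, theta_w=K / (a_n * L)
    )
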