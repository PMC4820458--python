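"""Band-profile comparison: tolerance matching, Dice similarity, distances.

Two restriction fingerprints are compared by deciding which bands
correspond.  Bands s_p and s_q are compatible when their sizes differ by at
most a relative tolerance applied to their mean:

    |s_p − s_q| <= tol · (s_p + s_q) / 2

(the field's customary "position tolerance", here applied to molecular
weight; 1% is the default).  Among compatible pairs a maximum-cardinality
one-to-one matching is computed, ties resolved by minimal total size
discrepancy, and the band-sharing similarity is the Dice (Nei–Li)
coefficient S = 2m / (n_p + n_q).  Distances 1 − S feed the UPGMA stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = [
    "BandProfile",
    "DistanceMatrix",
    "bands_compatible",
    "match_bands",
    "dice_similarity",
    "jaccard_similarity",
    "distance_matrix",
    "DEFAULT_TOLERANCE",
]

DEFAULT_TOLERANCE = 0.01

Source = Literal["virtual_digest", "gel_inferred"]


@dataclass(frozen=True)
class BandProfile:
    """One lane's band sizes (bp, descending); duplicates are co-migrating
    distinct fragments and are kept."""

    id: str
    sizes: tuple[float, ...]
    source: Source = "virtual_digest"

    def __post_init__(self) -> None:
        if not self.sizes:
            raise ValueError(
                f"profile {self.id!r} has no bands (an uncut lane still "
                "carries its single full-length band)"
            )
        if any(s <= 0 for s in self.sizes):
            raise ValueError(f"profile {self.id!r}: band sizes must be positive")
        object.__setattr__(self, "sizes", tuple(sorted(self.sizes, reverse=True)))

    def __len__(self) -> int:
        return len(self.sizes)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances over labelled profiles.

    Band-sharing distances live in [0, 1] (``unit_interval=True``, the
    default); cophenetic matrices of arbitrary trees may exceed 1 and set
    ``unit_interval=False``.
    """

    labels: tuple[str, ...]
    D: np.ndarray
    unit_interval: bool = True

    def __post_init__(self) -> None:
        D = np.asarray(self.D, dtype=float)
        n = len(self.labels)
        if D.shape != (n, n):
            raise ValueError("matrix shape must match label count")
        if not np.allclose(D, D.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(D) != 0):
            raise ValueError("diagonal must be zero")
        if D.min() < -1e-12:
            raise ValueError("distances must be non-negative")
        if self.unit_interval and D.max() > 1 + 1e-12:
            raise ValueError("distances must lie in [0, 1]")
        object.__setattr__(self, "D", D)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.D[i, j])


def bands_compatible(s_p: float, s_q: float, tol: float) -> bool:
    """True when two band sizes fall within the relative position tolerance."""
    return abs(s_p - s_q) <= tol * (s_p + s_q) / 2.0


def _assignment_matching(
    p_sizes: Sequence[float], q_sizes: Sequence[float], tol: float
) -> list[tuple[int, int]]:
    """Maximum-cardinality matching among tolerance-compatible band pairs,
    minimizing total |Δsize| among maximum matchings.

    Solved as a rectangular assignment problem: compatible pairs cost their
    size discrepancy, incompatible pairs a big-M penalty that dominates any
    achievable discrepancy total, so the optimizer first maximizes the
    number of compatible pairs and then minimizes total discrepancy.
    """
    np_, nq = len(p_sizes), len(q_sizes)
    big_m = (max(max(p_sizes), max(q_sizes)) + 1.0) * (np_ + nq + 1) * 1e6
    cost = np.full((np_, nq), big_m)
    for i, sp in enumerate(p_sizes):
        for j, sq in enumerate(q_sizes):
            if bands_compatible(sp, sq, tol):
                cost[i, j] = abs(sp - sq)
    rows, cols = linear_sum_assignment(cost)
    return sorted(
        (int(i), int(j)) for i, j in zip(rows, cols) if cost[i, j] < big_m
    )


def match_bands(
    p: BandProfile, q: BandProfile, tol: float = DEFAULT_TOLERANCE
) -> list[tuple[int, int]]:
    """One-to-one matching of bands between two profiles.

    Returns index pairs (into the descending size lists of ``p`` and ``q``)
    of a maximum-cardinality matching among tolerance-compatible pairs;
    ties are broken by minimal total size discrepancy.  Symmetric:
    ``match_bands(q, p)`` is the transpose.
    """
    if tol < 0:
        raise ValueError("tolerance must be >= 0")
    # canonical orientation so that (p, q) and (q, p) give transposed results
    if (p.sizes, p.id) <= (q.sizes, q.id):
        return _assignment_matching(p.sizes, q.sizes, tol)
    flipped = _assignment_matching(q.sizes, p.sizes, tol)
    return sorted((j, i) for i, j in flipped)


def dice_similarity(
    p: BandProfile, q: BandProfile, tol: float = DEFAULT_TOLERANCE
) -> float:
    """Dice (Nei–Li) band-sharing coefficient S = 2m / (n_p + n_q) in [0, 1]."""
    m = len(match_bands(p, q, tol))
    return 2.0 * m / (len(p) + len(q))


def jaccard_similarity(
    p: BandProfile, q: BandProfile, tol: float = DEFAULT_TOLERANCE
) -> float:
    """Jaccard band coefficient m / (n_p + n_q − m); alternative to Dice."""
    m = len(match_bands(p, q, tol))
    return m / (len(p) + len(q) - m)


_COEFFICIENTS = {"dice": dice_similarity, "jaccard": jaccard_similarity}


def distance_matrix(
    profiles: Sequence[BandProfile],
    tol: float = DEFAULT_TOLERANCE,
    coefficient: str = "dice",
) -> DistanceMatrix:
    """Pairwise band-sharing distances D[i, j] = 1 − S(i, j)."""
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    ids = [p.id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError("profile ids must be unique")
    try:
        sim = _COEFFICIENTS[coefficient]
    except KeyError:
        raise ValueError(
            f"unknown coefficient {coefficient!r}; choose from "
            f"{sorted(_COEFFICIENTS)}"
        ) from None

    n = len(profiles)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = 1.0 - sim(profiles[i], profiles[j], tol)
    return DistanceMatrix(labels=tuple(ids), D=D)
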