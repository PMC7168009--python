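"""Pairwise evolutionary distances: p-distance and Kimura 2-parameter.

Missing data (gaps, N, ambiguity codes) is handled by pairwise deletion by
default: a column is compared only where both sequences carry an unambiguous
base.  Complete deletion (drop any column with missing data anywhere) is
also available.  Saturated pairs (K2P log argument <= 0) are
flagged and set to a finite ceiling so downstream tree building still runs.

K2P: d = -1/2 ln[(1 - 2P - Q) sqrt(1 - 2Q)] with P, Q the transition and
transversion difference proportions over compared sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .seqio import MISSING, Alignment, SpeciesMap, encode

#: default distance assigned to saturated pairs
SATURATION_CEILING = 10.0

# purines A(0), G(2); pyrimidines C(1), T(3): a transition changes the base
# but keeps the class, so code parity identifies the class.


class NoOverlapError(ValueError):
    pass


@dataclass(frozen=True)
class PairwiseComparison:
    """Compared-site count and transition/transversion difference proportions."""

    n_sites: int
    P_ts: float
    Q_tv: float

    def __post_init__(self):
        if self.n_sites < 1:
            raise ValueError("a comparison needs at least one compared site")
        if not 0.0 <= self.P_ts + self.Q_tv <= 1.0 + 1e-12:
            raise ValueError("difference proportions must lie in [0, 1]")

    @property
    def p_distance(self) -> float:
        return self.P_ts + self.Q_tv


def compare_pair(a: str, b: str) -> PairwiseComparison:
    """Count transition/transversion differences under pairwise deletion."""
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    xa, xb = encode(a), encode(b)
    ok = (xa != MISSING) & (xb != MISSING)
    n = int(ok.sum())
    if n == 0:
        raise NoOverlapError("no overlap: zero comparable sites")
    diff = ok & (xa != xb)
    transition = diff & ((xa % 2) == (xb % 2))
    ts = int(transition.sum())
    tv = int(diff.sum()) - ts
    return PairwiseComparison(n, ts / n, tv / n)


def is_saturated(pc: PairwiseComparison) -> bool:
    return (1.0 - 2.0 * pc.P_ts - pc.Q_tv) <= 0.0 or (1.0 - 2.0 * pc.Q_tv) <= 0.0


def k2p(pc: PairwiseComparison, *, ceiling: float = SATURATION_CEILING) -> float:
    """Kimura 2-parameter distance; saturated pairs get ``ceiling``."""
    if is_saturated(pc):
        return ceiling
    return -0.5 * math.log(
        (1.0 - 2.0 * pc.P_ts - pc.Q_tv) * math.sqrt(1.0 - 2.0 * pc.Q_tv)
    )


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray
    model: str
    saturated: np.ndarray | None = None

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")

    def get(self, a: str, b: str) -> float:
        return float(self.d[self.labels.index(a), self.labels.index(b)])

    def submatrix(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        sat = self.saturated[np.ix_(idx, idx)] if self.saturated is not None else None
        return DistanceMatrix(list(labels), self.d[np.ix_(idx, idx)], self.model, sat)


def _pair_counts(mat: np.ndarray):
    """Vectorised compared/transition/transversion counts for all pairs.

    One-hot encodes the four bases; matrix products then give, for every
    ordered pair, the number of columns with each (base_i, base_j) combination.
    """
    valid = (mat != MISSING)
    onehot = [(mat == code) & valid for code in range(4)]
    F = np.stack([x.astype(np.float64) for x in onehot])  # (4, n, L)
    pair = np.einsum("anl,bml->abnm", F, F)  # (4, 4, n, n)
    n_sites = valid.astype(np.float64) @ valid.T.astype(np.float64)
    ts = pair[0, 2] + pair[2, 0] + pair[1, 3] + pair[3, 1]
    diff = pair.sum(axis=(0, 1)) - sum(pair[i, i] for i in range(4))
    tv = diff - ts
    return n_sites, ts, tv


def distance_matrix(
    aln: Alignment,
    model: str = "k2p",
    *,
    deletion: str = "pairwise",
    ceiling: float = SATURATION_CEILING,
) -> DistanceMatrix:
    """All-pairs distance matrix under the named model.

    model: ``"k2p"`` or ``"p"``; deletion: ``"pairwise"`` or ``"complete"``.
    """
    if deletion not in ("pairwise", "complete"):
        raise ValueError(f"unknown deletion policy {deletion!r}")
    mat = aln.matrix()
    if deletion == "complete":
        keep = ~np.any(mat == MISSING, axis=0)
        mat = mat[:, keep]
    return distances_from_matrix(mat, aln.vouchers, model, ceiling=ceiling)


def distances_from_matrix(
    mat: np.ndarray,
    labels: list[str],
    model: str = "k2p",
    *,
    ceiling: float = SATURATION_CEILING,
) -> DistanceMatrix:
    """Distances from an encoded (n, L) uint8 matrix (see ``seqio.encode``)."""
    if model not in ("k2p", "p"):
        raise ValueError(f"unknown model {model!r}")
    n_sites, ts, tv = _pair_counts(mat)
    n = len(labels)
    none = n_sites == 0
    np.fill_diagonal(none, False)
    if np.any(none):
        i, j = np.argwhere(none)[0]
        raise NoOverlapError(
            f"no overlap: zero comparable sites between "
            f"{labels[i]!r} and {labels[j]!r}"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        P = np.where(n_sites > 0, ts / np.maximum(n_sites, 1), 0.0)
        Q = np.where(n_sites > 0, tv / np.maximum(n_sites, 1), 0.0)
    if model == "p":
        d = P + Q
        saturated = np.zeros_like(d, dtype=bool)
    else:
        w1 = 1.0 - 2.0 * P - Q
        w2 = 1.0 - 2.0 * Q
        saturated = (w1 <= 0.0) | (w2 <= 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            d = -0.5 * np.log(np.where(saturated, 1.0, w1 * np.sqrt(np.abs(w2))))
        d = np.where(saturated, ceiling, d)
    np.fill_diagonal(d, 0.0)
    np.fill_diagonal(saturated, False)
    d = (d + d.T) / 2.0  # exact symmetry against float noise
    return DistanceMatrix(labels, d, model, saturated)


@dataclass(frozen=True)
class GroupMeans:
    """Unweighted means over unordered pairs; ``None`` where a stratum is empty."""

    overall: float | None
    within_species: float | None
    between_species: float | None


def group_mean_distances(dm: DistanceMatrix, sm: SpeciesMap) -> GroupMeans:
    species = [sm.species_of(label) for label in dm.labels]
    within, between, overall = [], [], []
    n = len(dm.labels)
    for i in range(n):
        for j in range(i + 1, n):
            v = float(dm.d[i, j])
            overall.append(v)
            (within if species[i] == species[j] else between).append(v)

    def mean(xs):
        return sum(xs) / len(xs) if xs else None

    return GroupMeans(mean(overall), mean(within), mean(between))


def write_distance_tsv(dm: DistanceMatrix, path, *, lower_triangle: bool = False):
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(dm.labels) + "\n")
        for i, label in enumerate(dm.labels):
            stop = i if lower_triangle else len(dm.labels)
            row = [f"{dm.d[i, j]:.6f}" for j in range(stop)]
            fh.write(label + ("\t" if row else "") + "\t".join(row) + "\n")


def write_phylip(dm: DistanceMatrix, path):
    with open(path, "w") as fh:
        fh.write(f"{len(dm.labels)}\n")
        for i, label in enumerate(dm.labels):
            row = " ".join(f"{dm.d[i, j]:.6f}" for j in range(len(dm.labels)))
            fh.write(f"{label}  {row}\n")
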