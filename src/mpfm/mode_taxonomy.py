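"""Mode pairing across decompositions, primary/secondary labelling,
reproducibility tiers, and binarised-support dice overlap."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from mpfm.core_io import ModeDecomposition

__all__ = [
    "ModePairing",
    "pair_modes",
    "label_primary_secondary",
    "tier_counts",
    "binarise",
    "dice",
]


@dataclass
class ModePairing:
    """One-to-one correspondence between two mode sets.

    ``pairs`` holds ``(index_A, index_B, signed_correlation)`` triples; the
    pairing is one-to-one on the smaller set, leftover indices of either
    set are listed as unmatched.
    """

    pairs: list[tuple[int, int, float]]
    unmatched_A: list[int] = field(default_factory=list)
    unmatched_B: list[int] = field(default_factory=list)

    @property
    def correlations(self) -> np.ndarray:
        return np.array([r for _, _, r in self.pairs])

    def b_for_a(self, index_a: int) -> int:
        for a, b, _ in self.pairs:
            if a == index_a:
                return b
        raise KeyError(index_a)


def _column_correlations(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson correlation between every column pair of A and B."""
    Ac = A - A.mean(axis=0, keepdims=True)
    Bc = B - B.mean(axis=0, keepdims=True)
    na = np.linalg.norm(Ac, axis=0)
    nb = np.linalg.norm(Bc, axis=0)
    na[na == 0] = np.inf
    nb[nb == 0] = np.inf
    return (Ac.T @ Bc) / np.outer(na, nb)


def pair_modes(maps_A: np.ndarray, maps_B: np.ndarray,
               greedy: bool = False) -> ModePairing:
    """Optimal one-to-one assignment between two sets of spatial maps.

    The assignment maximises the total absolute spatial correlation
    (Hungarian algorithm by default; a greedy best-match variant is
    available for sensitivity checks). Signed correlations are recorded so
    sign flips can be undone downstream. Zero-variance maps are excluded
    with a warning.
    """
    maps_A = np.asarray(maps_A, float)
    maps_B = np.asarray(maps_B, float)
    if maps_A.shape[0] != maps_B.shape[0]:
        raise ValueError("map sets must share the voxel dimension")
    var_a = maps_A.std(axis=0) > 0
    var_b = maps_B.std(axis=0) > 0
    if not var_a.all() or not var_b.all():
        warnings.warn("zero-variance maps excluded from pairing")
    ia = np.nonzero(var_a)[0]
    ib = np.nonzero(var_b)[0]
    corr = _column_correlations(maps_A[:, ia], maps_B[:, ib])
    score = np.abs(corr)

    if greedy:
        pairs = []
        used_a: set[int] = set()
        used_b: set[int] = set()
        order = np.dstack(np.unravel_index(np.argsort(-score, axis=None),
                                           score.shape))[0]
        for i, j in order:
            if i in used_a or j in used_b:
                continue
            pairs.append((int(ia[i]), int(ib[j]), float(corr[i, j])))
            used_a.add(int(i))
            used_b.add(int(j))
            if len(pairs) == min(len(ia), len(ib)):
                break
        rows = [p[0] for p in pairs]
        cols = [p[1] for p in pairs]
    else:
        r, c = linear_sum_assignment(-score)
        pairs = [(int(ia[i]), int(ib[j]), float(corr[i, j]))
                 for i, j in zip(r, c)]
        rows = [int(ia[i]) for i in r]
        cols = [int(ib[j]) for j in c]
    pairs.sort(key=lambda p: p[0])
    un_a = [int(i) for i in range(maps_A.shape[1]) if i not in rows]
    un_b = [int(j) for j in range(maps_B.shape[1]) if j not in cols]
    return ModePairing(pairs=pairs, unmatched_A=un_a, unmatched_B=un_b)


def label_primary_secondary(highD: ModeDecomposition,
                            lowD: ModeDecomposition) -> list[str]:
    """Label each high-order mode primary (best-matching a low-order mode)
    or secondary (the remainder)."""
    if highD.n_modes < lowD.n_modes:
        raise ValueError("highD must have at least as many modes as lowD")
    pairing = pair_modes(highD.group_maps, lowD.group_maps)
    primary = {a for a, _, _ in pairing.pairs}
    return ["primary" if j in primary else "secondary"
            for j in range(highD.n_modes)]


def tier_counts(pairing: ModePairing) -> tuple[int, int, int]:
    """Reproducibility tiers (very good / good / mediocre matching).

    Counts pairs with |r| >= 0.7, 0.5 <= |r| < 0.7, and |r| < 0.5;
    boundary values go to the higher tier.
    """
    r = np.abs(pairing.correlations)
    high = int(np.sum(r >= 0.7))
    mid = int(np.sum((r >= 0.5) & (r < 0.7)))
    low = int(np.sum(r < 0.5))
    return high, mid, low


def binarise(spatial_map: np.ndarray, threshold: float = 0.3) -> np.ndarray:
    """Boolean support of a map by hard thresholding (strictly above)."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return np.asarray(spatial_map) > threshold


def dice(support_A: np.ndarray, support_B: np.ndarray) -> float:
    """Dice similarity 2|A.B|/(|A|+|B|) of two boolean supports over the
    same voxel universe; 0 by convention if both are empty."""
    a = np.asarray(support_A, bool)
    b = np.asarray(support_B, bool)
    if a.shape != b.shape:
        raise ValueError("supports must share the voxel universe")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 0.0
    return float(2.0 * np.sum(a & b) / denom)
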