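"""Diversity and novelty analytics for molecule sets.

Includes the pairwise Tanimoto-distance distribution, the #Circles sphere
packing diversity measure (the largest subset of molecules whose pairwise
distances all exceed a threshold), and nearest-neighbor novelty against a
reference library.
"""

from __future__ import annotations

import numpy as np

from .chem_core import Molecule, all_pair_distances, bulk_tanimoto_distance

#: Exclusivity threshold used by the #Circles diversity measure.
CIRCLES_THRESHOLD = 0.7

#: Exact #Circles is exponential in set size; refuse beyond this.
EXACT_NCIRCLES_MAX = 25


def pairwise_distance_stats(mols: list[Molecule], bins: int = 20) -> dict:
    """Mean, population SD, and histogram of all unordered-pair distances."""
    if len(mols) < 2:
        raise ValueError("need at least 2 molecules")
    dists = np.array(all_pair_distances(mols))
    counts, edges = np.histogram(dists, bins=bins, range=(0.0, 1.0))
    return {
        "mean": float(dists.mean()),
        "sd": float(dists.std(ddof=0)),
        "histogram": {"counts": counts.tolist(), "edges": edges.tolist()},
    }


def _distance_matrix(mols: list[Molecule]) -> np.ndarray:
    n = len(mols)
    dist = np.zeros((n, n))
    for i in range(n - 1):
        d = bulk_tanimoto_distance(mols[i], mols[i + 1 :])
        dist[i, i + 1 :] = d
        dist[i + 1 :, i] = d
    return dist


def _exact_max_packing(conflict: np.ndarray) -> int:
    """Branch-and-bound maximum independent set on the conflict graph."""
    n = len(conflict)
    order = np.argsort(conflict.sum(axis=1))[::-1]  # high-degree first prunes faster
    conflict = conflict[np.ix_(order, order)]
    best = 0

    def recurse(candidates: np.ndarray, size: int) -> None:
        nonlocal best
        if size + len(candidates) <= best:
            return
        if len(candidates) == 0:
            best = max(best, size)
            return
        v = candidates[0]
        # branch 1: include v
        rest = candidates[1:]
        recurse(rest[~conflict[v, rest]], size + 1)
        # branch 2: exclude v
        recurse(rest, size)

    recurse(np.arange(n), 0)
    return best


def _greedy_packing(mols: list[Molecule], conflict: np.ndarray, dist: np.ndarray) -> int:
    """Farthest-point packing: deterministic lower bound on the exact value.

    Starts from the lexicographically first SMILES, then repeatedly adds the
    molecule farthest (in min-distance-to-selected terms) from the current
    packing, until no candidate clears the exclusivity threshold.
    """
    n = len(mols)
    start = min(range(n), key=lambda i: mols[i].smiles)
    selected = [start]
    min_dist = dist[start].copy()
    remaining = set(range(n)) - {start}
    while remaining:
        nxt = max(remaining, key=lambda i: (min_dist[i], mols[i].smiles))
        if conflict[nxt, selected].any():
            break
        selected.append(nxt)
        remaining.discard(nxt)
        min_dist = np.minimum(min_dist, dist[nxt])
    return len(selected)


def n_circles(
    mols: list[Molecule],
    threshold: float = CIRCLES_THRESHOLD,
    mode: str = "greedy",
) -> int:
    """Largest number of molecules with all pairwise distances > ``threshold``.

    ``mode='exact'`` solves the maximum independent set on the conflict
    graph by branch-and-bound (allowed up to 25 molecules); ``'greedy'``
    returns a deterministic farthest-point-packing lower bound.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    if not mols:
        raise ValueError("empty molecule list")
    dist = _distance_matrix(mols)
    conflict = dist <= threshold
    np.fill_diagonal(conflict, False)
    if mode == "exact":
        if len(mols) > EXACT_NCIRCLES_MAX:
            raise ValueError(
                f"exact mode limited to {EXACT_NCIRCLES_MAX} molecules; use mode='greedy'"
            )
        return _exact_max_packing(conflict)
    if mode == "greedy":
        return _greedy_packing(mols, conflict, dist)
    raise ValueError(f"unknown mode {mode!r}")


def novelty_nn_distance(mols: list[Molecule], reference: list[Molecule]) -> list[float]:
    """Per-molecule minimum Tanimoto distance to a reference library."""
    if not reference:
        raise ValueError("reference set must be non-empty")
    return [min(bulk_tanimoto_distance(m, reference)) for m in mols]
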