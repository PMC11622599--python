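"""Atomic sphere-overlap shape score between two pre-aligned conformers.

Each atom is a sphere of radius 0.7 x its van der Waals radius.  The score
is the total query-reference sphere-intersection volume divided by the
larger of the two self-overlap volumes (double sums over all ordered atom
pairs, diagonal included), so it lives in [0, 1] and equals 1 when the
reference duplicates the query's coordinates.  Alignment is the caller's
responsibility; a Kabsch helper is provided for rigid superposition of
matched atom indices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from rdkit import Chem

#: Bondi van der Waals radii (Å).
VDW_RADII: dict[str, float] = {
    "H": 1.20, "He": 1.40, "B": 1.92, "C": 1.70, "N": 1.55, "O": 1.52,
    "F": 1.47, "Ne": 1.54, "Si": 2.10, "P": 1.80, "S": 1.80, "Cl": 1.75,
    "Ar": 1.88, "As": 1.85, "Se": 1.90, "Br": 1.85, "Kr": 2.02, "Te": 2.06,
    "I": 1.98, "Xe": 2.16,
}

#: Sphere radius = this factor times the van der Waals radius.
RADIUS_SCALE = 0.7


@dataclass(frozen=True)
class SphereSet:
    """Atom centers (Å) with scaled van der Waals radii."""

    centers: np.ndarray  # (n, 3)
    radii: np.ndarray  # (n,)
    elements: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.centers.shape != (len(self.radii), 3) or len(self.radii) < 1:
            raise ValueError("need >= 1 sphere with 3D centers and matching radii")
        if np.any(self.radii <= 0):
            raise ValueError("all radii must be positive")

    @classmethod
    def from_rdkit_mol(cls, mol: Chem.Mol, conf_id: int = -1, scale: float = RADIUS_SCALE) -> "SphereSet":
        """Spheres for every atom of a conformer (only atoms present in the
        graph get spheres; implicit hydrogens contribute nothing)."""
        conf = mol.GetConformer(conf_id)
        elements = tuple(a.GetSymbol() for a in mol.GetAtoms())
        try:
            radii = np.array([scale * VDW_RADII[el] for el in elements])
        except KeyError as exc:
            raise KeyError(f"no van der Waals radius tabulated for element {exc}") from None
        return cls(centers=np.array(conf.GetPositions(), dtype=float), radii=radii, elements=elements)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "SphereSet":
        return SphereSet(self.centers @ rotation.T + translation, self.radii, self.elements)


def sphere_overlap_volume(c1: np.ndarray, r1: float, c2: np.ndarray, r2: float) -> float:
    """Exact intersection volume (Å³) of two spheres (lens formula)."""
    d = float(np.linalg.norm(np.asarray(c1, float) - np.asarray(c2, float)))
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        r = min(r1, r2)
        return 4.0 / 3.0 * math.pi * r**3
    return (
        math.pi
        * (r1 + r2 - d) ** 2
        * (d**2 + 2 * d * (r1 + r2) - 3 * (r1 - r2) ** 2)
        / (12 * d)
    )


def _overlap_matrix_sum(a: SphereSet, b: SphereSet) -> float:
    """Sum of pairwise sphere-intersection volumes over all ordered pairs."""
    d = np.linalg.norm(a.centers[:, None, :] - b.centers[None, :, :], axis=-1)
    r1 = a.radii[:, None]
    r2 = b.radii[None, :]
    vol = np.zeros_like(d)
    contained = d <= np.abs(r1 - r2)
    rmin = np.minimum(r1, r2)
    vol = np.where(contained, 4.0 / 3.0 * np.pi * np.broadcast_to(rmin, d.shape) ** 3, vol)
    lens = (~contained) & (d < r1 + r2)
    dl = np.where(lens, d, 1.0)  # avoid 0/0 where masked out
    lens_vol = (
        np.pi * (r1 + r2 - dl) ** 2 * (dl**2 + 2 * dl * (r1 + r2) - 3 * (r1 - r2) ** 2) / (12 * dl)
    )
    vol = np.where(lens, lens_vol, vol)
    return float(vol.sum())


def galign_score(query: SphereSet, reference: SphereSet) -> float:
    """Fraction of atomic overlap between two aligned sphere sets, in [0, 1].

    cross-overlap / max(query self-overlap, reference self-overlap); the
    self sums run over all ordered pairs including the diagonal.
    """
    cross = _overlap_matrix_sum(query, reference)
    denom = max(_overlap_matrix_sum(query, query), _overlap_matrix_sum(reference, reference))
    return float(np.clip(cross / denom, 0.0, 1.0))


def kabsch_superpose(moving: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid superposition of matched coordinate sets.

    Returns ``(rotation, translation)`` mapping ``moving`` onto ``target``
    (proper rotation; reflections are excluded).
    """
    moving = np.asarray(moving, float)
    target = np.asarray(target, float)
    mu_m, mu_t = moving.mean(axis=0), target.mean(axis=0)
    h = (moving - mu_m).T @ (target - mu_t)
    u, _, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, sign]) @ u.T
    return rot, mu_t - rot @ mu_m
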