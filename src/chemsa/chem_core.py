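"""Molecule representation, canonical SMILES, circular fingerprints, Tanimoto distance.

Every other module operates in the metric space defined here: molecules are
identified by their canonical SMILES and compared by the Tanimoto distance
(1 - Tanimoto similarity) between 2048-bit radius-2 Morgan fingerprints.
The fingerprint parameters are frozen in :data:`FP_RADIUS` / :data:`FP_NBITS`
so that all distances in a run (and across runs) are mutually comparable.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator
from rdkit.DataStructs import BulkTanimotoSimilarity, TanimotoSimilarity
from rdkit.DataStructs.cDataStructs import ExplicitBitVect

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

#: Morgan fingerprint parameters, frozen for reproducible distances.
FP_RADIUS = 2
FP_NBITS = 2048

_fpgen = rdFingerprintGenerator.GetMorganGenerator(
    radius=FP_RADIUS, fpSize=FP_NBITS, includeChirality=False, countSimulation=False
)


class ParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into valid chemistry."""


@dataclass(frozen=True)
class Molecule:
    """An immutable molecule: canonical SMILES + fingerprint + heavy-atom count.

    Construct via :func:`canonicalize`; the constructor does not validate.
    Equality and hashing are by canonical SMILES only.
    """

    smiles: str
    fingerprint: ExplicitBitVect = field(compare=False, hash=False, repr=False)
    n_heavy: int = field(compare=False, hash=False)

    def __hash__(self) -> int:  # dataclass eq=True would forbid custom hash
        return hash(self.smiles)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Molecule) and self.smiles == other.smiles

    def to_rdkit(self) -> Chem.Mol:
        return Chem.MolFromSmiles(self.smiles)


def fingerprint_of(mol: Chem.Mol) -> ExplicitBitVect:
    """Binary Morgan fingerprint with the frozen package-wide parameters."""
    return _fpgen.GetFingerprint(mol)


def canonicalize(smiles_in: str) -> Molecule:
    """Parse a SMILES string into a :class:`Molecule` with canonical SMILES.

    Idempotent: canonicalizing the canonical SMILES returns an equal Molecule.
    Multi-fragment inputs (salts, mixtures) keep the largest covalent
    component; the event is logged.

    Raises
    ------
    ParseError
        If the SMILES cannot be parsed or violates valence rules.
    """
    mol = Chem.MolFromSmiles(smiles_in)
    if mol is None:
        raise ParseError(f"unparseable or valence-invalid SMILES: {smiles_in!r}")
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if len(frags) > 1:
        logger.info("multi-fragment SMILES %r: keeping largest component", smiles_in)
        mol = max(frags, key=lambda m: m.GetNumHeavyAtoms())
    smiles = Chem.MolToSmiles(mol)
    n_heavy = mol.GetNumHeavyAtoms()
    if n_heavy < 1:
        raise ParseError(f"no heavy atoms in {smiles_in!r}")
    return Molecule(smiles=smiles, fingerprint=fingerprint_of(mol), n_heavy=n_heavy)


def tanimoto_distance(a: Molecule, b: Molecule) -> float:
    """1 - Tanimoto similarity between the two fingerprints, in [0, 1].

    If both fingerprints are empty (no bits set) the Tanimoto ratio is
    undefined; the distance is then 0 for identical SMILES and 1 otherwise.
    """
    if a.fingerprint.GetNumOnBits() == 0 and b.fingerprint.GetNumOnBits() == 0:
        logger.warning("Tanimoto distance between two empty fingerprints")
        return 0.0 if a.smiles == b.smiles else 1.0
    return 1.0 - TanimotoSimilarity(a.fingerprint, b.fingerprint)


def bulk_tanimoto_distance(query: Molecule, others: list[Molecule]) -> list[float]:
    """Distances from one molecule to many, via RDKit's vectorized kernel."""
    sims = BulkTanimotoSimilarity(query.fingerprint, [m.fingerprint for m in others])
    return [1.0 - s for s in sims]


def pairwise_mean_distance(mols: list[Molecule]) -> float:
    """Mean Tanimoto distance over all n(n-1)/2 unordered pairs."""
    if len(mols) < 2:
        raise ValueError("pairwise_mean_distance needs at least 2 molecules")
    total = 0.0
    npairs = 0
    for i, a in enumerate(mols[:-1]):
        sims = BulkTanimotoSimilarity(a.fingerprint, [m.fingerprint for m in mols[i + 1 :]])
        total += sum(1.0 - s for s in sims)
        npairs += len(sims)
    return total / npairs


def all_pair_distances(mols: list[Molecule]) -> list[float]:
    """All unordered-pair distances, in itertools.combinations order."""
    return [tanimoto_distance(a, b) for a, b in itertools.combinations(mols, 2)]
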