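"""BRICS retrosynthetic cleavage into single-attachment-point fragments.

BRICS (Breaking of Retrosynthetically Interesting Chemical Substructures)
defines 16 chemical-environment types at which acyclic bonds may be cleaved,
together with a compatibility relation saying which environment pairs may be
re-joined by virtual synthesis.  Bond detection delegates to RDKit's BRICS
pattern matcher; the compatibility relation is transcribed below from the
published rule set and frozen, so that joining decisions do not depend on
RDKit internals.

A fragment here always has exactly ONE attachment point, i.e. it arises from
a single bond cleavage.  The attachment placeholder is the conventional
isotope-labelled dummy atom ``[<link_type>*]``, so a fragment round-trips
through plain SMILES text.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdkit import Chem
from rdkit.Chem import BRICS

from .chem_core import Molecule

#: Number of BRICS link-environment types.
N_LINK_TYPES = 16

# Transcription of the published BRICS link-compatibility matrix (unordered
# pairs of environment labels whose fragments may be joined).  Label 2 was
# retired from the original rule set and is compatible with nothing; labels
# 7a/7b (alkene carbons) are collapsed onto 7.
_COMPATIBLE_PAIRS: frozenset[tuple[int, int]] = frozenset(
    {
        (1, 3), (1, 5), (1, 10),
        (3, 4), (3, 13), (3, 14), (3, 15), (3, 16),
        (4, 5), (4, 11),
        (5, 12), (5, 13), (5, 14), (5, 15), (5, 16),
        (6, 13), (6, 14), (6, 15), (6, 16),
        (7, 7),
        (8, 9), (8, 10), (8, 13), (8, 14), (8, 15), (8, 16),
        (9, 13), (9, 14), (9, 15), (9, 16),
        (10, 13), (10, 14), (10, 15), (10, 16),
        (11, 13), (11, 14), (11, 15), (11, 16),
        (13, 14), (13, 15), (13, 16),
        (14, 14), (14, 15), (14, 16),
        (15, 16),
        (16, 16),
    }
)

#: The alkene-alkene join (7, 7) forms a double bond; every other join is single.
DOUBLE_BOND_PAIRS: frozenset[tuple[int, int]] = frozenset({(7, 7)})


def compatibility_table() -> list[list[bool]]:
    """The 16x16 symmetric boolean join-compatibility relation."""
    table = [[False] * (N_LINK_TYPES + 1) for _ in range(N_LINK_TYPES + 1)]
    for a, b in _COMPATIBLE_PAIRS:
        table[a][b] = table[b][a] = True
    return [row[1:] for row in table[1:]]


def compatible(a: int, b: int) -> bool:
    """Whether fragments with link types ``a`` and ``b`` may be joined."""
    if not (1 <= a <= N_LINK_TYPES and 1 <= b <= N_LINK_TYPES):
        raise ValueError(f"link types must be in 1..{N_LINK_TYPES}, got ({a}, {b})")
    return (min(a, b), max(a, b)) in _COMPATIBLE_PAIRS


@dataclass(frozen=True)
class Fragment:
    """A sub-molecule with exactly one isotope-labelled attachment dummy.

    ``core_smiles`` is the canonical SMILES including the ``[<link>*]``
    placeholder; ``n_heavy`` counts real (non-dummy, non-H) atoms only.
    """

    core_smiles: str
    link_type: int
    n_heavy: int
    parent: str | None = field(default=None, compare=False)

    def to_rdkit(self) -> Chem.Mol:
        return Chem.MolFromSmiles(self.core_smiles)


def _link_label_to_int(label: str) -> int:
    # FindBRICSBonds labels are strings, '7a'/'7b' for the two alkene roles
    return int(label.rstrip("ab"))


def enumerate_cleavages(mol: Molecule) -> list[tuple[int, int, int]]:
    """All BRICS-cleavable bonds of a molecule.

    Returns ``(bond_index, link_type_begin, link_type_end)`` triples; ring
    bonds never appear (BRICS cleaves acyclic bonds only).  Molecules with no
    BRICS environment match return an empty list.
    """
    rdmol = mol.to_rdkit()
    out = []
    seen = set()
    for (a1, a2), (l1, l2) in BRICS.FindBRICSBonds(rdmol):
        bond = rdmol.GetBondBetweenAtoms(a1, a2)
        if bond.GetIdx() in seen:
            continue
        seen.add(bond.GetIdx())
        if bond.GetBeginAtomIdx() == a1:
            out.append((bond.GetIdx(), _link_label_to_int(l1), _link_label_to_int(l2)))
        else:
            out.append((bond.GetIdx(), _link_label_to_int(l2), _link_label_to_int(l1)))
    return out


def cleave_bond(mol: Molecule, bond_idx: int, link_begin: int, link_end: int) -> tuple[Fragment, Fragment]:
    """Cut one bond, yielding the two sides as single-attachment fragments.

    The dummy placed in the fragment containing the bond's begin atom carries
    that side's own link type (and vice versa), following the BRICS
    decomposition convention.
    """
    rdmol = mol.to_rdkit()
    # FragmentOnBonds attaches the FIRST dummy label to the fragment holding
    # the bond's END atom, so the pair is passed reversed to keep each side's
    # own environment label on its dummy.
    cut = Chem.FragmentOnBonds(rdmol, [bond_idx], dummyLabels=[(link_end, link_begin)])
    pieces = Chem.GetMolFrags(cut, asMols=True, sanitizeFrags=True)
    if len(pieces) != 2:  # pragma: no cover - single acyclic bond always splits in two
        raise RuntimeError(f"cleaving bond {bond_idx} of {mol.smiles} gave {len(pieces)} pieces")
    frags = []
    for piece in pieces:
        dummies = [a for a in piece.GetAtoms() if a.GetAtomicNum() == 0]
        assert len(dummies) == 1
        frags.append(
            Fragment(
                core_smiles=Chem.MolToSmiles(piece),
                link_type=dummies[0].GetIsotope(),
                n_heavy=piece.GetNumHeavyAtoms(),
                parent=mol.smiles,
            )
        )
    return frags[0], frags[1]


_fragment_cache: dict[tuple[str, int], set[Fragment]] = {}


def fragment_molecule(mol: Molecule, min_heavy_exclusive: int = 3) -> set[Fragment]:
    """All single-cut BRICS fragments with more than ``min_heavy_exclusive`` heavy atoms.

    Each BRICS bond contributes its two sides; fragments at or below the
    heavy-atom bound are discarded (the default keeps fragments of more than
    three atoms), and the result is deduplicated by (core SMILES, link type).
    Results are memoized by canonical SMILES.
    """
    key = (mol.smiles, min_heavy_exclusive)
    cached = _fragment_cache.get(key)
    if cached is not None:
        return set(cached)
    out: set[Fragment] = set()
    for bond_idx, l1, l2 in enumerate_cleavages(mol):
        for frag in cleave_bond(mol, bond_idx, l1, l2):
            if frag.n_heavy > min_heavy_exclusive:
                out.add(frag)
    _fragment_cache[key] = out
    return set(out)


def parse_fragment(smiles: str) -> Fragment:
    """Parse a fragment SMILES using the isotope-labelled dummy convention.

    Raises ``ValueError`` unless the SMILES has exactly one dummy atom whose
    isotope is a valid link type.
    """
    rdmol = Chem.MolFromSmiles(smiles)
    if rdmol is None:
        raise ValueError(f"unparseable fragment SMILES: {smiles!r}")
    dummies = [a for a in rdmol.GetAtoms() if a.GetAtomicNum() == 0]
    if len(dummies) != 1:
        raise ValueError(f"fragment must have exactly one attachment dummy: {smiles!r}")
    link = dummies[0].GetIsotope()
    if not 1 <= link <= N_LINK_TYPES:
        raise ValueError(f"attachment dummy isotope {link} out of range 1..16: {smiles!r}")
    return Fragment(
        core_smiles=Chem.MolToSmiles(rdmol),
        link_type=link,
        n_heavy=rdmol.GetNumHeavyAtoms(),
    )
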