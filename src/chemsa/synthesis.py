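"""Virtual synthesis: join compatible BRICS fragments into new molecules.

Trial molecules are built by picking one fragment from a seed molecule and
one partner fragment (from a bank molecule or a fragment database), each
drawn with probability proportional to a frequency-derived weight, and
forming the bond their attachment dummies encode.  With a uniform frequency
table the sampling is uniform; supplying bit counts from a reference corpus
biases the search toward substructures common in synthesized chemistry.

Join results and fragment weights are memoized at module level: both are
pure functions of their chemical inputs, and the annealing loop re-samples
the same pairs heavily.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem

from .chem_core import Molecule, canonicalize, fingerprint_of
from .fragmentation import (
    DOUBLE_BOND_PAIRS,
    Fragment,
    compatible,
    fragment_molecule,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class JoinFailure:
    """Failure value returned when two fragments cannot be joined."""

    reason: str


INCOMPATIBLE = JoinFailure("incompatible")

_join_cache: dict[tuple[str, str], Molecule | JoinFailure] = {}
_frag_bits_cache: dict[str, tuple[int, ...]] = {}


def join_fragments(a: Fragment, b: Fragment) -> Molecule | JoinFailure:
    """Join two single-attachment fragments into one molecule.

    If the link types are BRICS-compatible, the attachment atoms are bonded
    (double bond for the alkene-alkene pair, single otherwise), the dummies
    removed, and the product sanitized and canonicalized.  Returns a
    :class:`JoinFailure` (never raises) when the pair is incompatible or the
    product fails sanitization.
    """
    if not compatible(a.link_type, b.link_type):
        return INCOMPATIBLE
    key = (a.core_smiles, b.core_smiles)
    cached = _join_cache.get(key)
    if cached is None:
        cached = _join_uncached(a, b)
        _join_cache[key] = cached
        _join_cache[(b.core_smiles, a.core_smiles)] = cached
    return cached


def _join_uncached(a: Fragment, b: Fragment) -> Molecule | JoinFailure:
    mol_a, mol_b = a.to_rdkit(), b.to_rdkit()
    if mol_a is None or mol_b is None:
        return JoinFailure("unparseable fragment")
    combined = Chem.RWMol(Chem.CombineMols(mol_a, mol_b))
    dummies = [at.GetIdx() for at in combined.GetAtoms() if at.GetAtomicNum() == 0]
    if len(dummies) != 2:
        return JoinFailure("fragment lacks a single attachment dummy")
    anchors = []
    for d in dummies:
        nbrs = combined.GetAtomWithIdx(d).GetNeighbors()
        if len(nbrs) != 1:
            return JoinFailure("attachment dummy with multiple neighbors")
        anchors.append(nbrs[0].GetIdx())
    pair = (min(a.link_type, b.link_type), max(a.link_type, b.link_type))
    order = Chem.BondType.DOUBLE if pair in DOUBLE_BOND_PAIRS else Chem.BondType.SINGLE
    combined.AddBond(anchors[0], anchors[1], order)
    for d in sorted(dummies, reverse=True):
        combined.RemoveAtom(d)
    try:
        product = combined.GetMol()
        Chem.SanitizeMol(product)
        return canonicalize(Chem.MolToSmiles(product))
    except Exception as exc:  # valence clash or aromaticity failure
        return JoinFailure(f"sanitization: {exc}")


@dataclass
class FrequencyTable:
    """Occurrence counts of fingerprint bits in a reference corpus.

    ``counts`` maps a Morgan-fingerprint bit index to how often that bit is
    set across the corpus; missing bits count 0.  ``pseudocount`` is added
    inside the logarithm so unseen bits do not produce ``log(0)``.
    """

    counts: dict[int, float] = field(default_factory=dict)
    pseudocount: float = 1.0
    _weight_cache: dict[str, float] = field(default_factory=dict, repr=False, compare=False)

    @classmethod
    def uniform(cls) -> "FrequencyTable":
        """Empty table: every fragment gets the same weight (uniform sampling)."""
        return cls(counts={}, pseudocount=1.0)

    @classmethod
    def from_corpus(cls, mols: Sequence[Molecule], pseudocount: float = 1.0) -> "FrequencyTable":
        """Count set fingerprint bits over a (small) user corpus."""
        counts: dict[int, float] = {}
        for m in mols:
            for b in m.fingerprint.GetOnBits():
                counts[b] = counts.get(b, 0) + 1
        return cls(counts=counts, pseudocount=pseudocount)


def _fragment_bits(f: Fragment) -> tuple[int, ...]:
    bits = _frag_bits_cache.get(f.core_smiles)
    if bits is None:
        rdmol = f.to_rdkit()
        bits = tuple(fingerprint_of(rdmol).GetOnBits()) if rdmol is not None else ()
        _frag_bits_cache[f.core_smiles] = bits
    return bits


def fragment_weight(f: Fragment, table: FrequencyTable) -> float:
    """Sampling weight: mean over the fragment's set bits of log(count + pseudocount).

    Clamped at zero (a weight is a relative sampling propensity, never
    negative).  A fragment whose fingerprint has no set bits gets a floor of
    ``log(1 + pseudocount)`` so it remains sampleable; the event is logged.
    """
    cached = table._weight_cache.get(f.core_smiles)
    if cached is not None:
        return cached
    bits = _fragment_bits(f)
    if not bits:
        logger.warning("fragment %s has an empty fingerprint; floor weight used", f.core_smiles)
        weight = math.log(1.0 + table.pseudocount)
    else:
        mean_log = sum(
            math.log(table.counts.get(b, 0.0) + table.pseudocount) for b in bits
        ) / len(bits)
        weight = max(mean_log, 0.0)
    table._weight_cache[f.core_smiles] = weight
    return weight


def _sampling_probs(frags: Sequence[Fragment], table: FrequencyTable) -> np.ndarray:
    w = np.array([fragment_weight(f, table) for f in frags], dtype=float)
    total = w.sum()
    if total <= 0.0:  # all-equal (e.g. uniform table) -> uniform sampling
        return np.full(len(frags), 1.0 / len(frags))
    return w / total


def sorted_fragments(frags: set[Fragment] | Sequence[Fragment]) -> list[Fragment]:
    """Deterministic fragment ordering used everywhere sampling happens."""
    return sorted(frags, key=lambda f: (f.core_smiles, f.link_type))


def partner_pool_from_molecule(partner: Molecule) -> list[Fragment]:
    """Single-cut fragment pool of a partner molecule (deterministic order)."""
    return sorted_fragments(fragment_molecule(partner))


def generate_trials(
    seed: Molecule,
    partner_fragments: Sequence[Fragment],
    table: FrequencyTable | None = None,
    max_trials: int = 60,
    rng: np.random.Generator | None = None,
    attempt_factor: int = 1,
    min_heavy_exclusive: int = 3,
) -> list[Molecule]:
    """Synthesize up to ``max_trials`` unique molecules from a seed and partners.

    Repeatedly samples one seed-derived fragment and one partner fragment
    (independently, probability proportional to :func:`fragment_weight`) and
    joins them.  Unique successful products are collected over a budget of
    ``attempt_factor * max_trials`` join attempts (so with the default
    factor, "up to 60 molecules" means 60 sampled attempts whose failures
    and duplicates are simply lost), capped at ``max_trials`` products.
    Deterministic given the rng state.
    """
    if max_trials < 1:
        raise ValueError("max_trials must be >= 1")
    table = table if table is not None else FrequencyTable.uniform()
    rng = rng if rng is not None else np.random.default_rng()
    seed_frags = sorted_fragments(fragment_molecule(seed, min_heavy_exclusive))
    if not seed_frags:
        logger.debug("seed %s has no BRICS fragments; no trials", seed.smiles)
        return []
    if not partner_fragments:
        return []
    partner_fragments = list(partner_fragments)
    p_seed = _sampling_probs(seed_frags, table)
    p_partner = _sampling_probs(partner_fragments, table)
    budget = attempt_factor * max_trials
    # one vectorized draw for the whole attempt budget; attempts beyond the
    # product cap are simply unused, so determinism is preserved
    seed_idx = rng.choice(len(seed_frags), size=budget, p=p_seed)
    partner_idx = rng.choice(len(partner_fragments), size=budget, p=p_partner)
    products: dict[str, Molecule] = {}
    for si, pi in zip(seed_idx, partner_idx):
        result = join_fragments(seed_frags[si], partner_fragments[pi])
        if isinstance(result, Molecule) and result.smiles not in products:
            products[result.smiles] = result
            if len(products) >= max_trials:
                break
    return list(products.values())
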