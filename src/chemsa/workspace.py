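"""File I/O, library curation, and deterministic test fixtures.

Formats
-------
* SMILES files: one molecule per line, optional tab-separated name; blank
  lines and ``#`` comments ignored.
* Fragment files: SMILES lines using the isotope-labelled dummy convention.
* Bank CSV: rank, smiles, objective, sa_score.
* Frequency table: two-column TSV ``bit_index<TAB>count``.

Fixtures are drawn from a bundled list of ~300 curated drug-like SMILES so
that every pipeline stage is exercisable without downloads.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem

from .chem_core import Molecule, ParseError, canonicalize, tanimoto_distance
from .fragmentation import Fragment, fragment_molecule, parse_fragment
from .objectives import make_objective
from .synthesis import FrequencyTable, sorted_fragments

logger = logging.getLogger(__name__)

#: Default similarity threshold for non-redundancy curation.
CURATION_SIMILARITY = 0.7


def _iter_data_lines(path: str | Path) -> list[str]:
    text = Path(path).read_text()
    return [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]


def read_smiles_file(path: str | Path) -> list[Molecule]:
    """Read a SMILES file; malformed lines are counted, logged, and skipped.

    Raises if the file yields no molecules or if more than half the data
    lines are malformed (a wrong-format file, not a few bad records).
    """
    lines = _iter_data_lines(path)
    if not lines:
        raise ValueError(f"no molecule records in {path}")
    mols: list[Molecule] = []
    bad = 0
    for ln in lines:
        smiles = ln.split("\t")[0].split()[0]
        try:
            mols.append(canonicalize(smiles))
        except ParseError:
            bad += 1
    if bad:
        logger.warning("%s: skipped %d malformed of %d lines", path, bad, len(lines))
    if bad * 2 > len(lines):
        raise ValueError(f"{path}: {bad}/{len(lines)} lines malformed; wrong format?")
    if not mols:
        raise ValueError(f"no valid molecules in {path}")
    return mols


def read_fragment_file(path: str | Path) -> list[Fragment]:
    """Read a fragment SMILES file; lines violating the one-dummy convention
    are dropped with a logged count."""
    lines = _iter_data_lines(path)
    frags: list[Fragment] = []
    bad = 0
    for ln in lines:
        try:
            frags.append(parse_fragment(ln.split("\t")[0].split()[0]))
        except ValueError:
            bad += 1
    if bad:
        logger.warning("%s: dropped %d invalid fragment lines", path, bad)
    return frags


def write_smiles_file(mols: list[Molecule], path: str | Path) -> None:
    Path(path).write_text("".join(f"{m.smiles}\n" for m in mols))


def write_fragment_file(frags: list[Fragment], path: str | Path) -> None:
    Path(path).write_text("".join(f"{f.core_smiles}\n" for f in frags))


def write_bank_csv(bank, path: str | Path) -> None:
    """Bank as ranked CSV with objective and synthetic-accessibility columns."""
    sa = make_objective("sa")
    rows = sorted(bank.entries, key=lambda e: (e.value, e.mol.smiles))
    df = pd.DataFrame(
        {
            "rank": range(1, len(rows) + 1),
            "smiles": [e.mol.smiles for e in rows],
            "objective": [e.value for e in rows],
            "sa_score": [sa.evaluate(e.mol) for e in rows],
        }
    )
    df.to_csv(path, index=False)


def read_bank_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_frequency_table(path: str | Path, pseudocount: float = 1.0) -> FrequencyTable:
    df = pd.read_csv(path, sep="\t", header=None, names=["bit", "count"], comment="#")
    return FrequencyTable(
        counts={int(b): float(c) for b, c in zip(df["bit"], df["count"])},
        pseudocount=pseudocount,
    )


def curate_pool(mols: list[Molecule], similarity_threshold: float = CURATION_SIMILARITY) -> list[Molecule]:
    """Non-redundancy curation by leader clustering in input order.

    A molecule joins the first existing cluster whose leader is at least
    ``similarity_threshold`` Tanimoto-similar, else founds a new cluster;
    the cluster leaders are returned.  Order-dependent but deterministic.
    """
    if not 0.0 < similarity_threshold < 1.0:
        raise ValueError("similarity threshold must be in (0, 1)")
    leaders: list[Molecule] = []
    for m in mols:
        if all(1.0 - tanimoto_distance(m, l) < similarity_threshold for l in leaders):
            leaders.append(m)
    return leaders


# ---------------------------------------------------------------------------
# fixtures

def bundled_drug_smiles() -> list[str]:
    """The bundled list of curated drug-like SMILES (sorted, canonical)."""
    text = resources.files("chemsa.data").joinpath("drugs.smi").read_text()
    return sorted(
        ln.split("\t")[0] for ln in text.splitlines()
        if ln.strip() and not ln.startswith("#")
    )


def fixture_pool(n: int, rng_seed: int) -> list[Molecule]:
    """Deterministic n-molecule sample from the bundled drug-like list."""
    smiles = bundled_drug_smiles()
    if n > len(smiles):
        raise ValueError(f"requested {n} fixtures but bundle has {len(smiles)}")
    rng = np.random.default_rng(rng_seed)
    idx = rng.choice(len(smiles), size=n, replace=False)
    return [canonicalize(smiles[i]) for i in sorted(idx)]


def fixture_fragments(n: int, rng_seed: int, source_pool: int = 150) -> list[Fragment]:
    """A synthetic fragment database: single-cut fragments of a fixture pool,
    deduplicated by non-redundancy curation of their cores, sampled to n."""
    pool = fixture_pool(source_pool, rng_seed)
    frags = sorted_fragments({f for m in pool for f in fragment_molecule(m)})
    if n > len(frags):
        raise ValueError(f"requested {n} fragments but only {len(frags)} available")
    rng = np.random.default_rng(rng_seed)
    idx = rng.choice(len(frags), size=n, replace=False)
    return [frags[i] for i in sorted(idx)]


#: Small rigid molecules used for 3D-conformer fixtures.
_CONFORMER_SMILES = [
    "c1ccccc1", "c1ccncc1", "C1CCCCC1", "c1ccc2ccccc2c1", "CC(=O)O",
    "c1ccoc1", "c1ccsc1", "C1CCOC1", "O=C1CCCC1", "c1cnc2[nH]ccc2c1",
]


def fixture_conformers(n: int, rng_seed: int) -> list[Chem.Mol]:
    """Small molecules with embedded, optimized 3D coordinates."""
    if n > len(_CONFORMER_SMILES):
        raise ValueError(f"at most {len(_CONFORMER_SMILES)} conformer fixtures available")
    mols = []
    for smi in _CONFORMER_SMILES[:n]:
        mol = Chem.AddHs(Chem.MolFromSmiles(smi))
        AllChem.EmbedMolecule(mol, randomSeed=rng_seed)
        AllChem.MMFFOptimizeMolecule(mol)
        mols.append(Chem.RemoveHs(mol))
    return mols


def make_fixtures(kind: str, n: int, rng_seed: int, out_path: str | Path) -> Path:
    """Write a fixture file (pool/fragments: SMILES lines; conformers: SDF)."""
    out_path = Path(out_path)
    if kind == "pool":
        write_smiles_file(fixture_pool(n, rng_seed), out_path)
    elif kind == "fragments":
        write_fragment_file(fixture_fragments(n, rng_seed), out_path)
    elif kind == "conformers":
        writer = Chem.SDWriter(str(out_path))
        for mol in fixture_conformers(n, rng_seed):
            writer.write(mol)
        writer.close()
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return out_path
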