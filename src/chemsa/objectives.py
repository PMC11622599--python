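"""Pluggable objective functions with caching and unique-evaluation counting.

Every objective is MINIMIZED.  Scores whose natural direction is
maximize-better (QED, similarity to a target) are complemented or negated at
registration so the optimizer has a single convention.  Built-ins:

``sa``
    Synthetic accessibility score in [1, 10]; lower is easier to make.
``qed``
    Negated quantitative estimate of drug-likeness, in (-1, 0).
``logp``
    Crippen logP as-is (minimization favors hydrophilic molecules).
``simtarget``
    Tanimoto distance to a target SMILES; 0 at the target itself.
``external``
    A user-supplied callable or shell command (SMILES on stdin, one value
    per line on stdout) — the hook where a trained surrogate model plugs in.

Evaluations are cached by canonical SMILES, and the evaluation counter
counts unique molecules only, so it is directly comparable with the number
of objective-function calls an expensive scorer would actually pay for.
"""

from __future__ import annotations

import os
import subprocess
import sys
from typing import Callable

from rdkit import Chem, RDConfig
from rdkit.Chem import Crippen, QED

from .chem_core import Molecule, canonicalize, tanimoto_distance

sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
import sascorer  # noqa: E402  (RDKit contrib module, path set above)


class Objective:
    """A named, cached, minimized objective function over molecules."""

    def __init__(self, name: str, fn: Callable[[Molecule], float]):
        self.name = name
        self._fn = fn
        self._cache: dict[str, float] = {}

    @property
    def n_evaluations(self) -> int:
        """Number of distinct canonical SMILES evaluated so far."""
        return len(self._cache)

    def evaluate(self, mol: Molecule) -> float:
        """Objective value (finite real, smaller is better), cached by SMILES."""
        value = self._cache.get(mol.smiles)
        if value is None:
            try:
                value = float(self._fn(mol))
            except Exception as exc:
                raise RuntimeError(f"objective {self.name!r} failed on {mol.smiles}") from exc
            if value != value or value in (float("inf"), float("-inf")):
                raise RuntimeError(f"objective {self.name!r} non-finite on {mol.smiles}")
            self._cache[mol.smiles] = value
        return value


def _sa(mol: Molecule) -> float:
    return sascorer.calculateScore(mol.to_rdkit())


def _neg_qed(mol: Molecule) -> float:
    return -QED.qed(mol.to_rdkit())


def _logp(mol: Molecule) -> float:
    return Crippen.MolLogP(mol.to_rdkit())


def make_similarity_objective(target_smiles: str) -> Objective:
    """Tanimoto distance to a fixed target; the global minimum (0) is the target."""
    target = canonicalize(target_smiles)
    return Objective("simtarget", lambda m: tanimoto_distance(m, target))


def make_external_objective(command: str | Callable[[Molecule], float]) -> Objective:
    """Wrap a user scorer: a Python callable, or a shell command reading
    SMILES lines on stdin and writing one numeric value per line."""
    if callable(command):
        return Objective("external", command)

    def run(mol: Molecule) -> float:
        out = subprocess.run(
            command, shell=True, input=mol.smiles + "\n",
            capture_output=True, text=True, check=True,
        )
        return float(out.stdout.strip().splitlines()[0])

    return Objective("external", run)


def builtin_objectives() -> dict[str, Callable[..., Objective]]:
    """Registry of objective factories keyed by name."""
    return {
        "sa": lambda: Objective("sa", _sa),
        "qed": lambda: Objective("qed", _neg_qed),
        "logp": lambda: Objective("logp", _logp),
        "simtarget": make_similarity_objective,
        "external": make_external_objective,
    }


def make_objective(name: str, **params) -> Objective:
    """Instantiate a registered objective by name.

    ``simtarget`` needs ``target_smiles=...``; ``external`` needs
    ``command=...``.
    """
    registry = builtin_objectives()
    if name not in registry:
        raise ValueError(f"unknown objective {name!r}; available: {sorted(registry)}")
    return registry[name](**params)
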