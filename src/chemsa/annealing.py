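"""Chemical-space annealing: a niching global optimizer over molecules.

The optimizer maintains a fixed-size *bank* of mutually distinct molecules.
Each cycle, a batch of six seed molecules is drawn from the bank entries not
yet used as seeds (flags reset once every entry has seeded, so a full pass
over a 60-molecule bank spans ten cycles), and trial molecules are
synthesized from each seed by BRICS recombination with (a) the fragments of
a randomly chosen initial-bank molecule and (b) a random sample of a
fragment database.  A trial competes locally if it lands within a niching
radius ``R_cut`` of its nearest bank member — replacing that member when its
objective value is better — and globally otherwise, replacing the worst bank
member when it improves on it.

``R_cut`` starts at half the mean pairwise Tanimoto distance of the initial
bank and shrinks by a factor of 0.4**0.05 per cycle for 20 cycles (reaching
40% of its initial value), then stays constant: broad exploration first,
focused refinement later.  A default run performs 50 cycles.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .chem_core import Molecule, bulk_tanimoto_distance, pairwise_mean_distance
from .fragmentation import Fragment
from .objectives import Objective
from .synthesis import FrequencyTable, generate_trials, partner_pool_from_molecule

logger = logging.getLogger(__name__)

#: Per-cycle geometric shrink factor of the niching radius.
RCUT_DECAY = 0.4 ** 0.05
#: Cycle index after which the radius stays constant (radius ratio 0.4 there).
RCUT_FLOOR_CYCLE = 20


@dataclass
class BankEntry:
    mol: Molecule
    value: float
    used_as_seed: bool = False


@dataclass
class Bank:
    """Fixed-size population; no two entries share a canonical SMILES."""

    entries: list[BankEntry]

    @property
    def n(self) -> int:
        return len(self.entries)

    def molecules(self) -> list[Molecule]:
        return [e.mol for e in self.entries]

    def values(self) -> list[float]:
        return [e.value for e in self.entries]

    def best(self) -> BankEntry:
        return min(self.entries, key=lambda e: (e.value, e.mol.smiles))

    def reset_seed_flags(self) -> None:
        for e in self.entries:
            e.used_as_seed = False


@dataclass(frozen=True)
class AnnealingSchedule:
    """Geometric decay of the niching radius with a floor after 20 cycles."""

    r0: float
    decay: float = RCUT_DECAY
    floor_cycle: int = RCUT_FLOOR_CYCLE


def rcut_at(schedule: AnnealingSchedule, cycle: int) -> float:
    """Niching radius at a cycle: ``r0 * decay**min(cycle, floor_cycle)``."""
    if cycle < 0:
        raise ValueError("cycle must be >= 0")
    return schedule.r0 * schedule.decay ** min(cycle, schedule.floor_cycle)


@dataclass(frozen=True)
class RunConfig:
    n_bank: int = 60
    n_seeds_per_batch: int = 6
    n_cycles: int = 50
    max_trials_per_source: int = 60
    fragment_sample: int = 100
    rng_seed: int = 0
    min_frag_heavy: int = 3
    attempt_factor: int = 1

    def __post_init__(self) -> None:
        for name in ("n_bank", "n_seeds_per_batch", "n_cycles",
                     "max_trials_per_source", "fragment_sample"):
            if getattr(self, name) < (0 if name == "n_cycles" else 1):
                raise ValueError(f"{name} must be positive")


def init_bank(pool: list[Molecule], objective: Objective, n: int) -> Bank:
    """The ``n`` pool molecules with the best (lowest) objective values.

    The pool must be deduplicated by canonical SMILES; ties in value are
    broken lexicographically on SMILES so initialization is deterministic.
    """
    smiles = [m.smiles for m in pool]
    if len(set(smiles)) != len(smiles):
        raise ValueError("pool contains duplicate canonical SMILES")
    if len(pool) < n:
        raise ValueError(f"pool size {len(pool)} < bank size {n}")
    scored = sorted(
        ((objective.evaluate(m), m.smiles, m) for m in pool),
        key=lambda t: (t[0], t[1]),
    )
    return Bank([BankEntry(mol=m, value=v) for v, _, m in scored[:n]])


def initial_rcut(bank: Bank) -> float:
    """Half the mean pairwise distance among the initial bank molecules."""
    return pairwise_mean_distance(bank.molecules()) / 2.0


def select_seeds(bank: Bank, k: int, rng: np.random.Generator) -> list[BankEntry]:
    """Draw up to ``k`` distinct not-yet-used entries uniformly; mark them used."""
    unused = [i for i, e in enumerate(bank.entries) if not e.used_as_seed]
    if not unused:
        raise RuntimeError("all bank entries used as seeds; reset flags first")
    chosen = rng.choice(len(unused), size=min(k, len(unused)), replace=False)
    picked = [bank.entries[unused[i]] for i in sorted(chosen)]
    for e in picked:
        e.used_as_seed = True
    return picked


@dataclass(frozen=True)
class UpdateOutcome:
    kind: str  # replaced_nearest | replaced_worst | discarded
    replaced: BankEntry | None = None


def update_bank(bank: Bank, trial: Molecule, trial_value: float, rcut: float) -> UpdateOutcome:
    """Offer one trial to the bank under the niching rule.

    * trial duplicates a bank SMILES -> discarded;
    * nearest bank member within ``rcut`` -> replace it iff the trial value
      is strictly better, else discard;
    * nearest member farther than ``rcut`` -> replace the worst-valued
      member iff the trial improves on it, else discard.

    Nearest-entry ties break toward the better-valued entry, then
    lexicographic SMILES; the replacement entry inherits the used-as-seed
    flag so the within-cycle seed schedule keeps its fixed length.
    """
    if any(e.mol.smiles == trial.smiles for e in bank.entries):
        return UpdateOutcome("discarded")
    dists = bulk_tanimoto_distance(trial, bank.molecules())
    nearest_idx = min(
        range(bank.n),
        key=lambda i: (dists[i], bank.entries[i].value, bank.entries[i].mol.smiles),
    )
    if dists[nearest_idx] <= rcut:
        target = bank.entries[nearest_idx]
        if trial_value < target.value:
            bank.entries[nearest_idx] = BankEntry(trial, trial_value, target.used_as_seed)
            return UpdateOutcome("replaced_nearest", target)
        return UpdateOutcome("discarded")
    worst_idx = max(
        range(bank.n),
        key=lambda i: (bank.entries[i].value, bank.entries[i].mol.smiles),
    )
    target = bank.entries[worst_idx]
    if trial_value < target.value:
        bank.entries[worst_idx] = BankEntry(trial, trial_value, target.used_as_seed)
        return UpdateOutcome("replaced_worst", target)
    return UpdateOutcome("discarded")


@dataclass(frozen=True)
class CycleRecord:
    cycle: int
    rcut: float
    best: float
    mean: float
    worst: float
    n_evaluations: int

    def to_json(self) -> str:
        return json.dumps(self.__dict__)


@dataclass
class History:
    initial_best: float
    initial_rcut: float
    records: list[CycleRecord] = field(default_factory=list)

    @property
    def n_evaluations(self) -> int:
        return self.records[-1].n_evaluations if self.records else 0


def _bank_record(bank: Bank, cycle: int, rcut: float, objective: Objective) -> CycleRecord:
    values = bank.values()
    return CycleRecord(
        cycle=cycle,
        rcut=rcut,
        best=min(values),
        mean=float(np.mean(values)),
        worst=max(values),
        n_evaluations=objective.n_evaluations,
    )


def run(
    config: RunConfig,
    pool: list[Molecule],
    fragment_db: list[Fragment],
    objective: Objective,
    freq_table: FrequencyTable | None = None,
) -> tuple[Bank, History]:
    """Execute a full annealing run; deterministic given ``config.rng_seed``.

    ``pool`` supplies both the initial bank (its best-scoring members) and
    the partner molecules for seed recombination; ``fragment_db`` supplies
    database partner fragments, sampled ``config.fragment_sample`` at a time.
    """
    if not pool or not fragment_db:
        raise ValueError("pool and fragment_db must be non-empty")
    rng = np.random.default_rng(config.rng_seed)
    freq_table = freq_table if freq_table is not None else FrequencyTable.uniform()

    bank = init_bank(pool, objective, config.n_bank)
    initial_bank_mols = bank.molecules()
    schedule = AnnealingSchedule(r0=initial_rcut(bank))
    history = History(initial_best=bank.best().value, initial_rcut=schedule.r0)
    logger.info("initial bank: best=%.4f rcut0=%.4f", history.initial_best, schedule.r0)

    fragment_db = sorted(fragment_db, key=lambda f: (f.core_smiles, f.link_type))

    for cycle in range(config.n_cycles):
        rcut = rcut_at(schedule, cycle)
        # a pass through the bank spans several cycles; once every entry has
        # seeded, flags reset and the pass starts over
        if all(e.used_as_seed for e in bank.entries):
            bank.reset_seed_flags()
        seeds = select_seeds(bank, config.n_seeds_per_batch, rng)
        for seed_entry in seeds:
            trials = _trials_for_seed(
                seed_entry.mol, initial_bank_mols, fragment_db, freq_table, config, rng
            )
            for trial in trials:
                try:
                    value = objective.evaluate(trial)
                except RuntimeError as exc:
                    logger.warning("skipping trial %s: %s", trial.smiles, exc)
                    continue
                update_bank(bank, trial, value, rcut)
        history.records.append(_bank_record(bank, cycle, rcut, objective))

    return bank, history


def _trials_for_seed(
    seed: Molecule,
    initial_bank_mols: list[Molecule],
    fragment_db: list[Fragment],
    freq_table: FrequencyTable,
    config: RunConfig,
    rng: np.random.Generator,
) -> list[Molecule]:
    # source 1: fragments of one randomly chosen initial-bank molecule
    partner = initial_bank_mols[rng.integers(len(initial_bank_mols))]
    trials = generate_trials(
        seed, partner_pool_from_molecule(partner), freq_table,
        config.max_trials_per_source, rng, config.attempt_factor, config.min_frag_heavy,
    )
    # source 2: a random sample of the fragment database
    k = min(config.fragment_sample, len(fragment_db))
    idx = rng.choice(len(fragment_db), size=k, replace=False)
    sample = [fragment_db[i] for i in sorted(idx)]
    trials += generate_trials(
        seed, sample, freq_table,
        config.max_trials_per_source, rng, config.attempt_factor, config.min_frag_heavy,
    )
    return trials
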