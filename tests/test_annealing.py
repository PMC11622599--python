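"""Bank state, annealing schedule, seed cycling, and the update rule."""

import numpy as np
import pytest

from chemsa.annealing import (
    AnnealingSchedule,
    Bank,
    BankEntry,
    RunConfig,
    init_bank,
    initial_rcut,
    rcut_at,
    run,
    select_seeds,
    update_bank,
)
from chemsa.chem_core import canonicalize
from chemsa.objectives import Objective, make_objective

from test_chem_core import vec_molecule


def heavy_atom_objective():
    return Objective("n_heavy", lambda m: float(m.n_heavy))


class TestSchedule:
    def test_starts_at_r0(self):
        s = AnnealingSchedule(r0=0.42)
        assert rcut_at(s, 0) == 0.42

    def test_forty_percent_at_cycle_20(self):
        s = AnnealingSchedule(r0=0.37)
        assert rcut_at(s, 20) / s.r0 == pytest.approx(0.4, abs=1e-14)

    def test_constant_after_floor(self):
        s = AnnealingSchedule(r0=1.0)
        assert rcut_at(s, 35) == rcut_at(s, 20) == rcut_at(s, 50)

    def test_monotone_nonincreasing(self):
        s = AnnealingSchedule(r0=0.5)
        values = [rcut_at(s, c) for c in range(40)]
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_negative_cycle_rejected(self):
        with pytest.raises(ValueError):
            rcut_at(AnnealingSchedule(r0=0.5), -1)


class TestInitBank:
    def test_pool_of_exactly_n(self, pool100):
        bank = init_bank(pool100[:60], heavy_atom_objective(), 60)
        assert {e.mol.smiles for e in bank.entries} == {m.smiles for m in pool100[:60]}

    def test_selects_best_by_sort_oracle(self, pool100):
        obj = heavy_atom_objective()
        bank = init_bank(pool100, obj, 60)
        expected = sorted(pool100, key=lambda m: (float(m.n_heavy), m.smiles))[:60]
        assert [e.mol.smiles for e in bank.entries] == [m.smiles for m in expected]

    def test_duplicates_rejected(self, pool100):
        with pytest.raises(ValueError):
            init_bank(pool100 + [pool100[0]], heavy_atom_objective(), 60)

    def test_undersized_pool_rejected(self, pool100):
        with pytest.raises(ValueError):
            init_bank(pool100[:10], heavy_atom_objective(), 60)


class TestInitialRcut:
    def test_identical_fingerprints_zero(self):
        bank = Bank([BankEntry(vec_molecule([1, 2], f"m{i}"), 0.0) for i in range(4)])
        assert initial_rcut(bank) == 0.0

    def test_constructed_distance_08_gives_04(self):
        # three mutually disjoint fingerprints: every pairwise distance 1.0
        bank = Bank([BankEntry(vec_molecule([i], f"m{i}"), 0.0) for i in range(3)])
        assert initial_rcut(bank) == pytest.approx(0.5)

    def test_realistic_bank_in_sane_range(self, pool100):
        bank = init_bank(pool100, heavy_atom_objective(), 60)
        r0 = initial_rcut(bank)
        assert 0.0 < r0 <= 0.5


class TestSelectSeeds:
    def _bank(self, pool, n=12):
        return Bank([BankEntry(m, float(i)) for i, m in enumerate(pool[:n])])

    def test_fresh_bank_six_distinct_marked(self, pool100, rng):
        bank = self._bank(pool100)
        seeds = select_seeds(bank, 6, rng)
        assert len({e.mol.smiles for e in seeds}) == 6
        assert all(e.used_as_seed for e in seeds)
        assert sum(e.used_as_seed for e in bank.entries) == 6

    def test_clamps_to_remaining(self, pool100, rng):
        bank = self._bank(pool100, n=10)
        select_seeds(bank, 6, rng)
        second = select_seeds(bank, 6, rng)
        assert len(second) == 4
        with pytest.raises(RuntimeError):
            select_seeds(bank, 6, rng)

    def test_reproducible(self, pool100):
        picks = []
        for _ in range(2):
            bank = self._bank(pool100)
            got = select_seeds(bank, 6, np.random.default_rng(99))
            picks.append([e.mol.smiles for e in got])
        assert picks[0] == picks[1]


class TestUpdateBank:
    """Exhaustive truth table over {inside, outside R_cut} x {better, worse}."""

    def _bank(self):
        # two entries with controlled fingerprints; distances to the trial
        # are engineered through shared bit counts
        near = BankEntry(vec_molecule(range(0, 10), "near"), 5.0)
        far = BankEntry(vec_molecule(range(100, 110), "far-and-worst"), 9.0)
        return Bank([near, far])

    def trial(self, bits=range(0, 8)):
        # shares 8 of 10 bits with "near": distance 1 - 8/10 = 0.2
        return vec_molecule(bits, "trial")

    def test_inside_better_replaces_nearest(self):
        bank = self._bank()
        out = update_bank(bank, self.trial(), 4.0, rcut=0.3)
        assert out.kind == "replaced_nearest"
        assert out.replaced.mol.smiles == "near"
        assert sorted(bank.values()) == [4.0, 9.0]

    def test_inside_worse_discarded(self):
        bank = self._bank()
        out = update_bank(bank, self.trial(), 6.0, rcut=0.3)
        assert out.kind == "discarded"
        assert sorted(bank.values()) == [5.0, 9.0]

    def test_outside_better_than_worst_replaces_worst(self):
        bank = self._bank()
        out = update_bank(bank, self.trial(range(200, 210)), 6.0, rcut=0.3)
        assert out.kind == "replaced_worst"
        assert out.replaced.mol.smiles == "far-and-worst"
        assert sorted(bank.values()) == [5.0, 6.0]

    def test_outside_worse_than_worst_discarded(self):
        bank = self._bank()
        out = update_bank(bank, self.trial(range(200, 210)), 11.0, rcut=0.3)
        assert out.kind == "discarded"
        assert sorted(bank.values()) == [5.0, 9.0]

    def test_duplicate_smiles_discarded(self):
        bank = self._bank()
        out = update_bank(bank, vec_molecule(range(50, 60), "near"), -100.0, rcut=0.3)
        assert out.kind == "discarded"

    def test_value_multiset_monotone_over_random_updates(self, rng):
        """Any update leaves the value multiset unchanged or replaces exactly
        one element by a strictly smaller one (10^4 random updates)."""
        entries = [
            BankEntry(vec_molecule(rng.choice(2048, size=30, replace=False), f"m{i}"), float(v))
            for i, v in enumerate(rng.normal(size=20))
        ]
        bank = Bank(entries)
        for step in range(10_000):
            trial = vec_molecule(rng.choice(2048, size=30, replace=False), f"t{step}")
            before = sorted(bank.values())
            out = update_bank(bank, trial, float(rng.normal()), rcut=float(rng.uniform(0, 1)))
            after = sorted(bank.values())
            assert bank.n == 20
            assert len({e.mol.smiles for e in bank.entries}) == 20
            if out.kind == "discarded":
                assert after == before
            else:
                diff_old = [v for v in before if v not in after or after.count(v) < before.count(v)]
                assert sum(before) > sum(after)
        # value statistics never degrade
        assert min(bank.values()) <= min(float(e.value) for e in entries)


class TestRun:
    def test_zero_cycles_returns_initial_bank(self, pool100, fragdb200):
        obj = heavy_atom_objective()
        cfg = RunConfig(n_bank=20, n_cycles=0, rng_seed=3)
        bank, history = run(cfg, pool100, fragdb200, obj)
        expected = init_bank(pool100, heavy_atom_objective(), 20)
        assert [e.mol.smiles for e in bank.entries] == [e.mol.smiles for e in expected.entries]
        assert history.records == []

    def test_history_and_improvement(self, pool100, fragdb200):
        obj = make_objective("simtarget", target_smiles="CC(=O)Nc1ccc(OCC(O)CO)cc1")
        cfg = RunConfig(n_bank=15, n_cycles=4, rng_seed=11)
        bank, history = run(cfg, pool100, fragdb200, obj)
        assert len(history.records) == 4
        bests = [r.best for r in history.records]
        means = [r.mean for r in history.records]
        assert all(a >= b for a, b in zip(bests, bests[1:]))
        assert all(a >= b - 1e-12 for a, b in zip(means, means[1:]))
        assert bank.best().value <= history.initial_best
        assert history.n_evaluations >= cfg.n_bank
        # evaluation counter exposed per cycle, non-decreasing
        counts = [r.n_evaluations for r in history.records]
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_deterministic_given_seed(self, pool100, fragdb200):
        results = []
        for _ in range(2):
            obj = make_objective("simtarget", target_smiles="CC(=O)Nc1ccc(OCC(O)CO)cc1")
            cfg = RunConfig(n_bank=12, n_cycles=2, rng_seed=21)
            bank, history = run(cfg, pool100, fragdb200, obj)
            results.append(
                (
                    [(e.mol.smiles, e.value) for e in bank.entries],
                    [r.to_json() for r in history.records],
                )
            )
        assert results[0] == results[1]

    def test_degenerate_constant_objective_terminates(self, pool100, fragdb200):
        obj = Objective("const", lambda m: 0.0)
        cfg = RunConfig(n_bank=10, n_cycles=1, rng_seed=5)
        bank, history = run(cfg, pool100, fragdb200, obj)
        assert bank.n == 10 and len(history.records) == 1
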