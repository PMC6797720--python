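"""Automaton phases: proliferation, death, invasion, drug, full step."""

import numpy as np
import pytest

import chipca
from chipca import (
    DEAD,
    DRUG,
    EMPTY,
    SPECIES_BASE,
    WALL,
    DrugEvent,
    LatticeState,
    SpeciesSpec,
)

from conftest import flood_growth_oracle, random_blob_mask, simple_state

A = SPECIES_BASE
B = SPECIES_BASE + 1


class TestSeeding:
    def test_single_seed(self, open_mask):
        state = simple_state(open_mask, [(50, 50)])
        assert (state.grid == A).sum() == 1
        assert state.step_index == 0

    def test_seed_on_wall_rejected(self, channel_mask):
        state = LatticeState.from_mask(channel_mask)
        wall = tuple(np.argwhere(~channel_mask.allowed)[0])
        with pytest.raises(chipca.SeedingError, match=str(wall[0])):
            chipca.seed_cells(state, [wall], A)

    def test_seed_on_occupied_rejected(self, open_mask):
        state = simple_state(open_mask, [(50, 50)])
        with pytest.raises(chipca.SeedingError, match="occupied"):
            chipca.seed_cells(state, [(50, 50)], B)

    def test_two_species_at_opposite_inlets(self, channel_mask):
        rows, cols = np.where(channel_mask.allowed)
        left = (rows[cols == cols.min()][0], cols.min())
        right = (rows[cols == cols.max()][0], cols.max())
        state = LatticeState.from_mask(channel_mask)
        chipca.seed_cells(state, [left], A)
        chipca.seed_cells(state, [right], B)
        assert (state.grid == A).sum() == 1
        assert (state.grid == B).sum() == 1


class TestProliferation:
    def test_isolated_cell_yields_four_newborns(self, open_mask):
        state = simple_state(open_mask, [(50, 50)])
        newborn = chipca.proliferate_phase(state, A)
        assert newborn.sum() == 4
        rr, cc = np.where(newborn)
        assert sorted(zip(rr.tolist(), cc.tolist())) == [
            (49, 50), (50, 49), (50, 51), (51, 50)
        ]

    def test_one_pixel_channel_yields_two_newborns(self):
        allowed = np.zeros((5, 9), bool)
        allowed[2, :] = True  # 1-pixel-wide straight channel
        state = simple_state(chipca.DeviceMask(allowed), [(2, 4)])
        newborn = chipca.proliferate_phase(state, A)
        assert newborn.sum() == 2

    @pytest.mark.parametrize("n_steps", [1, 2, 5, 15])
    def test_deathless_growth_matches_flood_oracle(self, n_steps):
        """Occupied set after n deterministic steps equals the independent
        set-based flood oracle and the 2n^2+2n+1 ball count."""
        mask = chipca.DeviceMask(np.ones((2 * n_steps + 3,) * 2, bool))
        center = (n_steps + 1, n_steps + 1)
        state = simple_state(mask, [center])
        rng = np.random.default_rng(0)
        sp = SpeciesSpec(name="a")
        for _ in range(n_steps):
            chipca.step(state, [sp], {"a": A}, [], rng)
        occupied = {tuple(p) for p in np.argwhere(state.grid == A)}
        oracle = flood_growth_oracle(mask.allowed, [center], n_steps)
        assert occupied == set(oracle)
        assert len(occupied) == 2 * n_steps**2 + 2 * n_steps + 1


class TestDeath:
    def test_zero_death_prob_kills_nobody(self, open_mask):
        state = simple_state(open_mask, [(50, 50)])
        newborn = chipca.proliferate_phase(state, A)
        chipca.death_phase(state, newborn, 0.0, np.random.default_rng(0))
        assert (state.grid == DEAD).sum() == 0

    def test_certain_death_caps_live_at_seeds(self, open_mask):
        state = simple_state(open_mask, [(50, 50)])
        sp = SpeciesSpec(name="a", death_prob=1.0)
        rng = np.random.default_rng(0)
        for _ in range(10):
            chipca.step(state, [sp], {"a": A}, [], rng)
        assert (state.grid == A).sum() == 1  # only the seed survives

    def test_death_fraction_matches_binomial(self):
        """Dead fraction of ~10^4 newborns within 3 binomial SEs of P_d."""
        p = 0.3
        mask = chipca.DeviceMask(np.ones((200, 200), bool))
        state = LatticeState.from_mask(mask)
        newborn = np.zeros(mask.shape, bool)
        newborn[::2, ::2] = True  # 10,000 synthetic newborns
        state.grid[newborn] = A
        state.owner[newborn] = A
        chipca.death_phase(state, newborn, p, np.random.default_rng(7))
        n = int(newborn.sum())
        frac = (state.grid == DEAD).sum() / n
        assert abs(frac - p) <= 3 * np.sqrt(p * (1 - p) / n)

    def test_invalid_death_prob_rejected(self, open_mask):
        state = simple_state(open_mask, [(50, 50)])
        newborn = chipca.proliferate_phase(state, A)
        with pytest.raises(chipca.ConfigError):
            chipca.death_phase(state, newborn, 1.3, np.random.default_rng(0))

    def test_dead_pixels_propagate_own_species_only(self):
        """A dead cell keeps its colony's front moving but is a wall to
        other species."""
        allowed = np.zeros((3, 7), bool)
        allowed[1, :] = True
        mask = chipca.DeviceMask(allowed)
        state = simple_state(mask, [(1, 0)], A)
        state.grid[1, 1] = DEAD
        state.owner[1, 1] = A
        newborn = chipca.proliferate_phase(state, A)
        assert newborn[1, 2]  # grows past its own dead cell
        # but species B cannot colonize the dead pixel, ever
        state2 = simple_state(mask, [(1, 3)], B)
        state2.grid[1, 2] = DEAD
        state2.owner[1, 2] = A
        newborn2 = chipca.proliferate_phase(state2, B)
        assert not newborn2[1, 2]
        assert state2.grid[1, 2] == DEAD


class TestInvasion:
    def _two_species(self):
        return (
            [
                SpeciesSpec(name="green", color=(0, 255, 0)),
                SpeciesSpec(
                    name="blue", color=(0, 0, 255), invasive=True
                ),
            ],
            {"green": A, "blue": B},
        )

    def test_adjacent_cell_converts(self, open_mask):
        species, codes = self._two_species()
        state = simple_state(open_mask, [(50, 50)], A)
        chipca.seed_cells(state, [(50, 51)], B)
        chipca.invasion_phase(state, species, codes, np.random.default_rng(0))
        assert state.grid[50, 50] == B

    def test_isolated_cell_unchanged(self, open_mask):
        species, codes = self._two_species()
        state = simple_state(open_mask, [(50, 50)], A)
        chipca.seed_cells(state, [(60, 60)], B)
        chipca.invasion_phase(state, species, codes, np.random.default_rng(0))
        assert state.grid[50, 50] == A

    @pytest.mark.parametrize("k", [1, 3, 7])
    def test_chain_converts_one_link_per_step(self, k):
        """Synchronous snapshot semantics: the j-th cell of a chain
        converts exactly at step j."""
        species, codes = self._two_species()
        allowed = np.zeros((3, k + 3), bool)
        allowed[1, :] = True
        mask = chipca.DeviceMask(allowed)
        state = LatticeState.from_mask(mask)
        chipca.seed_cells(state, [(1, j) for j in range(1, k + 1)], A)
        chipca.seed_cells(state, [(1, 0)], B)
        rng = np.random.default_rng(0)
        for step_j in range(1, k + 1):
            chipca.invasion_phase(state, species, codes, rng)
            converted = (state.grid == B).sum() - 1
            assert converted == step_j

    def test_invasive_never_converts_invasive(self, open_mask):
        species = [
            SpeciesSpec(name="u", color=(0, 0, 255), invasive=True),
            SpeciesSpec(name="v", color=(255, 255, 0), invasive=True),
        ]
        codes = {"u": A, "v": B}
        state = simple_state(open_mask, [(50, 50)], A)
        chipca.seed_cells(state, [(50, 51)], B)
        chipca.invasion_phase(state, species, codes, np.random.default_rng(0))
        assert state.grid[50, 50] == A
        assert state.grid[50, 51] == B


class TestDrug:
    def _species(self):
        return (
            [
                SpeciesSpec(name="safe", color=(0, 255, 0)),
                SpeciesSpec(
                    name="target", color=(0, 0, 255), drug_sensitive=True
                ),
            ],
            {"safe": A, "target": B},
        )

    def test_diffusion_is_clipped_von_neumann_ball(self, channel_mask):
        """Drug spread after n firings equals the flood oracle's radius-n
        ball clipped to the mask."""
        species, codes = self._species()
        rows, cols = np.where(channel_mask.allowed)
        src = (int(np.median(rows[cols == cols[len(cols) // 2]])),
               int(cols[len(cols) // 2]))
        state = LatticeState.from_mask(channel_mask)
        event = DrugEvent(activation_step=1, sources=(src,), target="")
        rng = np.random.default_rng(0)
        n = 12
        for _ in range(n):
            chipca.step(state, species, codes, [event], rng)
        drug = {tuple(p) for p in np.argwhere(state.grid == DRUG)}
        oracle = flood_growth_oracle(channel_mask.allowed, [src], n - 1)
        assert drug == set(oracle)

    def test_non_sensitive_species_never_affected(self, open_mask):
        species, codes = self._species()
        state = simple_state(open_mask, [(50, 49)], A)  # "safe", period 1
        event = DrugEvent(activation_step=1, sources=((50, 50),), target="safe")
        rng = np.random.default_rng(0)
        sp_frozen = [SpeciesSpec(name="safe", color=(0, 255, 0), period=10**6),
                     species[1]]
        for _ in range(5):
            chipca.step(state, sp_frozen, codes, [event], rng)
        assert state.grid[50, 49] == A  # safe is not drug_sensitive

    def test_sensitive_cell_converts_on_next_drug_phase(self, open_mask):
        species, codes = self._species()
        state = simple_state(open_mask, [(50, 49)], B)
        sp_frozen = [species[0],
                     SpeciesSpec(name="target", color=(0, 0, 255),
                                 drug_sensitive=True, period=10**6)]
        event = DrugEvent(activation_step=1, sources=((50, 50),),
                          target="target")
        chipca.step(state, sp_frozen, codes, [event],
                    np.random.default_rng(0))
        assert state.grid[50, 49] == DRUG  # affected at the activation step
        assert state.owner[50, 49] == B  # still attributed to the species

    def test_affected_cells_do_not_proliferate(self, open_mask):
        """A drug-affected cell is sterile: it no longer spawns newborns."""
        state = LatticeState.from_mask(open_mask)
        state.grid[50, 50] = DRUG
        state.owner[50, 50] = B  # an affected cell of the target species
        newborn = chipca.proliferate_phase(state, B)
        assert newborn.sum() == 0


class TestStep:
    def test_idle_step_only_increments_counter(self, open_mask):
        state = simple_state(open_mask, [(50, 50)])
        sp = SpeciesSpec(name="a", period=10**6)
        before = state.grid.copy()
        chipca.step(state, [sp], {"a": A}, [], np.random.default_rng(0))
        assert np.array_equal(state.grid, before)
        assert state.step_index == 1

    def test_identical_seeds_give_bit_identical_runs(self, channel_mask):
        species = [
            SpeciesSpec(name="a", death_prob=0.3),
            SpeciesSpec(name="b", color=(0, 0, 255), death_prob=0.3),
        ]
        codes = {"a": A, "b": B}
        seed_px = tuple(np.argwhere(channel_mask.allowed)[0])
        seed_px2 = tuple(np.argwhere(channel_mask.allowed)[-1])
        grids = []
        for _ in range(2):
            state = LatticeState.from_mask(channel_mask)
            chipca.seed_cells(state, [seed_px], A)
            chipca.seed_cells(state, [seed_px2], B)
            rng = np.random.default_rng(123)
            history = []
            for _ in range(30):
                chipca.step(state, species, codes, [], rng)
                history.append(state.grid.copy())
            grids.append(history)
        for g1, g2 in zip(*grids):
            assert np.array_equal(g1, g2)

    @pytest.mark.parametrize("seed", range(4))
    def test_occupation_time_equals_bfs_distance(self, seed):
        """Deterministic period-1 growth colonizes every reachable pixel
        exactly at its 4-connected geodesic distance from the seed."""
        mask = random_blob_mask(np.random.default_rng(seed), shape=(40, 40))
        labels, sizes = chipca.connected_components(mask)
        comp = int(np.argmax(sizes)) + 1
        start = tuple(np.argwhere(labels == comp)[0])
        oracle = flood_growth_oracle(mask.allowed, [start], 10**6)
        state = simple_state(mask, [start])
        sp = SpeciesSpec(name="a")
        rng = np.random.default_rng(0)
        first_seen = {start: 0}
        horizon = max(oracle.values())
        for t in range(1, horizon + 1):
            chipca.step(state, [sp], {"a": A}, [], rng)
            for p in map(tuple, np.argwhere(state.grid == A)):
                first_seen.setdefault(p, t)
        assert first_seen == oracle

    def test_same_step_conflicts_resolved_one_winner(self, open_mask):
        """Two species claiming one pixel: exactly one wins, chosen from
        the RNG stream."""
        state = simple_state(open_mask, [(50, 49)], A)
        chipca.seed_cells(state, [(50, 51)], B)
        species = [
            SpeciesSpec(name="a"),
            SpeciesSpec(name="b", color=(0, 0, 255)),
        ]
        wins = set()
        for seed in range(20):
            s = state.copy()
            chipca.step(s, species, {"a": A, "b": B}, [],
                        np.random.default_rng(seed))
            winner = int(s.grid[50, 50])
            assert winner in (A, B)
            wins.add(winner)
        assert wins == {A, B}  # both outcomes occur across seeds


class TestInvariants:
    """Structural invariants checked along a full stochastic trajectory."""

    @pytest.fixture()
    def trajectory(self, channel_mask):
        species = [
            SpeciesSpec(name="healthy", death_prob=0.3),
            SpeciesSpec(name="invader", color=(0, 0, 255), death_prob=0.3,
                        invasive=True, drug_sensitive=True),
        ]
        codes = {"healthy": A, "invader": B}
        rows, cols = np.where(channel_mask.allowed)
        left = (int(rows[cols == cols.min()][0]), int(cols.min()))
        right = (int(rows[cols == cols.max()][0]), int(cols.max()))
        mid = (left[0], (left[1] + right[1]) // 2)
        event = DrugEvent(activation_step=25, sources=(mid,),
                          target="invader")
        state = LatticeState.from_mask(channel_mask)
        chipca.seed_cells(state, [left], A)
        chipca.seed_cells(state, [right], B)
        rng = np.random.default_rng(99)
        states = [state.copy()]
        for _ in range(60):
            chipca.step(state, species, codes, [event], rng)
            states.append(state.copy())
        return channel_mask, states

    def test_wall_set_is_immutable(self, trajectory):
        mask, states = trajectory
        for s in states:
            assert np.array_equal(s.grid == WALL, ~mask.allowed)

    def test_occupancy_is_monotone(self, trajectory):
        _, states = trajectory
        prev = None
        for s in states:
            occ = s.grid != EMPTY
            if prev is not None:
                assert (occ | prev == occ).all()  # empties never reappear
            prev = occ

    def test_dead_and_drug_are_absorbing(self, trajectory):
        _, states = trajectory
        for s0, s1 in zip(states, states[1:]):
            for code in (DEAD, DRUG):
                was = s0.grid == code
                # DRUG-affected stays DRUG; DEAD stays DEAD
                assert (s1.grid[was] == s0.grid[was]).all()

    def test_counts_conserve_grid_size(self, trajectory):
        _, states = trajectory
        for s in states:
            assert sum(chipca.count_states(s).values()) == s.grid.size
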