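"""The bounded-lattice cellular automaton.

Each pixel of the device mask holds one state code: wall, empty, a live
cell of some species, a dead cell, or drug.  A global step applies, in
order: proliferation (with newborn mortality) for every species whose
schedule fires, invasion, then drug diffusion/interaction.  All phase
decisions are computed synchronously from a pre-phase snapshot.

Growth follows the von Neumann (4-neighbor) rule: every empty allowed
pixel orthogonally adjacent to a colony becomes a newborn, so an isolated
seed in an open region grows as the von Neumann ball and the population
obeys y_n = y_{n-1} + 4n.  Each newborn independently dies with the
species' death probability P_d, giving the expected population

    y_n = y_0 + sum_{k=1..n} 4k (1 - P_d)  =  y_0 + 2n(n+1)(1 - P_d)

for an unobstructed single seed.  Dead pixels are absorbing: they occupy
their pixel forever and are never re-colonized by any species or by the
drug, but they still mark their own species' colony for proliferation
adjacency — this keeps the growth ring geometry intact and the expected
count law above exact, at the price that a dead cell does not wall off its
own kind (it does wall off other species and the drug).

Cell migration is deliberately absent: the model targets adherent lines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EMPTY",
    "WALL",
    "DEAD",
    "DRUG",
    "SPECIES_BASE",
    "RESERVED_COLORS",
    "DEFAULT_PALETTE",
    "SpeciesSpec",
    "DrugEvent",
    "LatticeState",
    "SeedingError",
    "ConfigError",
    "seed_cells",
    "proliferate_phase",
    "death_phase",
    "invasion_phase",
    "drug_phase",
    "step",
    "count_states",
    "vn_any",
]

# reserved state codes; species are assigned SPECIES_BASE, SPECIES_BASE+1, ...
EMPTY = 0
WALL = 1
DEAD = 2
DRUG = 3  # one shared code for drug-occupied pixels and drug-affected cells
SPECIES_BASE = 4

#: default rendering palette for the reserved codes (RGB)
DEFAULT_PALETTE = {
    EMPTY: (255, 255, 255),
    WALL: (0, 0, 0),
    DEAD: (255, 0, 0),
    DRUG: (255, 105, 180),
}
RESERVED_COLORS = frozenset(DEFAULT_PALETTE.values())


class SeedingError(ValueError):
    """A seed position is on a wall or an occupied pixel."""


class ConfigError(ValueError):
    """Invalid species / drug-event parameters."""


@dataclass(frozen=True)
class SpeciesSpec:
    """One cell type.

    Parameters
    ----------
    name : str
    color : RGB triple for rendering (must not clash with the reserved
        white/black/red/pink palette).
    death_prob : float in [0, 1]
        Per-newborn probability of immediate death (the P_d of the growth
        law; each newborn draws once, at birth; seeded cells never draw).
    period : int >= 1
        Fire proliferation every `period` global steps.  Ignored when
        `firing_steps` is given.
    firing_steps : explicit set of global step numbers (1-based) at which
        this species proliferates; produced from a calibrated schedule.
    invasive : bool
        Invasive cells convert adjacent non-invasive live cells to their
        own type.
    drug_sensitive : bool
        Whether a drug event targeting this species affects it.
    conversion_prob : float in [0, 1]
        Per-contact probability that an invasive neighbor converts a cell
        (1.0 = the deterministic adjacency rule).
    """

    name: str
    color: tuple[int, int, int] = (0, 255, 0)
    death_prob: float = 0.0
    period: int = 1
    firing_steps: frozenset[int] | None = None
    invasive: bool = False
    drug_sensitive: bool = False
    conversion_prob: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.death_prob <= 1.0:
            raise ConfigError(
                f"species {self.name!r}: death_prob must be in [0, 1], "
                f"got {self.death_prob}"
            )
        if not 0.0 <= self.conversion_prob <= 1.0:
            raise ConfigError(
                f"species {self.name!r}: conversion_prob must be in [0, 1]"
            )
        if self.firing_steps is None and self.period < 1:
            raise ConfigError(f"species {self.name!r}: period must be >= 1")
        color = tuple(int(c) for c in self.color)
        if color in RESERVED_COLORS:
            raise ConfigError(
                f"species {self.name!r}: color {color} collides with the "
                "reserved white/black/red/pink palette"
            )
        object.__setattr__(self, "color", color)
        if self.firing_steps is not None:
            object.__setattr__(
                self, "firing_steps", frozenset(int(s) for s in self.firing_steps)
            )

    def fires_at(self, t: int) -> bool:
        """Whether proliferation fires on global step ``t`` (1-based)."""
        if self.firing_steps is not None:
            return t in self.firing_steps
        return t % self.period == 0


@dataclass(frozen=True)
class DrugEvent:
    """Timed introduction of a diffusing agent targeting one species.

    The drug occupies its source pixels at ``activation_step``, then on
    every subsequent step where ``(step - activation_step)`` is a multiple
    of ``diffusion_period`` spreads into empty allowed pixels adjacent to
    the drug front.  On every active step, live cells of the target
    species adjacent to drug become drug-affected: absorbing and
    non-proliferating.  Other species are never touched.
    """

    activation_step: int
    sources: tuple[tuple[int, int], ...]
    diffusion_period: int = 1
    target: str = ""

    def __post_init__(self) -> None:
        if self.activation_step < 0:
            raise ConfigError("activation_step must be >= 0")
        if self.diffusion_period < 1:
            raise ConfigError("diffusion_period must be >= 1")
        object.__setattr__(
            self, "sources", tuple((int(r), int(c)) for r, c in self.sources)
        )


@dataclass
class LatticeState:
    """The per-pixel state grid plus the step counter.

    ``grid`` holds the public state codes.  ``owner`` remembers, for every
    pixel ever occupied by a species (live, dead or drug-affected), which
    species it belongs(ed) to; walls and plain drug pixels have owner 0.
    """

    grid: np.ndarray
    owner: np.ndarray
    allowed: np.ndarray
    step_index: int = 0
    newborns: dict[int, np.ndarray] = field(default_factory=dict)

    @classmethod
    def from_mask(cls, mask) -> "LatticeState":
        allowed = np.asarray(mask.allowed, dtype=bool)
        grid = np.where(allowed, EMPTY, WALL).astype(np.int16)
        owner = np.zeros_like(grid)
        return cls(grid=grid, owner=owner, allowed=allowed)

    def copy(self) -> "LatticeState":
        return LatticeState(
            grid=self.grid.copy(),
            owner=self.owner.copy(),
            allowed=self.allowed,
            step_index=self.step_index,
            newborns={k: v.copy() for k, v in self.newborns.items()},
        )


def vn_any(b: np.ndarray) -> np.ndarray:
    """True where >= 1 von Neumann (4-)neighbor of ``b`` is True."""
    out = np.zeros_like(b)
    out[1:, :] |= b[:-1, :]
    out[:-1, :] |= b[1:, :]
    out[:, 1:] |= b[:, :-1]
    out[:, :-1] |= b[:, 1:]
    return out


def seed_cells(
    state: LatticeState, positions, species_code: int
) -> LatticeState:
    """Place live cells of one species; every target pixel must be an
    empty allowed pixel.  Seeded cells are exempt from the death lottery
    (they are the y_0 of the growth law)."""
    for r, c in positions:
        r, c = int(r), int(c)
        if not (0 <= r < state.grid.shape[0] and 0 <= c < state.grid.shape[1]):
            raise SeedingError(f"seed ({r}, {c}) outside the lattice")
        if not state.allowed[r, c]:
            raise SeedingError(f"seed ({r}, {c}) is on a wall pixel")
        if state.grid[r, c] != EMPTY:
            raise SeedingError(f"seed ({r}, {c}) is already occupied")
        state.grid[r, c] = species_code
        state.owner[r, c] = species_code
    return state


def _colony(state_grid, state_owner, code: int) -> np.ndarray:
    """Pixels that propagate species ``code``: its live cells plus its
    dead cells (drug-affected cells do not proliferate)."""
    return (state_owner == code) & (
        (state_grid == code) | (state_grid == DEAD)
    )


def proliferate_phase(state: LatticeState, species_code: int) -> np.ndarray:
    """Synchronous growth of one species from the pre-phase snapshot.

    Every empty allowed pixel with >= 1 von Neumann neighbor in the
    species' colony becomes a newborn.  Returns the boolean newborn grid
    (also recorded in ``state.newborns``).
    """
    colony = _colony(state.grid, state.owner, species_code)
    newborn = (state.grid == EMPTY) & vn_any(colony)
    state.grid[newborn] = species_code
    state.owner[newborn] = species_code
    state.newborns[species_code] = newborn
    return newborn


def death_phase(
    state: LatticeState,
    newborn: np.ndarray,
    death_prob: float,
    rng: np.random.Generator,
) -> LatticeState:
    """Each newborn independently dies with probability ``death_prob``.

    Dead pixels turn to the absorbing DEAD code but keep their owner, so
    the colony's growth ring is unaffected.  Draws consume the run RNG in
    row-major order over the newborn set.
    """
    if not 0.0 <= death_prob <= 1.0:
        raise ConfigError(f"death_prob must be in [0, 1], got {death_prob}")
    coords = np.argwhere(newborn)  # row-major
    if len(coords) == 0 or death_prob == 0.0:
        return state
    dies = rng.random(len(coords)) < death_prob
    dead = coords[dies]
    state.grid[dead[:, 0], dead[:, 1]] = DEAD
    return state


def invasion_phase(
    state: LatticeState,
    species: list[SpeciesSpec],
    codes: dict[str, int],
    rng: np.random.Generator | None = None,
) -> LatticeState:
    """Convert non-invasive live cells adjacent to invasive cells.

    Synchronous: decisions use the pre-phase snapshot, so a chain of
    cells converts one link per step.  A cell adjacent to several invasive
    species goes to one of them uniformly at random; a conversion
    probability < 1 makes each contact stochastic.
    """
    invasive = [sp for sp in species if sp.invasive]
    if not invasive:
        return state
    snap = state.grid.copy()
    non_inv_codes = [
        codes[sp.name] for sp in species if not sp.invasive
    ]
    if not non_inv_codes:
        return state
    convertible = np.isin(snap, non_inv_codes)
    claims = []  # (species, code, claim grid)
    for sp in invasive:
        code = codes[sp.name]
        claim = convertible & vn_any(snap == code)
        claims.append((sp, code, claim))
    n_claims = np.sum([c for _, _, c in claims], axis=0)
    # unambiguous conversions first, then random tie-breaks, then the
    # optional per-conversion probability draw (row-major RNG order)
    target = np.zeros_like(snap)
    prob = np.zeros(snap.shape)
    for sp, code, claim in claims:
        sole = claim & (n_claims == 1)
        target[sole] = code
        prob[sole] = sp.conversion_prob
    conflict = np.argwhere(n_claims > 1)
    for r, c in conflict:
        claimants = [(sp, code) for sp, code, cl in claims if cl[r, c]]
        if rng is None:
            raise ConfigError("rng required to break invasion ties")
        sp, code = claimants[rng.integers(len(claimants))]
        target[r, c] = code
        prob[r, c] = sp.conversion_prob
    coords = np.argwhere(target > 0)
    for r, c in coords:
        p = prob[r, c]
        if p >= 1.0 or (rng is not None and rng.random() < p):
            state.grid[r, c] = target[r, c]
            state.owner[r, c] = target[r, c]
    return state


def drug_phase(
    state: LatticeState,
    event: DrugEvent,
    target_code: int | None,
    t: int,
) -> LatticeState:
    """One drug step at global step ``t`` (>= activation).

    Diffusion (into empty allowed pixels adjacent to the drug front)
    happens at activation and on every step where the offset from
    activation is a multiple of the diffusion period; the interaction with
    the target species happens on every active step.
    """
    if t < event.activation_step:
        return state
    if t == max(1, event.activation_step):  # steps are 1-based
        for r, c in event.sources:
            # injection occupies empty pixels and hits target cells directly
            if state.grid[r, c] == EMPTY or (
                target_code is not None and state.grid[r, c] == target_code
            ):
                state.grid[r, c] = DRUG
    elif (t - event.activation_step) % event.diffusion_period == 0:
        front = state.grid == DRUG
        spread = (state.grid == EMPTY) & vn_any(front)
        state.grid[spread] = DRUG
    if target_code is not None:
        affected = (state.grid == target_code) & vn_any(state.grid == DRUG)
        state.grid[affected] = DRUG  # owner kept: these are affected cells
    return state


def step(
    state: LatticeState,
    species: list[SpeciesSpec],
    codes: dict[str, int],
    events: list[DrugEvent],
    rng: np.random.Generator,
) -> LatticeState:
    """Advance the lattice by one global step.

    Order within the step: proliferation + newborn death for every species
    whose schedule fires (claims computed from one shared snapshot;
    same-pixel conflicts between species resolved uniformly at random),
    then invasion, then each drug event.  Fully deterministic given the
    RNG stream.
    """
    t = state.step_index + 1
    state.newborns = {}
    firing = [sp for sp in species if sp.fires_at(t)]
    if firing:
        snap_grid = state.grid.copy()
        snap_owner = state.owner.copy()
        empty = snap_grid == EMPTY
        claims = []
        for sp in firing:
            code = codes[sp.name]
            colony = _colony(snap_grid, snap_owner, code)
            claims.append((sp, code, empty & vn_any(colony)))
        n_claims = np.sum([c for _, _, c in claims], axis=0)
        winner = np.zeros_like(snap_grid)
        for sp, code, claim in claims:
            winner[claim & (n_claims == 1)] = code
        for r, c in np.argwhere(n_claims > 1):  # row-major tie-breaks
            claimants = [code for _, code, cl in claims if cl[r, c]]
            winner[r, c] = claimants[rng.integers(len(claimants))]
        for sp, code, _ in claims:
            newborn = winner == code
            state.grid[newborn] = code
            state.owner[newborn] = code
            state.newborns[code] = newborn
        for sp, code, _ in claims:  # death after all births, species order
            death_phase(state, state.newborns[code], sp.death_prob, rng)
    invasion_phase(state, species, codes, rng)
    for event in events:
        target_code = codes.get(event.target)
        tc = target_code if (
            event.target and _sensitive(species, event.target)
        ) else None
        drug_phase(state, event, tc, t)
    state.step_index = t
    return state


def _sensitive(species: list[SpeciesSpec], name: str) -> bool:
    for sp in species:
        if sp.name == name:
            return sp.drug_sensitive
    return False


def count_states(state: LatticeState) -> dict[int, int]:
    """Pixel count per state code; counts sum to the grid size."""
    codes, counts = np.unique(state.grid, return_counts=True)
    return {int(k): int(v) for k, v in zip(codes, counts)}
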