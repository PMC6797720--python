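"""Shared fixtures and independent oracles.

The oracles here are deliberately naive pure-Python implementations
(set-based flood fills, per-pixel geometry scans) kept independent of the
package's vectorized code paths.
"""

from __future__ import annotations

import numpy as np
import pytest

import chipca


def flood_growth_oracle(allowed: np.ndarray, seeds, n_steps: int):
    """Synchronous set-based growth: every empty allowed pixel adjacent to
    the colony joins it each step.  Returns dict pixel -> occupation step
    (seeds at 0)."""
    occupied = {tuple(p): 0 for p in seeds}
    frontier = set(occupied)
    n_rows, n_cols = allowed.shape
    for t in range(1, n_steps + 1):
        nxt = set()
        for r, c in frontier:
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if (
                    0 <= rr < n_rows
                    and 0 <= cc < n_cols
                    and allowed[rr, cc]
                    and (rr, cc) not in occupied
                ):
                    nxt.add((rr, cc))
        for p in nxt:
            occupied[p] = t
        frontier = nxt
        if not frontier:
            break
    return occupied


def bfs_components_oracle(allowed: np.ndarray):
    """4-connected component labels by plain BFS; labels start at 1."""
    labels = np.zeros(allowed.shape, dtype=int)
    current = 0
    for r0 in range(allowed.shape[0]):
        for c0 in range(allowed.shape[1]):
            if allowed[r0, c0] and labels[r0, c0] == 0:
                current += 1
                queue = [(r0, c0)]
                labels[r0, c0] = current
                while queue:
                    r, c = queue.pop()
                    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                        rr, cc = r + dr, c + dc
                        if (
                            0 <= rr < allowed.shape[0]
                            and 0 <= cc < allowed.shape[1]
                            and allowed[rr, cc]
                            and labels[rr, cc] == 0
                        ):
                            labels[rr, cc] = current
                            queue.append((rr, cc))
    return labels, current


def random_blob_mask(rng: np.random.Generator, shape=(60, 60), p=0.55):
    """Random boolean mask guaranteed to contain at least one allowed pixel."""
    allowed = rng.random(shape) < p
    if not allowed.any():
        allowed[shape[0] // 2, shape[1] // 2] = True
    return chipca.DeviceMask(allowed=allowed)


@pytest.fixture
def open_mask():
    """A 101x101 fully allowed lattice (open region, no walls)."""
    return chipca.DeviceMask(allowed=np.ones((101, 101), dtype=bool))


@pytest.fixture
def channel_spec():
    """Desk-scale straight-channel device spec."""
    return chipca.DeviceSpec(
        kind="single_channel",
        well_radius_um=400,
        channel_width_um=200,
        channel_length_um=1600,
        margin_um=40,
    )


@pytest.fixture
def channel_mask(channel_spec):
    return chipca.make_device(channel_spec)


def simple_state(mask, seeds, code=chipca.SPECIES_BASE):
    state = chipca.LatticeState.from_mask(mask)
    chipca.seed_cells(state, seeds, code)
    return state
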