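"""Run orchestration: seeded execution, per-step summaries, frames, demos."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import __version__
from .automaton import (
    DEAD,
    DEFAULT_PALETTE,
    DRUG,
    EMPTY,
    SPECIES_BASE,
    WALL,
    LatticeState,
    count_states,
    seed_cells,
    step,
)
from .config import SimulationConfig, schedule_firing_steps
from .masks import DeviceSpec, device_shapes, make_device
from .calibration import preset_schedule

__all__ = [
    "RunSummary",
    "RenderingError",
    "run_simulation",
    "render_frame",
    "demo_configs",
    "species_codes",
]

log = logging.getLogger("chipca")


class RenderingError(KeyError):
    """A lattice code present in the grid has no palette entry."""


@dataclass
class RunSummary:
    """Per-step state-code counts plus provenance.

    ``counts`` has one row per step 0..total_steps with columns
    ``step, empty, wall, dead, drug, <species...>`` (species in
    registration order); every row sums to the grid size.
    """

    counts: pd.DataFrame
    config_hash: str
    rng_seed: int
    version: str = __version__
    final_state: LatticeState | None = field(default=None, repr=False)

    def to_csv(self, path) -> None:
        self.counts.to_csv(path, index=False)


def species_codes(config: SimulationConfig) -> dict[str, int]:
    """Lattice codes assigned to the config's species, registration order."""
    return {
        sp.name: SPECIES_BASE + i for i, sp in enumerate(config.species)
    }


def _counts_row(state: LatticeState, codes: dict[str, int]) -> list[int]:
    tally = count_states(state)
    row = [state.step_index]
    for code in (EMPTY, WALL, DEAD, DRUG):
        row.append(tally.get(code, 0))
    for code in codes.values():
        row.append(tally.get(code, 0))
    return row


def run_simulation(
    config: SimulationConfig,
    out_dir=None,
    frames_every: int | None = None,
) -> RunSummary:
    """Execute a configured run and return its :class:`RunSummary`.

    Deterministic under ``config.rng_seed``.  When ``out_dir`` is given,
    writes ``counts.csv``, ``final.png``, ``final_state.csv`` (the raw
    integer grid), ``run.log`` and — when a frame stride is set — one
    ``frame_%06d.png`` per matching step.
    """
    mask = config.build_mask()
    codes = species_codes(config)
    state = LatticeState.from_mask(mask)
    for name, positions in config.seeds.items():
        seed_cells(state, positions, codes[name])

    out_path: Path | None = None
    handler = None
    if out_dir is not None:
        out_path = Path(out_dir)
        out_path.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(out_path / "run.log")
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(levelname)s %(message)s")
        )
        log.addHandler(handler)
        log.setLevel(logging.INFO)

    stride = frames_every if frames_every is not None else config.frames_every
    palette = dict(DEFAULT_PALETTE)
    for sp, code in zip(config.species, codes.values()):
        palette[code] = sp.color

    rng = np.random.default_rng(config.rng_seed)
    rows = [_counts_row(state, codes)]
    try:
        log.info(
            "run start: %d species, %d steps, seed %d, grid %dx%d",
            len(config.species), config.total_steps, config.rng_seed,
            *state.grid.shape,
        )
        if out_path and stride:
            render_frame(state, palette).save(out_path / "frame_000000.png")
        for _ in range(config.total_steps):
            step(state, list(config.species), codes, list(config.drugs), rng)
            rows.append(_counts_row(state, codes))
            if out_path and stride and state.step_index % stride == 0:
                render_frame(state, palette).save(
                    out_path / f"frame_{state.step_index:06d}.png"
                )
        columns = ["step", "empty", "wall", "dead", "drug", *codes]
        counts = pd.DataFrame(rows, columns=columns)
        summary = RunSummary(
            counts=counts,
            config_hash=config.config_hash(),
            rng_seed=config.rng_seed,
            final_state=state,
        )
        if out_path is not None:
            summary.to_csv(out_path / "counts.csv")
            render_frame(state, palette).save(out_path / "final.png")
            np.savetxt(out_path / "final_state.csv", state.grid, "%d", ",")
            log.info("run done: final counts %s", rows[-1][1:])
        return summary
    except OSError as exc:
        raise OSError(f"cannot write run output under {out_path}: {exc}") from exc
    finally:
        if handler is not None:
            log.removeHandler(handler)
            handler.close()


def render_frame(
    state: LatticeState, palette: dict[int, tuple[int, int, int]]
) -> Image.Image:
    """Pixel-for-pixel RGB image of the lattice in the palette's colors."""
    present = np.unique(state.grid)
    missing = [int(c) for c in present if int(c) not in palette]
    if missing:
        raise RenderingError(
            f"palette has no entry for lattice code(s) {missing}"
        )
    lut = np.zeros((int(present.max()) + 1, 3), dtype=np.uint8)
    for code, rgb in palette.items():
        if code <= present.max():
            lut[code] = rgb
    return Image.fromarray(lut[state.grid], mode="RGB")


# --------------------------------------------------------------------------
# packaged demo scenarios (desk scale)


def _disc_center_px(spec: DeviceSpec, index: int) -> tuple[int, int]:
    """Pixel coordinates of the center of the index-th disc shape."""
    shapes, _, _ = device_shapes(spec)
    discs = [sh for sh in shapes if hasattr(sh, "r")]
    d = discs[index]
    return int(d.cy / spec.pixel_size_um), int(d.cx / spec.pixel_size_um)


def demo_configs() -> dict[str, SimulationConfig]:
    """Ready-to-run demo scenarios mirroring the classic chip experiments:

    - ``single-channel-two-species``: two lines seeded at opposite inlets
      of a straight-channel device, growing to meet mid-channel.
    - ``single-channel-drug``: healthy + invasive lines, then a drug added
      mid-channel that interacts only with the invasive line.
    - ``radial``: three lines seeded in radially placed inlet wells,
      proliferating along the channels into the central chamber.
    - ``multi-chamber-metastasis``: invasive spread through a
      multi-chamber device, countered by a drug event.
    - ``calibrated-lines``: an 11-day N2A vs MC3T3 run driven by the
      calibrated preset schedules at 4 steps per culture day.
    """
    cfgs: dict[str, SimulationConfig] = {}

    chan = DeviceSpec(
        kind="single_channel",
        well_radius_um=400,
        channel_width_um=200,
        channel_length_um=1600,
        margin_um=40,
    )
    left, right = _disc_center_px(chan, 0), _disc_center_px(chan, 1)
    cfgs["single-channel-two-species"] = SimulationConfig(
        device=chan,
        species=(
            _sp("green", (0, 255, 0), death_prob=0.3, period=1),
            _sp("blue", (0, 0, 255), death_prob=0.3, period=2),
        ),
        seeds={"green": (left,), "blue": (right,)},
        total_steps=100,
        rng_seed=7,
    )

    # the drug is administered through the inlet the invasive line was
    # seeded in, once growth and invasion have saturated the channel
    cfgs["single-channel-drug"] = SimulationConfig(
        device=chan,
        species=(
            _sp("healthy", (0, 255, 0), death_prob=0.3, period=1),
            _sp(
                "invader", (0, 0, 255), death_prob=0.3, period=1,
                invasive=True, drug_sensitive=True,
            ),
        ),
        seeds={"healthy": (left,), "invader": (right,)},
        drugs=(
            _drug(activation_step=80, sources=(right,), target="invader"),
        ),
        total_steps=130,
        rng_seed=11,
    )

    radial = DeviceSpec(
        kind="radial",
        chamber_radius_um=400,
        channel_width_um=200,
        channel_length_um=600,
        well_radius_um=240,
        n_channels=4,
        margin_um=40,
    )
    wells = [_disc_center_px(radial, i) for i in (1, 2, 3)]
    cfgs["radial"] = SimulationConfig(
        device=radial,
        species=(
            _sp("green", (0, 255, 0), death_prob=0.3, period=1),
            _sp("blue", (0, 0, 255), death_prob=0.3, period=2),
            _sp("yellow", (255, 255, 0), death_prob=0.3, period=3),
        ),
        seeds={
            "green": (wells[0],),
            "blue": (wells[1],),
            "yellow": (wells[2],),
        },
        total_steps=90,
        rng_seed=3,
    )

    metas = DeviceSpec(
        kind="multi_chamber",
        chamber_width_um=400,
        chamber_height_um=300,
        channel_width_um=160,
        connector_length_um=100,
        well_radius_um=240,
        n_chambers=2,
        margin_um=40,
    )
    m_left, m_right = _disc_center_px(metas, 0), _disc_center_px(metas, 1)
    m_mid = (m_left[0], (m_left[1] + m_right[1]) // 2)
    cfgs["multi-chamber-metastasis"] = SimulationConfig(
        device=metas,
        species=(
            _sp("healthy", (0, 255, 0), death_prob=0.3, period=1),
            _sp(
                "invader", (0, 0, 255), death_prob=0.3, period=1,
                invasive=True, drug_sensitive=True,
            ),
        ),
        seeds={"healthy": (m_left,), "invader": (m_right,)},
        drugs=(
            _drug(activation_step=40, sources=(m_mid,), target="invader"),
        ),
        total_steps=90,
        rng_seed=5,
    )

    # 11-day calibrated run: 4 global steps per culture day; the preset
    # schedules were fitted to live-count fold-changes, so net viability is
    # already inside them and the demo runs with death_prob 0.
    steps_per_day = 4
    cfgs["calibrated-lines"] = SimulationConfig(
        device=chan,
        species=(
            _sp(
                "N2A", (0, 255, 0),
                firing_steps=schedule_firing_steps(
                    preset_schedule("N2A"), steps_per_day
                ),
            ),
            _sp(
                "MC3T3", (0, 0, 255),
                firing_steps=schedule_firing_steps(
                    preset_schedule("MC3T3"), steps_per_day
                ),
            ),
        ),
        seeds={"N2A": (left,), "MC3T3": (right,)},
        total_steps=10 * steps_per_day,
        rng_seed=1,
    )
    return cfgs


def _sp(name, color, **kw):
    from .automaton import SpeciesSpec

    return SpeciesSpec(name=name, color=color, **kw)


def _drug(**kw):
    from .automaton import DrugEvent

    return DrugEvent(**kw)
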