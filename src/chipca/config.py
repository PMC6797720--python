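"""Declarative run configuration.

A run is described by a YAML (or JSON) document:

.. code-block:: yaml

    mask:
      device: {kind: single_channel, well_radius_um: 400,
               channel_width_um: 200, channel_length_um: 1600}
      # or:  path: mask.png   (with optional luminance_threshold)
    species:
      - name: healthy
        color: [0, 255, 0]
        death_prob: 0.3          # aliases: P_d, P_m
        period: 1                # or schedule: {preset: N2A, steps_per_day: 4}
        invasive: false
        drug_sensitive: false
    seeds:
      healthy: [[22, 22]]        # 0-based (row, col), origin top-left
    drugs:
      - {activation_step: 30, sources: [[22, 80]],
         diffusion_period: 1, target: invader}
    total_steps: 80
    rng_seed: 42
    output: {frames_every: 10}

Coordinates are 0-based (row, col) with the origin at the top-left and
rows increasing downward.  ``validate_config`` returns the complete list
of violations rather than stopping at the first.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .automaton import ConfigError, DrugEvent, SpeciesSpec
from .calibration import Schedule, preset_schedule
from .masks import DeviceMask, DeviceSpec, GeometryError, load_mask, make_device

__all__ = [
    "SimulationConfig",
    "load_config",
    "validate_config",
    "schedule_firing_steps",
    "config_from_dict",
]

# accepted spellings of the death probability (the field the growth law
# calls P_d and the discounted sum calls P_m — same quantity)
_DEATH_ALIASES = ("death_prob", "P_d", "P_m", "p_d", "p_m", "pd", "pm")


@dataclass(frozen=True)
class SimulationConfig:
    """Fully validated description of one simulation run."""

    species: tuple[SpeciesSpec, ...]
    seeds: dict[str, tuple[tuple[int, int], ...]]
    total_steps: int
    rng_seed: int = 0
    mask_path: str | None = None
    luminance_threshold: int = 128
    device: DeviceSpec | None = None
    drugs: tuple[DrugEvent, ...] = ()
    frames_every: int | None = None
    source_hash: str | None = None  # sha256 of the config file, if any

    def build_mask(self) -> DeviceMask:
        if self.device is not None:
            return make_device(self.device, warn_disconnected=False)
        if self.mask_path is None:
            raise ConfigError("config has neither a device spec nor a mask path")
        return load_mask(self.mask_path, self.luminance_threshold)

    def config_hash(self) -> str:
        if self.source_hash is not None:
            return self.source_hash
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()

    def to_dict(self) -> dict:
        d = {
            "species": [
                {
                    **asdict(sp),
                    "firing_steps": (
                        sorted(sp.firing_steps)
                        if sp.firing_steps is not None
                        else None
                    ),
                }
                for sp in self.species
            ],
            "seeds": {k: [list(p) for p in v] for k, v in self.seeds.items()},
            "drugs": [asdict(ev) for ev in self.drugs],
            "total_steps": self.total_steps,
            "rng_seed": self.rng_seed,
            "frames_every": self.frames_every,
            "mask_path": self.mask_path,
            "luminance_threshold": self.luminance_threshold,
            "device": asdict(self.device) if self.device else None,
        }
        return d


def schedule_firing_steps(
    schedule: Schedule, steps_per_day: float, start_step: int = 1
) -> frozenset[int]:
    """Map a calibrated per-interval schedule to global firing steps.

    Each interval spanning ``s`` global steps fires its ``k`` iterations
    at evenly spaced offsets (earliest-first when ``s`` is not a multiple
    of ``k``), preserving the interval totals exactly.
    """
    steps: set[int] = set()
    base = start_step - 1
    for d0, d1, k in schedule.intervals:
        s = int(round((d1 - d0) * steps_per_day))
        if k > s:
            raise ConfigError(
                f"interval ({d0}, {d1}) needs {k} iterations but spans only "
                f"{s} global steps; increase steps_per_day"
            )
        for j in range(k):
            steps.add(base + 1 + (j * s) // k)
        base += s
    return frozenset(steps)


def _species_from_dict(raw: dict) -> SpeciesSpec:
    d = dict(raw)
    name = d.pop("name")
    death = 0.0
    for alias in _DEATH_ALIASES:
        if alias in d:
            death = float(d.pop(alias))
    color = tuple(d.pop("color", (0, 255, 0)))
    period = int(d.pop("period", 1))
    firing: frozenset[int] | None = None
    sched = d.pop("schedule", None)
    if sched is not None:
        steps_per_day = float(sched.get("steps_per_day", 4))
        start_step = int(sched.get("start_step", 1))
        if "preset" in sched:
            schedule = preset_schedule(sched["preset"])
        else:
            schedule = Schedule(
                tuple((a, b, int(k)) for a, b, k in sched["intervals"])
            )
        firing = schedule_firing_steps(schedule, steps_per_day, start_step)
    return SpeciesSpec(
        name=name,
        color=color,
        death_prob=death,
        period=period,
        firing_steps=firing,
        invasive=bool(d.pop("invasive", False)),
        drug_sensitive=bool(d.pop("drug_sensitive", False)),
        conversion_prob=float(d.pop("conversion_prob", 1.0)),
    )


def config_from_dict(raw: dict, source_hash: str | None = None) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a parsed raw mapping."""
    mask_sec = raw.get("mask", {})
    device = None
    if "device" in mask_sec:
        dev = dict(mask_sec["device"])
        kind = dev.pop("kind")
        device = DeviceSpec(kind=kind, **dev)
    species = tuple(_species_from_dict(s) for s in raw.get("species", []))
    seeds = {
        name: tuple((int(r), int(c)) for r, c in pts)
        for name, pts in (raw.get("seeds") or {}).items()
    }
    drugs = tuple(
        DrugEvent(
            activation_step=int(ev["activation_step"]),
            sources=tuple((int(r), int(c)) for r, c in ev["sources"]),
            diffusion_period=int(ev.get("diffusion_period", 1)),
            target=ev.get("target", ""),
        )
        for ev in raw.get("drugs", [])
    )
    output = raw.get("output") or {}
    return SimulationConfig(
        species=species,
        seeds=seeds,
        total_steps=int(raw.get("total_steps", 0)),
        rng_seed=int(raw.get("rng_seed", 0)),
        mask_path=mask_sec.get("path"),
        luminance_threshold=int(mask_sec.get("luminance_threshold", 128)),
        device=device,
        drugs=drugs,
        frames_every=output.get("frames_every"),
        source_hash=source_hash,
    )


def load_config(path) -> SimulationConfig:
    """Parse and fully validate a YAML/JSON run configuration.

    Raises :class:`~chipca.automaton.ConfigError` listing *all* violations
    if the document is semantically invalid.
    """
    path = Path(path)
    try:
        text = path.read_bytes()
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    except OSError as exc:
        raise ConfigError(f"cannot read {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    issues = validate_config(raw, base_dir=path.parent)
    if issues:
        raise ConfigError(
            f"{path}: {len(issues)} issue(s):\n  - " + "\n  - ".join(issues)
        )
    if raw.get("mask", {}).get("path"):
        raw = dict(raw)
        raw["mask"] = dict(raw["mask"])
        raw["mask"]["path"] = str((path.parent / raw["mask"]["path"]).resolve())
    return config_from_dict(raw, source_hash=hashlib.sha256(text).hexdigest())


def validate_config(source, base_dir=None) -> list[str]:
    """Collect every semantic violation in a config (never fail-fast).

    ``source`` may be a path, a raw mapping, or a built
    :class:`SimulationConfig`.  Returns an empty list when valid.
    """
    if isinstance(source, SimulationConfig):
        raw = source.to_dict()
        raw = {
            "mask": {
                k: v
                for k, v in {
                    "path": raw["mask_path"],
                    "device": raw["device"],
                    "luminance_threshold": raw["luminance_threshold"],
                }.items()
                if v is not None
            },
            "species": raw["species"],
            "seeds": raw["seeds"],
            "drugs": raw["drugs"],
            "total_steps": raw["total_steps"],
            "rng_seed": raw["rng_seed"],
        }
    elif isinstance(source, dict):
        raw = source
    else:
        p = Path(source)
        base_dir = p.parent
        try:
            raw = yaml.safe_load(p.read_text())
        except Exception as exc:
            return [f"cannot read/parse {p}: {exc}"]
        if not isinstance(raw, dict):
            return [f"{p}: top level must be a mapping"]

    issues: list[str] = []
    mask_sec = raw.get("mask") or {}
    mask = None
    if "device" in mask_sec and mask_sec["device"]:
        try:
            dev = dict(mask_sec["device"])
            kind = dev.pop("kind", None)
            if kind is None:
                issues.append("mask.device: missing 'kind'")
            else:
                mask = make_device(
                    DeviceSpec(kind=kind, **dev), warn_disconnected=False
                )
        except (GeometryError, TypeError) as exc:
            issues.append(f"mask.device: {exc}")
    elif mask_sec.get("path"):
        p = Path(mask_sec["path"])
        if base_dir is not None and not p.is_absolute():
            p = Path(base_dir) / p
        try:
            mask = load_mask(p, int(mask_sec.get("luminance_threshold", 128)))
        except Exception as exc:
            issues.append(f"mask.path: {exc}")
    else:
        issues.append("mask: needs either 'device' or 'path'")

    names: list[str] = []
    for i, raw_sp in enumerate(raw.get("species", [])):
        label = raw_sp.get("name", f"#{i}")
        if "name" not in raw_sp:
            issues.append(f"species #{i}: missing name")
        elif raw_sp["name"] in names:
            issues.append(f"species {label!r}: defined more than once")
        names.append(label)
        for alias in _DEATH_ALIASES:
            if alias in raw_sp:
                p = float(raw_sp[alias])
                if not 0.0 <= p <= 1.0:
                    issues.append(
                        f"species {label!r}: death_prob {p} outside [0, 1]"
                    )
        try:
            _species_from_dict({**raw_sp, "name": label, "death_prob": 0.0})
        except (ConfigError, KeyError, TypeError, ValueError) as exc:
            issues.append(f"species {label!r}: {exc}")
    if not names:
        issues.append("species: at least one species required")

    occupied: set[tuple[int, int]] = set()
    for name, pts in (raw.get("seeds") or {}).items():
        if name not in names:
            issues.append(f"seeds: unknown species {name!r}")
        for r, c in pts:
            r, c = int(r), int(c)
            if mask is not None:
                if not (0 <= r < mask.n_rows and 0 <= c < mask.n_cols):
                    issues.append(
                        f"seeds[{name}]: ({r}, {c}) outside the lattice"
                    )
                    continue
                if not mask.allowed[r, c]:
                    issues.append(
                        f"seeds[{name}]: ({r}, {c}) is on a wall pixel"
                    )
            if (r, c) in occupied:
                issues.append(f"seeds[{name}]: ({r}, {c}) seeded twice")
            occupied.add((r, c))

    for i, ev in enumerate(raw.get("drugs", [])):
        if ev.get("target") and ev["target"] not in names:
            issues.append(f"drugs #{i}: unknown target {ev['target']!r}")
        if int(ev.get("activation_step", 0)) < 0:
            issues.append(f"drugs #{i}: activation_step must be >= 0")
        if int(ev.get("diffusion_period", 1)) < 1:
            issues.append(f"drugs #{i}: diffusion_period must be >= 1")
        for r, c in ev.get("sources", []):
            r, c = int(r), int(c)
            if mask is not None and (
                not (0 <= r < mask.n_rows and 0 <= c < mask.n_cols)
                or not mask.allowed[r, c]
            ):
                issues.append(f"drugs #{i}: source ({r}, {c}) is forbidden")

    if int(raw.get("total_steps", 0)) < 0:
        issues.append("total_steps must be >= 0")
    return issues
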