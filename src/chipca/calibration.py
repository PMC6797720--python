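"""Growth analytics and schedule calibration.

The automaton's unobstructed single-seed growth law is

    y_n = y_{n-1} + 4 n            (no death)
    y_n = y_0 + sum_{k=1..n} 4 k (1 - P_d)     (newborn death prob P_d)

whose closed form is ``y_n = y0 + y0 * 2 n (n+1) (1 - P_d)`` when the y0
seeds grow as independent diamonds.  Calibration inverts this: given an
observed growth curve (mean cell count per culture day), find for each
interval between consecutive observations the number of proliferation
iterations whose predicted fold-change best matches the observed one.
The resulting per-interval schedule drives the species' firing steps in
the simulator.  Crowding is ignored here by design: cultures are counted
at low density, where diamond growth is a fair approximation.

Named presets ship the calibrated schedules for the N2A (mouse
neuroblastoma) and MC3T3 (osteoblast precursor) adherent lines over an
11-day culture.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "GrowthParams",
    "GrowthCurve",
    "Schedule",
    "expected_count",
    "iterations_for_growth",
    "schedule_from_curve",
    "preset_schedule",
    "curve_from_schedule",
    "PRESET_SCHEDULES",
]


@dataclass(frozen=True)
class GrowthParams:
    """Parameters of the closed-form growth law.

    y0 : initial seed count (>= 1); seeds are exempt from the death draw.
    death_prob : per-newborn death probability P_d in [0, 1].
    """

    y0: int = 1
    death_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.y0 < 1:
            raise ValueError("y0 must be >= 1")
        if not 0.0 <= self.death_prob <= 1.0:
            raise ValueError("death_prob must be in [0, 1]")


@dataclass(frozen=True)
class GrowthCurve:
    """Observed mean cell counts over culture days.

    ``observations`` is an ordered tuple of (day, mean_count) or
    (day, mean_count, sd); days strictly increasing, counts > 0.
    """

    observations: tuple[tuple, ...]

    def __post_init__(self) -> None:
        obs = tuple(tuple(float(x) for x in o) for o in self.observations)
        days = [o[0] for o in obs]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("days must be strictly increasing")
        if any(o[1] <= 0 for o in obs):
            raise ValueError("counts must be > 0")
        object.__setattr__(self, "observations", obs)

    @property
    def days(self) -> list[float]:
        return [o[0] for o in self.observations]

    @property
    def counts(self) -> list[float]:
        return [o[1] for o in self.observations]

    @classmethod
    def from_csv(cls, path) -> "GrowthCurve":
        df = pd.read_csv(path)
        cols = ["day", "mean_count"] + (["sd"] if "sd" in df.columns else [])
        return cls(tuple(tuple(row) for row in df[cols].itertuples(index=False)))

    def to_csv(self, path) -> None:
        has_sd = any(len(o) > 2 for o in self.observations)
        rows = [
            (o[0], o[1], o[2] if len(o) > 2 else "") for o in self.observations
        ]
        cols = ["day", "mean_count", "sd"] if has_sd else ["day", "mean_count"]
        pd.DataFrame(
            [r[: len(cols)] for r in rows], columns=cols
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class Schedule:
    """Per-interval proliferation iteration counts.

    ``intervals`` is an ordered tuple of (day_start, day_end, iterations);
    intervals are contiguous, non-overlapping, iterations >= 0.
    """

    intervals: tuple[tuple[float, float, int], ...]

    def __post_init__(self) -> None:
        iv = tuple(
            (float(a), float(b), int(k)) for a, b, k in self.intervals
        )
        for a, b, k in iv:
            if b <= a:
                raise ValueError(f"empty interval ({a}, {b})")
            if k < 0:
                raise ValueError("iterations must be >= 0")
        for (_, b0, _), (a1, _, _) in zip(iv, iv[1:]):
            if a1 != b0:
                raise ValueError("intervals must be contiguous")
        object.__setattr__(self, "intervals", iv)

    @property
    def iterations(self) -> tuple[int, ...]:
        return tuple(k for _, _, k in self.intervals)

    @property
    def total_iterations(self) -> int:
        return sum(self.iterations)

    @classmethod
    def from_csv(cls, path) -> "Schedule":
        df = pd.read_csv(path)
        return cls(
            tuple(
                (r.day_start, r.day_end, int(r.iterations))
                for r in df.itertuples(index=False)
            )
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            list(self.intervals), columns=["day_start", "day_end", "iterations"]
        ).to_csv(path, index=False)


# calibrated 11-day schedules for the two reference adherent lines
PRESET_SCHEDULES: dict[str, Schedule] = {
    "N2A": Schedule(
        ((1, 3, 2), (3, 5, 3), (5, 7, 6), (7, 9, 7), (9, 11, 7))
    ),
    "MC3T3": Schedule(
        ((1, 3, 2), (3, 5, 5), (5, 7, 7), (7, 9, 8), (9, 11, 7))
    ),
}


def expected_count(n: int, params: GrowthParams = GrowthParams()) -> float:
    """Expected cell count (live) after ``n`` proliferation iterations.

    Closed form of the discounted ring sum: each iteration k adds 4k
    newborns per seed diamond, a fraction (1 - P_d) of which survive.
    Seeds are treated as independent diamonds (counts additive).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    return params.y0 * (1.0 + 2.0 * n * (n + 1) * (1.0 - params.death_prob))


def iterations_for_growth(
    count_start: float,
    count_end: float,
    cumulative_prior: int,
    params: GrowthParams = GrowthParams(),
    k_max: int = 50,
) -> int:
    """Iterations whose predicted fold-change best matches the observed one.

    Brute-force argmin over k in 0..k_max of

        | expected_count(prior + k) / expected_count(prior)
          - count_end / count_start |

    with ties broken toward smaller k.
    """
    if count_start <= 0 or count_end <= 0:
        raise ValueError("counts must be > 0")
    if k_max < 0:
        raise ValueError("k_max must be >= 0")
    observed = count_end / count_start
    base = expected_count(cumulative_prior, params)
    best_k, best_err = 0, float("inf")
    for k in range(k_max + 1):
        err = abs(expected_count(cumulative_prior + k, params) / base - observed)
        if err < best_err:  # strict: ties keep the smaller k
            best_k, best_err = k, err
    return best_k


def schedule_from_curve(
    curve: GrowthCurve,
    params: GrowthParams = GrowthParams(),
    k_max: int = 50,
) -> Schedule:
    """Fit a per-interval iteration schedule to an observed growth curve.

    Greedy interval-by-interval fit: each consecutive observation pair
    gets the iteration count whose predicted fold-change from the current
    cumulative iteration position best matches the observed fold-change.
    """
    if len(curve.observations) < 2:
        raise ValueError("curve needs at least 2 observations")
    intervals = []
    cumulative = 0
    for (d0, c0, *_), (d1, c1, *_) in zip(
        curve.observations, curve.observations[1:]
    ):
        k = iterations_for_growth(c0, c1, cumulative, params, k_max)
        intervals.append((d0, d1, k))
        cumulative += k
    return Schedule(tuple(intervals))


def curve_from_schedule(
    schedule: Schedule, params: GrowthParams = GrowthParams()
) -> GrowthCurve:
    """Predicted growth curve of a schedule under the closed-form law
    (the forward model inverted by :func:`schedule_from_curve`)."""
    obs = [(schedule.intervals[0][0], expected_count(0, params))]
    cumulative = 0
    for _, d1, k in schedule.intervals:
        cumulative += k
        obs.append((d1, expected_count(cumulative, params)))
    return GrowthCurve(tuple(obs))


def preset_schedule(name: str) -> Schedule:
    """Look up a calibrated schedule preset by cell-line name."""
    try:
        return PRESET_SCHEDULES[name]
    except KeyError:
        raise KeyError(
            f"unknown schedule preset {name!r}; available: "
            f"{sorted(PRESET_SCHEDULES)}"
        ) from None
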