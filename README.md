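# chipca

Cellular-automata simulation of collective cell behaviour inside
microfluidic (lab-/organ-on-a-chip) devices.

Microfluidic chips culture cells inside channels and chambers whose
confinement shapes how populations grow, meet, invade each other and
respond to a drug. `chipca` turns a black/white top view of such a device
(white = cell-permitted, black = wall) into a bounded lattice in which one
pixel is one cell-sized square (20 × 20 µm by default), and steps a
multi-species cellular automaton on it. It is aimed at chip designers and
computational biologists who want a fast, reproducible first look at
collective dynamics in a candidate geometry before committing to
fabrication and culture.

## The model

Each lattice pixel holds one state: wall, empty, a live cell of some
species, a dead cell (red), or drug (pink). A global step applies, in
order, to every pixel synchronously (decisions from a pre-step snapshot):

1. **Proliferation** — for each species whose schedule fires, every empty
   allowed pixel with ≥ 1 von Neumann (4-)neighbour of that species'
   colony becomes a newborn. An isolated seed therefore grows as the von
   Neumann ball and its population follows

   *y*<sub>*n*</sub> = *y*<sub>*n*−1</sub> + 4*n*.

2. **Newborn death** — each newborn independently dies with the species'
   death probability *P*<sub>d</sub>, giving the expected count

   *y*<sub>*n*</sub> = *y*<sub>0</sub> + Σ<sub>*k*=1..*n*</sub> 4*k* (1 − *P*<sub>d</sub>)
   = *y*<sub>0</sub> + 2*n*(*n*+1)(1 − *P*<sub>d</sub>).

   Dead pixels persist, occupy their pixel forever, and are never
   re-colonised.

3. **Invasion** — live cells of a non-invasive species adjacent to an
   invasive species convert to it, one lattice layer per step.

4. **Drug** — a timed event seeds drug at source pixels; it diffuses into
   empty pixels with its own period and converts adjacent live cells of
   its *target* species into an absorbing, non-proliferating affected
   state. Other species are never touched.

Per-species proliferation *schedules* are calibrated from observed growth
curves (mean cell count per culture day) by inverting the closed form
above interval-by-interval; the calibrated 11-day schedules for the N2A
(neuroblastoma) and MC3T3 (osteoblast precursor) lines ship as presets.
Cell migration is intentionally not modelled (adherent lines).

## Worked example

Calibrate a schedule from a growth curve and run the 11-day two-line
demo (4 automaton steps per culture day):

```python
import chipca
from chipca.calibration import curve_from_schedule, preset_schedule

# the MC3T3 preset predicts this 11-day growth curve from one seed cell:
curve = curve_from_schedule(preset_schedule("MC3T3"))
print(list(zip(curve.days, curve.counts)))
# [(1.0, 1.0), (3.0, 13.0), (5.0, 113.0), (7.0, 421.0), (9.0, 1013.0), (11.0, 1741.0)]

# and the calibrator recovers the schedule exactly from that curve:
assert chipca.schedule_from_curve(curve).iterations == (2, 5, 7, 8, 7)

cfg = chipca.demo_configs()["calibrated-lines"]
summary = chipca.run_simulation(cfg)
print(summary.counts.iloc[[0, 8, 16, 24, 32, 40]].to_string(index=False))
```

```
 step  empty  wall  dead  drug  N2A  MC3T3
    0   3326  3888     0     0    1      1
    8   3302  3888     0     0   13     13
   16   3154  3888     0     0   61    113
   24   2642  3888     0     0  265    421
   32   1652  3888     0     0  685    991
   40    801  3888     0     0 1198   1329
```

The two lines are seeded one cell each in the opposite inlet wells of a
straight-channel device. Through day 3 (step 8) their schedules are
identical, so the counts match; from day 5 on the MC3T3 line fires more
proliferation iterations per interval and stays ahead, exactly as in
culture. Counts per row always sum to the lattice size; `wall` is the
device material, `empty` the remaining free medium.

The same is available from a shell:

```sh
chipca make-device --kind single_channel --well-radius-um 400 \
    --channel-length-um 1600 --out mask.png
chipca demos --list
chipca demos --run calibrated-lines --out out/ --frames-every 4
chipca calibrate --growth curve.csv --out schedule.csv
```

`chipca run --config run.yaml --out out/` executes a declarative YAML
config (mask or parametric device, species, seeds, drug events, RNG
seed); see `chipca/config.py` for the schema. Runs are bit-reproducible
under a fixed seed.

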