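# Methods

## Lattice and geometry

The simulation domain is a rectangular lattice derived from a black/white
raster of a device's top view. A pixel is one cell-sized square; the
physical scale `pixel_size_um` defaults to 20 µm and is metadata only —
no update rule depends on it. Coordinates are 0-based `(row, col)`,
origin top-left, rows increasing downward (raster convention).

**Binarization.** Real mask images carry anti-aliased borders and (for
JPEG) compression artifacts, i.e. grey pixels that are neither wall nor
medium. `load_mask` classifies every pixel by mean luminance against a
threshold (default 128, configurable): ≥ threshold → allowed, else wall.
Mapping grey to either side is defensible; the threshold form is chosen
so dark anti-aliasing keeps walls intact rather than opening spurious
channels, and both directions are reachable by moving the threshold.
After loading, exactly two states exist; a mask with zero allowed pixels
is rejected as unusable.

**Synthetic devices.** `make_device` rasterises a parametric layout — a
union of discs, axis-aligned and oriented rectangles — with a pixel-center
inclusion rule: a pixel is allowed iff its center lies inside the union.
This rule is deterministic and lets tests verify the raster against an
independent per-pixel point-in-shape scan (exact set equality). Supported
layouts: `single_channel` (two circular wells joined by a straight
channel; an optional `well_gap_um` decouples well spacing from channel
length so degenerate disconnected layouts can be expressed),
`radial` (central chamber, N evenly spaced channels ending in wells),
`multi_chamber` (two rows of chambers hanging off a central channel with
inlet/outlet wells), and `custom` (explicit shape union — used for
blood-brain-barrier-like assemblies, for which no canonical dimensions
exist). A layout that rasterises to more than one 4-connected component
raises a warning, not an error: some layouts are legitimately
disconnected.

## Automaton rules

States: `EMPTY`, `WALL`, `DEAD`, `DRUG`, plus one code per registered
species. Walls coincide with the mask's forbidden set at every step.
The neighbourhood is von Neumann (4-neighbour): the growth increment of
an isolated seed is then exactly 4*n* per step, matching the quadratic
growth law; a Moore neighbourhood would grow by 8*n* and break it, so it
is not offered.

A global step executes, in order:

1. **Proliferation** for every species whose schedule fires this step.
   All claims are computed from one shared pre-step snapshot; when two
   species claim the same empty pixel, the winner is drawn uniformly from
   the claimants using the run RNG (row-major scan over contested
   pixels) — unbiased and reproducible.
2. **Newborn death**: each newborn of a firing species independently
   becomes `DEAD` with that species' `death_prob` (draws row-major over
   the newborn set, species in registration order). The lottery applies
   once, at birth; seeded cells (the y₀) never draw.
3. **Invasion**: every live non-invasive cell with an invasive von
   Neumann neighbour (snapshot) converts to that species; a chain
   converts one link per step. Ties between several invasive neighbours
   are broken uniformly; an optional per-species `conversion_prob`
   (default 1.0) makes conversion stochastic.
4. **Drug**, per event: at activation the source pixels become drug
   (empty sources are occupied; a source holding a live target cell is
   hit directly). On steps whose offset from activation is a multiple of
   `diffusion_period`, the drug spreads into empty allowed pixels
   adjacent to the front — the same flood dynamic as proliferation, on
   its own clock. On every active step, live target-species cells
   adjacent to drug become affected. Non-target species are never
   affected.

`DEAD` and `DRUG` are absorbing; occupancy is monotone (an empty pixel
that becomes occupied never empties again).

**Dead cells and the growth front.** Dead pixels block every *other*
species and the drug, and are never re-colonised. They do, however,
still count as part of their own species' colony for proliferation
adjacency. This is a deliberate modelling choice: it is the unique local
reading under which the expected-count law
y₀ + 2n(n+1)(1−P_d) is exact for an unobstructed seed — if dead newborns
interrupted their own front, the ring increment would fall below 4n
(simulation puts the single-seed mean at n=10, P_d=0.3 near 96 instead
of 155) and the closed form used by the calibrator would not describe
the simulator. Biologically: a dying cell's neighbours keep
proliferating; mortality thins the population without stalling the
colony's advance.

**Drug states.** One lattice code (rendered pink) covers both
drug-occupied medium and drug-affected cells; the two are not
distinguished visually in the source imagery this model emulates. The
`owner` layer keeps the species attribution of affected cells.
Consequence of the shared code: affected cells also propagate the drug
front. Whether affected cells are dead or merely arrested is left open;
they are treated as absorbing and non-proliferating without being
counted as dead.

**Determinism.** One `numpy` Generator per run, seeded from the config;
all stochastic draws (death, conflict and invasion tie-breaks,
sub-unit conversion probabilities) consume it in a documented scan
order. Identical config + seed gives bit-identical trajectories; the
per-step counts CSV of a rerun is byte-identical.

## Growth law and calibration

For an isolated unobstructed seed with period-1 firing:

    live(n) = 1 + 2n(n+1)                   (P_d = 0)          exact
    E[live(n)] = 1 + 2n(n+1)(1 − P_d)       (newborn mortality) exact
    total(n) = live + dead = 1 + 2n(n+1)                        exact

`expected_count` implements the closed form; multiple seeds are treated
as independent diamonds (counts additive). Crowding — walls, collisions
with other colonies — is deliberately ignored in calibration: reference
growth curves come from low-density multi-well cultures where diamond
growth is a fair approximation, and the simulator itself handles
crowding at run time.

`iterations_for_growth` inverts the law per observation interval: a
brute-force argmin over k ∈ 0..k_max (default 50) of the absolute error
between predicted and observed fold-change, ties to the smaller k.
Brute force is chosen over a root-finder for transparency and exact
oracle-checkability; k_max = 50 is far beyond any realistic per-interval
iteration count. `schedule_from_curve` applies this greedily across
consecutive observation pairs, accumulating the cumulative iteration
position. Fold-change (not absolute count) is matched so the fit is
invariant to the y₀ normalisation of the curve.

The shipped presets — N2A (2, 3, 6, 7, 7) and MC3T3 (2, 5, 7, 8, 7)
iterations over days 1–3, 3–5, 5–7, 7–9, 9–11 — are calibrated 11-day
schedules for the two reference adherent lines. The death probability
P_d = 0.3 appears throughout the demos as the reference value used in
the trial simulations.

## Schedules on the global clock

A schedule states iterations per 2-day interval; it does not say when
within the interval they fire. The runner maps day intervals to spans of
global steps (`steps_per_day`, demo default 4) and distributes each
interval's k iterations at offsets ⌊j·s/k⌋ (j = 0..k−1) within its
s-step span — evenly spaced, earliest-first on remainders — preserving
interval totals exactly, which is all the schedule constrains. An
interval needing more iterations than it has steps is a configuration
error (raise, not clamp).

## Demos and what they show

Five packaged scenarios exercise the full rule set at desk scale (grids
of roughly 50 × 150 to 160 × 160 pixels, runs of 40–130 steps, well under
a second each): two lines meeting in a straight channel; an invasion +
drug scenario in the same channel; three lines converging through a
radial device; invasive spread with a drug event in a multi-chamber
layout; and the calibrated 11-day N2A/MC3T3 run. In the drug demo the
drug is administered through the inlet the invasive line was seeded in,
after growth and invasion have saturated the channel, so from the event
onward the target line's live count is non-increasing — the drug only
removes, and nothing is left for the target to gain. The calibrated demo
runs with P_d = 0: its schedules were fitted to live-count growth
curves, so net viability is already inside them and an extra death draw
would double-count mortality.

## Synthetic data vs real data

Everything here is synthetic: geometries are parametric rasterisations,
growth curves are generated from schedules via the closed form, and
masks with artifacts are produced by corrupting clean rasters. Passing
tests therefore demonstrate internal consistency — rule correctness
against independent oracles (set-based flood fills, BFS distances,
per-pixel geometry scans, binomial statistics), exact calibration
round-trips, and reproducibility — not agreement with any particular
wet-lab culture. Real cultures add what the model omits: migration,
contact inhibition gradients, nutrient fields, non-synchronous division,
and imaging noise beyond simple anti-aliasing.

## Known limitations

- No cell migration, no cellular-Potts energies, no nutrient or flow
  fields, no 3D lattices.
- Death is newborn-only; established cells never die, so long runs
  saturate rather than turn over.
- The drug does not displace or traverse occupied pixels; a confluent
  layer shields cells behind it except via the contact-conversion chain.
- Calibration assumes unobstructed diamond growth; schedules fitted from
  crowded cultures will under-estimate intrinsic rates.
- With conversion and death both active, 1-pixel corridors can be
  permanently blocked for other species by a single dead cell.
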