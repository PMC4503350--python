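# tumorca

Event-driven 3D cellular-automaton model of avascular tumor growth. Each
cell on a cubic lattice carries five binary hallmark flags — self-growth
(SG), ignore-growth-inhibit (IGI), evade-apoptosis (EA), effective
immortality (EI) and genetic instability (GI) — plus a telomere counter and
a mutation-rate denominator. A global priority queue schedules mitosis
events 5–10 iterations ahead; each popped event runs a fixed test cascade
(random death 1/a → genetic damage n/e → replicative limit → growth-factor
region → free space / IGI competition at 1/g). A hierarchical cancer-stem-cell
(CSC) compartment divides symmetrically with probability `p_s` or
asymmetrically into a differentiated cancer cell (DCC) bearing one random
hallmark, and idealized treatment schedules kill DCCs only — allowing
growth/regrowth dynamics to be compared across treatment strategies.

## Layout

| module | role |
|---|---|
| `tumorca.lattice` | cubic occupancy grid, Moore/von-Neumann neighborhoods, growth-factor region |
| `tumorca.cell_model` | genomes, mutation and death probabilities, iteration↔real-time mapping |
| `tumorca.engine` | priority-queue event loop and the mitosis test cascade |
| `tumorca.stem_cells` | CSC seeding, symmetric/asymmetric division |
| `tumorca.treatment` | pulse / continuous / periodic plans with threshold gating |
| `tumorca.observers_io` | per-iteration counts, slice snapshots, CSV/PGM/JSON I/O, config |
| `tumorca.scenarios` | named experiment presets, regrowth metrics, replicate helpers |

## CLI

```sh
# single run, flags or JSON config (flags override the config)
tumorca run --seed 1 --side 50 --iterations 6000 --csc-fraction 0.01 \
    --treatment-mode pulse --treatment-start 5000 --kill-prob 1.0 \
    --out-dir out/
tumorca run --config config.json --out-dir out/

# named reproductions (fig2, fig3, fig4a-d, fig5a-d), optionally scaled
tumorca scenario --name fig2 --scale 0.4 --replicates 10 --seed-base 0 \
    --out-dir out/

# central cross-section from a saved state dump
tumorca slice --state out/state.json --axis z --out slice.csv --pgm slice.pgm
```

`run` writes `timeseries.csv` (one row per iteration: population counts by
class, per-hallmark DCC counts, division/death/kill tallies), `state.json`
(final category grid), central slices as CSV and ASCII-PGM, and the resolved
`config.json`. A config file needs at least `{"seed": ...}`; every parameter
has an explicit key and unknown keys are rejected:

```json
{
  "seed": 1,
  "side": 50,
  "iterations": 8000,
  "params": {"g": 5.0},
  "csc": {"fraction": 0.01, "p_s": 0.01},
  "treatment": {"mode": "continuous", "start": 5000, "end": 6000,
                "kill_prob": 0.01}
}
```

Scenario presets keep the published schedules (e.g. the fig2 pulse at
iteration 5000) even when spatially scaled down, because the model's time
constants do not shrink with the lattice; `--scale` only reduces the grid
side.

## Notes

- All randomness flows through one seeded `random.Random` stream; identical
  seed + config ⇒ bit-identical trajectories.
- A surrounded IGI cell that loses its 1/g competition stays quiescent by
  default (`Params.igi_failure_kills=False`); the loser-dies variant is
  available but makes surrounded clones strictly subcritical (mean offspring
  2/g < 1), which precludes tumor growth in a space-filled grid.
- Full-scale runs (side 50, 6000–8000 iterations) take tens of minutes
  single-threaded; the scaled presets used in CI take seconds to a couple of
  minutes each.
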