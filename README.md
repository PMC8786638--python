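# ethotrack

Simulation, multi-species video tracking, group-behaviour metrics and
symbolic transfer-entropy inference for **robotic-predator ("ecology of
fear") arena experiments** with mixed groups of mosquitofish (*Gambusia
holbrooki*) and tadpoles (*Litoria moorei*).

The package is aimed at behavioural ecologists and ethorobotics researchers
who run (or simulate) closed-loop predator-robot assays: a circular 42-cm
arena filmed at 20 frames/s holds six mosquitofish, six tadpoles and, in the
exposed treatment, one robotic predator that patrols a stored trajectory and
attacks the mosquitofish closest to the tadpoles roughly once per minute,
with three-tier attack kinematics (contact < 1 cm, inspection 1-10 cm,
pursuit > 10 cm; 20 cm/s speed cap, 20 cm/s² acceleration cap, 1-s hold,
return to the pre-attack pose).

## What it provides

- **`ethotrack.arena`** — an agent-based trial simulator (ground-truth
  trajectories + attack logs) with the interactive predator controller and
  configurable directed behavioural coupling between the species, plus a
  renderer that turns trials into noisy grayscale frame stacks with known
  blob ground truth.
- **`ethotrack.tracking`** — a multi-species blob tracker: multiple
  thresholding and connected-component analysis, body-characteristic
  species classification (blob area × gray level), Munkres/Hungarian
  assignment of detections to tracks per species, and a constant-velocity
  Kalman predictor that fills missed detections (flagged `predicted`).
- **`ethotrack.metrics`** — per-trial group measures: average furthest
  neighbour distance (AFND), average inter-individual distance (AIID),
  distance swam, unsigned turning rate, and occupancy of the seven
  concentric 3-cm rings condensed into the central (0-15 cm) and external
  (15-21 cm) regions; plus Fulton's condition factor
  K = weight·length⁻³·10⁴.
- **`ethotrack.infoflow`** — group-level signals at half-second steps
  (mean magnitude of the group turning rate; number of animals in the
  central region), binary "+/-" symbolization, plug-in transfer entropy

  TE(M→T) = Σ Pr(T(t+1), T(t), M(t)) · log₂ [ Pr(T(t+1) | T(t), M(t)) / Pr(T(t+1) | T(t)) ]

  over the eight symbol triplets, and a trial-shuffling permutation test
  (mean TE across trials against the 95% quantile of a null built by
  shuffling the source group identities across trials).
- **`ethotrack.io`** — the delimited trajectory-table dialect shared by the
  simulator and the tracker, attack-log and config sidecars, experiment
  schedule arithmetic, and a `ethotrack` CLI chaining
  `simulate → render → track → metrics → te`.

## Worked example

```python
import numpy as np
from ethotrack import (
    CouplingSpec, Species, simulate_trial, group_signal, symbolize,
    permutation_test,
)
from ethotrack.metrics import summarize_species

# one 10-min exposed trial with unidirectional fish -> tadpole coupling
rec = simulate_trial(treatment="robot_exposed", duration=600.0, seed=2)
print(len(rec.attacks), rec.attacks[0].tier.value)

idx = rec.species_index(Species.MOSQUITOFISH)
s = summarize_species(rec.positions[:, idx, :], Species.MOSQUITOFISH,
                      geometry=rec.geometry, fps=rec.fps)
print(f"AFND {s.afnd:.1f} cm  AIID {s.aiid:.1f} cm  "
      f"central {s.central_time:.0f} s")

# directed information flow across 12 simulated trials
pairs = []
for k in range(12):
    r = simulate_trial(duration=600.0, seed=100 + k)
    m = symbolize(group_signal(r, "turning_magnitude", Species.MOSQUITOFISH))
    t = symbolize(group_signal(r, "turning_magnitude", Species.TADPOLE))
    pairs.append((m, t))
res = permutation_test(pairs, ("mosquitofish", "tadpole"), n_perm=2000, seed=0)
print(f"TE {res.observed_mean:.4f} bits vs null 95% {res.null_quantile_95:.4f}"
      f" -> significant: {res.significant}")
```

Output:

```
9 pursuit
AFND 6.4 cm  AIID 4.2 cm  central 272 s
TE 0.0066 bits vs null 95% 0.0028 -> significant: True
```

Nine attacks completed in the 10-minute trial (about one per minute, each
blocking the scheduler while the robot pursues, holds and returns); the
fish shoal keeps a ~4-cm mean spacing; and the mosquitofish→tadpole
transfer entropy of 0.0066 bits exceeds the shuffled-identity null's 95%
quantile, recovering the directed coupling built into the simulator.

The same pipeline runs from the shell:

```sh
ethotrack --seed 7 --out out/ simulate   # trajectory + attack tables
ethotrack --seed 7 --out out/ all        # ... through tracking and TE
```

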