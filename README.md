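# p53loop

A simulator for the core negative feedback loop between the tumor
suppressor p53 and its inhibitor Mdm2, for systems biologists studying
how one signalling hub produces stress-specific responses.

p53 integrates DNA damage, hypoxia, oncogene activation, nutrient
deprivation and drug treatment into a single node, yet the downstream
response differs per stress. This package models the mechanism behind
that flexibility: a four-species loop — free nuclear p53 (p), mdm2 mRNA
(m_m), free Mdm2 (m) and the p53–Mdm2 complex (c) —

    dp/dt   = σ − α·p − k_f·p·m + (k_b + γ)·c
    dm_m/dt = k_t·p² − β·m_m
    dm/dt   = k_tl·m_m − γ·m − k_f·p·m + (k_b + δ)·c
    dc/dt   = k_f·p·m − (k_b + δ + γ)·c

in which p53 activates mdm2 transcription (Hill coefficient 2) and Mdm2
targets complexed p53 for degradation (rate δ). There is no explicit
transcriptional delay: oscillations arise from the sequestration
nonlinearity of complex formation alone. Stresses enter as fold changes
of specific rate constants (DNA damage: γ↗ δ↘ k_D↗; hypoxia: k_t↘ δ↘;
oncogene/nitric oxide: δ↘; nutlin: k_D↗; ribonucleotide depletion: σ↗).

Provided layers:

* `p53loop.model` — right-hand side, analytic Jacobian, equilibria with
  linear stability (exact 1-D reduction plus bracketed root-finding)
* `p53loop.dynamics` — stiff ODE time courses with stress events, peak
  detection, oscillation metrics (average, amplitude, period, spikyness)
* `p53loop.stress` — the stress library, DNA-damage calibration to the
  ionizing-radiation peak schedule, SNP309 genotypes as k_t shifts
* `p53loop.scan` — 2-D phase diagrams with the spikyness = 2 contour and
  fold-change sensitivity curves over [1/5, 5]
* `p53loop.gillespie` — exact stochastic counterpart (direct method,
  numba-compiled) with nM ↔ molecule volume scaling
* `p53loop.sbml` / `p53loop.io` — SBML L3V2 exchange with a term-level
  diff reporter, CSV/JSON writers, run manifests
* `p53loop` CLI — `simulate`, `steady-state`, `scan`, `sensitivity`,
  `ssa`, `calibrate`, `export-sbml`

## Worked example

```python
import numpy as np
from p53loop import (
    default_parameters, resting_state, simulate, builtin_scenarios,
)
from p53loop.dynamics import detect_peaks

params = default_parameters()
rest = resting_state(params)
print(f"resting: total p53 = {rest.total_p53:.1f} nM "
      f"(free {rest.p:.1f}, bound {rest.c:.1f})")

damage = builtin_scenarios()["dna_damage"]
traj = simulate(params, rest, 16.0, events=[(0.0, damage)])
for i, (t, h) in enumerate(detect_peaks(traj.times, traj.p)[:3], 1):
    print(f"peak {i}: t = {t:5.2f} h, free p53 = {h:5.1f} nM")
```

prints

```
resting: total p53 = 107.5 nM (free 16.8, bound 90.8)
peak 1: t =  0.51 h, free p53 =  56.4 nM
peak 2: t =  6.03 h, free p53 =  27.8 nM
peak 3: t = 11.00 h, free p53 =  22.9 nM
```

Unstressed, the cell rests at ≈107 nM total p53, almost all of it
Mdm2-bound — low free p53 with high turnover. Applying the calibrated
DNA-damage scenario at t = 0 produces damped free-p53 oscillations whose
first three peaks land at ~30 min, ~6 h and ~11 h with the first peak
about twice the second and 2.5 times the third — the schedule observed
in irradiated single cells.

The same loop from the shell:

```sh
p53loop steady-state
p53loop simulate --stress hypoxia --duration 100 --out runs/hypoxia
p53loop ssa --stress dna_damage --volume-scale 500 --runs 3 --seed 1 --out runs/ssa
```

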