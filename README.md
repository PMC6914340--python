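# smcotrack

Dual-color single-molecule co-localization/co-tracking analysis of
membrane receptor dimerization, with a Monte-Carlo simulator of
monomer–dimer membrane dynamics under stochastic two-color labeling.

## The problem

Cytokine receptors such as gp130 signal when a ligand dimerizes two
receptor chains in the plasma membrane. In a dual-color TIRF experiment
the receptor population is labeled stochastically with two spectrally
separable fluorophores (e.g. via dye-conjugated anti-GFP nanobodies), and
correlated motion of a two-color pair — *co-locomotion* — is the
single-molecule readout of dimerization. Because labeling is random, a
dimer carries one label of each color only part of the time; the
observed co-trajectory count `AB` must be corrected for dimers that drew
two same-color labels:

```
AB* = AB / (2 · (A/(A+B)) · (B/(A+B)))          corrected dimer count
rel. co-locomotion = 2 · AB* / (A + B)          fraction of molecules in dimers
```

where `A` and `B` are the single-channel trajectory counts. This package
implements the full chain — channel registration from fiducial beads,
MTT-style localization linking, DBSCAN immobile exclusion, MSD and
two-fraction Brownian step-length mixture mobility analysis,
photobleaching-step counting, per-frame 100 nm co-localization,
co-trajectory reconstruction with a ≥10-step (~320 ms) filter, and the
correction above — plus a seeded simulator that generates two-color
localization streams with full ground truth, so every stage can be
validated without raw movies.

## Worked example

```python
from smcotrack import (SimulationConfig, simulate_membrane,
                       render_localizations, quantify_dimerization)

cfg = SimulationConfig(dimer_fraction=0.3, seed=1)   # 200 receptors, 150 frames @ 32 ms
truth = simulate_membrane(cfg)
table_a, table_b = render_localizations(truth, cfg)
result = quantify_dimerization(table_a, table_b)
print(result.summary())
```

prints

```
A=85 B=98 AB=12 AB*=24.12 rel. co-locomotion=0.2636 (radius 100 nm, >=10 steps)
```

85 and 98 molecules were tracked in the two channels (out of 200
receptors, ~90% labeled, split between the colors), 12 two-color
co-trajectories survived the 10-step filter, and the double-labeling
correction scales them to 24.1 dimers — a relative co-locomotion of
0.26, estimating the true simulated dimer fraction of 0.30 from a single
movie (averaging ~20 movies brings the estimate within ±0.05).

The same analysis is available from the shell:

```bash
smcotrack simulate --out-dir movie --dimer-fraction 0.3 --seed 1
smcotrack cotrack movie/channel_a.csv movie/channel_b.csv --out result.json
smcotrack mobility tracks.csv --out mobility.json     # after `smcotrack track`
```

See `docs/methods.md` for the model, parameter defaults and their
rationale, and known limitations.

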