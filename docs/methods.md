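# Methods

## Scope and model

`smcotrack` quantifies cytokine-receptor dimerization in the plasma
membrane from dual-color single-molecule localization data, together
with a Monte-Carlo generator of the underlying monomer–dimer dynamics.
The measurement principle: receptors are stochastically labeled with one
of two spectrally separable fluorophores, so a receptor dimer carries a
two-color signature with probability `2pq/(p+q)²` among labeled dimers.
Correlated motion of a two-color pair ("co-locomotion") is therefore a
direct readout of dimerization, after correcting for the dimers that —
by chance — carry two same-color labels.

The statistic reported is

```
AB* = AB / (2 · (A/(A+B)) · (B/(A+B)))
rel. co-locomotion = 2 · AB* / (A + B)
```

with `A`, `B` the single-channel trajectory counts, `AB` the observed
co-trajectory count and `AB*` the corrected count. `A/(A+B)` estimates
the labeling fraction `p/(p+q)`; for a fully dimeric, fully detected
sample with balanced labeling the statistic equals 1, and in general it
estimates the fraction of tracked molecules residing in dimers. Values
above 1 can occur through sampling noise and are reported with a
warning, never clipped.

## Synthetic-data generator

The simulator is the package's stand-in for live-cell TIRF movies and
defines the conditions under which the pipeline is validated.

**Dynamics.** `n_receptors` point molecules diffuse in a rectangular ROI
with reflective boundaries (periodic available). Each independent
diffusing unit takes Gaussian steps of SD `√(2·D·Δt)` per axis; a dimer
moves as a single unit at `d_dimer` with its two protomers at identical
positions (intra-dimer distance is far below the 100 nm co-localization
radius, so zero separation loses nothing the analysis could see). Two
modes:

* *static_fraction*: a fixed fraction of molecules is paired at t = 0 —
  an equilibrium snapshot of a (slowly exchanging) dimerizing ligand.
* *kinetic*: monomer pairs within a capture radius `r_c` (default
  100 nm, a simulator knob) associate per frame with probability
  `1 − exp(−k_on·Δt/(π·r_c²))`; dimers dissociate with probability
  `1 − exp(−k_off·Δt)`. Dissociated pairs are placed at contact
  distance and skip association for that frame, which limits (but does
  not remove) geminate-rebinding bias relative to the well-mixed
  mean-field fixed point; the test-suite oracle tolerates this at the
  25% level. Association/dissociation are evaluated once per frame,
  adequate for `k_off ≪ 1/Δt ≈ 30 s⁻¹`.

**Rendering.** Each receptor is assigned species A, B or dark once for
the whole movie with probabilities `(p_label_a, p_label_b, remainder)`.
Per frame, every labeled, unbleached molecule is detected with
probability `detection_eff` at its true position plus isotropic Gaussian
error of SD `sigma_loc_nm`; bleach times are geometric
(`bleach_rate` per frame) and irreversible. Each labeled molecule is an
independent emitter: a same-color double-labeled dimer produces two
overlapping localizations, not one brighter spot. This keeps the
per-molecule trajectory counts that the correction formula assumes; the
cost is that intensity summation and detector-level spot merging of
co-located emitters are not emulated.

**Defaults and what they represent.** 20×20 µm ROI at 0.5
receptors/µm² (200 molecules — a typical sparse single-molecule
regime; surface densities are rarely printed, this one is an editorial
choice), 150 frames at 32 ms/frame, `d_monomer` = 0.1 µm²/s,
`d_dimer` = 0.05 µm²/s (friction roughly doubles for a dimer),
`sigma_loc_nm` = 25 (typical EMCCD single-molecule precision),
`p_label_a = p_label_b` = 0.45 with 10% dark (balanced nanobody
labeling at >90% occupancy), `detection_eff` = 1 and `bleach_rate` = 0
(idealized acquisition — the validation conditions; realistic dropouts
and bleaching are available and exercised in dedicated tests). The
generator does not emulate blinking photophysics, raw pixel images,
spot-detection failures in dense regions, or membrane heterogeneity
(domains, confinement), so passing tests demonstrate correctness of the
analysis chain under Brownian, spatially homogeneous conditions — not
robustness to every artifact of real movies.

## Channel registration

A 2D affine transform (six parameters) is fitted to matched fiducial
bead localizations by linear least squares and maps channel B into
channel A's frame (the direction is a package convention). The fit is
exact on noiseless affine-related sets; its reported residual RMS is
per coordinate, so it converges to the per-axis bead localization noise
SD. Coordinates are nm throughout; pixel input is converted with a
declared pixel size (default 107 nm/px). Nonlinear chromatic
corrections are out of scope.

## Tracking

Distance-gated frame-to-frame linking with gap closing: localizations in
frame f are linked to open tracks within `max_step_nm · √(gap+1)`
(Brownian scaling across detection gaps), with `max_gap` = 1 by default.
The default search radius is `3·√(4·D_max·Δt)` with `D_max` = 0.3 µm²/s,
covering >99% of Brownian steps at plausible membrane mobility.
Assignment is greedy nearest-neighbor by default (order-stable; ties
broken by distance, then localization index) or per-frame optimal via
the Hungarian algorithm, which maximizes the number of links and then
minimizes total squared distance. Unlinked localizations seed new
(possibly singleton) tracks, so localizations are conserved. Full
probabilistic multi-hypothesis reconnection (blinking-aware scoring) is
deliberately omitted; in the sparse regime the distance gate dominates.
Trajectories with fewer than 10 steps (~320 ms at 32 ms/frame) are
discarded before any downstream statistic.

## Mobility

* **MSD**: time-averaged per track, pooled across tracks weighted by
  pair counts; lags spanning a detection gap are excluded. The
  diffusion constant is the slope/4 of an ordinary least-squares line
  over lags 2–10; the intercept is reported and absorbs the static
  localization-error offset `4σ²`. Negative slopes are flagged, not
  silently clipped.
* **Step-length mixture**: two-fraction mixture of 2D Brownian
  (Rayleigh-form) step-length densities,
  `p(r) = Σ_k α_k · r/(2D_kΔt) · exp(−r²/4D_kΔt)`, fitted by EM with
  closed-form M-steps, 5 seeded restarts, tolerance 1e−8 on the
  log-likelihood, max 500 iterations. The log-likelihood is asserted
  monotone every iteration. Components closer than 5% in D are declared
  unidentifiable (the weight carries no information) and a warning is
  raised. Steps from both channels are pooled by default.
* **Immobile exclusion**: DBSCAN (`eps` = 50 nm ≈ 2× localization
  precision, `min_samples` = 5) on each track's own localizations; a
  track is immobile when ≥80% of its points fall into one cluster.
  Immobile tracks are excluded from mobility statistics and from
  co-tracking.
* **Bleach-step counting**: optimal piecewise-constant segmentation by
  dynamic programming with a per-change-point penalty of `3σ²·log n`
  (σ from the median absolute deviation of first differences; minimum
  segment 3 frames); the count of downward level changes is the
  stoichiometry readout (a dimer bleaches in two steps).

## Co-tracking

Per frame, localizations detected in both channels within 100 nm are
paired one-to-one (maximum pair count, then minimum total distance).
Pair midpoints — symmetric in the channels — are linked with the same
single-channel linker, and co-trajectories shorter than 10 steps are
discarded; this length filter is the (only) chance-coincidence control,
since two independent walkers rarely stay within 100 nm for 320 ms. A
co-trajectory is identified by its constituent track pair, so fragments
created by a brief excursion beyond the radius are counted once. `A`
and `B` are counted after the same immobile-exclusion and minimum-steps
filters as `AB`, keeping numerator and denominator commensurate (both
choices are configurable). An optional frame-scrambled chance baseline
was considered and left out: the length filter alone suppresses the
all-monomer control to rel ≈ 0 at the default density.

## Validation conditions and problem sizes

The test-suite and the acceptance script validate, per run: the
correction identity on 10⁶ labeled dimer pairs (recovery within 1%);
end-to-end recovery of a 0.30 dimer fraction within ±0.05 over 20
simulated movies, with an all-monomer control below 0.02; strict
ordering of mean rel. co-locomotion across a five-condition affinity
series (true fractions 0.5, 0.45, 0.15, 0.05, 0 — mimicking a
high-to-no-affinity ligand panel) over 20 movies per condition; MSD
recovery of D = 0.1 µm²/s within 10% and of the 4σ² intercept within
15% from ~500 tracked molecules; mixture recovery of (α = 0.7,
D = 0.15/0.02 µm²/s) within ±0.1 and 20% from 10⁴ steps; and ≥95%
single-step detection at SNR 5 over 200 replicates. These sizes were
chosen to bring Monte-Carlo error comfortably below the stated
tolerances while keeping a full run around a minute on one core.

## Known limitations

* The kinetic mode's contact-placement rule after dissociation is a
  discretization convenience; apparent dwell times are mildly biased by
  residual geminate rebinding at high `k_on`.
* Same-color co-located emitters are rendered as two localizations; in
  a real detector they form one brighter spot, which would reduce `A`
  and `B` counts for same-color dimers and push rel. co-locomotion
  above 1 for fully dimeric samples.
* The relative co-locomotion estimator assumes both channels' labeling
  efficiencies are estimable from the trajectory counts themselves;
  strong channel-specific detection differences bias `p̂`.
* No anomalous-diffusion exponents, hidden-state segmentation, blinking
  model, or oligomers beyond dimers.
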