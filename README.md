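# teamsync

Intra-team movement synchronization and time-motion analysis from player
GPS tracking.

## The problem

In team sports, performance analysis from positional tracking usually
stops at time-motion demands: how far each player ran, and at which
intensities. But a team is a coordinated system — pairs of teammates
(*dyads*) continuously adjust their movements relative to each other.
`teamsync` quantifies both sides from the same raw 5 Hz GPS logs:

- **Time-motion**: total distance and distance per speed category
  (low < 3.6, moderate < 14.4, high < 19.8, very high ≥ 19.8 km·h⁻¹).
- **Dyadic synchronization**: for every pair of outfield players (45 pairs
  for 10 players) and each pitch axis, the instantaneous phase of each
  player's displacement is extracted with the Hilbert transform, and
  synchronization is summarized as the percentage of time the wrapped
  relative phase φ_A − φ_B stays in the near-in-phase band [−30°, 30°] —
  overall and stratified by the dyad's average speed category.
- **Structure and context**: k-means groups dyads into higher /
  intermediate / lower synchronization levels per axis, and one-way ANOVA
  (partial η², Fisher's LSD, Cohen's *d* with 95% CI) compares outcomes
  across opposition levels (first league / second league / amateur).

Because real match recordings are rarely shareable, the package includes a
first-class synthetic match generator: players are phase-coupled
oscillators around role anchors, with per-axis phase offsets drawn from a
von Mises(0, κ) distribution. κ is the coupling knob — large κ forces
in-phase movement, κ = 0 scatters phases uniformly — and every imposed
offset is recorded as ground truth, so the entire chain is testable with
known answers.

## Processing chain

raw lat/lon logs → shared 5 Hz time base (gap interpolation, flagged) →
UTM metres → rotation by the pitch angle θ fitted from the four field
vertices (x = longitudinal, y = lateral) → zero-phase Butterworth
smoothing → speeds/distances, phases, dyad statistics, clusters, group
comparisons.

## Worked example

```python
from teamsync import SimulationConfig, run_all

res = run_all(SimulationConfig(duration=1350.0), seed=6, matches_per_level=2)
a = res.anova["sync_overall_x"]
print(f"F({a.df_between}, {a.df_within}) = {a.F:.2f}, eta2 = {a.partial_eta_sq:.3f}")
```

Running `python examples/06_opposition_stats.py` (the same study) prints:

```
mean near-in-phase % by level and axis:
axis                 x     y
opposition_level
amateur           29.6  28.5
first_league      89.2  91.6
second_league     79.8  82.0

ANOVA (sync, overall):
  x: F(2, 267) = 93.08, p = 2.14e-31, partial eta^2 = 0.411
  y: F(2, 267) = 153.21, p = 4.83e-45, partial eta^2 = 0.534
```

Reading: with the opposition-dependent coupling presets (κ = 32 / 8 / 2
for first league / second league / amateur), the team spends far more time
near in-phase against the simulated stronger opponent; the ANOVA error df
of 267 reflects 45 dyads × 6 matches in 3 groups. The other scripts in
`examples/` each demonstrate one capability (simulation, preprocessing,
time-motion, phase analysis, clustering).

A `teamsync` console command exposes the same stages for shell use
(`simulate`, `preprocess`, `timemotion`, `sync`, `cluster`, `stats`,
`run-all`); see `teamsync --help`.

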