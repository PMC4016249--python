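"""Dyadic near-in-phase synchronization and its recovery of ground truth.

Each player's x (or y) series is Hilbert-transformed to an instantaneous
phase; a dyad's synchronization is the percentage of samples whose wrapped
phase difference lies within +/-30 degrees. Dyads whose imposed offset is
inside the band should score near 100%, those outside near 0%.
"""

import numpy as np

from teamsync import (
    SimulationConfig,
    compute_dyad_sync,
    generate_field_vertices,
    generate_match,
    preprocess_match,
)

cfg = SimulationConfig(duration=600.0, kappa_x=2.0, kappa_y=2.0,
                       noise_sd=0.0, drift_speed=0.0, gap_fraction=0.0, seed=4)
logs, truth = generate_match(cfg, "amateur")
trajs, _ = preprocess_match(logs, generate_field_vertices(cfg))
records = [r for r in compute_dyad_sync(trajs) if r.axis == "x"]

print(f"{'dyad':12s} {'imposed offset':>14s} {'% in [-30, 30]':>15s}")
for r in sorted(records, key=lambda r: abs(truth.dyad_offsets_deg["x"][r.dyad]))[:6]:
    off = truth.dyad_offsets_deg["x"][r.dyad]
    print(f"{r.dyad[0]}-{r.dyad[1]:6s} {off:13.1f}d {r.pct_in_phase_overall:14.1f}%")
print("...")
for r in sorted(records, key=lambda r: -abs(truth.dyad_offsets_deg["x"][r.dyad]))[:3]:
    off = truth.dyad_offsets_deg["x"][r.dyad]
    print(f"{r.dyad[0]}-{r.dyad[1]:6s} {off:13.1f}d {r.pct_in_phase_overall:14.1f}%")

pcts = np.array([r.pct_in_phase_overall for r in records])
print(f"\nteam mean near-in-phase (x axis): {pcts.mean():.1f}% over {len(records)} dyads")
# Small imposed offsets -> ~100%, large ones -> ~0%: the band statistic
# reads the imposed phase structure straight off the trajectories.
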