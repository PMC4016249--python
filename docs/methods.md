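# Methods

## Scope

`teamsync` implements a pipeline for intra-team coordination analysis from
player tracking: GPS preprocessing, time-motion metrics, Hilbert-transform
dyadic relative phase with a near-in-phase band statistic, k-means
grouping of dyads, and opposition-level group statistics — together with a
synthetic match generator that provides ground truth for all of it.

## Synthetic match model

Player *i*'s pitch-frame position is

x_i(t) = a_i^x + D_x(t) + A_x sin(2π t / T_x + φ_i^x) + ε,
y_i(t) = a_i^y + D_y(t) + A_y sin(2π t / T_y + φ_i^y) + ε,

where (a_i^x, a_i^y) is a role anchor (a nominal 4–4–2: four defenders,
four midfielders, two forwards), D(t) is a slow drift shared by the whole
team, modelled as uniform circular motion so its speed is exactly the
configured `drift_speed`, the sinusoids are the team's shared oscillation
per axis, φ_i ~ von Mises(0, κ_axis) is the player's phase offset, and ε
is i.i.d. Gaussian jitter. Positions are rotated by the pitch angle,
georeferenced by inverting the UTM projection about the configured pitch
centre, and a fraction of interior samples is deleted to emulate GPS
dropouts. All randomness flows from one seed; identical configs produce
byte-identical logs.

This is a deliberately stylised model: the movement law is an implementer
construct chosen so that (a) relative phase between any two players is a
known constant per axis, (b) coupling strength is a single interpretable
parameter κ, and (c) instantaneous speeds sweep through all four intensity
categories every oscillation period. It is **not** a model of soccer
tactics: there is no ball, no opponent, and no role-dependent movement
beyond the anchors.

### Defaults and what they mean

| parameter | default | rationale |
|---|---|---|
| `n_players` | 10 | outfield players of one 11-a-side team; yields 45 dyads |
| `duration` | 2700 s | one half |
| `sample_rate` | 5 Hz | common GPS unit rate |
| field | 105 × 68 m | standard full-size pitch |
| `osc_amp_x`, `osc_amp_y` | 15 m, 8 m | longitudinal swings larger than lateral; with the periods below, speeds span all four categories |
| `base_period_x`, `base_period_y` | 20 s, 15 s | collective attack–defence swing timescales; distinct per axis so the two axes are independent oscillations |
| `drift_speed`, `drift_period` | 0.3 m/s, 120 s | slow shared wander (loop radius ≈ 5.7 m) that keeps the team inside the pitch |
| `noise_sd` | 0.3 m | positional jitter of consumer-grade GPS after light smoothing |
| `gap_fraction` | 0 (study runs use 0–0.1) | dropout emulation; interior-only so endpoints anchor interpolation |
| κ presets | first 32, second 8, amateur 2 | stronger opposition ⇒ tighter in-phase coupling; von Mises sd ≈ 10°, 20°, 43° respectively. Overridable via `kappa_x`/`kappa_y` |

Two realism caveats follow from (c) above. First, a sinusoid spends most
of its period at moderate-to-high speed, so simulated per-half distances
(~2.5 km per 600 s) exceed what real players cover in a half; the
generator targets the *statistical structure* the pipeline measures
(phase relations, category coverage, group differences), not realistic
energy expenditure. Second, speeds are smooth and periodic rather than
intermittent sprint-like bursts. Passing tests therefore demonstrate
correctness of the measurement chain on known structure, not validity of
any movement model for real match data.

## Preprocessing

1. **Synchronization/interpolation.** All players are resampled onto one
   uniform grid at the nominal rate over the *intersection* of their time
   coverage (the dyadic statistics need simultaneous samples;
   extrapolation is never performed). Gaps are filled by linear
   interpolation of each coordinate — the simplest defensible choice at
   5 Hz — and filled samples are flagged in `valid_mask` so sensitivity
   remains auditable.
2. **Projection.** WGS84 lat/lon → UTM metres via a 6th-order Krüger
   series (sub-millimetre truncation error within a zone; forward and
   inverse mutually consistent to ~1e-14°). A batch spanning two UTM
   zones raises an error naming both zones rather than silently mixing
   frames.
3. **Pitch alignment.** The pitch angle θ is the direction of the longer
   side pair of the four projected field vertices (perimeter order,
   directions averaged on the half-circle), reduced mod 180°. Positions
   are rotated by −θ about the field centroid, so x runs goal-to-goal and
   y across the pitch. The mod-180 reduction means the attacking
   direction is not encoded; a global axis sign flip applied to all
   players changes no downstream statistic (distances and relative phase
   are invariant).
4. **Smoothing.** Zero-phase (forward–backward) 2nd-order Butterworth —
   the de-facto standard in movement science; the dual pass doubles the
   effective order and cancels phase lag. The conventional 3 Hz cutoff
   is not realizable at a 5 Hz sampling rate (Nyquist 2.5 Hz), so any
   cutoff ≥ Nyquist is clamped to 0.99 × Nyquist with a warning. The
   cutoff is a parameter, not a constant, precisely because this
   convention is ambiguous at low sample rates. The clamped filter's
   poles sit near the unit circle, so its edge transient decays slowly
   (~0.978ⁿ); accuracy tests evaluate the mid-series and the pipeline
   reports whole-series outputs unmodified.

## Time-motion

Speed at sample *i* is the planar displacement from sample *i−1* times
the rate (first sample replicates the second). Each displacement is
credited to the intensity category of the arriving sample's speed, so
category distances partition the total exactly. The published category
bounds leave 0.1 km/h gaps (3.5–3.6, 19.7–19.8); since speed is
continuous these are treated as rounding artifacts and implemented as
contiguous half-open bins with edges 3.6 / 14.4 / 19.8 km/h. Speeds are
computed after smoothing (differentiating raw 5 Hz GPS amplifies noise).
No dwell-time minimum is applied: classification is per sample.

## Phase synchronization

The signal fed to the analytic-signal (Hilbert) transform is the
pitch-aligned coordinate per axis, centred by subtracting its own series
mean over the analysed half; an optional moving-average detrend is
available for data with strong slow drift, but is off by default. Phase
is the angle of the analytic signal, wrapped to (−180°, 180°]. Relative
phase is the wrapped difference with a canonical (lexicographic) dyad
ordering fixing the sign. The synchronization statistic is the percentage
of samples in the closed band [−30°, 30°].

Speed stratification uses the *per-sample* mean of the two players'
speeds: each sample of a dyad's relative-phase series belongs to the
category of the dyad's average speed at that sample. (The alternative —
assigning each dyad one category by its match-average speed — would
collapse most dyads into one bin and leave the stratified statistics
degenerate.) Per-category percentages are relative to that category's
sample count, so the count-weighted mean of category percentages
recombines exactly to the overall percentage.

No samples are discarded for transform edge effects in reported outputs
(percentages describe the whole half); accuracy tests exclude the first
and last few seconds instead.

Degenerate input (a constant, zero-variance series) has no defined phase
and raises an explicit error.

## Dyad clustering

Feature: each dyad's overall sync percentage averaged over matches, per
axis (dyads are clustered, not dyad × match records; axes run
independently). K-means with k = 3 and 50 k-means++ restarts; groups are
ranked by centroid as higher / intermediate / lower. On 1-D data of ≤ 45
points the restarted solution attains the exact optimum found by a
dynamic-programming oracle (verified in tests; the DP is a test oracle
only, keeping k-means as the production method). Fewer than k distinct
values is an error, as is any empty cluster.

## Group statistics

One-way fixed-effects ANOVA per outcome across opposition levels, with
partial η² = SS_effect/(SS_effect + SS_error) (equal to plain η² in a
one-way design and to F·df_b/(F·df_b + df_w), an identity the tests
exercise). Pairwise comparisons are Fisher's LSD — unadjusted t-tests on
the pooled MS_error with the ANOVA's error df. Cohen's d uses the pooled
SD and the large-sample CI d ± 1.96·se with
se = √((n_a+n_b)/(n_a·n_b) + d²/(2(n_a+n_b−2))). Pairs are ordered with
the stronger opposition level first, so positive d means the outcome was
larger against the stronger opponent.

Unit of analysis: dyad × match for synchronization outcomes (45 × 6 = 270
observations; error df 267) and player × match for time-motion (10 × 6 =
60; error df 57). Treating the same dyad in different matches as
independent observations is a statistical caveat inherited from this
design: a mixed-effects re-analysis with dyad random effects would be the
stricter treatment and is deliberately out of scope.

## Numerical choices

- θ is averaged on the half-circle by doubling angles; values within
  1e-9° of 180 wrap to 0.
- Band endpoints are inclusive; wrapped angles live in (−180, 180] with
  −180 mapped to 180.
- An empty speed-category stratum yields a missing percentage (NaN) with
  count 0, and is dropped from group comparisons for that stratum.
- K-means ties and initialisation are controlled by an explicit seed; the
  study seed also derives per-match child seeds via `SeedSequence`, all
  below 2³¹.

## Problem sizes used in validation

The test suite exercises full-length halves only where the statistic
needs them; most tests use 120–600 s halves, which leave every per-axis
oscillation with ≥ 8 full periods and do not change any of the invariants
being checked. The coupling-recovery study uses 30 matches per κ ∈
{0, 2, 8, 32} at 600 s; the end-to-end acceptance run uses the full
default design (2700 s halves). The whole suite runs in well under five
minutes on one CPU.

## Known limitations

- The movement model is a coupled-oscillator construct; no claim is made
  that real players follow it (see the caveats above).
- Relative phase of two *different-frequency* signals is not constant;
  the generator imposes a shared frequency per axis, and real data where
  players oscillate at different tempos will show drifting relative
  phase, correctly reflected as low band occupancy.
- The LSD procedure does not control the family-wise error rate; it is
  provided as the conventional companion to the one-way ANOVA here.
- No GPS quality filtering (HDOP, satellite counts, spike rejection)
  beyond the low-pass filter.
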