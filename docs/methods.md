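# Methods

This note records the models, conventions and numerical choices behind the
package, and what the synthetic-data tests do and do not demonstrate.

## Region model and the permeation counter

The simulation box is divided along the pore axis into four regions by three
per-frame planes: the SF entrance `z_lower` (mean z of a configurable
"lower" landmark group, by default the oxygens flooring the lowest binding
site), the SF exit `z_upper` (top carbonyl layer), and their arithmetic mean
`z_mid`. Region assignment uses half-open intervals, lower bound inclusive,
so it is a total, deterministic function of z; a particle exactly on `z_mid`
is in region 3, exactly on `z_upper` in region 4.

An outward permeation event is a completed sequential traversal 1→2→3→4;
inward is the mirror. Particles first observed inside the SF (regions 2/3)
are not counted until they reach a terminal region. The counter is a
per-particle checkpoint automaton with *exclusive arming*: visiting region 1
arms the particle for outward counting and resets its checkpoints; visiting
region 4 arms it inward. While armed outward the checkpoints advance on
visits to 2 then 3 in order, and the first subsequent arrival in region 4
completes one event (attributed to that frame) and re-arms the particle from
region 4. Any terminal-region visit therefore breaks an in-progress passage
in the other direction. This choice — rather than letting a passage survive
a premature touch of the destination region — is forced by net-flux
bookkeeping: it is the unique variant that makes the counter exactly
antisymmetric under time reversal (reversing a region series swaps outward
and inward counts), which the property suite verifies along with exact
agreement against an independently written brute-force oracle.

Two estimator properties are documented rather than corrected: fast
recrossings between saved frames are invisible (frame-stride aliasing), and
coordinates are unwrapped at load so a periodic-image wrap can never mimic
a 1→4 teleport.

## Conductance and selectivity

`G = N_net · e / (t · |V|)` with the elementary charge at its 2019 SI exact
value; for negative-voltage runs the inward conductance is the negative of
the net-outward-based value. Replica averages carry Student-t 95% CIs
(`t(0.975, n−1)·s/√n`, sample SD); a single replica yields a mean with the
CI flagged undefined. Both the replica mean and the pooled estimate (total
net events over total time) are reported: the CI needs per-replica values,
while headline single numbers in the literature are pooled. `P_Na/P_K`
defaults to the ratio of replica-mean conductances from single-ion runs,
with a pooled count-ratio variant for strongly unequal durations — the two
differ when durations differ, which is why the method tag is recorded.

## Site occupancy and configurations

Binding sites are axial intervals. By default the SF span `[z_lower,
z_upper]` is split into four equal sites S4..S1, with a cavity site below
and S0 above; an alternative builder places the inter-site planes at the
coordinating-oxygen layer means (each site spans the gap between adjacent
layers), for use with MD landmarks. A site's occupant is the particle whose
z lies in the interval and within `radial_cutoff` (default 0.35 nm) of the
pore axis when in-plane coordinates exist; ions beat water, then
nearest-to-center, then particle id — a stable, reproducible tie-break.
Configuration strings read S1→S4 over {K, N, W, 0}; 'N' and '0' extend the
classic {K, W} alphabet so sodium runs and vacancies are expressible.
Transitions where an ion's site index changes by ≥2 in one frame interval
are classified `DIRECT_JUMP` (the KW**K**W → **K**WKW jumps seen when the
intermediate configuration is shorter-lived than the frame spacing);
all-particles-move-≤1-site changes are `STEPWISE`; the rest `OTHER`.
Density profiles histogram `z − z_lower` pooled frame-weighted over
replicas and normalize so the profile integrates to the mean per-frame
occupancy of the window.

## Flip model

A subunit is flipped when its N–CA–C–O dihedral lies in the closed window
[−130°, −50°] (angles on the (−180°, 180°] branch; closed ends are a
measure-zero convention fixed for determinism). Flip events are maximal
flipped runs; `min_duration` defaults to 1 frame — no debouncing or
smoothing is applied. The causality analysis tags an event water-first iff
S2 or S3 holds water in any of the `lookback` frames before onset; lookback
defaults to 1 frame as the most literal reading of "water already present",
and is exposed as a parameter precisely because longer windows change the
fraction for marginal events. Events with onset at frame 0 have no lookback
window and are excluded (reported separately); edge-truncated events keep
their tag but are excluded from duration statistics.

## The kinetic Monte Carlo generator

The generator is a continuous-time Markov chain over a single-file,
four-site column between two reservoirs, sampled exactly with the Gillespie
algorithm and only afterwards discretized to frames, so the ground truth is
independent of `dt`. Concerted column shifts insert a particle at one end,
advance every occupant one site and expel the occupant at the far end;
forward and backward shifts have rates `k` and `k/voltage_bias`.

* `DIRECT`: an all-ion column; one forward shift permeates one ion and
  water can never enter the SF, so the water-event count is zero by
  construction.
* `SOFT`: an alternating ion/water column. One knock-on cycle is two
  half-shifts — ion in/ion out, then water in/water out — separated by an
  exponential dwell in the intermediate (WKWK-like) configuration with decay
  rate twice the cycle rate, so the resting configuration dominates the
  census but the intermediate is visibly populated (the worked example shows
  0.69/0.31). Cycles are atomic: one begun but not completable before the
  trajectory end is discarded. Each completed cycle co-permeates exactly one
  ion and one water, so the ground-truth water:ion ratio of counted events
  is exactly 1.

Defaults emulate a high-current noninactivating channel at +300 mV:
`hop_rate` 49.4 cycles/µs (≈ 494 net events in 10 µs), `voltage_bias` 50
(backward shifts at 2% of forward). Sodium is a rate-scaled species
(entries thinned to 2% of the K⁺ rate) — enough to exercise the selectivity
estimators, with no energetic realism claimed. Occupants are emitted at
`site center + N(0, 0.05 nm)` truncated to lie strictly inside the site
interval, so site re-assignment from coordinates is exact by construction;
reservoir particles perform reflected random walks in slabs strictly inside
regions 1 and 4. Flip dynamics are a per-subunit two-state Markov chain
whose flip-on hazard is gated on water occupying S2/S3 in the previous
frame (`water_triggered`), ungated (`spontaneous`) or off; in the
water-triggered model every flip onset is, by construction, preceded by
water in S2/S3, which the causality analysis must recover as a water-first
fraction of 1. All randomness derives from one root seed through named
child streams; identical seeds give bit-identical output.

The analytic expectation of the permeation *counter* subtracts the initial
column occupants (4 ions in DIRECT; 2 ions + 2 waters in SOFT) from the raw
net-crossing expectation `(k − k/bias)·duration`, because the counter never
counts particles that start inside the SF. This is exact renewal
bookkeeping; both the raw and the counter expectation are exposed.

**What the generator does not emulate.** Real MD trajectories have
continuous ion motion, fluctuating boundaries, off-axis excursions, mixed
and partially occupied configurations, conformational changes of the filter
itself, and flip kinetics coupled to structure rather than to a two-state
hazard. Passing the recovery tests therefore shows that the analysis stack
measures what it claims on data whose truth is known — not that any real
channel conducts at these rates or with these censuses.

## Problem sizes and numerical choices

Test and acceptance runs use 1–2 µs of synthetic trajectory at 0.25–1 ns
frame spacing (4,001–8,001 frames, roughly 50–500 events) — large enough
for Poisson intervals to be meaningful, small enough to run in seconds.
Exact ground-truth recovery holds when the frame spacing is well below the
mean event waiting time (here 20 ns); the recovery tests use dt at 1/80 to
1/20 of it. Census fractions sum to 1 to 1e−12 by construction; conductance
arithmetic is closed-form; the Student-t shrinkage check compares replicated
samples at n = 40 vs 160, where the t-quantile is flat enough for the pure
1/√n law to show within 10%. Degenerate inputs are contracts, not crashes:
zero voltage, empty replica sets, inverted boundary planes and unknown
configuration keys all raise typed errors before any stage runs.

## Known limitations

* The counter's micro-behaviour on pathological strided sequences (e.g. a
  passage touching the destination region before completing) follows the
  antisymmetry-preserving convention above; other published scripts may
  count such sequences differently, and the difference only matters when
  the frame stride approaches the crossing time.
* Published selectivity ratios quoted with uncertainties cannot be
  reconstructed from in-text event counts alone (run durations of the
  sodium simulations are not all public); the package therefore reports its
  count-arithmetic estimate and records the method tag instead of asserting
  agreement.
* Density profiles, per-construct flip censuses and SF-width effects from
  real MD depend on force field and sampling; the synthetic suite checks
  the estimators' internal consistency, not those absolute values.
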