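# Methods

## The transport model

Each neurofilament is a rigid 1-D segment of length `filament_length`
(default 7.5 µm, the middle of the 5–10 µm range measured in culture) whose
leading edge follows a six-state continuous-time Markov chain:

```
ANTERO_RUN  <->  ANTERO_PAUSE_ON  <->  ANTERO_PAUSE_OFF
                       ^
                       |  (reversal)
                       v
RETRO_RUN   <->  RETRO_PAUSE_ON   <->  RETRO_PAUSE_OFF
```

Only the RUN states displace the filament (+`v_a` anterograde, −`v_r`
retrograde). Transitions are RUN ↔ PAUSE_ON and PAUSE_ON ↔ PAUSE_OFF within
a direction, and reversal between the two PAUSE_ON states. This topology is
a tree, so the stationary distribution satisfies detailed balance on every
edge; in particular the ratio of anterograde to retrograde occupancy equals
the ratio of the two reversal rates, which is what sets the directional
bias. Reversals directly between RUN states are not modeled; with reversal
far rarer than the run/pause cycle the distinction is not identifiable from
ensemble fluorescence, and the PAUSE_ON-mediated topology keeps the bias a
single closed-form ratio. The stationary distribution is computed from the
null space of the generator restricted to the (unique) recurrent class; a
chain with several absorbing sets (e.g. both reversal rates zero) raises an
explicit error naming them.

Simulation is exact event-driven (Gillespie) sampling: exponential waiting
times at each state's total exit rate, successor states from the embedded
jump chain, positions interpolated analytically between events. There is no
time-step discretization anywhere.

### Default rates and what they mean

| parameter | default | meaning |
|---|---|---|
| `v_a`, `v_r` | 0.5 µm/s | bout speed, both directions |
| `rate_run_to_pause_on` | 0.2 /s | bouts last ~5 s (~2.5 µm) |
| `rate_pause_on_to_run` | 0.0075 /s | on-track pauses mobilize slowly |
| `rate_on_to_off` | 0.04 /s | on-track pauses last ~20 s before disengaging |
| `rate_off_to_on` | 0.004 /s | off-track pauses ~4 min |
| `rate_reverse_a_to_r` | 0.002 /s | ~4% of on-track pause exits reverse |
| `rate_reverse_r_to_a` | 0.003 /s | asymmetry gives p_a/p_r = 1.5 (60% anterograde) |

These rates are a calibration, not a measurement: the constants of the
six-state model are not directly measurable in nerve. They were chosen once
so that the model reproduces the observed *measurement regime* of mature
myelinated axons: ~99.7% of filaments pausing at any instant, a distal flank
slope of S_d ≈ 0.15% of F_c(0) per minute for a 40-µm window (≈0.6% of the
activated fluorescence in a 15-µm distal window at 4 min), a 60/40
anterograde/retrograde split, a population velocity of ~0.03 mm/d, 4-min
flank series that are linear, and near-complete capture of the 4-min flux
by a 15-µm window.

Two deliberate departures from a literal reading of the biology are worth
recording. First, off-track pauses in the model last minutes, not the
"hour or more" often quoted from culture work. Hour-scale off-track pauses
starve the moving pool at the window boundary faster than it is replenished,
which makes the flank rise sag several percent below the `p·v/a` prediction
over a 4-min fit — contradicting the maintained linearity on which the
method rests. Minutes-scale off↔on exchange keeps the boundary population
at local equilibrium, and the measured slope then equals the model flux to
~1%. Second, reversal rates are kept small relative to all other pause
exits: frequent reversals let filaments re-cross the window boundary within
the fit interval, biasing the net slopes well below the gross fluxes (~25%
at reversal rates only 6× the default).

`KineticParameters.motile_demo()` is a second, culture-like parameter set
(frequent mobilization, fast off↔on exchange) kept for qualitative
demonstrations: with it the central window loses most of its mobile pool
within tens of minutes and the flanking-window fluorescence shows the full
rise / plateau / decline within an hour, with small windows peaking first.
The slow in-vivo defaults cannot show that decline inside 60 min and no
single rate set can: a flank that holds ~0.5% of F_c(0) at 4 min implies a
central loss rate of ~0.25%/min, so the central reservoir still holds ≳85%
of its fluorescence at 60 min and keeps feeding the flanks. The two regimes
bracket what passing tests show about real data: slope recovery and
corrections are validated in the in-vivo-like regime, the long-time shape
of the flank kinetics in the motile regime.

## Pulse-spread observables

Labeling: photoactivation marks the part of each filament inside the
central window `[0, a]` (`a` = 40 µm). Leading edges are placed uniformly on
`[0, a + L]`, and each filament carries the label of its overlap with the
window, which makes the labeled polymer mass *exactly* uniform over the
window — filaments straddling an edge are partially labeled. A `midpoint`
toggle labels whole filaments whose midpoint falls inside instead (the
documented simplification; it slightly blurs the initial edge). A window's
fluorescence is the summed overlap length of labeled segments with the
window; everything is normalized to the central window's initial content.
Mass is conserved identically; a simulation in which any labeled segment
reaches the domain boundary sets a `boundary_escape` flag, and the default
domain margin (60 µm + 2 filament lengths per side) keeps escapes out of
the 10-min protocol.

Measurement protocol (defaults following the experimental design): frames
every 30 s; the analysis clock starts after the ~1-min post-activation
dark-state relaxation of paGFP and frames before it are discarded; slopes
are ordinary least squares over the first 4 min (9 frames); the flanking
window for scalar results is 15 µm. The regression includes an intercept:
residual dark-state relaxation and background-subtraction error land in the
intercept rather than the slope. Negative fitted slopes are retained (they
occur with noise); axons whose total flux S_d + S_p is ≤ 0 are excluded
from percentage summaries (with a logged count) but kept in flux and
velocity summaries. Group summaries follow the population-average
convention: group-mean S_p and S_d are computed first and the group velocity
and percent anterograde are derived from those means, not averaged over
per-axon ratios (the two differ on heterogeneous groups).

Units: slopes are fractions of F_c(0) per minute internally (percent in
printed tables); `v̄ = a(S_d − S_p)` in µm/min is converted to mm/d
(×1440/1000).

## Synthetic imaging and corrections

Rendering emulates the appearance of photoactivated axons in nerve: one
axon per horizontal band separated by dark gaps (myelin), the activation
window a vertical stripe, pixel intensity
`flat · (e^(−γt) · signal + background) + dark + noise` with Poisson shot
noise on the photon terms and Gaussian read noise, written as 16-bit
unsigned with clipping treated as an error. Calibration frames follow the
experimental recipes: the dark field is the average of 100 zero-exposure
frames; the flat field images a uniform fluorescein layer through the same
vignette. Apparent axon diameters are drawn uniformly from 0.995–6.046 µm
(the observed range) and are metadata only — the generator does not couple
kinetics to diameter, so diameter correlations in synthetic data are null
by construction. The camera gain and noise amplitudes are package choices
(no published values exist); the dark-state relaxation term is off by
default because the protocol discards the first minute.

Corrections: `corrected = (raw − dark) / g` with
`g = (flat − dark)/mean(flat − dark)`, so a uniform scene keeps its mean.
The photobleach rate is fit from glycolytically inhibited (transport-frozen)
control axons, in which all central-window decay is bleaching: a pooled fit
of one shared γ with per-axon amplitude, log-domain closed form by default
(nonlinear least squares available), matching the pooled description of the
experimental fit; per-axon mode exists behind a flag. Background handling:
each window's preactivation sum is subtracted from that window's
post-activation sums before normalization (the experiment acquires a
preactivation image; the subtraction rule is this package's documented
choice). A negative fitted γ (rising controls) warns and clips to zero.

## Window-size extrapolation

The 4-min fluorescence captured by a flank of length `b` follows
`F(b) = F_total(1 − e^(−βb))` empirically. The fit is nonlinear least
squares constrained through the origin with both parameters bounded
nonnegative and multi-start initialization (β ∈ {0.05, 0.1, 0.3}/µm) to
avoid local minima; non-increasing data whose best plateau is ≤ 0 are
flagged degenerate rather than extrapolated silently. The fluorescence used
at each `b` is the 4-min value implied by the fitted slope (slope × 4 min),
not the raw 4-min frame — a deliberate choice to suppress single-frame
noise. Fits are performed on group-mean curves (population averages);
per-axon fitting exists but is noisy. Dividing the plateau by the fit time
gives the infinite-window slopes, from which velocity and directionality
follow as usual. Directionality, a ratio of slopes, is much less sensitive
to window size than velocity, a difference of slopes.

## Statistics

Per-axon results are treated as independent replicates. Shapiro–Wilk
screens each group (n < 3 or constant groups are flagged, not tested);
group comparisons use Kruskal–Wallis with post hoc two-sided Mann–Whitney
tests, Benjamini–Hochberg-adjusted within each measure family (fluxes,
velocities, diameters); the anterograde bias is a two-sided Wilcoxon
signed-rank test against 50%; diameter relationships use Pearson r with an
OLS slope and 95% CI. Exact small-sample p-values are used when n ≤ 25 with
no ties, the tie-corrected normal approximation otherwise (the experimental
reports do not specify; exact-when-possible is this package's choice).
All-tied omnibus input returns H = 0, p = 1.

## Numerical choices and problem sizes

- Stationary solve: bordered least-squares system on the recurrent class;
  occupancies clipped at 0 and renormalized (guard against −1e-18 round-off).
- Slope SEs come from the OLS fit; Monte-Carlo SEs in tests come from
  batch means (10 batches), keeping the oracle independent of the estimator.
- Simulated cohorts use 5,000 filaments per axon — the realistic polymer
  count for a 40-µm window of a ~3-µm axon (~1,000 filaments per
  cross-section, mean length 7.5 µm) — so per-axon slope scatter matches
  the few-tens-of-moving-filaments sampling regime of the real experiment;
  group means over 70 axons (the cohort size of the experimental design)
  then recover the generating fluxes to a few percent.
- Consistency checks against the closed forms use 60-µm flanks (complete
  capture); the scalar protocol default remains 15 µm.
- The bleach-rate fit uses 17 control axons, the inhibited-cohort size of
  the experimental design.

## Known limitations

- Filaments are rigid segments: no folding, severing, annealing, or
  length dynamics; "filament length" only sets label geometry and edge
  effects.
- 1-D transport: no track occupancy, motor mechanics, or axon geometry
  beyond a diameter label; rendered axons are straight horizontal bands.
- The generator does not couple kinetics to diameter, age, or position, so
  cross-axon biological covariance structure (and hence realistic diameter
  correlations) is absent from synthetic data.
- The six-state rate constants are calibrated, not fitted to data; absolute
  simulated fluxes are illustrative even though the estimator pipeline
  around them is fully tested.
- No analytical form is claimed for the window-size saturation law; it is
  an empirical description of the simulated capture curves.
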