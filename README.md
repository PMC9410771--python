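# pulsespread

Analysis of **pulse-spread fluorescence photoactivation** experiments:
measuring the directionality and population velocity of slow axonal transport
— specifically neurofilament transport in myelinated peripheral-nerve axons —
from the early-time spread of photoactivated fluorescence out of a short axon
segment.

Neurofilaments move along axonal microtubules in a rapid but intermittent
"stop-and-go" fashion, in both the anterograde and the retrograde direction.
In nerve, single filaments cannot be resolved, so a population method is
needed: photoactivate a 40-µm segment of axon (central window, initial
fluorescence F_c(0)), then measure the fluorescence F_p(t) and F_d(t)
appearing in windows flanking it on the proximal and distal sides. At early
times the normalized flank series rise linearly,

    F̃_d(t) = (p_a · v_a / a) · t ≡ S_d · t,
    F̃_p(t) = (p_r · v_r / a) · t ≡ S_p · t,

where `p_a`, `p_r` are the fractions of filaments in the anterograde and
retrograde moving states, `v_a`, `v_r` the bout speeds, and `a` the central
window length. Two lines of algebra then give the population mean velocity
and directional bias:

    v̄ = a · (S_d − S_p)            %anterograde = 100 · S_d / (S_d + S_p)

Because finite flanking windows miss filaments that pass through them, the
captured fluorescence saturates with window length `b` as
`F(b) = F_total · (1 − e^(−β·b))`; fitting this curve and dividing the
plateau by the measurement time extrapolates the slopes to infinite window
size.

## What is in the package

| module | contents |
|---|---|
| `pulsespread.kinetics` | six-state stochastic transport model (run / on-track pause / off-track pause, both directions), stationary distribution, closed-form slope/velocity predictions, exact event-driven ensemble simulation |
| `pulsespread.imaging` | rendering of simulated ensembles into realistic 16-bit time-lapse stacks (bleaching, vignette, dark offset, shot/read noise) plus dark/flat calibration frames and transport-frozen (glycolytic-inhibition) controls |
| `pulsespread.correction` | flat-field / dark-field correction and pooled exponential photobleach fitting from inhibited controls |
| `pulsespread.measure` | window measurement, 4-min slope fitting, velocity / directionality estimators, group summaries |
| `pulsespread.extrapolation` | window-size saturation fit and infinite-window extrapolation |
| `pulsespread.group_stats` | Shapiro–Wilk screen, Kruskal–Wallis + Mann–Whitney with Benjamini–Hochberg correction, Wilcoxon bias test, diameter correlations |
| `pulsespread.pipeline`, `pulsespread.cli` | end-to-end orchestration (`pulsespread run`) with per-stage subcommands |

The numbered scripts under `analysis/` are narrative drivers over the
library: worked-example arithmetic, model properties, window-size curves,
two-cohort pipeline run, extrapolation, and group statistics. They write
their tables under `results/`.

## Worked example

The estimators applied to reported group-mean fluxes for mouse tibial nerve
at 8 weeks, `S_d = 0.154` and `S_p = 0.122` % of F_c(0) per minute with a
40-µm activation window:

```python
>>> from pulsespread import compute_velocity, compute_directionality
>>> compute_velocity(0.00122, 0.00154, 40.0)   # mm/day, + = anterograde
0.018432
>>> compute_directionality(0.00122, 0.00154)   # (% anterograde, S_d/S_p)
(55.79710144927537, 1.2622950819672132)
```

i.e. a net anterograde population velocity of 0.018 mm/d with 55.8% of the
moving polymer traveling anterograde — slow transport, five orders of
magnitude below the ~0.5 µm/s bout speed of individual filaments, because
filaments pause most of the time. `analysis/01_worked_example_arithmetic.py`
prints the full table (tibial 2/4/8/16 weeks and sciatic 8 weeks, measured
and infinite-window columns).

A full synthetic experiment (70 axons per cohort rendered to noisy image
stacks, corrected, measured; `analysis/04_pipeline_cohorts.py`) prints:

```
bleach rate fitted from 17 inhibited axons: 0.001500 /s (true 0.0015)
    adult_like: n=70, S_d=0.153 %/min, S_p=0.104 %/min, v=0.0285 mm/d, 59.6% anterograde
 juvenile_like: n=70, S_d=0.292 %/min, S_p=0.198 %/min, v=0.0541 mm/d, 59.6% anterograde
```

recovering the generating model's fluxes (theory: S_d = 0.153, S_p = 0.102
%/min, 60.0% anterograde) through the full imaging and correction chain.

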