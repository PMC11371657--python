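# twitchtaxis

Analysis pipeline for **pili-based ("twitching") chemotaxis of
surface-attached bacteria**, built for microscopists and quantitative
microbiologists studying how rod-shaped cells such as *Pseudomonas
aeruginosa* navigate chemoattractant gradients on surfaces.

Swimming bacteria sense gradients *temporally* — they measure dC/dt as
they move.  Solitary twitching cells creep at V_C ≈ 0.2 µm min⁻¹, so over
their ~1 min response time they experience far larger concentration
differences across their ~3 µm bodies than over time.  The pipeline
quantifies the two observables that discriminate temporal from spatial
sensing:

1. **Reversal rates under pure temporal stimuli.**  A dispersed
   concentration front advected past the cells delivers
   dC/dt = (C_MAX − C_MIN)/τ with a vanishing spatial gradient
   dC/dx = (C_MAX − C_MIN)/(Uτ).  Reversal counts n_r over n_t trajectory
   points are modelled as Poisson; rates carry exact (Garwood) intervals
   and are compared between conditions with the conditional exact Poisson
   test (given N = n₁ + n₂, n₁ ~ Binomial(N, T₁/(T₁+T₂)) under equal
   rates).
2. **Repolarization events in stationary cells under an alternating
   spatial gradient.**  The retraction-motor fusion (PilT–YFP) marks the
   leading pole.  Per cell and fluorescence frame, a longitudinal
   max-intensity profile over 10 parallel lines yields pole intensities
   I₁, I₂ normalized by the mid-cell mean; I > I_MIN classifies poles as
   occupied (nonpolar / unipolar / bipolar, with a ratio rule splitting
   strongly asymmetric "bipolar" cells).  After a gradient swap, a
   stationary cell that re-localizes the fusion to a new pole (or moves
   off) scores a *correct* event if the new leading pole faces higher
   concentration; proportions carry Wilson intervals and exact binomial
   tests against 0.5.

Raw experimental image data of this kind is hundreds of gigabytes and not
redistributable, so the package ships a first-class **synthetic
microscopy generator**: rod cells rendered as blurred spherocylinders
with scripted motility (0.2 µm min⁻¹ creep, ~20× pili-release jumps,
Poisson reversals, a 5–10 % stationary fraction), polar fluorescent foci
with scripted polarity timelines and repolarization events, dual-channel
acquisition at 7.5 and 0.5 frames min⁻¹, and an analytic erf gradient
sampled into a dye channel.  Every stage of the analysis is validated
against this ground truth.

## Worked example

Gradient-design arithmetic for the dispersion-front experiment
(C_MAX = 1.16 mM, C_MIN = 0.84 mM, τ = 60 min, U = 27 mm min⁻¹):

```
$ twitchtaxis design-gradient --scenario taylor_aris
scenario_kind                taylor_aris
mean_c                       1
dcdt                         0.00533333
length_scale                 1.62e+06
dcdx                         1.97531e-07
fold_length_vs_width_scale   16200
fold_dcdx_below_ref          101250
```

Cells in this scenario see a mean concentration of 1 mM and a temporal
gradient of ~0.005 mM min⁻¹ — matched to what a moving cell experiences
in the 0.02 mM µm⁻¹ dual-flow gradient (0.2 × 0.02 = 0.004 mM min⁻¹) —
while the spatial gradient across a cell body is ~16,000-fold smaller
(2×10⁻⁷ mM µm⁻¹ over a 1.6 m length scale).

End-to-end synthetic run with six scripted repolarization events
(40 cells, 60 min, gradient swap at 44 min):

```python
from twitchtaxis.synthetic_microscopy import (
    alternating_gradient_scenario, default_event_script, simulate_experiment)
from twitchtaxis.pipeline_cli import analyze_simulation

cfg = alternating_gradient_scenario(
    n_cells=40, duration=60.0, swap_times=(44.0,), rng_seed=3,
    field_size=(400, 400),
    events=default_event_script(n_correct=5, n_incorrect=1, n_movement=2))
res = analyze_simulation(simulate_experiment(cfg))
print(res["events"])
```

prints (thresholds self-calibrated to I_MIN = 1.63, ratio_max = 1.83):

```
 cell_id  t_min        trigger initial_polarity direction_call temporal_change
       0   50.0 polarity_first         unipolar        correct         step_up
       1   56.0 movement_first         unipolar        correct         step_up
       4   52.0 polarity_first          bipolar        correct         step_up
       5   48.0 polarity_first         nonpolar        correct         step_up
      37   48.0 movement_first          bipolar      incorrect       step_down
      39   54.0 polarity_first         nonpolar        correct       step_down
```

All six scripted events are recovered: the event time, trigger
(polarity re-localization vs moving off), the pre-swap polarity state,
whether the new leading pole faced higher succinate (`correct`), and
whether the cell's location made the swap a concentration step-up or
step-down.  `res["summary"]` adds Wilson intervals and the exact binomial
test (here 5:1, p = 0.22 — six events are far below the published sample
size; with the published totals of 148 correct vs 23 incorrect the same
code gives a ratio of 6.4 and p < 10⁻¹⁰).

The same stages are exposed as CLI subcommands (`simulate`, `track`,
`polarity`, `events`, `rates`, `all`) operating on TIFF stacks and CSV
tables, each writing a manifest (config hash, seed, versions) so outputs
reproduce bit-for-bit.

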