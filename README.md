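# wigwag

Agent-based simulation and trajectory analysis of planarian
wall-preference behavior.

Planarians (*Dugesia japonica*) accumulate near the walls of their
containers even in darkness and even after decapitation, which suggests
the "preference" is not a sensory-guided taxis at all. `wigwag` models
the two spontaneous behaviors that suffice to produce it:

1. **straight-ahead motion** at constant speed, interrupted by
   stochastic **wigwag** head turns — an instantaneous heading change
   ξ ~ N(μ, σ) applied at intervals k ~ LogNormal(μ_log, σ_log); and
2. **wall-tangent sliding**: on contact the position is clamped to the
   wall and the heading realigned along the wall tangent closest to the
   incoming direction.

The update rule, on a 0.1-s tick with unit step length (speed 10
sim-units/s; 14/3 sim-units per mm):

```
θ_{t+k} = θ_t + ξ                      (wigwag, via an integer countdown i)
(x_{t+1}, y_{t+1}) = (x_t + sin θ_t, y_t + cos θ_t)
```

Around the simulator the package provides the full analysis pipeline
used to study the emergent behavior: equal-area wall/central region
partitions (and the donut arena's equal-area convex/concave split),
preference indices T_w/T and T_c/T, path linearity (T/N ratio), wall
contact/detachment episodes, incidence/reflection angles at the wall,
wigwag-event extraction from position tracks, occupancy maps by
Gaussian-kernel density estimation with least-squares cross-validated
bandwidth, and MLE fitting of the turn-angle (normal) and turn-interval
(lognormal) distributions with the accompanying tests (Wilcoxon
signed-rank, χ², Kolmogorov–Smirnov).

It is intended for computational ethologists and modellers who want a
tested, reproducible implementation of this minimal thigmotaxis-free
account of wall-following.

## Worked example

Simulate an intact-preset animal for 600 s in a 90-mm dish and measure
its wall preference:

```python
import wigwag as w

field = w.named_field("circle90")            # radius 210 sim-units = 45 mm
partition = w.partition_regions(field)       # 5-mm wall band, equal-area center
params = w.preset_params("intact").params    # ξ ~ N(-0.01, 0.34) rad, k ~ ln N(0.14, 0.48) s

traj = w.simulate(params, field, duration_s=600, seed=1)
pref = w.preference_indices(traj, partition)
print(pref.wall_index, pref.central_index)   # 0.362 0.226

episodes, mean_dwell = w.wall_episodes(traj, partition)
print(len(episodes), mean_dwell)             # 12 episodes, mean dwell 18.1 s
```

The agent spends 36% of the assay in the 5-mm wall band versus 23% in
the equal-area central region (uniform occupancy would give ~21% each),
visiting the wall 12 times and staying about 18 s per visit — wall
preference with sporadic detachments, from spontaneous behaviors alone.

Parameter recovery closes the loop — extract the wigwag events back out
of a track and refit them:

```python
open_traj = w.simulate(params, w.make_field("open"), 600, seed=1)
ext = w.extract_wigwag(open_traj)
fit = w.fit_normal_mle(ext.angles)
print(fit.n, fit.location, fit.scale)        # 446 events, -0.013, 0.342 rad
```

The fitted turn-angle distribution (mean −0.013, SD 0.342 rad) matches
the generating preset (−0.01 ± 0.34 rad) within sampling error.

The same pipeline is scriptable from the shell:

```sh
$ wigwag sweep --field rect30x60 --angle-sd 0.1 --angle-sd 0.3 --angle-sd 1.0 \
       --n-reps 5 --duration 600 --seed 1 --out sweep_out
 angle_sd  mean_wall_index  sd_wall_index  n
      0.1         0.870255       0.015256  5
      0.3         0.762306       0.019811  5
      1.0         0.576737       0.047146  5
```

Larger wigwag angles abolish the wall preference; longer intervals
(`--interval-logmean`) strengthen it. Other subcommands: `simulate`,
`analyze`, `fit`, `synth` (see `wigwag --help`).

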