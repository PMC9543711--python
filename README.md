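# wavegam

Travelling-wave decomposition of cyclic population growth from irregular
abundance surveys.

Many cyclic populations — voles are the textbook case — do not cycle in
lockstep across a region: the cycle's phase drifts with distance, as if the
oscillation *travelled* across the landscape at a constant speed. `wavegam`
fits and compares phenomenological travelling-wave models to transect-survey
data: it aggregates raw surveys into centroid-level quarterly growth rates,
models those growth rates as a penalized-spline smooth of *space-modified
time*, estimates the wave geometry (direction or epicentre, speed) by
simulated annealing, and ranks twelve competing wave hypotheses — from a
pure null through planar, expanding/contracting radial, river-split and
dual overlapping waves — by adjusted AIC. A synthetic-data module simulates
surveys over a known wave field so that the whole pipeline is testable
end-to-end without any field data.

## The model

The response is the quarterly log-difference growth rate of an abundance
index `N` (per cent of 33 transect sections with signs of activity),

```
r_{t,i} = ln(N_{t+1,i} + 3.03) − ln(N_{t,i} + 3.03)
```

for centroid `i` and quarter `t` (3.03 = 100/33, the smallest non-zero
index, keeps zeros finite). Each travelling-wave hypothesis defines a
signed distance `D_i` — `sin(θ)X + cos(θ)Y` for a planar wave with
direction θ, `∓√((γ−X)² + (ψ−Y)²)` for a radial wave expanding (−) from or
contracting (+) towards an epicentre `(γ, ψ)` — and a space-modified time

```
ρ_{t,i} = T_{t,i} + D_i / ζ
```

with `ζ` the wave speed (m/day). Conditional on the wave parameters, growth
rates follow a weighted Gaussian additive model, e.g. for dual overlapping
waves

```
r_{t,i} = α₁ + f₁(ρ₁,t,i) + f₂(ρ₂,t,i) + ε_{t,i},   Var(ε) ∝ 1/w_{t,i}
```

where the `f` are penalized thin-plate-family splines (≤12 basis functions,
≤10 per margin for the spatial tensor product) and
`w = n_t n_{t+1} / (n_t + n_{t+1})` reflects survey counts. Wave parameters
are estimated by minimising the inner GAM's AIC with a direct grid search
followed by simulated annealing (15,000 iterations by default); hypotheses
are compared by `adjustedAIC = AIC + 2K`, `K` the number of wave parameters
estimated outside the smoother. Confidence intervals come from likelihood
profiling with short annealing restarts.

## Worked example

Simulate a single expanding radial wave (epicentre at (70, 60) km, speed
500 m/day, 3-year cycle), aggregate the surveys, and refit the wave:

```python
from wavegam.experiments import recovery_experiment

res = recovery_experiment(seed=1, mode="uniform", iterations=3000)
print(f"epicentre error: {res.epicentre_error_km:.2f} km")
print(f"speed error:     {res.zeta_error:.1f} m/day")
print(f"growth observations: {res.n_growth_obs}")
```

prints

```
epicentre error: 0.58 km
speed error:     2.4 m/day
growth observations: 3226
```

— from 9,600 simulated surveys the annealer recovers the epicentre within
about half a kilometre and the speed within a few metres per day. The same
workflow is available from the shell:

```sh
wavegam run --config examples/demo.yaml
```

which simulates, preprocesses, fits a reduced model catalogue, writes the
adjusted-AIC comparison table and renders a predicted growth-rate field.
Individual stages (`simulate`, `preprocess`, `fit`, `compare`, `profile`,
`report`) are also exposed as subcommands.

## Layout

| module | contents |
| --- | --- |
| `wavegam.synth` | wave-field specs, survey simulation, adaptive designs |
| `wavegam.preprocess` | greedy 5-km centroid cover, quarterly aggregation, growth rates |
| `wavegam.waves` | distance equations, space-modified time, 12-model catalogue |
| `wavegam.smoother` | `PenalizedSplineGAM` — the weighted inner smoother |
| `wavegam.fit` | `WaveModelRegressor`, direct search, SANN, selection, profiles |
| `wavegam.report` | prediction fields, front speed, unit conversions |
| `wavegam.cli` | `wavegam` command-line workflow |

`PenalizedSplineGAM` and `WaveModelRegressor` follow scikit-learn estimator
conventions (`fit`/`predict`, `get_params`, fitted attributes with trailing
underscores) and compose with sklearn tooling. See `docs/methods.md` for
modelling details, numerical choices and known limitations.
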