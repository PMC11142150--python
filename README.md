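# actoflow

A 1D active-fluid model of cytoskeletal bulk flow, for cell biophysicists
who want to turn a subcellular velocity profile — from a kymograph of
speckles, docked mitochondria, or labelled actin — into mechanical
parameters: where the contractile machinery sits, how wide it is, how
front/back adhesion compares, and whether motor stress is dissipated by
traction or by internal viscosity.

## The model

The crosslinked cytoskeletal meshwork is treated as an active viscous fluid
on a 1D domain from the cell rear (x = 0) to the leading edge (x = L).
Steady-state force balance at every point reads

```
f ∂M/∂x + μ ∂²v/∂x² − ξ(x) v = 0
```

where `M(x) = M₀ exp(−((x − x_CZ)/σ)²)` is a Gaussian motor density centred
on the convergence zone, `μ` the meshwork viscosity, and `ξ(x)` a
friction-like adhesion coefficient taking values `ξ_L` / `ξ_R` left and
right of the convergence zone. Boundary conditions are no-gradient
(`v' = 0`) at both edges. The motor stress peaks at `x_CZ ± σ/√2` with
magnitude `F_max = √2 e^(−1/2) f M₀/σ ≈ 0.86 f M₀/σ`, and a single
dimensionless number

```
λ = 2μ/(σ² ξ_L)
```

controls the flow shape: small λ gives traction-dominated flow localized
within the dissipation length `√(μ/ξ)` of the convergence zone; large λ
gives near-uniform flow toward it. Only the ratios
(σ, x_CZ, ξ_R/ξ_L, F_max/ξ_L, μ/ξ_L) are identifiable from a velocity
profile, and those are what the fitting procedure recovers. Presets carry
published parameter sets for five motility modes: cytokinesis, amoeboid
migration, mesenchymal migration, neuronal migration and axon outgrowth.

## Worked example

Generate a synthetic mesenchymal-migration profile (2% measurement noise)
and fit it back:

```python
from actoflow import ActiveFlowModel
from actoflow.synthetic import generate_profile, get_preset, NoiseSpec

prof = generate_profile(get_preset("mesenchymal_migration"),
                        NoiseSpec(sd=0.02, seed=1))
res = ActiveFlowModel(prof).fit()
print(res.summary())
```

```
Active-fluid flow profile fit
==============================================
n observations                            2001
iterations                                   2
converged                                 True
RMS residual                          0.002737
RMS / max|v|                           0.03589
----------------------------------------------
parameter                             estimate
----------------------------------------------
convergence-zone position                28.05
motor distribution width                 5.594
adhesion ratio xi_R/xi_L                 6.949
motor strength Fmax/xi_L                 1.136
viscosity ratio mu/xi_L                  467.7
lambda = 2 mu/(sigma^2 xi_L)             29.89
----------------------------------------------
```

The generator used x_CZ = 28, σ = 4.7, ξ_R/ξ_L = 6.5, F_max/ξ_L = 1.65 and
μ/ξ_L = 500 (λ ≈ 45): position and adhesion ratio come back within a few
percent; σ and F_max/ξ_L trade off against each other under noise and land
within ~20–30%. `res.flow_summary()` reports the motility readouts — here
`com_velocity = 0.035` (the cell crawls forward) with anterograde flow
`plateau_left = 0.054` behind the convergence zone and retrograde flow
`plateau_right = −0.028` in front of it. A symmetric parameter set
(cytokinesis preset) gives `com_velocity ≈ 0`: flow converges on the
furrow but the cell stays put.

The same operations are available from the shell:

```
actoflow simulate --preset cytokinesis --out out/
actoflow synth --preset amoeboid_migration --noise-sd 0.02 --seed 3 --out synth/
actoflow fit --profile synth/profile.csv --out fit.txt
actoflow preset list
```

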