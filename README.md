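# empanet

Brain-network topology and trait empathy: a tested, reusable pipeline
linking the modular architecture of intrinsic functional connectomes to
psychometric empathy traits through a two-step mixed-effects framework.

## Who this is for

Network-neuroscience groups who want to relate nodal graph measures of
resting-state connectomes to questionnaire traits without rebuilding the
whole chain each time: connectome construction, multi-resolution community
detection with group consensus, nodal centrality/participation measures,
questionnaire scoring, and mixed-effects brain–behavior models with FDR
control. Because raw resting-state datasets of this kind are rarely
shareable, the package ships a first-class synthetic-cohort generator so
every stage — and the statistical calibration of the whole pipeline — is
testable end to end on any machine.

## What it computes

**Connectomes.** Node-by-time series become weighted connectomes via the
Fisher transform of the Pearson correlation, z = atanh(r), then binary
undirected graphs by proportional thresholding: exactly the strongest 10%
of possible edges are kept (configurable), so edge count is identical
across subjects and density cannot confound group comparisons.

**Modules.** Per subject, modularity

Q = (1/2m) Σᵢⱼ [Aᵢⱼ − γ kᵢkⱼ/(2m)] δ(cᵢ, cⱼ)

is maximized by Louvain wrapped in an iterated fine-tuning loop (re-run
seeded with the previous optimum until Q stops increasing), swept over the
structural resolution γ ∈ {0.3, 0.4, …, 5.0}. Group-level modules come
from consensus clustering of the cross-subject agreement matrix (1000
seeded restarts by default), screened by a permutation test.

**Nodal topology.** Five measures per node: degree kᵢ, betweenness
(unnormalized shortest-path fractions), closeness (Wasserman–Faust),
participation coefficient Pᵢ = 1 − Σₛ (kᵢₛ/kᵢ)², and within-module degree
z-score zᵢ.

**Traits.** The 30-item Empathic Experience Scale: vicarious experience
(VE) is the sum of the 15 odd items, intuitive understanding (IU) of the 15
even items; sums are Box–Cox transformed (profile-ML λ) and standardized.

**Association.** Per (γ, module, metric, trait), a REML linear mixed model

metricᵢⱼ = β₀ + β·traitⱼ + β_age·ageⱼ + β_sex·sexⱼ + β_int·traitⱼ·sexⱼ
           + uⱼ + bᵢ·traitⱼ + w_g(j) + εᵢⱼ

with subject intercepts uⱼ, a random trait slope bᵢ per node i, and a
scanning-group intercept w. The module-level β is the headline estimate;
node BLUPs b̂ᵢ localize it. A second pass refits after excluding nodes
whose conditional residuals fail an Anderson–Darling normality screen.
p-values are Benjamini–Hochberg corrected within each (γ, trait) family,
and modules significant at ≥ 2 resolutions get a pooled cross-γ model with
γ as a repeated measure.

## Worked example

Run the built-in demonstration — a synthetic cohort of 20 subjects with 60
nodes in 4 planted modules and a planted degree–VE slope of β = 3.2 in
module 0, swept over γ ∈ {0.5, 1.0, 1.5}:

```bash
empanet run-all --demo --out-dir demo_run --seed 0
```

```
done: 20 subjects, 3 resolutions, 3 FDR-significant associations -> demo_run
```

Inspecting `demo_run/associations.csv`, the three FDR-significant rows are
the planted effect, recovered at every resolution (top of the q-ranking):

```
gamma  module  metric  trait   beta      p          q
0.5    0       degree  ve      2.992     1.52e-07   3.0e-06
1.5    0       degree  ve      2.990     3.61e-07   7.2e-06
1.0    0       degree  ve      2.911     3.74e-07   7.2e-06
```

`beta ≈ 3.0` is the module-level degree change per standard deviation of
the (Box–Cox) vicarious-experience score — the planted 3.2 attenuated
slightly by the realized node slopes — and every other module × metric ×
trait combination stays above q = 0.05. The cross-γ repeated-measures model
(`associations_cross_gamma.csv`) pools the three resolutions into the
single headline estimate. `modularity.csv` shows mean Q falling from 0.59
at γ = 0.5 to 0.34 at γ = 1.5 while the module count grows — the expected
resolution trade-off.

The same stages are available piecewise (`empanet simulate`, `connectome`,
`communities`, `metrics`, `score`) and as library functions; a YAML
`RunConfig` drives file-based runs on real node time series or precomputed
connectivity matrices.

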