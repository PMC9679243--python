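# ipmviability

Multistate integral projection models (IPMs) and population viability
analysis for long-term censuses of perennial plants, plus the tools to ask
whether population-genetic diversity predicts demographic performance.

The package was built around the demography of a rare, self-compatible
rosette herb monitored on permanent 1 m² quadrats for eight annual censuses
(five populations, ~300–500 tagged plants each at the outset), but every
component is generic: it takes a long-format census table (population,
transect, quadrat, plant id, year, rosette diameter, survival, fruit count)
and produces stochastic growth rates, extinction probabilities, predicted
population sizes, and genetics–demography correlations.

## What it computes

**Life-cycle states and data correction.** A plant-year is NORMAL (live
rosette with a measurable diameter), BOLTER (alive, reproducing from the
terminal bud, no measurable rosette — diameter 0 or missing), or DORMANT
(alive belowground). Dormant plants are scored dead in the field, so a
survival record like `00011101` shows an apparent *reincarnation*; the
correction flips interior deaths flanked by live observations
(`00011111`) and scores dormancy as the disagreement between raw and
corrected records.

**Vital-rate regressions.** Each rate (survival, growth, flowering
probability, fruit count, and the six transitions among the three states)
is a GLM of rosette diameter *z* per population with year intercepts:
`g(E[y]) = β₀ + β₁z + β₂z² + year`. Four nested fixed-effect structures are
compared by small-sample AICc; the lowest-AICc model wins unless rivals sit
within 2 units, in which case the fewest-effects model is chosen. Growth is
a zero-left-truncated Gaussian regression (diameters cannot be ≤ 0).
Bolters and dormants carry *latent size* — the last recorded normal size —
so their rates can stay size-dependent.

**Multimatrix kernel.** The annual kernel is a 3×3 grid of n×n submatrices
(default n = 150 mesh points from 0 mm to 110% of the largest observed
diameter, midpoint rule). The NORMAL→NORMAL block combines survival,
state-retention and the Gaussian growth density (columns renormalized so
discretization never evicts mass), plus the recruitment pathway
fruits(z) × recruits-per-fruit × recruit-size density. Sizeless states sit
on block diagonals at their latent size and re-enter NORMAL through the
growth map.

**Stochastic projection.** λ_S is the geometric mean of annual growth
ratios over 50,000 steps of independently, uniformly drawn annual kernels,
with the state vector renormalized each step. Transient projections start
from the final census size, round the projected total to the nearest
integer each year (so absorption at zero is possible), and score extinction
at zero individuals over a 22-year horizon. Parameter uncertainty is a
parametric bootstrap: each replicate redraws every coefficient vector from
MVN(β̂, Σ̂) and fresh year deviations (the year variance itself redrawn
from a scaled chi-square), rebuilds the seven annual kernels, and
recomputes everything; 5000 replicates give percentile intervals.

**Genetics link.** Per-population diversity summaries (observed
heterozygosity H_O, gene diversity H_S, allelic richness R_S, inbreeding
coefficient F_IS, …) ship as a packaged table alongside the published
demographic outcomes and 2019 recensus densities. Pearson correlations are
computed after ln (λ_S, predicted N, density) and logit (H_O, F_IS, Pr_ext)
transforms, for all populations and for the East genetic group alone, and a
bias-adjusted Fisher-z power analysis quantifies the detectable effect size
at five populations.

## Worked example

Correlate the packaged genetic and demographic tables (this is exactly what
`ipmviability correlate` prints):

```text
$ ipmviability correlate --out corr.csv
predictor         outcome subset         r        p  n
      H_O lambda_s_median    all  0.814639 0.093089  5
      H_O     pr_ext_mean    all -0.968949 0.006538  5
      H_O pred_n2019_mean    all  0.632901 0.251777  5
      H_O    density_2019    all -0.098695 0.874542  5
     F_IS lambda_s_median    all -0.591076 0.293885  5
      ...
      H_O lambda_s_median   East  0.862534 0.137466  4
```

More heterozygous populations had higher stochastic growth rates
(r = 0.81 over five populations, 0.86 within the East group — marginally
significant at best) and markedly lower modeled extinction risk
(r = −0.97, p = 0.007), while the inbreeding coefficient F_IS tracked
nothing strongly. With five populations, power is the binding constraint:

```text
>>> from ipmviability import genetics
>>> genetics.critical_r_for_power(5, 0.75, 0.05)
0.9408309...   # only |r| > 0.94 is detectable with power 0.75 at α = 0.05
```

A full synthetic run — generate censuses, correct them, fit all vital
rates, assemble kernels, project (`desk` scale: 60 bootstraps × 2000 λ
steps × 100 trajectories; `full` reproduces the 5000 × 50,000 × 1000
analysis):

```bash
$ ipmviability run --seed 1 --out run1 --scale desk
```

which writes `run1/report.md` like:

```text
| population | median λ_S (95% CI) | mean Pr_ext (95% CI) | mean predicted N (95% CI) |
| CG | 0.576 (0.435–0.820) | 0.861 (0.118–1.000) | 57.4 (0.0–218.6)      |
| DC | 0.604 (0.466–0.842) | 0.893 (0.143–1.000) | 1.3 (0.0–3.4)         |
| JC | 0.739 (0.577–1.161) | 0.576 (0.005–1.000) | 509359.0 (0.0–746136.5) |
...
```

All λ_S medians sit well below 1 — the populations are projected to
decline — and most bootstrap replicates end in extinction within the
horizon. Predicted population size is strongly right-skewed (a handful of
boom-sequence replicates dominate the mean, as JC shows); the medians and
percentile intervals in `projection_summary.json` are the robust summaries.

## Layout

```
src/ipmviability/
  census.py      # I/O, reincarnation correction, dormancy scoring, states
  simulate.py    # individual-based synthetic censuses with ground truth
  vitals.py      # GLM vital rates, AICc selection, bootstrap draws
  kernel.py      # mesh, 3×3 multistate kernel assembly
  projection.py  # λ_S, transient projections, extinction, bootstrap CIs
  genetics.py    # transforms, correlations, power analysis, fixture tables
  pipeline.py    # simulate → clean → fit → kernels → project → correlate
  cli.py         # `ipmviability` command-line interface
  data/          # packaged genetics/demography/recensus tables
docs/methods.md  # modeling choices, defaults, and limitations in detail
```
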