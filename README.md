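# ffltune

How can a transcription factor that binds its targets *more weakly* drive
*higher* expression of a target gene?  In the yeast nitrogen catabolite
repression (NCR) network the activator GAT1 drives both the high-affinity
ammonium transporter gene *MEP2* and the repressor *DAL80*, which in turn
represses *MEP2* — an incoherent type-1 feedforward loop (I1-FFL).  When an
affinity-reducing GAT1 mutation lowers activation of the weak *DAL80*
promoter proportionally more than activation of the strong *MEP2* promoter,
the loss of repressor outweighs the loss of direct activation and steady-state
*MEP2* output rises.  `ffltune` implements the quantitative toolkit for
studying this phenomenon, for researchers analysing regulatory-network
evolution experiments.

## The model and statistics

The loop is modelled with linear production and first-order decay:

    dGAT1/dt  = 0
    dDAL80/dt = A·X·GAT1 − c·DAL80
    dMEP2/dt  = A·GAT1 − R·DAL80 − c·MEP2

with `A` the strength of MEP2 promoter activation by GAT1, `A·X` the DAL80
promoter activation, `R` the strength of repression by DAL80 and `c` a common
degradation rate.  The steady state is closed-form:

    DAL80* = A·X·GAT1/c,    MEP2* = A·GAT1·(1 − R·X/c)/c

so MEP2* relative to an ancestral state (A₀, X₀) is `A(1 − R·X/c) /
A₀(1 − R·X₀/c)` — which exceeds 1 on an open region with *both* A < A₀ and
X < X₀.

Around the model the package provides the supporting statistics used to
characterise such a system experimentally:

- **Binding affinity** (`ffltune.binding`): EMSA fraction-bound
  quantification and nonlinear least-squares fits of the two-parameter
  Michaelis–Menten binding model `Fr = Frmax·x/(x + Kx)`, with standard
  errors and per-parameter t-test p-values; PWM construction from
  top-scoring 8-mers of a protein binding microarray.
- **Selection on coding sequence** (`ffltune.selection`): per-codon dN and
  dS — proportions of observed over potential nonsynonymous/synonymous
  substitutions, pooled over all sequence pairs with mutational-pathway
  averaging — to expose purifying selection on a domain.
- **Fitness and expression statistics** (`ffltune.evostats`): selection
  coefficients from log-ratio regression of competition assays (95% CI
  suppressed below 5 time points), gene-set permutation tests of the
  affinity–expression correlation, and log10 FSC-A reporter normalization.
- **Synthetic data** (`ffltune.synthetic`): seeded generators for every
  input — EMSA titrations, codon alignments with a constrained domain,
  gene tables, competition time courses — with known ground truth.

## Worked example

```python
from ffltune import FFLParameters, relative_mep2, sweep_parameter_grid

ancestor = FFLParameters(a=1.0, x=0.4, r=2.0, c=1.0)
mutant = FFLParameters(a=0.8, x=0.2, r=2.0, c=1.0)
print(relative_mep2(mutant, ancestor))
# 2.4000000000000004
```

Both promoter activations dropped (direct MEP2 activation by 20%, DAL80
activation by 60%), yet steady-state MEP2 is 2.4× the ancestral level.
Sweeping the whole plane:

```python
import numpy as np
grid = sweep_parameter_grid(reference=(1.0, 0.4))
sub = grid.increased_mask[np.ix_(grid.a_values < 1, grid.x_values < 0.4)]
print(round(sub.mean(), 3))
# 0.598
```

About 60% of the quadrant in which both activations decreased still shows
increased MEP2 output — the parameter region available to adaptive
affinity-reducing mutations.  The `examples/` directory holds one short
script per capability (phase diagram, EMSA fit, dN/dS scan, permutation
correlation, competition fitness), each printing the numbers it computes
and what they mean.

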