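# fbdsky

Bayesian tip dating with the **fossilized birth–death (FBD) process** as the
tree prior: piecewise-constant birth, death and fossil-recovery rates, serial
fossil sampling, random or **diversified** sampling of extant taxa, sampled
ancestors via reversible-jump MCMC, and a strict-clock JC69 sequence model.
The package bundles a forward simulator, the exact tree-prior density, a
single-chain MCMC sampler and posterior/coverage summaries, so the whole
simulate → infer → calibrate loop runs from one library.

It is aimed at people developing or validating tip-dating machinery:
the simulators generate complete birth–death trees with fossils under
controlled sampling schemes, and the samplers recover the generating
parameters from those data.

## The model

A lineage-branching process starts at the crown age `x1` with two lineages.
Time is measured as age (present = 0) and divided into `l` intervals by ages
`t1 > … > tl = 0`; interval `i` has birth rate `λi`, death rate `μi` and
fossil-recovery rate `ψi`, and each lineage alive at `ti` is sampled there
with probability `ρi` (`ρl` = extant sampling probability). With

    Ai = sqrt((λi − μi − ψi)² + 4 λi ψi)
    Bi = ((1 − 2(1 − ρi) p_{i+1}(ti)) λi + μi + ψi) / Ai

the probability `pi(t)` that a lineage at age `t` leaves no sampled
descendant and the branch factor `qi(t)` have closed forms, and the density
of the observed tree factorises over branching times, fossil observations
and interval boundaries. A fossil on a lineage with later samples is a
*sampled ancestor* — represented as a zero-length side branch — and the
add-branch / delete-branch reversible-jump moves toggle each fossil between
its ancestor and tip configurations during MCMC.

Under **diversified sampling** exactly one extant descendant of every
lineage crossing a cutoff age `x_cut` is kept; the tree density is the
complete-sampling density times `(1 − 1/F(x_cut))^η`, with `η` the number of
pruned extant taxa and `F` a closed-form function of the birth and death
rates below the cutoff. Sampling operates on the canonical parameters
`d = λ − μ` (net diversification), `r = μ/λ` (turnover) and
`s = ψ/(μ+ψ)` (fossil-sampling proportion).

## Worked example

Simulate one fossilized birth–death data set (birth 0.3, death 0.2, fossil
recovery 0.1, half of the 100 extant taxa sampled) and sample the canonical
parameters from the FBD prior with the tree held fixed:

```python
import numpy as np
from fbdsky import (CanonicalParams, ChainConfig, FBDChain, FBDModel,
                    PriorSpec, simulate_fbd_tree)

rng = np.random.default_rng(1)
res = simulate_fbd_tree(strategy=1, rng=rng)        # 100 extant, rho = 0.5
print(len(res.tree.extant_tips()), len(res.tree.fossils()),
      res.tree.n_sampled_ancestors())
# 56 117 68    <- sampled extant tips, fossils, sampled ancestors

model = FBDModel(shift_ages=res.shift_ages, sampling=res.sampling)
chain = FBDChain(model, PriorSpec(), res.tree,
                 CanonicalParams([0.1], [0.5], [0.5]), rng,
                 fixed_tree=True,
                 config=ChainConfig(iterations=20_000, thin=10))
burned = chain.run().burned()
print(burned[["d_0", "r_0", "s_0"]].mean().round(3).to_dict())
# {'d_0': 0.084, 'r_0': 0.74, 's_0': 0.304}
```

The posterior means sit near the generating values `d = 0.1`, `r = 0.667`,
`s = 0.333` (a single replicate scatters — over 100 replicates the grand
means land within a few thousandths of the truth; see below). The same loop with sequence data attaches a
500-bp JC69 alignment and a strict clock and infers topology, node ages and
rates jointly:

```bash
fbdsky infer --prior T --iterations 30000 --seed 1 --out-dir out/
fbdsky simulate --strategy 2 --reps 3 --seed 7 --out-dir sims/
fbdsky coverage --study 1 --strategy 1 --reps 50 --seed 1 --out-dir cov/
```

Every CLI run writes a `manifest.json` (configuration + seed + version)
next to its outputs, so any artifact can be regenerated from the manifest
alone.

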