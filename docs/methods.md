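# Methods

## Model and density

The tree prior is the fossilized birth–death (FBD) process with
piecewise-constant rates. Ages increase into the past with the present at
0; boundaries `t1 > … > tl = 0` split time into intervals carrying birth
`λi`, death `μi` and fossil-recovery `ψi` rates, with event-sampling
probability `ρi` at each boundary (`ρl` = extant sampling). `I(t)` maps an
age to its interval via `ti < t ≤ t(i-1)`; an age exactly on a boundary
belongs to the younger-side interval, and a sample taken *at* a boundary is
recognised by an explicit flag, never by floating-point age comparison.

Two functions carry the density: `pi(t)`, the probability that a lineage at
age `t` leaves no sampled descendant, and the branch factor `qi(t)`
normalised to 1 at each interval's younger boundary. Both are closed forms
in `Ai = sqrt((λi−μi−ψi)² + 4λiψi)` and `Bi`, computed by a backward
recursion from `p_{l+1}(tl) = 1`. The observed-tree density conditioned on
the crown age multiplies: the conditioning factor `q1(x1)²/(1−p1(x1))²`,
`λ q` per non-root branching, `ψ` per sampled ancestor, `ψ p/q` per fossil
tip, and per boundary `[(1−ρi) q_{i+1}(ti)]^{ni} ρi^{Ni} q_{i+1}(ti)^{Ki}
p_{i+1}(ti)^{Mi}`. Stem conditioning replaces the first factor by
`q1(x0)/(1−p1(x0))` and includes the root branching. The density is *not*
conditioned on the number of extant taxa. Conversion from oriented to
labelled trees multiplies by `2^(m+M−1)/(m+M+k+K)!`; because the exponent
depends on how many fossils are ancestral, the factor is part of the MCMC
target, not a constant.

Everything is computed in log space. The exponent `Ai (ti − t)` is
non-positive inside an interval, so the closed forms cannot overflow even
for branch spans of 10^4 time units; the degenerate limit `Ai → 0`
(critical process without fossil sampling) is evaluated through
`expm1`-based limits with a switch tolerance of 1e-9 on `Ai`, and the
analogous `λk → μk` limit applies inside the diversified-sampling function
`F`.

### Diversified sampling

Diversified sampling keeps exactly one extant descendant per lineage
crossing a cutoff age `x_cut`. The density is the complete-sampling density
(extant sampling probability forced to 1) times `(1 − 1/F(x_cut))^η`, where
`η` is the number of pruned extant taxa — in inference derived from the
assumed sampled fraction `f` as `round(Nl (1−f)/f)` — and `F` follows the
interval recursion below the cutoff. `F` is only evaluated at skyline
boundaries; the cutoff is therefore always inserted as a boundary carrying
`ρ = 0`, with the fossil-recovery rate zeroed below it. During MCMC the
cutoff is not a free parameter: after every accepted tree change it is
recomputed as `(1 − 1e-6)` times the minimum of the youngest true branching
age and the youngest fossil age. The relative offset 1e-6 is small enough
that posterior summaries are insensitive to it (any value that keeps the
cutoff strictly below the youngest node behaves identically at double
precision for these tree depths).

## Sampler

A single Metropolis–Hastings chain updates (i) the canonical parameters
`d, r, s` per rate class and the clock rate, (ii) node ages, (iii) the
fossil configurations. Default move weights are 40% parameters, 30% node
ages, 15% the add/delete reversible-jump pair (chosen with equal
probability within the pair), 10% fossil slider + fossil SPR, 5% non-fossil
topology; burn-in defaults to 25% and thinning is configurable.

Parameter moves mix component-wise multipliers/reflected slides on
`(d, r, s)` with multipliers applied in `(λ, μ, ψ)` coordinates. The data
constrain the natural rates, so the canonical parameters are strongly
correlated a posteriori and component-wise moves alone mix slowly; the
rate-space multipliers carry the `(d, r, s)` change-of-variables Jacobian
(e.g. `c² (d'/d) ((μ+ψ)/(μ'+ψ))²` for the death-rate multiplier) and were
verified by recovering the exact hyperprior marginals when the tree factor
is switched off, and by effective-sample-size gains of roughly an order of
magnitude on fixed-tree runs.

The reversible-jump pair follows the published ratios: add-branch picks an
ancestral fossil (1/k'), draws the new bifurcation age uniformly on
`(y_f, c_f)` and has Hastings ratio `k'/(m'+1)` with Jacobian `c_f − y_f`;
delete-branch is the mirror image and is auto-rejected when the tip fossil
is younger than its sibling or its bifurcation is the root. After a
deletion, the Jacobian's `c_f` is the age of the attachment point's parent
in the post-deletion tree, which is exactly the window the reverse
add-branch draw uses; this choice was confirmed by the two-configuration
analytic oracle rather than assumed. The fossil SPR reattaches an ancestral
fossil at unchanged age to a uniformly chosen branch among those strictly
crossing that age (the crossing set is invariant under the move, so the
ratio is 1). The general subtree-prune-regraft draws the reattachment age
uniformly on the target segment's feasible span; its Hastings ratio is the
span ratio times the eligible-subtree count ratio `|cand(T)|/|cand(T')|` —
the count changes when a move alters which nodes sit directly under the
root, and omitting it measurably biases the sampler.

Likelihood evaluation uses Felsenstein pruning under JC69 and a strict
clock, with site-pattern compression, per-pattern rescaling, and per-node
partial caching: a move declares its dirty nodes (the changed node plus
ancestors) and only those partials are recomputed; clock-rate moves force a
full refresh and are therefore proposed at a reduced frequency (12% of
parameter moves). A debug mode recomputes the full posterior from scratch
at fixed intervals and asserts agreement with the incrementally maintained
value.

Fixed-tree (prior-only) runs freeze the tree statistics into a dedicated
evaluation kernel (scalar backward recursion plus one vectorised pass over
the node ages); it is exact — tested to 1e-8 against the general path on
all four sampling strategies — and about five times faster.

## Simulator

Complete birth–death trees start from a single origin lineage and are
conditioned on `n` extant taxa by the general-sampling approach: the
process runs to extinction or to a cap of `max(4n, n+20)` lineages, every
time span with exactly `n` extant lineages is recorded, and the stopping
time is drawn uniformly (length-weighted) over their union. Fossilization
is Poisson along branches (per-interval rates supported) with exact ages —
stratigraphic uniform bounds are an inference-side feature only — plus
optional Bernoulli sampling of every lineage crossing a horizon age.
Diversified extant sampling computes the cutoff as the midpoint between the
`(m−1)`-th and `m`-th oldest branching ages of the extant-reconstructed
tree (`m = round(f·n)` retained taxa; an internal assertion checks the
crossing count) and keeps one uniformly chosen extant descendant per
crossing lineage — the density does not depend on that choice. Pruning
removes everything without a sampled descendant; a fossil whose lineage
carries a later sample becomes a zero-length side branch (sampled
ancestor).

Because inference conditions on the crown age, simulated replicates whose
sampled tree would carry a sample above its own crown (a stem sampled
ancestor) are redrawn; such trees have no representation in the
crown-conditioned state space.

### What the generator does and does not emulate

The generator reproduces the study conditions: constant rates
`λ = 0.3, μ = 0.2, ψ = 0.1`, 100 extant taxa, extant sampling 0.5 (random
or diversified), an optional extra fossil-sampling horizon at age 10 with
probability 0.5, 500-bp JC69 alignments under a strict clock of 0.003 with
complete sequences for fossils and exactly known fossil ages. Real data
differ in every one of those respects — morphological partitions, missing
fossil characters, stratigraphic age uncertainty, rate variation across
lineages — so the calibration results certify the correctness of the
machinery under its own assumptions, not robustness to their violation
(except for the one deliberate misspecification study of the sampling
scheme).

## Calibration studies and problem sizes

Study I fixes each simulated tree and samples `(d, r, s)` from the FBD
prior (`d ~ Exponential(10)`, `r, s ~ Beta(1,1)`, `ρ` fixed to truth);
the package defaults use 100 replicates with 20,000-iteration chains
(thinning 10, 25% burn-in), which give effective sizes of several hundred
for `d` per replicate. Study II infers topology, ages, rates and the clock
from 500-bp alignments on strategy-2 trees under four prior settings
(true piecewise model T, constant-rate C, complete-sampling L, diversified
D) with `tmrca ~ Uniform(0, 1000)` and clock `~ Gamma(3, 1000)`; chains
start from the simulated tree with parameters at prior means. The
replicated runs use 6–10 replicates of 20,000–30,000 iterations; these
short chains make the studies runnable in minutes while leaving the
coverage estimates their binomial noise, which the calibration checks
account for through binomial bands at the realised replicate count.

HPD intervals use the shortest-window scan on sorted draws (ties toward
the lower start); the effective sample size uses the initial positive
sequence estimator. Replicate seeds derive deterministically from the
experiment seed, so every study is bit-reproducible.

## Known limitations

* Only JC69 with a strict clock; no partitioned models, rate
  heterogeneity, relaxed clocks, or morphological characters.
* Single chain; no Metropolis coupling, no marginal-likelihood estimation.
* Crown conditioning only in the samplers (the stem-conditioned density is
  implemented and tested, but the MCMC state has no origin-age parameter).
* The `(d, r, s)` parameterization cannot represent `ψ > 0` with `μ = 0`,
  and `s` is unidentifiable at `r = 0`.
* Newick round trips preserve branch lengths to 1e-10 (float re-anchoring
  at the present), not bit-exactly.
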