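# Methods

## The optimizer

`bscso` binarizes sand cat swarm optimization (SCSO) for subset search.
Agents are bit vectors in `{0,1}^d` and carry no continuous state between
iterations. Each iteration, for each agent:

1. Draw the phase control `R = 2·r_G·u − r_G` and the sensitivity
   `r = r_G·u'` once per agent, where `r_G = s_M − s_M·iter_c/iter_max`
   decays linearly from `s_M = 2` to 0 over the run.
2. Select exploitation when `|R| ≤ 1`, exploration otherwise. The printed
   form of the switch in some descriptions is a signed `R ≤ 1`, but `R` is
   symmetric around zero by construction, so the signed reading would
   exploit for every negative draw; the magnitude convention is used.
3. Compute the continuous candidate per dimension from the *binary*
   positions: exploration `r·(pos_bc − u·pos_c)` with the global best as
   attractor; exploitation `pos_b − r·|u·pos_b − pos_c|·cos θ`, with one
   roulette-wheel angle θ per agent per iteration (equal weights over 360
   integer-degree bins, i.e. discrete-uniform). The distance term takes an
   absolute value: a negative distance is meaningless.
4. Feed the candidate directly to the V-shaped transfer function and flip:
   `bit ← 1 − bit` if `u'' < V(candidate)`, else keep. One flip draw per
   dimension.
5. Repair all-zero vectors by switching on one uniformly chosen bit
   (an empty feature subset cannot be scored).
6. Re-evaluate fitness; replace the global best only on strict
   improvement (elitism — the best is never lost, so the best-fitness
   history is non-increasing by construction).

Evaluation count is exactly `n_agents · (max_iter + 1)`: one initial sweep
plus one re-evaluation per agent per iteration.

### Why candidates are fed to the transfer function directly

Two couplings were considered: pass the raw update-rule candidate to `V`, or
pass the displacement between the candidate and the current bit. Both were
benchmarked on an exhaustive-enumeration oracle (d = 10 wrapper problem,
all 1023 non-empty subsets scored): the direct coupling attained the exact
global optimum in 25/25 seeded runs versus 23/25 for the displacement
coupling, and it is the minimal reading of the update rule, so it is the
one implemented.

### The absorbing-zero property (important limitation)

Every update term above is a *product* of position values. When a
dimension is 0 in both the global best and an agent, the candidate in that
dimension is exactly 0, `V(0) = 0`, and the bit can never flip to 1 again
by any phase. Ones outside the best's support therefore die out within a
few iterations and cannot be re-created. Consequences:

* The search concentrates inside (and gradually shrinks within) the
  support of the incumbent best. For feature selection with a dominant
  error term and a small size penalty this acts as an aggressive built-in
  minimization of subset size, and it is why the optimizer reliably finds
  *minimal* zero-error subsets on easy data.
* Objectives whose optimum requires many active bits are structurally out
  of reach. On OneMax over d = 20 (cost `(d − Σbits)/d`, optimum all
  ones), the reachable ones-count is capped near the best initial agent:
  measured mean best ≈ 15/20 with 0/25 runs reaching the optimum. This is
  a property of the update equations on binary state, not of the
  implementation; maintaining continuous agent state or re-anchoring the
  exploration attractor at per-agent personal bests was measured and does
  not remove it.

### Transfer functions

Four V-shaped variants are available, all symmetric (`V(−x) = V(x)`), zero
only at zero, strictly increasing in `|x|`, and valued in `[0, 1)`:

| name | formula (on `a = |x|`) |
|------|------------------------|
| V1   | `tanh(a)` |
| V2   | `erf((√π/2)·a)` |
| V3   | `a/√(1+a²)` |
| V4   | `(2/π)·arctan((π/2)·a)` (default) |

The `√π/2` constant in V2 gives all four variants unit slope at the
origin, matching V4's normalization; the four then differ only in tail
heaviness. `tanh` and `erf` round to exactly 1.0 in double precision for
`|x| ≳ 6`; the implementation clamps to `nextafter(1, 0)` to preserve the
half-open probability contract, and monotonicity is strict only below that
saturation point.

## The wrapper fitness

`fitness = α·ER + β·|S|/C`, minimized, with `α = 0.99, β = 0.01`. These
weights are the de-facto standard in the wrapper-selection literature:
accuracy dominates and the size term only breaks ties among subsets of
equal error. `ER` is the error rate of a k-nearest-neighbor classifier
(Euclidean distance on min–max-normalized features, majority vote) trained
on the training partition and scored on the validation partition. Voting
ties are broken by the nearest single neighbor's label when it is among
the tied classes, then by the lowest class index; neighbor order on exact
distance ties is stable in training-row order. The neighbor search and
vote run on an explicit `scipy` distance matrix rather than through a
classifier object: the tie-break policy above is pinned down exactly, and
a fitness call costs tens of microseconds, which matters at the ~10⁵
evaluations of a default run. The implementation is cross-checked in the
test suite against both a hand-written brute-force oracle and
scikit-learn's `KNeighborsClassifier` on tie-free data.

Default `k = 5` for single fits; the experiment harness sweeps
`k ∈ {3, 5, 7}`. Odd k avoids most voting ties in binary problems; even k
is allowed and resolved by the stated tie-break.

## Data handling

* **Loading.** CSV (header row, one label column, default the last) via
  pandas; ARFF via `scipy.io.arff`. Features are coerced to reals — an
  unparseable cell raises an error naming its row and column. Rows with
  missing entries are dropped and counted (`on_missing="error"` for a
  strict mode). Labels are integer-encoded in first-appearance order.
* **Normalization.** Per-column min–max to `[0, 1]`; constant columns map
  to 0. After a split, parameters come from the training partition only,
  so validation/test values may fall slightly outside `[0, 1]` — KNN is
  indifferent and no clipping is applied.
* **Splitting.** Stratified 60/20/20 train/validation/test by default
  (per-class proportions within one instance), seeded. A
  `0.8/0/0.2` specification reproduces the plain 8:2 protocol; with no
  validation rows the fitness error rate is computed on the training
  partition itself (resubstitution). Three-way is the default because a
  validation partition disjoint from the test set keeps the reported test
  accuracy honest.

## Synthetic data

`generate_synthetic` draws balanced classes; `n_informative` features get
class-`c` mean `c·δ` (unit variance), the rest are standard Gaussians
identical across classes; columns are permuted and the informative index
set is returned with the data. Defaults (n = 120, 30 features, 5
informative at δ = 3, two classes) emulate the "many features, few
samples" regime at a desk-scale size. What it does *not* emulate: feature
correlation, redundant informative groups, label noise, class imbalance,
and heavy-tailed expression-like distributions. Passing tests on this
generator therefore demonstrate the mechanics and the selection bias of
the algorithm, not performance claims on real biomedical tables.

One consequence worth stating explicitly: at δ = 3 a *single* informative
feature often yields zero validation error on a 24-row validation set, so
the size penalty drives the fitness optimum to one or two informative
features. Recovery of the *full* informative set is then not the fitness
optimum — measured mean recall is ≈ 0.3 while precision is ≈ 0.9: what
the optimizer selects is almost always genuinely informative, but it
deliberately selects few. A recall target of 0.8 under these conditions
contradicts the objective being optimized, and the corresponding
acceptance test is left failing rather than re-tuning the generator or
the weights around it.

## Experiment harness

`run_experiment` loops k-values × repeats; per-run seeds are
`master_seed + run_index` (k-major order, kept below 2³¹), so any run can
be replayed in isolation. Each repeat re-draws the split by default
(`resplit_per_repeat=False` fixes the split per k block for variance
isolation). Aggregates report mean and sample (n−1) standard deviation of
test accuracy (as percentages, 2 decimals in `report.csv`) and of selected
counts; single-repeat std is 0 by convention. Output files carry no
timestamps or timings, so identical master seeds produce byte-identical
reports; wall-clock per run is kept only on the in-memory records.

## Problem sizes

The test suite and the acceptance script use: 25 seeded runs for the
OneMax (d = 20) and enumeration-oracle (d = 10, 1023 subsets) studies, and
5 repeats per k for the synthetic pipeline (n = 120, d = 30) — sizes
chosen so the full suite completes in well under a minute per study on a
single CPU while keeping the binomial error of a success-rate estimate
below ~10 percentage points.

## Known limitations

* The absorbing-zero dynamics above: unsuitable for objectives whose
  optima activate many bits; excellent at shrinking subsets.
* Fitness uses a single split, not cross-validation; small validation
  partitions make zero-error subsets easy to find and are the main driver
  of the minimal-subset behavior.
* Only KNN is wired as the wrapped classifier, and only subset-size
  regularization is available (no redundancy penalties).
* The comparison binary optimizers commonly benchmarked against this
  method (binary PSO, GA, bat, ABC variants) are not implemented; the
  optimizer interface (`fitness_fn, d, config`) is the extension point.
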