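# Methods

## Model and assumptions

The behavioral-control pathway is modeled as a two-layer feed-forward
network. The input is a one-hot vector over `N` behaviors (a pure decision
signal with no temporal structure), the hidden layer of size `R` stands for
the descending-neuron population, and the output layer of `M` binary motor
units is the motor code. Both layers are fully connected with subtractive
biases:

    a1 = W1' x - B1,   h = sigmoid(a1)
    a2 = W2' h - B2,   y = sigmoid(a2)

and the motor pattern is `y` thresholded at 0.5 (ties round to 1; they are
measure-zero in trained networks). A behavior is *learned* only if its
entire binarized output row equals the target row — per-entry accuracy is
never substituted, because a motor pattern with a single wrong unit is a
different behavior.

Because inputs are one-hot, each behavior owns one row of `W1`: the hidden
representation of behavior `i` is `sigmoid(W1[i] - B1)`. The model is
therefore equivalent to jointly learning `N` points in the unit cube
`(0,1)^R` and a shared linear-plus-sigmoid readout. This is what makes the
bottleneck width `R` the binding constraint, and it is why the whole
training loop is three dense matrix products in numpy — no autodiff
framework is needed.

Both layers apply the sigmoid. The output nonlinearity matters for more
than convergence: a sigmoid readout trained on 0/1 targets saturates, so
binarized outputs acquire a wide margin in pre-activation space, and
clamping one hidden unit often fails to flip any motor unit. A purely
linear readout leaves a fixed margin of 0.5 and yields networks whose
perturbation robustness collapses (we measured ~0.05 versus ~0.85 at
`R = 35`, `k = 10`) and whose capacity stalls well short of the operating
points reported for this class of model. The linear readout remains
available (`TrainingConfig(sigmoid_output=False)`) for studying exactly
this contrast.

## Training

Gradient descent with classical momentum on the mean-reduced MSE over all
`N` one-hot inputs (full batch). Defaults:

- `epochs = 1e5` — the loss curve is flat well before this at the study
  scale; an epoch is one full pass over the `N` commands.
- `learning_rate = 10.0` on the mean-reduced gradient, i.e. a per-entry
  step of 1e-3 at `N = M = 100`. The effective step scales with `1/(N*M)`,
  so smaller problems want proportionally smaller rates (the test suite
  uses 2-5 at `N = 10-40`); rates an order of magnitude higher destabilize
  the output layer and collapse the network.
- `momentum = 0.9`.
- Initialization: uniform `±1/sqrt(fan_in)` for all weights and biases,
  seeded; this keeps initial pre-activations in the sigmoid's dynamic
  range.
- A seeded shuffled mini-batch mode (`batch_size`) exists for studying
  update noise; full batch is the default because it makes "epoch"
  unambiguous and runs fastest vectorized.

Determinism: a `TrainingConfig.seed` fixes initialization and batch
shuffling; identical configs give bit-identical parameters. Non-finite
loss raises `TrainingFailure` with the epoch; sweep drivers record failed
cells instead of aborting.

## Behavioral matrix ensembles

`generate_random_matrix` places exactly `k` ones per row, uniformly without
replacement — every behavior recruits exactly `k` motor units, so row sums
are conserved by construction. `generate_modular_matrix` splits rows and
columns into `m` equal blocks; each row draws `k - sigma` active columns
uniformly inside its home block and `sigma` outside it. `sigma = 0` is
perfect modularity; increasing `sigma` interpolates toward random mixing.
The placement distribution inside the allowed sets is uniform — the
minimal assumption, since only the block structure and counts are
specified. Matrices with a target modularity are obtained by sweeping
`sigma` and reporting the realized score, not by optimizing toward a
score.

These ensembles emulate the *combinatorial structure* of a motor code:
fixed per-behavior sparsity, optional clustering of behaviors onto motor
pools. They do not emulate graded activation levels, correlations between
behaviors beyond block membership, temporal sequencing, or sensory
feedback — so passing tests say nothing about dynamics, only about the
static encoding problem.

## Descriptors

**Modularity.** The matrix is read as the adjacency of a directed graph on
`max(N, M)` nodes (edge `i -> j` iff entry `(i, j)` is 1), so row-block
`b` and column-block `b` are the same community, and the Newman score is
computed by networkx. The directed convention gives exactly
`(m - 1)/m` for `m` perfect equal blocks (0.8 at `m = 5`) and exactly 0
for a single all-inclusive community; whether a symmetrized convention was
intended elsewhere only affects noisy matrices, and only slightly.

**Entropy.** Closed forms `S = N log2 C(M, k)` and
`S = N log2[C(M/m, k - sigma) C(M - M/m, sigma)]`, evaluated with exact
integer binomials before taking logs, so `C(100, 50)` does not overflow.
Entropy is maximal at `k = M/2` and symmetric under `k <-> M - k`, which
is why "sparsity" means distance of `k` from `M/2`.

## Capacity estimation

`R_c` thresholds the *mean* fraction-learned curve over replicate matrices
at 0.98 on the swept grid (no interpolation; `R_c` is grid-valued). The
per-matrix crossing points are also reported, since thresholding the mean
and averaging per-matrix thresholds differ slightly in noisy regions.
Defaults for replicate counts follow the study design (10 matrices for
modular ensembles; 30 for the sparsity sweep), but every driver takes the
count as a parameter and the test suite runs reduced presets
(`N = M = 40`, 2e4 epochs, 4 replicates) that reproduce the orderings —
sparser and more modular codes need smaller bottlenecks — without the
full compute.

## Perturbations

Forced activation clamps a hidden unit's activation to 1 (deactivation: 0;
pairs: both units). Clamping is the default mechanism because it is exact;
the alternative `weight_injection` overwrites the unit's incoming weights
with ±1e3, which saturates the sigmoid to the same effect and is verified
unit-by-unit equivalent on trained networks. The bias is left untouched:
at ±1e3 the margin dwarfs any trained bias.

Conservation of a command is judged against the trained network's *own*
unperturbed binarized output, not the target — so imperfect learning does
not leak into robustness. Two statistics are reported: strict full-row
equality (the default `robustness`), and a lenient variant
(`robustness_active_only`) in which only switching *off* an originally
active motor unit breaks conservation. The strict reading matches
"outputs unaffected by the perturbation"; the lenient one matches "all
activated motor neurons remain unaffected". They track each other closely
(the lenient score is higher by a few points at the operating points we
measured).

## Mutual information

With uniform priors over the `N` commands and the original output set, the
MI between intended behavior and perturbed output is
`(1/M') sum_{n_i>0} log2(N/n_i)`, where `n_i` counts commands mapped onto
original output `i` and `M'` is the size of the original output set
(`= N` under perfect learning — distinct from the motor-unit count).
Commands mapped to novel rows contribute zero information. Without
stereotypy (all `n_i <= 1`) this reduces to `(conserved/M') log2 N`, i.e.
MI is proportional to robustness; the test suite verifies both the
closed form against a generic evaluation on the empirical joint and the
proportionality on trained networks. When learning is imperfect the
unperturbed outputs can collide; `mean_mutual_information` then uses the
distinct rows as the original output set.

## Problem sizes and numerical choices

The full study scale is `N = M = 100`, 1e5 epochs, 5-10 replicate
matrices; one such training takes tens of seconds on one CPU, so the
headline recomputation (`scripts/acceptance.py`, 11 trainings) runs in
minutes and uses 5 replicates per stochastic quantity. The test suite
works at `N = M <= 40` with shortened training, which preserves every
qualitative ordering at a fraction of the cost. Sigmoid arguments are
clipped at ±500 (well past double-precision saturation) to avoid overflow
warnings; binarization thresholds at exactly 0.5 with ties rounding up.

## Known limitations

- No recurrence, no temporal dynamics, no biophysical neurons — the model
  isolates the static encoding constraint only.
- Perturbations are binary (fully on/off); graded stimulation is out of
  scope.
- Community labels for the modularity score are given by construction,
  never inferred; unequal or overlapping modules are unsupported.
- Gradient descent is not guaranteed to find the network's true capacity;
  `R_c` is an optimizer-dependent operational quantity, which is exactly
  how it is defined in this line of work.
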