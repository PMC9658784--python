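# Methods

This note records the model, the numerical and design choices, what the
synthetic data does and does not emulate, and the known limitations.

## Graph semantics

Networks are multi-directed graphs of named computation nodes. Semantics
follow a small set of rules:

* a node activates only when **all** of its inbound edges for the receptor
  being fired carry a signal; incomplete inbound data is a silent no-op;
* with exactly one inbound edge the signal is unwrapped; with several, the
  node receives the ordered sequence (edge insertion order — the only order
  that defines stacking);
* node outputs are broadcast to every outbound edge, except generators,
  which are split one item per edge in edge order (this is how the
  convolution hands a distinct window cyphertext to each fold node);
  exhausting a generator early is an arity error;
* parallel edges are independent entities with independent signal slots;
* self-loops are left to the node's own termination logic; any other cycle
  raises during traversal (checked against the current recursion path);
* consumed inbound signals are cleared on activation so the next firing
  pass starts clean;
* edges declare which receptors they serve. Prediction branches and label
  ingresses are wired forward-only, which is what makes backward gathering
  well-defined: a decrypt node that feeds both softmax (trainable) and
  argmax (output-only) waits only on the softmax edge for its gradient.

The traversal is depth-first and blocking: a firing seeds one (node,
receptor, signal) triple and recurses into successors until no further node
can activate. Backward passes use the same machinery with the flow
direction reversed, seeded with 1.0 at the loss node.

## Automatic CKKS parameterisation

Discovery labels every node reachable from each cyphertext ingress with the
maximal accumulated multiplicative cost per source, where an edge into node
`B` costs `B.cost()`. Rotation and decrypt nodes are *concern* boundaries:
they truncate the walk and restart as fresh sources at cost zero, because a
rotation re-encrypts under new parameters. Grouping merges sources whose
labels co-occur on any node — the merge loop runs over **all** labelled
sources (ingresses first, then restarts in discovery order) with a
deterministic union-find, so the output is independent of hash ordering.
Correctness is defined against `brute_force_group_cost`, an independent
oracle that enumerates every simple source→boundary path and takes
connected components of the co-occurrence relation; the two agree on 200
random multi-directed graphs (≤ 12 nodes, ≤ 3 parallel edges, costs 0–3)
in the test suite.

Node costs count multiplicative depth only: one level per ct×ct or ct×pt
product stage, zero for additions, because only multiplications force a
modulus switch. Costs per node type: cross-correlation 1 (the masquerade
collapses each window to one Hadamard product), dense 1, polynomial
activations 2, everything else 0.

The CKKS heuristic builds, for group cost `c`, scale power `s` (default 40,
advisory warning below 30) and special-prime multiplier `p` (default 1.5),
the chain `[int(s·p), s × c, int(s·p)]` and chooses the smallest
power-of-two degree whose budget (27 bits per 1024 degree) covers the chain
sum. The 128-bit security level of the standard parameter tables is the
floor this budget rule reflects; no cryptographic claims are made by the
simulator itself.

## The cyphertext meta-object

`CyphertextMeta` packs a message left-justified into `degree/2` slots and
tracks scale, remaining chain, key id and a noise estimate. Multiplication
auto-relinearises and auto-rescales (consuming one prime); mixed-level
operands are aligned by switching the higher operand down; interaction
across keys or parameter sets raises. Values are computed with ordinary
float64 element-wise arithmetic and **no injected error**, so a plaintext
shadow and the encrypted run agree exactly — this is what makes the
equivalence tests bit-tight. Fold rotations sum the message region only
(padding never contributes), preserving that exactness.

Noise bookkeeping is additive in bits: encryption starts at 4 bits, an
addition adds 1, a multiplication adds 3 *net of its rescale*. The real
scheme's behaviour — multiplication is far noisier than addition, and the
rescale is what keeps growth manageable — is preserved as the qualitative
ordering, which is the tested contract; the constants sit in a configurable
`NoiseModel`. Decryption warns once fewer than 6 bits of headroom remain
below the scale and fails (garbles) at the scale itself. A `noisy=True`
backend adds seeded Gaussian slot noise scaled by `2^(noise_bits − scale)`
for robustness experiments; it is off by default because exactness is the
more valuable test property.

## Layers

Slot layout is the row-major flatten of the input tensor, 0-based, valid
(no-padding) windows, per-axis strides ≥ 1. The commuted bias uses the
`b/N` decomposition inside each product (`z = Σ(x_i w_i + b/N)`) because it
keeps the ordinary gradient rule `∂z/∂b = 1`; the alternative of adding the
full `b` per term and compensating with an `N`-scaled bias gradient is
algebraically equivalent but couples the gradient to the window size, so it
is documented rather than implemented.

The dense node takes its inputs as the ordered sequence carried by a single
inbound edge and weights each branch before summing. The per-branch
weighting form is the one consistent with a neuron that merges divergent
window/filter branches; for the scalar-per-branch case used by both built
networks it coincides with summing first.

The ReLU approximation's range `q` is updated during training by an
exponential moving average of the batch maximum magnitude (α = 0.1,
floor 10⁻³) so the polynomial's valid window follows the activations it
sees; a gradient-based update via `∂Ra/∂q = −4x²/(3πq²) + 1/(3π)` is
available behind `q_policy="grad"`. Neither rule is canonical — the choice
of EMA as default is ours, made for stability.

There is no max-pooling (a cyphertext exposes no order information —
strided convolution is the only down-sampling) and no batch normalisation;
the ReLU range tracker is the stabiliser. Softmax subtracts the maximum
before exponentiation; cross-entropy clamps logs at 10⁻¹²; argmax ties
break toward the lowest index. These are numerical-safety conventions, not
modelling choices.

## Networks and training

*sphira* (classification): flattened image → encrypt → masqueraded CC (one
filter by default; `n_filters` extends it) → one fold rotation per window →
activation → one dense neuron per class → activation → decrypt → softmax +
CCE (loss branch, fed by the one-hot label) and argmax → decode (prediction
branch). The ingress group costs 1 (the CC product), the post-rotation
group 5 (2 + 1 + 2), and the plaintext tail 0, so the automatic
parameterisation gives the ingress a 3-prime chain and the fold group a
7-prime chain; the depth-sufficiency tests confirm the provisioning is
exact — one more multiply anywhere would fail.

*constellation* (regression): feature-window → encrypt → 1-D CC spanning
the full feature axis → folds → sigmoid → dense merge → sigmoid → decrypt →
prediction + MSE. Targets are scaled by twice the training maximum so the
final sigmoid's comfortable output range covers them; predictions are
scaled back before reporting.

Training is stochastic gradient descent with batch size 1 (one firing per
example, matching the traversal's structure), learning rate 0.1 by default,
weights plaintext throughout. Labels travel in plaintext to the loss
circuit: the loss is necessarily computed after decryption either way, and
carrying the label encrypted up to that boundary adds a parameter group
without changing any computed value. FHE-side training, bootstrapping and
an FHE softmax are explicitly out of scope.

## Synthetic data

The image generator produces 8×8 geometric prototypes (bars, cross,
diagonal, block, ring, checker, corner) plus Gaussian noise clipped to
[0, 1], balanced classes ±1. It emulates the *pipeline shape* of an image
classification task (normalised pixel grids, label + pixel CSV dialect) at
a size where encrypted inference is desk-scale; it does not emulate the
visual complexity of real image sets, so passing tests demonstrate the
machinery, not state-of-the-art vision.

The yield generator drives twelve daily features (temperature, humidity,
light, wind speed/direction, precipitation, soil moisture and temperature,
irrigation status) from smooth seasonal + AR(1) latent weather, over
non-overlapping windows — overlapping randomly-split sequences would leak
future information, so the windows are disjoint and a time-blocked split
mode is provided. The target is a fixed, documented response: mean yield
1.2 scaled by `1 + 0.18·tanh(0.9·gdd + 0.6·light − 0.5·stress +
0.2·irrigation)` over standardised window aggregates, times multiplicative
noise with σ = noise_sd·√(horizon/7), so longer horizons are harder *by
construction*. Because the mapping is known, it doubles as the
parameter-recovery oracle: the regression network reaches < 5% held-out
MAPE on noiseless data. Real agronomic data has regime changes, missing
values and non-stationary noise that this generator deliberately omits.

## Problem sizes

The shipped experiments use sizes chosen to keep a full run on one CPU
comfortable: 200 images (two classes) for classification learning, ten
initialisation seeds per activation for the stability comparison (measured
as across-seed variance of first-epoch training accuracy — an
initialisation-stability probe; at convergence both variants saturate on
the separable toy task), 240 windows per horizon for regression, 50 random
inputs per network for the exact plaintext/cyphertext equivalence checks,
and 200 random graphs for the parameterisation oracle. All are pure
functions of their seeds.

## Known limitations

* The simulated backend models chain and noise bookkeeping but performs no
  encryption; security properties must come from a real backend plugged
  into `BackendInterface` (the parameter floors then follow the standard
  128-bit tables).
* Only inference is encrypted; gradients require the plaintext shadow and
  the backward receptors refuse cyphertext caches.
* One convolution filter and one layer per topology by default — the
  framework supports more via configuration, but deeper stacks need more
  rotation stages or larger chains.
* The traversal is recursive and single-threaded; very deep graphs would
  hit recursion limits before performance limits.
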