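# fhenet

Encrypted deep-learning over multi-directed computation graphs, with
automatic levelled-CKKS parameterisation.

## The problem

Fully homomorphic encryption (FHE) lets a third party compute on data it can
never read: a client encrypts its inputs, the server evaluates a neural
network directly on the cyphertexts, and only the client can decrypt the
predictions. This matters most where data will not be shared otherwise —
medical records, trade secrets, and agri-food operations such as fruit-yield
forecasting, where growers treat environmental and yield records as
commercially sensitive.

Levelled CKKS, the FHE scheme used here, imposes hard constraints that rule
out ordinary deep-learning libraries:

* cyphertexts are SIMD slot vectors (capacity = polynomial degree / 2) that
  can only be operated on **whole** and **element-wise**; a single slot can
  never be read, so there is no max-pooling, no argmax, no folding a
  cyphertext onto itself;
* only addition and multiplication exist; division, exponentials and
  comparisons (softmax, exact ReLU/sigmoid, losses) must be approximated by
  low-degree polynomials or moved behind a decryption boundary;
* every multiplication consumes one prime of a finite modulus-switching
  chain; the chain length must be decided **at encryption time**, so the
  multiplicative depth a cyphertext will experience must be known in
  advance; and cyphertexts that interact must share parameters and key.

`fhenet` addresses the last point automatically. Networks are *node-centric
multi-directed graphs*: nodes are computation objects exposing `forward` and
`backward` receptors, edges move signals between them, and an edge's weight
is the multiplicative-depth cost of the node it points to. A depth-first
*neuronal firing* procedure activates a node once all of its inbound edges
carry data, then propagates the result (broadcast, or split per-edge for
generator outputs).

## Automatic parameterisation (autoFHE)

Given the graph, the parameteriser:

1. **discovers** sources and costs — walks every path from each cyphertext
   ingress, labelling each node with the maximal accumulated cost per
   source, truncating and restarting at *concern* nodes (key rotations and
   decrypts, where keys change);
2. **groups** sources whose labels co-occur on any node (they interact, so
   they must share parameters and key), taking each group's cost as the
   longest path any member must survive;
3. **parameterises** each group with an RNS-CKKS heuristic: for cost `c` and
   scale power `s` (default 40) a coefficient-modulus chain of `c` primes of
   `s` bits flanked by two special primes of `int(1.5 s)` bits, and the
   smallest power-of-two polynomial degree whose bit budget (27 bits per
   1024 degree) covers the chain, e.g. `c=3, s=40` → chain
   `[60, 40, 40, 40, 60]`, degree 16384.

A deterministic simulated CKKS backend (`fhenet.ckks`) enforces the
constraint list on every call — automatic relinearisation and rescaling,
chain accounting, modulus-switch alignment of mixed-level operands, a noise
estimate, and hard errors on key mismatch or depth exhaustion — while
keeping slot values numerically exact, so encrypted and plaintext runs of
the same graph agree bit for bit. A `BackendInterface` seam accepts real
CKKS libraries.

## FHE-compatible layers

* **Kernel masquerade** — each convolution window's kernel is merged with a
  zero mask into one input-shaped sparse tensor, so a whole-cyphertext
  Hadamard product realises the window in a single multiplicative level;
  the layer emits one cyphertext per window via a generator.
* **Commuted bias** — the bias is distributed as `b/N` into each of the `N`
  window products so the later fold-sum (a key rotation that re-encrypts
  the slot sum) reproduces `Σ x_i w_i + b` exactly:
  `z = Σ_i (x_i w_i + b/N)`.
* **Polynomial activations** — ReLU ≈ `(4/3πq)x² + x/2 + q/3π` with a
  dynamically tracked range `q`, and sigmoid ≈ `0.5 + 0.197x − 0.004x³`;
  both cost two levels and run identically on plaintexts.
* **Plaintext circuits** — softmax (`e^{a_i}/Σ_j e^{a_j}`), categorical
  cross-entropy, argmax/one-hot prediction and MSE live behind the
  decryption boundary and refuse cyphertexts explicitly.

Two reference topologies are built in: **sphira** (image classification:
CC → fold rotations → activation → one dense neuron per class → activation
→ decrypt → softmax/CCE loss and argmax prediction branches) and
**constellation** (1-D time-series regression for environmental yield
forecasting: CC over time → sigmoid → dense merge → sigmoid → decrypt →
prediction and MSE). Training is plain SGD on the plaintext shadow — FHE
training is out of scope; inference runs on either representation.

## Worked example

```python
import numpy as np
from fhenet import (build_sphira, sphira_mini_config, train, infer,
                    parameterise_ckks)
from fhenet.data import gen_toy_images, split_train_test

params = parameterise_ckks(3)          # provision for 3 multiplications
print("chain:", params.coeff_mod_bit_sizes,
      "degree:", params.poly_modulus_degree,
      "slots:", params.slot_capacity)

dataset = gen_toy_images(n=200, shape=(8, 8), K=2, noise_sd=0.1, seed=42)
train_set, test_set = split_train_test(dataset, 0.8, seed=42)

graph = build_sphira(sphira_mini_config(seed=42))
groups = graph.meta["groups"]
print("parameter groups (cost):",
      {i: c for i, c in enumerate(groups.group_cost)})

history = train(graph, train_set, epochs=10, stop_accuracy=0.99)
print(f"epoch {len(history['loss'])}: loss={history['loss'][-1]:.4f} "
      f"accuracy={history['accuracy'][-1]:.3f}")

x = test_set.images[0]
print("plaintext prediction: ", infer(graph, x))
print("cyphertext prediction:", infer(graph, x, encrypted=True))
```

prints

```
chain: (60, 40, 40, 40, 60) degree: 16384 slots: 8192
parameter groups (cost): {0: 1, 1: 5, 2: 0}
epoch 2: loss=0.0023 accuracy=1.000
plaintext prediction:  0
cyphertext prediction: 0
```

The three parameter groups are the ingress segment (one multiplication — the
masqueraded convolution — before the fold rotations), the post-rotation
segment (activation 2 + dense 1 + activation 2 = 5 levels), and the
zero-cost plaintext tail behind the decrypts. Training converges within two
epochs on the separable toy images, and the encrypted forward pass returns
exactly the plaintext prediction.

The same workflow is available from a shell:

```bash
fhenet parameterise sphira-mini
fhenet generate -c config.json
fhenet train -c config.json
fhenet infer -c config.json
```

## Layout

```
src/fhenet/
  graph.py      multi-directed graph + neuronal firing (receptors, signals)
  autofhe.py    source/cost discovery, group merging, CKKS heuristic
  ckks.py       cyphertext meta-object + simulated backend
  layers.py     masqueraded CC, dense, activations, loss/prediction circuits
  networks.py   sphira / constellation builders, train / infer, MAPE
  data.py       synthetic images & yield series, CSV reader, splits
  serialise.py  node-link JSON + array archive persistence
  cli.py        command-line surface
docs/methods.md  model assumptions, parameter choices, limitations
```
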