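# kneemil

Exam-level multi-label classification of three-view knee MRI studies —
multiple-instance learning over slices with multi-scale attention
aggregation, learned view fusion, a seed-paired evaluation protocol,
and a constrained performance-optimization solver.

## The problem

A knee MRI examination is three stacks of grayscale slices acquired in
orthogonal planes (sagittal, coronal, axial), annotated only at the
study level with three binary labels: *abnormal*, *ACL tear*,
*meniscus tear* (any tear implies abnormal). The modelling question is
how to map an ordered bag of slices per view — with no slice-level
supervision — to three calibrated exam probabilities. This is a
multiple-instance learning problem: evidence for a tear is usually
concentrated in a few contiguous slices of particular views, so how
slice embeddings are *aggregated* matters as much as how they are
encoded.

`kneemil` is a desk-scale, fully seedable workbench for this task. It
ships its own synthetic exam generator (benchmark directory layout,
planted label-dependent lesions), so every stage — preprocessing,
training, evaluation, statistics — runs end-to-end on one CPU with no
downloads.

## The model

Each slice is encoded by a shared strided convolutional encoder into a
D-vector. Within each view the sequence of S slice embeddings
`h_1..h_S` is summarized by the multi-scale attention aggregator:

1. **Multi-scale temporal pooling** — sliding-window means along the
   slice axis at kernel sizes {1, 3, 5} (windows truncated at stack
   edges), capturing evidence at different anatomical extents;
2. each scale is projected D → E, given learned scale and positional
   embeddings, and the three token sets are concatenated (3S tokens);
3. **self-attention** — pre-norm multi-head scaled-dot-product layers
   mix tokens across slices and scales;
4. **learned-query readout** — softmax weights `a_i` over tokens give
   the view embedding `z = Σ a_i t_i`; the weights are exposed for
   inspection of which slices drove the prediction.

The three view embeddings are fused by concatenation and a two-layer
MLP producing three logits; sigmoids give the exam probabilities
`P(y_k = 1 | exam)`, trained with per-label binary cross-entropy.
Mean pooling, max pooling and gated attention-MIL pooling
(`a_i ∝ exp(wᵀ(tanh(V h_i) ⊙ σ(U h_i)))`) are built in as aggregation
baselines, and view-averaging replaces learned fusion for ablations.

Evaluation reports macro AUROC, macro AUPRC, macro F1 at threshold
0.5, and the Brier score, each macro-averaged over the three labels;
multi-seed comparisons use mean ± sample sd and two-sided paired
t-tests, paired by seed.

A separate module formalizes performance planning under biomechanical
feasibility constraints: minimize `J(u) = -P(u) + β·R(u)` over an
action vector `u` subject to box bounds, a step-smoothness budget
`‖u_{t+1} − u_t‖₂ ≤ δ` and squared-hinge inequality penalties, solved
by projected gradient descent with gradients from the package's own
reverse-mode automatic differentiation. The same autodiff engine
powers the neural model, so the whole package has no deep-learning
framework dependency.

## Worked example

```bash
python examples/03_train_and_evaluate.py
```

trains the tiny configuration (S=8 slices at 32 px, 32-dim encoder,
one attention layer) for five epochs on 200 synthetic exams and prints:

```
validation macro AUROC by epoch: [0.683, 0.957, 1.0, 1.0, 1.0]
selected epoch: 2

test metrics (one row per label + macro average):
   label  auroc  auprc  f1  brier
abnormal    1.0    1.0 1.0    0.0
     acl    1.0    1.0 1.0    0.0
meniscus    1.0    1.0 1.0    0.0
   macro    1.0    1.0 1.0    0.0
```

The planted lesions are fully recoverable at this signal strength, so
a converged run ranks every positive above every negative (AUROC 1.0)
with near-zero Brier score; the learning curve shows the model finding
the signal within two epochs. The other scripts in `examples/` cover
dataset generation, preprocessing, the seed-paired protocol, the
constrained optimizer, and the multimodal extension units.

A thin CLI wraps the same library functions:

```bash
kneemil synth --config config.yaml --out data/
kneemil train --config config.yaml --out run/
kneemil protocol --config config.yaml --methods multiscale_attention,mean --out tables/
kneemil pom --problem problem.yaml --out trace.csv
```

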