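# poismix

Unsupervised learning with a normalized Poisson mixture — by batch EM, and by
an online neural circuit in which feedforward inhibition, Hebbian plasticity
with synaptic scaling, and softmax lateral competition together approximate
that EM.

## The scientific problem

Cortical circuits combine two normalization mechanisms that both regulate a
neuron's total drive: fast, unspecific **feedforward inhibition** (which
effectively normalizes each stimulus to a constant total intensity) and
**synaptic scaling** (a homeostatic, activity-gated rescaling of a neuron's
excitatory weights).  This package implements a concrete model of their
interaction during learning and the statistical model that makes the circuit's
computation interpretable:

**Generative model.**  A stimulus `y ∈ R_+^D` belongs to one of `C` classes;
class `c` has a *generative field* `W_c` (a mean-rate pattern) and pixels are
independent Poisson draws, `y_d ~ Poisson(W_cd)`.  Classes are equally likely
and every field is normalized to a common total, `Σ_d W_cd = A`.  Under this
constraint the class posterior collapses to a softmax of synaptic-drive-like
projections

    p(c | y) = softmax_c ( Σ_d y_d log W_cd ),

exactly the computation of a population of neurons with logarithmically
saturating synapses and softmax lateral inhibition.

**Neural learning rule.**  Weights change online by Hebbian plasticity with
multiplicative synaptic scaling,

    ΔW_cd = ε g_c (y_d − W_cd),      g = softmax(Σ_d y_d f(W_cd)),

with `f(w) = log w` for `w ≥ 1` (and `w − 1` below), or fully linear
`f(w) = w − 1`.  With inputs normalized to `A`, each weight row's sum is
automatically attracted to `A` (no global normalization signal needed), and
the learned weights approximate the maximum-likelihood generative fields: the
circuit's fixed points satisfy `W_cd ≈ ⟨g_c y_d⟩ / ⟨g_c⟩`.  Batch EM for the
same model (E-step: the softmax posterior; M-step:
`W_cd = A Σ_n q_nc y_nd / Σ_n q_nc Σ_d' y_nd'`) is the optimal reference.

The practical payoff studied here: learning on the normalized stimulus
subspace avoids locally optimal solutions far more often than learning on
unnormalized stimuli, and removing feedforward inhibition while keeping
synaptic scaling breaks learning badly.

The package provides, as scikit-learn style estimators and thin functional
wrappers:

- `PoissonMixtureEM` — constrained/unconstrained batch EM with optional
  linear annealing of `A` and free-energy monitoring;
- `NeuralCircuitLearner` — the online learner with plain/offset/off input
  normalization, log-saturating or linear synapses, and synaptic scaling /
  explicit weight normalization / pure Hebbian controls;
- `MixtureLabelClassifier` and `knn_classify` — a second processing stage
  that attaches class labels to the learned components from a small labeled
  subset (`p(l|y) = Σ_c T[l,c] p(c|y)`), plus an L3-norm k-NN baseline;
- a blocks stimulus generator (overlapping rectangles with Poisson noise,
  constrained and unconstrained-contrast variants), an MNIST IDX reader,
  field matching / replication harnesses, and a `poismix` CLI
  (`generate`, `train-em`, `train-circuit`, `classify`, `replicate`,
  `report`).

It is aimed at computational-neuroscience and machine-learning researchers
who want a compact, tested reference implementation of posterior-as-circuit
learning and its ablations.

## Worked example

```python
import numpy as np
import poismix as pm

spec = pm.BlocksSpec(seed=0)                      # 16x16 grid, C=4, A=300
X, labels, truth = pm.generate_blocks_dataset(spec, 1000)

em = pm.PoissonMixtureEM(n_components=4, A=300.0, random_state=0).fit(X)
print(f"EM converged after {em.n_iter_} iterations, "
      f"log-likelihood {em.trace_.final_loglik:.1f}")

circuit = pm.NeuralCircuitLearner(variant="log_saturating", A=300.0,
                                  random_state=0).fit(X)
print(f"circuit final log-likelihood {circuit.trace_.final_loglik:.1f}")

for name, fields in [("EM", em.fields_), ("circuit", circuit.weights_)]:
    m = pm.match_fields(fields, truth)
    print(f"{name}: per-field error {np.round(m.per_field_error, 3)}, "
          f"global optimum: {m.is_global}")
```

Output:

```
EM converged after 10 iterations, log-likelihood -352684.7
circuit final log-likelihood -352858.6
EM: per-field error [0.045 0.049 0.046 0.045], global optimum: True
circuit: per-field error [0.045 0.049 0.046 0.044], global optimum: True
```

The four rectangle fields are recovered up to class permutation by both
learners (per-field normalized mean absolute error well under the 0.15
global-optimum threshold), and the online circuit lands within a fraction of
a percent of the EM likelihood.

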