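# hillode

Prior-regularized Hill-kinetics neural ODEs for learning gene-regulatory
dynamics from (pseudo)time-series expression data — and for extracting the
signed gene regulatory network (GRN) the learned dynamics encode.

## The problem

Temporal gene-expression patterns are driven by a sparse causal network of
transcription-factor (TF) → target interactions. Fitting an ordinary
differential equation dg/dt = f(g) to expression trajectories can both
predict unobserved time points and, if the model is structured well, expose
that network. Generic black-box ODE learners predict well but encode
gene-gene correlations rather than regulation; rigid kinetic models do not
scale. `hillode` sits in between: a neural ODE whose architecture mimics
Hill-Langmuir binding kinetics, regularized toward a user-supplied prior
network so that the fitted dynamics stay biologically parsimonious.

## The model

Expression values are normalized to [0, 1]. The derivative of the n-gene
state g is modeled as a feedback process

    dg/dt = ReLU(v) ⊙ ( W∪ [cΣ(g) ; cΠ(g)] − g )

with an additive and a multiplicative single-layer block,

    cΣ(g) = WΣ φΣ(g) + bΣ
    cΠ(g) = exp( WΠ φΠ(g) + bΠ )

and Hill-like activations centered on the middle of the expression range,

    φΣ(x) = (x − 0.5) / (1 + |x − 0.5|)        (shifted softsign)
    φΠ(x) = log( φΣ(x) + 1 )

The Hill-Langmuir occupancy curve H(P) = P^α/(κ^α + P^α) is softsign-shaped
in (P/κ)^α, so these activations let single units encode sigmoidal TF
effects; the log/exp pair turns hidden-layer sums into products, capturing
multiplicative co-regulation. The per-gene gate ReLU(v_i) can freeze genes
with no upstream regulators exactly.

Training minimizes

    L_mod = (1 − λ_prior) · L_data + λ_prior · L_prior

where L_data is the mean squared error between observed transitions and the
model's integrated predictions, and L_prior compares the model's velocity at
random "ghost" states γ_k ~ U(0,1)^n against the linear prior prediction
P*(γ) = (A − I)γ built from a signed prior adjacency A ∈ {−1,0,+1}^(n×n)
(e.g. a promoter motif map). λ_prior is tuned on a validation split.

Because the fitted derivative network is smooth and closed-form, the encoded
GRN is read out directly from model coefficients: the score of edge j → i is
the mean analytic Jacobian ∂(dg_i/dt)/∂g_j over reference states, with the
architectural self-decay removed from the diagonal. No sensitivity analyses
or perturbation runs are needed.

The package also ships

- a **simulator** of ground-truth signed GRNs (heavy-tailed out-degrees,
  per-edge Hill kinetics) and noisy trajectories, so the full
  train → extract → evaluate loop runs with no external data;
- **evaluation** metrics (edge-recovery AUC, out-degree correlation, and the
  balanced-accuracy-optimal threshold C_max with its TPR/TNR);
- **perturbation analysis**: gene influence scores (mean downstream change
  after perturbing one gene's initial value) and pathway influence scores
  with permutation p-values and z-scores (GMT input).

## Worked example

Simulate a 20-gene / 34-edge system, add 2.5% noise, corrupt the prior
commensurately, fit, and evaluate:

```python
import numpy as np
import hillode as h

cfg   = h.SimConfig(n_genes=20, n_edges=34, n_trajectories=60, seed=7)
truth = h.generate_grn(cfg)
trajs = h.add_noise(h.simulate_trajectories(truth, cfg), 1/40, seed=8)
train, val, test = h.split_trajectories(trajs, (40, 10, 10), seed=9)
prior = h.corrupt_prior(truth, 0.05, seed=10)

est = h.HillODE(lambda_prior=0.1, epochs=600, random_state=0).fit(
    train, prior=prior, validation=val)
grn = h.extract_grn(est.params_)
rep = h.evaluate(grn, truth.adjacency)
print(f"AUC={rep.auc:.3f} rho_out={rep.rho_out:.3f} "
      f"TPR/TNR at C_max: {rep.tpr_max:.2f}/{rep.tnr_max:.2f}")
```

prints

```
AUC=0.991 rho_out=0.722 TPR/TNR at C_max: 0.97/0.97
```

i.e. ranking candidate edges by |extracted score| recovers the generating
edge set almost perfectly (AUC 0.991), estimated regulator strength tracks
true out-degree (Spearman ρ 0.72), and at the best single threshold 97% of
true edges and 97% of non-edges are classified correctly. Influence scores
from the same fitted model rank the network's hub regulators highest:

```python
infl = h.influence_scores(est.params_, n_init=100, seed=0)
```

A command-line interface covers the same pipeline:
`hillode simulate | train | extract-grn | evaluate | perturb | pathways`
(see `hillode --help`).

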