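# mlscape

Energy-landscape analysis of machine-learning cost functions, applied to
clinical outcome prediction.

Training a classifier means minimizing a cost function over its parameters —
a surface that, for non-convex models, supports many local minima connected
by saddle points, exactly like the potential energy surface of a molecule.
`mlscape` brings the molecular-landscape toolchain (basin-hopping global
optimization, transition-state searches, disconnectivity graphs) to the
landscapes of two softmax classifiers trained to predict binary hospital
outcomes (death in hospital vs. survival) from irregular 48-hour time series
of vital-sign and laboratory measurements. It is written for researchers who
want to ask not just *how well does the fit predict* but *what does the
training landscape look like* — how many minima exist, how they are
connected, and whether the landscape's funnel structure explains why short
global-optimization runs reliably find the best fit.

The original study ran on a credentialed critical-care database that cannot
be redistributed, so the package ships a synthetic-cohort generator with a
known latent logistic outcome model: every pipeline stage is testable
against a computable Bayes-optimal answer.

## Models and cost

Two fitting functions map scaled patient features `x ∈ R^{N_in}` to a pair
of outputs, one per outcome class:

- a three-layer neural network with one tanh hidden layer,

  `y_i = w_i^bo + Σ_j w_ij^(1) tanh(w_j^bh + Σ_k w_jk^(2) x_k)`,

- a convex quadratic alternative,

  `y_i = w^(0)(i) + Σ_k w_k^(1)(i) x_k + Σ_{k, j≥k} w_kj^(2)(i) x_k x_j`,

  with `N_out (1 + N_in (N_in + 3)/2)` parameters.

Outputs become class probabilities by softmax, `p_c = e^{y_c} / (e^{y_0} +
e^{y_1})`, and the training cost is the regularized cross-entropy

`E(W; X) = −(1/N_data) Σ_α ln p_{c(α)}(W; x^α) + λ W²`,

where `W²` penalizes **all** parameters, biases included — which lifts the
softmax bias-shift zero mode to an exact Hessian eigenvalue `2λ`. First and
second derivatives of both costs are analytic, which the saddle-point
machinery requires.

Local minimization is a custom L-BFGS (RMS-gradient convergence, `10⁻⁶`
loose / `10⁻¹⁰` tight) with a modified-Newton finishing stage; global
optimization is basin-hopping with a Metropolis accept/reject step, storing
every distinct minimum found. Transition states (index-1 saddles) are
located by a doubly-nudged elastic band followed by hybrid
eigenvector-following, and the resulting stationary-point databases are
rendered as disconnectivity graphs. Prediction quality is the area under
the ROC curve on held-out patients, computed per Eq.-level semantics: the
trapezoidal integral of `T_pr` over `F_pr` equals the Mann–Whitney pairwise
statistic (death = positive class = outcome 0).

## Worked example

`examples/simulate_and_fit.py` generates a 1000-patient synthetic cohort
(three informative measurements, latent logistic outcome model), assembles
last-hour features, and fits both classifiers:

```
cohort: 1000 patients, 389 deaths
Bayes-optimal AUC of the generating model: 0.791
features: 719 complete patients, 359 train / 360 test
quadratic fit: test AUC 0.807 (1 minimum — convex)
network fit:   test AUC 0.801 (best of 2 distinct minima, at minimum #1)
```

The Bayes oracle (0.791) is the discrimination achievable by the true
generating log-odds; both fits land within test-set sampling error of it,
confirming the pipeline recovers the signal. The quadratic cost, being
strictly convex, can only ever hold one minimum; the network cost holds
several, and the best held-out AUC over all of them is reported.

Other examples: `landscape_tour.py` (minima → transition states →
disconnectivity graph on an analytic three-well landscape, barriers checked
against closed forms), `sweep_design.py` (combinatorial survey enumeration
and a miniature sweep), `roc_basics.py` (ROC/AUC semantics). A thin CLI
wraps the same pipeline: `mlscape simulate | fit | sweep | landscape |
dgraph | evaluate` (see `--help`).

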