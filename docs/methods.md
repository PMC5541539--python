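# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `mlscape`, in the order data flows through the package.

## Synthetic cohorts

Real critical-care records are irregular: each patient carries timestamped
measurements of some subset of a measurement panel over a 48-hour window,
plus a binary outcome (0 = death in hospital, 1 = survival). The generator
(`mlscape.cohort`) emulates that structure from a fully known model so that
downstream estimates have a computable target:

- **Latent values.** Each patient has one latent value per measurement item,
  drawn i.i.d. lognormal with unit mean (shape `σ = 0.5`, location
  `μ = −σ²/2`). Lognormal keeps values positive like physiological
  measurements, and unit mean makes the pipeline's divide-by-mean feature
  scaling a near-identity, so recovery experiments are interpretable.
- **Outcome.** Bernoulli with log-odds of death equal to
  `intercept + Σ_k coeff_k · latent_k`. The Monte-Carlo AUC of this true
  log-odds (`oracle_bayes_auc`) is the Bayes-optimal discrimination — an
  upper bound in expectation on what any fitted model can reach.
- **Observations.** Per present item, a Poisson number of timestamps
  (default intensity 5 per 48 h, matching sparsely measured labs) uniform on
  [0, 48), each observing `latent + N(0, noise_sd)` with default
  `noise_sd = 0.1` (small relative to the latent spread ≈ 0.53, so hourly
  averaging has something to average without drowning the signal).
- **Missingness.** Item-wise per patient (the whole item absent with
  probability 0.1 by default), mirroring the per-item patient counts of real
  panels and exercising the pipeline's per-combination exclusion rule.

All randomness flows from a single integer seed through one generator in a
fixed draw order, so cohorts are bitwise reproducible.

What the generator does **not** model: correlations among items, temporal
drift within the window, informative missingness, outcome-dependent
measurement frequency. Tests passing on these cohorts therefore validate
the *machinery* (windowing, fitting, landscape mapping, AUC semantics), not
clinical transportability.

## Preprocessing

Hourly windows are indexed backwards in time: window 1 is the most recent
hour, window 48 the earliest. Window `i` covers `(48−i, 48−i+1]` hours from
the window start; the half-open convention prevents double counting, and a
timestamp of exactly 0.0 (legal, but on no half-open boundary) is assigned
to window 48. Measurements of an item are averaged within each window.

Empty windows are filled from the *chronologically earliest* non-empty,
non-zero hourly average — i.e. the largest-index window. We read
"earliest" literally as earliest in time; a latest-value carry-forward
would also be clinically defensible but is not what the rule says. A
patient with no non-empty non-zero window for a requested item is flagged
all-missing and excluded from that item combination, which is why the
usable patient count varies with the combination. The degenerate case of a
vector whose only observations average exactly zero likewise has no fill
source and is treated as all-missing.

A feature is the mean of the filled windows over the requested hour range.
Each column is then **divided** by its mean over all patients (an additive
shift would also "shift the mean to unity" but would not preserve the
positive, ratio-scaled character of the inputs). The means are computed
over the full population — train and test together — which mirrors the
original pipeline's per-item all-patient averages; it is a mild, documented
information leak that affects only the two scaling constants per column.
The split itself is a seeded random partition into equal halves, the extra
patient going to testing when the count is odd.

## Cost surfaces

Both classifiers produce two outputs `(y_0, y_1)` turned into probabilities
by a max-subtracted softmax; log-probabilities are computed as
`y_c − logsumexp(y)`. The cost is mean cross-entropy plus `λ ‖W‖²` over
the *entire* parameter vector including biases. Penalizing biases is
deliberate: unregularized, the cost is exactly invariant under a uniform
shift of both output biases (softmax sees only `y_0 − y_1`), producing a
zero Hessian eigenvalue everywhere; the ridge term turns that direction
into an exact eigenvector with eigenvalue `2λ`, which the tests verify to
near machine precision.

Gradients and Hessians are fully analytic. The network Hessian is the
Gauss–Newton term `J^T (diag(p) − p p^T) J` plus the curvature of the tanh
layer (first and second derivatives of tanh through the hidden
activations), assembled block-wise; the quadratic model's outputs are
linear in its parameters (constant, linear, and one copy of each unordered
input pair), so its data Hessian is the pure Gauss–Newton form and the
total cost is strictly convex with smallest eigenvalue ≥ `2λ`. Finite
differences appear only in tests, as the independent oracle.

Parameter flattening orders are fixed (network: output biases, hidden
biases, hidden→output weights row-major, input→hidden weights row-major;
quadratic: constants, linear row-major, upper-triangle quadratic row-major)
so serialized databases and optimization traces are stable.

## Local minimization

The minimizer contract is a root-mean-square gradient bound,
`‖g‖/√dim ≤ tol`, with `10⁻⁶` for in-loop ("loose") minimizations and
`10⁻¹⁰` ("tight") for every minimum stored in a database — tight enough
that distinct minima are distinguishable by cost value alone.

The workhorse is a hand-written L-BFGS (memory 10, Armijo backtracking with
quadratic interpolation, per-iteration Euclidean step cap, memory reset on
non-descent directions). With small ridge coefficients the cost has
eigenvalues down to `2λ ≈ 10⁻⁵`, and a first-order method crawls over the
last orders of magnitude of gradient norm; when a Hessian is available the
pipeline therefore hands off to a modified-Newton stage (spectrum clamped
positive through an eigendecomposition, monotone acceptance) once L-BFGS
reaches `10⁻⁴`. If the Newton stage stalls — it can zigzag where negative
curvature separates basins — the two stages alternate with a progressively
tighter handoff before the minimization is declared failed. A variant of
the L-BFGS core without line search relaxes elastic bands, whose
doubly-nudged force is not the gradient of any scalar.

## Basin-hopping

Global optimization perturbs every coordinate of the last *accepted*
minimum by independent uniform draws in `[−s, +s]`, re-minimizes at the
loose tolerance, and accepts by the Metropolis rule (downhill always;
uphill with probability `exp(−ΔE/T)`). Defaults `s = 1.0`, `T = 1.0` in
cost units are deliberately large — the aim is a survey of minima, not a
careful anneal — and both are exposed in `BasinHopConfig`. Every new
minimum, accepted or not, is re-converged at the tight tolerance and
stored. Starting weights, when not supplied, are uniform in `[−1, 1]` per
coordinate, matching the scale of unit-mean features.

The minima database deduplicates on cost value (absolute tolerance `10⁻⁸`,
two orders above the tight convergence floor and well below typical minima
gaps) *and* parameter coincidence (relative Euclidean tolerance `10⁻²`).
The parameter check exists because exactly degenerate minima are real:
symmetry-related network fits (hidden-node permutations, tanh sign flips)
and the toy fixtures' mirror wells share one cost value while being
distinct points, and the landscape machinery must keep them apart.
Energy-tied entries are kept in insertion order, which makes database
serialization order-stable. Note one consequence: symmetry copies of the
same fit count as separate minima in database sizes.

## Transition states and disconnectivity

Saddle candidates between a minima pair come from a doubly-nudged elastic
band: 11 interior images (default) linearly interpolated between fixed
endpoints, relaxed under the perpendicular component of the true gradient
plus the parallel spring gradient plus a retained fraction (0.1) of the
perpendicular spring component, with spring constant 1.0 and band tolerance
`10⁻³`. Chain-local maxima in cost are the candidates. These defaults are
config-exposed; the validation landscapes are insensitive to them.

Hybrid eigenvector-following refines a candidate to an index-1 saddle: per
outer iteration, a bounded uphill Newton step along the smallest-eigenvalue
Hessian direction, then L-BFGS minimization with gradient projected off
that direction. The smallest eigenpair comes from a dense
eigendecomposition — all landscapes handled here have at most a few dozen
parameters, so iterative eigensolvers would add complexity without benefit.
Convergence is on the full RMS gradient at the tight tolerance, after which
the Hessian index is verified to be exactly one (anything else raises).

Steepest-descent connectivity displaces `±10⁻³‖W‖` (floor `10⁻⁴`) along
the downhill eigenvector and minimizes tightly; the two endpoints are
matched to database minima by parameter-space proximity (robust to
degenerate energies), inserting new minima when no match exists. Database
connection proceeds nearest-pair-first (Euclidean distance between minima
in different components) within a pair-attempt budget.

The disconnectivity graph partitions minima into superbasins at thresholds
`E_min + i·ΔE`: two minima share a superbasin when a path of transition
states at or below the threshold links them. Merges are recorded as tree
nodes (children ordered by basin size, then energy); the minimax "downhill
barrier" from any minimum to the global minimum — the quantity whose
smallness defines a single-funnel landscape — is computed on the minimum
spanning tree of the transition-state graph, whose path realizes the
minimax edge value.

## Evaluation

The positive class is outcome 0 (death). ROC thresholds are the descending
unique predicted death probabilities plus a sentinel above the maximum;
scores exactly at the threshold count as predicted positive (the Heaviside
ambiguity at zero argument is resolved to 1 — the choice is invisible in
the AUC, whose tie handling is fixed by the pairwise equivalence). AUC is
the trapezoidal integral of the curve, which equals the Mann–Whitney
statistic — the probability a random death outscores a random survivor,
ties counted half — exactly, with or without ties; tests verify this
identity against a brute-force pair count and scikit-learn.

A "run" of the sweep harness is one item combination × time range ×
architecture × ridge coefficient; exclusion cells (a time range dropped for
a particular architecture) are subtracted from the Cartesian product. Model
selection over a minima database takes the *best* held-out AUC over all
stored minima, since different training minima generalize differently.
Repeat statistics re-randomize both the split and the optimizer seed per
repeat and report mean and sample (n−1) standard deviation. Model
agreement between the network and quadratic fits is the Pearson correlation
of paired best AUCs, with the least-squares line for plotting.

## Problem sizes

Default validation scales, chosen as the smallest sizes at which each claim
is sharp: derivative checks on 20 random parameter draws over 30–60 patient
rows; convexity on 50 random starts; landscape validation on the analytic
toys (closed-form stationary points); end-to-end recovery on a 4000-patient
cohort with three informative items (test-half AUC standard error ≈ 0.01,
comfortably inside the 0.03/0.05 recovery bands); network fits with 3
hidden nodes and 200 basin-hopping steps, which on these funnel-shaped
landscapes finds the low-lying minima many times over.

## Known limitations

- Landscape tools assume dense Hessians are affordable; they are not meant
  for networks beyond a few hundred parameters.
- The band relaxation can miss saddles on pathological paths (it only
  proposes candidates between the selected pair); the connection budget
  bounds effort, not completeness.
- The cohort generator's independence assumptions make synthetic AUCs
  optimistic relative to clinical data with correlated, confounded
  measurements.
- Scaling means computed over train+test leak two constants per column; on
  real deployments compute them on training data only.
- No kinetics: rate constants, transition-network dynamics and
  heat-capacity analyses over the stationary-point databases are out of
  scope.
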