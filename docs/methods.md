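# Methods

This note documents the models implemented in `spikemeta`, the choices made
where the design was genuinely open, and what the synthetic benchmarks do
and do not demonstrate.

## Neuron models

All dynamics are simulated in discrete time with step `dt = 1 ms` and
0-based, half-open time indexing.

**LIF.** Membrane potential `v_j(t) = alpha*v_j(t-1) + I_j(t) - v_th*z_j(t-1)`
with decay `alpha = exp(-dt/tau_m)` (`tau_m = 15 ms`).  A spike
`z_j(t) = H(v_j(t) - A_j(t))` is emitted when the membrane reaches the
effective threshold; spikes reach postsynaptic targets after the
transmission delay `d = 1 ms`.  After a spike the neuron is refractory for
`t_refrac = 5 ms` (`z` forced to 0; the membrane keeps integrating).

**Reset rule.** The reset after a spike is a *soft* reset (`v <- v - v_th`),
chosen because it keeps the membrane's gradient path alive for
eligibility-trace learning; a clamp-to-zero ("hard") reset is available via
`NeuronParams(reset="hard")` for the forward dynamics (the gradient engine
supports the soft rule, which all training uses).

**ALIF.** Adaptive threshold `A_j(t) = beta*a_j(t) + v_th`,
`a_j(t) = mu*a_j(t-1) + z_j(t-1)`, `mu = exp(-dt/tau_a)` with
`tau_a = 200 ms` and adaptation impact `beta = 0.4902`.  A fraction
`q_ada = 40.5%` of neurons in each pool is adaptive (seeded assignment).
Adaptation is what gives the recurrent network memory on the second scale —
and, through repetition suppression, a natural novelty signal that the
few-shot matching task exploits.

**TLIF.** A two-compartment neuron: the basal dendrite integrates input
spikes filtered by the causal double-exponential kernel
`kappa(t) = (e^(-t/tau_L) - e^(-t/tau_s)) / (tau_L - tau_s)`
(`tau_L = 10 ms > tau_s = 2.5 ms`; `kappa` integrates to 1) into a dendritic
potential `v_b = W_in s + b`, which couples into the soma with conductance
ratio `g_b/g_l`.  The soma follows one explicit Euler step per `dt` of a
leaky integrator with time constant `tau = C_m/g_l = 20 ms`; thresholding,
adaptation and refractoriness are identical to the LIF soma.  The dendritic
bias `b` is a fixed constant (default 0), not a trained parameter.

**Readout.** Non-spiking leaky units,
`y_k(t) = nu*(y_k(t-1) - b_k) + (1-nu) * W_out z(t) + b_k`,
`nu = exp(-dt/tau_out)`, `tau_out = 10 ms` — the recursive form of the
explicit low-pass sum over past spikes (the equivalence is asserted to
1e-10 in the tests).

## Surrogate gradient

The spike nonlinearity is non-differentiable; the backward pass replaces its
derivative with the triangular pseudo-derivative
`psi_j(t) = 0.3 * max(0, 1 - |theta_j(t) - v_j(t)| / v_th)`, where `theta`
is `v_th` for plain LIF and the adaptive threshold `A_j(t)` otherwise.
`psi = 0` during the refractory period, so no credit flows through silenced
neurons.  Every other edge of the unrolled computation graph (leak, soft
reset, adaptation, delayed recurrence, readout filter) is differentiated
exactly.  Tests verify that reverse-time accumulation (BPTT) agrees to
machine precision with an independent forward-mode (RTRL-style) derivation
on small toys, and with central finite differences on the readout path,
which contains no spike nonlinearity.

## Eligibility traces

For synapse `(j, i)` the eligibility vector follows the state Jacobian
recursion; in closed form:

* LIF: `e_ji(t) = psi_j(t) * zbar_i(t - d)` with `zbar` the presynaptic
  low-pass trace (decay `alpha`);
* ALIF: `e_ji(t) = psi_j(t) * (zbar_i(t-d) - beta*eps_a_ji(t))`,
  `eps_a_ji(t) = (rho - beta*psi_j(t-1))*eps_a_ji(t-1) + psi_j(t-1)*zbar_i(t-d-1)`.

The decay `rho` of the adaptation component is set equal to
`mu = exp(-dt/tau_a)`, consistent with the threshold's own decay.  The
recursions are verified against brute-force forward accumulation of the
2x2 state Jacobians.  BPTT-with-surrogate is the default trainer; the
eligibility traces power the meta-learner's within-episode plasticity.

## Robust ensemble loss

Four base losses are combined as
`sum_j lam_j^2 L_j + eta1*(S - 1) + eta2*(S - 1)^2`, `S = sum_j lam_j^2`:

1. **Mixture-correntropy loss** `1 - Vhat`,
   `Vhat = mean_i [lam_mix*G_s1(e_i) + (1-lam_mix)*G_s2(e_i)]` with Gaussian
   kernels and `e_i = ||y_i - yhat_i||_2`.  Defaults `sigma1 = 1`,
   `sigma2 = 4`, `lam_mix = 0.5` (kernel widths are not prescribed by the
   reference hyperparameters; these span a narrow and a broad kernel on the
   unit error scale).  The loss is bounded by 1 and its influence function
   is redescending, which is what confers robustness to outliers.
2. **Cross-entropy**, either the multiclass form on softmax outputs or the
   two-phase binary form that samples `sigmoid(y)` at the last step of each
   query item.  Classification episodes use the multiclass form; two-phase
   episodes use the binary form.
3. **Firing-rate regularizer** `lam_f * sum_j (f_j - f_target)^2` with `f_j`
   in Hz, `f_target = 20 Hz`, `lam_f = 1`.
4. **Voltage regularizer**: mean one-sided quadratic penalties on
   `v > A` and `v < -v_th`, scale `lam_v = 1e-2`.

With `f_j` expressed in Hz a silent 100-neuron network starts with a rate
loss of order 10^4, so the *plain* gradient-descent step on the trainable
weights `lam` clips its gradient at norm 10 in the training loops (the bare
update rule is exposed unclipped).  The augmented-Lagrangian fixed point
satisfies `S = 1 - (L_min + eta1)/(2*eta2)` when a single base loss
survives, i.e. the constraint is met up to a bias inversely proportional to
`eta2`; the constraint-convergence test therefore uses the strong-penalty
regime (`eta2 = 100`, bias 0.0055).

For the *study* tasks (few-shot matching, motor control) the ensemble
weights are fixed at the reference sweep's optimum — MMCC 0.2,
cross-entropy 0.8, rate 0.5, voltage 0.5 — mirroring how the reference
experiments evaluate fixed weight settings; the trainable-weight machinery
is exercised and tested separately.  Motor episodes substitute the
trajectory mean squared error for the cross-entropy member, which has no
meaning for a regression target.

## Meta-learning architecture

Two recurrent spiking networks: the **learner** (default 180 TLIF + 260 LIF
neurons, following the architecture text; the hyperparameter table's 447 is
recorded as a discrepancy and not used) and the **teacher** (239 LIF/ALIF
neurons) whose readout emits one learning signal per learner neuron,
low-pass filtered with `tau_LS = 10 ms`.  The teacher sees the learner's
spikes (one step lagged), the phase-ID channel and the task's target
channel, and is consulted only during phase 1 / the training trial.

**Within-episode plasticity.** At the phase boundary the learner's input
and recurrent weights receive the three-factor update
`dW_ji = -eta_inner * sum_{t in phase 1} LS_j(t) * e_ji(t)`.
How the learning signals combine with the network state is not fully
prescribed by the source architecture; the product-with-eligibility form is
the natural three-factor rule consistent with the eligibility formalism.
`eta_inner` is a free rate: a small pilot calibration chose 0.05 for
matching episodes and 0.15 for motor episodes (values giving within-episode
updates of the same order as the base weights without destabilizing the
phase-2 rollout).

**Outer loop.** The ensemble loss of the phase-2 outputs is backpropagated
through the rollouts.  Second-order meta-gradients are out of scope, so
`dW` is treated as constant when differentiating with respect to the
learner's base weights (first order).  The teacher still receives an exact
gradient because `dW` is linear in its learning signals:
`dL/dLS_j(t) = -eta_inner * sum_i dL/dW_ji * e_ji(t)`, with the eligibility
traces replayed from the recorded phase-1 rollout and the filter adjoint
applied.  Two further deliberate restrictions: (i) the teacher's credit is
computed from the *task* loss only — the regularizers shape the slow
weights directly but are kept out of the fast-plasticity pathway (when they
are included, the early rate-regularizer gradient, orders of magnitude
larger than the task gradient, trains the teacher to regulate firing rates
instead of the task); (ii) the gradient path from the teacher's input back
into the learner's phase-1 spikes is dropped (a weak indirect path, in the
same first-order spirit).  Weights update with Adam (`beta1 = 0.9`,
`beta2 = 0.999`, `eps = 1e-8`, global gradient clip 100, learning rate
1.915e-3); the ensemble weights, when trainable, with plain gradient
descent at 2e-3.

## Synthetic tasks

**Spike patterns.** Class templates are inhomogeneous Poisson rasters with
per-neuron rates uniform in 2-50 Hz (full-scale dataset: 1,000 classes,
25 instances each; templates default to 100 neurons x 200 ms, both
configurable).  "Poisson noise added to a template" is realized by OR-ing
nuisance Poisson spikes (rate `sigma_noise` Hz) onto the template raster,
so an instance *is* its template plus noise; the alternative reading —
Gaussian-perturbed rates followed by a full Poisson redraw — is available
via `NoiseSpec(poisson_mode="rate_redraw")` but makes instances of a class
share nothing but a rate vector, which is unreadable within a 20 ms item
and would degenerate the matching protocol.  Deletion noise removes each
spike independently with probability `P_del`.  Salt-and-pepper noise
inverts a random 15% of pixels (per-pixel Bernoulli).

**Matching episodes.** N-way one-shot matching (default N = 5): one support
item (phase 1, phase-ID channel 0), then one query per sampled class in
random order (phase 2, phase-ID 1), exactly one query matching the support
class.  The readout is sampled at the last step of each query; the episode
decision is the argmax over queries (ties resolve to the lowest index).
The episode protocol for spike patterns mirrors the image protocol, which
is the only one the source describes.

**Motor control.** A two-joint kinematic arm (`L1 = L2 = 0.5`, initial pose
`(pi/4, pi/2)`), target end-effector paths generated as sums of three
low-frequency sinusoids per joint (amplitude up to 0.8 rad, anchored at the
initial pose) — building the path in joint space makes reachability
automatic and gives an exact implied-velocity roundtrip.  The learner
receives a clock input (equal non-overlapping slots) and outputs joint
angular velocities, Euler-integrated through the forward kinematics.
Training and testing trials are separate rollouts (state reset between
them); torque-level dynamics are out of scope.

**Image episodes.** A three-block convolutional encoder (16/32/64 filters,
3x3 kernels, batch-statistics normalization, ReLU, 2x2 average pooling)
maps 28x28 grayscale images to 576 feature currents.  The loader accepts an
alphabet/character/sample directory of PNGs; no image dataset is bundled
and no benchmark claim is tied to images.

## Scaled study conditions

Full-architecture training at reference scale (440 + 239 neurons, batch
285) is far beyond a desk CPU; the behavioural checks run scaled-down
versions whose sizes were fixed once:

* *Matching*: 10 classes x 50 pattern neurons x 30 ms items,
  `sigma_noise = 5 Hz`, 100-neuron LIF/ALIF learner, 60-neuron teacher,
  batch 16, 500 outer iterations; evaluation on 300 fresh episodes from the
  same family.  Post-training accuracy must exceed chance (0.2) by twice
  its binomial standard error.
* *Motor*: 250 ms episodes, 10 clock channels, 60-neuron learner,
  40-neuron teacher, batch 16, 150 outer iterations; the within-episode
  update must reduce the test-trial error on >= 80% of 48 fresh episodes.
  A property of first-order meta-training worth noting: with long outer
  training the base weights absorb the average task structure (the
  pre-update error falls), so the *marginal* benefit of the inner update is
  clearest in early-to-mid training — the scaled oracle measures it there.
* *Robustness ordering*: five seeds, ensemble weights vs. cross-entropy
  alone, 80 outer iterations each; the accuracy drop from `P_del` 0 to 0.3
  of the ensemble model must not exceed (in median) that of the
  cross-entropy model.

What passing these tests shows: the full pipeline — surrogate BPTT,
eligibility-based fast weights, teacher-derived learning signals, robust
ensemble objective — learns above chance and transfers a one-shot target
into a within-episode weight update at desk scale.  What it does not show:
the reference-scale benchmark numbers (e.g. image-dataset accuracy), which
require the external image dataset and orders of magnitude more compute;
nothing in this package asserts them.

## Numerical choices

* Logarithms clamp their arguments at 1e-12.
* Gaussian weight init, per-matrix std `1/sqrt(fan_in)`; recurrent
  diagonals are zero and kept zero.
* Global gradient-norm clip 100 (weights), 10 (ensemble-weight step inside
  the training loops).
* Non-finite state or loss values abort with an error naming the step or
  the offending base loss.
* All generators and training loops are pure functions of their seeds;
  reruns are bit-identical.

## Known limitations

* Gradients with respect to the *input stream* are implemented for networks
  whose driven rows are LIF; propagating them through the dendritic filter
  of TLIF rows is not supported (encoder features should drive LIF rows).
* The convolutional encoder is forward-only: the gradient chain stops at
  the learner's input boundary (where `surrogate_bptt` can expose `dx`), so
  image episodes run with a fixed random encoder rather than one trained
  jointly with the outer loop.  No quantitative claim here depends on the
  image pathway.
* The online (eligibility-only) update mode covers the within-episode
  plasticity; full online training of the outer loop is not implemented —
  the outer loop is BPTT by design.
* The smoothed-network comparison for hidden-weight gradients is
  qualitative (sign and rough magnitude): a binary-spiking rollout and a
  sigmoid-relaxed one follow different trajectories, so exact agreement is
  not expected away from the threshold.
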