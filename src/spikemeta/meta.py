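"""Learning-to-learn architecture: learner, teacher, and the two-loop protocol.

Two recurrent spiking subnetworks cooperate:

* the **learner** (hippocampus-inspired; a mix of two-compartment and plain
  LIF neurons, a fraction of them with threshold adaptation) solves each
  individual task instance;
* the **teacher** (prefrontal-cortex-inspired; LIF/ALIF) observes the
  learner's spikes together with the phase ID and the task's target channel
  and emits one *learning signal* per learner neuron, low-pass filtered with
  time constant ``tau_ls``.  Learning signals flow teacher -> learner and
  only during phase 1 (the training trial).

Within an episode the learner's input and recurrent weights receive a
three-factor update at the phase boundary,

``dW_ji = -eta_inner * sum_{t in phase 1} LS_j(t) * e_ji(t)``,

the product of the filtered top-down learning signal and the forward
eligibility trace of each synapse.  Phase 2 runs with the updated weights
and no learning signals.

The **outer loop** trains all slowly-changing parameters (both networks'
weights and the ensemble-loss weights) by backpropagating the ensemble loss
of the phase-2 outputs through the rollouts.  The within-episode update
``dW`` is treated as a constant when differentiating with respect to the
learner's base weights (a first-order scheme; second-order meta-gradients
are out of scope).  The teacher nevertheless receives an exact gradient:
``dW`` is *linear* in its learning signals, so
``dL/dLS_j(t) = -eta_inner * sum_i dL/dW_ji * e_ji(t)`` follows from the
chain rule through an affine map, with the eligibility traces replayed from
the recorded phase-1 rollout.

An optional convolutional encoder (visual-pathway-inspired) turns 28x28
grayscale images into feature currents for the learner's input channels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .gradients import (AdamState, adam_step, clip_gradients,
                        surrogate_bptt, update_ensemble_weights)
from .losses import (CorrentropyConfig, EnsembleLossConfig, RegularizerConfig,
                     ensemble_objective, mmcc_loss, mmcc_loss_grad,
                     rate_regularizer, rate_regularizer_grad,
                     voltage_regularizer, voltage_regularizer_grads, EPS)
from .neurons import (DendriteParams, NetworkWeights, NeuronParams, Rollout,
                      simulate_network)
from .tasks import (FewShotEpisode, arm_jacobian,
                    integrate_motor_commands, generate_motor_task)

__all__ = [
    "MetaConfig", "MetaNetworks", "MotorEpisode", "InnerTrialResult",
    "init_meta_networks", "run_inner_trial", "run_outer_loop",
    "evaluate_fewshot", "run_motor_inner_trial", "run_motor_outer_loop",
    "evaluate_motor", "build_motor_episode_batch", "ConvEncoder", "conv_encode",
    "sigmoid",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class MetaConfig:
    """Sizes and rates of the two-network architecture."""

    n_hsnn: int = 440          # learner size (180 two-compartment + 260 LIF)
    n_tlif: int = 180
    n_psnn: int = 239          # teacher size
    q_ada: float = 0.405       # fraction of neurons with threshold adaptation
    eta_inner: float = 0.05    # within-episode plasticity rate
    tau_ls: float = 10.0       # learning-signal filter time constant (ms)
    lr: float = 1.915e-3       # Adam learning rate (outer loop, weights)
    lr_out: float = 2e-3       # ensemble-weight learning rate
    seed: int = 0
    params: NeuronParams = field(default_factory=NeuronParams)
    dparams: DendriteParams = field(default_factory=DendriteParams)
    correntropy: CorrentropyConfig = field(default_factory=CorrentropyConfig)
    regularizer: RegularizerConfig = field(default_factory=RegularizerConfig)

    @property
    def rho_ls(self) -> float:
        return math.exp(-self.params.dt / self.tau_ls)


@dataclass
class MetaNetworks:
    """Learner + teacher weights, neuron-kind layout, and the shared params."""

    hsnn: NetworkWeights
    psnn: NetworkWeights
    hsnn_kinds: np.ndarray
    hsnn_adaptive: np.ndarray
    psnn_adaptive: np.ndarray
    cfg: MetaConfig
    vnn: "ConvEncoder | None" = None

    def learner_rollout(self, x: np.ndarray, dw_in=None, dw_rec=None,
                        dw_from: int = 0) -> Rollout:
        return simulate_network(self.hsnn, self.cfg.params, x,
                                kinds=self.hsnn_kinds, dparams=self.cfg.dparams,
                                adaptive=self.hsnn_adaptive,
                                dw_in=dw_in, dw_rec=dw_rec, dw_from=dw_from)

    def teacher_rollout(self, x: np.ndarray) -> Rollout:
        return simulate_network(self.psnn, self.cfg.params, x,
                                adaptive=self.psnn_adaptive)


def init_meta_networks(n_in: int, n_out: int, cfg: MetaConfig,
                       n_teacher_extra: int = 2,
                       vnn: "ConvEncoder | None" = None) -> MetaNetworks:
    """Seeded initialization of both networks.

    The learner's first ``n_tlif`` neurons are two-compartment, the rest
    plain LIF; adaptation is assigned to a random ``q_ada`` fraction of each
    pool.  The teacher reads the learner's spikes plus ``n_teacher_extra``
    task channels and emits one readout per learner neuron (the learning
    signals).
    """
    rng = np.random.default_rng(cfg.seed)
    hsnn = NetworkWeights.initialize(n_in, cfg.n_hsnn, n_out, rng)
    psnn = NetworkWeights.initialize(cfg.n_hsnn + n_teacher_extra,
                                     cfg.n_psnn, cfg.n_hsnn, rng)
    kinds = np.array(["tlif"] * cfg.n_tlif + ["lif"] * (cfg.n_hsnn - cfg.n_tlif))
    h_ada = rng.random(cfg.n_hsnn) < cfg.q_ada
    p_ada = rng.random(cfg.n_psnn) < cfg.q_ada
    return MetaNetworks(hsnn=hsnn, psnn=psnn, hsnn_kinds=kinds,
                        hsnn_adaptive=h_ada, psnn_adaptive=p_ada, cfg=cfg,
                        vnn=vnn)


# ---------------------------------------------------------------------------
# Eligibility pass over a recorded phase-1 rollout (forward in time)
# ---------------------------------------------------------------------------

def _eligibility_pass(roll: Rollout, weights: NetworkWeights,
                      params: NeuronParams, t_stop: int,
                      ls: np.ndarray | None = None,
                      g_in: np.ndarray | None = None,
                      g_rec: np.ndarray | None = None):
    """Stream the per-synapse eligibility traces over ``[0, t_stop)``.

    With ``ls`` given, accumulates the three-factor products and returns the
    within-episode updates ``(dw_in, dw_rec)`` *per unit plasticity rate*
    (callers scale by ``-eta_inner``).  With per-sample weight gradients
    ``(g_in, g_rec)`` given instead, returns the adjoint learning-signal
    seed ``sum_i g_ji * e_ji(t)`` of shape ``(B, N, t_stop)``.
    """
    B, N, _ = roll.z.shape
    n_in = weights.n_in
    d = params.d
    rho = params.rho
    decay, gain_in, gain_rec, beta = (roll.decay, roll.in_gain,
                                      roll.rec_gain, roll.beta)
    tlif = roll.tlif_mask
    x_lif = roll.x
    x_tlif = roll.x_filt if tlif.any() else None

    eps_in = np.zeros((B, N, n_in))
    eps_in_a = np.zeros((B, N, n_in))
    eps_rec = np.zeros((B, N, N))
    eps_rec_a = np.zeros((B, N, N))
    psi_prev = np.zeros((B, N))

    accumulate = ls is not None
    if accumulate:
        dw_in = np.zeros((B, N, n_in))
        dw_rec = np.zeros((B, N, N))
    else:
        seed = np.zeros((B, N, t_stop))

    for t in range(t_stop):
        # presynaptic input per postsynaptic group (TLIF rows see filtered input)
        pre_in = np.broadcast_to(x_lif[:, None, :, t], (B, N, n_in)).copy()
        if tlif.any():
            pre_in[:, tlif, :] = x_tlif[:, None, :, t]
        z_del = roll.z[:, :, t - d] if t - d >= 0 else np.zeros((B, N))

        eps_in_prev = eps_in.copy()
        eps_rec_prev = eps_rec.copy()
        eps_in = decay[None, :, None] * eps_in + gain_in[None, :, None] * pre_in
        eps_rec = decay[None, :, None] * eps_rec \
            + gain_rec[None, :, None] * z_del[:, None, :]
        fac = (rho - beta[None, :] * psi_prev)[:, :, None]
        eps_in_a = fac * eps_in_a + psi_prev[:, :, None] * eps_in_prev
        eps_rec_a = fac * eps_rec_a + psi_prev[:, :, None] * eps_rec_prev

        psi_t = roll.psi[:, :, t]
        e_in = psi_t[:, :, None] * (eps_in - beta[None, :, None] * eps_in_a)
        e_rec = psi_t[:, :, None] * (eps_rec - beta[None, :, None] * eps_rec_a)
        psi_prev = psi_t

        if accumulate:
            dw_in += ls[:, :, t][:, :, None] * e_in
            dw_rec += ls[:, :, t][:, :, None] * e_rec
        else:
            seed[:, :, t] = np.einsum("bji,bji->bj", g_in, e_in) \
                + np.einsum("bji,bji->bj", g_rec, e_rec)

    if accumulate:
        idx = np.arange(N)
        dw_rec[:, idx, idx] = 0.0
        return dw_in, dw_rec
    return seed


def _learning_signals(teacher_roll: Rollout, rho_ls: float) -> np.ndarray:
    """Low-pass filtered teacher readout: LS(t) = rho*LS(t-1) + (1-rho)*y(t)."""
    return lfilter([1.0 - rho_ls], [1.0, -rho_ls], teacher_roll.y, axis=-1)


def _ls_filter_adjoint(g_ls: np.ndarray, rho_ls: float) -> np.ndarray:
    """Adjoint of the learning-signal filter: reversed-time low-pass."""
    rev = g_ls[..., ::-1]
    out = lfilter([1.0 - rho_ls], [1.0, -rho_ls], rev, axis=-1)
    return out[..., ::-1]


def _lagged(z: np.ndarray) -> np.ndarray:
    """One-step-lagged spikes (the teacher sees the learner's previous step)."""
    out = np.zeros_like(z)
    out[:, :, 1:] = z[:, :, :-1]
    return out


@dataclass
class InnerTrialResult:
    roll_full: Rollout          # learner over the whole episode (updates active)
    roll_phase1: Rollout        # learner over phase 1 with base weights
    roll_teacher: Rollout
    ls: np.ndarray              # (B, N_h, T1) learning signals
    dw_in: np.ndarray           # (B, N_h, n_in) within-episode update
    dw_rec: np.ndarray          # (B, N_h, N_h)
    teacher_x: np.ndarray
    t_switch: int


def run_inner_trial(nets: MetaNetworks, episode: FewShotEpisode,
                    cfg: MetaConfig | None = None) -> InnerTrialResult:
    """One two-phase episode with within-episode plasticity.

    Phase 1: the learner processes the support items with its base weights
    while the teacher, reading the learner's (lagged) spikes plus the phase-ID
    and target channels, emits learning signals.  The three-factor update is
    computed from learning signals x eligibility traces and applied at the
    phase boundary.  Phase 2: the full episode is rolled out with the update
    active from the boundary on (learning signals are identically zero there
    by construction — the teacher is simply never consulted).
    """
    cfg = cfg or nets.cfg
    if episode.x.shape[1] != nets.hsnn.n_in:
        raise ValueError("episode channels do not match the learner's input size")
    t1 = episode.t_switch
    roll1 = nets.learner_rollout(episode.x[:, :, :t1])
    teacher_x = np.concatenate([_lagged(roll1.z),
                                episode.teacher_extra[:, :, :t1]], axis=1)
    roll_t = nets.teacher_rollout(teacher_x)
    ls = _learning_signals(roll_t, cfg.rho_ls)
    dw_in, dw_rec = _eligibility_pass(roll1, nets.hsnn, cfg.params, t1, ls=ls)
    dw_in *= -cfg.eta_inner
    dw_rec *= -cfg.eta_inner
    roll_full = nets.learner_rollout(episode.x, dw_in=dw_in, dw_rec=dw_rec,
                                     dw_from=t1)
    return InnerTrialResult(roll_full=roll_full, roll_phase1=roll1,
                            roll_teacher=roll_t, ls=ls, dw_in=dw_in,
                            dw_rec=dw_rec, teacher_x=teacher_x, t_switch=t1)


def _episode_sample_steps(episode: FewShotEpisode) -> np.ndarray:
    """Steps at which the single readout is scored: end of each query item."""
    return episode.t_switch + (np.arange(episode.n_query) + 1) * episode.t_item - 1


def _matching_losses(inner: InnerTrialResult, episode: FewShotEpisode,
                     cfg: MetaConfig, lam: np.ndarray):
    """Base losses and adjoint seeds for a matching-episode batch."""
    y = inner.roll_full.y[:, 0, :]
    steps = _episode_sample_steps(episode)
    B = y.shape[0]
    sig = sigmoid(y[:, steps])
    labels = episode.labels

    L1 = mmcc_loss(labels, sig, cfg.correntropy)
    p = np.clip(sig, EPS, 1.0 - EPS)
    L2 = float((-(labels * np.log(p)
                  + (1.0 - labels) * np.log(1.0 - p)).sum(axis=1)).mean())
    reg = cfg.regularizer
    L3h, _ = rate_regularizer(inner.roll_full.raster, reg)
    L3t, _ = rate_regularizer(inner.roll_teacher.raster, reg)
    L4h = voltage_regularizer(inner.roll_full.v, inner.roll_full.A, reg)
    L4t = voltage_regularizer(inner.roll_teacher.v, inner.roll_teacher.A, reg)
    base = np.array([L1, L2, L3h + L3t, L4h + L4t])

    lam2 = lam ** 2
    # the cross-entropy-with-logits shortcut (sigma - l) already includes the
    # sigmoid derivative; the correntropy term does not:
    dy = np.zeros_like(inner.roll_full.y)
    dy[:, 0, steps] = lam2[0] * mmcc_loss_grad(labels, sig, cfg.correntropy) \
        * sig * (1.0 - sig) + lam2[1] * (sig - labels) / B
    seeds_h = {
        "dL_dy": dy,
        "dL_dz": lam2[2] * rate_regularizer_grad(inner.roll_full.raster, reg),
    }
    gv, gA = voltage_regularizer_grads(inner.roll_full.v, inner.roll_full.A, reg)
    seeds_h["dL_dv"] = lam2[3] * gv
    seeds_h["dL_dA"] = lam2[3] * gA
    seeds_t = {
        "dL_dz": lam2[2] * rate_regularizer_grad(inner.roll_teacher.raster, reg),
    }
    gv, gA = voltage_regularizer_grads(inner.roll_teacher.v,
                                       inner.roll_teacher.A, reg)
    seeds_t["dL_dv"] = lam2[3] * gv
    seeds_t["dL_dA"] = lam2[3] * gA
    return base, seeds_h, seeds_t


def _outer_step(nets: MetaNetworks, inner: InnerTrialResult, seeds_h: dict,
                seeds_t: dict, cfg: MetaConfig, opt: AdamState,
                pdict: dict) -> None:
    """Shared outer-loop update: learner BPTT, teacher credit, Adam.

    The learner's base weights receive the full ensemble gradient.  The
    teacher's credit flows through d(task loss)/d(within-episode update)
    only: the regularizers shape the slow weights but are kept out of the
    fast-plasticity pathway, whose job is the task itself.
    """
    grads_h = surrogate_bptt(inner.roll_full, nets.hsnn,
                             dw_in=inner.dw_in, dw_rec=inner.dw_rec,
                             dw_from=inner.t_switch, **seeds_h)
    grads_task = surrogate_bptt(inner.roll_full, nets.hsnn,
                                dL_dy=seeds_h["dL_dy"],
                                dw_in=inner.dw_in, dw_rec=inner.dw_rec,
                                dw_from=inner.t_switch, per_sample=True)
    g_ls = -cfg.eta_inner * _eligibility_pass(
        inner.roll_phase1, nets.hsnn, cfg.params, inner.t_switch,
        g_in=grads_task.dw_in, g_rec=grads_task.dw_rec)
    dy_teacher = _ls_filter_adjoint(g_ls, cfg.rho_ls)
    grads_t = surrogate_bptt(inner.roll_teacher, nets.psnn,
                             dL_dy=dy_teacher, **seeds_t)
    grads = {"h_w_in": grads_h.w_in, "h_w_rec": grads_h.w_rec,
             "h_w_out": grads_h.w_out, "h_b_out": grads_h.b_out,
             "p_w_in": grads_t.w_in, "p_w_rec": grads_t.w_rec,
             "p_w_out": grads_t.w_out, "p_b_out": grads_t.b_out}
    grads = clip_gradients(grads)
    adam_step(opt, pdict, grads, cfg.lr)
    nets.hsnn.w_in, nets.hsnn.w_rec = pdict["h_w_in"], pdict["h_w_rec"]
    nets.hsnn.w_out, nets.hsnn.b_out = pdict["h_w_out"], pdict["h_b_out"]
    nets.psnn.w_in, nets.psnn.w_rec = pdict["p_w_in"], pdict["p_w_rec"]
    nets.psnn.w_out, nets.psnn.b_out = pdict["p_w_out"], pdict["p_b_out"]
    np.fill_diagonal(nets.hsnn.w_rec, 0.0)
    np.fill_diagonal(nets.psnn.w_rec, 0.0)


def _param_dict(nets: MetaNetworks) -> dict:
    return {"h_w_in": nets.hsnn.w_in, "h_w_rec": nets.hsnn.w_rec,
            "h_w_out": nets.hsnn.w_out, "h_b_out": nets.hsnn.b_out,
            "p_w_in": nets.psnn.w_in, "p_w_rec": nets.psnn.w_rec,
            "p_w_out": nets.psnn.w_out, "p_b_out": nets.psnn.b_out}


def run_outer_loop(nets: MetaNetworks, family, cfg: MetaConfig | None,
                   n_iters: int, seed: int,
                   ensemble: EnsembleLossConfig | None = None,
                   opt: AdamState | None = None,
                   rng: np.random.Generator | None = None) -> list:
    """Meta-train on matching episodes.

    ``family(rng) -> FewShotEpisode`` supplies a fresh episode batch per
    iteration.  Returns the per-iteration log (loss breakdown, ensemble
    weights, training-batch accuracy).  Deterministic given ``seed``.
    """
    cfg = cfg or nets.cfg
    rng = rng if rng is not None else np.random.default_rng(seed)
    ensemble = ensemble or EnsembleLossConfig.random_init(rng)
    opt = opt if opt is not None else AdamState()
    pdict = _param_dict(nets)
    log: list[dict] = []
    for it in range(n_iters):
        episode = family(rng)
        inner = run_inner_trial(nets, episode, cfg)
        base, seeds_h, seeds_t = _matching_losses(inner, episode, cfg,
                                                  ensemble.lam)
        breakdown = ensemble_objective(base, ensemble)
        if not np.isfinite(breakdown.total):
            raise FloatingPointError(f"outer loop diverged at iteration {it}")
        _outer_step(nets, inner, seeds_h, seeds_t, cfg, opt, pdict)
        if ensemble.trainable:
            ensemble.lam = update_ensemble_weights(
                ensemble.lam, base, ensemble.eta1, ensemble.eta2, cfg.lr_out,
                max_grad_norm=10.0)
        steps = _episode_sample_steps(episode)
        pred = inner.roll_full.y[:, 0, steps].argmax(axis=1)
        acc = float((pred == episode.match_index).mean())
        row = {"iteration": it, "L1": base[0], "L2": base[1], "L3": base[2],
               "L4": base[3], "penalty": breakdown.penalty,
               "total": breakdown.total, "accuracy": acc}
        for j in range(4):
            row[f"lam{j + 1}"] = float(ensemble.lam[j])
        log.append(row)
    return log


def evaluate_fewshot(nets: MetaNetworks, episodes, cfg: MetaConfig | None = None,
                     runner=None) -> dict:
    """Fraction of episodes whose phase-2 decision is correct.

    The decision is the argmax of the readout over the query sample steps
    (ties break to the lowest index, which :func:`numpy.argmax` provides).
    ``episodes`` is a FewShotEpisode batch or a list of them; ``runner`` may
    override the default inner-trial rollout (it must map
    ``(nets, episode) -> (B, T) readout trace``).
    """
    cfg = cfg or nets.cfg
    if not isinstance(episodes, (list, tuple)):
        episodes = [episodes]
    outcomes = []
    for ep in episodes:
        if runner is not None:
            y = np.asarray(runner(nets, ep))
        else:
            y = run_inner_trial(nets, ep, cfg).roll_full.y[:, 0, :]
        steps = _episode_sample_steps(ep)
        pred = y[:, steps].argmax(axis=1)
        outcomes.extend((pred == ep.match_index).tolist())
    outcomes = np.asarray(outcomes, dtype=bool)
    return {"accuracy": float(outcomes.mean()), "n_episodes": int(outcomes.size),
            "outcomes": outcomes}


# ---------------------------------------------------------------------------
# Motor control episodes
# ---------------------------------------------------------------------------

@dataclass
class MotorEpisode:
    """A batch of one-shot motor episodes: same clock input, fresh targets."""

    clock: np.ndarray       # (B, n_clock, T)
    target: np.ndarray      # (B, 2, T) end-effector target per step
    link_lengths: tuple
    phi0: np.ndarray
    dt: float

    @property
    def n_batch(self) -> int:
        return self.clock.shape[0]

    @property
    def T(self) -> int:
        return self.clock.shape[2]


def build_motor_episode_batch(n_batch: int, seed: int = 0,
                              duration_ms: float = 500.0,
                              n_clock_channels: int = 20, dt: float = 1.0,
                              link_lengths: tuple = (0.5, 0.5)) -> MotorEpisode:
    rng = np.random.default_rng(seed)
    tasks = [generate_motor_task(duration_ms, n_clock_channels,
                                 seed=int(rng.integers(2 ** 31)), dt=dt,
                                 link_lengths=link_lengths)
             for _ in range(n_batch)]
    return MotorEpisode(clock=np.stack([t.clock_input for t in tasks]),
                        target=np.stack([t.target_trajectory for t in tasks]),
                        link_lengths=link_lengths, phi0=tasks[0].phi0, dt=dt)


@dataclass
class MotorInnerResult:
    roll_train: Rollout
    roll_test: Rollout
    roll_teacher: Rollout
    ls: np.ndarray
    dw_in: np.ndarray
    dw_rec: np.ndarray
    trajectory: np.ndarray   # (B, 2, T) post-update end-effector path
    t_switch: int            # 0: the update acts over the whole test trial


def run_motor_inner_trial(nets: MetaNetworks, ep: MotorEpisode,
                          cfg: MetaConfig | None = None) -> MotorInnerResult:
    """Training trial (teacher sees the target, emits learning signals) then
    testing trial (updated learner reproduces the movement unaided).

    The learner's input is the clock signal in both trials; its two readouts
    are the joint angular-velocity commands.  State is reset between trials.
    """
    cfg = cfg or nets.cfg
    roll_tr = nets.learner_rollout(ep.clock)
    teacher_x = np.concatenate([_lagged(roll_tr.z), ep.target,
                                np.zeros((ep.n_batch, 1, ep.T))], axis=1)
    roll_t = nets.teacher_rollout(teacher_x)
    ls = _learning_signals(roll_t, cfg.rho_ls)
    dw_in, dw_rec = _eligibility_pass(roll_tr, nets.hsnn, cfg.params, ep.T, ls=ls)
    dw_in *= -cfg.eta_inner
    dw_rec *= -cfg.eta_inner
    roll_te = nets.learner_rollout(ep.clock, dw_in=dw_in, dw_rec=dw_rec,
                                   dw_from=0)
    traj = integrate_motor_commands(nets_phi0(ep), roll_te.y,
                                    ep.link_lengths, dt=ep.dt)
    return MotorInnerResult(roll_train=roll_tr, roll_test=roll_te,
                            roll_teacher=roll_t, ls=ls, dw_in=dw_in,
                            dw_rec=dw_rec, trajectory=traj, t_switch=0)


def nets_phi0(ep: MotorEpisode) -> np.ndarray:
    return ep.phi0


def _command_angles(phi0: np.ndarray, commands: np.ndarray,
                    dt: float) -> np.ndarray:
    """Integrated joint angles (B, 2, T): phi(t) = phi0 + dts * sum_{s<t} cmd(s)."""
    dts = dt / 1000.0
    csum = np.cumsum(commands, axis=-1) * dts
    phi = np.zeros_like(commands)
    phi[..., 1:] = csum[..., :-1]
    return phi + phi0[:, None]


def _trajectory_grad_to_commands(dL_dpos: np.ndarray, commands: np.ndarray,
                                 phi0: np.ndarray, link_lengths: tuple,
                                 dt: float) -> np.ndarray:
    """Adjoint of Euler integration + forward kinematics.

    ``dL/dcmd(s) = dts * sum_{t > s} J(phi(t))^T dL/dpos(t)`` with
    ``J`` the 2x2 kinematic Jacobian.
    """
    phi = _command_angles(phi0, commands, dt)          # (B, 2, T)
    J = arm_jacobian(np.moveaxis(phi, 1, 2), link_lengths)  # (B, T, 2, 2)
    q = np.einsum("btij,bit->bjt", J, dL_dpos)         # J^T dL/dpos, (B, 2, T)
    rev = np.cumsum(q[..., ::-1], axis=-1)[..., ::-1]  # inclusive suffix sum
    out = np.zeros_like(q)
    out[..., :-1] = rev[..., 1:]                       # strictly-future sum
    return out * (dt / 1000.0)


def _motor_losses(inner: MotorInnerResult, ep: MotorEpisode, cfg: MetaConfig,
                  lam: np.ndarray):
    """Base losses and adjoint seeds for a motor-episode batch.

    The correntropy member scores the per-step Euclidean trajectory errors;
    the second member is the trajectory mean squared error (cross-entropy has
    no meaning for a regression target).
    """
    traj, target = inner.trajectory, ep.target
    B, _, T = traj.shape
    flat_t = np.moveaxis(target, 1, 2).reshape(B * T, 2)
    flat_p = np.moveaxis(traj, 1, 2).reshape(B * T, 2)
    L1 = mmcc_loss(flat_t, flat_p, cfg.correntropy)
    err = traj - target
    L2 = float((err ** 2).sum(axis=1).mean())
    reg = cfg.regularizer
    L3a, _ = rate_regularizer(inner.roll_train.raster, reg)
    L3b, _ = rate_regularizer(inner.roll_test.raster, reg)
    L3t, _ = rate_regularizer(inner.roll_teacher.raster, reg)
    L4a = voltage_regularizer(inner.roll_train.v, inner.roll_train.A, reg)
    L4b = voltage_regularizer(inner.roll_test.v, inner.roll_test.A, reg)
    L4t = voltage_regularizer(inner.roll_teacher.v, inner.roll_teacher.A, reg)
    base = np.array([L1, L2, L3a + L3b + L3t, L4a + L4b + L4t])

    lam2 = lam ** 2
    g_flat = mmcc_loss_grad(flat_t, flat_p, cfg.correntropy)
    dL_dpos = lam2[0] * np.moveaxis(g_flat.reshape(B, T, 2), 2, 1) \
        + lam2[1] * 2.0 * err / (B * T)
    dy = _trajectory_grad_to_commands(dL_dpos, inner.roll_test.y,
                                      nets_phi0(ep), ep.link_lengths, ep.dt)
    gv_b, gA_b = voltage_regularizer_grads(inner.roll_test.v,
                                           inner.roll_test.A, reg)
    seeds_test = {
        "dL_dy": dy,
        "dL_dz": lam2[2] * rate_regularizer_grad(inner.roll_test.raster, reg),
        "dL_dv": lam2[3] * gv_b, "dL_dA": lam2[3] * gA_b,
    }
    gv_a, gA_a = voltage_regularizer_grads(inner.roll_train.v,
                                           inner.roll_train.A, reg)
    seeds_train = {
        "dL_dz": lam2[2] * rate_regularizer_grad(inner.roll_train.raster, reg),
        "dL_dv": lam2[3] * gv_a, "dL_dA": lam2[3] * gA_a,
    }
    gv_t, gA_t = voltage_regularizer_grads(inner.roll_teacher.v,
                                           inner.roll_teacher.A, reg)
    seeds_teacher = {
        "dL_dz": lam2[2] * rate_regularizer_grad(inner.roll_teacher.raster, reg),
        "dL_dv": lam2[3] * gv_t, "dL_dA": lam2[3] * gA_t,
    }
    return base, seeds_test, seeds_train, seeds_teacher


def run_motor_outer_loop(nets: MetaNetworks, family, cfg: MetaConfig | None,
                         n_iters: int, seed: int,
                         ensemble: EnsembleLossConfig | None = None,
                         opt: AdamState | None = None,
                         rng: np.random.Generator | None = None) -> list:
    """Meta-train the motor task; ``family(rng) -> MotorEpisode``."""
    cfg = cfg or nets.cfg
    rng = rng if rng is not None else np.random.default_rng(seed)
    ensemble = ensemble or EnsembleLossConfig.random_init(rng)
    opt = opt if opt is not None else AdamState()
    pdict = _param_dict(nets)
    log: list[dict] = []
    for it in range(n_iters):
        ep = family(rng)
        inner = run_motor_inner_trial(nets, ep, cfg)
        base, seeds_test, seeds_train, seeds_teacher = _motor_losses(
            inner, ep, cfg, ensemble.lam)
        breakdown = ensemble_objective(base, ensemble)
        if not np.isfinite(breakdown.total):
            raise FloatingPointError(f"outer loop diverged at iteration {it}")

        grads_h = surrogate_bptt(inner.roll_test, nets.hsnn,
                                 dw_in=inner.dw_in, dw_rec=inner.dw_rec,
                                 dw_from=0, **seeds_test)
        grads_task = surrogate_bptt(inner.roll_test, nets.hsnn,
                                    dL_dy=seeds_test["dL_dy"],
                                    dw_in=inner.dw_in, dw_rec=inner.dw_rec,
                                    dw_from=0, per_sample=True)
        grads_h1 = surrogate_bptt(inner.roll_train, nets.hsnn, **seeds_train)
        g_ls = -cfg.eta_inner * _eligibility_pass(
            inner.roll_train, nets.hsnn, cfg.params, ep.T,
            g_in=grads_task.dw_in, g_rec=grads_task.dw_rec)
        dy_teacher = _ls_filter_adjoint(g_ls, cfg.rho_ls)
        grads_t = surrogate_bptt(inner.roll_teacher, nets.psnn,
                                 dL_dy=dy_teacher, **seeds_teacher)
        grads = {"h_w_in": grads_h.w_in + grads_h1.w_in,
                 "h_w_rec": grads_h.w_rec + grads_h1.w_rec,
                 "h_w_out": grads_h.w_out + grads_h1.w_out,
                 "h_b_out": grads_h.b_out + grads_h1.b_out,
                 "p_w_in": grads_t.w_in, "p_w_rec": grads_t.w_rec,
                 "p_w_out": grads_t.w_out, "p_b_out": grads_t.b_out}
        grads = clip_gradients(grads)
        adam_step(opt, pdict, grads, cfg.lr)
        nets.hsnn.w_in, nets.hsnn.w_rec = pdict["h_w_in"], pdict["h_w_rec"]
        nets.hsnn.w_out, nets.hsnn.b_out = pdict["h_w_out"], pdict["h_b_out"]
        nets.psnn.w_in, nets.psnn.w_rec = pdict["p_w_in"], pdict["p_w_rec"]
        nets.psnn.w_out, nets.psnn.b_out = pdict["p_w_out"], pdict["p_b_out"]
        np.fill_diagonal(nets.hsnn.w_rec, 0.0)
        np.fill_diagonal(nets.psnn.w_rec, 0.0)
        if ensemble.trainable:
            ensemble.lam = update_ensemble_weights(
                ensemble.lam, base, ensemble.eta1, ensemble.eta2, cfg.lr_out,
                max_grad_norm=10.0)
        row = {"iteration": it, "L1": base[0], "L2": base[1], "L3": base[2],
               "L4": base[3], "penalty": breakdown.penalty,
               "total": breakdown.total, "post_mse": base[1]}
        for j in range(4):
            row[f"lam{j + 1}"] = float(ensemble.lam[j])
        log.append(row)
    return log


def evaluate_motor(nets: MetaNetworks, ep: MotorEpisode,
                   cfg: MetaConfig | None = None) -> dict:
    """Pre- and post-update trajectory MSE per episode of the batch."""
    cfg = cfg or nets.cfg
    inner = run_motor_inner_trial(nets, ep, cfg)
    roll_pre = nets.learner_rollout(ep.clock)
    traj_pre = integrate_motor_commands(nets_phi0(ep), roll_pre.y,
                                        ep.link_lengths, dt=ep.dt)
    mse = lambda tr: ((tr - ep.target) ** 2).sum(axis=1).mean(axis=1)  # noqa: E731
    return {"pre_mse": mse(traj_pre), "post_mse": mse(inner.trajectory),
            "improved": mse(inner.trajectory) < mse(traj_pre)}


# ---------------------------------------------------------------------------
# Convolutional encoder (visual pathway)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int = 3) -> np.ndarray:
    """(B, C, H, W) -> (B, H*W, C*k*k) patches with same-padding."""
    B, C, H, W = x.shape
    pad = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((B, C, k * k, H, W))
    idx = 0
    for di in range(k):
        for dj in range(k):
            cols[:, :, idx] = xp[:, :, di:di + H, dj:dj + W]
            idx += 1
    return cols.reshape(B, C * k * k, H * W).transpose(0, 2, 1)


class ConvEncoder:
    """Three-block non-spiking image encoder (conv 3x3 -> batchnorm -> ReLU ->
    2x2 average pool), with 16/32/64 filters, for 28x28 grayscale input.

    The units are simple rate units (ReLU); the flattened final feature map
    (64 x 3 x 3 = 576 values) drives the learner's input channels as currents.
    Normalization uses the statistics of the processed batch, so a single
    image is encoded deterministically.
    """

    FILTERS = (16, 32, 64)
    K = 3

    def __init__(self, seed: int = 0, in_channels: int = 1):
        rng = np.random.default_rng(seed)
        self.layers = []
        c_in = in_channels
        for c_out in self.FILTERS:
            fan_in = c_in * self.K * self.K
            self.layers.append({
                "w": rng.normal(0.0, 1.0 / math.sqrt(fan_in),
                                size=(c_out, fan_in)),
                "b": np.zeros(c_out),
                "gamma": np.ones(c_out),
                "beta": np.zeros(c_out),
            })
            c_in = c_out

    @property
    def n_features(self) -> int:
        return self.FILTERS[-1] * 3 * 3

    def forward(self, images: np.ndarray) -> np.ndarray:
        """(B, 28, 28) or (28, 28) grayscale in [0, 1] -> (B, 576) features."""
        x = np.asarray(images, dtype=float)
        single = x.ndim == 2
        if single:
            x = x[None]
        if x.ndim == 3:
            x = x[:, None]
        if x.shape[-2:] != (28, 28):
            raise ValueError("expected 28x28 images")
        for layer in self.layers:
            B, C, H, W = x.shape
            cols = _im2col(x, self.K)                       # (B, H*W, C*9)
            conv = cols @ layer["w"].T + layer["b"]          # (B, H*W, C_out)
            conv = conv.transpose(0, 2, 1).reshape(B, -1, H, W)
            mean = conv.mean(axis=(0, 2, 3), keepdims=True)
            var = conv.var(axis=(0, 2, 3), keepdims=True)
            xhat = (conv - mean) / np.sqrt(var + 1e-5)
            out = layer["gamma"][None, :, None, None] * xhat \
                + layer["beta"][None, :, None, None]
            out = np.maximum(out, 0.0)
            Hp, Wp = (out.shape[2] // 2) * 2, (out.shape[3] // 2) * 2
            out = out[:, :, :Hp, :Wp]
            x = out.reshape(out.shape[0], out.shape[1], Hp // 2, 2,
                            Wp // 2, 2).mean(axis=(3, 5))
        feats = x.reshape(x.shape[0], -1)
        return feats[0] if single else feats


def conv_encode(image: np.ndarray, vnn: ConvEncoder) -> np.ndarray:
    """Encode one 28x28 grayscale image into the 576-dim feature vector."""
    return vnn.forward(image)
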