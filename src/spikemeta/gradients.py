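"""Gradient machinery: eligibility traces, surrogate BPTT, and the trainer.

Two complementary routes to the same surrogate gradient are provided:

* :func:`surrogate_bptt` — reverse-time accumulation through the recorded
  rollout.  The derivative of the spike nonlinearity is replaced by the
  triangular pseudo-derivative ``psi`` recorded during the forward pass;
  every other edge of the computation graph (leaky integration, soft reset,
  threshold adaptation, delayed recurrence, leaky readout) is differentiated
  exactly.  This is the default trainer.
* eligibility traces (:func:`eligibility_lif`, :func:`eligibility_alif`,
  :class:`OnlineEligibility`) — per-synapse quantities propagated *forward*
  in time.  Multiplied by a top-down learning signal they yield local,
  online weight updates; the meta-learner uses them for its within-episode
  plasticity.

The optimizer is Adam for the synaptic weights and plain gradient descent
for the ensemble-loss weights ``lam`` (whose gradient has the closed form
``2 lam_j (L_j + eta1 + 2 eta2 (sum lam^2 - 1))``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .losses import (CorrentropyConfig, EnsembleLossConfig, RegularizerConfig,
                     cross_entropy, cross_entropy_logits_grad,
                     ensemble_objective, mmcc_loss,
                     mmcc_loss_grad, rate_regularizer, rate_regularizer_grad,
                     softmax, voltage_regularizer, voltage_regularizer_grads)
from .neurons import NetworkWeights, NeuronParams, Rollout, simulate_network

GRAD_CLIP_NORM = 100.0

__all__ = [
    "TraceState", "OnlineEligibility", "Gradients", "AdamState",
    "low_pass_spikes", "eligibility_lif", "eligibility_alif",
    "surrogate_bptt", "adam_step", "clip_gradients",
    "update_ensemble_weights", "train", "TrainResult",
]


def low_pass_spikes(raster: np.ndarray, alpha: float) -> np.ndarray:
    """Low-pass filtered spikes ``zbar(t) = alpha*zbar(t-1) + z(t)`` along the last axis."""
    if not 0.0 <= alpha < 1.0:
        raise ValueError("alpha must lie in [0, 1)")
    arr = np.asarray(raster, dtype=float)
    return lfilter([1.0], [1.0, -alpha], arr, axis=-1)


def _shift(arr: np.ndarray, d: int) -> np.ndarray:
    """arr(t - d) along the last axis, zero-padded on the left."""
    if d == 0:
        return arr
    out = np.zeros_like(arr)
    out[..., d:] = arr[..., :-d]
    return out


def eligibility_lif(psi: np.ndarray, zbar: np.ndarray, d: int = 1) -> np.ndarray:
    """LIF eligibility trace ``e_ji(t) = psi_j(t) * zbar_i(t - d)``.

    ``psi`` is ``(n_post, T)``, ``zbar`` is ``(n_pre, T)``; returns
    ``(n_post, n_pre, T)``.
    """
    psi = np.asarray(psi, dtype=float)
    zb = _shift(np.asarray(zbar, dtype=float), d)
    return psi[:, None, :] * zb[None, :, :]


def eligibility_alif(psi: np.ndarray, zbar: np.ndarray, params: NeuronParams,
                     beta: float | None = None, d: int = 1):
    """ALIF eligibility traces.

    Advances, for every synapse (j, i),

    ``eps_a(t) = (rho - beta*psi_j(t-1)) * eps_a(t-1) + psi_j(t-1) * zbar_i(t-d-1)``
    ``e(t)     = psi_j(t) * (zbar_i(t-d) - beta * eps_a(t))``

    with ``eps_a(0) = 0``.  Returns ``(e, eps_a)``, both ``(n_post, n_pre, T)``.
    """
    psi = np.asarray(psi, dtype=float)
    zbar = np.asarray(zbar, dtype=float)
    b = params.beta_adapt if beta is None else beta
    rho = params.rho
    n_post, T = psi.shape
    n_pre = zbar.shape[0]
    zb_d = _shift(zbar, d)
    eps_a = np.zeros((n_post, n_pre, T))
    e = np.zeros((n_post, n_pre, T))
    prev = np.zeros((n_post, n_pre))
    for t in range(T):
        if t > 0:
            zb_hist = zb_d[:, t - 1]  # zbar(t - d - 1)
            prev = (rho - b * psi[:, t - 1])[:, None] * prev \
                + psi[:, t - 1][:, None] * zb_hist[None, :]
        eps_a[:, :, t] = prev
        e[:, :, t] = psi[:, t][:, None] * (zb_d[None, :, t] - b * prev)
    return e, eps_a


@dataclass
class TraceState:
    """Streaming per-synapse eligibility state, batched ``(B, n_post, n_pre)``."""

    eps_v: np.ndarray   # low-pass presynaptic trace per synapse (postsyn decay)
    eps_a: np.ndarray   # adaptation component
    zbar: np.ndarray    # plain presynaptic low-pass trace (B, n_pre)
    psi_prev: np.ndarray  # psi of the previous step (B, n_post)
    zbar_hist: list = field(default_factory=list)  # delayed zbar snapshots

    @classmethod
    def zeros(cls, B: int, n_post: int, n_pre: int) -> "TraceState":
        return cls(eps_v=np.zeros((B, n_post, n_pre)),
                   eps_a=np.zeros((B, n_post, n_pre)),
                   zbar=np.zeros((B, n_pre)),
                   psi_prev=np.zeros((B, n_post)))


class OnlineEligibility:
    """Forward-time eligibility for a (possibly mixed) postsynaptic pool.

    Handles per-postsynaptic-neuron membrane decay and input gain (so LIF and
    two-compartment neurons coexist) and the adaptation component for
    adaptive neurons.  ``step`` consumes the presynaptic activity of step
    ``t - d`` together with the current surrogate derivatives and returns the
    eligibility traces ``e_ji(t)`` of the step.
    """

    def __init__(self, B: int, n_post: int, n_pre: int, params: NeuronParams,
                 decay: np.ndarray, gain: np.ndarray, beta: np.ndarray):
        self.params = params
        self.decay = decay          # (n_post,)
        self.gain = gain            # (n_post,)
        self.beta = beta            # (n_post,)
        self.state = TraceState.zeros(B, n_post, n_pre)

    def step(self, psi_t: np.ndarray, z_pre_delayed: np.ndarray) -> np.ndarray:
        """One step; ``z_pre_delayed`` is the presynaptic vector from ``t - d``."""
        s = self.state
        rho = self.params.rho
        eps_v_old = s.eps_v.copy()
        s.eps_v = self.decay[None, :, None] * s.eps_v \
            + self.gain[None, :, None] * z_pre_delayed[:, None, :]
        s.eps_a = (rho - self.beta[None, :] * s.psi_prev)[:, :, None] * s.eps_a \
            + s.psi_prev[:, :, None] * eps_v_old
        e = psi_t[:, :, None] * (s.eps_v - self.beta[None, :, None] * s.eps_a)
        s.psi_prev = psi_t
        return e


@dataclass
class Gradients:
    """Gradient blocks for one network (summed over the batch)."""

    w_in: np.ndarray
    w_rec: np.ndarray
    w_out: np.ndarray
    b_out: np.ndarray
    # per-sample gradients w.r.t. the within-episode weight offsets
    dw_in: np.ndarray | None = None
    dw_rec: np.ndarray | None = None
    dx: np.ndarray | None = None  # gradient w.r.t. the input stream

    def as_dict(self) -> dict:
        return {"w_in": self.w_in, "w_rec": self.w_rec,
                "w_out": self.w_out, "b_out": self.b_out}


def surrogate_bptt(rollout: Rollout, weights: NetworkWeights,
                   dL_dy: np.ndarray | None = None,
                   dL_dz: np.ndarray | None = None,
                   dL_dv: np.ndarray | None = None,
                   dL_dA: np.ndarray | None = None,
                   dw_in: np.ndarray | None = None,
                   dw_rec: np.ndarray | None = None,
                   dw_from: int = 0,
                   per_sample: bool = False,
                   want_dx: bool = False) -> Gradients:
    """Backpropagation through time over a recorded rollout.

    Adjoint seeds: ``dL_dy`` on the readout trace ``(B, K, T)``, ``dL_dz`` on
    the spikes, ``dL_dv``/``dL_dA`` on the membrane/threshold traces (from the
    voltage regularizer).  Where a spike is emitted the Heaviside derivative
    is replaced by the recorded surrogate ``psi``; the soft reset, threshold
    adaptation, delayed recurrence and readout filter are differentiated
    exactly.  Per-sample weight offsets ``dw_in``/``dw_rec`` active from step
    ``dw_from`` are honoured; with ``per_sample=True`` their own per-sample
    gradients (restricted to the steps where they act) are returned as well.
    """
    if rollout.params.reset != "soft":
        raise NotImplementedError("BPTT implemented for the soft reset rule")
    p = rollout.params
    z, v, psi = rollout.z, rollout.v, rollout.psi
    B, N, T = z.shape
    K = weights.n_out
    n_in = weights.n_in
    nu, mu, vth, d = p.nu, p.mu, p.v_th, p.d
    decay, in_gain, rec_gain, beta = (rollout.decay, rollout.in_gain,
                                      rollout.rec_gain, rollout.beta)
    tlif = rollout.tlif_mask
    lif_rows = ~tlif

    g_v_hist = np.zeros((B, N, T))
    g_a_next = np.zeros((B, N))
    g_y_next = np.zeros((B, K))
    gw_in = np.zeros_like(weights.w_in)
    gw_rec = np.zeros_like(weights.w_rec)
    gw_out = np.zeros_like(weights.w_out)
    gb_out = np.zeros_like(weights.b_out)
    pdw_in = np.zeros((B,) + weights.w_in.shape) if per_sample else None
    pdw_rec = np.zeros((B,) + weights.w_rec.shape) if per_sample else None
    if want_dx and tlif.any():
        # would require the adjoint of the dendritic input filter; encoder
        # features should drive LIF input rows instead
        raise NotImplementedError(
            "input gradients through the dendritic filter are not supported")
    ds_in = np.zeros((B, n_in, T)) if want_dx else None  # dL/d(input drive source)

    for t in range(T - 1, -1, -1):
        if dL_dy is not None:
            g_y = dL_dy[:, :, t] + nu * g_y_next
            gw_out += (1.0 - nu) * np.einsum("bk,bj->kj", g_y, z[:, :, t])
            gb_out += dL_dy[:, :, t].sum(axis=0)
            gz = (1.0 - nu) * (g_y @ weights.w_out)
            g_y_next = g_y
        else:
            gz = np.zeros((B, N))
        if dL_dz is not None:
            gz = gz + dL_dz[:, :, t]
        if t + 1 < T:
            gz = gz - vth * g_v_hist[:, :, t + 1]   # soft reset path
            gz = gz + g_a_next                      # a(t+1) = mu a(t) + z(t)
        if t + d < T:
            gvf = g_v_hist[:, :, t + d] * rec_gain
            gz = gz + gvf @ weights.w_rec
            if dw_rec is not None and t + d >= dw_from:
                gz = gz + np.einsum("bji,bj->bi", dw_rec, gvf)
        g_A = -psi[:, :, t] * gz
        if dL_dA is not None:
            g_A = g_A + dL_dA[:, :, t]
        g_a_next = beta * g_A + mu * (g_a_next if t + 1 < T else 0.0)
        g_v = psi[:, :, t] * gz
        if dL_dv is not None:
            g_v = g_v + dL_dv[:, :, t]
        if t + 1 < T:
            g_v = g_v + decay * g_v_hist[:, :, t + 1]
        g_v_hist[:, :, t] = g_v

        gv_in = g_v * in_gain
        if lif_rows.any():
            gw_in[lif_rows] += np.einsum("bj,bi->ji", gv_in[:, lif_rows],
                                         rollout.x[:, :, t])
        if tlif.any():
            gw_in[tlif] += np.einsum("bj,bi->ji", gv_in[:, tlif],
                                     rollout.x_filt[:, :, t])
        if t - d >= 0:
            gv_rec = g_v * rec_gain
            gw_rec += np.einsum("bj,bi->ji", gv_rec, z[:, :, t - d])
            if per_sample and t >= dw_from:
                pdw_rec += np.einsum("bj,bi->bji", gv_rec, z[:, :, t - d])
        if per_sample and t >= dw_from:
            if lif_rows.any():
                m = np.where(lif_rows, gv_in, 0.0)
                pdw_in += np.einsum("bj,bi->bji", m, rollout.x[:, :, t])
            if tlif.any():
                m = np.where(tlif, gv_in, 0.0)
                pdw_in += np.einsum("bj,bi->bji", m, rollout.x_filt[:, :, t])
        if want_dx:
            ds_in[:, :, t] += gv_in @ weights.w_in
            if dw_in is not None and t >= dw_from:
                ds_in[:, :, t] += np.einsum("bji,bj->bi", dw_in, gv_in)

    np.fill_diagonal(gw_rec, 0.0)
    if per_sample:
        idx = np.arange(N)
        pdw_rec[:, idx, idx] = 0.0

    return Gradients(w_in=gw_in, w_rec=gw_rec, w_out=gw_out, b_out=gb_out,
                     dw_in=pdw_in, dw_rec=pdw_rec, dx=ds_in)


@dataclass
class AdamState:
    """First/second-moment accumulators keyed by parameter name."""

    m: dict = field(default_factory=dict)
    v: dict = field(default_factory=dict)
    step: int = 0
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8


def adam_step(opt: AdamState, params: dict, grads: dict, lr: float) -> dict:
    """One Adam update on a dict of arrays; returns the updated dict (in place)."""
    opt.step += 1
    t = opt.step
    for k, g in grads.items():
        if k not in opt.m:
            opt.m[k] = np.zeros_like(params[k])
            opt.v[k] = np.zeros_like(params[k])
        opt.m[k] = opt.beta1 * opt.m[k] + (1 - opt.beta1) * g
        opt.v[k] = opt.beta2 * opt.v[k] + (1 - opt.beta2) * g * g
        mhat = opt.m[k] / (1 - opt.beta1 ** t)
        vhat = opt.v[k] / (1 - opt.beta2 ** t)
        params[k] = params[k] - lr * mhat / (np.sqrt(vhat) + opt.eps)
    return params


def clip_gradients(grads: dict, max_norm: float = GRAD_CLIP_NORM) -> dict:
    total = math.sqrt(sum(float((g ** 2).sum()) for g in grads.values()))
    if total > max_norm:
        scale = max_norm / total
        grads = {k: g * scale for k, g in grads.items()}
    return grads


def update_ensemble_weights(lam: np.ndarray, base_losses: np.ndarray,
                            eta1: float, eta2: float, lr: float,
                            max_grad_norm: float | None = None) -> np.ndarray:
    """Plain gradient-descent step on the ensemble weights (losses held fixed).

    ``max_grad_norm`` optionally clips the gradient norm; the training loops
    use this because early in training a base loss (typically the rate
    regularizer of a near-silent network) can be orders of magnitude larger
    than the others and would otherwise make the plain GD step overshoot.
    """
    lam = np.asarray(lam, dtype=float)
    s = float((lam ** 2).sum())
    grad = 2.0 * lam * (np.asarray(base_losses, dtype=float)
                        + eta1 + 2.0 * eta2 * (s - 1.0))
    if max_grad_norm is not None:
        norm = float(np.linalg.norm(grad))
        if norm > max_grad_norm:
            grad = grad * (max_grad_norm / norm)
    return lam - lr * grad


@dataclass
class TrainResult:
    weights: NetworkWeights
    lam: np.ndarray
    log: list          # one dict per iteration: L1..L4, lam1..lam4, penalty, total
    final_rates_hz: np.ndarray


def _softmax_vjp(p: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Vector-Jacobian product of softmax rows: dL/dlogits from dL/dp."""
    return p * (g - (g * p).sum(axis=-1, keepdims=True))


def train(weights: NetworkWeights, params: NeuronParams, sampler,
          n_iters: int, seed: int,
          ensemble: EnsembleLossConfig | None = None,
          correntropy: CorrentropyConfig | None = None,
          regularizer: RegularizerConfig | None = None,
          lr: float = 1.915e-3, lr_lam: float = 2e-3,
          adaptive: np.ndarray | None = None,
          kinds: np.ndarray | None = None, dparams=None,
          readout_window: float = 0.25) -> TrainResult:
    """Joint training of synaptic weights W (Adam) and ensemble weights lam (GD).

    ``sampler(rng)`` must return a minibatch ``(x, y_onehot)`` with
    ``x`` of shape ``(B, n_in, T)``.  Class logits are the readout averaged
    over the final ``readout_window`` fraction of the rollout.  Per iteration
    the four base losses (mixture correntropy, cross-entropy, rate, voltage)
    are combined with weights ``lam_j^2``, backpropagated with
    :func:`surrogate_bptt`, and logged.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    ensemble = ensemble or EnsembleLossConfig.random_init(rng)
    correntropy = correntropy or CorrentropyConfig()
    regularizer = regularizer or RegularizerConfig(v_th=params.v_th)
    opt = AdamState()
    pdict = {"w_in": weights.w_in, "w_rec": weights.w_rec,
             "w_out": weights.w_out, "b_out": weights.b_out}
    log: list[dict] = []
    rates = np.zeros(weights.n_hidden)

    for it in range(n_iters):
        x, y_true = sampler(rng)
        roll = simulate_network(weights, params, x, kinds=kinds,
                                dparams=dparams, adaptive=adaptive)
        B, _, T = roll.z.shape
        w0 = int(T * (1.0 - readout_window))
        window = slice(w0, T)
        nwin = T - w0
        logits = roll.y[:, :, window].mean(axis=2)
        probs = softmax(logits)

        L1 = mmcc_loss(y_true, probs, correntropy)
        L2 = cross_entropy(y_true, probs)
        L3, f = rate_regularizer(roll.raster, regularizer)
        L4 = voltage_regularizer(roll.v, roll.A, regularizer)
        rates = f
        breakdown = ensemble_objective(np.array([L1, L2, L3, L4]), ensemble)

        lam2 = ensemble.lam ** 2
        dL_dlogits = lam2[0] * _softmax_vjp(probs, mmcc_loss_grad(y_true, probs,
                                                                  correntropy)) \
            + lam2[1] * cross_entropy_logits_grad(y_true, logits)
        dL_dy = np.zeros_like(roll.y)
        dL_dy[:, :, window] = dL_dlogits[:, :, None] / nwin
        dL_dz = lam2[2] * rate_regularizer_grad(roll.raster, regularizer)
        gv, gA = voltage_regularizer_grads(roll.v, roll.A, regularizer)
        grads = surrogate_bptt(roll, weights, dL_dy=dL_dy, dL_dz=dL_dz,
                               dL_dv=lam2[3] * gv, dL_dA=lam2[3] * gA)
        gdict = clip_gradients(grads.as_dict())
        adam_step(opt, pdict, gdict, lr)
        weights.w_in, weights.w_rec = pdict["w_in"], pdict["w_rec"]
        weights.w_out, weights.b_out = pdict["w_out"], pdict["b_out"]
        np.fill_diagonal(weights.w_rec, 0.0)

        if ensemble.trainable:
            ensemble.lam = update_ensemble_weights(
                ensemble.lam, breakdown.base, ensemble.eta1, ensemble.eta2,
                lr_lam, max_grad_norm=10.0)

        acc = float((probs.argmax(axis=1) == y_true.argmax(axis=1)).mean())
        row = {"iteration": it, "L1": L1, "L2": L2, "L3": L3, "L4": L4,
               "penalty": breakdown.penalty, "total": breakdown.total,
               "accuracy": acc, "mean_rate_hz": float(f.mean())}
        for j in range(4):
            row[f"lam{j + 1}"] = float(ensemble.lam[j])
        log.append(row)
        if not np.isfinite(breakdown.total):
            raise FloatingPointError(f"training diverged at iteration {it}")

    return TrainResult(weights=weights, lam=ensemble.lam, log=log,
                       final_rates_hz=rates)
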