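"""Base loss functions and the heterogeneous ensemble objective.

Four base losses are combined with trainable weights ``lam = (l1..l4)``:

1. **Mixture-correntropy loss** — ``1 - Vhat`` where ``Vhat`` is the two-kernel
   mixture correntropy between targets and predictions.  Correntropy is a
   kernel-based local similarity bounded in ``(0, 1]``; its influence function
   is redescending, so gross outliers contribute a bounded (saturating)
   penalty, unlike the unbounded linear influence of squared error.
2. **Cross-entropy** — the usual multiclass form, plus a two-phase binary
   variant that samples the readout at the end of each query item.
3. **Firing-rate regularizer** — quadratic pull of each neuron's mean rate
   (Hz) toward a target rate.
4. **Voltage regularizer** — one-sided quadratic penalties on membrane
   excursions above the effective threshold or below ``-v_th``.

The ensemble total is the augmented-Lagrangian form

``sum_j lam_j^2 * L_j + eta1*(sum lam^2 - 1) + eta2*(sum lam^2 - 1)^2``

whose penalty terms steer the squared weights onto the simplex-like
constraint ``sum lam_j^2 = 1`` during training.

Each loss ships with its analytic gradient with respect to the quantity the
gradient engine needs (readout values, spikes, or membrane traces).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EPS = 1e-12  # clamp inside logarithms

__all__ = [
    "CorrentropyConfig", "RegularizerConfig", "EnsembleLossConfig",
    "LossBreakdown", "gaussian_kernel", "mixture_correntropy", "mmcc_loss",
    "mmcc_loss_grad", "influence_function", "softmax", "cross_entropy",
    "cross_entropy_logits_grad", "phase_cross_entropy", "phase_sample_steps",
    "phase_cross_entropy_grad", "rate_regularizer", "rate_regularizer_grad",
    "voltage_regularizer", "voltage_regularizer_grads", "ensemble_objective",
    "ensemble_lam_gradient",
]


@dataclass
class CorrentropyConfig:
    """Two-kernel mixture correntropy: widths sigma1/sigma2, mixture weight lam_mix."""

    sigma1: float = 1.0
    sigma2: float = 4.0
    lam_mix: float = 0.5
    S: int = 2

    def __post_init__(self) -> None:
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ValueError("kernel widths must be positive")
        if not 0.0 <= self.lam_mix <= 1.0:
            raise ValueError("lam_mix must lie in [0, 1]")
        if self.S != 2:
            raise ValueError("the mixture uses exactly two kernels")


@dataclass
class RegularizerConfig:
    f_target: float = 20.0   # target firing rate (Hz)
    lam_f: float = 1.0       # rate-regularizer scale
    lam_v: float = 1e-2      # voltage-regularizer scale
    v_th: float = 1.0

    def __post_init__(self) -> None:
        if self.f_target < 0 or self.lam_f < 0 or self.lam_v < 0:
            raise ValueError("regularizer scales and target rate must be >= 0")


@dataclass
class EnsembleLossConfig:
    """Trainable combination weights, ordered (MMCC, cross-entropy, rate, voltage)."""

    lam: np.ndarray = field(default_factory=lambda: np.full(4, 0.5))
    eta1: float = 0.1
    eta2: float = 10.0
    trainable: bool = True

    def __post_init__(self) -> None:
        self.lam = np.asarray(self.lam, dtype=float)
        if self.lam.shape != (4,):
            raise ValueError("the ensemble combines exactly four base losses")
        if self.eta2 < 0:
            raise ValueError("eta2 must be non-negative")

    @classmethod
    def random_init(cls, rng: np.random.Generator, **kw) -> "EnsembleLossConfig":
        """Uniform-random weights rescaled onto the constraint sum lam^2 = 1."""
        lam = rng.uniform(0.0, 1.0, size=4)
        lam /= np.linalg.norm(lam)
        return cls(lam=lam, **kw)


@dataclass
class LossBreakdown:
    base: np.ndarray        # the four base loss values L_j
    weighted_sum: float     # sum lam_j^2 L_j
    penalty: float          # eta1*(S-1) + eta2*(S-1)^2, S = sum lam^2
    total: float


def gaussian_kernel(e: np.ndarray | float, sigma: float) -> np.ndarray:
    """``exp(-||e||^2 / (2 sigma^2))`` applied elementwise to scalar errors."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    e = np.asarray(e, dtype=float)
    return np.exp(-(e ** 2) / (2.0 * sigma ** 2))


def _errors(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-sample scalar error e_i = ||x_i - y_i||_2 (rows are samples)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("sample arrays must have identical shapes")
    if x.size == 0:
        raise ValueError("empty samples")
    diff = x - y
    if diff.ndim == 1:
        return np.abs(diff)
    return np.linalg.norm(diff.reshape(diff.shape[0], -1), axis=1)


def mixture_correntropy(x: np.ndarray, y: np.ndarray,
                        cfg: CorrentropyConfig) -> float:
    """Sample estimator of the two-kernel mixture correntropy Vhat in (0, 1]."""
    e = _errors(x, y)
    v = cfg.lam_mix * gaussian_kernel(e, cfg.sigma1) \
        + (1.0 - cfg.lam_mix) * gaussian_kernel(e, cfg.sigma2)
    return float(v.mean())


def mmcc_loss(targets: np.ndarray, predictions: np.ndarray,
              cfg: CorrentropyConfig) -> float:
    """Mixture-correntropy loss ``1 - Vhat``: zero iff the fit is perfect, < 1 always."""
    return 1.0 - mixture_correntropy(targets, predictions, cfg)


def mmcc_loss_grad(targets: np.ndarray, predictions: np.ndarray,
                   cfg: CorrentropyConfig) -> np.ndarray:
    """d(1 - Vhat)/d predictions (same shape as predictions)."""
    t = np.asarray(targets, dtype=float)
    p = np.asarray(predictions, dtype=float)
    diff = p - t
    flat = diff.reshape(diff.shape[0], -1) if diff.ndim > 1 else diff[:, None]
    e2 = (flat ** 2).sum(axis=1)
    n = flat.shape[0]
    g1 = np.exp(-e2 / (2.0 * cfg.sigma1 ** 2)) / cfg.sigma1 ** 2
    g2 = np.exp(-e2 / (2.0 * cfg.sigma2 ** 2)) / cfg.sigma2 ** 2
    coef = (cfg.lam_mix * g1 + (1.0 - cfg.lam_mix) * g2) / n
    grad = coef[:, None] * flat
    return grad.reshape(diff.shape)


def influence_function(e: np.ndarray | float, sigma: float) -> np.ndarray:
    """``psi(e) = -dG_sigma/de = (e/sigma^2) exp(-e^2/(2 sigma^2))`` up to sign.

    Returned with the conventional sign of the cited derivative,
    ``psi(e) = -(e/sigma^2) exp(-e^2/(2 sigma^2))``: odd, bounded, and
    redescending (|psi| -> 0 as |e| -> inf).
    """
    e = np.asarray(e, dtype=float)
    return -(e / sigma ** 2) * np.exp(-(e ** 2) / (2.0 * sigma ** 2))


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    m = logits - logits.max(axis=axis, keepdims=True)
    ex = np.exp(m)
    return ex / ex.sum(axis=axis, keepdims=True)


def cross_entropy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Multiclass cross-entropy ``-sum_i y_i log(yhat_i)`` averaged over rows.

    ``y_pred`` holds probabilities (softmax applied upstream); zero
    probabilities on the true class are clamped at ``EPS``.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    ce = -(y_true * np.log(np.clip(y_pred, EPS, None))).sum(axis=-1)
    return float(ce.mean())


def cross_entropy_logits_grad(y_true: np.ndarray, logits: np.ndarray) -> np.ndarray:
    """Gradient of mean cross-entropy w.r.t. the logits: (softmax - y)/n_rows."""
    p = softmax(logits)
    n = y_true.shape[0] if y_true.ndim > 1 else 1
    return (p - y_true) / n


def phase_sample_steps(n_query: int, t_img: int) -> np.ndarray:
    """Readout sampling steps of the two-phase protocol.

    Query ``n`` (1-based, after one support item) occupies steps
    ``[n*t_img, (n+1)*t_img)``; the readout only counts once the item has been
    fully presented, i.e. at the last step of each query window.
    """
    return np.array([(n + 1) * t_img - 1 for n in range(1, n_query + 1)])


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def phase_cross_entropy(readout_trace: np.ndarray, labels: np.ndarray,
                        t_img: int) -> float:
    """Binary cross-entropy of the matching protocol.

    ``readout_trace`` is ``(B, T)`` (single readout unit); ``labels`` is
    ``(B, n_query)`` with entries in {0, 1}.  The sigmoid of the readout is
    sampled at the end of each query item and scored against the match label;
    the per-episode loss is the *sum* over queries, averaged over the batch.
    """
    readout_trace = np.atleast_2d(np.asarray(readout_trace, dtype=float))
    labels = np.atleast_2d(np.asarray(labels, dtype=float))
    steps = phase_sample_steps(labels.shape[1], t_img)
    if readout_trace.shape[1] <= steps[-1]:
        raise ValueError(
            f"readout trace of length {readout_trace.shape[1]} too short; "
            f"need at least {steps[-1] + 1} steps")
    p = np.clip(_sigmoid(readout_trace[:, steps]), EPS, 1.0 - EPS)
    ce = -(labels * np.log(p) + (1.0 - labels) * np.log(1.0 - p)).sum(axis=1)
    return float(ce.mean())


def phase_cross_entropy_grad(readout_trace: np.ndarray, labels: np.ndarray,
                             t_img: int) -> np.ndarray:
    """Gradient w.r.t. the full readout trace (nonzero only at sample steps)."""
    readout_trace = np.atleast_2d(np.asarray(readout_trace, dtype=float))
    labels = np.atleast_2d(np.asarray(labels, dtype=float))
    steps = phase_sample_steps(labels.shape[1], t_img)
    grad = np.zeros_like(readout_trace)
    p = _sigmoid(readout_trace[:, steps])
    grad[:, steps] = (p - labels) / readout_trace.shape[0]
    return grad


def rate_regularizer(raster, cfg: RegularizerConfig,
                     dt: float | None = None):
    """Quadratic penalty on per-neuron mean rates: ``lam_f * sum_j (f_j - f_target)^2``.

    ``f_j`` is the average spike count per unit time over batch and duration,
    expressed in Hz.  Accepts a :class:`~spikemeta.neurons.SpikeRaster` or a
    plain ``(B, N, T)`` array plus ``dt`` (ms).  Returns ``(loss, f_j)``.
    """
    events = raster.events if hasattr(raster, "events") else np.asarray(raster)
    step_ms = raster.dt if hasattr(raster, "dt") else dt
    if step_ms is None:
        raise ValueError("dt (ms) required when passing a bare array")
    B, _, T = events.shape
    f = events.sum(axis=(0, 2)) / (B * T * step_ms / 1000.0)
    loss = cfg.lam_f * float(((f - cfg.f_target) ** 2).sum())
    return loss, f


def rate_regularizer_grad(raster, cfg: RegularizerConfig,
                          dt: float | None = None) -> np.ndarray:
    """dL/dz(n, j, t) — constant per neuron, broadcast over batch and time."""
    events = raster.events if hasattr(raster, "events") else np.asarray(raster)
    step_ms = raster.dt if hasattr(raster, "dt") else dt
    B, _, T = events.shape
    denom = B * T * step_ms / 1000.0
    _, f = rate_regularizer(raster, cfg, dt=step_ms)
    per_neuron = cfg.lam_f * 2.0 * (f - cfg.f_target) / denom
    return np.broadcast_to(per_neuron[None, :, None], events.shape).copy()


def voltage_regularizer(v_trace: np.ndarray, A_trace: np.ndarray,
                        cfg: RegularizerConfig) -> float:
    """Mean one-sided quadratic penalty on membrane excursions.

    ``(lam_v / (B*T)) * sum_{n,t,j} [max(0, v - A)^2 + max(0, -v - v_th)^2]``.
    """
    v = np.asarray(v_trace, dtype=float)
    A = np.asarray(A_trace, dtype=float)
    if v.shape != A.shape:
        raise ValueError("voltage and threshold traces must be aligned")
    B, _, T = v.shape
    over = np.maximum(0.0, v - A)
    under = np.maximum(0.0, -v - cfg.v_th)
    return cfg.lam_v / (B * T) * float((over ** 2 + under ** 2).sum())


def voltage_regularizer_grads(v_trace: np.ndarray, A_trace: np.ndarray,
                              cfg: RegularizerConfig):
    """Gradients (dL/dv, dL/dA) of the voltage penalty, same shapes as the traces."""
    v = np.asarray(v_trace, dtype=float)
    A = np.asarray(A_trace, dtype=float)
    B, _, T = v.shape
    c = cfg.lam_v / (B * T)
    over = np.maximum(0.0, v - A)
    under = np.maximum(0.0, -v - cfg.v_th)
    return c * (2.0 * over - 2.0 * under), c * (-2.0 * over)


def ensemble_objective(base_losses: np.ndarray,
                       cfg: EnsembleLossConfig) -> LossBreakdown:
    """Augmented-Lagrangian ensemble total with squared-weight combination."""
    L = np.asarray(base_losses, dtype=float)
    if L.shape != (4,):
        raise ValueError("expected four base losses")
    if not np.all(np.isfinite(L)):
        names = ("mmcc", "cross_entropy", "rate", "voltage")
        bad = [names[i] for i in range(4) if not np.isfinite(L[i])]
        raise FloatingPointError(f"non-finite base loss: {', '.join(bad)}")
    s = float((cfg.lam ** 2).sum())
    weighted = float((cfg.lam ** 2 * L).sum())
    penalty = cfg.eta1 * (s - 1.0) + cfg.eta2 * (s - 1.0) ** 2
    return LossBreakdown(base=L, weighted_sum=weighted, penalty=penalty,
                         total=weighted + penalty)


def ensemble_lam_gradient(base_losses: np.ndarray,
                          cfg: EnsembleLossConfig) -> np.ndarray:
    """Closed-form d(total)/d lam_j = 2 lam_j (L_j + eta1 + 2 eta2 (sum lam^2 - 1))."""
    L = np.asarray(base_losses, dtype=float)
    s = float((cfg.lam ** 2).sum())
    return 2.0 * cfg.lam * (L + cfg.eta1 + 2.0 * cfg.eta2 * (s - 1.0))
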