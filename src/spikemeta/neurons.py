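"""Discrete-time spiking neuron dynamics.

Implements the three neuron models used throughout the package:

* **LIF** — leaky integrate-and-fire with exponential membrane decay
  ``alpha = exp(-dt/tau_m)``, soft reset (``v <- v - v_th`` on spike) and an
  absolute refractory period.
* **ALIF** — LIF with a spike-triggered adaptive threshold
  ``A(t) = beta * a(t) + v_th``, ``a(t) = mu * a(t-1) + z(t-1)``,
  ``mu = exp(-dt/tau_a)``.
* **TLIF** — a two-compartment neuron whose basal dendrite integrates
  double-exponentially filtered input spikes into a dendritic potential
  ``v_b = W_in @ s_input + b`` that drives the soma through a conductance
  ratio ``g_b / g_l``; the soma is advanced by one explicit Euler step and
  shares the threshold/adaptation/refractory machinery of the LIF soma.

Spikes are binary, emitted when the membrane reaches the (possibly adaptive)
threshold, and reach postsynaptic neurons after an integer transmission delay
``d`` (in steps).  Readout units are non-spiking leaky integrators of the
hidden spike trains (decay ``nu = exp(-dt/tau_out)``).

All state arrays are batched with shape ``(batch, neurons)``; full rollouts
are produced by :func:`simulate_network`, which records everything the loss
functions and the gradient engine need.  The forward pass contains no
randomness: identical inputs give bit-identical rollouts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "NeuronParams",
    "DendriteParams",
    "NetworkWeights",
    "NeuronState",
    "SpikeRaster",
    "Rollout",
    "NumericalFailure",
    "lif_step",
    "alif_threshold_update",
    "tlif_step",
    "input_response_filter",
    "readout_update",
    "pseudo_derivative",
    "simulate_network",
]

PSI_PEAK = 0.3  # maximum of the surrogate spike derivative


class NumericalFailure(RuntimeError):
    """Raised when a state variable becomes non-finite during simulation."""


@dataclass
class NeuronParams:
    """Constants of the point-neuron dynamics (times in ms, thresholds dimensionless)."""

    tau_m: float = 15.0       # membrane time constant
    tau_out: float = 10.0     # readout time constant
    tau_a: float = 200.0      # threshold-adaptation time constant
    v_th: float = 1.0         # baseline firing threshold
    beta_adapt: float = 0.4902  # impact of threshold adaptation
    t_refrac: float = 5.0     # refractory duration (ms)
    d: int = 1                # recurrent transmission delay (steps)
    dt: float = 1.0           # integration step (ms)
    # Reset rule after a spike: "soft" subtracts v_th, "hard" clamps v to 0.
    reset: str = "soft"

    def __post_init__(self) -> None:
        if min(self.tau_m, self.tau_out, self.tau_a) <= 0 or self.dt <= 0:
            raise ValueError("all time constants and dt must be positive")
        if self.v_th <= 0:
            raise ValueError("v_th must be positive")
        if self.d < 1:
            raise ValueError("transmission delay must be at least one step")
        if self.t_refrac < 0:
            raise ValueError("t_refrac must be non-negative")
        if self.reset not in ("soft", "hard"):
            raise ValueError("reset must be 'soft' or 'hard'")

    @property
    def alpha(self) -> float:
        """Membrane decay factor exp(-dt/tau_m)."""
        return math.exp(-self.dt / self.tau_m)

    @property
    def mu(self) -> float:
        """Adaptation decay factor exp(-dt/tau_a)."""
        return math.exp(-self.dt / self.tau_a)

    @property
    def nu(self) -> float:
        """Readout decay factor exp(-dt/tau_out)."""
        return math.exp(-self.dt / self.tau_out)

    @property
    def rho(self) -> float:
        """Decay of the adaptation eligibility component (set equal to mu)."""
        return self.mu

    @property
    def n_refrac_steps(self) -> int:
        return int(round(self.t_refrac / self.dt))


@dataclass
class DendriteParams:
    """Constants of the basal-dendrite compartment of the TLIF neuron."""

    g_l: float = 0.1        # leak conductance
    g_b: float = 0.2        # basal dendrite conductance
    c_m: float = 2.0        # membrane capacitance (gives tau = c_m/g_l = 20 ms)
    tau_l: float = 10.0     # long synaptic time constant (ms)
    tau_s: float = 2.5      # short synaptic time constant (ms)
    bias: float | np.ndarray = 0.0  # per-neuron dendritic bias b_i

    def __post_init__(self) -> None:
        if self.g_l <= 0:
            raise ValueError("g_l must be positive")
        if self.g_b < 0:
            raise ValueError("g_b must be non-negative")
        if not (self.tau_l > self.tau_s > 0):
            raise ValueError("need tau_l > tau_s > 0 (degenerate kernel otherwise)")

    @property
    def tau(self) -> float:
        """Somatic time constant C_m / g_l (ms)."""
        return self.c_m / self.g_l

    def soma_decay(self, dt: float) -> float:
        """One-step Euler decay factor of the soma: 1 - (dt/tau)(1 + g_b/g_l)."""
        c = dt / self.tau
        return 1.0 - c * (1.0 + self.g_b / self.g_l)

    def dendrite_gain(self, dt: float) -> float:
        """Coupling of the dendritic potential into the soma per Euler step."""
        return (dt / self.tau) * (self.g_b / self.g_l)

    def recurrent_gain(self, dt: float) -> float:
        """Coupling of delayed recurrent spikes into the soma per Euler step."""
        return dt / self.tau


@dataclass
class NetworkWeights:
    """The three weight matrices of a recurrent network plus the readout bias.

    ``w_rec`` carries no self-connections: its diagonal is forced to zero on
    construction and kept zero by the optimizer.
    """

    w_in: np.ndarray   # (n_hidden, n_in)
    w_rec: np.ndarray  # (n_hidden, n_hidden), zero diagonal
    w_out: np.ndarray  # (n_out, n_hidden)
    b_out: np.ndarray  # (n_out,)
    w_init: dict = field(default_factory=dict)  # snapshot of initial weights

    def __post_init__(self) -> None:
        self.w_in = np.asarray(self.w_in, dtype=float)
        self.w_rec = np.asarray(self.w_rec, dtype=float)
        self.w_out = np.asarray(self.w_out, dtype=float)
        self.b_out = np.asarray(self.b_out, dtype=float)
        n = self.w_rec.shape[0]
        if self.w_rec.shape != (n, n):
            raise ValueError("w_rec must be square")
        if self.w_in.shape[0] != n or self.w_out.shape[1] != n:
            raise ValueError("inconsistent hidden dimension across weight matrices")
        if self.b_out.shape != (self.w_out.shape[0],):
            raise ValueError("b_out shape must match w_out rows")
        np.fill_diagonal(self.w_rec, 0.0)
        if not self.w_init:
            self.snapshot()

    def snapshot(self) -> None:
        self.w_init = {
            "w_in": self.w_in.copy(),
            "w_rec": self.w_rec.copy(),
            "w_out": self.w_out.copy(),
            "b_out": self.b_out.copy(),
        }

    @property
    def n_hidden(self) -> int:
        return self.w_rec.shape[0]

    @property
    def n_in(self) -> int:
        return self.w_in.shape[1]

    @property
    def n_out(self) -> int:
        return self.w_out.shape[0]

    @classmethod
    def initialize(cls, n_in: int, n_hidden: int, n_out: int,
                   rng: np.random.Generator) -> "NetworkWeights":
        """Gaussian init with per-matrix std 1/sqrt(fan_in)."""
        w_in = rng.normal(0.0, 1.0 / math.sqrt(n_in), size=(n_hidden, n_in))
        w_rec = rng.normal(0.0, 1.0 / math.sqrt(n_hidden), size=(n_hidden, n_hidden))
        w_out = rng.normal(0.0, 1.0 / math.sqrt(n_hidden), size=(n_out, n_hidden))
        b_out = np.zeros(n_out)
        return cls(w_in=w_in, w_rec=w_rec, w_out=w_out, b_out=b_out)


@dataclass
class NeuronState:
    """Instantaneous state of a population, batched ``(batch, neurons)``."""

    v: np.ndarray             # membrane potentials
    a: np.ndarray             # adaptation variables
    A: np.ndarray             # effective thresholds (beta*a + v_th)
    z: np.ndarray             # binary spike outputs of the current step
    refrac_count: np.ndarray  # remaining silenced steps (int)
    v_b: np.ndarray | None = None  # dendritic potentials (TLIF only)

    @classmethod
    def zeros(cls, batch: int, n: int, v_th: float = 1.0) -> "NeuronState":
        return cls(
            v=np.zeros((batch, n)),
            a=np.zeros((batch, n)),
            A=np.full((batch, n), v_th),
            z=np.zeros((batch, n)),
            refrac_count=np.zeros((batch, n), dtype=int),
            v_b=np.zeros((batch, n)),
        )


@dataclass
class SpikeRaster:
    """Binary spike events, shape ``(batch, neurons, steps)``."""

    events: np.ndarray
    dt: float = 1.0

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events)
        if self.events.ndim != 3:
            raise ValueError("raster must be (batch, neurons, steps)")
        u = np.unique(self.events)
        if not np.all(np.isin(u, (0, 1))):
            raise ValueError("raster entries must be binary")

    @property
    def n_batch(self) -> int:
        return self.events.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.events.shape[1]

    @property
    def T(self) -> int:
        return self.events.shape[2]

    def rates_hz(self) -> np.ndarray:
        """Per-neuron mean firing rate in Hz, averaged over batch and time."""
        dur_s = self.T * self.dt / 1000.0
        return self.events.sum(axis=(0, 2)) / (self.n_batch * dur_s)


def _check_shapes(state: NeuronState, drive: np.ndarray) -> None:
    if drive.shape != state.v.shape:
        raise ValueError(
            f"drive shape {drive.shape} does not match state shape {state.v.shape}")


def alif_threshold_update(state: NeuronState, params: NeuronParams,
                          beta: float | np.ndarray | None = None) -> NeuronState:
    """Advance the adaptive threshold one step: a <- mu*a + z_prev, A = beta*a + v_th."""
    b = params.beta_adapt if beta is None else beta
    a = params.mu * state.a + state.z
    A = b * a + params.v_th
    return replace(state, a=a, A=A)


def _fire(state: NeuronState, v: np.ndarray, A: np.ndarray,
          params: NeuronParams) -> NeuronState:
    """Shared spike emission / refractory logic (reset happens on the next step)."""
    can_spike = state.refrac_count == 0
    z = (((v - A) >= 0.0) & can_spike).astype(float)
    refrac = np.where(z > 0, params.n_refrac_steps,
                      np.maximum(state.refrac_count - 1, 0))
    return replace(state, v=v, A=A, z=z, refrac_count=refrac.astype(int))


def lif_step(state: NeuronState, syn_input: np.ndarray, params: NeuronParams,
             weights: NetworkWeights | None = None,
             delayed_spikes: np.ndarray | None = None,
             beta: float | np.ndarray = 0.0) -> NeuronState:
    """One step of (A)LIF dynamics.

    ``syn_input`` is the external per-neuron current (already projected through
    the input weights); ``delayed_spikes`` is the hidden raster slice from
    ``t - d`` and is projected through ``weights.w_rec`` if both are given.
    ``beta = 0`` gives a plain LIF neuron, ``beta > 0`` an ALIF neuron.

    The spike of the *previous* step enters here twice: it triggers the soft
    reset of ``v`` and increments the adaptation variable ``a``.
    """
    syn_input = np.asarray(syn_input, dtype=float)
    _check_shapes(state, syn_input)
    drive = syn_input
    if weights is not None and delayed_spikes is not None:
        if delayed_spikes.shape[-1] != weights.w_rec.shape[1]:
            raise ValueError("delayed_spikes incompatible with w_rec")
        drive = drive + delayed_spikes @ weights.w_rec.T
    st = alif_threshold_update(state, params, beta=beta)
    if params.reset == "soft":
        v = params.alpha * state.v + drive - params.v_th * state.z
    else:
        v = params.alpha * state.v * (1.0 - state.z) + drive
    return _fire(st, v, st.A, params)


def tlif_step(state: NeuronState, input_filtered: np.ndarray,
              dparams: DendriteParams, params: NeuronParams,
              weights: NetworkWeights | None = None,
              delayed_spikes: np.ndarray | None = None,
              beta: float | np.ndarray = 0.0) -> NeuronState:
    """One Euler step of the two-compartment neuron.

    ``input_filtered`` holds the kernel-filtered input traces ``s_j^input(t)``
    (shape ``(batch, n_in)``); the dendritic potential is
    ``v_b = W_in @ s + b`` and couples into the soma with gain
    ``(dt/tau)(g_b/g_l)``.  Spiking uses the same threshold machinery as the
    LIF soma.
    """
    if dparams.tau <= 0:
        raise ValueError("somatic time constant tau must be positive")
    input_filtered = np.asarray(input_filtered, dtype=float)
    if weights is not None:
        v_b = input_filtered @ weights.w_in.T + dparams.bias
    else:
        v_b = input_filtered + dparams.bias
    _check_shapes(state, v_b)
    rec = np.zeros_like(v_b)
    if weights is not None and delayed_spikes is not None:
        rec = delayed_spikes @ weights.w_rec.T
    st = alif_threshold_update(state, params, beta=beta)
    decay = dparams.soma_decay(params.dt)
    v = (decay * state.v + dparams.dendrite_gain(params.dt) * v_b
         + dparams.recurrent_gain(params.dt) * rec)
    if params.reset == "soft":
        v = v - params.v_th * state.z
    else:
        v = v * (1.0 - state.z)
    st = _fire(st, v, st.A, params)
    return replace(st, v_b=v_b)


def input_response_filter(spikes: np.ndarray, dparams: DendriteParams,
                          dt: float = 1.0) -> np.ndarray:
    """Filter input spike trains with the causal double-exponential kernel.

    ``kappa(t) = (exp(-t/tau_l) - exp(-t/tau_s)) / (tau_l - tau_s)`` for
    ``t >= 0``; the filtered trace is ``s(t) = sum_k kappa(t - t_k)``.
    ``spikes`` is ``(..., T)``; filtering runs along the last axis.
    """
    if dparams.tau_l == dparams.tau_s:
        raise ValueError("tau_l == tau_s gives a degenerate kernel")
    spikes = np.asarray(spikes, dtype=float)
    a_l = math.exp(-dt / dparams.tau_l)
    a_s = math.exp(-dt / dparams.tau_s)
    p_l = lfilter([1.0], [1.0, -a_l], spikes, axis=-1)
    p_s = lfilter([1.0], [1.0, -a_s], spikes, axis=-1)
    return (p_l - p_s) / (dparams.tau_l - dparams.tau_s)


def readout_update(y_prev: np.ndarray, z_t: np.ndarray,
                   weights: NetworkWeights, params: NeuronParams) -> np.ndarray:
    """One step of the leaky readout.

    ``y(t) = nu*(y(t-1) - b) + (1-nu) * W_out @ z(t) + b`` — the recursive form
    of the explicit low-pass sum ``y_k(t) = (1-nu) sum_{t'<=t} nu^(t-t') W_out z(t') + b``.
    """
    nu = params.nu
    return nu * (y_prev - weights.b_out) + (1.0 - nu) * (z_t @ weights.w_out.T) \
        + weights.b_out


def pseudo_derivative(v: np.ndarray, A: np.ndarray | float,
                      params: NeuronParams, kind: str = "lif",
                      refractory: np.ndarray | None = None) -> np.ndarray:
    """Surrogate derivative of the spike nonlinearity.

    Triangular, peaked at the threshold with height 0.3:
    ``psi = 0.3 * max(0, 1 - |theta - v| / v_th)`` where ``theta`` is the
    baseline threshold ``v_th`` for plain LIF and the effective adaptive
    threshold ``A`` for ALIF/TLIF.  Zero during the refractory period so no
    gradient flows through silenced neurons.
    """
    v = np.asarray(v, dtype=float)
    theta = params.v_th if kind == "lif" else np.asarray(A, dtype=float)
    psi = PSI_PEAK * np.maximum(0.0, 1.0 - np.abs(theta - v) / params.v_th)
    if refractory is not None:
        psi = np.where(refractory, 0.0, psi)
    return psi


@dataclass
class Rollout:
    """Everything recorded during a forward simulation (time-last arrays)."""

    z: np.ndarray        # (B, N, T) hidden spikes
    v: np.ndarray        # (B, N, T) membrane potentials
    a: np.ndarray        # (B, N, T) adaptation variables
    A: np.ndarray        # (B, N, T) effective thresholds
    psi: np.ndarray      # (B, N, T) surrogate derivatives (0 while refractory)
    y: np.ndarray        # (B, K, T) readout traces
    x: np.ndarray        # (B, n_in, T) raw input drive
    x_filt: np.ndarray | None  # (B, n_in, T) kernel-filtered input (if TLIF present)
    decay: np.ndarray    # (N,) per-neuron membrane decay factor
    in_gain: np.ndarray  # (N,) per-neuron gain on the input drive
    rec_gain: np.ndarray  # (N,) per-neuron gain on recurrent drive
    beta: np.ndarray     # (N,) per-neuron adaptation impact
    tlif_mask: np.ndarray  # (N,) bool
    params: NeuronParams

    @property
    def raster(self) -> SpikeRaster:
        return SpikeRaster(events=self.z.astype(np.uint8), dt=self.params.dt)


def neuron_coefficients(params: NeuronParams, kinds: np.ndarray,
                        dparams: DendriteParams | None):
    """Per-neuron (decay, input-gain, recurrent-gain) vectors for a mixed pool."""
    n = len(kinds)
    tlif = np.asarray([k == "tlif" for k in kinds])
    decay = np.full(n, params.alpha)
    in_gain = np.ones(n)
    rec_gain = np.ones(n)
    if tlif.any():
        if dparams is None:
            raise ValueError("TLIF neurons present but no DendriteParams given")
        decay[tlif] = dparams.soma_decay(params.dt)
        in_gain[tlif] = dparams.dendrite_gain(params.dt)
        rec_gain[tlif] = dparams.recurrent_gain(params.dt)
    return decay, in_gain, rec_gain, tlif


def simulate_network(weights: NetworkWeights, params: NeuronParams,
                     x: np.ndarray | SpikeRaster,
                     kinds: np.ndarray | None = None,
                     dparams: DendriteParams | None = None,
                     adaptive: np.ndarray | None = None,
                     dw_in: np.ndarray | None = None,
                     dw_rec: np.ndarray | None = None,
                     dw_from: int = 0,
                     state: NeuronState | None = None) -> Rollout:
    """Full forward rollout of a recurrent network on an input stream.

    Parameters
    ----------
    x : array ``(batch, n_in, T)`` of input currents (binary for spike input),
        or a :class:`SpikeRaster`.
    kinds : per-neuron tags ``{"lif", "tlif"}``; default all-LIF.
    adaptive : boolean mask of neurons with threshold adaptation (ALIF
        machinery); adaptivity is orthogonal to the compartment kind.
    dw_in, dw_rec : optional per-sample weight offsets ``(batch, ...)`` — used
        by the meta-learner to apply within-episode plasticity.  They act
        only from step ``dw_from`` onward (the phase boundary).
    state : optional initial state (default zeros), e.g. to continue an episode.

    Deterministic: there is no randomness in the forward dynamics.
    """
    if isinstance(x, SpikeRaster):
        x = x.events
    x = np.asarray(x, dtype=float)
    if x.ndim != 3:
        raise ValueError("input must be (batch, n_in, T)")
    B, n_in, T = x.shape
    n = weights.n_hidden
    if n_in != weights.n_in:
        raise ValueError(f"input has {n_in} channels, w_in expects {weights.n_in}")
    if kinds is None:
        kinds = np.full(n, "lif")
    decay, in_gain, rec_gain, tlif = neuron_coefficients(params, kinds, dparams)
    beta = np.zeros(n)
    if adaptive is not None:
        beta[np.asarray(adaptive, dtype=bool)] = params.beta_adapt

    x_filt = None
    if tlif.any():
        x_filt = input_response_filter(x, dparams, dt=params.dt)

    # Pre-project input drives: (B, T, N).  TLIF rows read the filtered trace.
    drive = np.einsum("nj,bjt->btn", weights.w_in, x)
    if tlif.any():
        drive_f = np.einsum("nj,bjt->btn", weights.w_in, x_filt)
        drive[:, :, tlif] = drive_f[:, :, tlif]
    if dw_in is not None:
        extra = np.einsum("bnj,bjt->btn", dw_in, x[:, :, dw_from:])
        if tlif.any():
            extra_f = np.einsum("bnj,bjt->btn", dw_in, x_filt[:, :, dw_from:])
            extra[:, :, tlif] = extra_f[:, :, tlif]
        drive[:, dw_from:] += extra
    if tlif.any() and dparams is not None:
        drive[:, :, tlif] += np.asarray(dparams.bias) if np.ndim(dparams.bias) == 0 \
            else np.asarray(dparams.bias)[tlif]
    drive *= in_gain  # per-neuron coupling

    st = state if state is not None else NeuronState.zeros(B, n, params.v_th)
    v, a, z = st.v.copy(), st.a.copy(), st.z.copy()
    refrac = st.refrac_count.copy()
    n_ref = params.n_refrac_steps
    d = params.d

    Z = np.zeros((B, n, T))
    V = np.zeros((B, n, T))
    Aa = np.zeros((B, n, T))
    Atr = np.zeros((B, n, T))
    Psi = np.zeros((B, n, T))
    Y = np.zeros((B, weights.n_out, T))
    y = np.tile(weights.b_out, (B, 1))

    for t in range(T):
        z_del = Z[:, :, t - d] if t - d >= 0 else np.zeros((B, n))
        rec = z_del @ weights.w_rec.T
        if dw_rec is not None and t >= dw_from:
            rec = rec + np.einsum("bni,bi->bn", dw_rec, z_del)
        a = params.mu * a + z
        A = beta * a + params.v_th
        v = decay * v + drive[:, t] + rec_gain * rec - params.v_th * z \
            if params.reset == "soft" else decay * v * (1.0 - z) + drive[:, t] \
            + rec_gain * rec
        silenced = refrac > 0
        z = np.where(silenced, 0.0, ((v - A) >= 0.0).astype(float))
        refrac = np.where(z > 0, n_ref, np.maximum(refrac - 1, 0))
        psi = PSI_PEAK * np.maximum(0.0, 1.0 - np.abs(A - v) / params.v_th)
        psi = np.where(silenced, 0.0, psi)
        y = params.nu * (y - weights.b_out) + (1.0 - params.nu) * (z @ weights.w_out.T) \
            + weights.b_out
        Z[:, :, t] = z
        V[:, :, t] = v
        Aa[:, :, t] = a
        Atr[:, :, t] = A
        Psi[:, :, t] = psi
        Y[:, :, t] = y
        if not np.isfinite(v).all():
            raise NumericalFailure(f"non-finite membrane potential at step {t}")

    return Rollout(z=Z, v=V, a=Aa, A=Atr, psi=Psi, y=Y, x=x, x_filt=x_filt,
                   decay=decay, in_gain=in_gain, rec_gain=rec_gain, beta=beta,
                   tlif_mask=tlif, params=params)
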