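"""Synthetic task generators.

Three benchmark families, all generated programmatically and reproducible
from a seed:

* **Noisy spike patterns** — class templates are inhomogeneous Poisson
  rasters with per-neuron rates drawn uniformly from 2-50 Hz; an instance is
  its template with nuisance Poisson spikes superimposed (rate
  ``sigma_noise``; a rate-perturb-and-redraw mode is available behind a
  flag), optionally followed by random spike deletion with probability
  ``p_del``.  Both corruptions are non-Gaussian in spike space.
* **Two-phase episodes** — the N-way one-shot *matching* protocol: a single
  support item is presented in phase 1, then one query per sampled class in
  phase 2, exactly one of which belongs to the support class.  A dedicated
  input channel encodes the phase (0/1).
* **Two-joint-arm motor control** — a smooth random reachable end-effector
  trajectory (built from low-frequency random joint-angle paths, which makes
  reachability automatic) to be traced in 500 ms, with a clock-like spike
  input tiling the episode in equal slots.

Salt-and-pepper corruption for image episodes flips a random 15% of pixels
by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpikePatternDataset", "NoiseSpec", "ArmTask", "JointState",
    "generate_templates", "instantiate_poisson_noise",
    "superimpose_poisson_noise", "apply_deletion_noise",
    "salt_pepper", "build_episode", "build_episode_batch",
    "load_image_directory", "build_image_episode_batch",
    "arm_forward_kinematics", "arm_jacobian", "generate_motor_task",
    "integrate_motor_commands",
]


@dataclass
class NoiseSpec:
    kind: str = "poisson"        # {"poisson", "deletion", "salt_pepper"}
    sigma_noise: float = 0.0     # strength of the Poisson corruption (Hz)
    p_del: float = 0.0           # per-spike deletion probability
    flip_frac: float = 0.15      # pixel-flip fraction
    # How "Poisson noise added to a template" is realized:
    #  - "superimpose": nuisance Poisson spikes at rate sigma_noise (Hz) are
    #    OR-ed onto the template raster, so instances of a class preserve the
    #    template's spike timing (an instance IS the template plus noise);
    #  - "rate_redraw": every instance redraws all spikes from the template's
    #    rate profile perturbed per neuron by a Gaussian offset of SD
    #    sigma_noise — instances then share only their rate signature.
    poisson_mode: str = "superimpose"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_del <= 1.0:
            raise ValueError("p_del must lie in [0, 1]")
        if not 0.0 <= self.flip_frac <= 1.0:
            raise ValueError("flip_frac must lie in [0, 1]")
        if self.sigma_noise < 0:
            raise ValueError("sigma_noise must be non-negative")
        if self.kind not in ("poisson", "deletion", "salt_pepper"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.poisson_mode not in ("superimpose", "rate_redraw"):
            raise ValueError(f"unknown poisson_mode {self.poisson_mode!r}")


@dataclass
class SpikePatternDataset:
    """Class templates plus lazily generated noisy instances.

    Instances are regenerated on demand from per-(class, instance) child
    seeds, so a full-scale dataset (1,000 classes x 25 instances) never has
    to be materialized in memory at once.
    """

    templates: np.ndarray        # (n_classes, n_neurons, T) uint8
    rates: np.ndarray            # (n_classes, n_neurons) template rates (Hz)
    n_per_class: int
    dt: float
    rate_range: tuple
    seed: int
    noise: NoiseSpec = field(default_factory=NoiseSpec)

    @property
    def n_classes(self) -> int:
        return self.templates.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.templates.shape[1]

    @property
    def duration_ms(self) -> float:
        return self.templates.shape[2] * self.dt

    @property
    def T(self) -> int:
        return self.templates.shape[2]

    def instance(self, class_id: int, k: int) -> np.ndarray:
        """The k-th noisy instance of a class, shape (n_neurons, T)."""
        if not 0 <= k < self.n_per_class:
            raise IndexError(f"instance index {k} out of range")
        child = np.random.default_rng(
            [self.seed, 1_000_003, int(class_id), int(k)])
        if self.noise.poisson_mode == "superimpose":
            inst = superimpose_poisson_noise(
                self.templates[class_id], self.noise.sigma_noise, self.dt,
                n_instances=1, rng=child)[0]
        else:
            inst = instantiate_poisson_noise(
                self.rates[class_id], self.T, self.dt,
                sigma_noise=self.noise.sigma_noise, n_instances=1, rng=child)[0]
        if self.noise.p_del > 0:
            inst = apply_deletion_noise(inst, self.noise.p_del, rng=child)
        return inst

    def instances(self, class_id: int) -> list:
        return [self.instance(class_id, k) for k in range(self.n_per_class)]


def generate_templates(n_classes: int, n_neurons: int, duration_ms: float,
                       rate_range: tuple = (2.0, 50.0), dt: float = 1.0,
                       seed: int = 0, n_per_class: int = 25,
                       noise: NoiseSpec | None = None) -> SpikePatternDataset:
    """Draw class templates as inhomogeneous Poisson rasters.

    Each template neuron gets a rate uniform in ``rate_range`` (Hz); the
    template raster is a Bernoulli draw with per-bin probability
    ``rate * dt / 1000`` (at most one spike per bin).
    """
    if n_neurons <= 0 or duration_ms <= 0:
        raise ValueError("n_neurons and duration must be positive")
    if rate_range[1] > 1000.0 / dt:
        raise ValueError("upper rate bound exceeds one spike per bin")
    rng = np.random.default_rng(seed)
    T = int(round(duration_ms / dt))
    rates = rng.uniform(rate_range[0], rate_range[1], size=(n_classes, n_neurons))
    p = rates * dt / 1000.0
    templates = (rng.random((n_classes, n_neurons, T)) < p[:, :, None]
                 ).astype(np.uint8)
    return SpikePatternDataset(templates=templates, rates=rates,
                               n_per_class=n_per_class, dt=dt,
                               rate_range=tuple(rate_range), seed=seed,
                               noise=noise or NoiseSpec())


def instantiate_poisson_noise(template_rates: np.ndarray, T: int, dt: float,
                              sigma_noise: float, n_instances: int,
                              seed: int | None = None,
                              rng: np.random.Generator | None = None) -> np.ndarray:
    """Redraw Poisson instances from a Gaussian-perturbed rate profile.

    Each instance perturbs every neuron's template rate by an independent
    Gaussian offset with SD ``sigma_noise`` (Hz), clamps at zero, and redraws
    spikes.  With ``sigma_noise = 0`` instances still differ from the
    template through Poisson variability alone.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    rates = np.asarray(template_rates, dtype=float)
    offsets = rng.normal(0.0, sigma_noise, size=(n_instances,) + rates.shape) \
        if sigma_noise > 0 else np.zeros((n_instances,) + rates.shape)
    pert = np.clip(rates[None] + offsets, 0.0, 1000.0 / dt)
    p = pert * dt / 1000.0
    return (rng.random((n_instances,) + rates.shape + (T,))
            < p[..., None]).astype(np.uint8)


def superimpose_poisson_noise(template: np.ndarray, sigma_noise: float,
                              dt: float, n_instances: int,
                              seed: int | None = None,
                              rng: np.random.Generator | None = None) -> np.ndarray:
    """OR nuisance Poisson spikes (rate ``sigma_noise`` Hz) onto a template raster.

    Instances keep every template spike; corruption only adds events.  With
    ``sigma_noise = 0`` the instances are exact template copies.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    template = np.asarray(template)
    p = sigma_noise * dt / 1000.0
    extra = rng.random((n_instances,) + template.shape) < p
    return np.maximum(template[None], extra.astype(template.dtype))


def apply_deletion_noise(raster: np.ndarray, p_del: float,
                         seed: int | None = None,
                         rng: np.random.Generator | None = None) -> np.ndarray:
    """Delete each spike independently with probability ``p_del``; zeros untouched."""
    if not 0.0 <= p_del <= 1.0:
        raise ValueError("p_del must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    raster = np.asarray(raster)
    keep = rng.random(raster.shape) >= p_del
    return (raster * keep).astype(raster.dtype)


def salt_pepper(image: np.ndarray, flip_frac: float = 0.15,
                seed: int | None = None,
                rng: np.random.Generator | None = None) -> np.ndarray:
    """Invert a random subset of pixels of expected fraction ``flip_frac``.

    Works on binary or [0, 1] grayscale images; a flipped pixel ``x`` becomes
    ``1 - x``.
    """
    if not 0.0 <= flip_frac <= 1.0:
        raise ValueError("flip_frac must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    img = np.asarray(image, dtype=float)
    mask = rng.random(img.shape) < flip_frac
    return np.where(mask, 1.0 - img, img)


# ---------------------------------------------------------------------------
# Two-phase matching episodes
# ---------------------------------------------------------------------------

@dataclass
class FewShotEpisode:
    """A batch of N-way one-shot matching episodes, assembled as input streams.

    ``x`` feeds the learner: the item channels followed by one phase-ID
    channel (0 during phase 1, 1 during phase 2).  ``teacher_extra`` holds the
    channels the teacher sees beyond the learner's spikes (phase ID and a
    target channel, zero outside phase 1).  ``labels`` marks for every query
    whether it matches the support class; exactly one does.
    """

    x: np.ndarray              # (B, n_channels + 1, T_total)
    teacher_extra: np.ndarray  # (B, 2, T_total)
    labels: np.ndarray         # (B, n_query) binary
    match_index: np.ndarray    # (B,) position of the matching query
    classes: np.ndarray        # (B, n_way) sampled class ids
    t_item: int                # steps per item
    t_switch: int              # first step of phase 2
    n_query: int

    @property
    def n_batch(self) -> int:
        return self.x.shape[0]

    @property
    def T(self) -> int:
        return self.x.shape[2]


def build_episode(dataset: SpikePatternDataset, n_way: int = 5,
                  k_shot: int = 1, noise: NoiseSpec | None = None,
                  seed: int = 0, classes: np.ndarray | None = None) -> FewShotEpisode:
    """A single matching episode (batch of one); see :func:`build_episode_batch`."""
    return build_episode_batch(dataset, n_batch=1, n_way=n_way, k_shot=k_shot,
                               noise=noise, seed=seed, classes=classes)


def build_episode_batch(dataset: SpikePatternDataset, n_batch: int,
                        n_way: int = 5, k_shot: int = 1,
                        noise: NoiseSpec | None = None, seed: int = 0,
                        classes: np.ndarray | None = None) -> FewShotEpisode:
    """Sample a batch of N-way one-shot matching episodes.

    Phase 1 presents ``k_shot`` instances of one support class; phase 2
    presents one query instance per sampled class in random order.  Exactly
    one query matches the support class, and no raster instance is reused
    between phases.
    """
    noise = noise or dataset.noise
    rng = np.random.default_rng(seed)
    if dataset.n_classes < n_way:
        raise ValueError("dataset has fewer classes than n_way")
    if dataset.n_per_class < k_shot + 1:
        raise ValueError("need at least k_shot + 1 instances per class")
    t_item = dataset.T
    n_query = n_way
    T_total = (k_shot + n_query) * t_item
    n_ch = dataset.n_neurons
    x = np.zeros((n_batch, n_ch + 1, T_total))
    teacher_extra = np.zeros((n_batch, 2, T_total))
    labels = np.zeros((n_batch, n_query))
    match_index = np.zeros(n_batch, dtype=int)
    all_classes = np.zeros((n_batch, n_way), dtype=int)
    t_switch = k_shot * t_item

    def _noisy(class_id: int, k: int) -> np.ndarray:
        if noise.poisson_mode == "superimpose":
            inst = superimpose_poisson_noise(
                dataset.templates[class_id], noise.sigma_noise, dataset.dt,
                n_instances=1, rng=rng)[0]
        else:
            inst = instantiate_poisson_noise(
                dataset.rates[class_id], t_item, dataset.dt,
                sigma_noise=noise.sigma_noise, n_instances=1, rng=rng)[0]
        if noise.p_del > 0:
            inst = apply_deletion_noise(inst, noise.p_del, rng=rng)
        return inst

    for b in range(n_batch):
        cls = classes if classes is not None else \
            rng.choice(dataset.n_classes, size=n_way, replace=False)
        support_class = cls[0]
        order = rng.permutation(n_way)
        all_classes[b] = cls
        for s in range(k_shot):
            x[b, :n_ch, s * t_item:(s + 1) * t_item] = _noisy(support_class, s)
        for q, ci in enumerate(order):
            sl = slice(t_switch + q * t_item, t_switch + (q + 1) * t_item)
            x[b, :n_ch, sl] = _noisy(cls[ci], k_shot + q)
            if cls[ci] == support_class:
                labels[b, q] = 1.0
                match_index[b] = q
    x[:, n_ch, t_switch:] = 1.0              # phase-ID channel
    teacher_extra[:, 0, t_switch:] = 1.0     # phase ID for the teacher
    # target channel stays zero for matching episodes (no explicit teaching
    # signal exists in phase 1; the support item itself defines the task)
    return FewShotEpisode(x=x, teacher_extra=teacher_extra, labels=labels,
                          match_index=match_index, classes=all_classes,
                          t_item=t_item, t_switch=t_switch, n_query=n_query)


def load_image_directory(root) -> dict:
    """Load a directory of 28x28 grayscale PNGs laid out as
    ``alphabet/character/sample.png`` into ``{"alphabet/character": [arrays]}``.

    Images are scaled to [0, 1].  This is the optional source for image
    episodes; no dataset is bundled with the package.
    """
    from pathlib import Path

    from PIL import Image

    root = Path(root)
    classes: dict = {}
    for alphabet in sorted(p for p in root.iterdir() if p.is_dir()):
        for character in sorted(p for p in alphabet.iterdir() if p.is_dir()):
            imgs = []
            for png in sorted(character.glob("*.png")):
                with Image.open(png) as im:
                    arr = np.asarray(im.convert("L"), dtype=float) / 255.0
                if arr.shape != (28, 28):
                    raise ValueError(f"{png}: expected 28x28 grayscale")
                imgs.append(arr)
            if imgs:
                classes[f"{alphabet.name}/{character.name}"] = imgs
    if not classes:
        raise ValueError(f"no alphabet/character/sample.png images under {root}")
    return classes


def build_image_episode_batch(classes: dict, encoder, n_batch: int,
                              n_way: int = 5, t_img: int = 20,
                              noise: NoiseSpec | None = None,
                              seed: int = 0) -> FewShotEpisode:
    """N-way one-shot matching episodes from encoded images.

    Each image is encoded by ``encoder`` (e.g. the convolutional encoder)
    into feature currents held constant for ``t_img`` steps; salt-and-pepper
    noise, when requested, corrupts the pixels before encoding.
    """
    noise = noise or NoiseSpec(kind="salt_pepper", flip_frac=0.0)
    rng = np.random.default_rng(seed)
    names = sorted(classes)
    if len(names) < n_way:
        raise ValueError("need at least n_way image classes")
    n_feat = encoder.n_features
    T_total = (1 + n_way) * t_img
    x = np.zeros((n_batch, n_feat + 1, T_total))
    teacher_extra = np.zeros((n_batch, 2, T_total))
    labels = np.zeros((n_batch, n_way))
    match_index = np.zeros(n_batch, dtype=int)
    cls_idx = np.zeros((n_batch, n_way), dtype=int)

    def encode(img):
        if noise.kind == "salt_pepper" and noise.flip_frac > 0:
            img = salt_pepper(img, noise.flip_frac, rng=rng)
        return encoder.forward(img)

    for b in range(n_batch):
        chosen = rng.choice(len(names), size=n_way, replace=False)
        cls_idx[b] = chosen
        support = names[chosen[0]]
        pool = classes[support]
        sup_i, match_i = rng.choice(len(pool), size=2, replace=False) \
            if len(pool) > 1 else (0, 0)
        x[b, :n_feat, :t_img] = encode(pool[sup_i])[:, None]
        order = rng.permutation(n_way)
        for q, ci in enumerate(order):
            name = names[chosen[ci]]
            sl = slice((1 + q) * t_img, (2 + q) * t_img)
            if name == support:
                img = pool[match_i]
                labels[b, q] = 1.0
                match_index[b] = q
            else:
                img = classes[name][rng.integers(len(classes[name]))]
            x[b, :n_feat, sl] = encode(img)[:, None]
    x[:, n_feat, t_img:] = 1.0
    teacher_extra[:, 0, t_img:] = 1.0
    return FewShotEpisode(x=x, teacher_extra=teacher_extra, labels=labels,
                          match_index=match_index, classes=cls_idx,
                          t_item=t_img, t_switch=t_img, n_query=n_way)


# ---------------------------------------------------------------------------
# Two-joint arm motor control
# ---------------------------------------------------------------------------

@dataclass
class JointState:
    angles: np.ndarray       # (phi1, phi2) rad
    velocities: np.ndarray   # (phi1dot, phi2dot) rad/s


@dataclass
class ArmTask:
    """A randomly generated reachable target movement plus the clock input."""

    link_lengths: tuple            # (L1, L2)
    target_trajectory: np.ndarray  # (2, T) end-effector (x, y) per step
    target_angles: np.ndarray      # (2, T) generating joint-angle path
    clock_input: np.ndarray        # (n_clock, T) binary
    duration_ms: float
    dt: float
    phi0: np.ndarray               # initial pose (rad)

    @property
    def T(self) -> int:
        return self.target_trajectory.shape[1]

    def implied_velocities(self) -> np.ndarray:
        """Discrete angular velocities (rad/s) whose Euler integral retraces the path."""
        dphi = np.diff(self.target_angles, axis=1)
        v = np.zeros_like(self.target_angles)
        v[:, :-1] = dphi / (self.dt / 1000.0)
        return v


def arm_forward_kinematics(angles: np.ndarray, link_lengths: tuple) -> np.ndarray:
    """End-effector position: x = L1 cos(p1) + L2 cos(p1+p2), y analogous.

    ``angles`` has shape ``(..., 2)``; returns ``(..., 2)``.
    """
    L1, L2 = link_lengths
    a = np.asarray(angles, dtype=float)
    p1 = a[..., 0]
    p12 = a[..., 0] + a[..., 1]
    return np.stack([L1 * np.cos(p1) + L2 * np.cos(p12),
                     L1 * np.sin(p1) + L2 * np.sin(p12)], axis=-1)


def arm_jacobian(angles: np.ndarray, link_lengths: tuple) -> np.ndarray:
    """Jacobian d(x, y)/d(phi1, phi2), shape ``(..., 2, 2)``."""
    L1, L2 = link_lengths
    a = np.asarray(angles, dtype=float)
    p1 = a[..., 0]
    p12 = a[..., 0] + a[..., 1]
    j11 = -L1 * np.sin(p1) - L2 * np.sin(p12)
    j12 = -L2 * np.sin(p12)
    j21 = L1 * np.cos(p1) + L2 * np.cos(p12)
    j22 = L2 * np.cos(p12)
    return np.stack([np.stack([j11, j12], axis=-1),
                     np.stack([j21, j22], axis=-1)], axis=-2)


def generate_motor_task(duration_ms: float = 500.0, n_clock_channels: int = 20,
                        seed: int = 0, dt: float = 1.0,
                        link_lengths: tuple = (0.5, 0.5),
                        phi0: tuple = (np.pi / 4, np.pi / 2),
                        amplitude: float = 0.8) -> ArmTask:
    """A random smooth target movement plus the clock-like input signal.

    The target is built in joint space as a sum of three low-frequency
    sinusoids per joint around the initial pose (amplitude <= ``amplitude``
    rad), which keeps every point of the Euclidean path trivially inside the
    workspace.  Clock channels tile the episode with equal, non-overlapping
    active slots.
    """
    rng = np.random.default_rng(seed)
    T = int(round(duration_ms / dt))
    t = np.arange(T) / T
    phi = np.tile(np.asarray(phi0, dtype=float)[:, None], (1, T))
    for j in range(2):
        for m in range(1, 4):
            amp = rng.uniform(0.0, amplitude / m)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            phi[j] += amp * np.sin(2.0 * np.pi * m * t + phase) \
                - amp * np.sin(phase)  # anchor the path at phi0
    target = arm_forward_kinematics(phi.T, link_lengths).T
    clock = np.zeros((n_clock_channels, T))
    edges = np.linspace(0, T, n_clock_channels + 1).astype(int)
    for c in range(n_clock_channels):
        clock[c, edges[c]:edges[c + 1]] = 1.0
    return ArmTask(link_lengths=tuple(link_lengths), target_trajectory=target,
                   target_angles=phi, clock_input=clock,
                   duration_ms=duration_ms, dt=dt,
                   phi0=np.asarray(phi0, dtype=float))


def integrate_motor_commands(initial: JointState | np.ndarray,
                             velocity_commands: np.ndarray,
                             link_lengths: tuple, dt: float = 1.0) -> np.ndarray:
    """Euler-integrate angular-velocity commands and map through the kinematics.

    ``velocity_commands`` is ``(..., 2, T)`` in rad/s; the returned trajectory
    ``(..., 2, T)`` has ``p(t) = FK(phi(t))`` with
    ``phi(t) = phi0 + (dt/1000) * sum_{s<t} commands(s)`` — so the command at
    step ``t`` first moves the arm at step ``t + 1``.
    """
    phi0 = initial.angles if isinstance(initial, JointState) else np.asarray(initial)
    cmd = np.asarray(velocity_commands, dtype=float)
    dts = dt / 1000.0
    csum = np.cumsum(cmd, axis=-1) * dts
    phi = np.empty_like(cmd)
    phi[..., 0] = 0.0
    phi[..., 1:] = csum[..., :-1]
    phi = phi + phi0[..., :, None] if phi0.ndim == 1 else phi + phi0[..., None]
    # angles axis is the second-to-last: move it last for the kinematics call
    pos = arm_forward_kinematics(np.moveaxis(phi, -2, -1), link_lengths)
    return np.moveaxis(pos, -1, -2)
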