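"""Plain-text experiment configuration.

A config file is a sequence of ``key: value`` lines (``#`` comments and blank
lines ignored).  Defaults reproduce the reference hyperparameter table:
membrane 15 ms, readout 10 ms, delay 1 ms, refractory 5 ms, target rate
20 Hz, outer learning rate 2e-3, rate regularizer 1.0, threshold 1.0,
voltage regularizer 1e-2, 20 ms per image, adaptation 200 ms, learning rate
1.915e-3, learner 180 two-compartment + 260 LIF neurons, adaptive fraction
40.5%, adaptation impact 0.4902, batch 285, teacher 239 neurons, learning
signal filter 10 ms.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

__all__ = ["ExperimentConfig", "default_config", "load_config", "dump_config",
           "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass
class ExperimentConfig:
    # task
    task: str = "patterns"          # {patterns, images, motor}
    seed: int = 0
    out_dir: str = "runs"
    # neuron dynamics (ms unless noted)
    tau_m: float = 15.0
    tau_out: float = 10.0
    tau_a: float = 200.0
    v_th: float = 1.0
    beta_adapt: float = 0.4902
    t_refrac: float = 5.0
    delay_ms: float = 1.0
    dt: float = 1.0
    # dendrite
    g_l: float = 0.1
    g_b: float = 0.2
    c_m: float = 2.0
    tau_l: float = 10.0
    tau_s: float = 2.5
    # regularizers
    f_target: float = 20.0
    lam_f: float = 1.0
    lam_v: float = 1e-2
    # correntropy
    sigma1: float = 1.0
    sigma2: float = 4.0
    lam_mix: float = 0.5
    # ensemble
    eta1: float = 0.1
    eta2: float = 10.0
    # architecture
    n_hsnn: int = 440
    n_tlif: int = 180
    n_psnn: int = 239
    q_ada: float = 0.405
    # episode structure
    t_img: float = 20.0             # ms per item
    n_way: int = 5
    k_shot: int = 1
    # dataset geometry
    n_classes: int = 1000
    n_per_class: int = 25
    n_neurons: int = 100
    duration_ms: float = 200.0
    rate_low: float = 2.0
    rate_high: float = 50.0
    sigma_noise: float = 0.0
    p_del: float = 0.0
    flip_frac: float = 0.15
    # motor
    motor_duration_ms: float = 500.0
    n_clock: int = 20
    link1: float = 0.5
    link2: float = 0.5
    # training
    n_batch: int = 285
    n_iters: int = 1000
    lr: float = 1.915e-3            # eta (Adam)
    lr_out: float = 2e-3            # eta_out (ensemble weights)
    eta_inner: float = 0.05
    tau_ls: float = 10.0

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def default_config() -> ExperimentConfig:
    return ExperimentConfig()


def load_config(path: str | Path | None) -> ExperimentConfig:
    """Parse a ``key: value`` config file; unknown keys raise ConfigError."""
    cfg = ExperimentConfig()
    if path is None:
        return cfg
    valid = {f.name: f.type for f in fields(ExperimentConfig)}
    casts = {f.name: type(getattr(cfg, f.name)) for f in fields(ExperimentConfig)}
    text = Path(path).read_text()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if ":" not in line:
            raise ConfigError(f"line {lineno}: expected 'key: value', got {raw!r}")
        key, value = (s.strip() for s in line.split(":", 1))
        if key not in valid:
            raise ConfigError(f"line {lineno}: unknown config key {key!r}")
        try:
            setattr(cfg, key, casts[key](value))
        except ValueError as exc:
            raise ConfigError(
                f"line {lineno}: bad value for {key!r}: {value!r}") from exc
    return cfg


def dump_config(cfg: ExperimentConfig, path: str | Path) -> None:
    lines = [f"{f.name}: {getattr(cfg, f.name)}" for f in fields(cfg)]
    Path(path).write_text("\n".join(lines) + "\n")
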