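"""Serialization: rasters, traces, checkpoints, and run manifests."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .neurons import SpikeRaster

__all__ = ["save_raster_npz", "load_raster_npz", "raster_to_events",
           "events_to_raster", "write_event_list", "read_event_list",
           "traces_to_csv", "save_checkpoint", "load_checkpoint",
           "write_manifest", "write_log_csv"]


def save_raster_npz(path, raster: SpikeRaster, neuron_ids=None) -> None:
    """Compressed array container with named arrays events/dt/neuron_ids."""
    ids = np.arange(raster.n_neurons) if neuron_ids is None else np.asarray(neuron_ids)
    np.savez_compressed(path, events=raster.events.astype(np.uint8),
                        dt=np.array(raster.dt), neuron_ids=ids)


def load_raster_npz(path) -> SpikeRaster:
    with np.load(path) as data:
        return SpikeRaster(events=data["events"], dt=float(data["dt"]))


def raster_to_events(raster: SpikeRaster, batch: int = 0) -> np.ndarray:
    """Two-column (neuron_id, time_ms) event list of one batch element."""
    n, t = np.nonzero(raster.events[batch])
    return np.column_stack([n, t * raster.dt])


def events_to_raster(events: np.ndarray, n_neurons: int, T: int,
                     dt: float = 1.0) -> SpikeRaster:
    out = np.zeros((1, n_neurons, T), dtype=np.uint8)
    for nid, t_ms in np.atleast_2d(events):
        out[0, int(nid), int(round(t_ms / dt))] = 1
    return SpikeRaster(events=out, dt=dt)


def write_event_list(path, raster: SpikeRaster, batch: int = 0) -> None:
    ev = raster_to_events(raster, batch)
    np.savetxt(path, ev, fmt=["%d", "%.3f"], header="neuron_id time_ms")


def read_event_list(path, n_neurons: int, T: int, dt: float = 1.0) -> SpikeRaster:
    ev = np.loadtxt(path, ndmin=2)
    if ev.size == 0:
        ev = np.zeros((0, 2))
    return events_to_raster(ev, n_neurons, T, dt)


def traces_to_csv(path, trace: np.ndarray, value_name: str = "value",
                  batch: int = 0) -> None:
    """Long-format CSV (step, neuron, value) of one batch element of a trace."""
    arr = trace[batch]
    n, T = arr.shape
    df = pd.DataFrame({
        "step": np.repeat(np.arange(T), n),
        "neuron": np.tile(np.arange(n), T),
        value_name: arr.T.reshape(-1),
    })
    df.to_csv(path, index=False)


def save_checkpoint(path, weights_dict: dict, lam: np.ndarray,
                    iteration: int, seed: int, opt=None, rng=None) -> None:
    """All weight matrices, ensemble weights, optimizer moments, the episode
    generator's state, iteration, and seed — everything a resumed run needs
    to continue the unbroken trajectory."""
    payload = {f"w_{k}": v for k, v in weights_dict.items()}
    payload["lam"] = np.asarray(lam)
    payload["iteration"] = np.array(iteration)
    payload["seed"] = np.array(seed)
    if opt is not None:
        payload["opt_step"] = np.array(opt.step)
        for k, v in opt.m.items():
            payload[f"m_{k}"] = v
        for k, v in opt.v.items():
            payload[f"v2_{k}"] = v
    if rng is not None:
        payload["rng_state"] = np.array(json.dumps(rng.bit_generator.state))
    np.savez_compressed(path, **payload)


def load_checkpoint(path) -> dict:
    with np.load(path) as data:
        return {k: data[k].copy() for k in data.files}


def restore_optimizer(ck: dict):
    """Rebuild an Adam state from checkpoint arrays (None if absent)."""
    from .gradients import AdamState
    if "opt_step" not in ck:
        return None
    opt = AdamState(step=int(ck["opt_step"]))
    for k, v in ck.items():
        if k.startswith("m_"):
            opt.m[k[2:]] = v
        elif k.startswith("v2_"):
            opt.v[k[3:]] = v
    return opt


def restore_rng(ck: dict):
    """Rebuild the episode generator from its checkpointed state (None if absent)."""
    if "rng_state" not in ck:
        return None
    rng = np.random.default_rng(0)
    rng.bit_generator.state = json.loads(str(ck["rng_state"]))
    return rng


def save_episode_npz(path, episode) -> None:
    """Serialize a two-phase episode batch as named arrays."""
    np.savez_compressed(path, x=episode.x, teacher_extra=episode.teacher_extra,
                        labels=episode.labels, match_index=episode.match_index,
                        classes=episode.classes,
                        meta=np.array([episode.t_item, episode.t_switch,
                                       episode.n_query]))


def load_episode_npz(path):
    from .tasks import FewShotEpisode
    with np.load(path) as d:
        t_item, t_switch, n_query = (int(v) for v in d["meta"])
        return FewShotEpisode(x=d["x"].copy(),
                              teacher_extra=d["teacher_extra"].copy(),
                              labels=d["labels"].copy(),
                              match_index=d["match_index"].copy(),
                              classes=d["classes"].copy(),
                              t_item=t_item, t_switch=t_switch,
                              n_query=n_query)


def write_manifest(path, **entries) -> None:
    def _clean(v):
        if isinstance(v, (np.integer,)):
            return int(v)
        if isinstance(v, (np.floating,)):
            return float(v)
        if isinstance(v, np.ndarray):
            return v.tolist()
        return v
    Path(path).write_text(json.dumps({k: _clean(v) for k, v in entries.items()},
                                     indent=2, sort_keys=True) + "\n")


def write_log_csv(path, log: list) -> None:
    pd.DataFrame(log).to_csv(path, index=False)
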