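"""Plain-text (YAML) run configuration.

A config file carries the model parameters, the noise specification and
the simulation settings, either nested::

    I: 0.265
    alpha: 0.7
    beta: 0.75
    epsilon: 0.08
    noise:
      kind: additive
      sigma0: 0.01
    sim:
      dt: 0.01
      T: 1000.0
      seed: 1

or with flat dotted keys (``noise.kind: additive``).  Omitted fields
fall back to the reference excitable-regime values.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

from .fhn_model import ModelParams, NoiseSpec
from .sde import SimConfig

__all__ = ["RunConfig", "load_config", "default_config", "save_config"]


@dataclass(frozen=True)
class RunConfig:
    params: ModelParams
    noise: NoiseSpec
    sim: SimConfig

    def to_dict(self) -> dict:
        d = {
            "I": self.params.I,
            "alpha": self.params.alpha,
            "beta": self.params.beta,
            "epsilon": self.params.epsilon,
            "noise": asdict(self.noise),
            "sim": {
                "dt": self.sim.dt,
                "T": self.sim.T,
                "seed": self.sim.seed,
                "initial_state": list(self.sim.initial_state),
                "scheme": self.sim.scheme,
            },
        }
        return d


def default_config() -> RunConfig:
    return RunConfig(params=ModelParams(), noise=NoiseSpec(), sim=SimConfig())


def _unflatten(raw: dict) -> dict:
    out: dict = {}
    for key, value in raw.items():
        parts = str(key).split(".")
        node = out
        for p in parts[:-1]:
            node = node.setdefault(p, {})
        if isinstance(value, dict):
            node.setdefault(parts[-1], {}).update(value)
        else:
            node[parts[-1]] = value
    return out


def load_config(path) -> RunConfig:
    """Read a YAML config file into a :class:`RunConfig`."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    raw = _unflatten(raw)
    params = ModelParams(
        I=float(raw.get("I", 0.265)),
        alpha=float(raw.get("alpha", 0.7)),
        beta=float(raw.get("beta", 0.75)),
        epsilon=float(raw.get("epsilon", 0.08)),
    )
    nz = raw.get("noise", {})
    noise = NoiseSpec(kind=nz.get("kind", "additive"),
                      sigma0=float(nz.get("sigma0", 0.01)))
    sm = raw.get("sim", {})
    seed = sm.get("seed")
    init = sm.get("initial_state", (-1.00125, -0.4))
    sim = SimConfig(
        dt=float(sm.get("dt", 0.01)),
        T=float(sm.get("T", 1000.0)),
        seed=None if seed is None else int(seed),
        initial_state=tuple(float(x) for x in init),
        scheme=sm.get("scheme", "euler_heun"),
    )
    return RunConfig(params=params, noise=noise, sim=sim)


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
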