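"""YAML run configuration with layered defaults and schema validation.

Every default equals the studied value where one exists: rho = 1000,
nu = 1.85e-6, R0 = 0.05, x_center = 0.5, u_max = 0.00925, normalization
(1 kg, 0.1 m, 10.811 s), per-iteration batch (160, 160, 160, 160, 3200),
case ranges A in [0.015, 0.035] and sigma in [0.10, 0.18].
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .geometry import A_RANGE, DEFAULT_COUNTS, SIGMA_RANGE
from .losses import FluidProperties, LossWeights, NormalizationConstants
from .networks import (CASE_INPUTS, COORD_INPUTS, TSC_INPUTS, NetworkSpec)

__all__ = ["RunConfig", "load_config", "default_config", "config_hash",
           "write_manifest"]


@dataclass
class RunConfig:
    # geometry
    R0: float = 0.05
    x_center: float = 0.5
    length: float = 1.0
    # fluid
    rho: float = 1000.0
    nu: float = 1.85e-6
    # normalization
    V_kg: float = 1.0
    V_m: float = 0.1
    V_s: float = 10.811
    u_max: float = 0.00925
    # case grid
    A_range: tuple = A_RANGE
    sigma_range: tuple = SIGMA_RANGE
    n_A: int = 4
    n_sigma: int = 4
    n_A_val: int = 9
    n_sigma_val: int = 5
    # architecture
    arch: str = "mixed"
    main_widths: tuple = (64, 64, 64)
    hyper_widths: tuple = ()
    head_features: int | None = None
    n_modes: int | None = None
    use_tsc: bool = True
    multi_case_inputs: bool = True        # append (A, sigma) for mixed kind
    input_bias: bool = True
    # training
    iterations: int = 1000
    counts: tuple = DEFAULT_COUNTS
    pool_factor: int = 1000
    iterations_per_epoch: int = 1000
    learning_rate: float = 1e-3
    lr_min: float = 1e-5
    betas: tuple = (0.9, 0.999)
    log_every: int = 100
    w_physics: float = 1.0
    w_bc: float = 1.0
    w_derivative: float = 1.0
    gpinn: bool = False
    # evaluation
    eval_points: int = 10_000
    wss_convention: str = "as_printed"
    # run
    seed: int = 0
    output_dir: str = "runs"

    # -- derived objects ----------------------------------------------------

    def fluid(self) -> FluidProperties:
        return FluidProperties(rho=self.rho, nu=self.nu)

    def norms(self) -> NormalizationConstants:
        return NormalizationConstants(V_kg=self.V_kg, V_m=self.V_m,
                                      V_s=self.V_s)

    def loss_weights(self) -> LossWeights:
        return LossWeights(w_physics=self.w_physics, w_bc=self.w_bc,
                           w_derivative=self.w_derivative)

    def input_names(self) -> tuple:
        names = COORD_INPUTS
        if self.use_tsc:
            names = names + TSC_INPUTS
        if self.arch == "mixed" and self.multi_case_inputs:
            names = names + CASE_INPUTS
        return names

    def network_spec(self) -> NetworkSpec:
        return NetworkSpec(kind=self.arch,
                           main_widths=tuple(self.main_widths),
                           hyper_widths=tuple(self.hyper_widths),
                           head_features=self.head_features,
                           n_modes=self.n_modes,
                           input_names=self.input_names(),
                           input_bias=self.input_bias)

    def training_config(self):
        from .model import TrainingConfig

        return TrainingConfig(iterations=self.iterations,
                              counts=tuple(self.counts),
                              pool_factor=self.pool_factor,
                              iterations_per_epoch=self.iterations_per_epoch,
                              learning_rate=self.learning_rate,
                              lr_min=self.lr_min, betas=tuple(self.betas),
                              seed=self.seed, log_every=self.log_every,
                              gpinn=self.gpinn)


def default_config() -> RunConfig:
    return RunConfig()


def load_config(path) -> RunConfig:
    """Load YAML over the defaults; unknown keys are a schema error."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")
    valid = set(RunConfig.__dataclass_fields__)
    unknown = sorted(set(raw) - valid)
    if unknown:
        raise ValueError(f"unknown config keys: {unknown}")
    cfg = RunConfig(**raw)
    cfg.network_spec()  # validates architecture fields
    return cfg


def config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_manifest(cfg: RunConfig, path, extra: dict | None = None) -> None:
    """Reproducibility manifest: config hash, seed, version, timestamp."""
    from . import __version__

    manifest = {"config": asdict(cfg), "config_hash": config_hash(cfg),
                "seed": cfg.seed, "package_version": __version__,
                "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S")}
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
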