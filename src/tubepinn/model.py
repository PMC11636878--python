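"""Multi-case PINN model and fit results.

:class:`StenosisPINN` bundles the problem definition — geometry family,
fluid, normalization, architecture and training cases — the way a
statsmodels model bundles data and design.  :meth:`StenosisPINN.fit` runs
Adam on the physics-constrained loss and returns
:class:`PINNFitResults`, which carries the trained network, the
convergence trace, diagnostics and prediction/evaluation helpers.

Each iteration draws the configured number of points per region (inlet,
outlet, the two walls, interior), splits them across the training cases,
and takes one Adam step on the total normalized loss.  Interior points
come from a pre-generated per-case pool ``pool_factor`` times the batch
quota, refreshed every epoch; boundary points are drawn fresh.  A second
training phase can activate the gradient-enhanced (gPINN) derivative
loss after initial convergence.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, replace

import numpy as np

from .autodiff import Tensor
from .geometry import (DEFAULT_COUNTS, CaseParameters, ChannelGeometry,
                       CollocationSet, build_case_grid, radius_profile)
from .losses import (U_MAX_DEFAULT, FluidProperties, LossBreakdown,
                     LossWeights, NormalizationConstants, loss_graph)
from .networks import (NetworkSpec, TrainedModel, build_model,
                       load_checkpoint, save_checkpoint)

__all__ = ["TrainingConfig", "ConvergenceTrace", "StenosisPINN",
           "PINNFitResults", "train", "train_gpinn_phase",
           "checkpoint_roundtrip"]


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization schedule; defaults follow the studied batch layout."""

    iterations: int = 1000
    counts: tuple = DEFAULT_COUNTS          # inlet, outlet, walls, interior
    pool_factor: int = 1000
    iterations_per_epoch: int = 1000
    learning_rate: float = 1e-3
    lr_min: float = 1e-5
    betas: tuple = (0.9, 0.999)
    eps: float = 1e-8
    seed: int = 0
    log_every: int = 100
    gpinn: bool = False
    divergence_factor: float = 1e6
    divergence_patience: int = 100

    def __post_init__(self):
        if sum(self.counts) <= 0:
            raise ValueError("region counts must sum to a positive batch")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")

    @property
    def points_per_iteration(self) -> int:
        return int(sum(self.counts))

    @property
    def points_per_epoch(self) -> int:
        return self.points_per_iteration * self.iterations_per_epoch


@dataclass
class ConvergenceTrace:
    """Sequence of (step, loss breakdown, elapsed seconds, phase)."""

    records: list = field(default_factory=list)

    def append(self, step: int, breakdown: LossBreakdown, elapsed: float,
               phase: str = "plain") -> None:
        if self.records and step <= self.records[-1]["step"]:
            raise ValueError("trace steps must be strictly increasing")
        if not np.isfinite(breakdown.total):
            raise ValueError("non-finite loss cannot be traced")
        rec = {"step": step, "elapsed_s": elapsed, "phase": phase}
        rec.update(breakdown.to_dict())
        self.records.append(rec)

    def __len__(self):
        return len(self.records)

    @property
    def steps(self):
        return [r["step"] for r in self.records]

    @property
    def totals(self):
        return [r["total"] for r in self.records]

    def to_frame(self):
        import pandas as pd

        flat = []
        for r in self.records:
            row = {k: v for k, v in r.items() if k != "derivative_terms"}
            for dk, dv in r.get("derivative_terms", {}).items():
                row[f"derivative_{dk}"] = dv
            flat.append(row)
        return pd.DataFrame(flat)

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for r in self.records:
                fh.write(json.dumps(r) + "\n")

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


class _Adam:
    def __init__(self, params: list[Tensor], lr: float, betas, eps: float):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def state(self) -> dict:
        return {"t": self.t, "m": self.m, "v": self.v}

    def load_state(self, state: dict) -> None:
        self.t = int(state["t"])
        self.m = [np.array(a) for a in state["m"]]
        self.v = [np.array(a) for a in state["v"]]


class _CasePool:
    """Per-case interior point pool and boundary samplers."""

    def __init__(self, geom: ChannelGeometry, n_interior: int,
                 pool_factor: int, rng: np.random.Generator):
        self.geom = geom
        self.n_interior = n_interior
        self.pool_size = max(pool_factor * max(n_interior, 1), 1)
        # inverse-CDF table for arc-length-uniform wall sampling
        xs = np.linspace(0.0, geom.length, 2001)
        ds = np.sqrt(1.0 + geom.radius_slope(xs) ** 2)
        s = np.concatenate([[0.0],
                            np.cumsum((ds[1:] + ds[:-1]) / 2 * np.diff(xs))])
        self._arc_s, self._arc_x = s, xs
        self.refresh(rng)

    def refresh(self, rng: np.random.Generator) -> None:
        x = rng.uniform(0.0, self.geom.length, self.pool_size)
        r = radius_profile(x, self.geom)
        y = rng.uniform(-1.0, 1.0, self.pool_size) * r * (1 - 1e-12)
        self.pool = np.stack([x, y], axis=1)

    def interior(self, n: int, rng) -> np.ndarray:
        idx = rng.integers(0, self.pool_size, size=n)
        return self.pool[idx]

    def wall_x(self, n: int, rng) -> np.ndarray:
        u = rng.uniform(0.0, self._arc_s[-1], size=n)
        return np.interp(u, self._arc_s, self._arc_x)


class StenosisPINN:
    """Physics-informed surrogate for the stenotic-channel flow family.

    Parameters
    ----------
    spec
        Network architecture (see :class:`~tubepinn.networks.NetworkSpec`).
    cases
        Training cases; defaults to the 16-case grid.  A single
        :class:`CaseParameters` may be given for single-case training.
    """

    def __init__(self, spec: NetworkSpec,
                 cases: list[CaseParameters] | CaseParameters | None = None,
                 R0: float = 0.05, x_center: float = 0.5, length: float = 1.0,
                 fluid: FluidProperties = FluidProperties(),
                 norms: NormalizationConstants = NormalizationConstants(),
                 loss_weights: LossWeights = LossWeights(),
                 u_max: float = U_MAX_DEFAULT):
        self.spec = spec
        if cases is None:
            cases = build_case_grid().training_cases
        if isinstance(cases, CaseParameters):
            cases = [cases]
        self.cases = list(cases)
        self.R0, self.x_center, self.length = R0, x_center, length
        self.fluid, self.norms = fluid, norms
        self.loss_weights = loss_weights
        self.u_max = u_max

    def geometry(self, case: CaseParameters) -> ChannelGeometry:
        return ChannelGeometry(case=case, R0=self.R0, x_center=self.x_center,
                               length=self.length)

    # -- batching ----------------------------------------------------------

    def _quotas(self, counts) -> list[tuple]:
        """Split each region count across cases, remainder round-robin."""
        n_cases = len(self.cases)
        quotas = []
        for k, c in enumerate(counts):
            base, rem = divmod(int(c), n_cases)
            quotas.append([base + (1 if i < rem else 0)
                           for i in range(n_cases)])
        return [tuple(q[i] for q in quotas) for i in range(n_cases)]

    def _batch(self, pools: list[_CasePool], quotas, rng) -> CollocationSet:
        xs, ys, regs, cidx = [], [], [], []
        for i, (pool, quota) in enumerate(zip(pools, quotas)):
            n_in, n_out, n_wt, n_wb, n_int = quota
            geom = pool.geom
            R_in = float(radius_profile(0.0, geom))
            R_out = float(radius_profile(geom.length, geom))
            blocks = [
                (np.zeros(n_in), rng.uniform(-R_in, R_in, n_in), "inlet"),
                (np.full(n_out, geom.length),
                 rng.uniform(-R_out, R_out, n_out), "outlet"),
            ]
            xw = pool.wall_x(n_wt, rng)
            blocks.append((xw, radius_profile(xw, geom), "wall_top"))
            xw = pool.wall_x(n_wb, rng)
            blocks.append((xw, -radius_profile(xw, geom), "wall_bottom"))
            pts = pool.interior(n_int, rng)
            blocks.append((pts[:, 0], pts[:, 1], "interior"))
            for x, y, reg in blocks:
                xs.append(x); ys.append(y)
                regs += [reg] * x.size
                cidx += [i] * x.size
        x = np.concatenate(xs); y = np.concatenate(ys)
        return CollocationSet(points=np.stack([x, y], axis=1),
                              region=np.array(regs, dtype=object),
                              tsc=np.zeros((x.size, 8)),
                              case_index=np.array(cidx, dtype=int),
                              cases=self.cases)

    # -- fitting -----------------------------------------------------------

    def fit(self, config: TrainingConfig | None = None,
            start: TrainedModel | None = None,
            optimizer_state: dict | None = None,
            start_step: int = 0,
            trace: ConvergenceTrace | None = None,
            callback=None, **kwargs) -> "PINNFitResults":
        """Run Adam on the physics-constrained loss.

        ``kwargs`` override fields of ``config`` (e.g. ``iterations=5000``).
        ``start``/``optimizer_state``/``start_step`` resume a previous run.
        """
        config = config or TrainingConfig()
        if kwargs:
            config = replace(config, **kwargs)
        model = start if start is not None else build_model(
            self.spec, seed=config.seed)
        rng = np.random.default_rng(config.seed + 1)
        pools = None
        quotas = self._quotas(config.counts)
        params = list(model.params.values())
        opt = _Adam(params, config.learning_rate, config.betas, config.eps)
        if optimizer_state is not None:
            opt.load_state(optimizer_state)
        trace = trace if trace is not None else ConvergenceTrace()
        phase = "gpinn" if config.gpinn else "plain"
        weights = self.loss_weights
        if not config.gpinn:
            weights = replace(weights, w_derivative=0.0)
        # a zero-weight derivative term contributes nothing; skipping its
        # graph keeps the run bit-identical to plain training
        gpinn_active = config.gpinn and weights.w_derivative > 0.0
        t0 = time.perf_counter()
        initial_total = None
        diverged_streak = 0
        n_int_per_case = max(q[4] for q in quotas)
        bd = LossBreakdown()
        for it in range(config.iterations):
            step = start_step + it
            if pools is None or it % config.iterations_per_epoch == 0:
                if pools is None:
                    pools = [_CasePool(self.geometry(c), n_int_per_case,
                                       config.pool_factor, rng)
                             for c in self.cases]
                else:
                    for p in pools:
                        p.refresh(rng)
            batch = self._batch(pools, quotas, rng)
            opt.zero_grad()
            total, bd = loss_graph(
                model, batch, cases=self.cases, fluid=self.fluid,
                norms=self.norms, weights=weights, u_max=self.u_max,
                geom_factory=self.geometry, gpinn=gpinn_active)
            total.backward()
            lr = config.lr_min + 0.5 * (config.learning_rate - config.lr_min) \
                * (1.0 + np.cos(np.pi * it / max(config.iterations, 1)))
            opt.step(lr=lr)
            if initial_total is None:
                initial_total = bd.total
            if bd.total > config.divergence_factor * max(initial_total, 1e-300):
                diverged_streak += 1
                if diverged_streak >= config.divergence_patience:
                    raise RuntimeError(
                        f"training diverged: loss {bd.total:.3e} exceeded "
                        f"{config.divergence_factor:.0e} x initial for "
                        f"{diverged_streak} consecutive steps")
            else:
                diverged_streak = 0
            if (it % config.log_every == 0) or it == config.iterations - 1:
                trace.append(step + 1, bd, time.perf_counter() - t0,
                             phase=phase)
            if callback is not None:
                callback(step, model, bd)
        model.metadata.update({"iterations": start_step + config.iterations,
                               "seed": config.seed, "phase": phase})
        return PINNFitResults(problem=self, model=model, trace=trace,
                              config=config, final_loss=bd,
                              optimizer_state=opt.state(),
                              next_step=start_step + config.iterations)

    def fit_gpinn_phase(self, results: "PINNFitResults",
                        **kwargs) -> "PINNFitResults":
        """Resume a converged fit with the derivative (gPINN) loss active."""
        config = replace(results.config, gpinn=True)
        if kwargs:
            config = replace(config, **kwargs)
        return self.fit(config=config, start=results.model,
                        optimizer_state=results.optimizer_state,
                        start_step=results.next_step, trace=results.trace)


@dataclass
class PINNFitResults:
    """Trained multi-case PINN with its convergence history."""

    problem: StenosisPINN
    model: TrainedModel
    trace: ConvergenceTrace
    config: TrainingConfig
    final_loss: LossBreakdown
    optimizer_state: dict | None = None
    next_step: int = 0

    # -- prediction and evaluation ----------------------------------------

    def predict(self, x, y, case: CaseParameters | None = None):
        """(u, v, p) arrays at physical points for one case."""
        from .networks import predict_fields

        case = case or self.problem.cases[0]
        return predict_fields(self.model, x, y, case,
                              self.problem.geometry(case))

    def wall_wss(self, x_wall, case: CaseParameters | None = None,
                 side: str = "top", convention: str = "as_printed"):
        from .evaluation import model_wall_wss

        case = case or self.problem.cases[0]
        return model_wall_wss(self.model, x_wall, case,
                              self.problem.geometry(case),
                              fluid=self.problem.fluid, side=side,
                              convention=convention)

    def evaluate_cases(self, cases, reference_source, n_points: int = 10_000,
                       seed: int = 0):
        from .evaluation import case_grid_errors

        return case_grid_errors(self.model, cases, reference_source,
                                geom_factory=self.problem.geometry,
                                n_points=n_points, seed=seed,
                                fluid=self.problem.fluid)

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        bd = self.final_loss
        spec = self.model.spec
        lines = [
            "StenosisPINN fit results",
            "=" * 58,
            f"architecture        {spec.kind}  "
            f"(main {list(spec.main_widths)}"
            + (f", hyper {list(spec.hyper_widths)}" if spec.hyper_widths
               else "") + ")",
            f"trainable params    {self.model.n_parameters():,}",
            f"training cases      {len(self.problem.cases)}",
            f"iterations          {self.next_step}",
            f"points/iteration    {self.config.points_per_iteration}",
            "-" * 58,
            f"continuity loss     {bd.continuity:.4e}",
            f"momentum loss       {bd.momentum:.4e}",
            f"wall no-slip        {_fmt(bd.wall_noslip)}",
            f"outlet pressure     {_fmt(bd.outlet_pressure)}",
            f"inlet u profile     {_fmt(bd.inlet_u)}",
            f"inlet v             {_fmt(bd.inlet_v)}",
        ]
        for k, v in bd.derivative_terms.items():
            lines.append(f"derivative {k:<9}{v:.4e}")
        lines += ["-" * 58, f"total loss          {bd.total:.4e}"]
        return "\n".join(lines)

    def plot_convergence(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.trace.to_frame()
        for phase, grp in df.groupby("phase"):
            ax.semilogy(grp["step"], grp["total"], label=phase)
        ax.set_xlabel("iteration")
        ax.set_ylabel("total aggregated loss")
        ax.legend()
        return ax

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        """Checkpoint model, trace and optimizer state to HDF5."""
        import h5py

        save_checkpoint(self.model, path)
        with h5py.File(path, "a") as f:
            f.attrs["trace"] = json.dumps(self.trace.records)
            f.attrs["next_step"] = self.next_step
            if self.optimizer_state is not None:
                g = f.create_group("adam")
                g.attrs["t"] = self.optimizer_state["t"]
                for i, (m, v) in enumerate(zip(self.optimizer_state["m"],
                                               self.optimizer_state["v"])):
                    g.create_dataset(f"m{i}", data=m)
                    g.create_dataset(f"v{i}", data=v)

    @classmethod
    def load(cls, path, problem: StenosisPINN) -> "PINNFitResults":
        import h5py

        model = load_checkpoint(path)
        with h5py.File(path, "r") as f:
            records = json.loads(f.attrs["trace"])
            next_step = int(f.attrs["next_step"])
            opt_state = None
            if "adam" in f:
                g = f["adam"]
                n = len([k for k in g if k.startswith("m")])
                opt_state = {"t": int(g.attrs["t"]),
                             "m": [g[f"m{i}"][:] for i in range(n)],
                             "v": [g[f"v{i}"][:] for i in range(n)]}
        trace = ConvergenceTrace(records=records)
        bd = LossBreakdown()
        if records:
            last = records[-1]
            bd = LossBreakdown(
                continuity=last["continuity"], momentum=last["momentum"],
                wall_noslip=last["wall_noslip"],
                outlet_pressure=last["outlet_pressure"],
                inlet_u=last["inlet_u"], inlet_v=last["inlet_v"],
                derivative_terms=last.get("derivative_terms", {}),
                total=last["total"])
        return cls(problem=problem, model=model, trace=trace,
                   config=TrainingConfig(), final_loss=bd,
                   optimizer_state=opt_state, next_step=next_step)


def _fmt(v):
    return "absent" if v is None else f"{v:.4e}"


# ---------------------------------------------------------------------------
# functional wrappers mirroring the procedural interface
# ---------------------------------------------------------------------------

def train(problem: StenosisPINN, config: TrainingConfig) -> PINNFitResults:
    return problem.fit(config=config)


def train_gpinn_phase(problem: StenosisPINN, results: PINNFitResults,
                      **kwargs) -> PINNFitResults:
    return problem.fit_gpinn_phase(results, **kwargs)


def checkpoint_roundtrip(results: PINNFitResults, path) -> PINNFitResults:
    results.save(path)
    return PINNFitResults.load(path, results.problem)
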