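"""Desk-scale verification benchmarks.

The headline recovery benchmark trains a small mixed network on the
degenerate straight channel (A = 0), where the exact Poiseuille solution
is known, and tracks the relative L2 error of the streamwise velocity on
a 50 x 50 evaluation grid.  Run with and without the tube-specific
coordinate inputs it also measures how many iterations each variant needs
to reach a target accuracy, probing the TSC convergence advantage at a
size a single CPU handles in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluation import analytic_straight_channel, relative_l2
from .geometry import CaseParameters
from .model import StenosisPINN, TrainingConfig
from .networks import COORD_INPUTS, TSC_INPUTS, NetworkSpec

__all__ = ["RecoveryResult", "poiseuille_recovery"]


@dataclass
class RecoveryResult:
    use_tsc: bool
    eps_u_history: list = field(default_factory=list)   # (iterations, pct)
    iterations_to_target: int | None = None
    final_eps_u: float = float("nan")
    final_eps_p: float = float("nan")

    @property
    def reached(self) -> bool:
        return self.iterations_to_target is not None


def poiseuille_recovery(use_tsc: bool = True, seed: int = 0,
                        max_iterations: int = 8000, chunk: int = 500,
                        target_pct: float = 5.0,
                        widths: tuple = (64, 64, 64),
                        counts: tuple = (64, 64, 64, 64, 256),
                        grid_n: int = 50) -> RecoveryResult:
    """Train on the A = 0 case until eps_u drops below ``target_pct``.

    Training proceeds in chunks of ``chunk`` Adam iterations (cosine decay
    restarting per chunk); the error is evaluated between chunks against
    the analytic Poiseuille field.
    """
    case = CaseParameters(A=0.0, sigma=0.134)
    names = COORD_INPUTS + (TSC_INPUTS if use_tsc else ())
    spec = NetworkSpec(kind="mixed", main_widths=widths, input_names=names)
    problem = StenosisPINN(spec, cases=case)
    ana = analytic_straight_channel(u_max=problem.u_max, R0=problem.R0,
                                    length=problem.length,
                                    fluid=problem.fluid)
    gx, gy = np.meshgrid(np.linspace(0.0, problem.length, grid_n),
                         np.linspace(-problem.R0, problem.R0, grid_n))
    gx, gy = gx.ravel(), gy.ravel()
    u_ref, _, p_ref = ana.evaluate(gx, gy)

    cfg = TrainingConfig(iterations=chunk, counts=counts,
                         pool_factor=max(50, chunk // 10),
                         iterations_per_epoch=chunk, seed=seed,
                         log_every=chunk)
    out = RecoveryResult(use_tsc=use_tsc)
    res = None
    done = 0
    while done < max_iterations:
        res = problem.fit(cfg,
                          start=res.model if res else None,
                          optimizer_state=res.optimizer_state if res else None,
                          start_step=res.next_step if res else 0,
                          trace=res.trace if res else None)
        done = res.next_step
        u_pred, _, p_pred = res.predict(gx, gy, case)
        eps_u = relative_l2(u_pred, u_ref)
        out.eps_u_history.append((done, eps_u))
        out.final_eps_u = eps_u
        out.final_eps_p = relative_l2(p_pred, p_ref)
        if eps_u < target_pct:
            out.iterations_to_target = done
            break
    return out
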