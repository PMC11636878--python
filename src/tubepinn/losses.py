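"""Unit-normalized Navier-Stokes residuals, boundary losses and gPINN terms.

Steady incompressible flow without body forces:

    continuity:  du/dx + dv/dy = 0
    momentum:    (u . grad) u + (1/rho) grad p - nu laplacian(u) = 0

Each loss term is made dimensionless by the unit-normalization constants
``V_kg = 1 kg``, ``V_m = 0.1 m`` (inlet diameter) and ``V_s = 10.811 s``
(so that ``V_m / V_s`` equals the inlet peak velocity 0.00925 m/s):
continuity residuals scale with ``V_s``; momentum residuals with
``(V_m V_s^-2)^-1``; velocity BCs with ``(V_m V_s^-1)^-1``; pressure with
``(V_kg V_m^-1 V_s^-2)^-1``.  With these normalizations all loss weights
default to 1.

The gradient-enhanced (gPINN) term penalizes the squared derivative of
every normalized residual with respect to the case parameters (A, sigma),
each normalized by its range width so the term stays dimensionless.  The
derivative includes the geometric dependence of the TSC features and the
wall/inlet point positions on the case parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .geometry import (A_RANGE, SIGMA_RANGE, CaseParameters, ChannelGeometry,
                       CollocationSet, radius_jet)
from .jets import Jet
from .networks import TrainedModel, forward_jets

__all__ = [
    "FluidProperties", "NormalizationConstants", "LossWeights",
    "LossBreakdown", "pde_residuals_from_jets", "pde_residuals",
    "physics_loss", "bc_loss", "gpinn_loss", "total_loss", "loss_graph",
]

U_MAX_DEFAULT = 0.00925


@dataclass(frozen=True)
class FluidProperties:
    """Incompressible Newtonian fluid: density [kg/m^3], kinematic viscosity [m^2/s]."""

    rho: float = 1000.0
    nu: float = 1.85e-6

    def __post_init__(self):
        if self.rho <= 0 or self.nu <= 0:
            raise ValueError("fluid properties must be positive")

    @property
    def mu_dyn(self) -> float:
        """Dynamic (shear) viscosity rho * nu [Pa s]."""
        return self.rho * self.nu


@dataclass(frozen=True)
class NormalizationConstants:
    V_kg: float = 1.0
    V_m: float = 0.1
    V_s: float = 10.811

    @property
    def u_norm(self) -> float:
        """Velocity unit V_m / V_s (the inlet peak speed to 4 s.f.)."""
        return self.V_m / self.V_s

    @property
    def mom_norm(self) -> float:
        """Acceleration unit V_m / V_s^2."""
        return self.V_m / self.V_s ** 2

    @property
    def p_norm(self) -> float:
        """Pressure unit V_kg / (V_m V_s^2)."""
        return self.V_kg / (self.V_m * self.V_s ** 2)


@dataclass(frozen=True)
class LossWeights:
    w_physics: float = 1.0
    w_bc: float = 1.0
    w_derivative: float = 1.0

    def __post_init__(self):
        if min(self.w_physics, self.w_bc, self.w_derivative) < 0:
            raise ValueError("loss weights must be nonnegative")


@dataclass
class LossBreakdown:
    """Per-term normalized losses; absent BC regions are None, not zero."""

    continuity: float = 0.0
    momentum: float = 0.0
    wall_noslip: float | None = None
    outlet_pressure: float | None = None
    inlet_u: float | None = None
    inlet_v: float | None = None
    derivative_terms: dict = field(default_factory=dict)
    total: float = 0.0

    @property
    def physics(self) -> float:
        return self.continuity + self.momentum

    @property
    def bc(self) -> float:
        return sum(t for t in (self.wall_noslip, self.outlet_pressure,
                               self.inlet_u, self.inlet_v) if t is not None)

    @property
    def derivative(self) -> float:
        return sum(self.derivative_terms.values())

    def to_dict(self) -> dict:
        return {"continuity": self.continuity, "momentum": self.momentum,
                "wall_noslip": self.wall_noslip,
                "outlet_pressure": self.outlet_pressure,
                "inlet_u": self.inlet_u, "inlet_v": self.inlet_v,
                "derivative_terms": dict(self.derivative_terms),
                "total": self.total}


# ---------------------------------------------------------------------------
# residuals
# ---------------------------------------------------------------------------

def _value(x):
    return x.data if isinstance(x, Tensor) else np.asarray(x)


def _mean(x):
    return x.mean() if isinstance(x, (Tensor, np.ndarray)) else x


def _check_finite(jets, what: str):
    for j in jets:
        v = _value(j.val)
        if not np.all(np.isfinite(v)):
            idx = np.flatnonzero(~np.isfinite(v).ravel())[:5]
            raise FloatingPointError(
                f"non-finite {what} at flat indices {idx.tolist()}")


def _forward(model, X, Y, A, S, geom):
    """Dispatch: a TrainedModel or any object exposing forward_jets."""
    if isinstance(model, TrainedModel):
        return forward_jets(model, X, Y, A, S, geom)
    return model.forward_jets(X, Y, A, S, geom)


def pde_residuals_from_jets(u: Jet, v: Jet, p: Jet,
                            fluid: FluidProperties) -> tuple[Jet, Jet, Jet]:
    """Continuity and momentum residuals as jets.

    Inputs carry spatial derivative channels (x, y, xx, yy) and optionally
    case channels; the returned jets carry values plus whatever case
    derivatives remain representable, which feeds the gPINN loss.
    """
    u_x, u_y = u.shift("x"), u.shift("y")
    v_x, v_y = v.shift("x"), v.shift("y")
    cont = u_x + v_y
    lap_u = u.shift("x").shift("x") + u.shift("y").shift("y")
    lap_v = v.shift("x").shift("x") + v.shift("y").shift("y")
    inv_rho = 1.0 / fluid.rho
    mom_x = u * u_x + v * u_y + inv_rho * p.shift("x") - fluid.nu * lap_u
    mom_y = u * v_x + v * v_y + inv_rho * p.shift("y") - fluid.nu * lap_v
    _check_finite((cont, mom_x, mom_y), "PDE residual")
    return cont, mom_x, mom_y


def pde_residuals(model: TrainedModel, x, y, case: CaseParameters,
                  geom: ChannelGeometry, fluid: FluidProperties,
                  case_derivatives: bool = False):
    """Residual jets of a model at interior points (exact derivatives)."""
    x = np.asarray(x, dtype=float).reshape(-1, 1)
    y = np.asarray(y, dtype=float).reshape(-1, 1)
    X = Jet(x, {"x": np.ones_like(x)})
    Y = Jet(y, {"y": np.ones_like(y)})
    if case_derivatives:
        A = Jet.variable(case.A, "A")
        S = Jet.variable(case.sigma, "s")
    else:
        A, S = Jet.constant(case.A), Jet.constant(case.sigma)
    u, v, p = _forward(model, X, Y, A, S, geom)
    return pde_residuals_from_jets(u, v, p, fluid)


def physics_loss(cont, mom_x, mom_y,
                 norms: NormalizationConstants = NormalizationConstants()):
    """Mean squared normalized PDE residuals (dimensionless scalar).

    Accepts jets, tensors or arrays; jets contribute their values.
    """
    c = cont.val if isinstance(cont, Jet) else cont
    mx = mom_x.val if isinstance(mom_x, Jet) else mom_x
    my = mom_y.val if isinstance(mom_y, Jet) else mom_y
    c_term = (norms.V_s ** 2) * _mean(c * c)
    m_term = (_mean(mx * mx) + _mean(my * my)) * norms.mom_norm ** -2
    return c_term + m_term


# ---------------------------------------------------------------------------
# boundary conditions
# ---------------------------------------------------------------------------

def bc_residual_jets(model: TrainedModel, colloc: CollocationSet,
                     case: CaseParameters, geom: ChannelGeometry,
                     u_max: float = U_MAX_DEFAULT,
                     norms: NormalizationConstants = NormalizationConstants(),
                     case_derivatives: bool = False) -> dict[str, list[tuple]]:
    """Normalized BC residual jets per region present in ``colloc``.

    Each region maps to a list of component groups; jets inside one group
    share the same points (e.g. the wall velocity components u and v), so
    the mean-squared term averages over points, not components.  Wall and
    inlet point positions are expressed through the geometry jets so their
    dependence on (A, sigma) is differentiated when requested.
    """
    if case_derivatives:
        A = Jet.variable(case.A, "A")
        S = Jet.variable(case.sigma, "s")
    else:
        A, S = Jet.constant(case.A), Jet.constant(case.sigma)
    out: dict[str, list[Jet]] = {}

    def fwd(x, Y):
        X = Jet.constant(x.reshape(-1, 1))
        return _forward(model, X, Y, A, S, geom)

    for side in ("wall_top", "wall_bottom"):
        idx = colloc.select(side)
        if idx.size == 0:
            continue
        x = colloc.points[idx, 0]
        sign = 1.0 if side.endswith("top") else -1.0
        Xj = Jet.constant(x.reshape(-1, 1))
        Yw = sign * radius_jet(Xj, A, S, geom)
        u, v, p = _forward(model, Xj, Yw, A, S, geom)
        inv = 1.0 / norms.u_norm
        out.setdefault("wall", []).append((u * inv, v * inv))

    idx = colloc.select("outlet")
    if idx.size:
        x = colloc.points[idx, 0]
        Y = Jet.constant(colloc.points[idx, 1].reshape(-1, 1))
        u, v, p = fwd(x, Y)
        out["outlet"] = [(p * (1.0 / norms.p_norm),)]

    idx = colloc.select("inlet")
    if idx.size:
        x = colloc.points[idx, 0]
        Y = Jet.constant(colloc.points[idx, 1].reshape(-1, 1))
        u, v, p = fwd(x, Y)
        R_in = radius_jet(Jet.constant(np.zeros((idx.size, 1))), A, S, geom)
        target = u_max * (1.0 - (Y / R_in) * (Y / R_in))
        inv = 1.0 / norms.u_norm
        out["inlet_u"] = [((u - target) * inv,)]
        out["inlet_v"] = [(v * inv,)]
    return out


def bc_loss(residuals: dict[str, list[tuple]]) -> dict[str, object]:
    """Mean-squared normalized BC terms, each over its own point count."""
    terms: dict[str, object] = {}
    for key, groups in residuals.items():
        ss, n = None, 0
        for group in groups:
            n += _value(group[0].val).size
            for j in group:
                v = j.val
                s = (v * v).sum()
                ss = s if ss is None else ss + s
        terms[key] = ss * (1.0 / n)
    return terms


# ---------------------------------------------------------------------------
# gPINN derivative loss
# ---------------------------------------------------------------------------

_LAMBDA_WIDTHS = {"A": A_RANGE[1] - A_RANGE[0],
                  "s": SIGMA_RANGE[1] - SIGMA_RANGE[0]}


def gpinn_loss(domain_residuals: tuple[Jet, Jet, Jet],
               bc_residuals: dict[str, list[Jet]],
               norms: NormalizationConstants = NormalizationConstants()
               ) -> dict[str, object]:
    """Squared case-parameter derivatives of all normalized residuals.

    Domain residuals are normalized as in the physics loss before
    differentiation; BC residuals arrive already normalized.  Each case
    parameter is normalized by its range width.  Returns one term per
    (region group, parameter) pair.
    """
    cont, mom_x, mom_y = domain_residuals
    normalized = [cont * norms.V_s, mom_x * (1.0 / norms.mom_norm),
                  mom_y * (1.0 / norms.mom_norm)]
    terms: dict[str, object] = {}
    for lam, width in _LAMBDA_WIDTHS.items():
        acc = None
        for r in normalized:
            d = r.get(lam)
            if d is None:
                continue
            _check_finite([Jet(d)], f"gPINN domain derivative d/d{lam}")
            s = ((width * d) ** 2).sum()
            acc = s if acc is None else acc + s
        if acc is not None:
            n_pts = _value(normalized[0].val).size
            terms[f"domain_{lam}"] = acc * (1.0 / max(n_pts, 1))
        bacc, bn = None, 0
        for groups in bc_residuals.values():
            for group in groups:
                seen = False
                for j in group:
                    d = j.get(lam)
                    if d is None:
                        continue
                    _check_finite([Jet(d)], f"gPINN BC derivative d/d{lam}")
                    s = ((width * d) ** 2).sum()
                    bacc = s if bacc is None else bacc + s
                    seen = True
                if seen:
                    bn += _value(group[0].val).size
        if bacc is not None:
            terms[f"bc_{lam}"] = bacc * (1.0 / bn)
    return terms


def total_loss(parts: LossBreakdown, weights: LossWeights) -> float:
    """Weighted sum of physics, BC and (optional) derivative terms."""
    return (weights.w_physics * parts.physics
            + weights.w_bc * parts.bc
            + weights.w_derivative * parts.derivative)


# ---------------------------------------------------------------------------
# full loss graph for one batch
# ---------------------------------------------------------------------------

def loss_graph(model: TrainedModel, colloc: CollocationSet,
               cases: list[CaseParameters] | None = None,
               fluid: FluidProperties = FluidProperties(),
               norms: NormalizationConstants = NormalizationConstants(),
               weights: LossWeights = LossWeights(),
               u_max: float = U_MAX_DEFAULT,
               geom_factory=None,
               gpinn: bool = False):
    """Build the total-loss tensor and its breakdown for one batch.

    Points in ``colloc`` are grouped by ``case_index``; each group is
    evaluated on its own geometry.  Returns ``(total, LossBreakdown)``
    where ``total`` is a scalar :class:`Tensor` ready for backprop.
    """
    cases = cases if cases is not None else colloc.cases
    if geom_factory is None:
        geom_factory = lambda c: ChannelGeometry(case=c)

    sums: dict[str, list] = {}

    def add(key, term_sum, n):
        if key not in sums:
            sums[key] = [term_sum, n]
        else:
            sums[key][0] = sums[key][0] + term_sum
            sums[key][1] += n

    deriv_sums: dict[str, list] = {}
    for ci in np.unique(colloc.case_index):
        case = cases[ci]
        geom = geom_factory(case)
        mask = colloc.case_index == ci
        sub = CollocationSet(points=colloc.points[mask],
                             region=colloc.region[mask],
                             tsc=colloc.tsc[mask],
                             case_index=colloc.case_index[mask],
                             cases=cases)
        interior = sub.select("interior")
        dom_res = None
        if interior.size:
            x, y = sub.points[interior, 0], sub.points[interior, 1]
            dom_res = pde_residuals(model, x, y, case, geom, fluid,
                                    case_derivatives=gpinn)
            cont, mom_x, mom_y = dom_res
            n = interior.size
            add("continuity", (norms.V_s ** 2) * (cont.val * cont.val).sum(), n)
            add("momentum",
                ((mom_x.val * mom_x.val).sum()
                 + (mom_y.val * mom_y.val).sum()) * norms.mom_norm ** -2, n)
        bc_res = bc_residual_jets(model, sub, case, geom, u_max=u_max,
                                  norms=norms, case_derivatives=gpinn)
        for key, groups in bc_res.items():
            name = {"wall": "wall_noslip", "outlet": "outlet_pressure",
                    "inlet_u": "inlet_u", "inlet_v": "inlet_v"}[key]
            for group in groups:
                ss = None
                for j in group:
                    s = (j.val * j.val).sum()
                    ss = s if ss is None else ss + s
                add(name, ss, _value(group[0].val).size)
        if gpinn:
            gterms = gpinn_loss(dom_res, bc_res, norms=norms) \
                if dom_res is not None else gpinn_loss(
                    (Jet.constant(np.zeros((0, 1))),) * 3, bc_res, norms=norms)
            for key, t in gterms.items():
                if key not in deriv_sums:
                    deriv_sums[key] = [t, 1]
                else:
                    deriv_sums[key][0] = deriv_sums[key][0] + t
                    deriv_sums[key][1] += 1

    bd = LossBreakdown()
    total = None

    def finish(key, weight):
        nonlocal total
        if key not in sums:
            return None
        term = sums[key][0] * (1.0 / sums[key][1])
        contrib = weight * term
        total = contrib if total is None else total + contrib
        return float(term.data) if isinstance(term, Tensor) \
            else float(np.asarray(term))

    c = finish("continuity", weights.w_physics)
    bd.continuity = 0.0 if c is None else c
    m = finish("momentum", weights.w_physics)
    bd.momentum = 0.0 if m is None else m
    bd.wall_noslip = finish("wall_noslip", weights.w_bc)
    bd.outlet_pressure = finish("outlet_pressure", weights.w_bc)
    bd.inlet_u = finish("inlet_u", weights.w_bc)
    bd.inlet_v = finish("inlet_v", weights.w_bc)
    for key, (t, ncase) in deriv_sums.items():
        term = t * (1.0 / ncase)
        contrib = weights.w_derivative * term
        total = contrib if total is None else total + contrib
        bd.derivative_terms[key] = float(_value(term)) if not isinstance(
            term, Tensor) else float(term.data)
    if total is None:
        total = Tensor(0.0)
    bd.total = float(_value(total)) if not isinstance(total, Tensor) \
        else float(total.data)
    return total, bd
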