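"""Reference solutions, error metrics and wall shear stress.

The verification workhorse is the straight-channel (A = 0) Poiseuille
solution, which satisfies the governing equations and all boundary
conditions exactly:

    u(y) = u_max (1 - y^2 / R0^2),   v = 0,
    p(x) = 2 rho nu u_max (L - x) / R0^2      (zero at the outlet).

Accuracy against any reference field is quantified by the relative L2
error in percent, ``100 * ||pred - ref||_2 / ||ref||_2``.

Wall shear stress follows the printed formula
``WSS = mu | (grad v + grad v^T)/2 . n |``; note this is half the
conventional Newtonian wall traction ``2 mu E . n`` for simple shear, so a
``convention`` flag offers ``{"as_printed", "conventional_2x"}``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .geometry import (CaseParameters, ChannelGeometry, radius_profile,
                       wall_normals)
from .jets import Jet
from .losses import U_MAX_DEFAULT, FluidProperties
from .networks import TrainedModel, predict_fields

__all__ = [
    "FlowFieldSample", "ErrorReport", "relative_l2", "wall_shear_stress",
    "AnalyticStraightChannel", "analytic_straight_channel",
    "PointCloudReference", "import_reference", "export_field",
    "model_wall_wss", "case_grid_errors",
]


@dataclass
class FlowFieldSample:
    """Point-cloud flow field: coordinates [m], velocities [m/s], pressure [Pa]."""

    points: np.ndarray          # (N, 2)
    u: np.ndarray
    v: np.ndarray
    p: np.ndarray
    provenance: str = "model"   # model | analytic | imported

    def __post_init__(self):
        n = self.points.shape[0]
        for name in ("u", "v", "p"):
            arr = np.asarray(getattr(self, name), dtype=float).ravel()
            setattr(self, name, arr)
            if arr.shape[0] != n:
                raise ValueError(f"field {name} length != point count")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"field {name} contains non-finite values")


@dataclass
class ErrorReport:
    """Relative L2 errors (percent) of one case against a reference."""

    case: CaseParameters
    epsilon_u: float
    epsilon_v: float
    epsilon_p: float
    epsilon_wss_mag: float | None
    N: int
    interpolation: str | None = None


def relative_l2(pred, ref) -> float:
    """100 * ||pred - ref||_2 / ||ref||_2 over flattened arrays."""
    pred = np.asarray(pred, dtype=float).ravel()
    ref = np.asarray(ref, dtype=float).ravel()
    if pred.shape != ref.shape or ref.size == 0:
        raise ValueError("pred and ref must have equal nonzero length")
    denom = np.linalg.norm(ref)
    if denom == 0.0:
        raise ZeroDivisionError(
            "reference field is identically zero; relative L2 undefined")
    return 100.0 * np.linalg.norm(pred - ref) / denom


def wall_shear_stress(grad_v: np.ndarray, normals: np.ndarray,
                      mu_dyn: float, convention: str = "as_printed"
                      ) -> np.ndarray:
    """WSS magnitude [Pa] from velocity-gradient tensors at wall points.

    ``grad_v[n, i, j] = d v_i / d x_j``; ``normals`` are unit outward
    normals.  ``as_printed`` uses mu |E n| with E the rate-of-strain
    tensor; ``conventional_2x`` uses the Newtonian traction 2 mu |E n|.
    """
    grad_v = np.asarray(grad_v, dtype=float)
    normals = np.asarray(normals, dtype=float)
    norms = np.linalg.norm(normals, axis=-1)
    if not np.allclose(norms, 1.0, atol=1e-8):
        raise ValueError("wall normals must be unit vectors")
    E = 0.5 * (grad_v + np.swapaxes(grad_v, -1, -2))
    traction = np.einsum("nij,nj->ni", E, normals)
    mag = mu_dyn * np.linalg.norm(traction, axis=-1)
    if convention == "conventional_2x":
        return 2.0 * mag
    if convention != "as_printed":
        raise ValueError("convention must be 'as_printed' or 'conventional_2x'")
    return mag


# ---------------------------------------------------------------------------
# analytic reference
# ---------------------------------------------------------------------------

class AnalyticStraightChannel:
    """Exact Poiseuille solution of the A = 0 straight channel."""

    def __init__(self, u_max: float = U_MAX_DEFAULT, R0: float = 0.05,
                 length: float = 1.0,
                 fluid: FluidProperties = FluidProperties()):
        self.u_max, self.R0, self.length, self.fluid = u_max, R0, length, fluid

    def evaluate(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        u = self.u_max * (1.0 - y ** 2 / self.R0 ** 2)
        v = np.zeros_like(u)
        p = (2.0 * self.fluid.rho * self.fluid.nu * self.u_max
             * (self.length - x) / self.R0 ** 2)
        return u, v, p

    def sample(self, x, y) -> FlowFieldSample:
        u, v, p = self.evaluate(x, y)
        return FlowFieldSample(points=np.stack(
            [np.asarray(x, float).ravel(), np.asarray(y, float).ravel()],
            axis=1), u=u, v=v, p=p, provenance="analytic")

    def jets(self, x, y) -> tuple[Jet, Jet, Jet]:
        """(u, v, p) jets with exact spatial derivative channels."""
        x = np.asarray(x, dtype=float).reshape(-1, 1)
        y = np.asarray(y, dtype=float).reshape(-1, 1)
        z = np.zeros_like(y)
        k = self.u_max / self.R0 ** 2
        u = Jet(self.u_max - k * y ** 2,
                {"y": -2.0 * k * y, "yy": np.full_like(y, -2.0 * k)})
        v = Jet(z, {})
        px = 2.0 * self.fluid.rho * self.fluid.nu * k
        p = Jet(px * (self.length - x), {"x": np.full_like(x, -px)})
        return u, v, p

    def forward_jets(self, X: Jet, Y: Jet, A, S, geom) -> tuple[Jet, Jet, Jet]:
        """Closed-form (u, v, p) via jet arithmetic.

        Lets the analytic solution flow through the same residual and
        boundary-loss machinery as a trained network (duck-typed model).
        """
        inv_R = 1.0 / self.R0
        yn = Y * inv_R
        u = self.u_max * (1.0 - yn * yn)
        zeros = np.zeros_like(np.asarray(Y.val, dtype=float))
        v = Jet.constant(zeros)
        px = 2.0 * self.fluid.rho * self.fluid.nu * self.u_max / self.R0 ** 2
        p = px * (self.length - X)
        return u, v, p

    def wall_wss(self, x, side: str = "top",
                 convention: str = "as_printed") -> np.ndarray:
        """Closed-form WSS magnitude at the wall (uniform along x)."""
        x = np.asarray(x, dtype=float)
        base = self.fluid.mu_dyn * self.u_max / self.R0
        if convention == "conventional_2x":
            base = 2.0 * base
        return np.full_like(x, base)


def analytic_straight_channel(u_max: float = U_MAX_DEFAULT, R0: float = 0.05,
                              length: float = 1.0,
                              fluid: FluidProperties = FluidProperties()
                              ) -> AnalyticStraightChannel:
    return AnalyticStraightChannel(u_max=u_max, R0=R0, length=length,
                                   fluid=fluid)


# ---------------------------------------------------------------------------
# imported references
# ---------------------------------------------------------------------------

class PointCloudReference:
    """Reference flow field given as a scattered point cloud.

    Evaluation at requested points uses barycentric-linear interpolation
    with nearest-point fallback outside the convex hull; when the request
    exactly matches the stored points no interpolation is applied.
    """

    def __init__(self, field: FlowFieldSample):
        self.field = field
        self.method_used: str | None = None

    def evaluate(self, x, y):
        from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator

        x = np.asarray(x, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        pts = np.stack([x, y], axis=1)
        stored = self.field.points
        if pts.shape == stored.shape and np.array_equal(pts, stored):
            self.method_used = "none"
            return self.field.u, self.field.v, self.field.p
        out = []
        for comp in (self.field.u, self.field.v, self.field.p):
            lin = LinearNDInterpolator(stored, comp)
            vals = lin(pts)
            missing = np.isnan(vals)
            if np.any(missing):
                near = NearestNDInterpolator(stored, comp)
                vals[missing] = near(pts[missing])
            out.append(vals)
        self.method_used = "barycentric-linear+nearest"
        return tuple(out)


def import_reference(path, format: str | None = None) -> FlowFieldSample:
    """Load a reference field (x, y, u, v, p) from CSV or legacy-ASCII VTK."""
    path = str(path)
    if format is None:
        format = "VTK" if path.lower().endswith(".vtk") else "CSV"
    if format.upper() == "CSV":
        import pandas as pd

        df = pd.read_csv(path)
        missing = {"x", "y", "u", "v", "p"} - set(df.columns)
        if missing:
            raise ValueError(f"reference CSV missing fields {sorted(missing)}")
        return FlowFieldSample(points=df[["x", "y"]].to_numpy(),
                               u=df["u"].to_numpy(), v=df["v"].to_numpy(),
                               p=df["p"].to_numpy(), provenance="imported")
    if format.upper() == "VTK":
        return _read_legacy_vtk(path)
    raise ValueError("format must be CSV or VTK")


def _read_legacy_vtk(path) -> FlowFieldSample:
    """Minimal legacy-ASCII VTK reader: POINTS + POINT_DATA u/v/p.

    Accepts scalars named u, v, p, or a 3-component vector 'velocity'
    plus a scalar 'p'/'pressure'.  z-coordinates must be constant (2D).
    """
    with open(path) as fh:
        tokens = fh.read().split()
    def find(kw, start=0):
        for i in range(start, len(tokens)):
            if tokens[i].upper() == kw:
                return i
        return -1
    ip = find("POINTS")
    if ip < 0:
        raise ValueError("VTK file has no POINTS block")
    n = int(tokens[ip + 1])
    coords = np.array(tokens[ip + 3: ip + 3 + 3 * n],
                      dtype=float).reshape(n, 3)
    if np.ptp(coords[:, 2]) > 1e-12:
        raise ValueError("VTK point cloud is not 2D (z varies)")
    fields: dict[str, np.ndarray] = {}
    i = find("POINT_DATA")
    if i < 0:
        raise ValueError("VTK file has no POINT_DATA block")
    j = i + 2
    while j < len(tokens):
        kw = tokens[j].upper()
        if kw == "SCALARS":
            name = tokens[j + 1].lower()
            k = find("LOOKUP_TABLE", j)
            vals = np.array(tokens[k + 2: k + 2 + n], dtype=float)
            fields[name] = vals
            j = k + 2 + n
        elif kw == "VECTORS":
            name = tokens[j + 1].lower()
            vals = np.array(tokens[j + 3: j + 3 + 3 * n],
                            dtype=float).reshape(n, 3)
            fields[name] = vals
            j = j + 3 + 3 * n
        else:
            j += 1
    u = v = p = None
    if "velocity" in fields:
        u, v = fields["velocity"][:, 0], fields["velocity"][:, 1]
    if "u" in fields:
        u = np.ravel(fields["u"])
    if "v" in fields:
        v = np.ravel(fields["v"])
    for key in ("p", "pressure"):
        if key in fields:
            p = np.ravel(fields[key])
    if u is None or v is None or p is None:
        raise ValueError("VTK file lacks u/v/p (or velocity+pressure) data")
    return FlowFieldSample(points=coords[:, :2], u=u, v=v, p=p,
                           provenance="imported")


def export_field(field: FlowFieldSample, path) -> None:
    import pandas as pd

    pd.DataFrame({"x": field.points[:, 0], "y": field.points[:, 1],
                  "u": field.u, "v": field.v, "p": field.p}
                 ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# model-side quantities
# ---------------------------------------------------------------------------

def model_wall_wss(model: TrainedModel, x_wall, case: CaseParameters,
                   geom: ChannelGeometry,
                   fluid: FluidProperties = FluidProperties(),
                   side: str = "top",
                   convention: str = "as_printed") -> np.ndarray:
    """WSS magnitude of the model along one wall, via exact derivatives."""
    x_wall = np.asarray(x_wall, dtype=float)
    sign = 1.0 if side == "top" else -1.0
    y_wall = sign * radius_profile(x_wall, geom)
    u, v, _ = predict_fields(model, x_wall, y_wall, case, geom,
                             derivatives=True)

    def ch(j, c):
        d = j.get(c)
        if d is None:
            return np.zeros(x_wall.size)
        return (d.data if isinstance(d, Tensor) else np.asarray(d)).ravel()
    grad = np.empty((x_wall.size, 2, 2))
    grad[:, 0, 0], grad[:, 0, 1] = ch(u, "x"), ch(u, "y")
    grad[:, 1, 0], grad[:, 1, 1] = ch(v, "x"), ch(v, "y")
    normals = wall_normals(x_wall, geom, side=side)
    return wall_shear_stress(grad, normals, fluid.mu_dyn,
                             convention=convention)


def case_grid_errors(model: TrainedModel, cases, reference_source,
                     geom_factory=None, n_points: int = 10_000,
                     n_wall: int = 200, seed: int = 0,
                     fluid: FluidProperties = FluidProperties()):
    """Relative L2 errors per case on seeded random interior points.

    ``reference_source(case)`` returns an object with ``evaluate(x, y)``
    and optionally ``wall_wss(x, side)`` (e.g.
    :class:`AnalyticStraightChannel` or :class:`PointCloudReference`), or
    None to skip the case.  Returns ``(reports, table)`` where ``table``
    is a contour-ready dataframe (A, sigma, eps_u, eps_v, eps_p, eps_wss).
    """
    import pandas as pd

    if geom_factory is None:
        geom_factory = lambda c: ChannelGeometry(case=c)
    reports, rows = [], []
    for k, case in enumerate(cases):
        ref = reference_source(case)
        if ref is None:
            continue
        geom = geom_factory(case)
        rng = np.random.default_rng(seed + k)
        x = rng.uniform(0.0, geom.length, n_points)
        r = radius_profile(x, geom)
        y = rng.uniform(-1.0, 1.0, n_points) * r * (1 - 1e-9)
        up, vp, pp = predict_fields(model, x, y, case, geom)
        ur, vr, pr = ref.evaluate(x, y)
        eps_wss = None
        if hasattr(ref, "wall_wss"):
            xw = np.linspace(0.0, geom.length, n_wall)
            wss_pred = model_wall_wss(model, xw, case, geom, fluid=fluid)
            wss_ref = ref.wall_wss(xw, side="top")
            eps_wss = relative_l2(wss_pred, wss_ref)
        rep = ErrorReport(case=case, epsilon_u=relative_l2(up, ur),
                          epsilon_v=relative_l2(vp, vr)
                          if np.linalg.norm(vr) > 0 else float(
                              100.0 * np.linalg.norm(vp)
                              / np.linalg.norm(ur)),
                          epsilon_p=relative_l2(pp, pr),
                          epsilon_wss_mag=eps_wss, N=n_points,
                          interpolation=getattr(ref, "method_used", None))
        reports.append(rep)
        rows.append({"A": case.A, "sigma": case.sigma,
                     "eps_u": rep.epsilon_u, "eps_v": rep.epsilon_v,
                     "eps_p": rep.epsilon_p, "eps_wss": rep.epsilon_wss_mag})
    return reports, pd.DataFrame(rows)
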