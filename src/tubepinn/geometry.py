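"""Parameterized stenotic channel family, collocation sampling and TSCs.

The geometry is a straight 2D channel of length ``L`` (default 1 m) whose
half-width narrows in the middle following a Gaussian dip,

    R(x) = R0 - A * exp(-(x - x_c)^2 / (2 sigma^2)),

with reference half-width ``R0 = 0.05`` m and dip center ``x_c = 0.5`` m.
The case parameters ``lambda = (A, sigma)`` give the narrowing amplitude
(severity) and axial length scale.  ``y = 0`` is the centerline; walls sit
at ``y = +-R(x)``.

Eight tube-specific coordinates (TSCs) are derived from ``(x, y)``:
centerline distance ``c`` in (-1, 1), locally normalized width
``L_n = y / R(x)``, the wall-distance surrogate ``d_sq = 1 - L_n^2``,
and the products ``c^2, L_n^2, c*d_sq, c*L_n, L_n*d_sq``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .jets import Jet, jet_exp

__all__ = [
    "CaseParameters", "ChannelGeometry", "TSCVector", "CollocationSet",
    "CaseGrid", "radius_profile", "compute_tsc", "sample_collocation",
    "build_case_grid", "inlet_profile", "wall_normals", "tsc_jets",
    "radius_jet", "TSC_NAMES", "REGIONS", "A_RANGE", "SIGMA_RANGE",
    "DEFAULT_COUNTS",
]

TSC_NAMES = ("c", "L_n", "d_sq", "c_sq", "L_n_sq", "c_dsq", "c_Ln", "Ln_dsq")
REGIONS = ("inlet", "outlet", "wall_top", "wall_bottom", "interior")
A_RANGE = (0.015, 0.035)
SIGMA_RANGE = (0.10, 0.18)
# batch points per training iteration: inlet, outlet, wall_top, wall_bottom, interior
DEFAULT_COUNTS = (160, 160, 160, 160, 3200)

_WALL_TOL = 1e-12


@dataclass(frozen=True)
class CaseParameters:
    """One geometry case: narrowing amplitude ``A`` [m] and length ``sigma`` [m]."""

    A: float
    sigma: float

    def __post_init__(self):
        if self.A < 0:
            raise ValueError("narrowing amplitude A must be >= 0")
        if self.sigma <= 0:
            raise ValueError("narrowing length scale sigma must be > 0")
        in_range = (self.A == 0.0 or A_RANGE[0] <= self.A <= A_RANGE[1]) and \
            SIGMA_RANGE[0] <= self.sigma <= SIGMA_RANGE[1]
        if not in_range and self.A != 0.0:
            warnings.warn(
                f"case (A={self.A}, sigma={self.sigma}) lies outside the "
                f"studied ranges A in {A_RANGE}, sigma in {SIGMA_RANGE}",
                stacklevel=2)


@dataclass(frozen=True)
class ChannelGeometry:
    """Channel of length ``length`` with a Gaussian narrowing of ``case``."""

    case: CaseParameters
    R0: float = 0.05
    x_center: float = 0.5
    length: float = 1.0

    def __post_init__(self):
        r_min = self.R0 - self.case.A
        if r_min <= 0:
            raise ValueError("narrowing closes the channel: R(x_center) <= 0")

    def radius(self, x):
        return radius_profile(x, self)

    def radius_slope(self, x):
        """dR/dx, used for analytic wall normals."""
        x = np.asarray(x, dtype=float)
        A, s, xc = self.case.A, self.case.sigma, self.x_center
        return A * (x - xc) / s ** 2 * np.exp(-(x - xc) ** 2 / (2 * s ** 2))


def radius_profile(x, geom: ChannelGeometry):
    """Half-width R(x) = R0 - A exp(-(x - x_c)^2 / (2 sigma^2)); vectorized."""
    x = np.asarray(x, dtype=float)
    A, s, xc = geom.case.A, geom.case.sigma, geom.x_center
    return geom.R0 - A * np.exp(-(x - xc) ** 2 / (2 * s ** 2))


def radius_jet(X: Jet, A: Jet, S: Jet, geom: ChannelGeometry) -> Jet:
    """R(x; A, sigma) as a jet, carrying all tracked derivatives."""
    dx = X - geom.x_center
    return geom.R0 - A * jet_exp(-(dx * dx) / (2.0 * (S * S)))


@dataclass(frozen=True)
class TSCVector:
    """The eight tube-specific coordinates evaluated at a set of points."""

    c: np.ndarray
    L_n: np.ndarray
    d_sq: np.ndarray
    c_sq: np.ndarray
    L_n_sq: np.ndarray
    c_dsq: np.ndarray
    c_Ln: np.ndarray
    Ln_dsq: np.ndarray

    def as_array(self) -> np.ndarray:
        """(N, 8) array in :data:`TSC_NAMES` order."""
        return np.stack([getattr(self, n) for n in TSC_NAMES], axis=-1)


def compute_tsc(x, y, geom: ChannelGeometry) -> TSCVector:
    """Tube-specific coordinates of points inside or on the channel.

    Raises ``ValueError`` for points beyond the walls (relative tolerance
    1e-9 on the local half-width).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    R = radius_profile(x, geom)
    if np.any(np.abs(y) > R * (1.0 + 1e-9)):
        bad = np.argmax(np.abs(y) - R)
        raise ValueError(
            f"point outside channel: |y|={np.abs(y).flat[bad]:.6g} > "
            f"R={R.flat[bad]:.6g}")
    c = 2.0 * x / geom.length - 1.0
    L_n = y / R
    d_sq = 1.0 - L_n ** 2
    return TSCVector(c=c, L_n=L_n, d_sq=d_sq, c_sq=c ** 2, L_n_sq=L_n ** 2,
                     c_dsq=c * d_sq, c_Ln=c * L_n, Ln_dsq=L_n * d_sq)


def tsc_jets(X: Jet, Y: Jet, A: Jet, S: Jet, geom: ChannelGeometry) -> list[Jet]:
    """The eight TSC features as jets (same order as :data:`TSC_NAMES`).

    Built from jet arithmetic so every tracked derivative — including the
    dependence of the features on the case parameters through R(x) — is
    exact.
    """
    R = radius_jet(X, A, S, geom)
    c = (2.0 / geom.length) * X - 1.0
    L_n = Y / R
    d_sq = 1.0 - L_n * L_n
    return [c, L_n, d_sq, c * c, L_n * L_n, c * d_sq, c * L_n, L_n * d_sq]


@dataclass
class CollocationSet:
    """Sampled points with region tags, TSC values and case assignment."""

    points: np.ndarray                 # (N, 2) x, y in metres
    region: np.ndarray                 # (N,) strings from REGIONS
    tsc: np.ndarray                    # (N, 8) in TSC_NAMES order
    case_index: np.ndarray             # (N,) int index into `cases`
    cases: list[CaseParameters] = field(default_factory=list)

    def __len__(self):
        return self.points.shape[0]

    def select(self, region: str) -> np.ndarray:
        return np.flatnonzero(self.region == region)

    # -- external interfaces ----------------------------------------------

    def to_frame(self):
        import pandas as pd

        A = np.array([self.cases[i].A for i in self.case_index])
        s = np.array([self.cases[i].sigma for i in self.case_index])
        cols = {"x": self.points[:, 0], "y": self.points[:, 1],
                "region": self.region, "case_A": A, "case_sigma": s}
        for j, name in enumerate(TSC_NAMES):
            cols[name] = self.tsc[:, j]
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CollocationSet":
        import pandas as pd

        df = pd.read_csv(path)
        pairs = list(dict.fromkeys(zip(df["case_A"], df["case_sigma"])))
        cases = [CaseParameters(A=a, sigma=s) for a, s in pairs]
        index = {p: i for i, p in enumerate(pairs)}
        case_index = np.array([index[(a, s)] for a, s in
                               zip(df["case_A"], df["case_sigma"])])
        return cls(points=df[["x", "y"]].to_numpy(),
                   region=df["region"].to_numpy(dtype=object),
                   tsc=df[list(TSC_NAMES)].to_numpy(),
                   case_index=case_index, cases=cases)

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["schema"] = "tubepinn.collocation.v1"
            f.create_dataset("points", data=self.points)
            f.create_dataset("region", data=np.char.encode(
                self.region.astype(str)))
            f.create_dataset("tsc", data=self.tsc)
            f.create_dataset("case_index", data=self.case_index)
            f.create_dataset("case_A", data=[c.A for c in self.cases])
            f.create_dataset("case_sigma", data=[c.sigma for c in self.cases])

    @classmethod
    def from_hdf5(cls, path) -> "CollocationSet":
        import h5py

        with h5py.File(path, "r") as f:
            if f.attrs.get("schema") != "tubepinn.collocation.v1":
                raise ValueError("not a tubepinn collocation file")
            cases = [CaseParameters(A=float(a), sigma=float(s))
                     for a, s in zip(f["case_A"][:], f["case_sigma"][:])]
            return cls(points=f["points"][:],
                       region=np.char.decode(f["region"][:]).astype(object),
                       tsc=f["tsc"][:], case_index=f["case_index"][:],
                       cases=cases)


def _arc_length_sample(geom: ChannelGeometry, n: int, rng) -> np.ndarray:
    """x-positions uniform in arc length along a wall curve."""
    xs = np.linspace(0.0, geom.length, 2001)
    ds = np.sqrt(1.0 + geom.radius_slope(xs) ** 2)
    s = np.concatenate([[0.0], np.cumsum((ds[1:] + ds[:-1]) / 2 * np.diff(xs))])
    u = rng.uniform(0.0, s[-1], size=n)
    return np.interp(u, s, xs)


def sample_collocation(geom: ChannelGeometry,
                       counts=DEFAULT_COUNTS,
                       rng_seed: int = 0,
                       case_index: int = 0,
                       cases: list[CaseParameters] | None = None
                       ) -> CollocationSet:
    """Uniformly sample collocation points per region, deterministically.

    ``counts`` orders as (inlet, outlet, wall_top, wall_bottom, interior).
    Interior points are uniform in x then uniform in y within the local
    half-width; boundary points are uniform along their curve; wall points
    sit exactly on y = +-R(x).
    """
    counts = tuple(int(c) for c in counts)
    if any(c < 0 for c in counts):
        raise ValueError("counts must be nonnegative")
    rng = np.random.default_rng(rng_seed)
    n_in, n_out, n_wt, n_wb, n_int = counts
    R_in = float(radius_profile(0.0, geom))
    R_out = float(radius_profile(geom.length, geom))
    xs, ys, regs = [], [], []

    x = np.zeros(n_in)
    y = rng.uniform(-R_in, R_in, size=n_in)
    xs.append(x); ys.append(y); regs += ["inlet"] * n_in

    x = np.full(n_out, geom.length)
    y = rng.uniform(-R_out, R_out, size=n_out)
    xs.append(x); ys.append(y); regs += ["outlet"] * n_out

    x = _arc_length_sample(geom, n_wt, rng)
    xs.append(x); ys.append(radius_profile(x, geom)); regs += ["wall_top"] * n_wt

    x = _arc_length_sample(geom, n_wb, rng)
    xs.append(x); ys.append(-radius_profile(x, geom)); regs += ["wall_bottom"] * n_wb

    x = rng.uniform(0.0, geom.length, size=n_int)
    r = radius_profile(x, geom)
    y = rng.uniform(-1.0, 1.0, size=n_int) * r
    # keep interior strictly inside the walls
    y = np.clip(y, -r * (1 - 1e-12), r * (1 - 1e-12))
    xs.append(x); ys.append(y); regs += ["interior"] * n_int

    x = np.concatenate(xs); y = np.concatenate(ys)
    tsc = compute_tsc(x, y, geom).as_array()
    if cases is None:
        cases = [geom.case]
    return CollocationSet(points=np.stack([x, y], axis=1),
                          region=np.array(regs, dtype=object),
                          tsc=tsc,
                          case_index=np.full(x.shape[0], case_index, dtype=int),
                          cases=cases)


def wall_normals(x, geom: ChannelGeometry, side: str = "top") -> np.ndarray:
    """Outward unit normals of the wall curve y = +-R(x).

    Computed analytically from the radius profile; n ~ (-dR/dx, +-1),
    normalized.  The slope term matters at the narrowing shoulders.
    """
    x = np.asarray(x, dtype=float)
    slope = geom.radius_slope(x)
    sign = 1.0 if side == "top" else -1.0
    n = np.stack([-sign * slope, sign * np.ones_like(x)], axis=-1)
    return n / np.linalg.norm(n, axis=-1, keepdims=True)


def inlet_profile(y, u_max: float = 0.00925, R_inlet: float = 0.05):
    """Parabolic inlet axial velocity u(y) = u_max (1 - y^2 / R^2)."""
    y = np.asarray(y, dtype=float)
    return u_max * (1.0 - y ** 2 / R_inlet ** 2)


@dataclass(frozen=True)
class CaseGrid:
    training_cases: list[CaseParameters]
    validation_cases: list[CaseParameters]


def build_case_grid(n_A: int = 4, n_sigma: int = 4,
                    n_A_val: int = 9, n_sigma_val: int = 5,
                    A_range=A_RANGE, sigma_range=SIGMA_RANGE) -> CaseGrid:
    """Training/validation case grids over the narrowing-parameter plane.

    Training: Cartesian product of ``n_A`` arithmetically spaced amplitudes
    and ``n_sigma`` logarithmically spaced length scales (both including
    the range endpoints).  Validation: amplitudes at arithmetic
    half-offsets and length scales at logarithmic half-offsets, strictly
    interior, hence disjoint from the training set by construction.
    """
    if n_A < 2 or n_sigma < 2:
        raise ValueError("need at least 2 values per case parameter")
    A_tr = np.linspace(A_range[0], A_range[1], n_A)
    s_tr = np.geomspace(sigma_range[0], sigma_range[1], n_sigma)
    training = [CaseParameters(A=float(a), sigma=float(s))
                for a in A_tr for s in s_tr]

    dA = (A_range[1] - A_range[0]) / n_A_val
    A_val = A_range[0] + (np.arange(n_A_val) + 0.5) * dA
    log_ratio = np.log(sigma_range[1] / sigma_range[0])
    s_val = sigma_range[0] * np.exp(
        (np.arange(n_sigma_val) + 0.5) / n_sigma_val * log_ratio)
    validation = [CaseParameters(A=float(a), sigma=float(s))
                  for a in A_val for s in s_val]
    return CaseGrid(training_cases=training, validation_cases=validation)


def wall_polyline(geom: ChannelGeometry, n: int = 400):
    """Wall curves as a dataframe (x, y_top, y_bottom) for plotting/export."""
    import pandas as pd

    x = np.linspace(0.0, geom.length, n)
    r = radius_profile(x, geom)
    return pd.DataFrame({"x": x, "y_top": r, "y_bottom": -r})
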