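"""Network architectures for multi-case PINN surrogates.

Three ways of conditioning one flow surrogate on the geometry case
``lambda = (A, sigma)``:

* **mixed** — lambda is appended to the coordinate features of a single
  fully connected SiLU network ``f_m``.
* **hypernetwork** — a side network ``f_h(lambda)`` emits *every* weight
  and bias of ``f_m``; only ``theta_h`` is trainable.
* **modes** — DeepONet-style: ``f_h(lambda)`` emits a bank of B modes
  ``M`` (B x 3) and ``f_m(x)`` emits mode weights ``q`` (B,); the output
  is the inner product ``y_i = sum_j q_j M_ji``.

All hidden layers use SiLU; the output layer is affine.  Forward passes
run on :class:`~tubepinn.jets.Jet` inputs so exact spatial and
case-parameter derivatives of the outputs come out alongside the values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import Tensor
from .geometry import TSC_NAMES, ChannelGeometry, tsc_jets
from .jets import Jet, jet_concat, jet_silu

__all__ = [
    "NetworkSpec", "TrainedModel", "ModesOutput", "count_parameters",
    "build_published_architectures", "build_model", "forward_jets",
    "predict_fields", "save_checkpoint", "load_checkpoint",
    "COORD_INPUTS", "TSC_INPUTS", "CASE_INPUTS",
]

COORD_INPUTS = ("x", "y")
TSC_INPUTS = TSC_NAMES
CASE_INPUTS = ("A", "sigma")


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture description; sufficient to build and count a network.

    ``input_bias`` controls whether the first hidden layer of the main
    trainable stack carries a bias vector (for the hypernetwork kind this
    is the first layer of ``f_h``; the generated ``f_m`` always has full
    biases).
    """

    kind: str                                  # mixed | hypernetwork | modes
    main_widths: tuple[int, ...]
    input_names: tuple[str, ...]
    hyper_widths: tuple[int, ...] = ()
    head_features: int | None = None           # penultimate width of f_h
    n_outputs: int = 3
    n_modes: int | None = None                 # modes kind only (B)
    input_bias: bool = True

    def __post_init__(self):
        if self.kind not in ("mixed", "hypernetwork", "modes"):
            raise ValueError(f"unknown network kind {self.kind!r}")
        if any(w < 1 for w in self.main_widths + self.hyper_widths):
            raise ValueError("all widths must be >= 1")
        if self.kind == "mixed" and self.hyper_widths:
            raise ValueError("mixed kind takes no hypernetwork widths")
        if self.kind == "modes" and (self.n_modes is None or self.n_modes < 1):
            raise ValueError("modes kind requires n_modes B >= 1")
        if self.kind in ("hypernetwork", "modes") and not self.hyper_widths:
            raise ValueError(f"{self.kind} kind requires hyper_widths")

    @property
    def n_inputs(self) -> int:
        return len(self.input_names)


def _fcnn_dims(n_in: int, widths, n_out: int) -> list[tuple[int, int]]:
    dims = [n_in, *widths, n_out]
    return [(dims[i], dims[i + 1]) for i in range(len(dims) - 1)]


def _fcnn_count(n_in: int, widths, n_out: int, first_bias: bool) -> int:
    total = sum(fi * fo + fo for fi, fo in _fcnn_dims(n_in, widths, n_out))
    if not first_bias and widths:
        total -= widths[0]
    return total


def _hyper_head_widths(spec: NetworkSpec) -> tuple[int, ...]:
    if spec.head_features is None:
        return spec.hyper_widths
    return (*spec.hyper_widths, spec.head_features)


def count_parameters(spec: NetworkSpec) -> int:
    """Exact number of trainable scalars of a spec.

    For the hypernetwork kind only ``theta_h`` counts (the main-network
    parameters are generated, not trained); for the modes kind both
    ``f_m`` and ``f_h`` count.
    """
    if spec.kind == "mixed":
        return _fcnn_count(spec.n_inputs, spec.main_widths, spec.n_outputs,
                           spec.input_bias)
    if spec.kind == "hypernetwork":
        p_main = _fcnn_count(spec.n_inputs, spec.main_widths, spec.n_outputs,
                             first_bias=True)
        return _fcnn_count(len(CASE_INPUTS), _hyper_head_widths(spec), p_main,
                           spec.input_bias)
    # modes
    return (_fcnn_count(spec.n_inputs, spec.main_widths, spec.n_modes,
                        spec.input_bias)
            + _fcnn_count(len(CASE_INPUTS), _hyper_head_widths(spec),
                          spec.n_outputs * spec.n_modes, first_bias=True))


def build_published_architectures(budget: str = "large") -> dict[str, NetworkSpec]:
    """The three multi-case architectures at the studied parameter budgets.

    ``large`` targets ~2.2 M trainable parameters, ``downsized`` ~0.8 M.
    The free knobs (number of modes B) are brute-force tuned so every
    architecture sits within +-0.1% of the Mixed budget.
    """
    if budget == "large":
        mixed_w, modes_w, head = (856,) * 4, (851,) * 3, 10
    elif budget == "downsized":
        mixed_w, modes_w, head = (516,) * 4, (513,) * 3, 3
    else:
        raise ValueError("budget must be 'large' or 'downsized'")
    coord_tsc = COORD_INPUTS + TSC_INPUTS
    mixed = NetworkSpec(kind="mixed", main_widths=mixed_w,
                        input_names=coord_tsc + CASE_INPUTS, input_bias=True)
    target = count_parameters(mixed)
    hyper = NetworkSpec(kind="hypernetwork", main_widths=(256,) * 4,
                        input_names=coord_tsc, hyper_widths=(32,) * 5,
                        head_features=head, input_bias=True)
    # largest B keeping the modes network within +0.1% of the mixed budget
    def modes_with(B):
        return NetworkSpec(kind="modes", main_widths=modes_w,
                           input_names=coord_tsc, hyper_widths=(32,) * 5,
                           head_features=head, n_modes=B, input_bias=True)
    per_mode = count_parameters(modes_with(2)) - count_parameters(modes_with(1))
    base = count_parameters(modes_with(1)) - per_mode
    B = int((target * 1.001 - base) // per_mode)
    while count_parameters(modes_with(B)) > target * 1.001:
        B -= 1
    return {"mixed": mixed, "hypernetwork": hyper, "modes": modes_with(B)}


# ---------------------------------------------------------------------------
# parameter construction and forward evaluation
# ---------------------------------------------------------------------------

# fixed affine feature normalization: feature_hat = (feature - offset) / scale
_DEFAULT_FEATURE_SCALES = {
    "x": (0.5, 0.5), "y": (0.0, 0.05),
    **{name: (0.0, 1.0) for name in TSC_NAMES},
    "A": (0.025, 0.010), "sigma": (0.14, 0.04),
}
# fixed output scaling: physical = network_output * scale
# u, v scale with the inlet peak speed; p with rho * u_max^2-like unit
_DEFAULT_OUTPUT_SCALES = (0.00925, 0.00925, 0.0856)


@dataclass
class ModesOutput:
    """Mode bank M (B x 3) and per-point mode weights q (N x B)."""

    M: np.ndarray
    q: np.ndarray

    def combine(self) -> np.ndarray:
        return self.q @ self.M


@dataclass
class TrainedModel:
    """A network spec plus its (possibly trained) parameter tensors."""

    spec: NetworkSpec
    params: dict[str, Tensor]
    feature_scales: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_FEATURE_SCALES))
    output_scales: tuple[float, float, float] = _DEFAULT_OUTPUT_SCALES
    metadata: dict = field(default_factory=dict)

    def parameter_vector(self) -> np.ndarray:
        return np.concatenate([p.data.ravel() for p in self.params.values()])

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.params.values())


def _init_fcnn(prefix: str, n_in: int, widths, n_out: int, first_bias: bool,
               rng: np.random.Generator, params: dict[str, Tensor],
               final_w_std: float | None = None,
               final_b: np.ndarray | None = None) -> None:
    """Variance-scaling init (std 1/sqrt(fan_in)), zero biases."""
    for i, (fi, fo) in enumerate(_fcnn_dims(n_in, widths, n_out)):
        last = i == len(widths)
        std = final_w_std if (last and final_w_std is not None) \
            else 1.0 / np.sqrt(fi)
        params[f"{prefix}/W{i}"] = Tensor(
            rng.normal(0.0, std, size=(fi, fo)), requires_grad=True)
        if i == 0 and not first_bias:
            continue
        b = np.zeros(fo) if not (last and final_b is not None) else final_b
        params[f"{prefix}/b{i}"] = Tensor(b.copy(), requires_grad=True)


def _fcnn_init_vector(n_in: int, widths, n_out: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Flattened standard initialization of an FCNN (weights then bias per layer)."""
    chunks = []
    for fi, fo in _fcnn_dims(n_in, widths, n_out):
        chunks.append(rng.normal(0.0, 1.0 / np.sqrt(fi), size=fi * fo))
        chunks.append(np.zeros(fo))
    return np.concatenate(chunks)


def build_model(spec: NetworkSpec, seed: int = 0,
                feature_scales: dict | None = None,
                output_scales: tuple[float, float, float] | None = None
                ) -> TrainedModel:
    """Initialize a trainable model for ``spec``, deterministically seeded.

    The hypernetwork's final layer starts with near-zero weights and a bias
    equal to a standard initialization of the generated main network, so
    training begins from a sensible ``f_m`` with weak case dependence.
    """
    rng = np.random.default_rng(seed)
    params: dict[str, Tensor] = {}
    if spec.kind == "mixed":
        _init_fcnn("fm", spec.n_inputs, spec.main_widths, spec.n_outputs,
                   spec.input_bias, rng, params)
    elif spec.kind == "hypernetwork":
        theta0 = _fcnn_init_vector(spec.n_inputs, spec.main_widths,
                                   spec.n_outputs, rng)
        _init_fcnn("fh", len(CASE_INPUTS), _hyper_head_widths(spec),
                   theta0.size, spec.input_bias, rng, params,
                   final_w_std=1e-3, final_b=theta0)
    else:  # modes
        _init_fcnn("fm", spec.n_inputs, spec.main_widths, spec.n_modes,
                   spec.input_bias, rng, params)
        # the case branch always carries full biases (input_bias governs f_m)
        _init_fcnn("fh", len(CASE_INPUTS), _hyper_head_widths(spec),
                   spec.n_outputs * spec.n_modes, True, rng, params,
                   final_w_std=1e-2)
    fs = dict(_DEFAULT_FEATURE_SCALES)
    if feature_scales:
        fs.update(feature_scales)
    return TrainedModel(spec=spec, params=params, feature_scales=fs,
                        output_scales=output_scales or _DEFAULT_OUTPUT_SCALES,
                        metadata={"seed": seed})


def _jet_col(j: Jet, i: int) -> Jet:
    sl = (slice(None), slice(i, i + 1))
    return Jet(j.val[sl], {ch: v[sl] for ch, v in j.d.items()})


def _jet_reshape(j: Jet, shape) -> Jet:
    def rs(v):
        return v.reshape(*shape) if isinstance(v, Tensor) else v.reshape(shape)
    return Jet(rs(j.val), {ch: rs(v) for ch, v in j.d.items()})


def _fcnn_forward(layers: list[tuple[Jet, Jet | None]], X: Jet) -> Jet:
    """Apply affine layers with SiLU between them; final layer affine only."""
    h = X
    for i, (W, b) in enumerate(layers):
        z = h.matmul(W)
        if b is not None:
            z = z + b
        h = jet_silu(z) if i < len(layers) - 1 else z
    return h


def _collect_layers(prefix: str, params: dict[str, Tensor],
                    n_layers: int) -> list[tuple[Jet, Jet | None]]:
    layers = []
    for i in range(n_layers):
        W = Jet(params[f"{prefix}/W{i}"])
        b_t = params.get(f"{prefix}/b{i}")
        layers.append((W, Jet(b_t) if b_t is not None else None))
    return layers


def _generated_layers(theta: Jet, n_in: int, widths, n_out: int
                      ) -> list[tuple[Jet, Jet]]:
    """Slice a flat (1, P) parameter jet into main-network layers."""
    needed = sum(fi * fo + fo for fi, fo in _fcnn_dims(n_in, widths, n_out))
    emitted = (theta.val.data if isinstance(theta.val, Tensor)
               else np.asarray(theta.val)).size
    if emitted != needed:
        raise ValueError(
            f"hypernetwork emits {emitted} values but the main network "
            f"needs {needed} parameters")
    layers = []
    off = 0
    for fi, fo in _fcnn_dims(n_in, widths, n_out):
        W = _jet_reshape(_slice_flat(theta, off, fi * fo), (fi, fo))
        off += fi * fo
        b = _jet_reshape(_slice_flat(theta, off, fo), (fo,))
        off += fo
        layers.append((W, b))
    return layers


def _slice_flat(j: Jet, off: int, n: int) -> Jet:
    sl = (slice(0, 1), slice(off, off + n))
    return Jet(j.val[sl], {ch: v[sl] for ch, v in j.d.items()})


def forward_jets(model: TrainedModel, X: Jet, Y: Jet,
                 A: Jet | float, S: Jet | float,
                 geom: ChannelGeometry) -> tuple[Jet, Jet, Jet]:
    """Evaluate (u, v, p) as jets at points (X, Y) for case (A, S).

    The feature vector is assembled from ``spec.input_names``; TSC features
    are derived from the geometry with full jet arithmetic, so spatial and
    case derivatives flow through them exactly.
    """
    spec = model.spec
    A = A if isinstance(A, Jet) else Jet.constant(float(A))
    S = S if isinstance(S, Jet) else Jet.constant(float(S))
    tsc = None
    if any(n in TSC_NAMES for n in spec.input_names):
        tsc = dict(zip(TSC_NAMES, tsc_jets(X, Y, A, S, geom)))
    feats = []
    for name in spec.input_names:
        if name == "x":
            f = X
        elif name == "y":
            f = Y
        elif name in TSC_NAMES:
            f = tsc[name]
        elif name == "A":
            f = A
        elif name == "sigma":
            f = S
        else:
            raise ValueError(f"unknown input feature {name!r}")
        off, scale = model.feature_scales.get(name, (0.0, 1.0))
        f = (f - off) * (1.0 / scale)
        feats.append(_as_column(f, X))
    Xf = jet_concat(feats, axis=1)

    if spec.kind == "mixed":
        layers = _collect_layers("fm", model.params, len(spec.main_widths) + 1)
        out = _fcnn_forward(layers, Xf)
    elif spec.kind == "hypernetwork":
        theta = _hyper_theta(model, A, S)
        layers = _generated_layers(theta, spec.n_inputs, spec.main_widths,
                                   spec.n_outputs)
        out = _fcnn_forward(layers, Xf)
    else:  # modes
        fm_layers = _collect_layers("fm", model.params,
                                    len(spec.main_widths) + 1)
        q = _fcnn_forward(fm_layers, Xf)                      # (N, B)
        M = _modes_bank(model, A, S)                          # (B, 3)
        out = q.matmul(M)

    out = out * np.asarray(model.output_scales)
    return _jet_col(out, 0), _jet_col(out, 1), _jet_col(out, 2)


def _case_features(model: TrainedModel, A: Jet, S: Jet) -> Jet:
    offA, scA = model.feature_scales.get("A", (0.0, 1.0))
    offS, scS = model.feature_scales.get("sigma", (0.0, 1.0))
    Ah = (A - offA) * (1.0 / scA)
    Sh = (S - offS) * (1.0 / scS)
    return jet_concat([_as_row(Ah), _as_row(Sh)], axis=1)


def _hyper_theta(model: TrainedModel, A: Jet, S: Jet) -> Jet:
    lam = _case_features(model, A, S)
    n_h = len(_hyper_head_widths(model.spec)) + 1
    fh_layers = _collect_layers("fh", model.params, n_h)
    return _fcnn_forward(fh_layers, lam)                       # (1, P)


def _modes_bank(model: TrainedModel, A: Jet, S: Jet) -> Jet:
    lam = _case_features(model, A, S)
    n_h = len(_hyper_head_widths(model.spec)) + 1
    fh_layers = _collect_layers("fh", model.params, n_h)
    flat = _fcnn_forward(fh_layers, lam)                       # (1, 3B)
    return _jet_reshape(flat, (model.spec.n_modes, model.spec.n_outputs))


def _as_column(f: Jet, ref: Jet) -> Jet:
    """Broadcast a (possibly scalar) jet to an (N, 1) column like ref."""
    n = np.asarray(ref.val).shape[0]

    def col(v):
        if isinstance(v, Tensor):
            return v if v.data.ndim == 2 else v.reshape(-1, 1)
        v = np.asarray(v, dtype=float)
        if v.ndim == 0:
            return np.full((n, 1), float(v))
        return v.reshape(n, 1)
    return Jet(col(f.val), {ch: col(v) for ch, v in f.d.items()})


def _as_row(f: Jet) -> Jet:
    def row(v):
        if isinstance(v, Tensor):
            return v.reshape(1, 1)
        return np.asarray(v, dtype=float).reshape(1, 1)
    return Jet(row(f.val), {ch: row(v) for ch, v in f.d.items()})


def modes_output(model: TrainedModel, x, y, case, geom: ChannelGeometry
                 ) -> ModesOutput:
    """Expose the modes decomposition: bank M (B x 3) and weights q (N x B).

    ``combine()`` on the result reproduces the network output before the
    fixed output scaling.
    """
    if model.spec.kind != "modes":
        raise ValueError("modes_output requires a modes-kind model")
    x = np.asarray(x, dtype=float).reshape(-1, 1)
    y = np.asarray(y, dtype=float).reshape(-1, 1)
    A = Jet.constant(float(case.A))
    S = Jet.constant(float(case.sigma))
    tsc = dict(zip(TSC_NAMES, tsc_jets(Jet.constant(x), Jet.constant(y),
                                       A, S, geom)))
    feats = []
    for name in model.spec.input_names:
        f = {"x": Jet.constant(x), "y": Jet.constant(y), **tsc}[name]
        off, scale = model.feature_scales.get(name, (0.0, 1.0))
        feats.append(_as_column((f - off) * (1.0 / scale), Jet.constant(x)))
    Xf = jet_concat(feats, axis=1)
    fm_layers = _collect_layers("fm", model.params,
                                len(model.spec.main_widths) + 1)
    q = _fcnn_forward(fm_layers, Xf)
    M = _modes_bank(model, A, S)

    def arr(j):
        return j.val.data if isinstance(j.val, Tensor) else np.asarray(j.val)
    return ModesOutput(M=arr(M), q=arr(q))


def predict_fields(model: TrainedModel, x: np.ndarray, y: np.ndarray,
                   case, geom: ChannelGeometry,
                   derivatives: bool = False):
    """Plain-value (or value+derivative) prediction at physical points.

    Returns arrays ``(u, v, p)``; with ``derivatives=True`` returns the
    three output jets instead (spatial channels populated).
    """
    x = np.asarray(x, dtype=float).reshape(-1, 1)
    y = np.asarray(y, dtype=float).reshape(-1, 1)
    if derivatives:
        X = Jet(x, {"x": np.ones_like(x), "xx": np.zeros_like(x)})
        Y = Jet(y, {"y": np.ones_like(y), "yy": np.zeros_like(y)})
    else:
        X, Y = Jet.constant(x), Jet.constant(y)
    u, v, p = forward_jets(model, X, Y, case.A, case.sigma, geom)
    if derivatives:
        return u, v, p

    def val(j):
        d = j.val.data if isinstance(j.val, Tensor) else j.val
        return np.asarray(d).ravel()
    return val(u), val(v), val(p)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

_SCHEMA = "tubepinn.model.v1"


def save_checkpoint(model: TrainedModel, path) -> None:
    """HDF5 checkpoint: spec as JSON attribute + named parameter arrays."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["schema"] = _SCHEMA
        f.attrs["spec"] = json.dumps(asdict(model.spec))
        f.attrs["feature_scales"] = json.dumps(model.feature_scales)
        f.attrs["output_scales"] = json.dumps(list(model.output_scales))
        f.attrs["metadata"] = json.dumps(model.metadata)
        f.attrs["param_order"] = json.dumps(list(model.params.keys()))
        g = f.create_group("params")
        total = 0.0
        for name, p in model.params.items():
            g.create_dataset(name, data=p.data)
            total += float(np.sum(p.data))
        f.attrs["param_checksum"] = total


def load_checkpoint(path) -> TrainedModel:
    import h5py

    with h5py.File(path, "r") as f:
        if f.attrs.get("schema") != _SCHEMA:
            raise ValueError("not a tubepinn model checkpoint (schema mismatch)")
        sd = json.loads(f.attrs["spec"])
        sd["main_widths"] = tuple(sd["main_widths"])
        sd["hyper_widths"] = tuple(sd["hyper_widths"])
        sd["input_names"] = tuple(sd["input_names"])
        spec = NetworkSpec(**sd)
        params = {}
        total = 0.0

        def walk(grp, prefix=""):
            nonlocal total
            for key, item in grp.items():
                name = f"{prefix}{key}"
                if isinstance(item, h5py.Group):
                    walk(item, name + "/")
                else:
                    data = item[:]
                    params[name] = Tensor(data, requires_grad=True)
                    total += float(np.sum(data))
        walk(f["params"])
        order = json.loads(f.attrs["param_order"])
        if set(order) != set(params):
            raise ValueError("checkpoint integrity check failed "
                             "(parameter names do not match stored order)")
        params = {name: params[name] for name in order}
        if not np.isclose(total, float(f.attrs["param_checksum"]),
                          rtol=1e-12, atol=1e-12):
            raise ValueError("checkpoint integrity check failed "
                             "(parameter checksum mismatch)")
        fs = {k: tuple(v) for k, v in
              json.loads(f.attrs["feature_scales"]).items()}
        return TrainedModel(spec=spec, params=params, feature_scales=fs,
                            output_scales=tuple(
                                json.loads(f.attrs["output_scales"])),
                            metadata=json.loads(f.attrs["metadata"]))
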