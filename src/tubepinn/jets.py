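"""Forward-mode derivative propagation ("jets") up to mixed third order.

A :class:`Jet` carries a value together with a sparse set of partial
derivatives with respect to the spatial coordinates (``x``, ``y``) and the
geometry case parameters (``A``: narrowing amplitude, ``s``: narrowing
length scale sigma).  The tracked channels are exactly those the physics
losses consume:

* first order:            x, y, A, s
* second order (spatial): xx, yy
* mixed second order:     xA, yA, xs, ys
* mixed third order:      xxA, yyA, xxs, yys

Second spatial derivatives feed the viscous terms of the momentum residual;
the mixed channels feed the gradient-enhanced (gPINN) loss, which needs
case-parameter derivatives of residuals that themselves contain second
spatial derivatives.  Channel payloads may be plain numpy arrays (analytic
fields, geometry features) or :class:`~tubepinn.autodiff.Tensor` nodes
(network outputs), interchangeably — both support the same arithmetic.

Derivative channels that are identically zero are simply absent, so the
cost of a jet is proportional to the derivatives actually needed.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, sigmoid

__all__ = ["Jet", "jet_exp", "jet_inv", "jet_silu", "jet_concat", "SPATIAL", "CASE"]

SPATIAL = ("x", "y")
CASE = ("A", "s")

# signature of each tracked derivative channel as a tuple of base directions
_SIG = {
    "x": ("x",), "y": ("y",), "A": ("A",), "s": ("s",),
    "xx": ("x", "x"), "yy": ("y", "y"),
    "xA": ("x", "A"), "yA": ("y", "A"), "xs": ("x", "s"), "ys": ("y", "s"),
    "xxA": ("x", "x", "A"), "yyA": ("y", "y", "A"),
    "xxs": ("x", "x", "s"), "yys": ("y", "y", "s"),
}
_FIRST = [c for c, s in _SIG.items() if len(s) == 1]
_SECOND = [c for c, s in _SIG.items() if len(s) == 2]
_THIRD = [c for c, s in _SIG.items() if len(s) == 3]


def _chan(sig: tuple[str, ...]) -> str | None:
    """Canonical channel name for a direction multiset, or None if untracked."""
    key = "".join(sorted(sig, key=lambda d: (d in CASE, d)))
    return key if key in _SIG else None


class Jet:
    __slots__ = ("val", "d")

    def __init__(self, val, d: dict | None = None):
        self.val = val
        self.d = d if d is not None else {}

    # -- seeds -------------------------------------------------------------

    @staticmethod
    def variable(val, direction: str) -> "Jet":
        """Seed an independent variable: unit derivative along ``direction``."""
        one = np.ones_like(np.asarray(val, dtype=float))
        return Jet(val, {direction: one})

    @staticmethod
    def constant(val) -> "Jet":
        return Jet(val, {})

    def get(self, ch: str):
        return self.d.get(ch)

    # -- arithmetic --------------------------------------------------------

    def _coerce(self, other) -> "Jet":
        if isinstance(other, Jet):
            return other
        return Jet(other, {})

    def __add__(self, other):
        o = self._coerce(other)
        d = dict(self.d)
        for ch, v in o.d.items():
            d[ch] = v if ch not in d else d[ch] + v
        return Jet(self.val + o.val, d)

    __radd__ = __add__

    def __neg__(self):
        return Jet(-self.val, {ch: -v for ch, v in self.d.items()})

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def _product(self, other: "Jet", op) -> "Jet":
        """Generalized Leibniz rule; ``op(a, b)`` is ``a*b`` or ``a@b``."""
        f, g = self, other
        d: dict = {}

        def add(ch, term):
            d[ch] = term if ch not in d else d[ch] + term

        for ch in _FIRST:
            if ch in f.d:
                add(ch, op(f.d[ch], g.val))
            if ch in g.d:
                add(ch, op(f.val, g.d[ch]))
        for ch in _SECOND:
            a, b = _SIG[ch]
            if ch in f.d:
                add(ch, op(f.d[ch], g.val))
            if ch in g.d:
                add(ch, op(f.val, g.d[ch]))
            if a == b:
                if a in f.d and a in g.d:
                    add(ch, 2.0 * op(f.d[a], g.d[a]))
            else:
                if a in f.d and b in g.d:
                    add(ch, op(f.d[a], g.d[b]))
                if b in f.d and a in g.d:
                    add(ch, op(f.d[b], g.d[a]))
        for ch in _THIRD:
            a, a2, b = _SIG[ch]  # signature (a, a, b), a spatial, b case
            aa, ab = a + a, _chan((a, b))
            if ch in f.d:
                add(ch, op(f.d[ch], g.val))
            if ch in g.d:
                add(ch, op(f.val, g.d[ch]))
            if aa in f.d and b in g.d:
                add(ch, op(f.d[aa], g.d[b]))
            if b in f.d and aa in g.d:
                add(ch, op(f.d[b], g.d[aa]))
            if ab in f.d and a in g.d:
                add(ch, 2.0 * op(f.d[ab], g.d[a]))
            if a in f.d and ab in g.d:
                add(ch, 2.0 * op(f.d[a], g.d[ab]))
        return Jet(op(f.val, g.val), d)

    def __mul__(self, other):
        o = self._coerce(other)
        return self._product(o, lambda a, b: a * b)

    def __rmul__(self, other):
        return self._coerce(other) * self

    def matmul(self, other: "Jet") -> "Jet":
        return self._product(self._coerce(other), lambda a, b: a @ b)

    def __truediv__(self, other):
        return self * jet_inv(self._coerce(other))

    def __rtruediv__(self, other):
        return self._coerce(other) * jet_inv(self)

    def __pow__(self, n: float):
        return apply_smooth(
            self,
            self.val ** n,
            lambda v: n * v ** (n - 1.0),
            lambda v: n * (n - 1.0) * v ** (n - 2.0),
            lambda v: n * (n - 1.0) * (n - 2.0) * v ** (n - 3.0),
        )

    # -- derivative extraction --------------------------------------------

    def shift(self, direction: str) -> "Jet":
        """Jet of the partial derivative of this jet along ``direction``.

        Tracks whichever channels of the derivative remain representable;
        used to express PDE residuals as jets so their case-parameter
        derivatives come out by the same arithmetic.
        """
        if direction not in self.d:
            return Jet(np.zeros_like(np.asarray(self.val, dtype=float))
                       if not isinstance(self.val, Tensor)
                       else Tensor(np.zeros_like(self.val.data)), {})
        d: dict = {}
        for ch, sig in _SIG.items():
            src = _chan(sig + (direction,))
            if src is not None and src in self.d:
                d[ch] = self.d[src]
        return Jet(self.d[direction], d)


def apply_smooth(f: Jet, val, d1f, d2f, d3f=None) -> Jet:
    """Chain rule for a smooth scalar function applied elementwise.

    ``val`` is the function value at ``f.val``; ``d1f``, ``d2f``, ``d3f``
    map the input value to the first/second/third derivative.  The third
    derivative is only evaluated when a mixed third-order channel is live.
    """
    d: dict = {}
    d1 = d1f(f.val)
    need2 = any(ch in f.d for ch in _FIRST)
    d2 = d2f(f.val) if need2 else None
    for ch in _FIRST:
        if ch in f.d:
            d[ch] = d1 * f.d[ch]
    for ch in _SECOND:
        a, b = _SIG[ch]
        term = None
        if a in f.d and b in f.d:
            term = d2 * f.d[a] * f.d[b] if a != b else d2 * f.d[a] * f.d[a]
        if ch in f.d:
            t2 = d1 * f.d[ch]
            term = t2 if term is None else term + t2
        if term is not None:
            d[ch] = term
    need3 = any(
        (_SIG[ch][0] in f.d and _SIG[ch][2] in f.d) for ch in _THIRD)
    d3 = d3f(f.val) if (need3 and d3f is not None) else None
    for ch in _THIRD:
        a, _, b = _SIG[ch]
        aa, ab = a + a, _chan((a, b))
        term = None
        if a in f.d and b in f.d:
            if d3 is None:
                raise ValueError("third derivative required but not provided")
            term = d3 * f.d[a] * f.d[a] * f.d[b]
        if aa in f.d and b in f.d:
            t = d2 * f.d[aa] * f.d[b]
            term = t if term is None else term + t
        if a in f.d and ab in f.d:
            t = 2.0 * d2 * f.d[a] * f.d[ab]
            term = t if term is None else term + t
        if ch in f.d:
            t = d1 * f.d[ch]
            term = t if term is None else term + t
        if term is not None:
            d[ch] = term
    return Jet(val, d)


def jet_exp(f: Jet) -> Jet:
    if isinstance(f.val, Tensor):
        e = f.val.exp()
    else:
        e = np.exp(f.val)
    return apply_smooth(f, e, lambda v: e, lambda v: e, lambda v: e)


def jet_inv(f: Jet) -> Jet:
    return f ** -1.0


def jet_silu(f: Jet) -> Jet:
    """SiLU (swish) activation with derivatives up to third order.

    silu(z) = z * sigma(z); derivatives expressed through the logistic
    sigma so they differentiate cleanly in reverse mode as well.
    """
    z = f.val
    if isinstance(z, Tensor):
        t = sigmoid(z)
    else:
        t = np.where(z >= 0, 1.0 / (1.0 + np.exp(-np.abs(z))),
                     np.exp(-np.abs(z)) / (1.0 + np.exp(-np.abs(z))))
    tp = t * (1.0 - t)           # sigma'
    val = z * t
    d1 = t + z * tp
    d2 = tp * (2.0 + z * (1.0 - 2.0 * t))
    d3 = tp * ((1.0 - 2.0 * t) * (3.0 + z * (1.0 - 2.0 * t)) - 2.0 * z * tp)
    return apply_smooth(f, val, lambda v: d1, lambda v: d2, lambda v: d3)


def _zeros_like(ref):
    if isinstance(ref, Tensor):
        return Tensor(np.zeros_like(ref.data))
    return np.zeros_like(np.asarray(ref, dtype=float))


def jet_concat(jets: list[Jet], axis: int = 1) -> Jet:
    """Concatenate jets along ``axis``, zero-filling absent channels."""
    from .autodiff import concat as t_concat

    channels = set()
    for j in jets:
        channels.update(j.d.keys())
    any_tensor = any(isinstance(j.val, Tensor) for j in jets) or any(
        isinstance(v, Tensor) for j in jets for v in j.d.values())

    def cat(parts):
        if any_tensor or any(isinstance(p, Tensor) for p in parts):
            return t_concat(parts, axis=axis)
        return np.concatenate(parts, axis=axis)

    val = cat([j.val for j in jets])
    d = {}
    for ch in channels:
        parts = [j.d[ch] if ch in j.d else _zeros_like(j.val) for j in jets]
        d[ch] = cat(parts)
    return Jet(val, d)
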