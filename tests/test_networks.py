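"""Architectures: exact parameter counts, equivalences, differentiability."""

import numpy as np
import pytest

from tubepinn.autodiff import Tensor
from tubepinn.geometry import CaseParameters, ChannelGeometry
from tubepinn.jets import Jet
from tubepinn.networks import (CASE_INPUTS, COORD_INPUTS, TSC_INPUTS,
                               NetworkSpec, build_model,
                               build_published_architectures, count_parameters,
                               forward_jets, load_checkpoint,
                               save_checkpoint, _fcnn_dims)

COORD_TSC = COORD_INPUTS + TSC_INPUTS


class TestCountParameters:
    @pytest.mark.parametrize("widths,names,bias,expected", [
        ((384,) * 4, COORD_INPUTS, False, 445_443),
        ((512,) * 4, COORD_INPUTS, False, 790_531),
        ((1024,) * 4, COORD_INPUTS, False, 3_153_923),
        ((256,) * 4, COORD_TSC, False, 200_707),
        ((856,) * 4, COORD_TSC + CASE_INPUTS, True, 2_214_475),
        ((516,) * 4, COORD_TSC + CASE_INPUTS, True, 808_575),
    ])
    def test_mixed_counts_match_published_tables(self, widths, names, bias,
                                                 expected):
        spec = NetworkSpec(kind="mixed", main_widths=widths,
                           input_names=names, input_bias=bias)
        assert count_parameters(spec) == expected

    def test_count_equals_bruteforce_enumeration(self):
        """Counting formula vs actually allocating every trainable array."""
        rng = np.random.default_rng(5)
        for _ in range(50):
            kind = rng.choice(["mixed", "hypernetwork", "modes"])
            n_in = int(rng.integers(2, 13))
            widths = tuple(int(w) for w in
                           rng.integers(1, 20, size=rng.integers(1, 4)))
            spec = NetworkSpec(
                kind=kind, main_widths=widths,
                input_names=tuple(f"f{i}" for i in range(n_in))[:2]
                + tuple(TSC_INPUTS[:max(0, n_in - 2)]),
                hyper_widths=(int(rng.integers(2, 8)),) * 2
                if kind != "mixed" else (),
                head_features=int(rng.integers(2, 6))
                if kind != "mixed" else None,
                n_modes=int(rng.integers(1, 7)) if kind == "modes" else None,
                input_bias=bool(rng.integers(0, 2)))
            model = build_model(spec, seed=0)
            assert count_parameters(spec) == model.n_parameters()

    def test_budget_trio_within_band(self):
        for budget in ("large", "downsized"):
            specs = build_published_architectures(budget)
            counts = {k: count_parameters(s) for k, s in specs.items()}
            m = counts["mixed"]
            for k, c in counts.items():
                assert abs(c - m) / m <= 1e-3, (budget, k, c, m)

    def test_large_mixed_count(self):
        specs = build_published_architectures("large")
        assert count_parameters(specs["mixed"]) == 2_214_475

    def test_downsized_mixed_count(self):
        specs = build_published_architectures("downsized")
        assert count_parameters(specs["mixed"]) == 808_575

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            NetworkSpec(kind="unknown", main_widths=(4,), input_names=("x",))
        with pytest.raises(ValueError):
            NetworkSpec(kind="modes", main_widths=(4,), hyper_widths=(4,),
                        input_names=("x",), n_modes=0)
        with pytest.raises(ValueError):
            NetworkSpec(kind="hypernetwork", main_widths=(4,),
                        input_names=("x",))


@pytest.fixture
def geom_case():
    case = CaseParameters(A=0.025, sigma=0.134)
    return ChannelGeometry(case=case), case


def _points(n=50, seed=2):
    rng = np.random.default_rng(seed)
    return (rng.uniform(0.1, 0.9, (n, 1)), rng.uniform(-0.02, 0.02, (n, 1)))


def _vals(j):
    return j.val.data if isinstance(j.val, Tensor) else np.asarray(j.val)


class TestModesNetwork:
    def _modes_model(self, B=5):
        spec = NetworkSpec(kind="modes", main_widths=(8, 8), hyper_widths=(4,),
                           head_features=3, n_modes=B, input_names=COORD_TSC)
        return build_model(spec, seed=4)

    def test_zero_modes_give_zero_output(self, geom_case):
        geom, case = geom_case
        model = self._modes_model()
        # zero the final f_h layer -> emitted mode bank M is exactly zero
        last = max(int(k.split("W")[1]) for k in model.params
                   if k.startswith("fh/W"))
        model.params[f"fh/W{last}"] = Tensor(
            np.zeros_like(model.params[f"fh/W{last}"].data),
            requires_grad=True)
        model.params[f"fh/b{last}"] = Tensor(
            np.zeros_like(model.params[f"fh/b{last}"].data),
            requires_grad=True)
        x, y = _points()
        u, v, p = forward_jets(model, Jet.constant(x), Jet.constant(y),
                               case.A, case.sigma, geom)
        assert np.all(_vals(u) == 0) and np.all(_vals(v) == 0)
        assert np.all(_vals(p) == 0)

    def test_output_linear_in_mode_bank(self, geom_case):
        """Doubling the emitted modes doubles the output exactly."""
        geom, case = geom_case
        model = self._modes_model()
        x, y = _points()
        u1, v1, p1 = forward_jets(model, Jet.constant(x), Jet.constant(y),
                                  case.A, case.sigma, geom)
        last = max(int(k.split("W")[1]) for k in model.params
                   if k.startswith("fh/W"))
        for key in (f"fh/W{last}", f"fh/b{last}"):   # final layer is affine in M
            model.params[key] = Tensor(2.0 * model.params[key].data,
                                       requires_grad=True)
        u2, v2, p2 = forward_jets(model, Jet.constant(x), Jet.constant(y),
                                  case.A, case.sigma, geom)
        for a, b in ((u1, u2), (v1, v2), (p1, p2)):
            assert np.array_equal(2.0 * _vals(a), _vals(b))

    def test_single_mode_basis_selection(self, geom_case):
        """B = 1 with M = (1, 0, 0): u equals the mode weight, v = p = 0."""
        geom, case = geom_case
        spec = NetworkSpec(kind="modes", main_widths=(6,), hyper_widths=(3,),
                           head_features=2, n_modes=1, input_names=COORD_TSC)
        model = build_model(spec, seed=1)
        last = max(int(k.split("W")[1]) for k in model.params
                   if k.startswith("fh/W"))
        model.params[f"fh/W{last}"] = Tensor(
            np.zeros_like(model.params[f"fh/W{last}"].data),
            requires_grad=True)
        model.params[f"fh/b{last}"] = Tensor(np.array([1.0, 0.0, 0.0]),
                                             requires_grad=True)
        x, y = _points(20)
        u, v, p = forward_jets(model, Jet.constant(x), Jet.constant(y),
                               case.A, case.sigma, geom)
        assert np.all(_vals(v) == 0) and np.all(_vals(p) == 0)
        # u equals q1 scaled by the fixed output scaling
        assert np.all(np.abs(_vals(u)) > 0)


    def test_modes_decomposition_reproduces_forward(self, geom_case):
        """q @ M (plus output scaling) equals the forward pass exactly."""
        from tubepinn.networks import modes_output, predict_fields

        geom, case = geom_case
        model = self._modes_model()
        x = np.linspace(0.1, 0.9, 9)
        y = np.linspace(-0.02, 0.02, 9)
        mo = modes_output(model, x, y, case, geom)
        assert mo.M.shape == (5, 3) and mo.q.shape == (9, 5)
        u, v, p = predict_fields(model, x, y, case, geom)
        rec = mo.combine() * np.asarray(model.output_scales)
        assert np.allclose(rec[:, 0], u, atol=1e-15)
        assert np.allclose(rec[:, 1], v, atol=1e-15)
        assert np.allclose(rec[:, 2], p, atol=1e-15)


class TestHypernetwork:
    def test_frozen_lambda_equals_plain_fcnn(self, geom_case):
        """The composite with fixed case equals an FCNN with the emitted theta."""
        import tubepinn.networks as nw

        geom, case = geom_case
        spec = NetworkSpec(kind="hypernetwork", main_widths=(8, 8),
                           hyper_widths=(4, 4), head_features=3,
                           input_names=COORD_TSC)
        model = build_model(spec, seed=1)
        theta = nw._hyper_theta(model, Jet.constant(case.A),
                                Jet.constant(case.sigma)).val.data.ravel()
        plain_spec = NetworkSpec(kind="mixed", main_widths=(8, 8),
                                 input_names=COORD_TSC)
        plain = build_model(plain_spec, seed=0)
        off = 0
        for i, (fi, fo) in enumerate(_fcnn_dims(len(COORD_TSC), (8, 8), 3)):
            plain.params[f"fm/W{i}"] = Tensor(
                theta[off:off + fi * fo].reshape(fi, fo), requires_grad=True)
            off += fi * fo
            plain.params[f"fm/b{i}"] = Tensor(theta[off:off + fo],
                                              requires_grad=True)
            off += fo
        rng = np.random.default_rng(3)
        x = rng.uniform(0.0, 1.0, (1000, 1))
        y = rng.uniform(-0.03, 0.03, (1000, 1))
        uh, vh, ph = forward_jets(model, Jet.constant(x), Jet.constant(y),
                                  case.A, case.sigma, geom)
        up, vp, pp = forward_jets(plain, Jet.constant(x), Jet.constant(y),
                                  case.A, case.sigma, geom)
        for a, b in ((uh, up), (vh, vp), (ph, pp)):
            assert np.max(np.abs(_vals(a) - _vals(b))) < 1e-12

    def test_head_dimension_mismatch_detected(self, geom_case):
        geom, case = geom_case
        spec = NetworkSpec(kind="hypernetwork", main_widths=(8, 8),
                           hyper_widths=(4,), head_features=2,
                           input_names=COORD_TSC)
        model = build_model(spec, seed=0)
        # corrupt the final f_h layer so the emitted theta is too short
        last = max(int(k.split("W")[1]) for k in model.params
                   if k.startswith("fh/W"))
        W = model.params[f"fh/W{last}"].data
        model.params[f"fh/W{last}"] = Tensor(W[:, :-10], requires_grad=True)
        model.params[f"fh/b{last}"] = Tensor(
            model.params[f"fh/b{last}"].data[:-10], requires_grad=True)
        x, y = _points(5)
        with pytest.raises(Exception):
            forward_jets(model, Jet.constant(x), Jet.constant(y),
                         case.A, case.sigma, geom)


class TestDifferentiability:
    @pytest.mark.parametrize("kind", ["mixed", "hypernetwork", "modes"])
    def test_second_derivatives_match_finite_differences(self, kind,
                                                         geom_case):
        geom, case = geom_case
        names = COORD_TSC + (CASE_INPUTS if kind == "mixed" else ())
        spec = NetworkSpec(
            kind=kind, main_widths=(10, 10),
            hyper_widths=(4,) if kind != "mixed" else (),
            head_features=3 if kind != "mixed" else None,
            n_modes=4 if kind == "modes" else None, input_names=names)
        model = build_model(spec, seed=6)
        rng = np.random.default_rng(8)
        x = rng.uniform(0.1, 0.9, (100, 1))
        y = rng.uniform(-0.02, 0.02, (100, 1))
        X = Jet(x, {"x": np.ones_like(x)})
        Y = Jet(y, {"y": np.ones_like(y)})
        u, _, _ = forward_jets(model, X, Y, case.A, case.sigma, geom)

        def val(xv, yv):
            uu, _, _ = forward_jets(model, Jet.constant(xv), Jet.constant(yv),
                                    case.A, case.sigma, geom)
            return _vals(uu)
        # steps of 1e-4 on normalized coordinates = 1e-4 * scale physically
        hx, hy = 1e-4 * 0.5, 1e-4 * 0.05
        d2x = (val(x + hx, y) - 2 * val(x, y) + val(x - hx, y)) / hx ** 2
        d2y = (val(x, y + hy) - 2 * val(x, y) + val(x, y - hy)) / hy ** 2
        for ad, num in ((_vals(Jet(u.get("xx"))), d2x),
                        (_vals(Jet(u.get("yy"))), d2y)):
            scale = np.maximum(np.abs(num), 1e-4 * np.max(np.abs(num)))
            assert np.max(np.abs(ad - num) / scale) < 1e-4


class TestCheckpoints:
    def test_roundtrip_bit_exact(self, geom_case, tmp_path):
        geom, case = geom_case
        spec = NetworkSpec(kind="mixed", main_widths=(8, 8),
                           input_names=COORD_TSC)
        model = build_model(spec, seed=9)
        path = tmp_path / "model.h5"
        save_checkpoint(model, path)
        back = load_checkpoint(path)
        assert back.spec == model.spec
        assert list(back.params) == list(model.params)
        for k in model.params:
            assert np.array_equal(back.params[k].data, model.params[k].data)
        x, y = _points(100)
        u1, _, _ = forward_jets(model, Jet.constant(x), Jet.constant(y),
                                case.A, case.sigma, geom)
        u2, _, _ = forward_jets(back, Jet.constant(x), Jet.constant(y),
                                case.A, case.sigma, geom)
        assert np.array_equal(_vals(u1), _vals(u2))

    def test_corrupted_checkpoint_detected(self, tmp_path):
        import h5py

        spec = NetworkSpec(kind="mixed", main_widths=(8,),
                           input_names=COORD_INPUTS)
        model = build_model(spec, seed=0)
        path = tmp_path / "model.h5"
        save_checkpoint(model, path)
        with h5py.File(path, "a") as f:
            f["params/fm/W0"][0, 0] += 1.0   # silent corruption
        with pytest.raises(ValueError, match="integrity"):
            load_checkpoint(path)

    def test_wrong_schema_rejected(self, tmp_path):
        import h5py

        path = tmp_path / "other.h5"
        with h5py.File(path, "w") as f:
            f.attrs["schema"] = "something.else"
        with pytest.raises(ValueError, match="schema"):
            load_checkpoint(path)
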