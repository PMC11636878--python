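"""Normalized residual losses: oracles, closed forms, invariances."""

import numpy as np
import pytest

from tubepinn.evaluation import analytic_straight_channel
from tubepinn.geometry import (CaseParameters, ChannelGeometry,
                               sample_collocation)
from tubepinn.jets import Jet
from tubepinn.losses import (FluidProperties, LossBreakdown, LossWeights,
                             NormalizationConstants, bc_loss,
                             bc_residual_jets, gpinn_loss, loss_graph,
                             pde_residuals, pde_residuals_from_jets,
                             physics_loss, total_loss)

NORMS = NormalizationConstants()
FLUID = FluidProperties()


class TestNormalization:
    def test_velocity_unit_matches_u_max(self):
        assert NORMS.u_norm == pytest.approx(0.00925, rel=5e-4)

    def test_fluid_validation(self):
        with pytest.raises(ValueError):
            FluidProperties(rho=-1.0)
        assert FLUID.mu_dyn == pytest.approx(1.85e-3)


class TestPhysicsLoss:
    def test_zero_residuals(self):
        z = np.zeros((10, 1))
        assert physics_loss(z, z, z) == 0.0

    def test_unit_continuity_normalization_identity(self):
        c = np.array([[1.0 / NORMS.V_s]])
        z = np.zeros((1, 1))
        assert physics_loss(c, z, z) == pytest.approx(1.0, rel=1e-14)

    def test_momentum_vector_norm_sums_components(self):
        z = np.zeros((1, 1))
        m = np.array([[NORMS.mom_norm]])
        assert physics_loss(z, m, m) == pytest.approx(2.0, rel=1e-14)

    def test_poiseuille_annihilates_residuals(self):
        ana = analytic_straight_channel()
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1, 3200)
        y = rng.uniform(-0.05, 0.05, 3200)
        u, v, p = ana.jets(x, y)
        cont, mx, my = pde_residuals_from_jets(u, v, p, FLUID)
        assert physics_loss(cont, mx, my) < 1e-10

    def test_constant_field_zero_residuals(self):
        n = 20
        z = np.zeros((n, 1))
        u = Jet(z + 0.0, {})
        v = Jet(z + 0.0, {})
        p = Jet(z + 3.0, {})
        cont, mx, my = pde_residuals_from_jets(u, v, p, FLUID)
        assert np.all(cont.val == 0) and np.all(mx.val == 0)
        assert np.all(my.val == 0)


class TestResidualOracle:
    def test_residuals_match_finite_differences(self, small_mixed_model,
                                                mid_geom, mid_case,
                                                interior_points):
        """Autodiff residuals vs residuals assembled from FD derivatives."""
        x, y = interior_points
        cont, mx, my = pde_residuals(small_mixed_model, x, y, mid_case,
                                     mid_geom, FLUID)
        from tubepinn.networks import predict_fields

        h = 1e-4 * 0.05    # step on the narrow coordinate scale
        def fields(xs, ys):
            return predict_fields(small_mixed_model, xs, ys, mid_case,
                                  mid_geom)
        u0, v0, p0 = fields(x, y)
        uxp, vxp, pxp = fields(x + h, y)
        uxm, vxm, pxm = fields(x - h, y)
        uyp, vyp, pyp = fields(x, y + h)
        uym, vym, pym = fields(x, y - h)
        ux, vx, px = [(a - b) / (2 * h) for a, b in
                      ((uxp, uxm), (vxp, vxm), (pxp, pxm))]
        uy, vy, py = [(a - b) / (2 * h) for a, b in
                      ((uyp, uym), (vyp, vym), (pyp, pym))]
        uxx = (uxp - 2 * u0 + uxm) / h ** 2
        uyy = (uyp - 2 * u0 + uym) / h ** 2
        vxx = (vxp - 2 * v0 + vxm) / h ** 2
        vyy = (vyp - 2 * v0 + vym) / h ** 2
        cont_fd = ux + vy
        mx_fd = u0 * ux + v0 * uy + px / FLUID.rho - FLUID.nu * (uxx + uyy)
        my_fd = u0 * vx + v0 * vy + py / FLUID.rho - FLUID.nu * (vxx + vyy)
        for ad, fd in ((cont, cont_fd), (mx, mx_fd), (my, my_fd)):
            vals = ad.val.data.ravel()
            scale = np.maximum(np.abs(fd), 1e-4 * np.max(np.abs(fd)))
            assert np.max(np.abs(vals - fd) / scale) < 1e-4


class TestBCLoss:
    def test_zero_model_closed_form_inlet_deficit(self, straight_geom,
                                                  straight_case):
        """A model emitting (0,0,0): inlet u term -> 8/15 in the integral limit."""
        class ZeroModel:
            def forward_jets(self, X, Y, A, S, geom):
                z = np.zeros_like(np.asarray(Y.val, dtype=float))
                return Jet(z, {}), Jet(z, {}), Jet(z, {})

        # dense, symmetric inlet sampling approximates the uniform integral
        n = 20000
        y = np.linspace(-0.05, 0.05, n)
        from tubepinn.geometry import CollocationSet

        colloc = CollocationSet(
            points=np.stack([np.zeros(n), y], axis=1),
            region=np.array(["inlet"] * n, dtype=object),
            tsc=np.zeros((n, 8)), case_index=np.zeros(n, dtype=int),
            cases=[straight_case])
        res = bc_residual_jets(ZeroModel(), colloc, straight_case,
                               straight_geom)
        terms = bc_loss(res)
        assert terms["inlet_v"] == 0.0
        assert float(terms["inlet_u"]) == pytest.approx(8.0 / 15.0, rel=1e-3)

    def test_wall_normalization_identity(self, straight_geom, straight_case):
        """u = V_m/V_s on the walls gives a wall term of exactly 1."""
        class ConstModel:
            def forward_jets(self, X, Y, A, S, geom):
                z = np.zeros_like(np.asarray(Y.val, dtype=float))
                return Jet(z + NORMS.u_norm, {}), Jet(z, {}), Jet(z, {})

        colloc = sample_collocation(straight_geom, counts=(0, 0, 40, 40, 0),
                                    rng_seed=1)
        terms = bc_loss(bc_residual_jets(ConstModel(), colloc, straight_case,
                                         straight_geom))
        assert float(terms["wall"]) == pytest.approx(1.0, rel=1e-12)

    def test_missing_region_absent_not_zero(self, straight_geom,
                                            straight_case, small_mixed_model):
        colloc = sample_collocation(straight_geom, counts=(5, 0, 5, 5, 0),
                                    rng_seed=2)
        res = bc_residual_jets(small_mixed_model, colloc, straight_case,
                               straight_geom)
        assert "outlet" not in res
        _, bd = loss_graph(small_mixed_model, colloc)
        assert bd.outlet_pressure is None

    def test_analytic_solution_satisfies_all_bcs(self, straight_geom):
        ana = analytic_straight_channel()
        colloc = sample_collocation(straight_geom, rng_seed=3)
        case = straight_geom.case
        terms = bc_loss(bc_residual_jets(ana, colloc, case, straight_geom))
        for key, val in terms.items():
            assert float(val) < 1e-12, key


class TestGPINN:
    def test_lambda_independent_harness_gives_zero(self):
        """Residual jets without case channels produce no derivative terms."""
        z = np.zeros((10, 1))
        res = (Jet(z, {}), Jet(z, {}), Jet(z, {}))
        terms = gpinn_loss(res, {})
        assert terms == {}

    def test_nonnegative_and_finite(self, small_mixed_model, mid_geom,
                                    mid_case):
        colloc = sample_collocation(mid_geom, counts=(6, 6, 6, 6, 30),
                                    rng_seed=5)
        x = colloc.points[colloc.select("interior"), 0]
        y = colloc.points[colloc.select("interior"), 1]
        dom = pde_residuals(small_mixed_model, x, y, mid_case, mid_geom,
                            FLUID, case_derivatives=True)
        bcs = bc_residual_jets(small_mixed_model, colloc, mid_case, mid_geom,
                               case_derivatives=True)
        terms = gpinn_loss(dom, bcs)
        assert set(terms) == {"domain_A", "domain_s", "bc_A", "bc_s"}
        for v in terms.values():
            fv = float(v.data) if hasattr(v, "data") else float(v)
            assert np.isfinite(fv) and fv >= 0

    def test_case_derivatives_match_finite_differences(self, small_mixed_model,
                                                       mid_geom, mid_case):
        """d(normalized residual)/d(A, sigma) vs central differences."""
        rng = np.random.default_rng(2)
        x = rng.uniform(0.2, 0.8, 40)
        r = 0.9 * np.minimum(
            np.abs(mid_geom.radius(x)), 0.05)
        y = rng.uniform(-1, 1, 40) * r

        def norm_res(A, s):
            c = CaseParameters(A=A, sigma=s)
            g = ChannelGeometry(case=c)
            cont, mx, my = pde_residuals(small_mixed_model, x, y, c, g, FLUID)
            return np.concatenate([
                cont.val.data * NORMS.V_s,
                mx.val.data / NORMS.mom_norm,
                my.val.data / NORMS.mom_norm], axis=1)

        cont, mx, my = pde_residuals(small_mixed_model, x, y, mid_case,
                                     mid_geom, FLUID, case_derivatives=True)
        h = 1e-5
        for lam, (dA, ds) in (("A", (h, 0)), ("s", (0, h))):
            ad = np.concatenate([
                cont.get(lam).data * NORMS.V_s,
                mx.get(lam).data / NORMS.mom_norm,
                my.get(lam).data / NORMS.mom_norm], axis=1)
            num = (norm_res(mid_case.A + dA, mid_case.sigma + ds)
                   - norm_res(mid_case.A - dA, mid_case.sigma - ds)) / (2 * h)
            scale = np.maximum(np.abs(num), 1e-3 * np.max(np.abs(num)))
            assert np.max(np.abs(ad - num) / scale) < 1e-3


class TestTotalLoss:
    def test_weighted_sum_examples(self):
        bd = LossBreakdown(continuity=0.1, momentum=0.1, wall_noslip=0.2,
                           outlet_pressure=0.05, inlet_u=0.03, inlet_v=0.02)
        assert total_loss(bd, LossWeights(1, 1, 1)) == pytest.approx(0.5)
        bd.derivative_terms = {"domain_A": 0.1}
        assert total_loss(bd, LossWeights(1, 1, 1)) == pytest.approx(0.6)
        assert total_loss(LossBreakdown(), LossWeights()) == 0.0

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(w_physics=-1.0)


class TestInvariances:
    def test_perturbation_scaling_is_quadratic(self, straight_geom):
        """Losses of (analytic + eps * smooth field) grow as O(eps^2)."""
        class Perturbed:
            def __init__(self, eps):
                self.eps = eps
                self.base = analytic_straight_channel()

            def forward_jets(self, X, Y, A, S, geom):
                u, v, p = self.base.forward_jets(X, Y, A, S, geom)
                bump = self.eps * (X * (1.0 - X)) * (Y * 20.0)
                return (u + bump * NORMS.u_norm, v + bump * NORMS.u_norm,
                        p + bump * NORMS.p_norm)

        colloc = sample_collocation(straight_geom,
                                    counts=(80, 80, 80, 80, 800), rng_seed=6)
        eps = np.array([1e-3, 1e-2, 1e-1])
        totals = []
        for e in eps:
            _, bd = loss_graph(Perturbed(e), colloc)
            totals.append(bd.total)
        slope = np.polyfit(np.log(eps), np.log(totals), 1)[0]
        assert abs(slope - 2.0) < 0.1

    def test_loss_breakdown_total_identity(self, small_mixed_model, mid_geom):
        colloc = sample_collocation(mid_geom, counts=(8, 8, 8, 8, 40),
                                    rng_seed=7)
        w = LossWeights(w_physics=2.0, w_bc=0.5, w_derivative=1.0)
        _, bd = loss_graph(small_mixed_model, colloc, weights=w, gpinn=True)
        assert bd.total == pytest.approx(total_loss(bd, w), rel=1e-12)
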