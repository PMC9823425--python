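"""CSI cost functional, backpropagation, updates and the model API."""

import numpy as np
import pytest

import csifem as cf
from csifem.csi import (
    CSIState,
    backprop_init,
    cost_fd,
    cost_fs,
    run_csi,
    _chi_update,
)
from csifem.operators import contrast_from_materials, omega_from_exact


@pytest.fixture(scope="module")
def exact_point(small_fixture):
    """Exact (chi, omega) of the same-mesh homogeneous-head fixture."""
    fx = small_fixture
    contrast = contrast_from_materials(fx.materials, fx.head_mask)
    omegas = [
        omega_from_exact(contrast, fx.fields.etot[t], fx.mesh, variant="edge")
        for t in range(len(fx.fields.etot))
    ]
    return contrast, omegas


class TestCostFunctional:
    def test_fs_at_zero_source_is_exactly_one(self, small_fixture, small_ops):
        fx = small_fixture
        zeros = [np.zeros(small_ops.R.shape[1], complex)] * fx.data.shape[1]
        assert cost_fs(zeros, fx.data, small_ops) == 1.0

    def test_fs_fd_vanish_at_exact_solution(self, small_fixture, small_ops,
                                            exact_point):
        fx = small_fixture
        contrast, omegas = exact_point
        fs = cost_fs(omegas, fx.data, small_ops)
        einc_slots = [small_ops.slots_from_edges(e) for e in fx.fields.einc]
        fd = cost_fd(np.repeat(contrast.chi, 6), omegas, einc_slots,
                     small_ops)
        assert fs < 1e-16
        assert fd < 1e-16

    def test_fd_zero_when_object_equation_satisfied(self, small_ops, rng):
        """If w = chi (E_inc + G_D w) exactly, the domain residual is zero."""
        n = small_ops.R.shape[1]
        w = rng.standard_normal(n) + 1j * rng.standard_normal(n)
        w = np.where(small_ops.slot_mask, w, 0.0)
        chi_slots = np.where(small_ops.slot_mask, 0.4 - 0.1j, 0.0)
        gdw = small_ops.slots_from_edges(small_ops.gd(w))
        # synthesize the consistent incident field slots
        einc_slots = [np.where(small_ops.slot_mask,
                               w / (0.4 - 0.1j) - gdw, 0.0)]
        fd = cost_fd(chi_slots, [w], einc_slots, small_ops)
        assert fd < 1e-20

    def test_fd_zero_contrast_raises(self, small_fixture, small_ops):
        fx = small_fixture
        omegas = [np.zeros(small_ops.R.shape[1], complex)] * fx.data.shape[1]
        einc_slots = [small_ops.slots_from_edges(e) for e in fx.fields.einc]
        with pytest.raises(ValueError, match="backpropagation"):
            cost_fd(np.zeros_like(omegas[0]), omegas, einc_slots, small_ops)

    def test_fs_zero_data_raises(self, small_ops):
        with pytest.raises(ValueError):
            cost_fs([np.zeros(small_ops.R.shape[1])], np.zeros((4, 1)),
                    small_ops)


class TestBackpropagation:
    def test_gamma_is_the_one_parameter_minimizer(self, small_fixture,
                                                  small_ops):
        """Perturbing the backpropagation weight by +-10% increases the
        per-transmitter data error ||d - gamma GS GS^H d||."""
        fx = small_fixture
        omegas, _ = backprop_init(fx.data, small_ops)
        for t in range(fx.data.shape[1]):
            d = fx.data[:, t]
            w1 = small_ops.gs_adjoint(d)
            gamma = np.linalg.norm(omegas[t]) / np.linalg.norm(w1)
            gsgsh = small_ops.gs(w1)

            def err(g):
                return np.linalg.norm(d - g * gsgsh)

            assert err(gamma) < err(0.9 * gamma)
            assert err(gamma) < err(1.1 * gamma)

    def test_zero_transmitter_warns_and_zeroes(self, small_fixture,
                                               small_ops):
        data = small_fixture.data.copy()
        data[:, 1] = 0.0
        with pytest.warns(RuntimeWarning, match="zero data"):
            omegas, _ = backprop_init(data, small_ops)
        assert (omegas[1] == 0).all()
        assert np.linalg.norm(omegas[0]) > 0

    def test_all_zero_data_raises(self, small_ops):
        with pytest.raises(ValueError):
            backprop_init(np.zeros((4, 4)), small_ops)

    def test_initial_guess_localizes_inclusion(self, same_mesh_stroke):
        """Thresholding |chi| implied by the backpropagation guess puts the
        majority of the hottest cells in the true inclusion half."""
        phantom, stroke, ds = same_mesh_stroke
        from csifem.operators import CSIOperators
        from csifem.scenario import measurement_matrix

        doi = phantom.layers[0].contains(ds.mesh.barycenters)
        ops = CSIOperators(ds.system, measurement_matrix(ds.mesh, ds.acq),
                           ds.mesh, ds.materials.kb2, doi)
        omegas, gd_cache = backprop_init(ds.data, ops)
        einc_slots = [ops.slots_from_edges(e) for e in ds.einc]
        st = CSIState(0, np.zeros(ds.mesh.n_tets, complex), omegas, gd_cache)
        chi0 = _chi_update(st, einc_slots, ops)
        # hottest 10% of DoI cells: majority on the inclusion side (x > cx)
        mags = np.abs(chi0[doi])
        cells = np.where(doi)[0][np.argsort(mags)[-len(mags) // 10:]]
        x_side = ds.mesh.barycenters[cells, 0] > phantom.layers[0].center[0]
        assert x_side.mean() > 0.5


class TestUpdates:
    def test_chi_update_closed_form_single_transmitter(self, small_ops, rng):
        """With T = 1 and G_D w = 0 the update reduces to the cell-wise
        least-squares quotient w . conj(E_inc) / |E_inc|^2."""
        I = small_ops.mesh.n_tets
        einc_slots = [np.where(small_ops.slot_mask,
                               rng.standard_normal(6 * I)
                               + 1j * rng.standard_normal(6 * I), 0.0)]
        w = np.where(small_ops.slot_mask,
                     rng.standard_normal(6 * I) + 1j * rng.standard_normal(6 * I),
                     0.0)
        st = CSIState(0, np.zeros(I, complex), [w],
                      [np.zeros(small_ops.mesh.n_edges, complex)])
        chi = _chi_update(st, einc_slots, small_ops)
        E = einc_slots[0].reshape(I, 6)
        W = w.reshape(I, 6)
        expected = np.einsum("ik,ik->i", np.conj(E), W) / np.maximum(
            np.einsum("ik,ik->i", np.abs(E) ** 2, np.ones((I, 6))), 1e-300)
        doi = small_ops.doi_mask
        np.testing.assert_allclose(chi[doi], expected[doi], rtol=1e-12)

    def test_gradient_stationary_at_exact_solution(self, small_fixture,
                                                   small_ops, exact_point):
        """At the exact same-mesh solution the omega-gradient of the cost
        is at the numerical floor relative to the backprop-start gradient."""
        fx = small_fixture
        contrast, omegas = exact_point
        chi_s = np.repeat(contrast.chi, 6)
        eta_s = np.sum(np.abs(fx.data) ** 2)
        einc_slots = [small_ops.slots_from_edges(e) for e in fx.fields.einc]
        eta_d = sum(np.sum(np.abs(chi_s * e) ** 2) for e in einc_slots)

        def gradient(omega, t):
            gdw = small_ops.gd(omega)
            r = fx.data[:, t] - small_ops.msense @ gdw
            rho = chi_s * einc_slots[t] - omega + chi_s * \
                small_ops.slots_from_edges(gdw)
            back = small_ops.rhs_adjoint(
                -(small_ops._Mh @ r) / eta_s
                + small_ops.edges_from_slots(np.conj(chi_s) * rho) / eta_d)
            return back - rho / eta_d

        g_exact = gradient(omegas[0], 0)
        w0, _ = backprop_init(fx.data, small_ops)
        g_start = gradient(w0[0], 0)
        assert np.linalg.norm(g_exact) <= 1e-8 * np.linalg.norm(g_start)

    def test_fcsi_monotone_under_exact_line_search(self, same_mesh_stroke):
        _, _, ds = same_mesh_stroke
        state = run_csi(ds, n_iter=15)
        f = np.array([fs + fd for _, fs, fd in state.history])
        assert (np.diff(f) <= 1e-12 * f[0]).all()

    def test_doi_restriction_shrinks_unknowns(self, same_mesh_stroke):
        phantom, _, ds = same_mesh_stroke
        model_full = cf.ContrastSourceInversion(ds, doi="phantom")
        model_half = cf.ContrastSourceInversion(ds, doi="half")
        n_full = int(model_full.doi_mask.sum())
        n_half = int(model_half.doi_mask.sum())
        assert 0 < n_half < n_full
        # omega storage is proportional to DoI cells (6 slots per cell)
        from csifem.operators import CSIOperators
        from csifem.scenario import measurement_matrix

        ops = CSIOperators(ds.system, measurement_matrix(ds.mesh, ds.acq),
                           ds.mesh, ds.materials.kb2, model_half.doi_mask)
        assert ops.slot_mask.sum() == 6 * n_half


class TestModelAPI:
    @pytest.fixture(scope="class")
    def fitted(self, same_mesh_stroke):
        _, _, ds = same_mesh_stroke
        model = cf.ContrastSourceInversion(ds, variant="edge")
        return model, model.fit(n_iter=12)

    def test_history_identity(self, fitted):
        _, res = fitted
        np.testing.assert_allclose(res.history["FCSI"],
                                   res.history["FS"] + res.history["FD"])

    def test_summary_mentions_key_quantities(self, fitted):
        _, res = fitted
        s = res.summary()
        assert "edge" in s and "iterations" in s and "F_CSI" in s

    def test_reconstruction_maps_back_to_materials(self, fitted,
                                                   same_mesh_stroke):
        _, _, ds = same_mesh_stroke
        _, res = fitted
        eps = ds.materials.eps_b * (1 + res.chi)
        np.testing.assert_allclose(res.eps_r, eps.real)
        assert (res.sigma >= -1e-12).any()  # conductivities are physical-ish

    def test_fit_deterministic(self, same_mesh_stroke):
        _, _, ds = same_mesh_stroke
        r1 = cf.ContrastSourceInversion(ds, variant="edge").fit(n_iter=5)
        r2 = cf.ContrastSourceInversion(ds, variant="edge").fit(n_iter=5)
        assert (r1.chi == r2.chi).all()
        assert (r1.history.values == r2.history.values).all()

    def test_invalid_variant_rejected(self, same_mesh_stroke):
        _, _, ds = same_mesh_stroke
        with pytest.raises(ValueError):
            cf.ContrastSourceInversion(ds, variant="novel")
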