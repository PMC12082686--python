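import math

import numpy as np
import pytest
from scipy.linalg import expm

from masjump import tensors as T
from masjump import exchange as X
from masjump.spinops import embed_two_spin, make_spin_operators

_h = make_spin_operators(0.5)
_IZSZ = embed_two_spin(_h.Iz, _h.identity) @ embed_two_spin(_h.identity, _h.Iz)
_TDIP = (2 / math.sqrt(6)) * _IZSZ
_IX = embed_two_spin(_h.Ix, _h.identity)


def _omf(tensor, model, crys, rotor):
    return np.array([[T.mas_fourier_components(tensor, e, c, rotor)
                      for e in model.site_eulers] for c in crys])


class TestJumpModels:
    def test_three_site_rate_matrix(self):
        m = X.three_site_cone(70.5, 250.0)
        ev = np.sort(np.linalg.eigvalsh(m.rate_matrix))
        np.testing.assert_allclose(ev, [-750.0, -750.0, 0.0], atol=1e-9)
        assert np.max(np.abs(m.rate_matrix.sum(axis=0))) < 1e-12
        assert np.max(np.abs(m.rate_matrix @ m.populations)) < 1e-12

    def test_three_site_zero_angle_sites_identical(self, dip5k):
        m = X.three_site_cone(0.0, 10.0)
        comps = [T.rotate_components(T.spherical_components(dip5k.delta), e)
                 for e in m.site_eulers]
        for c in comps[1:]:
            np.testing.assert_allclose(c, comps[0], atol=1e-12)

    def test_three_site_average_minus_third(self, dip5k):
        m = X.three_site_cone(70.5, 1.0)
        avg = X.averaged_delta(dip5k, m)
        assert avg / dip5k.delta == pytest.approx(-1 / 3, abs=2e-3)
        comps = X.averaged_tensor_components(dip5k, m)
        assert np.max(np.abs(comps[[0, 1, 3, 4]])) < 1e-9 * abs(comps[2])

    def test_nine_site_structure(self, dip5k):
        m = X.nine_site(20.0, 70.5, 3.0, 7.0)
        K = m.rate_matrix
        assert np.max(np.abs(K.sum(axis=0))) < 1e-12
        assert np.max(np.abs(K @ np.full(9, 1 / 9))) < 1e-12
        # fast-limit product rule P2(theta1) P2(theta2)
        expect = dip5k.delta * T.order_parameter(20.0) * T.order_parameter(70.5)
        assert X.averaged_delta(dip5k, m) == pytest.approx(expect, rel=1e-10)
        # theta1 = 0: reduces to the three-site average at theta2
        m0 = X.nine_site(0.0, 70.5, 3.0, 7.0)
        m3 = X.three_site_cone(70.5, 7.0)
        assert X.averaged_delta(dip5k, m0) == pytest.approx(
            X.averaged_delta(dip5k, m3), rel=1e-10)


class TestExchangeSuperoperator:
    def test_zero_rate_and_stationarity(self):
        m = X.three_site_cone(70.5, 0.0)
        assert np.max(np.abs(X.exchange_superoperator(m, 2))) == 0.0
        m2 = X.three_site_cone(70.5, 11.0)
        Kh = X.exchange_superoperator(m2, 2)
        uniform = np.tile(np.eye(2).reshape(-1), 3) / 3
        assert np.max(np.abs(Kh @ uniform)) < 1e-12

    @pytest.mark.parametrize("d", [2, 3])
    def test_eigenvalue_multiplicity(self, d):
        m = X.three_site_cone(70.5, 5.0)
        ev = np.sort(np.linalg.eigvalsh(X.exchange_superoperator(m, d)))
        expect = np.sort(np.concatenate([np.full(d * d, -15.0), np.full(d * d, -15.0),
                                         np.zeros(d * d)]))
        np.testing.assert_allclose(ev, expect, atol=1e-9)


class TestCompositeGenerator:
    def test_site_count_mismatch(self):
        m = X.three_site_cone(70.5, 1.0)
        with pytest.raises(ValueError):
            X.build_composite_generator([np.eye(2)] * 2, m)

    def test_block_structure(self):
        from masjump.spinops import commutation_superop

        m = X.three_site_cone(70.5, 4.0)
        hams = [w * _h.Iz for w in (1.0, 2.0, 3.0)]
        G = X.build_composite_generator(hams, m)
        assert G.shape == (12, 12)
        manual = X.exchange_superoperator(m, 2).astype(complex)
        for s, H in enumerate(hams):
            manual[4 * s:4 * s + 4, 4 * s:4 * s + 4] += -1j * commutation_superop(H)
        np.testing.assert_allclose(G, manual, atol=1e-14)
        # k=0 generator is block diagonal over sites
        G0 = X.build_composite_generator(hams, X.three_site_cone(70.5, 0.0))
        off = G0.copy()
        for s in range(3):
            off[4 * s:4 * s + 4, 4 * s:4 * s + 4] = 0
        assert np.max(np.abs(off)) == 0.0


class TestPropagation:
    def test_zero_interaction_constant_signal(self, rotor20, powder_small):
        model = X.three_site_cone(70.5, 1e3)
        omf = _omf(T.Rank2Tensor.from_hz(0.0), model, powder_small[:4], rotor20)
        eng = X.PeriodEngine(omf, _TDIP, model, rotor20,
                             [X.Segment(rotor20.tau_r, n_step=8)])
        sig = X.propagate(eng, _IX, _IX, rotor20.tau_r * np.arange(5)).real
        np.testing.assert_allclose(sig, 1.0, atol=1e-12)

    def test_single_site_matches_hilbert(self, rotor20, dip5k):
        c = T.Crystallite(0.4, 1.0, 0.7, 1.0)
        model = X.single_site()
        omf = _omf(dip5k, model, [c], rotor20)
        n_step = 64
        eng = X.PeriodEngine(omf, _TDIP, model, rotor20,
                             [X.Segment(rotor20.tau_r, n_step=n_step)],
                             sample_offsets=[rotor20.tau_r / 2])
        grid = np.array([0.0, 0.5, 1.0, 2.5]) * rotor20.tau_r
        sig = X.propagate(eng, _IX, _IX, grid).real[0]
        dt = rotor20.tau_r / n_step
        for gi, t in enumerate(grid):
            U = np.eye(4, dtype=complex)
            for k in range(int(round(t / dt))):
                w = T.mas_frequency(dip5k, (0, 0, 0), c, rotor20, (k + 0.5) * dt)
                U = expm(-1j * w * _TDIP * dt) @ U
            rho = U @ _IX @ U.conj().T
            expect = np.trace(_IX @ rho).real / np.trace(_IX @ _IX).real
            assert sig[gi] == pytest.approx(expect, abs=1e-10)

    def test_identical_sites_invisible(self, rotor20, dip5k, powder_small):
        crys = powder_small[:5]
        m_deg = X.three_site_cone(0.0, 1e5)
        omf = _omf(dip5k, m_deg, crys, rotor20)
        eng = X.PeriodEngine(omf, _TDIP, m_deg, rotor20,
                             [X.Segment(rotor20.tau_r, n_step=48)])
        grid = rotor20.tau_r * np.arange(6)
        sig = X.propagate(eng, _IX, _IX, grid).real
        m1 = X.single_site()
        omf1 = _omf(dip5k, m1, crys, rotor20)
        eng1 = X.PeriodEngine(omf1, _TDIP, m1, rotor20,
                              [X.Segment(rotor20.tau_r, n_step=48)])
        sig1 = X.propagate(eng1, _IX, _IX, grid).real
        np.testing.assert_allclose(sig, sig1, atol=1e-9)

    def test_no_exchange_equals_weighted_mean(self, rotor20, dip5k, powder_small):
        crys = powder_small[:4]
        m = X.three_site_cone(70.5, 0.0)
        omf = _omf(dip5k, m, crys, rotor20)
        sched = [X.Segment(rotor20.tau_r, n_step=48)]
        grid = rotor20.tau_r * np.arange(6)
        sig = X.propagate(X.PeriodEngine(omf, _TDIP, m, rotor20, sched),
                          _IX, _IX, grid).real
        acc = np.zeros_like(sig)
        for e in m.site_eulers:
            om1 = np.array([[T.mas_fourier_components(dip5k, e, c, rotor20)]
                            for c in crys])
            eng = X.PeriodEngine(om1, _TDIP, X.single_site(), rotor20, sched)
            acc += X.propagate(eng, _IX, _IX, grid).real / 3
        np.testing.assert_allclose(sig, acc, atol=1e-9)

    def test_fast_exchange_equals_preaveraged(self, rotor20, dip5k, powder_small):
        crys = powder_small[:6]
        m = X.three_site_cone(70.5, 1e11)
        omf = _omf(dip5k, m, crys, rotor20)
        sched = [X.Segment(rotor20.tau_r, n_step=48)]
        grid = rotor20.tau_r * np.arange(8)
        sig = X.propagate(X.PeriodEngine(omf, _TDIP, m, rotor20, sched),
                          _IX, _IX, grid).real
        avg = T.Rank2Tensor(delta=X.averaged_delta(dip5k, m))
        om1 = _omf(avg, X.single_site(), crys, rotor20)
        ref = X.propagate(X.PeriodEngine(om1, _TDIP, X.single_site(), rotor20, sched),
                          _IX, _IX, grid).real
        assert np.max(np.abs(sig - ref)) < 1e-3

    def test_composite_trace_conserved(self, rotor20, dip5k, powder_small):
        crys = powder_small[:3]
        m = X.three_site_cone(70.5, 2e4)
        omf = _omf(dip5k, m, crys, rotor20)
        eng = X.PeriodEngine(omf, _TDIP, m, rotor20,
                             [X.Segment(rotor20.tau_r, n_step=48)])
        rho = eng.composite_state(_IX + 0.5 * np.eye(4))
        for _ in range(7):
            rho = np.einsum("cij,cj->ci", eng.period_propagator, rho)
        traces = rho.reshape(len(crys), 3, 4, 4).diagonal(axis1=2, axis2=3).sum(axis=(1, 2))
        np.testing.assert_allclose(traces.real, 2.0, atol=1e-10)
        assert np.max(np.abs(traces.imag)) < 1e-10

    def test_powder_trajectory_rules(self, powder_small):
        sig = np.arange(12, dtype=float).reshape(4, 3)
        crys = powder_small[:4]
        avg = X.powder_trajectory(sig, crys)
        doubled = X.powder_trajectory(np.vstack([sig, sig]),
                                      crys + crys)
        np.testing.assert_allclose(avg, doubled, atol=1e-12)
        with pytest.raises(ValueError):
            X.powder_trajectory(sig, [])


def test_monte_carlo_oracle_agrees_with_sle(rotor20, dip5k):
    """Explicit jump-trajectory averaging reproduces the stochastic-Liouville
    free dipolar dephasing within 3 sigma of the Monte-Carlo error."""
    crys = T.zcw_orientations(20, three_angle=True)[:6]
    grid = rotor20.tau_r * np.arange(0, 33)
    for kex in (1e2, 1e3, 1e4):
        m = X.three_site_cone(70.5, kex)
        omf = _omf(dip5k, m, crys, rotor20)
        eng = X.PeriodEngine(omf, _TDIP, m, rotor20,
                             [X.Segment(rotor20.tau_r, n_step=64)])
        sle = X.powder_trajectory(X.propagate(eng, _IX, _IX, grid).real, crys)
        mc, sem = X.monte_carlo_free_evolution(dip5k, m, rotor20, crys, grid,
                                               n_traj=10000, seed=11)
        dev = np.abs(sle - mc) / np.maximum(sem, 1e-9)
        assert dev[1:].max() < 3.0, f"kex={kex}: {dev.max():.1f} sigma"
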