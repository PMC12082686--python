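import math

import numpy as np
import pytest

from masjump import tensors as T
from masjump import exchange as X
from masjump import sequences as Q

ZERO = T.Rank2Tensor.from_hz(0.0)


@pytest.fixture(scope="module")
def crys34():
    return T.zcw_orientations(30)


@pytest.fixture(scope="module")
def crys89():
    return T.zcw_orientations(80, three_angle=True)


class TestCP:
    def test_zero_coupling_no_transfer(self, rotor20, crys34):
        spec = Q.CPSpec(contact_grid=np.arange(0, 11) * rotor20.tau_r / 2)
        traj = Q.cp_curve(spec, ZERO, X.single_site(), rotor20, crys34[:3])
        assert np.max(np.abs(traj.signal)) < 1e-12

    def test_matching_condition_logged(self, rotor20, crys34, dip5k):
        spec = Q.CPSpec(nu1_I=93e3, nu1_S=73e3,
                        contact_grid=np.arange(0, 5) * rotor20.tau_r / 2)
        traj = Q.cp_curve(spec, dip5k, X.single_site(), rotor20, crys34[:3])
        assert traj.meta["match_offset_zq_hz"] == pytest.approx(0.0)
        with pytest.raises(ValueError):
            Q.cp_curve(Q.CPSpec(nu1_I=0.0), dip5k, X.single_site(), rotor20, crys34)

    def test_fast_exchange_triples_first_maximum(self, rotor20, crys34, dip5k):
        spec = Q.CPSpec(contact_grid=np.arange(0, 81) * rotor20.tau_r / 2)
        rigid = Q.cp_curve(spec, dip5k, X.single_site(), rotor20, crys34)
        fast = Q.cp_curve(spec, dip5k, X.three_site_cone(70.5, 1e11),
                          rotor20, crys34)
        t_r = rigid.t[np.argmax(rigid.signal)]
        t_f = fast.t[np.argmax(fast.signal)]
        assert t_f / t_r == pytest.approx(3.0, rel=0.15)

    def test_tilted_lock_scales_coupling(self, rotor20, crys34, dip5k):
        """Tilting the I lock toward z scales the effective coupling ~ sin(tilt)."""
        s90 = Q.CPSpec(contact_grid=np.arange(0, 101) * rotor20.tau_r / 2)
        s20 = Q.CPSpec(tilt_deg=20.0,
                       contact_grid=np.arange(0, 161) * rotor20.tau_r / 2)
        c90 = Q.cp_curve(s90, dip5k, X.single_site(), rotor20, crys34)
        c20 = Q.cp_curve(s20, dip5k, X.single_site(), rotor20, crys34)
        ratio = c90.t[np.argmax(c90.signal)] / c20.t[np.argmax(c20.signal)]
        assert ratio == pytest.approx(math.sin(math.radians(20)), rel=0.2)


class TestREDOR:
    def test_zero_coupling_flat(self, rotor20, crys34):
        s, s0, frac = Q.redor_curves(Q.REDORSpec(ideal_pulses=True, n_rotor_max=8),
                                     ZERO, X.single_site(), rotor20, crys34[:3])
        assert np.max(np.abs(frac.signal)) < 1e-9
        np.testing.assert_allclose(s0.signal, 1.0, atol=1e-9)

    def test_universal_curve_scaling(self, rotor20, crys89, dip5k):
        """dS/S0 depends on delta and tau only through their product."""
        _, _, f1 = Q.redor_curves(Q.REDORSpec(ideal_pulses=True, n_rotor_max=32),
                                  dip5k, X.single_site(), rotor20, crys89)
        _, _, f2 = Q.redor_curves(Q.REDORSpec(ideal_pulses=True, n_rotor_max=16),
                                  T.Rank2Tensor.from_hz(10000.0),
                                  X.single_site(), rotor20, crys89)
        np.testing.assert_allclose(f2.signal, f1.signal[1::2], atol=5e-3)

    def test_shifted_pulses_scale_by_sin_2pi_eps(self, rotor20, crys89, dip5k):
        """eps = 0.45 at 5 kHz matches classic REDOR at 1545 Hz."""
        _, _, fe = Q.redor_curves(
            Q.REDORSpec(ideal_pulses=True, shift_eps=0.45, n_rotor_max=48),
            dip5k, X.single_site(), rotor20, crys89)
        _, _, fc = Q.redor_curves(
            Q.REDORSpec(ideal_pulses=True, n_rotor_max=48),
            T.Rank2Tensor.from_hz(5000.0 * math.sin(2 * math.pi * 0.45)),
            X.single_site(), rotor20, crys89)
        assert np.max(np.abs(fe.signal - fc.signal)) < 5e-3

    def test_finite_pulses_close_to_ideal(self, rotor20, crys34, dip5k):
        _, _, fi = Q.redor_curves(Q.REDORSpec(ideal_pulses=True, n_rotor_max=16),
                                  dip5k, X.single_site(), rotor20, crys34)
        _, _, ff = Q.redor_curves(Q.REDORSpec(pi_pulse_nu1=100e3, n_rotor_max=16),
                                  dip5k, X.single_site(), rotor20, crys34)
        assert np.max(np.abs(fi.signal - ff.signal)) < 0.05

    def test_s0_decays_under_exchange(self, rotor20, crys34, dip5k):
        """Intermediate exchange produces the T2'-type decay of the reference
        echo; rigid S0 stays at 1."""
        _, s0, _ = Q.redor_curves(Q.REDORSpec(ideal_pulses=True, n_rotor_max=200),
                                  dip5k, X.three_site_cone(70.5, 1e4),
                                  rotor20, crys34)
        assert s0.signal[-1] < 0.75
        assert np.all(np.diff(s0.signal) < 1e-6)


class TestRSequences:
    def test_phase_and_amplitude_rules(self, rotor20):
        w = Q.RSequenceSpec()           # R10_1^3
        assert math.degrees(w.phase) == pytest.approx(54.0)
        assert w.nu1(rotor20) == pytest.approx(5 * rotor20.nu_r)
        r18 = Q.RSequenceSpec(N=18, n=1, nu=7, target="csa")
        assert math.degrees(r18.phase) == pytest.approx(70.0)
        assert r18.nu1(rotor20) == pytest.approx(9 * rotor20.nu_r)
        assert Q.RSequenceSpec(window_fraction=0.5).nu1(rotor20) == \
            pytest.approx(10 * rotor20.nu_r)
        with pytest.raises(ValueError):
            Q.RSequenceSpec(window_fraction=1.0).nu1(rotor20)

    def test_wpars_flat_without_coupling(self, rotor20, crys34):
        traj = Q.wpars_curve(Q.RSequenceSpec(n_block_max=6), ZERO,
                             X.single_site(), rotor20, crys34[:3])
        np.testing.assert_allclose(traj.signal, 1.0, atol=1e-9)

    def test_wpars_fast_exchange_third_frequency(self, rotor20, crys34, dip5k):
        spec = Q.RSequenceSpec(n_block_max=50)
        rigid = Q.wpars_curve(spec, dip5k, X.single_site(), rotor20, crys34)
        fast = Q.wpars_curve(spec, dip5k, X.three_site_cone(70.5, 1e11),
                             rotor20, crys34)
        ratio = fast.t[np.argmin(fast.signal)] / rigid.t[np.argmin(rigid.signal)]
        assert ratio == pytest.approx(3.0, rel=0.15)

    def test_window_scales_coupling_up(self, rotor20, crys34, dip5k):
        plain = Q.wpars_curve(Q.RSequenceSpec(n_block_max=40), dip5k,
                              X.single_site(), rotor20, crys34)
        wind = Q.wpars_curve(Q.RSequenceSpec(window_fraction=0.4, n_block_max=40),
                             dip5k, X.single_site(), rotor20, crys34)
        assert wind.t[np.argmin(wind.signal)] < plain.t[np.argmin(plain.signal)]

    def test_r18_flat_without_csa(self, rotor20, crys34):
        traj = Q.r18_csa_curve(Q.RSequenceSpec(N=18, nu=7, target="csa",
                                               n_block_max=6),
                               ZERO, X.single_site(), rotor20, crys34[:3])
        np.testing.assert_allclose(traj.signal, 1.0, atol=1e-9)

    def test_target_validation(self, rotor20, crys34, dip5k):
        with pytest.raises(ValueError):
            Q.wpars_curve(Q.RSequenceSpec(target="csa"), dip5k,
                          X.single_site(), rotor20, crys34)
        with pytest.raises(ValueError):
            Q.r18_csa_curve(Q.RSequenceSpec(target="dipolar"), dip5k,
                            X.single_site(), rotor20, crys34)


class TestOffMAS:
    def test_magic_angle_pure_j_modulation(self, rotor20, crys34):
        spec = Q.OffMASSpec(J=-90.0, offset_deg=0.0, window=0.02)
        ten = T.dipolar_delta(T.DipolarGeometry.from_isotopes("1H", "15N", 1.05))
        traj = Q.offmas_echo(spec, ten, X.single_site(), rotor20, crys34[:4])
        np.testing.assert_allclose(traj.signal, np.cos(math.pi * -90.0 * traj.t),
                                   atol=1e-8)

    def test_rigid_small_offset_matches_closed_form(self, rotor20, crys89):
        """Full off-MAS echo vs. the small-offset closed form, < 2 % RMS."""
        spec = Q.OffMASSpec(J=-90.0, offset_deg=0.05, window=0.08)
        ten = T.dipolar_delta(T.DipolarGeometry.from_isotopes("1H", "15N", 1.05))
        sim = Q.offmas_echo(spec, ten, X.single_site(), rotor20, crys89)
        cf = Q.closed_form_offmas(spec, ten.delta, tau=sim.t)
        rms = np.sqrt(np.mean((sim.signal - cf.signal) ** 2))
        assert rms < 0.02

    def test_fast_exchange_sign_change_slows_modulation(self, rotor20, crys89):
        """S = -1/3 flips the residual coupling sign, so a positive offset
        reduces the modulation frequency in the fast limit."""
        ten = T.dipolar_delta(T.DipolarGeometry.from_isotopes("1H", "15N", 1.05))
        spec = Q.OffMASSpec(J=-90.0, offset_deg=0.10, window=0.03)
        rigid = Q.offmas_echo(spec, ten, X.single_site(), rotor20, crys89)
        fast = Q.offmas_echo(spec, ten, X.three_site_cone(70.5, 1e11),
                             rotor20, crys89)
        t0 = np.cos(math.pi * -90.0 * rigid.t)
        # rigid dephases away from pure J faster than the fast-exchange curve
        assert np.mean(np.abs(rigid.signal - t0)) > np.mean(np.abs(fast.signal - t0))

    def test_large_offset_warns(self, rotor20, crys34, dip5k):
        with pytest.warns(UserWarning):
            Q.offmas_echo(Q.OffMASSpec(offset_deg=6.0, window=0.002), dip5k,
                          X.single_site(), rotor20, crys34[:2])

    def test_closed_form_properties(self):
        spec = Q.OffMASSpec(J=-90.0, offset_deg=0.0)
        tau = np.linspace(1e-4, 0.05, 60)
        cf = Q.closed_form_offmas(spec, 2 * math.pi * 21e3, tau=tau)
        np.testing.assert_allclose(cf.signal, np.cos(math.pi * -90 * tau), atol=1e-12)
        spec2 = Q.OffMASSpec(J=-90.0, offset_deg=0.3)
        zero_d = Q.closed_form_offmas(spec2, 0.0, tau=tau)
        np.testing.assert_allclose(zero_d.signal, np.cos(math.pi * -90 * tau),
                                   atol=1e-12)
        plus = Q.closed_form_offmas(spec2, 2 * math.pi * 21e3, tau=tau)
        spec_m = Q.OffMASSpec(J=-90.0, offset_deg=-0.3)
        minus = Q.closed_form_offmas(spec_m, -2 * math.pi * 21e3, tau=tau)
        np.testing.assert_allclose(plus.signal, minus.signal, atol=1e-12)


class TestQuad:
    @pytest.fixture(scope="class")
    def crysq(self):
        return T.zcw_orientations(300, three_angle=True)

    def test_sidebands_at_rotor_harmonics(self, rotor20, crysq):
        spec = Q.QuadSpec(window=0.01)
        fid = Q.quad_fid(spec, X.single_site(), rotor20, crysq)
        sp = Q.quad_spectrum(fid, display_lb=100.0)
        I, f = sp.intensity, sp.freq
        peaks = [f[i] for i in range(1, len(f) - 1)
                 if I[i] > I[i - 1] and I[i] > I[i + 1] and I[i] > 0.1 * I.max()]
        res = np.array(peaks) / rotor20.nu_r
        np.testing.assert_allclose(res, np.round(res), atol=0.02)

    def test_second_order_is_small_at_high_field(self, rotor20, crysq):
        """At 18.7 T the second-order correction changes sideband
        intensities by < 1 % of the maximum."""
        on = Q.quad_fid(Q.QuadSpec(window=0.01), X.single_site(), rotor20, crysq)
        off = Q.quad_fid(
            Q.QuadSpec(quad=T.QuadrupoleSpec(Cqcc=160e3, second_order=False),
                       window=0.01),
            X.single_site(), rotor20, crysq)
        from masjump.fitting import center_sideband_manifold
        from masjump.exchange import Trajectory

        # remove the (common-mode) second-order isotropic shift before
        # comparing the intensity distributions
        onc = center_sideband_manifold(on)
        offc = center_sideband_manifold(off)
        sp_on = Q.quad_spectrum(Trajectory(on.t, onc.signal), display_lb=100.0)
        sp_off = Q.quad_spectrum(Trajectory(off.t, offc.signal), display_lb=100.0)
        a = np.abs(sp_on.intensity) / np.abs(sp_on.intensity).max()
        b = np.abs(sp_off.intensity) / np.abs(sp_off.intensity).max()
        assert np.max(np.abs(a - b)) < 0.01

    def test_second_order_shifts_match_static_diagonalization(self):
        """The quadrupolar second-order level shifts agree with exact
        diagonalization of the static Hamiltonian (error O(delta^3/omega0^2))."""
        from scipy.linalg import eigh

        from masjump.sequences import _T2, _second_order_shifts
        from masjump.spinops import make_spin_operators

        s1 = make_spin_operators(1.0)
        qs = T.QuadrupoleSpec(Cqcc=160e3)
        ten = T.quad_delta(qs)
        om0 = qs.larmor
        rot_static = T.RotorSpec(nu_r=20e3,
                                 offset_deg=-math.degrees(T.THETA_MAGIC))
        for beta in (0.3, 0.9, 1.4):
            c = T.Crystallite(0.0, beta, 0.0, 1.0)
            AR = T.rotor_frame_components(ten, (0, 0, 0), c)
            H = om0 * s1.Iz + sum((-1) ** mu * AR[(-mu) + 2] * _T2[mu]
                                  for mu in range(-2, 3))
            E = np.sort(eigh(H)[0])[::-1]
            E0 = om0 * np.array([1, 0, -1]) + AR[2].real * np.diag(_T2[0]).real
            exact = E - E0
            mine = _second_order_shifts(AR[None, None, :], rot_static, om0)[0, 0]
            np.testing.assert_allclose(mine, exact, atol=1.0)  # rad/s; shifts ~100

    def test_dwell_guard(self, rotor20, crysq):
        with pytest.raises(ValueError, match="spectral width"):
            Q.quad_fid(Q.QuadSpec(window=0.005, samples_per_period=4),
                       X.single_site(), rotor20, crysq[:5])


def test_site_relabeling_invariance(rotor20, crys34, dip5k):
    """Permuting the three cone sites leaves the powder trajectory unchanged."""
    m = X.three_site_cone(70.5, 5e3)
    perm = [1, 2, 0]
    m_p = X.JumpModel(site_eulers=tuple(m.site_eulers[i] for i in perm),
                      populations=m.populations[perm],
                      rate_matrix=m.rate_matrix[np.ix_(perm, perm)],
                      label="permuted")
    spec = Q.RSequenceSpec(n_block_max=12)
    a = Q.wpars_curve(spec, dip5k, m, rotor20, crys34[:6])
    b = Q.wpars_curve(spec, dip5k, m_p, rotor20, crys34[:6])
    np.testing.assert_allclose(a.signal, b.signal, atol=1e-10)
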