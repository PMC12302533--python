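"""NPC stretch gating, rupture permeability/flux and the well-mixed forms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanoyap import (RuptureSpec, TransportParams, dynamic_rupture_course,
                     free_nuclear_fraction, ner_permeability, npc_import_rate,
                     rupture_flux, wellmixed_nc, wellmixed_nc_with_rupture)
from nanoyap.nucleus import NEPatch
from nanoyap.transport import TransportError

TP = TransportParams(k_inb=0.001, k_in=0.01, k_out_npc=0.008, alpha_0=5.0,
                     k_bind=4.0, k_unbind=1.0)


def two_patches(sa_def=100.0, sa_undef=300.0, alpha=3.0):
    return [NEPatch("deformed", sa_def, alpha, 2.0),
            NEPatch("undeformed", sa_undef, 1.0, 0.0)]


class TestNpcImportRate:
    def test_no_stretch_baseline(self):
        assert npc_import_rate(2.0, 1.0, TP) == pytest.approx(
            TP.k_inb + TP.k_in * 2.0)

    def test_one_efold_of_stretch(self):
        assert npc_import_rate(2.0, 1.0 + TP.alpha_0, TP) == pytest.approx(
            TP.k_inb + math.e * TP.k_in * 2.0)

    def test_compression_reduces_import(self):
        assert npc_import_rate(2.0, 0.8, TP) < npc_import_rate(2.0, 1.0, TP)

    @settings(derandomize=True, max_examples=50)
    @given(a1=st.floats(0.1, 10.0), a2=st.floats(0.1, 10.0),
           npc=st.floats(0.0, 20.0))
    def test_strictly_increasing_in_alpha(self, a1, a2, npc):
        lo, hi = sorted((a1, a2))
        assert npc_import_rate(npc, lo, TP) <= npc_import_rate(npc, hi, TP)

    def test_invalid_alpha0_rejected(self):
        with pytest.raises(Exception):
            TransportParams(k_inb=0.001, k_in=0.01, k_out_npc=0.008,
                            alpha_0=0.0, k_bind=1.0, k_unbind=1.0)


class TestFreeNuclearFraction:
    def test_values(self):
        assert free_nuclear_fraction(1.0) == 1.0
        assert free_nuclear_fraction(4.0) == 0.25
        assert free_nuclear_fraction(5.0) == pytest.approx(0.2)

    def test_consistent_with_binding_rates(self):
        assert TP.upsilon == pytest.approx(1 + TP.k_bind / TP.k_unbind,
                                           rel=1e-12)

    def test_upsilon_below_one_rejected(self):
        with pytest.raises(TransportError):
            free_nuclear_fraction(0.5)


class TestNerPermeability:
    SPEC = RuptureSpec(sigma_ner=0.2, k_rupture=1e5, z_ne=3.2)

    def test_closed_at_t0(self):
        assert ner_permeability(0.0, 0.0, 3.2, 0.0, self.SPEC) == 0.0

    def test_fully_open_center(self):
        assert ner_permeability(0.0, 0.0, 3.2, 1e9, self.SPEC) == \
            pytest.approx(1.0)

    def test_one_time_constant(self):
        assert ner_permeability(0.0, 0.0, 3.2, self.SPEC.t_0, self.SPEC) == \
            pytest.approx(1 - math.exp(-1))

    def test_one_sigma_off_center(self):
        assert ner_permeability(self.SPEC.sigma_ner, 0.0, 3.2, 1e9,
                                self.SPEC) == pytest.approx(math.exp(-1))

    @settings(derandomize=True, max_examples=60)
    @given(x=st.floats(-1, 1), y=st.floats(-1, 1), dz=st.floats(-1, 1),
           t1=st.floats(0, 50), t2=st.floats(0, 50))
    def test_bounded_monotone_in_time_radially_decreasing(self, x, y, dz,
                                                          t1, t2):
        lo, hi = sorted((t1, t2))
        p_lo = ner_permeability(x, y, 3.2 + dz, lo, self.SPEC)
        p_hi = ner_permeability(x, y, 3.2 + dz, hi, self.SPEC)
        assert 0.0 <= p_lo <= p_hi <= 1.0
        closer = ner_permeability(x / 2, y / 2, 3.2 + dz, hi, self.SPEC)
        assert closer >= p_hi - 1e-15 or abs(dz) > 0  # radial decrease in xy
        assert ner_permeability(0, 0, 3.2, hi, self.SPEC) >= p_hi

    def test_bad_sigma_rejected(self):
        with pytest.raises(TransportError):
            RuptureSpec(sigma_ner=0.0, k_rupture=1.0, z_ne=3.2)


class TestRuptureFlux:
    def test_diffusive_equilibrium_is_zero(self):
        y_free = 0.4
        assert rupture_flux(y_free, TP.upsilon * y_free, 1.0, TP, 1e5) == \
            pytest.approx(0.0, abs=1e-12)

    def test_closed_pore_no_flux(self):
        assert rupture_flux(1.0, 0.0, 0.0, TP, 1e5) == 0.0

    def test_unretained_direct_evaluation(self):
        tp1 = TP.with_upsilon(1.0)
        assert rupture_flux(0.7, 0.0, 1.0, tp1, 1e5) == pytest.approx(
            1e5 * 0.7)


class TestWellMixedForms:
    def test_degenerate_no_deformed_area(self):
        ne = [NEPatch("undeformed", 400.0, 1.0, 0.0)]
        out = wellmixed_nc(0.8, ne, 2.0, 2.0, 1.0, TP)
        assert out["nc_ratio"] == pytest.approx(
            0.8 * npc_import_rate(2.0, 1.0, TP) / TP.k_out_npc)

    def test_partition_invariance_without_stretch(self):
        uniform = wellmixed_nc(0.8, [NEPatch("undeformed", 400.0, 1.0, 0.0)],
                               2.0, 2.0, 1.0, TP)
        split = wellmixed_nc(0.8, two_patches(120.0, 280.0), 2.0, 2.0, 1.0, TP)
        assert split["nc_ratio"] == pytest.approx(uniform["nc_ratio"])

    def test_matches_two_compartment_ode_steady_state(self):
        """Random parameter draws: the closed form equals the steady state
        of the explicit import/export ODE to 1e-6."""
        from scipy.integrate import solve_ivp

        rng = np.random.default_rng(7)
        for _ in range(25):
            tp = TransportParams(
                k_inb=rng.uniform(1e-4, 1e-2), k_in=rng.uniform(1e-3, 0.05),
                k_out_npc=rng.uniform(1e-3, 0.05), alpha_0=rng.uniform(1, 10),
                k_bind=rng.uniform(0, 5), k_unbind=1.0)
            sa_def, sa_undef = rng.uniform(10, 200), rng.uniform(100, 500)
            alpha, npc = rng.uniform(1, 8), rng.uniform(0.1, 5)
            vc, vn = 2300.0, 550.0
            kin = npc_import_rate(npc, alpha, tp) * sa_def \
                + npc_import_rate(npc, 1.0, tp) * sa_undef
            kout = tp.k_out_npc * (sa_def + sa_undef)

            def rhs(t, y):
                j = kin * y[0] - kout * y[1]
                return [-j / vc, j / vn]

            sol = solve_ivp(rhs, (0, 5e5), [1.0, 0.0], method="BDF",
                            rtol=1e-10, atol=1e-12)
            yc, yn = sol.y[:, -1]
            out = wellmixed_nc(1.0, two_patches(sa_def, sa_undef, alpha),
                               npc, npc, alpha, tp)
            assert yn / yc == pytest.approx(out["nc_ratio"], rel=1e-6)

    def test_rupture_form_reduces_exactly_at_zero_pore(self):
        ne = two_patches()
        base = wellmixed_nc(0.8, ne, 2.0, 2.0, 3.0, TP)
        tiny = RuptureSpec(sigma_ner=1e-12, k_rupture=0.0, z_ne=3.2)
        with_r = wellmixed_nc_with_rupture(0.8, ne, 2.0, 2.0, 3.0, TP, tiny)
        assert with_r["nc_ratio"] == base["nc_ratio"]

    def test_dominant_rupture_approaches_upsilon(self):
        ne = two_patches()
        for ups in (1.0, 2.5, 5.0):
            tp = TP.with_upsilon(ups)
            rup = RuptureSpec(sigma_ner=0.2, k_rupture=1e12, z_ne=3.2)
            out = wellmixed_nc_with_rupture(1.0, ne, 2.0, 2.0, 3.0, tp, rup)
            assert out["nc_ratio"] == pytest.approx(ups, rel=1e-4)

    def test_rupture_sign_matches_upsilon_vs_baseline(self):
        """With all cytosolic YAP/TAZ free, rupture raises steady N/C iff
        upsilon exceeds the no-rupture N/C (100 random draws)."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            tp = TransportParams(
                k_inb=rng.uniform(1e-4, 1e-2), k_in=rng.uniform(1e-3, 0.05),
                k_out_npc=rng.uniform(1e-3, 0.05), alpha_0=rng.uniform(1, 10),
                k_bind=rng.uniform(0, 6), k_unbind=1.0)
            ne = two_patches(rng.uniform(10, 200), rng.uniform(100, 500),
                             rng.uniform(1, 6))
            npc = rng.uniform(0.1, 5)
            rup = RuptureSpec(sigma_ner=rng.uniform(0.05, 0.3),
                              k_rupture=rng.uniform(1e3, 1e5), z_ne=3.2)
            base = wellmixed_nc(1.0, ne, npc, npc, ne[0].alpha, tp)
            with_r = wellmixed_nc_with_rupture(1.0, ne, npc, npc,
                                               ne[0].alpha, tp, rup)
            delta = with_r["nc_ratio"] - base["nc_ratio"]
            expected = tp.upsilon - base["nc_ratio"]
            assert delta == pytest.approx(0.0, abs=1e-12) \
                if abs(expected) < 1e-12 else np.sign(delta) == np.sign(expected)

    def test_monotone_in_pore_area(self):
        """N/C increases with SA_NER when upsilon exceeds the baseline N/C
        and decreases when it falls below."""
        ne = two_patches()
        for ups, sign in ((6.0, 1), (1.0, -1)):
            tp = TP.with_upsilon(ups)
            ncs = []
            for sig in np.linspace(0.02, 0.4, 12):
                rup = RuptureSpec(sigma_ner=sig, k_rupture=1e4, z_ne=3.2)
                ncs.append(wellmixed_nc_with_rupture(
                    1.0, ne, 2.0, 2.0, 3.0, tp, rup)["nc_ratio"])
            diffs = np.diff(ncs)
            assert np.all(sign * diffs > 0)


class TestDynamicRupture:
    def test_no_rupture_coefficient_is_baseline(self, pillar_geometry,
                                                ne_undeformed, params,
                                                flat_steady):
        from nanoyap.signaling import assemble_rhs, simulate

        y0 = flat_steady.steady.vector()
        rup0 = RuptureSpec(sigma_ner=0.1, k_rupture=0.0, z_ne=3.2)
        traj = dynamic_rupture_course(pillar_geometry, ne_undeformed, params,
                                      rup0, state0=y0, t_end=2000.0)
        base = simulate(assemble_rhs(pillar_geometry, ne_undeformed, params),
                        y0, t_end=2000.0, params=params)
        assert np.allclose(traj.states[-1], base.states[-1], rtol=1e-6)

    def test_mass_conserved_with_open_pore(self, pillar_geometry,
                                           ne_undeformed, params,
                                           flat_steady):
        rup = RuptureSpec(sigma_ner=0.2, k_rupture=1e5, z_ne=3.2)
        traj = dynamic_rupture_course(pillar_geometry, ne_undeformed, params,
                                      rup, state0=flat_steady.steady.vector(),
                                      t_end=5000.0)
        from nanoyap.signaling import STATE_NAMES
        i = {n: k for k, n in enumerate(STATE_NAMES)}
        yap = params.v_cyto * (traj.states[:, i["yap_p"]]
                               + traj.states[:, i["yap_cyto"]]) \
            + params.v_nuc * traj.states[:, i["yap_nuc"]]
        assert np.abs(yap - yap[0]).max() / yap[0] < 1e-3

    def test_frozen_cytoskeleton_converges_to_closed_form(
            self, pillar_geometry, ne_undeformed, params, flat_steady):
        """With the cytoskeletal state frozen, the dynamic N/C settles on
        the closed-form rupture steady state within 2%."""
        from nanoyap.signaling import phi_free

        s = flat_steady.steady
        rup = RuptureSpec(sigma_ner=0.15, k_rupture=1e4, z_ne=3.2)
        traj = dynamic_rupture_course(
            pillar_geometry, ne_undeformed, params, rup,
            state0=s.vector(), t_end=20000.0, freeze_cytoskeleton=True)
        nc_dyn = float(traj.nc_ratio()[-1])
        closed = wellmixed_nc_with_rupture(
            phi_free(traj.steady), ne_undeformed, s["npc_a"], s["npc_a"],
            1.0, params.transport, rup)
        assert nc_dyn == pytest.approx(closed["nc_ratio"], rel=2e-2)
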