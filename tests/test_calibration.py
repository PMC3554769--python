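"""Biophysical calibration chain: unit conversions, binding equilibrium,
steady-state solving and full parameter derivation."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from emtmir.calibration import (AVOGADRO, CalibrationError, CalibrationPrimitives,
                                derive_parameter_set, equilibrium_complex,
                                halflife_to_rate, molecules_to_concentration,
                                solve_upstream_steady_state, sphere_geometry)
from emtmir.model import ModelDomainError, rhs_array


class TestConversions:
    @pytest.mark.parametrize("t_half,expected", [
        (math.log(2.0), 1.0),
        (30.0, math.log(2.0) / 30.0),
    ])
    def test_halflife_closed_form(self, t_half, expected):
        assert halflife_to_rate(t_half) == pytest.approx(expected, rel=1e-12)

    @given(st.floats(min_value=1e-3, max_value=1e5))
    def test_halflife_inverse_proportionality(self, t_half):
        assert halflife_to_rate(2 * t_half) == pytest.approx(
            halflife_to_rate(t_half) / 2, rel=1e-12)

    def test_molarity_of_avogadro_in_one_liter(self):
        assert molecules_to_concentration(AVOGADRO, 1.0) == pytest.approx(1.0)
        assert molecules_to_concentration(0.0, 1.0) == 0.0

    @given(st.floats(min_value=1.0, max_value=1e9),
           st.floats(min_value=1e-15, max_value=1.0))
    def test_molarity_intensive(self, count, volume):
        a = molecules_to_concentration(count, volume)
        b = molecules_to_concentration(2 * count, 2 * volume)
        assert b == pytest.approx(a, rel=1e-12)

    def test_sphere_unit_case(self):
        r, area = sphere_geometry(4.0 * math.pi / 3.0)
        assert r == pytest.approx(1.0)
        assert area == pytest.approx(4.0 * math.pi)

    @given(st.floats(min_value=1e-18, max_value=1e3))
    def test_sphere_algebraic_identity(self, volume):
        _, area = sphere_geometry(volume)
        assert area ** 3 == pytest.approx(36.0 * math.pi * volume ** 2, rel=1e-9)

    def test_sphere_scaling(self):
        r1, a1 = sphere_geometry(1.0)
        r2, a2 = sphere_geometry(8.0)
        assert r2 == pytest.approx(2 * r1)
        assert a2 == pytest.approx(4 * a1)

    @pytest.mark.parametrize("fn,args", [
        (halflife_to_rate, (0.0,)),
        (molecules_to_concentration, (1.0, -2.0)),
        (sphere_geometry, (-1.0,)),
        (equilibrium_complex, (1.0, 1.0, 0.0, 1.0)),
    ])
    def test_domain_errors(self, fn, args):
        with pytest.raises(ModelDomainError):
            fn(*args)


class TestBindingEquilibrium:
    def test_no_ligand_no_complex(self):
        assert equilibrium_complex(0.0, 1e5, 1e-4, 1.0) == 0.0

    def test_saturation_limit(self):
        assert equilibrium_complex(1e15, 1e5, 1e-4, 1.0) == pytest.approx(1e5, rel=1e-6)

    def test_half_occupancy_at_kd(self):
        kon, koff = 2.5e-4, 0.5
        kd = koff / kon
        assert equilibrium_complex(kd, 8e4, kon, koff) == pytest.approx(4e4)


class TestUpstreamSteadyState:
    def test_residual_contract(self, params):
        x6 = params.steady_state.let7
        x1, x2, x3 = solve_upstream_steady_state(params, x6)
        state = params.steady_state.as_array().copy()
        state[:3] = [x1, x2, x3]
        resid = rhs_array(state, params)[:3]
        turnover = np.array([params.deg_sos * x3 * x1, params.deg_ras * x2,
                             params.deg_erk * x3])
        assert np.all(np.abs(resid) / turnover < 1e-9)

    def test_zero_drive_gives_dead_cascade(self, params):
        p = dataclasses.replace(params, egfr_complex=0.0)
        assert solve_upstream_steady_state(p, params.steady_state.let7) == (0, 0, 0)

    def test_erk_monotone_in_egfr_level(self, params):
        x6 = params.steady_state.let7
        erks = [solve_upstream_steady_state(
            params.with_values(egfr_complex=m * params.egfr_complex), x6)[2]
            for m in np.geomspace(0.2, 20.0, 10)]
        assert np.all(np.diff(erks) > 0)


class TestDeriveParameterSet:
    def test_degradation_rates_from_half_lives(self, primitives, params):
        for species, key in [("myc", "myc"), ("mir9", "mir9"), ("let7", "let7"),
                             ("ecad", "ecad"), ("mmp", "mmp")]:
            expected = math.log(2.0) / primitives.half_lives[key]
            assert getattr(params, f"deg_{species}") == pytest.approx(expected, rel=1e-12)

    def test_totals_use_cytoplasm_volume(self, primitives, params):
        per_nM = 1e-9 * AVOGADRO * primitives.cytoplasm_volume
        assert params.sos_total == pytest.approx(primitives.molecule_counts["sos"] / per_nM)
        assert params.erk_total == pytest.approx(primitives.molecule_counts["erk"] / per_nM)

    def test_myc_uses_nucleus_volume(self, primitives, params):
        per_nM = 1e-9 * AVOGADRO * primitives.nucleus_volume
        assert params.steady_state.myc == pytest.approx(
            primitives.molecule_counts["myc_nucleus"] / per_nM)

    def test_mmp_steady_state_uses_tissue_density(self, primitives, params):
        expected = (primitives.mmp_copies_per_gram_tissue
                    * primitives.lung_tissue_density / AVOGADRO * 1e9)
        assert params.steady_state.mmp == pytest.approx(expected, rel=1e-12)

    def test_healthy_state_is_fixed_point(self, params):
        ss = params.steady_state.as_array()
        d = rhs_array(ss, params)
        deg = np.array([params.deg_sos * ss[2], params.deg_ras, params.deg_erk,
                        params.deg_myc, params.deg_mir9, params.deg_let7,
                        params.deg_ecad, params.deg_mmp])
        assert np.max(np.abs(d) / (deg * ss)) < 1e-6

    def test_closure_holds_for_other_primitives(self, primitives):
        """The fixed-point property is structural, not tuned to the defaults."""
        counts = dict(primitives.molecule_counts, let7=3e4, myc_nucleus=2e4)
        hl = dict(primitives.half_lives, myc=45.0, mmp=500.0)
        prim = dataclasses.replace(primitives, molecule_counts=counts,
                                   half_lives=hl, egf_count=2e4)
        p = derive_parameter_set(prim)
        ss = p.steady_state.as_array()
        d = rhs_array(ss, p)
        deg = np.array([p.deg_sos * ss[2], p.deg_ras, p.deg_erk, p.deg_myc,
                        p.deg_mir9, p.deg_let7, p.deg_ecad, p.deg_mmp])
        assert np.max(np.abs(d) / (deg * ss)) < 1e-6

    def test_volume_scaling_of_concentrations(self, primitives):
        """Scaling all volumes by c divides count-derived concentrations by c
        and leaves steady-state/Km saturation ratios unchanged."""
        c = 2.0
        scaled = dataclasses.replace(
            primitives,
            hela_total_volume=c * primitives.hela_total_volume,
            cytoplasm_volume=c * primitives.cytoplasm_volume,
            nucleus_volume=c * primitives.nucleus_volume)
        a, b = derive_parameter_set(primitives), derive_parameter_set(scaled)
        assert b.sos_total == pytest.approx(a.sos_total / c, rel=1e-12)
        assert b.steady_state.myc == pytest.approx(a.steady_state.myc / c, rel=1e-12)
        assert (b.steady_state.myc / b.k_myc_on_mir9 ==
                pytest.approx(a.steady_state.myc / a.k_myc_on_mir9, rel=1e-12))
        assert (b.sos_total / b.km_sos_act ==
                pytest.approx(a.sos_total / a.km_sos_act, rel=1e-12))

    def test_derivation_is_deterministic(self, primitives):
        a = derive_parameter_set(primitives)
        b = derive_parameter_set(CalibrationPrimitives.from_dict(primitives.to_dict()))
        assert a.to_dict() == b.to_dict()

    def test_invalid_primitives_name_the_step(self, primitives):
        bad = dataclasses.replace(primitives, cytoplasm_volume=2 * primitives.hela_total_volume)
        with pytest.raises(CalibrationError, match="cytoplasm"):
            derive_parameter_set(bad)
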