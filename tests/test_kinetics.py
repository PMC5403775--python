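import numpy as np
import pytest
from scipy.integrate import solve_ivp

import ritdose as rd
from ritdose.decay import MBQ_PER_ML_TO_BQ_PER_KG, InvalidParameterError
from ritdose.kinetics import (
    DEFAULT_BLOOD_VOLUME_ML,
    DEFAULT_FLUID_VOLUME_ML,
    DEFAULT_K_TRANSFER_PER_S,
)


class TestSpecificActivityRatio:
    def test_reported_ratio(self, product, nuclide):
        """45.6 GBq/umol implies ~3.3e3 antibodies per Bi-213 atom, 1:3000 rounded."""
        ratio = rd.antibody_per_nuclide_ratio(product, nuclide)
        assert ratio == pytest.approx(3346.0, rel=2e-3)
        assert rd.antibody_per_nuclide_ratio_rounded(product, nuclide) == 3000

    def test_one_atom_per_antibody_identity(self, nuclide):
        from ritdose.decay import AVOGADRO

        sa_bq_per_mol = AVOGADRO * nuclide.decay_constant
        p = rd.AntibodyProduct(sa_bq_per_mol / 1e15, 10.0, 1.0)
        assert rd.antibody_per_nuclide_ratio(p, nuclide) == pytest.approx(1.0, rel=1e-12)

    def test_inverse_proportionality(self, product, nuclide):
        half = rd.AntibodyProduct(
            product.specific_activity_gbq_per_umol / 2.0,
            product.injected_mass_ug,
            product.injected_volume_ml,
            immunoreactive_fraction=product.immunoreactive_fraction,
        )
        assert rd.antibody_per_nuclide_ratio(half, nuclide) == pytest.approx(
            2.0 * rd.antibody_per_nuclide_ratio(product, nuclide), rel=1e-12
        )


class TestTwoCompartmentModel:
    def test_decoupled_limit_is_pure_decay(self, nuclide):
        params = rd.CompartmentParams(0.0, 0.0)
        res = rd.simulate_biokinetics(params, 3e9, nuclide, horizon_s=3600.0)
        lam = nuclide.decay_constant
        np.testing.assert_allclose(
            res.fluid_tac.conc, 3e9 * np.exp(-lam * res.times), rtol=1e-10
        )
        assert np.all(res.blood_tac.conc == 0.0)

    def test_mass_balance(self, nuclide):
        res = rd.simulate_biokinetics(rd.default_params(), 3e9, nuclide)
        assert res.mass_balance_error() < 1e-3

    def test_nonnegative_and_fluid_monotone(self, nuclide):
        res = rd.simulate_biokinetics(rd.default_params(), 3e9, nuclide)
        assert np.all(res.fluid_tac.conc >= 0) and np.all(res.blood_tac.conc >= 0)
        assert np.all(np.diff(res.fluid_tac.conc) <= 0)

    def test_fast_transfer_depletes_fluid_integral(self, nuclide):
        lam = nuclide.decay_constant
        params = rd.CompartmentParams(k_transfer_per_s=50 * lam, k_clear_per_s=0.0)
        res = rd.simulate_biokinetics(params, 3e9, nuclide, horizon_s=8.0 / lam)
        a_fluid = rd.time_integrated_activity_conc(res.fluid_tac, nuclide, tail="none")
        # closed form: C0/(k_t + lambda) = C0/(51 lambda)
        assert a_fluid == pytest.approx(3e9 / (51 * lam), rel=5e-3)
        assert a_fluid < 0.05 * 3e9 / lam

    def test_matches_numeric_ode_solver(self, nuclide):
        """Closed-form solution vs an independent stiff ODE integration."""
        params = rd.default_params()
        lam = nuclide.decay_constant
        kt, kc = params.k_transfer_per_s, params.k_clear_per_s

        def rhs(t, y):
            f, b = y
            return [-(kt + lam) * f, kt * f - (kc + lam) * b]

        res = rd.simulate_biokinetics(params, 3e9, nuclide, horizon_s=3600.0)
        sol = solve_ivp(rhs, (0, 3600.0), [res.injected_bq, 0.0], t_eval=res.times,
                        rtol=1e-10, atol=1e-6, method="LSODA")
        np.testing.assert_allclose(res.fluid_bq, sol.y[0], rtol=1e-6)
        np.testing.assert_allclose(res.blood_bq, sol.y[1], rtol=1e-5, atol=1e-3)

    def test_default_transfer_rate_reproduces_blood_dose(self, nuclide):
        """k_transfer calibration: blood curve integrates to 1.3 Gy at 3 MBq/mL."""
        params = rd.default_params()
        res = rd.simulate_biokinetics(
            params, 3.0 * MBQ_PER_ML_TO_BQ_PER_KG, nuclide, horizon_s=20.0 / nuclide.decay_constant
        )
        dose = rd.blood_dose(res.blood_tac, nuclide, tail="physical").dose_gy
        assert dose == pytest.approx(1.3, rel=5e-3)

    def test_negative_rates_rejected(self):
        with pytest.raises(InvalidParameterError):
            rd.CompartmentParams(-1.0, 0.0)

    def test_calibration_closed_form(self, nuclide):
        kt = rd.calibrate_transfer_rate(1.3, 3e9, nuclide)
        assert kt == pytest.approx(DEFAULT_K_TRANSFER_PER_S, rel=1e-12)
        lam = nuclide.decay_constant
        v_ratio = DEFAULT_FLUID_VOLUME_ML / DEFAULT_BLOOD_VOLUME_ML
        tia = kt * 3e9 * v_ratio / ((kt + lam) * (1e-5 + lam))
        assert tia * nuclide.delta_j == pytest.approx(1.3, rel=1e-12)


class TestOccupancy:
    def test_instant_binding_limit(self):
        params = rd.CompartmentParams(0.0, 0.0, k_on_per_m_s=1e12, k_off_per_s=0.0)
        occ = rd.bound_fraction_vs_time(params, 1e-6, t_grid=np.array([0.0, 1e-3, 1.0]))
        assert occ.equilibrium_occupancy == pytest.approx(1.0)
        assert occ.occupancy[-1] == pytest.approx(1.0, rel=1e-6)
        assert occ.t95_s < 1e-5

    def test_saturation_within_minutes_at_study_concentration(self, product):
        """10 ug/mL antibody saturates antigen well inside 10 minutes."""
        occ = rd.bound_fraction_vs_time(rd.default_params(), product.molar_concentration())
        assert occ.t95_s < 600.0

    def test_irreversible_closed_form(self):
        params = rd.CompartmentParams(0.0, 0.0, k_on_per_m_s=1e5, k_off_per_s=0.0)
        c = 2e-8
        t = np.linspace(0.0, 2000.0, 50)
        occ = rd.bound_fraction_vs_time(params, c, t_grid=t)
        assert occ.equilibrium_occupancy == 1.0
        np.testing.assert_allclose(occ.occupancy, 1.0 - np.exp(-1e5 * c * t), rtol=1e-12)

    def test_zero_concentration_is_zero_occupancy(self):
        occ = rd.bound_fraction_vs_time(rd.default_params(), 0.0)
        assert np.all(occ.occupancy == 0.0)

    def test_monotone_in_time_and_concentration(self, product):
        params = rd.default_params()
        lo = rd.bound_fraction_vs_time(params, 1e-9)
        hi = rd.bound_fraction_vs_time(params, 1e-7)
        assert np.all(np.diff(lo.occupancy) >= 0)
        assert np.all(hi.occupancy >= lo.occupancy)
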