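import math

import numpy as np
import pytest
from scipy.integrate import quad

import ritdose as rd
from ritdose.decay import MEV_TO_J, InvalidParameterError
from ritdose.microdose import (
    SphericalCluster,
    _bath_batch,
    _chord_deposit_mev,
    _random_unit,
    bound_decays_per_cluster,
    default_range_model,
)


class TestRangeModel:
    def test_nodes_return_themselves(self):
        m = default_range_model()
        for e, r in zip(m.energies_mev, m.ranges_um):
            assert rd.alpha_range(e, m) == pytest.approx(r, rel=1e-12)

    def test_monotone_in_energy(self):
        m = default_range_model()
        assert rd.alpha_range(8.376, m) > rd.alpha_range(5.87, m)

    def test_midpoints_bracketed_by_adjacent_nodes(self):
        m = default_range_model()
        for i in range(len(m.energies_mev) - 1):
            mid = math.sqrt(m.energies_mev[i] * m.energies_mev[i + 1])
            r = rd.alpha_range(mid, m)
            assert m.ranges_um[i] < r < m.ranges_um[i + 1]

    def test_out_of_table_energy_rejected(self):
        with pytest.raises(InvalidParameterError):
            rd.alpha_range(20.0)

    def test_inverse_round_trip(self):
        m = default_range_model()
        for e in (0.7, 2.5, 5.87, 8.376):
            assert m.residual_energy_mev(m.range_um(e)) == pytest.approx(e, rel=1e-9)

    def test_tissue_ranges_are_plausible(self):
        # the two Bi-213 chain alphas: ~47 um and ~85 um in unit-density tissue
        assert rd.alpha_range(5.87) == pytest.approx(47.0, rel=0.02)
        assert rd.alpha_range(8.376) == pytest.approx(85.0, rel=0.02)


class TestTrackDeposition:
    def test_deposit_never_exceeds_emitted(self, nuclide):
        m = default_range_model()
        rng = np.random.default_rng(7)
        n = 20000
        x = rng.normal(scale=30.0, size=(n, 3))
        u = _random_unit(rng, n)
        e0 = np.full(n, 8.376)
        dep = _chord_deposit_mev(x, u, e0, 25.0, m)
        assert np.all(dep >= 0.0)
        assert np.all(dep <= e0 + 1e-12)

    def test_track_fully_inside_deposits_all_energy(self):
        m = default_range_model()
        x = np.array([[0.0, 0.0, 0.0]])
        u = np.array([[0.0, 0.0, 1.0]])
        e0 = np.array([5.0])
        dep = _chord_deposit_mev(x, u, e0, 1000.0, m)
        assert dep[0] == pytest.approx(5.0, rel=1e-9)

    def test_batch_energy_bookkeeping(self, nuclide):
        """Weighted deposits in a bath batch never exceed the emitted energy."""
        rng = np.random.default_rng(11)
        contrib, emitted, _ = _bath_batch(rng, 50000, 30.0, nuclide, "half-space",
                                          default_range_model())
        assert np.all(contrib >= 0.0)
        assert np.all(contrib <= emitted + 1e-25)
        assert contrib.sum() < emitted.sum()


class TestBathDose:
    def test_reproducible_bit_for_bit(self, nuclide):
        a = rd.bath_dose_per_tia(30.0, nuclide, histories=20000, seed=5)
        b = rd.bath_dose_per_tia(30.0, nuclide, histories=20000, seed=5)
        assert a == b

    def test_linear_in_bath_concentration(self, nuclide):
        cl = SphericalCluster(30.0)
        d1, _ = rd.dose_from_bath(cl, 1e12, nuclide, histories=20000, seed=5)
        d3, _ = rd.dose_from_bath(cl, 3e12, nuclide, histories=20000, seed=5)
        assert d3 == pytest.approx(3.0 * d1, rel=1e-12)
        assert d1 >= 0.0

    def test_standard_error_scales_as_inverse_sqrt_histories(self, nuclide):
        counts = [4000, 40000, 400000]
        ses = [rd.bath_dose_per_tia(30.0, nuclide, histories=n, seed=3)[1] for n in counts]
        slope = np.polyfit(np.log(counts), np.log(ses), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.1)

    def test_zero_histories_rejected(self, nuclide):
        with pytest.raises(InvalidParameterError):
            rd.bath_dose_per_tia(30.0, nuclide, histories=0)

    def test_unknown_geometry_rejected(self, nuclide):
        with pytest.raises(InvalidParameterError):
            rd.bath_dose_per_tia(30.0, nuclide, geometry="doughnut", histories=100)


class TestBoundDose:
    def test_zero_bound_activity_is_zero_dose(self, nuclide):
        cl = SphericalCluster(9.0)
        dose, se = rd.dose_from_bound(cl, 0.0, nuclide, histories=1000, seed=1)
        assert dose == 0.0

    def test_unknown_placement_rejected(self, nuclide):
        with pytest.raises(InvalidParameterError):
            rd.bound_dose_per_decay(9.0, nuclide, placement="everywhere", histories=100)

    def test_volume_self_dose_reaches_equilibrium_for_huge_sphere(self, nuclide):
        """Uniform volume source, radius >> range: mean deposit per decay = Delta."""
        g, se = rd.bound_dose_per_decay(2000.0, nuclide, placement="volume",
                                        histories=100000, seed=2)
        mass = 1000.0 * (4.0 / 3.0) * math.pi * (2000.0e-6) ** 3
        assert g * mass == pytest.approx(nuclide.delta_j, rel=0.01)

    def test_surface_source_matches_quadrature_oracle(self, nuclide):
        """MC vs an independent numeric integral over emission angles.

        For a surface decay, only the inward hemisphere intersects the
        sphere, along a chord 2 a cos(alpha); the mean deposit is
        (1/2) integral of [E(R0) - E(R0 - min(2a cos a, R0))] sin(a) da,
        branch-averaged.
        """
        a = 9.0
        m = default_range_model()

        def mean_dep_mev(e0):
            r0 = m.range_um(e0)

            def integrand(alpha):
                chord = min(2.0 * a * math.cos(alpha), r0)
                return (e0 - m.residual_energy_mev(r0 - chord)) * math.sin(alpha)

            val, _ = quad(integrand, 0.0, math.pi / 2.0, limit=200)
            return 0.5 * val

        oracle = sum(em.branch * mean_dep_mev(em.energy_mev) for em in nuclide.emissions)
        mass = 1000.0 * (4.0 / 3.0) * math.pi * (a * 1e-6) ** 3
        oracle_gy_per_decay = oracle * MEV_TO_J / mass
        mc, se = rd.bound_dose_per_decay(a, nuclide, placement="surface",
                                         histories=400000, seed=9)
        assert mc == pytest.approx(oracle_gy_per_decay, rel=0.02)


class TestScenarioAssembly:
    def test_total_is_specific_plus_unspecific(self, nuclide, product):
        df = rd.microtumor_dose_table([(3.0, product)], [9.0, 30.0], nuclide,
                                      histories=20000, seed=4)
        np.testing.assert_allclose(
            df["total_gy"], df["specific_gy"] + df["unspecific_gy"], rtol=1e-14
        )

    def test_specific_dose_saturation_invariance(self, nuclide, product):
        """With antigens saturated and mass scaling with activity, the specific
        dose barely rises from 3 to 9 MBq/mL."""
        prod9 = rd.AntibodyProduct(45.6, 30.0, 1.0, immunoreactive_fraction=0.91)
        df = rd.microtumor_dose_table([(3.0, product), (9.0, prod9)], [9.0], nuclide,
                                      histories=20000, seed=4)
        s3 = df[df.conc_mbq_per_ml == 3.0].specific_gy.iloc[0]
        s9 = df[df.conc_mbq_per_ml == 9.0].specific_gy.iloc[0]
        assert s9 >= s3
        assert s9 <= 1.1 * s3

    def test_single_cell_uses_all_antigens(self, nuclide, product):
        target = rd.CellTarget()
        params = rd.default_params()
        single = bound_decays_per_cluster(SphericalCluster(4.5), product, target,
                                          params, nuclide)
        cluster = bound_decays_per_cluster(SphericalCluster(9.0), product, target,
                                           params, nuclide)
        # surface-accessible antigens on an r=9 cluster are (9/4.5)^2 = 4x a cell's
        assert cluster == pytest.approx(4.0 * single, rel=1e-12)
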