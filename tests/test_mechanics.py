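"""Strain-energy signalling, migration direction and Hertz contact."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tislet import (CellState, MechanicsParams, Phenotype, attenuated_signal,
                    hertz_repulsion, migration_direction,
                    strain_energy_density, total_signal, velocity_parameter)
from tislet.mechanics import contact_overlap


def make_cell(i, pos, phenotype=Phenotype.EPITHELIAL, radius=8.0, force=30.0,
              elasticity=0.5):
    return CellState(id=i, phenotype=phenotype, position=np.array(pos, float),
                     radius=radius, force=force, elasticity=elasticity)


class TestStrainEnergyDensity:
    def test_zero_force_deposits_no_energy(self):
        assert strain_energy_density(0.0, 5.0, 8.0) == 0.0

    def test_reference_value(self):
        # F=30, E_s=5, R=8: F²/(2π² E_s R⁴) = 900/404258.99… ≈ 2.226e-3
        expected = 900.0 / (2.0 * math.pi ** 2 * 5.0 * 8.0 ** 4)
        assert strain_energy_density(30.0, 5.0, 8.0) == pytest.approx(expected)
        assert expected == pytest.approx(2.226e-3, rel=2e-4)

    @given(st.floats(0.1, 100.0), st.floats(0.5, 4.0))
    @settings(max_examples=50, deadline=None)
    def test_homogeneity(self, force, c):
        m = strain_energy_density(force, 5.0, 8.0)
        assert strain_energy_density(c * force, 5.0, 8.0) == \
            pytest.approx(c ** 2 * m, rel=1e-12)
        assert strain_energy_density(force, 5.0, c * 8.0) == \
            pytest.approx(m / c ** 4, rel=1e-12)

    @pytest.mark.parametrize("modulus,radius", [(0.0, 8.0), (-1.0, 8.0),
                                                (5.0, 0.0), (5.0, -2.0)])
    def test_invalid_arguments(self, modulus, radius):
        with pytest.raises(ValueError):
            strain_energy_density(30.0, modulus, radius)


class TestAttenuatedSignal:
    def test_probe_at_source(self):
        assert attenuated_signal(3.0, 1.0, [0, 0], [0, 0], 8.0) == 3.0

    def test_one_radius_one_efold(self):
        got = attenuated_signal(3.0, 1.0, [0, 0], [8.0, 0], 8.0)
        assert got == pytest.approx(3.0 * math.exp(-1.0), rel=1e-12)

    def test_monotone_decay(self):
        s1 = attenuated_signal(1.0, 2.0, [0, 0], [8.0, 0], 8.0)
        s2 = attenuated_signal(1.0, 2.0, [0, 0], [16.0, 0], 8.0)
        assert s2 < s1


class TestTotalSignal:
    def test_single_cell_senses_only_itself(self, params):
        c = make_cell(0, [0, 0])
        m0 = strain_energy_density(30.0, params.substrate_modulus, 8.0)
        assert total_signal(c, [c], params) == pytest.approx(m0)

    def test_two_cell_symmetry(self, params):
        a = make_cell(0, [0, 0])
        b = make_cell(1, [20.0, 0])
        m0 = strain_energy_density(30.0, params.substrate_modulus, 8.0)
        expected = m0 * (1.0 + math.exp(-params.attenuation * 20.0 / 8.0))
        assert total_signal(a, [a, b], params) == pytest.approx(expected)
        assert total_signal(b, [a, b], params) == \
            pytest.approx(total_signal(a, [a, b], params))

    def test_matches_brute_force_oracle(self, params, rng):
        cells = [make_cell(i, rng.uniform(-40, 40, 2),
                           force=rng.uniform(20, 40)) for i in range(10)]
        lam = params.attenuation
        for probe in cells:
            # independent double loop straight from the definition
            expected = 0.0
            for other in cells:
                m0 = other.force ** 2 / (2 * math.pi ** 2
                                         * params.substrate_modulus
                                         * other.radius ** 4)
                d = np.linalg.norm(probe.position - other.position)
                expected += m0 * (1.0 if other.id == probe.id
                                  else math.exp(-lam * d / other.radius))
            assert total_signal(probe, cells, params) == \
                pytest.approx(expected, rel=1e-12)

    def test_tlymphocytes_do_not_emit(self, params):
        a = make_cell(0, [0, 0])
        t = make_cell(1, [10.0, 0], phenotype=Phenotype.TLYMPHOCYTE,
                      radius=5.0, elasticity=250.0)
        assert total_signal(a, [a, t], params) == \
            pytest.approx(total_signal(a, [a], params))


class TestMigrationDirection:
    def test_two_cells_point_away_from_neighbour(self, params):
        a = make_cell(0, [0, 0])
        b = make_cell(1, [20.0, 0])
        z = migration_direction(a, [a, b], params)
        assert z == pytest.approx([-1.0, 0.0])

    def test_equilateral_centroid_cancels(self, params):
        centre = make_cell(0, [0.0, 0.0])
        others = [make_cell(i + 1, [30 * math.cos(a), 30 * math.sin(a)])
                  for i, a in enumerate(np.arange(3) * 2 * math.pi / 3)]
        z = migration_direction(centre, [centre] + others, params)
        assert np.allclose(z, 0.0)

    def test_asymmetric_matches_brute_force(self, params):
        cells = [make_cell(0, [0, 0]), make_cell(1, [15.0, 3.0]),
                 make_cell(2, [-4.0, 11.0])]
        lam = params.attenuation
        z = np.zeros(2)
        for other in cells[1:]:
            m0 = strain_energy_density(other.force, params.substrate_modulus,
                                       other.radius)
            diff = cells[0].position - other.position
            d = np.linalg.norm(diff)
            z += m0 * math.exp(-lam * d / other.radius) * diff / d
        expected = z / np.linalg.norm(z)
        got = migration_direction(cells[0], cells, params)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_unit_norm_or_zero(self, params, rng):
        cells = [make_cell(i, rng.uniform(-50, 50, 2)) for i in range(8)]
        for c in cells:
            z = migration_direction(c, cells, params)
            n = np.linalg.norm(z)
            assert n == pytest.approx(1.0, abs=1e-9) or n == 0.0

    def test_coincident_positions_never_divide_by_zero(self, params):
        a = make_cell(0, [5.0, 5.0])
        b = make_cell(1, [5.0, 5.0])
        z = migration_direction(a, [a, b], params)
        assert np.all(np.isfinite(z))


class TestVelocityParameter:
    def test_reference_value(self):
        assert velocity_parameter(60.0, 8.0, 0.2, 30.0) == pytest.approx(5120.0)

    def test_scalings(self):
        a = velocity_parameter(60.0, 8.0, 0.2, 30.0)
        assert velocity_parameter(60.0, 8.0, 0.4, 30.0) == pytest.approx(a / 2)
        assert velocity_parameter(60.0, 16.0, 0.2, 30.0) == pytest.approx(8 * a)

    def test_zero_force_rejected(self):
        with pytest.raises(ValueError):
            velocity_parameter(60.0, 8.0, 0.2, 0.0)


class TestHertzRepulsion:
    def test_no_overlap_no_force(self):
        assert hertz_repulsion(0.5, 0.0, 8.0) == 0.0
        assert hertz_repulsion(0.5, -3.0, 8.0) == 0.0

    def test_reference_value(self):
        # h = R: (4/(15√2))·(E_c/π)·1^{5/2} with E_c = 0.5
        expected = 4.0 / (15.0 * math.sqrt(2.0)) * 0.5 / math.pi
        assert hertz_repulsion(0.5, 8.0, 8.0) == pytest.approx(expected)
        assert expected == pytest.approx(0.0300, abs=5e-5)

    @given(st.floats(0.1, 8.0))
    @settings(max_examples=30, deadline=None)
    def test_power_law_scaling(self, h):
        assert hertz_repulsion(0.5, 2 * h, 16.0) == pytest.approx(
            2.0 ** 2.5 * hertz_repulsion(0.5, h, 16.0), rel=1e-12)

    def test_continuous_at_contact(self):
        assert hertz_repulsion(0.5, 1e-12, 8.0) == pytest.approx(0.0, abs=1e-20)

    def test_overlap_helper_clips(self):
        assert contact_overlap([0, 0], [20, 0], 8.0, 8.0) == 0.0
        assert contact_overlap([0, 0], [10, 0], 8.0, 8.0) == pytest.approx(6.0)
        assert contact_overlap([0, 0], [10, 0], 8.0, 5.0) == pytest.approx(3.0)
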