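import math

import numpy as np
import pytest

from thalamap.swc import Compartment, CompartmentSeries, resample_compartments
from thalamap.synthetic import circular_boundary
from thalamap.tropism import (
    RAD_TO_DEG,
    NucleusGeometry,
    TropismProfile,
    average_angular_deviation,
    classify_edge,
    compartment_deviation,
    deviation_vs_distance,
    proportion_closer_than_soma,
    tropism_profile,
)
from trees import random_neuron

ORIGIN = np.zeros(3)


def unit_compartment(origin, direction, length=1.0):
    origin = np.asarray(origin, float)
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    return Compartment(
        origin, origin + length * direction, length, 3, 1
    )


def series_of(compartments):
    return CompartmentSeries("test", list(compartments))


class TestCompartmentDeviation:
    def test_toward_center(self):
        assert compartment_deviation(
            [10, 0, 0], [9, 0, 0], ORIGIN
        ) == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal(self):
        assert compartment_deviation(
            [10, 0, 0], [10, 1, 0], ORIGIN
        ) == pytest.approx(math.pi / 2, abs=1e-12)

    def test_away_from_center(self):
        assert compartment_deviation(
            [10, 0, 0], [11, 0, 0], ORIGIN
        ) == pytest.approx(math.pi, abs=1e-12)

    def test_origin_at_center_is_excluded(self):
        assert math.isnan(compartment_deviation([0, 0, 0], [1, 0, 0], ORIGIN))


class TestAverageDeviation:
    def test_single_toward_center(self):
        series = series_of([unit_compartment([10, 0, 0], [-1, 0, 0])])
        assert average_angular_deviation(series, ORIGIN) == pytest.approx(0.0)

    def test_six_axis_symmetry(self):
        directions = [
            [1, 0, 0], [-1, 0, 0],
            [0, 1, 0], [0, -1, 0],
            [0, 0, 1], [0, 0, -1],
        ]
        series = series_of(
            unit_compartment([10, 0, 0], d) for d in directions
        )
        # deviations {pi, 0, pi/2 x4} -> mean pi/2
        assert average_angular_deviation(series, ORIGIN) == pytest.approx(
            math.pi / 2
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_arccos_oracle(self, seed):
        neuron = random_neuron(seed, kappa=1.5)
        series = resample_compartments(neuron)
        devs = []
        for c in series:
            v = c.endpoint - c.origin
            core = ORIGIN - c.origin
            cosang = float(v @ core) / (
                np.linalg.norm(v) * np.linalg.norm(core)
            )
            devs.append(math.acos(max(-1.0, min(1.0, cosang))))
        assert average_angular_deviation(series, ORIGIN) == pytest.approx(
            float(np.mean(devs)), abs=1e-9
        )

    def test_rotation_about_soma_center_axis_invariant(self):
        # soma on the x axis, center at the origin: rotate about x
        neuron = random_neuron(3, kappa=2.0)
        series = resample_compartments(neuron)
        angle = 1.1
        c, s = math.cos(angle), math.sin(angle)
        rot = np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)
        rotated = series_of(
            Compartment(rot @ cp.origin, rot @ cp.endpoint, cp.length, 3, 1)
            for cp in series
        )
        assert average_angular_deviation(rotated, ORIGIN) == pytest.approx(
            average_angular_deviation(series, ORIGIN), abs=1e-9
        )

    def test_all_excluded_raises(self):
        series = series_of([unit_compartment([0, 0, 0], [1, 0, 0])])
        with pytest.raises(ValueError, match="excluded"):
            average_angular_deviation(series, ORIGIN)


class TestProportionCloser:
    def test_all_between_soma_and_center(self):
        soma = np.array([10.0, 0.0, 0.0])
        series = series_of(
            [unit_compartment([5, 0, 0], [-1, 0, 0]),
             unit_compartment([3, 0, 0], [-1, 0, 0])]
        )
        assert proportion_closer_than_soma(series, soma, ORIGIN) == 1.0

    def test_all_farther(self):
        soma = np.array([10.0, 0.0, 0.0])
        series = series_of([unit_compartment([20, 0, 0], [1, 0, 0])])
        assert proportion_closer_than_soma(series, soma, ORIGIN) == 0.0

    def test_half_and_half(self):
        soma = np.array([10.0, 0.0, 0.0])
        series = series_of(
            [unit_compartment([5, 0, 0], [0, 1, 0]),
             unit_compartment([20, 0, 0], [0, 1, 0])]
        )
        assert proportion_closer_than_soma(series, soma, ORIGIN) == 0.5

    def test_scaling_about_center_invariant(self):
        soma = np.array([10.0, 0.0, 0.0])
        rng = np.random.default_rng(0)
        comps = [
            unit_compartment(rng.uniform(-30, 30, 3), rng.normal(size=3))
            for _ in range(50)
        ]
        base = proportion_closer_than_soma(series_of(comps), soma, ORIGIN)
        scaled = [
            Compartment(3.0 * c.origin, 3.0 * c.endpoint, 3.0 * c.length, 3, 1)
            for c in comps
        ]
        assert proportion_closer_than_soma(
            series_of(scaled), 3.0 * soma, ORIGIN
        ) == pytest.approx(base)


class TestClassifyEdge:
    @pytest.fixture
    def geometry(self):
        return NucleusGeometry(
            center=ORIGIN, boundary=circular_boundary((0, 0), 100.0)
        )

    def test_soma_on_boundary_is_edge(self, geometry):
        assert classify_edge([100, 0, 0], geometry) == "edge"

    def test_soma_at_center_is_non_edge(self, geometry):
        assert classify_edge([0, 0, 0], geometry) == "non-edge"

    def test_ninety_percent_radius_is_edge(self, geometry):
        assert classify_edge([0, 90, 0], geometry) == "edge"

    def test_mid_radius_is_non_edge(self, geometry):
        assert classify_edge([35, 35, 0], geometry) == "non-edge"

    def test_outside_warns_and_is_edge(self, geometry):
        with pytest.warns(UserWarning, match="outside"):
            assert classify_edge([150, 0, 0], geometry) == "edge"

    def test_spherical_radius_model(self):
        geometry = NucleusGeometry(center=ORIGIN, radius_um=100.0)
        assert classify_edge([90, 0, 0], geometry) == "edge"
        assert classify_edge([10, 0, 0], geometry) == "non-edge"

    def test_absolute_threshold(self):
        geometry = NucleusGeometry(
            center=ORIGIN, radius_um=100.0,
            edge_threshold=5.0, threshold_kind="um",
        )
        assert classify_edge([96, 0, 0], geometry) == "edge"
        assert classify_edge([90, 0, 0], geometry) == "non-edge"

    def test_center_outside_boundary_rejected(self):
        with pytest.raises(ValueError, match="inside"):
            NucleusGeometry(
                center=np.array([500.0, 0.0, 0.0]),
                boundary=circular_boundary((0, 0), 100.0),
            )


class TestRadiallySymmetricArbor:
    def test_mean_deviation_is_half_pi(self):
        # compartments whose directions are isotropic independent of their
        # positions: the textbook radially symmetric arbor around the center
        rng = np.random.default_rng(0)
        comps = []
        for _ in range(5000):
            origin = rng.normal(scale=30.0, size=3)
            direction = rng.normal(size=3)
            comps.append(unit_compartment(origin, direction))
        series = series_of(comps)
        assert average_angular_deviation(series, ORIGIN) == pytest.approx(
            math.pi / 2, abs=0.1
        )


class TestDeviationVsDistance:
    def _profile(self, dist, dev):
        return TropismProfile(f"n{dist}", dist, dev, 0.5, "non-edge")

    def test_exact_negative_linear(self):
        profiles = [self._profile(d, 2.0 - 0.01 * d) for d in (10, 20, 30, 40)]
        result = deviation_vs_distance(profiles)
        assert result.statistic == pytest.approx(-1.0)

    def test_constant_deviation_raises(self):
        profiles = [self._profile(d, 1.0) for d in (10, 20, 30)]
        with pytest.raises(ValueError, match="variance"):
            deviation_vs_distance(profiles)

    def test_too_few_profiles(self):
        with pytest.raises(ValueError):
            deviation_vs_distance([self._profile(1, 1.0)])


def test_rad_to_deg_constant():
    assert round(RAD_TO_DEG, 1) == 57.3


def test_tropism_profile_end_to_end():
    geometry = NucleusGeometry(
        center=ORIGIN, boundary=circular_boundary((0, 0), 400.0)
    )
    profile = tropism_profile(random_neuron(1, kappa=4.0), geometry)
    assert 0.0 <= profile.average_angular_deviation <= math.pi
    assert 0.0 <= profile.proportion_closer <= 1.0
    assert profile.soma_center_distance == pytest.approx(300.0)
    assert profile.edge_class in ("edge", "non-edge")
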