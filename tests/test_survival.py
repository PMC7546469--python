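import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from hsscreen.cassette import (
    Cassette,
    CompoundRecord,
    ValidationError,
    WellObservation,
)
from hsscreen.survival import (
    ControlExtinctError,
    dc_derivative,
    derivative_set,
    dt_derivative,
    mean_condition_survival,
    normalize,
    per_molar_to_per_millimolar,
    surfaces_from_cassette,
    survival_rate,
)
from conftest import CONCS, TEMPS, make_surface

finite_sn = st.floats(min_value=0.0, max_value=5.0, allow_nan=False)


class TestSurvivalRate:
    @pytest.mark.parametrize(
        "alive,total,expected", [(12, 24, 0.5), (20, 20, 1.0), (0, 23, 0.0)]
    )
    def test_examples(self, alive, total, expected):
        assert survival_rate(alive, total) == expected

    def test_zero_total_is_undefined_well(self):
        with pytest.raises(ValidationError, match="positive"):
            survival_rate(0, 0)

    def test_alive_above_total_rejected(self):
        with pytest.raises(ValidationError):
            survival_rate(5, 4)


def well(alive, total, rep=1):
    return WellObservation("c", 1e-6, 38.0, alive, total, rep)


class TestMeanConditionSurvival:
    def test_unweighted_mean(self):
        wells = [well(8, 20, 1), well(10, 20, 2), well(12, 20, 3)]
        assert mean_condition_survival(wells) == pytest.approx(0.5)

    def test_single_well_identity(self):
        assert mean_condition_survival([well(16, 20)]) == pytest.approx(0.8)

    def test_equal_rates_different_totals(self):
        wells = [well(10, 20, 1), well(12, 24, 2), well(15, 30, 3)]
        assert mean_condition_survival(wells) == pytest.approx(0.5)

    def test_pooled_mode_weights_by_worms(self):
        # rates 0.5 and 1.0; unweighted mean 0.75, pooled (5+40)/(10+40)=0.9
        wells = [well(5, 10, 1), well(40, 40, 2)]
        assert mean_condition_survival(wells) == pytest.approx(0.75)
        assert mean_condition_survival(wells, pooled=True) == pytest.approx(0.9)

    def test_permutation_invariance(self):
        wells = [well(3, 21, 1), well(19, 25, 2), well(11, 23, 3)]
        assert mean_condition_survival(wells) == mean_condition_survival(wells[::-1])

    def test_empty_collection_rejected(self):
        with pytest.raises(ValidationError):
            mean_condition_survival([])


class TestNormalize:
    @pytest.mark.parametrize(
        "s,control,expected", [(0.45, 0.9, 0.5), (0.9, 0.9, 1.0), (0.9, 0.6, 1.5)]
    )
    def test_ratio(self, s, control, expected):
        assert normalize(s, control) == pytest.approx(expected)

    def test_extinct_control_is_error(self):
        with pytest.raises(ControlExtinctError):
            normalize(0.5, 0.0)


class TestDerivatives:
    def test_flat_surface_has_zero_derivatives(self):
        surface = make_surface("c", [1.0] * 6)
        for t in TEMPS:
            assert dc_derivative(surface, t) == 0.0
        for c in CONCS:
            assert dt_derivative(surface, c) == 0.0

    def test_dc_against_arithmetic_oracle(self):
        surface = make_surface(
            "c", {(1e-6, 38.0): 1.0, (1e-5, 38.0): 1.009, (1e-4, 38.0): 1.09}
        )
        # independent arithmetic: mean of the two forward differences
        oracle = ((1.009 - 1.0) / 9e-6 + (1.09 - 1.009) / 9e-5) / 2
        assert oracle == pytest.approx(950.0)
        assert dc_derivative(surface, 38.0) == pytest.approx(950.0)

    def test_dc_antisymmetry(self):
        surface = make_surface(
            "c", {(1e-6, 40.0): 1.0, (1e-5, 40.0): 0.991, (1e-4, 40.0): 0.91}
        )
        assert dc_derivative(surface, 40.0) == pytest.approx(-950.0)

    @pytest.mark.parametrize(
        "low,high,expected", [(0.8, 1.0, 0.1), (1.2, 0.8, -0.2), (0.7, 0.7, 0.0)]
    )
    def test_dt_finite_difference(self, low, high, expected):
        surface = make_surface("c", {(1e-5, 38.0): low, (1e-5, 40.0): high})
        assert dt_derivative(surface, 1e-5) == pytest.approx(expected)

    def test_missing_cell_propagates_as_absent(self):
        surface = make_surface("c", {(1e-6, 38.0): 1.0, (1e-5, 38.0): 1.1})
        with pytest.raises(ValidationError, match="missing cell"):
            dc_derivative(surface, 38.0)
        derivs = derivative_set(surface)
        assert derivs.dc == {} and derivs.dt == {}

    @given(
        sn=st.lists(finite_sn, min_size=6, max_size=6),
        k=st.floats(min_value=0.1, max_value=10, allow_nan=False),
    )
    def test_dc_linearity_in_surface(self, sn, k):
        base = make_surface("c", sn)
        scaled = make_surface("c", [v * k for v in sn])
        for t in TEMPS:
            assert dc_derivative(scaled, t) == pytest.approx(
                k * dc_derivative(base, t), rel=1e-9, abs=1e-9
            )

    def test_millimolar_conversion_round_trip(self):
        assert per_molar_to_per_millimolar(950.0) == pytest.approx(0.95)
        assert per_molar_to_per_millimolar(per_molar_to_per_millimolar(1.0) * 1e6) == 1.0


class TestSurfacesFromCassette:
    @staticmethod
    def build(control_alive_40=10):
        compounds = (CompoundRecord("A"),)
        obs = []
        for conc in CONCS:
            for temp in TEMPS:
                obs.append(WellObservation("A", conc, temp, 10, 20, 1))
        obs.append(WellObservation("A", 0.0, 38.0, 10, 20, 1))
        obs.append(WellObservation("A", 0.0, 40.0, control_alive_40, 20, 1))
        return Cassette(compounds, observations=tuple(obs))

    def test_normalization_against_own_controls(self):
        surfaces = surfaces_from_cassette(self.build())
        surface = surfaces["A"]
        assert surface.is_complete
        for cell in surface.sn:
            assert surface.sn[cell] == pytest.approx(1.0)

    def test_extinct_control_drops_cells_not_pipeline(self):
        surfaces = surfaces_from_cassette(self.build(control_alive_40=0))
        surface = surfaces["A"]
        assert not surface.is_complete
        assert all(t == 40.0 for _, t in surface.missing_cells)
        assert all(math.isfinite(v) for v in surface.sn.values())

    def test_shared_dmso_control_fallback(self):
        compounds = (CompoundRecord("A"), CompoundRecord("DMSO"))
        obs = [
            WellObservation("A", c, t, 15, 20, 1) for c in CONCS for t in TEMPS
        ]
        obs += [
            WellObservation("DMSO", 0.0, 38.0, 15, 20, 1),
            WellObservation("DMSO", 0.0, 40.0, 5, 20, 1),
        ]
        surfaces = surfaces_from_cassette(Cassette(compounds, observations=tuple(obs)))
        assert "DMSO" not in surfaces
        assert surfaces["A"].sn[(1e-6, 38.0)] == pytest.approx(1.0)
        assert surfaces["A"].sn[(1e-6, 40.0)] == pytest.approx(3.0)
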