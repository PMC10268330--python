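import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from protoendo.dosing import (
    BUFFER,
    LIPID,
    SolutionState,
    StimulusSpec,
    StockSpec,
    apply_stimulus,
    buffer_volume_for_shock,
    dilute,
    micelle_volume_for_growth,
)
from protoendo.errors import InfeasibleStockError

BUFFER_STOCK = StockSpec(BUFFER, 1000.0)
MICELLE_STOCK = StockSpec(LIPID, 100.0)


def well(volume=100.0, bicine=50.0, oleate=0.5):
    return SolutionState(volume=volume,
                         concentrations={BUFFER: bicine, LIPID: oleate})


class TestBufferVolume:
    @pytest.mark.parametrize("dcv,printed", [
        (25.0, 2.70), (50.0, 5.56), (100.0, 11.76)])
    def test_reported_stimulus_volumes(self, dcv, printed):
        v = buffer_volume_for_shock(well(), BUFFER_STOCK, dcv)
        assert round(v, 2) == printed

    def test_zero_shock_zero_volume(self):
        assert buffer_volume_for_shock(well(), BUFFER_STOCK, 0.0) == 0.0

    def test_infeasible_stock_rejected(self):
        with pytest.raises(InfeasibleStockError):
            buffer_volume_for_shock(well(), StockSpec(BUFFER, 60.0), 25.0)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(dcv=st.floats(0.1, 400.0), v0=st.floats(10.0, 1000.0))
    def test_mixing_reproduces_target_concentration(self, dcv, v0):
        state = SolutionState(volume=v0, concentrations={BUFFER: 50.0})
        v = buffer_volume_for_shock(state, BUFFER_STOCK, dcv)
        c_final = (50.0 * v0 + BUFFER_STOCK.concentration * v) / (v0 + v)
        assert c_final == pytest.approx(50.0 + dcv, rel=1e-9)


class TestMicelleVolume:
    @pytest.mark.parametrize("dca,printed", [
        (0.5, 0.5), (1.0, 1.0), (2.5, 2.5), (5.0, 5.0)])
    def test_nominal_volumes_match_reported_cells(self, dca, printed):
        v = micelle_volume_for_growth(well(), MICELLE_STOCK, dca, "nominal")
        assert v == pytest.approx(printed, rel=1e-12)

    def test_zero_addition(self):
        assert micelle_volume_for_growth(well(), MICELLE_STOCK, 0.0) == 0.0

    def test_exact_vs_nominal_bounded_over_condition_grid(self):
        """Self-dilution corrections over the 3x4 stimulus grid: small
        for dilute additions, up to ~6% at the strongest micelle dose."""
        for dca in (0.5, 1.0, 2.5, 5.0):
            nom = micelle_volume_for_growth(well(), MICELLE_STOCK, dca,
                                            "nominal")
            exact = micelle_volume_for_growth(well(), MICELLE_STOCK, dca,
                                              "exact")
            rel = abs(exact - nom) / nom
            assert rel < 0.065
            if dca <= 1.0:
                assert rel < 0.02

    def test_exact_mode_mixing_reproduces_target(self):
        v = micelle_volume_for_growth(well(), MICELLE_STOCK, 5.0, "exact")
        c_final = (0.5 * 100.0 + 100.0 * v) / (100.0 + v)
        assert c_final == pytest.approx(5.5, rel=1e-9)


class TestDilute:
    def test_tenfold_dilution_of_lipid(self):
        state = SolutionState(volume=10.0, concentrations={LIPID: 5.0})
        out = dilute(state, 1, 9, {BUFFER: 50.0})
        assert out.conc(LIPID) == pytest.approx(0.5)
        assert out.volume == pytest.approx(100.0)

    def test_identity_dilution(self):
        state = well()
        out = dilute(state, 1, 0)
        assert out.concentrations == state.concentrations

    def test_matched_diluent_is_fixed_point(self):
        state = SolutionState(volume=10.0, concentrations={BUFFER: 50.0})
        out = dilute(state, 1, 9, {BUFFER: 50.0})
        assert out.conc(BUFFER) == pytest.approx(50.0)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(c=st.floats(0.0, 100.0), parts=st.integers(1, 20))
    def test_dilution_conserves_moles(self, c, parts):
        state = SolutionState(volume=10.0, concentrations={LIPID: c})
        out = dilute(state, 1, parts)
        assert out.conc(LIPID) * out.volume == pytest.approx(
            c * 10.0, rel=1e-12, abs=1e-12)


class TestApplyStimulus:
    def test_two_sequential_events_reach_reported_endpoint(self):
        state = well()
        stim = StimulusSpec(dcv=100.0, dca=2.5)
        for _ in range(2):
            state = apply_stimulus(state, stim, mode="nominal")
        assert state.conc(BUFFER) == pytest.approx(250.0)
        assert state.conc(LIPID) == pytest.approx(5.5)

    def test_single_event_intermediate(self):
        out = apply_stimulus(well(), StimulusSpec(dcv=100.0, dca=2.5))
        assert out.conc(BUFFER) == pytest.approx(150.0)
        assert out.conc(LIPID) == pytest.approx(3.0)

    def test_zero_stimulus_is_identity(self):
        out = apply_stimulus(well(), StimulusSpec())
        assert out.concentrations == well().concentrations

    def test_exact_mode_conserves_moles_of_each_species(self):
        vb = buffer_volume_for_shock(well(), BUFFER_STOCK, 100.0)
        vm = micelle_volume_for_growth(well(), MICELLE_STOCK, 2.5, "exact")
        out = apply_stimulus(well(), StimulusSpec(dcv=100.0, dca=2.5),
                             mode="exact", buffer_stock=BUFFER_STOCK,
                             micelle_stock=MICELLE_STOCK)
        assert out.volume == pytest.approx(100.0 + vb + vm, rel=1e-12)
        assert out.conc(BUFFER) * out.volume == pytest.approx(
            50.0 * 100.0 + 1000.0 * vb, rel=1e-12)
        assert out.conc(LIPID) * out.volume == pytest.approx(
            0.5 * 100.0 + 100.0 * vm, rel=1e-12)
        # each species lands near its nominal target; the cross-dilution
        # by the other stock's volume costs ~10% at the strongest shock
        assert out.conc(BUFFER) == pytest.approx(150.0, rel=0.03)
        assert out.conc(LIPID) == pytest.approx(3.0, rel=0.12)

    def test_co_added_tracer_recorded(self):
        out = apply_stimulus(
            well(), StimulusSpec(dcv=100.0, dca=2.5,
                                 co_added={"cGAMPfluo": 0.1}))
        assert out.conc("cGAMPfluo") == pytest.approx(0.1)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(dcv=st.floats(1.0, 300.0), dca=st.floats(0.1, 5.0))
    def test_nominal_and_exact_agree_for_concentrated_stocks(self, dcv, dca):
        strong_buffer = StockSpec(BUFFER, 1e7)
        strong_micelle = StockSpec(LIPID, 1e7)
        nom = apply_stimulus(well(), StimulusSpec(dcv=dcv, dca=dca),
                             mode="nominal")
        exact = apply_stimulus(well(), StimulusSpec(dcv=dcv, dca=dca),
                               mode="exact", buffer_stock=strong_buffer,
                               micelle_stock=strong_micelle)
        assert exact.conc(BUFFER) == pytest.approx(nom.conc(BUFFER), rel=1e-3)
        assert exact.conc(LIPID) == pytest.approx(nom.conc(LIPID), rel=1e-3)
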