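"""Simulator physics: closed-form auto-PEEP, PEEP shift, flow-limitation
envelope behaviour, occlusion equilibration, calibration."""
import math

import numpy as np
import pytest

from peepabsorb import (
    Compartment,
    LungModel,
    VentilatorSettings,
    calibrate_two_compartment_patient,
    occluded_total_peep,
    simulate_breaths,
    simulate_occlusion,
    steady_state_autopeep,
    steady_state_volumes,
)
from peepabsorb.errors import (
    CalibrationError,
    InvalidModelError,
    InvalidSettingsError,
    StepSizeError,
)
from peepabsorb.mechanics import measure_plateau
from peepabsorb.simulator import (
    _calibrate_nonfl_resistance,
    advance_breaths,
    closed_form_autopeep,
)


def _simulated_autopeep(model, settings, fs=100.0):
    """Auto-PEEP measured the bedside way: breathe to steady state from
    relaxation volume, occlude at end-expiration, read the plateau."""
    v = advance_breaths(model, settings, np.zeros(model.n_compartments), 200)
    occ = simulate_occlusion(model, settings, v, "end_expiratory", 4.0,
                             sample_rate=fs, seed=0)
    return measure_plateau(occ) - settings.applied_peep


class TestClosedFormOracle:
    def test_reference_case(self, single_rc, default_settings):
        # tau = 1 s, Te = 2 s: auto-PEEP = (VT/C)/(e^2 - 1) = 10/6.389
        expected = 10.0 / (math.e**2 - 1.0)
        assert expected == pytest.approx(1.565, abs=5e-4)
        sim = _simulated_autopeep(single_rc, default_settings)
        assert sim == pytest.approx(expected, rel=0.01)

    @pytest.mark.parametrize("r,c,te", [
        (5.0, 0.03, 0.75), (10.0, 0.05, 1.5), (30.0, 0.1, 3.0),
        (20.0, 0.03, 3.0), (5.0, 0.1, 0.75),
    ])
    def test_grid_subset(self, r, c, te):
        model = LungModel((Compartment(resistance=r, compliance=c),),
                          noise_sd=0.0)
        settings = VentilatorSettings(0.5, 60.0 / (te + 1.0), 1.0)
        sim = _simulated_autopeep(model, settings)
        oracle = closed_form_autopeep(0.5, c, te, 1.0 / (r * c))
        assert sim == pytest.approx(oracle, rel=0.01)

    def test_long_expiration_limit(self, single_rc):
        settings = VentilatorSettings(0.5, 2.0, 1.0)   # Te = 29 s >> tau
        assert steady_state_autopeep(single_rc, settings) < 1e-6


class TestPeepShift:
    @pytest.mark.parametrize("peep", [2.0, 5.0, 8.0])
    def test_nonfl_autopeep_invariant_to_peep(self, single_rc,
                                              default_settings, peep):
        """Without flow limitation, applied PEEP shifts the equilibrium by
        exactly the applied PEEP: auto-PEEP is unchanged."""
        ap0 = steady_state_autopeep(single_rc, default_settings)
        ap = steady_state_autopeep(single_rc, default_settings.with_peep(peep))
        assert ap == pytest.approx(ap0, abs=0.1)

    def test_pure_fl_complete_absorption(self, default_settings):
        """A fully envelope-governed expiration shields the compartment from
        any applied PEEP below its auto-PEEP: total PEEP does not change."""
        k = math.log(1 + 0.5 * 19.0 / 10.0) / 2.0
        comp = Compartment(resistance=20.0, compliance=1 / 19.0,
                           flow_limited=True, envelope_slope=k,
                           expiratory_resistance=2.0)
        model = LungModel((comp,), noise_sd=0.0)
        p0 = occluded_total_peep(model, default_settings)
        assert p0 == pytest.approx(10.0, abs=0.05)
        for peep in (2.0, 5.0, 8.0):
            p = occluded_total_peep(model, default_settings.with_peep(peep))
            assert p == pytest.approx(p0, abs=1e-6)


class TestMonotonicity:
    def test_autopeep_monotone_in_te_and_vt(self):
        comp = Compartment(resistance=25.0, compliance=0.05)
        model = LungModel((comp,), noise_sd=0.0)
        aps = [steady_state_autopeep(model, VentilatorSettings(0.5, 60 / (te + 1), 1.0))
               for te in (1.0, 1.5, 2.0, 3.0, 4.0)]
        assert all(a >= b - 1e-12 for a, b in zip(aps, aps[1:]))
        aps_vt = [steady_state_autopeep(model, VentilatorSettings(vt, 20.0, 1.0))
                  for vt in (0.3, 0.4, 0.5, 0.6)]
        assert all(b >= a - 1e-12 for a, b in zip(aps_vt, aps_vt[1:]))


class TestWaveforms:
    def test_mass_conservation_and_volume_zeroing(self, single_rc,
                                                  default_settings):
        v0 = steady_state_volumes(single_rc, default_settings)
        rec = simulate_breaths(single_rc, default_settings, 3,
                               sample_rate=100.0, seed=0, initial_volumes=v0)
        for b in rec.intervals("breath"):
            m = b.mask(rec.time)
            vol = rec.volume[m]
            assert abs(vol[0]) < 0.01 * default_settings.tidal_volume
            assert abs(vol[-1]) < 0.01 * default_settings.tidal_volume
            assert vol.max() == pytest.approx(default_settings.tidal_volume,
                                              rel=0.02)
        # expired volume from integrated flow matches VT
        b = rec.intervals("breath")[1]
        m = b.mask(rec.time) & (rec.phase == "exp")
        expired = -np.trapezoid(rec.flow[m], rec.time[m])
        assert expired == pytest.approx(default_settings.tidal_volume, rel=0.03)

    def test_uniform_time_axis_and_determinism(self, mixed_lung_model,
                                               default_settings):
        r1 = simulate_breaths(mixed_lung_model, default_settings, 2, seed=7)
        r2 = simulate_breaths(mixed_lung_model, default_settings, 2, seed=7)
        assert np.array_equal(r1.airway_pressure, r2.airway_pressure)
        dt = np.diff(r1.time)
        assert np.allclose(dt, dt[0])

    def test_step_size_error(self, single_rc, default_settings):
        with pytest.raises(StepSizeError):
            simulate_breaths(single_rc, default_settings, 1, sample_rate=0.5)

    def test_invalid_settings(self):
        with pytest.raises(InvalidSettingsError):
            VentilatorSettings(0.5, 40.0, 2.0)   # Te = -0.5 s
        with pytest.raises(InvalidSettingsError):
            VentilatorSettings(-0.5, 20.0, 1.0)

    def test_model_invariants(self):
        with pytest.raises(InvalidModelError):
            LungModel(())
        with pytest.raises(InvalidModelError):
            Compartment(resistance=10, compliance=0.05, flow_limited=True)
        with pytest.raises(InvalidModelError):
            LungModel((Compartment(resistance=10, compliance=0.05,
                                   volume_share=0.6),))


class TestOcclusion:
    def test_plateau_is_compliance_weighted_mean(self):
        model = LungModel((
            Compartment(resistance=20.0, compliance=0.02, volume_share=1 / 3),
            Compartment(resistance=20.0, compliance=0.04, volume_share=2 / 3),
        ), noise_sd=0.0)
        settings = VentilatorSettings(0.5, 15.0, 1.0)
        vols = np.array([0.02 * 6.0, 0.04 * 12.0])    # Palv 6 and 12 cmH2O
        occ = simulate_occlusion(model, settings, vols, "end_expiratory", 4.0,
                                 seed=0)
        expected = (0.02 * 6 + 0.04 * 12) / 0.06
        assert measure_plateau(occ) == pytest.approx(expected, abs=0.05)
        assert expected == 10.0

    def test_single_compartment_identity(self, single_rc):
        settings = VentilatorSettings(0.5, 15.0, 1.0)
        occ = simulate_occlusion(single_rc, settings, np.array([0.05 * 9.0]),
                                 "end_expiratory", 4.0, seed=0)
        assert measure_plateau(occ) == pytest.approx(9.0, abs=1e-9)
        assert np.max(np.abs(occ.flow)) < 1e-12

    def test_mixed_lung_equal_compliance_mean(self, mixed_lung_model, default_settings):
        vols = steady_state_volumes(mixed_lung_model, default_settings)
        occ = simulate_occlusion(mixed_lung_model, default_settings, vols,
                                 "end_expiratory", 4.0, seed=0)
        assert measure_plateau(occ) == pytest.approx(7.0, abs=0.2)


class TestCalibration:
    def test_mixed_lung_targets_and_total(self, mixed_lung_model, default_settings):
        achieved = steady_state_volumes(mixed_lung_model, default_settings) \
            / np.array([c.compliance for c in mixed_lung_model.compartments])
        assert achieved == pytest.approx([4.0, 10.0], abs=0.1)
        assert occluded_total_peep(mixed_lung_model, default_settings) \
            == pytest.approx(7.0, abs=0.1)

    def test_mixed_lung_with_applied_peep(self, mixed_lung_model, default_settings):
        """PEEP of 6 cmH2O raises total PEEP from 7 to 10: the open region
        takes up the full applied PEEP, the flow-limited one none."""
        peep6 = default_settings.with_peep(6.0)
        assert occluded_total_peep(mixed_lung_model, peep6) \
            == pytest.approx(10.0, abs=0.1)
        palv = steady_state_volumes(mixed_lung_model, peep6) \
            / np.array([c.compliance for c in mixed_lung_model.compartments])
        assert palv[0] - 6.0 == pytest.approx(4.0, abs=0.1)   # unchanged
        assert palv[1] == pytest.approx(10.0, abs=0.1)        # shielded

    def test_symmetric_nonfl_pair(self, default_settings):
        c_i = (1 / 19.0) / 2
        r = _calibrate_nonfl_resistance(5.0, c_i, 0.5, default_settings)
        model = LungModel((
            Compartment(resistance=r, compliance=c_i, volume_share=0.5),
            Compartment(resistance=r, compliance=c_i, volume_share=0.5),
        ), noise_sd=0.0)
        assert occluded_total_peep(model, default_settings) \
            == pytest.approx(5.0, abs=0.1)

    def test_unreachable_target_raises(self, default_settings):
        # an envelope cannot trap less pressure than the Ohmic pathway allows
        with pytest.raises(CalibrationError):
            calibrate_two_compartment_patient(4.0, 0.05, default_settings)
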