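"""Hysteresis-loop extraction and metrics."""

import numpy as np
import pytest

import spinemech as sm
from spinemech.errors import (
    CycleOutOfRangeError,
    PartialProtocolError,
    ProtocolMismatchError,
)


def linear_loop(slope, amplitude=0.5, n=400, mode="axial"):
    """Loss-free loop: load triangle, deformation = load / slope."""
    phase = np.arange(n + 1) / n
    load = amplitude * np.where(
        phase < 0.25, 4 * phase,
        np.where(phase < 0.75, 2 - 4 * phase, 4 * phase - 4),
    )
    return sm.HysteresisLoop(deformation=load / slope, load=load,
                             mode=mode, cycle_index=1)


class TestExtractCycle:
    def test_final_cycle_covers_the_last_second(self, female_cd_truth):
        rec = sm.generate_recording(
            sm.RecordingProtocol.axial_cyclic(sampling_rate=100.0),
            female_cd_truth, noise_sd=0.0,
        )
        loop = sm.extract_cycle(rec, cycle_index=20, frequency=1.0)
        assert len(loop.load) == pytest.approx(101, abs=1)
        # covers one full period: both load extremes present
        assert loop.load.max() == pytest.approx(0.5, rel=1e-9)
        assert loop.load.min() == pytest.approx(-0.5, rel=1e-9)

    def test_too_short_recording_is_out_of_range(self, female_cd_truth):
        rec = sm.generate_recording(
            sm.RecordingProtocol.axial_cyclic(n_cycles=10, sampling_rate=100.0),
            female_cd_truth, noise_sd=0.0,
        )
        with pytest.raises(CycleOutOfRangeError):
            sm.extract_cycle(rec, cycle_index=20)

    @pytest.mark.parametrize("fs", [100.0, 250.0, 1000.0])
    def test_sample_count_matches_generator_bookkeeping(self, female_cd_truth, fs):
        rec = sm.generate_recording(
            sm.RecordingProtocol.axial_cyclic(sampling_rate=fs),
            female_cd_truth, noise_sd=0.0,
        )
        loop = sm.extract_cycle(rec, cycle_index=20)
        assert abs(len(loop.load) - (fs + 1)) <= 1

    def test_offset_load_falls_back_to_minimum(self, female_cd_truth):
        rec = sm.generate_recording(
            sm.RecordingProtocol.axial_cyclic(sampling_rate=100.0),
            female_cd_truth, noise_sd=0.0,
        )
        rec.load = rec.load + 1.0  # never crosses zero
        loop = sm.extract_cycle(rec, cycle_index=19)
        assert len(loop.load) >= 40

    def test_loop_closure_is_reported(self, clean_axial_loop):
        assert max(clean_axial_loop.closure_error()) < 0.05


class TestAxialMetrics:
    def test_recovers_generating_truth_exactly(self, clean_axial_loop,
                                               female_cd_truth):
        m = sm.axial_metrics(clean_axial_loop)
        assert m.stiffness_negative == pytest.approx(16.59, rel=1e-9)
        assert m.stiffness_positive == pytest.approx(9.15, rel=1e-9)
        assert m.range_of_motion == pytest.approx(0.19, rel=1e-9)
        assert m.neutral_zone_length == pytest.approx(0.07, rel=1e-9)
        assert m.load_range == pytest.approx(1.0, rel=1e-9)
        assert m.neutral_zone_length <= m.range_of_motion

    def test_linear_loop_closed_form(self):
        """For a pure line of slope s: both stiffnesses equal s and the
        neutral zone is (2 * nz_fraction * amplitude) / s exactly."""
        s = 12.5
        loop = linear_loop(s)
        m = sm.axial_metrics(loop)
        assert m.stiffness_positive == pytest.approx(s, rel=1e-9)
        assert m.stiffness_negative == pytest.approx(s, rel=1e-9)
        assert m.neutral_zone_length == pytest.approx(2 * 0.1 * 0.5 / s, rel=1e-9)
        assert m.range_of_motion == pytest.approx(1.0 / s, rel=1e-9)

    def test_mirror_symmetric_loop_has_equal_limbs(self):
        m = sm.axial_metrics(linear_loop(7.0))
        assert m.stiffness_positive == pytest.approx(m.stiffness_negative, rel=1e-9)

    @pytest.mark.parametrize("c", [0.25, 4.0])
    def test_scale_equivariance_in_deformation(self, clean_axial_loop, c):
        base = sm.axial_metrics(clean_axial_loop)
        scaled_loop = sm.HysteresisLoop(
            deformation=clean_axial_loop.deformation * c,
            load=clean_axial_loop.load,
            mode="axial", cycle_index=clean_axial_loop.cycle_index,
        )
        scaled = sm.axial_metrics(scaled_loop)
        assert scaled.range_of_motion == pytest.approx(c * base.range_of_motion)
        assert scaled.neutral_zone_length == pytest.approx(
            c * base.neutral_zone_length)
        assert scaled.stiffness_positive == pytest.approx(
            base.stiffness_positive / c)
        assert scaled.stiffness_negative == pytest.approx(
            base.stiffness_negative / c)

    def test_unreached_load_limit_reports_attained_extremes(self):
        loop = linear_loop(10.0, amplitude=0.3)
        with pytest.raises(PartialProtocolError) as err:
            sm.axial_metrics(loop, load_limit=0.5)
        assert err.value.attained_max == pytest.approx(0.3)

    def test_one_signed_load_is_a_protocol_mismatch(self):
        phase = np.arange(101) / 100
        load = 0.25 + 0.2 * np.sin(2 * np.pi * phase)
        loop = sm.HysteresisLoop(deformation=load / 10, load=load,
                                 mode="axial", cycle_index=1)
        with pytest.raises(ProtocolMismatchError):
            sm.axial_metrics(loop)

    def test_wrong_mode_is_rejected(self, clean_torsional_loop):
        with pytest.raises(ProtocolMismatchError):
            sm.axial_metrics(clean_torsional_loop)

    def test_sigmoid_loop_shape_recovers_approximately(self, female_cd_truth):
        """The smooth-blend generator is a different functional form, so
        recovery is approximate — guards against analyzing only the shape
        the analyzer was designed around."""
        rec = sm.generate_recording(
            sm.RecordingProtocol.axial_cyclic(loop_shape="sigmoid"),
            female_cd_truth, noise_sd=0.0,
        )
        m = sm.axial_metrics(sm.extract_cycle(rec, 20))
        assert m.stiffness_negative == pytest.approx(16.59, rel=0.15)
        assert m.stiffness_positive == pytest.approx(9.15, rel=0.15)
        assert m.neutral_zone_length == pytest.approx(0.07, rel=0.35)

    def test_intersection_nz_variant_is_sane(self, clean_axial_loop):
        cfg = sm.PipelineConfig(nz_method="intersection")
        m = sm.axial_metrics(clean_axial_loop, cfg)
        assert 0 < m.neutral_zone_length <= m.range_of_motion


class TestTorsionalMetrics:
    def test_recovers_generating_truth_exactly(self, clean_torsional_loop,
                                               female_cd_truth):
        m = sm.torsional_metrics(clean_torsional_loop)
        assert m.stiffness_mean == pytest.approx(0.016, rel=1e-9)
        assert m.load_range == pytest.approx(0.003, rel=1e-9)
        assert m.neutral_zone_length == pytest.approx(
            female_cd_truth.torsional_neutral_zone, rel=1e-9)

    def test_stiffness_mean_averages_the_limbs(self, clean_torsional_loop):
        m = sm.torsional_metrics(clean_torsional_loop)
        assert m.stiffness_mean == pytest.approx(
            (m.stiffness_positive + m.stiffness_negative) / 2, rel=1e-12)

    def test_linear_torque_rotation_loop(self):
        """torque = 0.016 * rotation -> mean stiffness 0.016 N·m/rad."""
        loop = linear_loop(1 / 0.016, amplitude=np.radians(10), mode="torsional")
        # deformation = load/slope built in load space; rebuild properly:
        rotation = loop.deformation
        loop = sm.HysteresisLoop(deformation=rotation, load=0.016 * rotation,
                                 mode="torsional", cycle_index=1)
        m = sm.torsional_metrics(loop)
        assert m.stiffness_mean == pytest.approx(0.016, rel=1e-9)

    def test_torque_extremes_give_load_range(self, female_cd_truth):
        rec = sm.generate_recording(
            sm.RecordingProtocol.torsional_cyclic(), female_cd_truth,
            noise_sd=0.0,
        )
        m = sm.torsional_metrics(sm.extract_cycle(rec, 20))
        assert m.load_range == pytest.approx(0.003, rel=1e-9)

    def test_noisy_loop_recovery_is_unbiased_enough(self, female_cd_truth):
        """Bench-level torque noise: group-mean recovery within a few %."""
        vals = []
        for seed in range(12):
            rec = sm.generate_recording(
                sm.RecordingProtocol.torsional_cyclic(), female_cd_truth,
                seed=seed,
            )
            m = sm.torsional_metrics(sm.extract_cycle(rec, 20))
            vals.append(m.stiffness_mean)
        assert np.mean(vals) == pytest.approx(0.016, rel=0.15)
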