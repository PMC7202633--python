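"""Generator contracts: round trips, determinism, cohort structure."""

import numpy as np
import pytest
from scipy import stats as sps

import spinemech as sm
from spinemech.errors import DesignDegenerateError, GeneratorContractError


class TestRoundTrips:
    def test_axial_loop_round_trip(self, clean_axial_loop, female_cd_truth):
        m = sm.axial_metrics(clean_axial_loop)
        t = female_cd_truth
        assert m.stiffness_negative == pytest.approx(t.compressive_stiffness,
                                                     rel=1e-3)
        assert m.stiffness_positive == pytest.approx(t.tensile_stiffness,
                                                     rel=1e-3)
        assert m.range_of_motion == pytest.approx(t.rom, rel=1e-3)
        assert m.neutral_zone_length == pytest.approx(t.neutral_zone, rel=1e-3)

    def test_torsional_loop_round_trip(self, clean_torsional_loop,
                                       female_cd_truth):
        m = sm.torsional_metrics(clean_torsional_loop)
        t = female_cd_truth
        assert m.stiffness_mean == pytest.approx(t.torsional_stiffness, rel=1e-3)
        assert m.load_range == pytest.approx(t.torque_range, rel=1e-3)
        assert m.neutral_zone_length == pytest.approx(
            t.torsional_neutral_zone, rel=1e-3)

    def test_creep_round_trip_residual(self, clean_creep_recording):
        fit = sm.fit_creep(clean_creep_recording)
        assert fit.residual_rms < 1e-8

    def test_failure_round_trip(self, female_cd_truth):
        rec = sm.generate_recording(
            sm.RecordingProtocol.torsion_to_failure(), female_cd_truth,
            noise_sd=0.0,
        )
        m = sm.detect_failure(rec, sm.PipelineConfig(smoothing_window_s=0.0))
        assert m.failure_strength == pytest.approx(
            female_cd_truth.failure_strength, rel=1e-3)
        assert m.angle_to_failure == pytest.approx(
            female_cd_truth.angle_to_failure, rel=1e-3)


class TestDeterminism:
    @pytest.mark.parametrize("kind", ["axial_cyclic", "creep",
                                      "torsional_cyclic", "torsion_to_failure"])
    def test_same_seed_is_byte_identical(self, tmp_path, female_cd_truth, kind):
        protocol = {
            "axial_cyclic": sm.RecordingProtocol.axial_cyclic(sampling_rate=100.0),
            "creep": sm.RecordingProtocol.creep(duration=60.0),
            "torsional_cyclic":
                sm.RecordingProtocol.torsional_cyclic(sampling_rate=100.0),
            "torsion_to_failure": sm.RecordingProtocol.torsion_to_failure(),
        }[kind]
        paths = []
        for run in range(2):
            rec = sm.generate_recording(protocol, female_cd_truth, seed=42)
            path = tmp_path / f"{kind}_{run}.csv"
            sm.write_recording(rec, path)
            paths.append(path.read_bytes())
        assert paths[0] == paths[1]
        other = sm.generate_recording(protocol, female_cd_truth, seed=43)
        assert not np.array_equal(other.load, rec.load) or not np.array_equal(
            other.deformation, rec.deformation)

    def test_cohort_is_deterministic(self, small_design):
        a = sm.generate_cohort(small_design, seed=5)
        b = sm.generate_cohort(small_design, seed=5)
        assert a.truths.equals(b.truths)
        assert a.outcomes.equals(b.outcomes)


class TestContracts:
    def test_infeasible_torsional_neutral_zone_is_rejected(self):
        truth = sm.SpecimenTruth(
            torsional_stiffness=0.016, torque_range=0.003,
            torsional_neutral_zone=0.39,  # exceeds the ±10° sweep
        )
        with pytest.raises(GeneratorContractError):
            sm.generate_recording(
                sm.RecordingProtocol.torsional_cyclic(), truth, noise_sd=0.0)

    def test_negative_truth_is_rejected(self):
        with pytest.raises(GeneratorContractError):
            sm.SpecimenTruth(failure_strength=-1.0, angle_to_failure=1.0)

    def test_neutral_zone_cannot_exceed_rom(self):
        with pytest.raises(GeneratorContractError):
            sm.SpecimenTruth(rom=0.1, neutral_zone=0.2)

    def test_missing_truth_fields_are_reported(self):
        with pytest.raises(GeneratorContractError, match="missing"):
            sm.generate_recording(
                sm.RecordingProtocol.axial_cyclic(), sm.SpecimenTruth())

    def test_undersampled_protocol_is_rejected(self):
        with pytest.raises(GeneratorContractError):
            sm.RecordingProtocol.axial_cyclic(sampling_rate=10.0)


@pytest.fixture(scope="module")
def small_design():
    """Cheap protocols: truths are unaffected, recordings are tiny."""
    protocols = {
        "axial_cyclic": sm.RecordingProtocol.axial_cyclic(
            n_cycles=2, sampling_rate=100.0),
        "creep": sm.RecordingProtocol.creep(duration=30.0),
        "torsional_cyclic": sm.RecordingProtocol.torsional_cyclic(
            n_cycles=2, sampling_rate=100.0),
        "torsion_to_failure": sm.RecordingProtocol.torsion_to_failure(
            sampling_rate=50.0),
    }
    return sm.CohortDesign.reference(sexes=("female",), n_per_cell=8,
                                     protocols=protocols)


class TestCohort:
    def test_structure_and_positivity(self, small_design):
        result = sm.generate_cohort(small_design, seed=11)
        assert len(result.truths) == 32
        assert len(result.recordings) == 32 * 4
        assert len(result.manifest) == 32 * 4
        mech = result.truths.drop(columns=["specimen_id", "sex", "genotype",
                                           "diet"])
        assert (mech > 0).all().all()
        assert (result.truths.neutral_zone <= result.truths.rom).all()
        assert (result.truths.tau1 < result.truths.tau2).all()
        assert set(result.outcomes.columns) >= {
            "noto_band_fraction", "cells_per_mm2", "dhi"}

    def test_different_seeds_same_distribution(self, small_design):
        """Kolmogorov–Smirnov across seeds: same sampling distributions."""
        a = sm.generate_cohort(small_design, seed=21).truths
        b = sm.generate_cohort(small_design, seed=22).truths
        cols = ["compressive_stiffness", "rom", "tau2", "k0",
                "torsional_stiffness", "failure_strength"]
        pvals = [sps.ks_2samp(a[c], b[c]).pvalue for c in cols]
        assert np.median(pvals) > 0.01
        assert not a[cols].equals(b[cols])

    def test_single_animal_cells_propagate_to_stats_error(self, small_design):
        design = sm.CohortDesign(
            cells=[("female", g, d, 1) for g in ("Control", "DbDb")
                   for d in ("CD", "WD")],
            protocols=dict(small_design.protocols),
        )
        result = sm.generate_cohort(design, seed=3)
        assert len(result.recordings) == 4 * 4
        with pytest.raises(DesignDegenerateError):
            sm.two_way_anova(result.truths.rom, result.truths.genotype,
                             result.truths.diet)

    def test_files_written_match_reader(self, tmp_path, small_design):
        result = sm.generate_cohort(small_design, seed=13, out_dir=tmp_path)
        row = result.manifest.iloc[0]
        rec = sm.read_recording(tmp_path / row.path)
        specimen_id, kind, original = result.recordings[0]
        assert rec.specimen_id == specimen_id
        assert rec.test_kind == kind
        assert np.array_equal(rec.load, original.load)
        assert np.array_equal(rec.deformation, original.deformation)
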