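"""Creep model: forward simulation, closed forms, and fit recovery."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import spinemech as sm
from spinemech.errors import InvalidModelError, ProtocolMismatchError

FEMALE_CD = dict(k0=11.66, k1=12.64, k2=3.15, tau1=51.71, tau2=739.0)


def model(**overrides):
    return sm.FiveParamModel(**{**FEMALE_CD, **overrides})


positive = st.floats(min_value=0.05, max_value=500.0)


class TestForwardModel:
    def test_instantaneous_response_is_elastic(self):
        d = sm.simulate_creep(model(), 0.5, [0.0])
        assert d[0] == pytest.approx(0.5 / 11.66, rel=1e-12)

    def test_asymptote_matches_total_displacement(self):
        d = sm.simulate_creep(model(), 0.5, [1e7])
        total = sm.derive_creep_quantities(model(), 0.5)["total_displacement"]
        assert d[-1] == pytest.approx(total, rel=1e-9)
        assert total == pytest.approx(0.2412, abs=5e-5)

    def test_zero_load_gives_zero_displacement(self):
        assert np.all(sm.simulate_creep(model(), 0.0, np.linspace(0, 100, 11)) == 0)

    def test_empty_times_give_empty_series(self):
        assert sm.simulate_creep(model(), 0.5, []).size == 0

    @given(k0=positive, k1=positive, k2=positive,
           tau1=st.floats(1.0, 100.0), tau2=st.floats(100.0, 5000.0),
           force=st.floats(0.01, 10.0))
    def test_monotone_and_bounded(self, k0, k1, k2, tau1, tau2, force):
        m = sm.FiveParamModel(k0, k1, k2, tau1, tau2)
        t = np.linspace(0, 10 * tau2, 200)
        d = sm.simulate_creep(m, force, t)
        assert np.all(np.diff(d) >= -1e-15)
        assert d[0] == pytest.approx(force / k0, rel=1e-12)
        assert np.all(d <= force * (1 / k0 + 1 / k1 + 1 / k2) + 1e-12)

    def test_fast_time_constants_reduce_to_pure_elastic(self):
        m = model(tau1=1e-6, tau2=2e-6)
        t = np.linspace(0.1, 100, 50)
        expected = 0.5 * (1 / m.k0 + 1 / m.k1 + 1 / m.k2)
        assert sm.simulate_creep(m, 0.5, t) == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize("bad", [
        dict(k0=0.0), dict(k1=-1.0), dict(tau2=0.0), dict(k2=np.nan),
    ])
    def test_invalid_parameters_raise(self, bad):
        with pytest.raises(InvalidModelError):
            model(**bad)

    def test_arm_order_is_canonical(self):
        swapped = sm.FiveParamModel(k0=11.66, k1=3.15, k2=12.64,
                                    tau1=739.0, tau2=51.71)
        assert swapped == model()


class TestDerivedQuantities:
    @pytest.mark.parametrize("params, force, creep, total", [
        # hand arithmetic from the group-mean stiffnesses
        (dict(k1=12.64, k2=3.15, k0=11.66), 0.5, 0.198287, 0.241169),
        (dict(k1=1.0, k2=1.0, k0=1.0), 1.0, 2.0, 3.0),
        (dict(k0=16.03, k1=27.17, k2=4.08), 0.5, 0.140952, 0.172143),
    ])
    def test_closed_forms(self, params, force, creep, total):
        q = sm.derive_creep_quantities(model(**params), force)
        assert q["creep_displacement"] == pytest.approx(creep, abs=1e-5)
        assert q["total_displacement"] == pytest.approx(total, abs=1e-5)
        assert q["total_displacement"] == pytest.approx(
            q["elastic_displacement"] + q["creep_displacement"], abs=1e-9
        )

    def test_force_must_be_positive(self):
        with pytest.raises(ValueError):
            sm.derive_creep_quantities(model(), 0.0)


class TestFit:
    def test_noiseless_recovery_within_a_tenth_percent(self, clean_creep_recording):
        fit = sm.fit_creep(clean_creep_recording)
        truth = model()
        for name in ("k0", "k1", "k2", "tau1", "tau2"):
            rel = abs(getattr(fit.model, name) / getattr(truth, name) - 1)
            assert rel < 1e-3, name
        assert fit.converged
        assert fit.residual_rms < 1e-8
        assert fit.total_displacement == pytest.approx(
            fit.elastic_displacement + fit.creep_displacement, abs=1e-9
        )

    def test_agrees_with_grid_search_oracle(self):
        """Independent oracle: (tau1, tau2) grid with linear compliance solve."""
        truth = model()
        t = np.arange(0, 2700.0, 1.0)
        d = sm.simulate_creep(truth, 0.5, t)

        best = (np.inf, None)
        tau1_grid = np.geomspace(5, 200, 25)
        tau2_grid = np.geomspace(150, 3000, 25)
        for tau1 in tau1_grid:
            for tau2 in tau2_grid:
                if tau1 >= tau2:
                    continue
                basis = np.column_stack([
                    np.ones_like(t),
                    1 - np.exp(-t / tau1),
                    1 - np.exp(-t / tau2),
                ])
                coef, res, *_ = np.linalg.lstsq(basis, d, rcond=None)
                cost = float(res[0]) if res.size else np.inf
                if cost < best[0]:
                    best = (cost, (tau1, tau2, coef))
        tau1_b, tau2_b, coef = best[1]
        # grid resolution: one geometric step
        step1 = tau1_grid[1] / tau1_grid[0]
        step2 = tau2_grid[1] / tau2_grid[0]
        fit = sm.fit_creep(
            sm.TimeSeriesRecording(time=t, load=np.full(t.size, 0.5),
                                   deformation=d, test_kind="creep")
        )
        assert tau1_b / step1 <= fit.model.tau1 <= tau1_b * step1
        assert tau2_b / step2 <= fit.model.tau2 <= tau2_b * step2
        assert 0.5 / coef[0] == pytest.approx(fit.model.k0, rel=0.05)

    def test_label_stability_under_arm_permutation(self, female_cd_truth):
        """Swapping the generator's Kelvin arms never changes the sorted fit."""
        swapped = sm.FiveParamModel(k0=11.66, k1=3.15, k2=12.64,
                                    tau1=739.0, tau2=51.71)
        t = np.arange(0, 2700.0, 0.5)
        rec = sm.TimeSeriesRecording(
            time=t, load=np.full(t.size, 0.5),
            deformation=sm.simulate_creep(swapped, 0.5, t), test_kind="creep",
        )
        fit = sm.fit_creep(rec)
        assert fit.model.tau1 < fit.model.tau2
        assert fit.model.tau1 == pytest.approx(51.71, rel=1e-3)
        assert fit.model.k1 == pytest.approx(12.64, rel=1e-3)

    def test_noisy_recovery_median_error(self, female_cd_truth):
        """Monte-Carlo: sigma=0.002 mm sensor noise, median errors < 5%."""
        protocol = sm.RecordingProtocol.creep()
        errors = []
        for seed in range(20):
            rec = sm.generate_recording(protocol, female_cd_truth,
                                        noise_sd=0.002, seed=seed)
            fit = sm.fit_creep(rec)
            truth = female_cd_truth.creep_model
            errors.append([
                abs(getattr(fit.model, p) / getattr(truth, p) - 1)
                for p in ("k0", "k1", "k2", "tau1", "tau2")
            ])
        med = np.median(np.array(errors), axis=0)
        assert np.all(med < 0.05), med

    def test_ramp_is_trimmed_before_fitting(self, female_cd_truth):
        protocol = sm.RecordingProtocol.creep(ramp_duration=5.0)
        rec = sm.generate_recording(protocol, female_cd_truth, noise_sd=0.0)
        fit = sm.fit_creep(rec)
        assert fit.model.k0 == pytest.approx(11.66, rel=0.02)
        assert fit.model.tau2 == pytest.approx(739.0, rel=0.05)

    def test_oscillating_load_is_a_protocol_mismatch(self):
        t = np.linspace(0, 100, 1000)
        rec = sm.TimeSeriesRecording(
            time=t, load=0.5 + 0.3 * np.sin(t), deformation=np.ones_like(t),
        )
        with pytest.raises(ProtocolMismatchError):
            sm.fit_creep(rec)
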