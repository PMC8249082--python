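"""Synthetic coupled-signal generator: ground truth, spectra, recoverability."""

import numpy as np
import pytest
from scipy import signal

import physioconn as pc
from physioconn.synthetic import (
    Coupling,
    CouplingSpec,
    NodeDynamics,
    _run_recursion,
    _stack,
    build_model,
    make_testbed,
    seizure_epochs,
    simulate,
)

pytestmark = pytest.mark.filterwarnings("ignore:window of")


class TestGroundTruthModel:
    def test_ar2_coefficients_from_pole_parameters(self):
        nd = NodeDynamics(40.0, 0.95)
        a1, a2 = nd.ar2_coeffs(500.0)
        assert a1 == pytest.approx(2 * 0.95 * np.cos(2 * np.pi * 40 / 500))
        assert a2 == pytest.approx(-0.95**2)

    def test_coupling_entries_land_in_coefficient_array(self):
        spec = CouplingSpec(
            channel_labels=["a", "b"], organ_map={"a": "BRAIN", "b": "HEART"},
            node_dynamics=[NodeDynamics(10.0, 0.5), NodeDynamics(20.0, 0.5)],
            couplings=[Coupling("a", "b", lag=2, strength=0.3)],
        )
        m = build_model(spec)
        assert m.coeffs[1, 1, 0] == 0.3
        assert m.coeffs[0, 0, 1] == 0.0  # no reverse coupling

    def test_invalid_couplings_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            Coupling("a", "a", 1, 0.1)
        with pytest.raises(ValueError, match="lag"):
            Coupling("a", "b", 0, 0.1)

    def test_unstable_spec_rejected_with_radius(self):
        # a strong feedback loop destabilizes (acyclic graphs never can)
        spec = CouplingSpec(
            channel_labels=["a", "b"], organ_map={"a": "BRAIN", "b": "HEART"},
            node_dynamics=[NodeDynamics(10.0, 0.9), NodeDynamics(10.0, 0.9)],
            couplings=[Coupling("a", "b", 1, 2.0), Coupling("b", "a", 1, 2.0)],
        )
        with pytest.raises(ValueError, match="unstable"):
            build_model(spec)

    def test_pole_radius_bounds_enforced(self):
        spec = CouplingSpec(
            channel_labels=["a"], organ_map={"a": "BRAIN"},
            node_dynamics=[NodeDynamics(10.0, 1.0)],
        )
        with pytest.raises(ValueError, match="radius"):
            build_model(spec)


class TestSimulation:
    def test_seed_determinism_bit_exact(self):
        a = make_testbed("WT_LIKE", duration_s=10, seed=11).recording
        b = make_testbed("WT_LIKE", duration_s=10, seed=11).recording
        np.testing.assert_array_equal(a.data, b.data)
        c = make_testbed("WT_LIKE", duration_s=10, seed=12).recording
        assert not np.array_equal(a.data, c.data)

    def test_shape_labels_and_rate(self):
        rec = make_testbed("KO_LIKE", duration_s=20, seed=0).recording
        assert rec.data.shape == (10_000, 6)
        assert rec.channel_labels == ["EEG1", "EEG2", "EEG3", "EEG4", "ECG", "PLETH"]
        assert rec.fs == 500.0

    def test_fast_path_matches_recursion(self):
        spec = make_testbed("WT_LIKE", duration_s=4, seed=3).spec
        fast = simulate(spec).data
        model = build_model(spec)
        rng = np.random.default_rng(spec.seed)
        n, burn = int(4 * 500), 10 * spec.order
        noise = rng.standard_normal((n + burn, 6)) * spec._per_channel(spec.noise_sd)
        slow = _run_recursion([(n + burn, _stack(model.coeffs))], 6, spec.order, noise)
        slow = slow[burn:] * spec._per_channel(spec.unit_scale)
        np.testing.assert_allclose(fast, slow, atol=1e-8 * np.abs(slow).max())

    def test_resonator_peak_at_design_frequency(self):
        rec = make_testbed("WT_LIKE", duration_s=120, seed=4).recording
        f, pxx = signal.welch(rec.data[:, 2], fs=500.0, nperseg=4096)
        peak = f[np.argmax(pxx)]
        assert abs(peak - 40.0) < 2.0  # EEG3 resonates at 40 Hz

    def test_unit_scale_sets_channel_magnitudes(self):
        rec = make_testbed("WT_LIKE", duration_s=30, seed=5).recording
        rms = rec.data.std(axis=0)
        assert rms[4] > 10 * rms[0] > 10 * rms[5]  # ECG >> EEG >> PLETH


class TestDirectionalityRecovery:
    def test_designed_coupling_detected_reverse_near_alpha(self):
        """One-way ECG -> EEG1 coupling: detected forward, chance-level reverse."""
        spec = CouplingSpec(
            node_dynamics=[
                NodeDynamics(7.0, 0.90), NodeDynamics(11.0, 0.90),
                NodeDynamics(40.0, 0.90), NodeDynamics(80.0, 0.90),
                NodeDynamics(12.0, 0.95), NodeDynamics(4.0, 0.95),
            ],
            couplings=[Coupling("ECG", "EEG1", 1, 0.40)],
            duration_s=100.0, seed=6,
        )
        conn = pc.analyze_recording(simulate(spec), method="asymptotic", order=7)
        near_f0 = (conn.grid.freqs >= 7) & (conn.grid.freqs <= 17)
        forward = conn.mask[:, 0, 4, near_f0].any(axis=1).mean()
        reverse = conn.mask[:, 4, 0, :].mean()
        assert forward >= 0.95
        assert reverse < 0.15


class TestSeizureScenario:
    def test_epoch_schedule(self):
        epochs = seizure_epochs(3600.0)
        assert epochs[0] == (150.0, 230.0)
        assert all(b - a == 80.0 for a, b in epochs)
        assert all(b <= 0.6 * 3600 for _, b in epochs)
        diffs = np.diff([a for a, _ in epochs])
        assert np.all(diffs == 300.0)

    def test_events_match_epochs_and_ictal_ground_truth(self):
        tb = make_testbed("KO_SEIZING", duration_s=1200, seed=7)
        assert [t for t, _ in tb.events] == [a for a, _ in seizure_epochs(1200)]
        hot = {(c.from_channel, c.to_channel): c.strength for c in tb.ictal_couplings}
        assert hot[("EEG3", "PLETH")] > dict(
            ((c.from_channel, c.to_channel), c.strength) for c in tb.spec.couplings
        )[("EEG3", "PLETH")]

    def test_brain_to_lungs_flow_elevated_during_seizures(self):
        tb = make_testbed("KO_SEIZING", duration_s=900, seed=8)
        conn = pc.analyze_recording(tb.recording, method="asymptotic", order=7)
        conn.meta["events"] = tb.events
        # Off-resonance band: near the 40-Hz EEG3 resonance the GPDC column
        # is saturated, so the ictal coupling change is read out where the
        # source's own spectrum is flat.
        band = (140.0, 150.0)
        raw = pc.extract_band_timeseries(conn, ("BRAIN", "LUNGS"), band)
        in_epoch = np.zeros(raw.times_s.size, dtype=bool)
        for onset, offset in seizure_epochs(900):
            in_epoch |= (raw.times_s >= onset) & (raw.times_s < offset)
        from physioconn.group_stats import mannwhitney

        assert raw.values[in_epoch].mean() > 1.3 * raw.values[~in_epoch].mean()
        assert mannwhitney(raw.values[in_epoch], raw.values[~in_epoch]).p_value < 1e-3
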