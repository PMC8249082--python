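"""Band definitions, organ-pair pooling, profiles, significance fractions."""

import numpy as np
import pytest

import physioconn as pc
from physioconn.aggregation import WindowedConnectivity


def _toy_conn(gpdc, p_values, freqs, labels, organ_map, alpha=0.05):
    W = gpdc.shape[0]
    return WindowedConnectivity(
        gpdc=gpdc, p_values=p_values, alpha=alpha,
        grid=pc.FrequencyGrid(np.asarray(freqs, dtype=float), 500.0),
        channel_labels=labels, organ_map=organ_map,
        times_s=10.0 * np.arange(W),
    )


@pytest.fixture
def two_channel_conn():
    """2 windows, ECG+PLETH, 3 frequencies, everything significant by default."""
    freqs = [5.0, 6.0, 7.0]
    gpdc = np.zeros((2, 2, 2, 3))
    # PLETH <- ECG (i=1, j=0): window 0 has {0.1, 0.2, 0.3}, window 1 {0.4, 0.5, 0.6}
    gpdc[0, 1, 0] = [0.1, 0.2, 0.3]
    gpdc[1, 1, 0] = [0.4, 0.5, 0.6]
    p = np.full_like(gpdc, 0.01)
    return _toy_conn(gpdc, p, freqs, ["ECG", "PLETH"],
                     {"ECG": "HEART", "PLETH": "LUNGS"})


class TestDefineBands:
    def test_reference_banding_excludes_mains_harmonics(self):
        bg = pc.define_bands(10.0, 200.0, 60.0)
        assert len(bg.bands) == 20
        excluded = [b for b, ex in zip(bg.bands, bg.excluded) if ex]
        assert excluded == [(50.0, 60.0), (110.0, 120.0), (170.0, 180.0)]
        assert len(bg.retained) == 17

    def test_line_zero_disables_exclusion(self):
        bg = pc.define_bands(10.0, 200.0, 0.0)
        assert len(bg.retained) == 20

    def test_width_must_divide_range(self):
        with pytest.raises(ValueError, match="divide"):
            pc.define_bands(7.0, 200.0, 60.0)

    def test_bands_are_half_open_upper_inclusive(self):
        bg = pc.define_bands()
        grid = pc.FrequencyGrid.default()
        # 60 Hz itself falls in the excluded (50, 60] band
        from physioconn.aggregation import _in_band

        assert _in_band(grid, (50.0, 60.0))[np.where(grid.freqs == 60.0)[0][0]]
        assert not _in_band(grid, (60.0, 70.0))[np.where(grid.freqs == 60.0)[0][0]]


class TestPooling:
    def test_hand_pooled_mean(self, two_channel_conn):
        vals = pc.pool_organ_pair(two_channel_conn, ("HEART", "LUNGS"), (0.0, 10.0))
        assert vals.size == 6
        assert vals.mean() == pytest.approx(0.35)

    def test_all_nonsignificant_gives_empty_pool(self, two_channel_conn):
        two_channel_conn.p_values[:] = 0.9
        vals = pc.pool_organ_pair(two_channel_conn, ("HEART", "LUNGS"), (0.0, 10.0))
        assert vals.size == 0

    def test_same_organ_pair_rejected(self, two_channel_conn):
        with pytest.raises(ValueError, match="inter-organ"):
            pc.pool_organ_pair(two_channel_conn, ("HEART", "HEART"), (0.0, 10.0))

    def test_brain_heart_pools_four_channel_pairs(self, six_channel_recording):
        conn = pc.analyze_recording(
            six_channel_recording, method="asymptotic", order=7
        )
        pairs = conn.channel_pairs(("BRAIN", "HEART"))
        assert len(pairs) == 4  # 4 EEG sources x 1 ECG target

    def test_window_order_invariance(self, two_channel_conn):
        c = two_channel_conn
        flipped = WindowedConnectivity(
            gpdc=c.gpdc[::-1], p_values=c.p_values[::-1], alpha=c.alpha,
            grid=c.grid, channel_labels=c.channel_labels, organ_map=c.organ_map,
            times_s=c.times_s,
        )
        a = np.sort(pc.pool_organ_pair(c, ("HEART", "LUNGS"), (0.0, 10.0)))
        b = np.sort(pc.pool_organ_pair(flipped, ("HEART", "LUNGS"), (0.0, 10.0)))
        np.testing.assert_array_equal(a, b)


class TestProfiles:
    def test_empty_band_zero_assigned(self, two_channel_conn):
        bg = pc.define_bands()
        two_channel_conn.p_values[:, 0, 1, :] = 0.9  # LUNGS -> HEART all n.s.
        prof = pc.band_profile(two_channel_conn, ("LUNGS", "HEART"), bg)
        assert np.all(prof.zero_assigned)
        assert np.all(prof.mean == 0.0) and np.all(prof.sem == 0.0)

    def test_single_value_band_sem_zero(self, two_channel_conn):
        two_channel_conn.p_values[:] = 0.9
        two_channel_conn.p_values[0, 1, 0, 0] = 0.01
        bg = pc.define_bands()
        prof = pc.band_profile(two_channel_conn, ("HEART", "LUNGS"), bg)
        assert prof.n_values[0] == 1
        assert prof.mean[0] == pytest.approx(0.1)
        assert prof.sem[0] == 0.0 and not prof.zero_assigned[0]

    def test_two_value_sem(self):
        from physioconn.aggregation import _summarize

        n, mean, sem, zero = _summarize(np.array([0.2, 0.4]))
        assert (n, zero) == (2, False)
        assert mean == pytest.approx(0.3)
        assert sem == pytest.approx(0.1, rel=1e-6)

    def test_conservation_over_bands(self, six_channel_recording):
        conn = pc.analyze_recording(six_channel_recording, method="asymptotic")
        bg = pc.define_bands()
        pair = ("HEART", "BRAIN")
        full_no_exclusion = pc.pool_organ_pair(conn, pair, (0.0, 200.0))
        per_band = sum(
            pc.pool_organ_pair(conn, pair, b).size for b in bg.bands
        )
        assert per_band == full_no_exclusion.size

    def test_full_range_pool_equals_fullband_average(self, six_channel_recording):
        conn = pc.analyze_recording(six_channel_recording, method="asymptotic")
        bg = pc.define_bands()
        pair = ("HEART", "BRAIN")
        pooled = pc.pool_full_spectrum(conn, pair, bg)
        fb = pc.fullband_average(conn, pair, bg)
        assert fb["n"] == pooled.size
        assert fb["mean"] == pytest.approx(pooled.mean())


class TestSignificanceFraction:
    def test_all_true_and_all_false(self, two_channel_conn):
        bg = pc.define_bands()
        two_channel_conn.p_values[:] = 0.0
        tab = pc.significance_fraction(two_channel_conn, bg)
        hl = tab[(tab.from_organ == "HEART") & (tab.to_organ == "LUNGS")]
        assert np.all(hl[hl.n_total > 0].fraction_significant == 1.0)
        two_channel_conn.p_values[:] = 1.0
        tab = pc.significance_fraction(two_channel_conn, bg)
        hl = tab[(tab.from_organ == "HEART") & (tab.to_organ == "LUNGS")]
        assert np.all(hl[hl.n_total > 0].fraction_significant == 0.0)

    def test_partial_fraction_counts(self, two_channel_conn):
        two_channel_conn.p_values[:] = 0.9
        # 3 of the 6 HEART->LUNGS values in (0, 10] significant
        two_channel_conn.p_values[0, 1, 0, :] = 0.01
        bg = pc.define_bands()
        tab = pc.significance_fraction(two_channel_conn, bg)
        row = tab[(tab.from_organ == "HEART") & (tab.to_organ == "LUNGS")
                  & (tab.band_low_hz == 0.0)].iloc[0]
        assert row.n_total == 6 and row.n_significant == 3
        assert row.fraction_significant == pytest.approx(0.5)
        assert row.pct_not_significant == pytest.approx(50.0)
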