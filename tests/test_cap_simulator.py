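"""CAP propagation, referencing, series assembly and noise properties."""

import dataclasses

import numpy as np
import pytest

from cuffdrift.cap_simulator import (
    FIBER_CLASSES,
    MultiChannelRecording,
    NodeSet,
    PathwaySpec,
    SourceTemplate,
    add_noise,
    assemble_time_series,
    build_cap_bank,
    default_pathway,
    global_peak_index,
    place_nodes,
    series_noise_sigma,
    simulate_cap,
    tripole_reference,
)
from cuffdrift.volume_conductor import compute_leadfield


def straight_pathway(label, fiber_class, length_mm=26.0):
    cp = np.stack([np.zeros(2), np.full(2, 0.3), np.array([0.0, length_mm])], axis=1)
    return PathwaySpec(label, cp, FIBER_CLASSES[fiber_class], np.zeros((1, 2)))


class TestTemplate:
    def test_charge_balance(self, template):
        s = template.samples
        assert abs(s.sum()) / np.abs(s).max() < 1e-9

    def test_finite_support(self, template):
        t = np.array([-template.duration_ms, template.duration_ms])
        assert np.array_equal(template(t), [0.0, 0.0])

    def test_invalid_width_rejected(self):
        with pytest.raises(ValueError):
            SourceTemplate(sigma_ms=0.0)


class TestPlaceNodes:
    @pytest.mark.parametrize(
        "fiber_class,expected",
        [("Aalpha", 16), ("Abeta", 23)],  # floor(26 / spacing) + 1
    )
    def test_node_count_on_straight_path(self, fiber_class, expected):
        pw = straight_pathway("tibial", fiber_class)
        assert len(place_nodes(pw)) == expected

    def test_arc_spacing(self):
        pw = straight_pathway("tibial", "Aalpha")
        nodes = place_nodes(pw)
        gaps = np.diff(nodes.arclengths_mm)
        assert np.allclose(gaps, 1.70)

    def test_chord_not_longer_than_arc_on_curved_path(self, tibial_pathway):
        nodes = place_nodes(tibial_pathway)
        chords = np.linalg.norm(np.diff(nodes.positions_mm, axis=0), axis=1)
        spacing = tibial_pathway.fiber.node_spacing_mm
        assert np.all(chords <= spacing + 1e-9)

    def test_offset_trajectories_stay_inside_fascicle(self, tissue, tibial_pathway):
        fasc = tissue.fascicle("tibial")
        cx, cy = fasc.center_xy
        r_endo = fasc.radius_mm - tissue.perineurium_thickness_mm
        for b in range(tibial_pathway.n_offsets):
            pos = place_nodes(tibial_pathway, b).positions_mm
            r = np.hypot(pos[:, 0] - cx, pos[:, 1] - cy)
            assert np.all(r < r_endo)

    def test_too_short_path_rejected(self):
        with pytest.raises(ValueError):
            place_nodes(straight_pathway("tibial", "Aalpha", length_mm=1.0))


@pytest.fixture(scope="module")
def straight_cap(geometry, tissue, template):
    """Clean unreferenced CAP on a straight tibial trajectory, 30 mm span."""
    pw = straight_pathway("tibial", "Aalpha", length_mm=30.0)
    cp = pw.control_points_mm + np.array([0.0, 0.0, -3.5])
    pw = dataclasses.replace(pw, control_points_mm=cp)
    nodes = place_nodes(pw)
    lf = compute_leadfield(geometry, tissue, nodes.positions_mm)
    rec = simulate_cap(lf, nodes, template, pw.fiber.conduction_velocity_m_s)
    return rec, nodes, lf


class TestSimulateCap:
    def test_zero_template_gives_zero_recording(self, geometry, tissue, straight_cap):
        _, nodes, lf = straight_cap
        rec = simulate_cap(lf, nodes, SourceTemplate(amplitude=0.0), 94.86)
        assert not rec.samples.any()

    def test_linearity_in_amplitude(self, straight_cap, template):
        rec, nodes, lf = straight_cap
        rec2 = simulate_cap(lf, nodes, SourceTemplate(amplitude=2.0), 94.86)
        assert np.allclose(rec2.samples, 2.0 * rec.samples, rtol=1e-12)

    def test_channel_integrals_vanish(self, straight_cap):
        """Charge balance carries over to every channel's time integral."""
        rec, _, _ = straight_cap
        rel = np.abs(rec.samples.sum(axis=1)) / np.abs(rec.samples).sum(axis=1)
        assert np.max(rel) < 1e-6

    def test_ring_peak_lag_matches_velocity(self, geometry, straight_cap):
        """Ring 1 -> ring 7 peak lag = axial distance / conduction velocity."""
        rec, _, _ = straight_cap
        ch1, ch7 = 0 * 8 + 2, 6 * 8 + 2  # slot nearest the tibial fascicle
        lag = np.argmax(np.abs(rec.samples[ch7])) - np.argmax(np.abs(rec.samples[ch1]))
        dz = geometry.ring_axial_positions_mm[6] - geometry.ring_axial_positions_mm[0]
        expected = dz / 94.86 * 1e-3 * rec.sampling_rate_hz
        assert abs(lag - expected) <= 1.0

    def test_slower_fiber_lags_more(self, geometry, tissue, template):
        lags = {}
        for fc in ("Aalpha", "Abeta"):
            pw = straight_pathway("tibial", fc, length_mm=30.0)
            pw = dataclasses.replace(
                pw, control_points_mm=pw.control_points_mm + np.array([0.0, 0.0, -3.5])
            )
            nodes = place_nodes(pw)
            lf = compute_leadfield(geometry, tissue, nodes.positions_mm)
            rec = simulate_cap(lf, nodes, template, pw.fiber.conduction_velocity_m_s)
            ch1, ch7 = 2, 6 * 8 + 2
            lags[fc] = np.argmax(np.abs(rec.samples[ch7])) - np.argmax(np.abs(rec.samples[ch1]))
        assert lags["Abeta"] > lags["Aalpha"]

    def test_invalid_velocity_rejected(self, straight_cap, template):
        _, nodes, lf = straight_cap
        with pytest.raises(ValueError):
            simulate_cap(lf, nodes, template, 0.0)


class TestTripoleReference:
    def test_common_mode_annihilated(self, geometry):
        rec = MultiChannelRecording(samples=np.ones((56, 40)) * 3.7)
        out = tripole_reference(rec, geometry)
        assert np.allclose(out.samples, 0.0, atol=1e-12)

    def test_middle_ring_signal_untouched(self, geometry):
        samples = np.zeros((56, 30))
        samples[3 * 8 + 4, 10:20] = 1.0  # one middle-ring channel
        out = tripole_reference(MultiChannelRecording(samples=samples), geometry)
        assert np.array_equal(out.samples, samples)

    def test_outer_ring_mean_is_zero_after_referencing(self, geometry):
        rng = np.random.default_rng(4)
        rec = MultiChannelRecording(samples=rng.normal(size=(56, 50)))
        out = tripole_reference(rec, geometry)
        outer = np.r_[0:8, 48:56]
        assert np.allclose(out.samples[outer].mean(axis=0), 0.0, atol=1e-12)

    def test_double_referencing_rejected(self, geometry):
        rec = MultiChannelRecording(samples=np.ones((56, 10)), referenced=True)
        with pytest.raises(ValueError):
            tripole_reference(rec, geometry)


@pytest.fixture(scope="module")
def small_bank(geometry, tissue, tibial_pathway, template):
    return build_cap_bank(geometry, tissue, tibial_pathway, template)


class TestAssembleSeries:
    def test_event_count_and_length(self, small_bank):
        series = assemble_time_series(small_bank, n_events=50, duration_s=0.5, seed=1)
        assert series.n_samples == 15_000
        assert len(series.event_peaks) == 50

    def test_minimum_separation(self, small_bank):
        series = assemble_time_series(small_bank, n_events=100, duration_s=0.5, seed=2)
        onsets = series.event_peaks - small_bank.peak_offset
        assert np.min(np.diff(onsets)) >= small_bank.clip_len

    def test_single_event_silence_elsewhere(self, small_bank):
        series = assemble_time_series(small_bank, n_events=1, duration_s=0.1, seed=3)
        onset = series.event_peaks[0] - small_bank.peak_offset
        mask = np.ones(series.n_samples, bool)
        mask[onset : onset + small_bank.clip_len] = False
        assert not series.samples[:, mask].any()
        assert series.samples[:, ~mask].any()

    def test_seeded_determinism(self, small_bank):
        a = assemble_time_series(small_bank, 40, 0.4, seed=9)
        b = assemble_time_series(small_bank, 40, 0.4, seed=9)
        assert np.array_equal(a.samples, b.samples)
        assert np.array_equal(a.event_peaks, b.event_peaks)

    def test_infeasible_packing_rejected(self, small_bank):
        with pytest.raises(ValueError, match="pack"):
            assemble_time_series(small_bank, n_events=1000, duration_s=0.1, seed=0)


class TestNoise:
    def test_target_snr_reached(self, small_bank):
        series = assemble_time_series(small_bank, n_events=300, duration_s=2.0, seed=5)
        noisy = add_noise(series, -5.0, seed=6)
        p_sig = np.mean(series.samples**2)
        p_noise = np.mean((noisy.samples - series.samples) ** 2)
        measured = 10 * np.log10(p_sig / p_noise)
        assert measured == pytest.approx(-5.0, abs=0.1)

    def test_high_snr_limit(self, small_bank):
        series = assemble_time_series(small_bank, n_events=20, duration_s=0.2, seed=5)
        noisy = add_noise(series, 100.0, seed=6)
        peak = np.abs(series.samples).max()
        assert np.max(np.abs(noisy.samples - series.samples)) < 1e-3 * peak

    def test_standard_snr_grid_sigma_ordering(self, small_bank):
        sigmas = [series_noise_sigma(small_bank, s) for s in (-5.0, -10.0, -15.0)]
        assert sigmas[0] < sigmas[1] < sigmas[2]

    def test_zero_signal_rejected(self):
        rec = MultiChannelRecording(samples=np.zeros((56, 100)))
        with pytest.raises(ValueError):
            add_noise(rec, -5.0, seed=0)

    def test_sigma_matches_materialized_series(self, small_bank):
        """Per-window sigma equals the sigma of the real assembled series."""
        n, dur = 120, 0.5
        series = assemble_time_series(small_bank, n, dur, seed=7)
        p_sig = np.mean(series.samples**2)
        expected = np.sqrt(p_sig / 10.0 ** (-5.0 / 10.0))
        assert series_noise_sigma(small_bank, -5.0, n, dur) == pytest.approx(expected, rel=1e-12)


class TestPeakIndex:
    def test_tie_breaks_earliest_then_lowest_channel(self):
        x = np.zeros((3, 10))
        x[2, 4] = 1.0
        x[1, 4] = 1.0
        x[0, 7] = 1.0
        t, c = global_peak_index(x)
        assert (t, c) == (4, 1)

    def test_bank_clips_are_peak_centered(self, small_bank):
        for clip in small_bank.clips:
            t, _ = global_peak_index(clip)
            assert t == small_bank.peak_offset
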