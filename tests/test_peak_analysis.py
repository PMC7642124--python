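import numpy as np
import pytest

from dicect.errors import PairingError, RangeError, ValidationError
from dicect.peak_analysis import (EdgeCandidate, detect_edge_peaks,
                                  pair_edges, segment_stats, smooth_profile)
from dicect.profile_model import LineProfile


class TestSmoothProfile:
    def test_constant_profile_reproduced_exactly(self, make_profile):
        sp = smooth_profile(make_profile(np.full(50, 7.0)))
        scale = 7.0
        assert np.abs(sp.smoothed - 7.0).max() < 1e-9 * scale
        assert np.abs(sp.derivative).max() < 1e-9 * scale

    def test_zero_penalty_reproduces_cubic(self, make_profile):
        x = np.linspace(0, 10, 100)
        y = 2 + 3 * x - 0.5 * x ** 2 + 0.01 * x ** 3
        sp = smooth_profile(make_profile(y), smoothing=0.0)
        assert np.abs(sp.smoothed - y).max() / np.abs(y).max() < 1e-6

    def test_gcv_residual_below_injected_noise(self, make_profile):
        rng = np.random.default_rng(1)
        x = np.linspace(0, 20, 500)
        clean = 1000.0 / (1.0 + np.exp(-(x - 10) / 0.5))
        noisy = clean + rng.normal(0, 50.0, x.size)
        prof = make_profile(noisy, length_mm=20.0)
        sp = smooth_profile(prof)
        residual_sd = np.std(noisy - sp.smoothed, ddof=1)
        assert residual_sd < 50.0

    def test_rejects_bad_input(self, make_profile):
        bad = make_profile(np.zeros(20))
        bad.intensities[3] = np.nan
        with pytest.raises(ValidationError, match="finite"):
            smooth_profile(bad)


class TestDetectEdgePeaks:
    def test_flat_derivative_yields_nothing(self, make_profile):
        sp = smooth_profile(make_profile(np.full(50, 3.0)))
        assert detect_edge_peaks(sp) == []

    def test_sigmoid_step_located_at_center(self, make_profile):
        x = np.linspace(0, 10, 200)
        y = 1000.0 / (1.0 + np.exp(-(x - 5.0) / 0.3))
        cands = detect_edge_peaks(smooth_profile(make_profile(y)))
        assert len(cands) == 1
        c = cands[0]
        assert c.sign == "rising" and c.signed_height > 0
        # the generating sigmoid's derivative peaks exactly at 5 mm
        assert abs(c.position_mm - 5.0) <= 0.5 * (x[1] - x[0])

    def test_two_edge_tissue_recovers_both_fronts(self, make_profile):
        x = np.linspace(0, 10, 500)
        y = np.full_like(x, 100.0)
        y[(x >= 3.0) & (x <= 7.0)] += 900.0
        cands = detect_edge_peaks(smooth_profile(make_profile(y)))
        spacing = x[1] - x[0]
        strong = sorted(cands, key=lambda c: -c.prominence)[:2]
        strong.sort(key=lambda c: c.position_mm)
        assert strong[0].sign == "rising" and strong[1].sign == "falling"
        assert abs(strong[0].position_mm - 3.0) <= spacing
        assert abs(strong[1].position_mm - 7.0) <= spacing


def cand(pos, height, prominence=None):
    return EdgeCandidate(position_mm=pos, signed_height=height,
                         sign="rising" if height > 0 else "falling",
                         prominence=abs(height) if prominence is None
                         else prominence)


class TestPairEdges:
    def test_symmetric_pair_about_midpoint(self):
        es = pair_edges([cand(2.0, 100.0), cand(8.0, -100.0)],
                        expected_pairs=1, midpoint_mm=5.0)
        assert es.paired_edges == (2.0, 8.0)
        assert es.strengths == (100.0, 100.0)
        assert es.pairing_source == "automatic"

    def test_override_skips_central_trough(self):
        # an unstained tissue core produces a spurious interior peak pair
        cands = [cand(2.0, 100.0), cand(4.0, -150.0), cand(6.0, 150.0),
                 cand(8.0, -100.0)]
        es = pair_edges(cands, expected_pairs=1, midpoint_mm=5.0,
                        override=[2.0, 8.0], override_window_mm=0.5)
        assert es.paired_edges == (2.0, 8.0)
        assert es.pairing_source == "override"

    def test_too_few_candidates_is_an_error(self):
        with pytest.raises(PairingError, match="1 left"):
            pair_edges([cand(2.0, 100.0)], expected_pairs=1, midpoint_mm=5.0)

    def test_override_without_nearby_candidate_is_an_error(self):
        with pytest.raises(PairingError, match="3"):
            pair_edges([cand(2.0, 100.0), cand(8.0, -100.0)],
                       expected_pairs=1, midpoint_mm=5.0,
                       override=[3.0, 8.0], override_window_mm=0.2)

    def test_suppression_rejects_ringing_sidelobe(self):
        # side-lobe 0.1 mm from the main peak must not displace the true
        # second edge under a 0.3 mm suppression radius
        cands = [cand(2.0, 500.0), cand(2.1, -400.0), cand(4.0, -300.0),
                 cand(6.0, 300.0), cand(8.0, -500.0)]
        es = pair_edges(cands, expected_pairs=2, midpoint_mm=5.0,
                        suppression_mm=0.3)
        assert es.paired_edges[:2] == (2.0, 4.0)


class TestSegmentStats:
    def test_constant_segment(self, make_profile):
        sp = smooth_profile(make_profile(np.full(100, 12.0)))
        s = segment_stats(sp, (2.0, 8.0))
        assert s.mean_hu == pytest.approx(12.0)
        assert s.median_hu == pytest.approx(12.0)
        assert s.sd_hu == pytest.approx(0.0, abs=1e-9)
        assert s.iqr_hu == pytest.approx(0.0, abs=1e-9)

    def test_closed_form_five_values(self):
        # bypass smoothing: stats operate on the stored smoothed values
        from dicect.peak_analysis import SmoothedProfile
        x = np.linspace(0, 6, 7)
        vals = np.array([0.0, 1, 2, 3, 4, 5, 0.0])
        sp = SmoothedProfile(positions=x, smoothed=vals,
                             derivative=np.zeros_like(x),
                             smoothing_parameter=0.0, smoothing_method="fixed")
        s = segment_stats(sp, (0.5, 5.5))
        assert s.mean_hu == pytest.approx(3.0)
        assert s.median_hu == pytest.approx(3.0)
        assert s.sd_hu == pytest.approx(np.sqrt(2.5), rel=1e-6)  # 1.5811
        assert s.n_samples == 5

    def test_linear_ramp_iqr(self, make_profile):
        x = np.linspace(0, 10, 500)
        prof = make_profile(100.0 + 50.0 * x)
        sp = smooth_profile(prof, smoothing=0.0)
        s = segment_stats(sp, (0.0, 10.0))
        ramp_range = 500.0
        assert s.iqr_hu == pytest.approx(0.5 * ramp_range, rel=0.01)

    def test_range_and_degeneracy_errors(self, make_profile):
        sp = smooth_profile(make_profile(np.zeros(100)))
        with pytest.raises(RangeError, match="outside"):
            segment_stats(sp, (-1.0, 5.0))
        with pytest.raises(RangeError, match="interior"):
            segment_stats(sp, (5.0, 5.05))


@pytest.fixture(scope="module")
def noisy_profile():
    from dicect.synthetic import generate_profile, goldfish_slice_spec
    spec = goldfish_slice_spec(1, noise_sd=80.0, seed=3)
    prof, _ = generate_profile(spec, 48.0)
    return prof


class TestInvariances:
    def test_mirror_symmetry(self, noisy_profile):
        """Reversing a profile reverses edge positions and swaps signs."""
        p = noisy_profile
        L = p.positions[0] + p.positions[-1]
        rev = LineProfile(species=p.species, specimen_id=p.specimen_id,
                          slice_index=p.slice_index, time_h=p.time_h,
                          positions=L - p.positions[::-1],
                          intensities=p.intensities[::-1])
        c1 = detect_edge_peaks(smooth_profile(p))
        c2 = detect_edge_peaks(smooth_profile(rev))
        assert len(c1) == len(c2)
        pos1 = [c.position_mm for c in c1]
        pos2 = sorted(L - c.position_mm for c in c2)
        np.testing.assert_allclose(pos1, pos2, atol=1e-9)
        signs2 = {round(L - c.position_mm, 6): c.sign for c in c2}
        for c in c1:
            assert signs2[round(c.position_mm, 6)] != c.sign

    def test_scale_equivariance(self, noisy_profile):
        """Intensity scaling by c > 0 scales strengths and statistics by c."""
        p = noisy_profile
        scaled = LineProfile(species=p.species, specimen_id=p.specimen_id,
                             slice_index=p.slice_index, time_h=p.time_h,
                             positions=p.positions,
                             intensities=3.0 * p.intensities)
        sp1, sp3 = smooth_profile(p), smooth_profile(scaled)
        np.testing.assert_allclose(sp3.smoothed, 3.0 * sp1.smoothed,
                                   rtol=1e-9)
        c1 = detect_edge_peaks(sp1)
        c3 = detect_edge_peaks(sp3)
        np.testing.assert_allclose([c.signed_height for c in c3],
                                   [3.0 * c.signed_height for c in c1],
                                   rtol=1e-6)
        s1 = segment_stats(sp1, (3.0, 5.0))
        s3 = segment_stats(sp3, (3.0, 5.0))
        for a, b in ((s3.mean_hu, s1.mean_hu), (s3.sd_hu, s1.sd_hu),
                     (s3.iqr_hu, s1.iqr_hu)):
            assert a == pytest.approx(3.0 * b, rel=1e-9)
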