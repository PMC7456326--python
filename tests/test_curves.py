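"""Curve analysis: contour transform, increment detection, classification."""

import numpy as np
import pytest

from catchkit.curves import (
    CurveRecord,
    Increment,
    RejectedCurveError,
    RuptureDetectionError,
    align_and_superimpose_histograms,
    analyze_curve,
    classify_pathway,
    detect_unfolding_increments,
    expected_contour_increment,
    extract_rupture_and_loading_rate,
    filter_fingerprint_curves,
    to_contour_length_space,
)
from catchkit.elasticity import Environment, WLCParams, wlc_extension, wlc_force
from catchkit.simulate import (
    PullingProtocol,
    default_network,
    simulate_constant_speed,
)

ENV = Environment()


def test_xmod_expected_increment_arithmetic():
    # 116 residues x 0.365 nm/aa - 5.3 nm folded length = 37 nm
    v = expected_contour_increment(116, 5.3)
    assert v == pytest.approx(116 * 0.365 - 5.3, abs=1e-12)
    assert v == pytest.approx(37.0, abs=0.1)


class TestContourTransform:
    def test_frc_consistent_stretch_is_a_single_exact_plateau(self):
        """Data generated by the FRC force law itself transforms to a
        plateau with machine-precision spread."""
        from catchkit.elasticity import FRCParams
        p = FRCParams()
        forces = np.linspace(15.0, 300.0, 1500)
        frac = np.where(forces * p.b / ENV.kBT < p.frc_persistence / p.b,
                        1 - (4 * forces * p.frc_persistence / ENV.kBT) ** -0.5,
                        1 - (2 * forces * p.b / ENV.kBT) ** -1)
        trace = to_contour_length_space(200.0 * frac, forces)
        assert trace.contour_length.max() - trace.contour_length.min() < 1e-9
        assert detect_unfolding_increments(trace) == []

    def test_single_wlc_stretch_gives_one_plateau(self):
        """A WLC-generated stretch concentrates into one plateau (no
        increments); the residual spread reflects the WLC/FRC model
        difference, bounded well below any unfolding increment."""
        wlc = WLCParams(Lc=200.0)
        x_hi = wlc_extension(300.0, wlc, ENV)
        x = np.arange(0.05, x_hi, 0.05)
        trace = to_contour_length_space(x, wlc_force(x, wlc, ENV))
        iqr = np.subtract(*np.percentile(trace.contour_length, [75, 25]))
        assert iqr < 10.0
        assert detect_unfolding_increments(trace) == []

    def test_two_plateau_curve_shows_the_unfolding_increment(self):
        wlc1, wlc2 = WLCParams(Lc=200.0), WLCParams(Lc=232.0)
        f1 = np.linspace(12.0, 90.0, 1500)
        f2 = np.linspace(45.0, 90.0, 1500)
        x = np.concatenate([wlc_extension(f1, wlc1, ENV),
                            wlc_extension(f2, wlc2, ENV)])
        trace = to_contour_length_space(x, np.concatenate([f1, f2]))
        incs = detect_unfolding_increments(trace)
        assert len(incs) == 1
        assert incs[0].size == pytest.approx(32.0, abs=2.0)

    def test_all_zero_force_curve_is_rejected(self):
        with pytest.raises(RejectedCurveError):
            to_contour_length_space(np.linspace(0, 100, 50), np.zeros(50))


class TestIncrementsOnSimulatedCurves:
    def find_curve(self, pathway, seed0=0):
        net = default_network()
        prot = PullingProtocol(speed=400.0)
        for i in range(400):
            c = simulate_constant_speed(net, prot,
                                        np.random.default_rng(seed0 + i))
            if c.ruptured and c.true_pathway == pathway:
                return c
        raise AssertionError(f"no {pathway} curve found")

    def test_p2_curve_increments_match_simulated_events(self):
        """A pathway-2 curve carries four fingerprint sub-steps (15/17 nm,
        totalling 64 nm) and one XMod step (37 nm), all within +-2 nm."""
        c = self.find_curve("P2")
        trace = to_contour_length_space(c.extension, c.force)
        incs = detect_unfolding_increments(trace)
        subs = sorted(i.size for i in incs if 11 <= i.size <= 21)
        xmod = [i.size for i in incs if 34 <= i.size <= 42]
        assert len(subs) == 4
        assert sorted(subs) == pytest.approx([15, 15, 17, 17], abs=2.0)
        assert sum(subs) == pytest.approx(64.0, abs=3.0)
        assert len(xmod) == 1
        assert xmod[0] == pytest.approx(37.0, abs=2.0)

    def test_increment_sizes_do_not_depend_on_pulling_speed(self, study_frame):
        """Contour-length increments are geometric, not kinetic."""
        means = [grp.loc[grp["fingerprint_ok"], "fp_total"].mean()
                 for _, grp in study_frame.groupby("speed")]
        assert max(means) - min(means) < 1.0


class TestFingerprintFilter:
    def rec(self, sizes):
        return CurveRecord(source_id="t", rupture_force=400.0,
                           increments=[Increment(position=100.0 + i, size=s)
                                       for i, s in enumerate(sizes)])

    def test_valid_double_fingerprint_accepted(self):
        recs = [self.rec([15.0, 17.0, 15.0, 17.0])]
        assert filter_fingerprint_curves(recs) == recs
        assert recs[0].fingerprint_ok

    def test_single_domain_or_merged_increment_rejected(self):
        for sizes in ([15.0, 17.0], [32.0], [32.0, 15.0, 17.0]):
            recs = [self.rec(sizes)]
            assert filter_fingerprint_curves(recs) == []
            assert not recs[0].fingerprint_ok

    def test_batch_acceptance_rate_at_least_95pct(self, study_frame):
        grp = study_frame[(study_frame["speed"] == 400.0)
                          & study_frame["ruptured"]]
        assert grp["fingerprint_ok"].mean() >= 0.95


class TestClassification:
    def test_xmod_step_forces_p2(self):
        rec = CurveRecord(source_id="a", rupture_force=180.0,
                          increments=[Increment(0, s)
                                      for s in (15, 17, 15, 17, 37.5)])
        assert classify_pathway(rec) == "P2"
        assert rec.xmod_step_present

    def test_threshold_separates_p1_from_p3(self):
        hi = CurveRecord(source_id="a", rupture_force=520.0,
                         increments=[Increment(0, s) for s in (15, 17, 15, 17)])
        lo = CurveRecord(source_id="b", rupture_force=190.0,
                         increments=[Increment(0, s) for s in (15, 17, 15, 17)])
        assert classify_pathway(hi) == "P1"
        assert classify_pathway(lo) == "P3"

    def test_confusion_vs_simulator_truth(self, study_frame):
        """Pathway recovery on the full 400 nm/s batch: >=97% accuracy and
        per-pathway fractions within binomial 3 sigma of the truth."""
        grp = study_frame[(study_frame["speed"] == 400.0)
                          & study_frame["ruptured"]]
        acc = (grp["pathway"] == grp["true_pathway"]).mean()
        assert acc >= 0.97
        n = len(grp)
        for p in ("P1", "P2", "P3"):
            truth = (grp["true_pathway"] == p).mean()
            est = (grp["pathway"] == p).mean()
            sigma = np.sqrt(truth * (1 - truth) / n)
            assert abs(est - truth) <= 3 * sigma + 3.0 / n

    def test_classification_robust_to_small_force_offset(self):
        net = default_network()
        c = simulate_constant_speed(net, PullingProtocol(speed=400.0),
                                    np.random.default_rng(3))
        base = analyze_curve(c)
        shifted = type("C", (), {})()
        shifted.time, shifted.extension = c.time, c.extension
        shifted.force = np.where(c.force > 0, c.force + 4.0, c.force)
        after = analyze_curve(shifted)
        assert base.pathway == after.pathway


class TestRuptureExtraction:
    def test_linear_ramp_recovers_slope_exactly(self):
        t = np.linspace(0, 5.0, 2501)
        f = 100.0 * t
        f[f > 400.0] = 0.0
        x = np.linspace(0, 50.0, 2501)
        rupture, rate = extract_rupture_and_loading_rate(t, x, f)
        assert rupture == pytest.approx(400.0, abs=0.5)
        assert rate == pytest.approx(100.0, rel=1e-9)

    def test_simulated_rupture_force_within_5pN_of_event(self):
        net = default_network()
        for seed in range(3):
            c = simulate_constant_speed(net, PullingProtocol(speed=400.0),
                                        np.random.default_rng(seed))
            if not c.ruptured:
                continue
            rupture, rate = extract_rupture_and_loading_rate(
                c.time, c.extension, c.force)
            assert rupture == pytest.approx(c.rupture_event.force, abs=5.0)
            # window-averaged slope vs. instantaneous rate at the event:
            # same order, the secant lags the diverging WLC stiffness
            assert rate == pytest.approx(c.rupture_event.loading_rate, rel=0.4)
            assert rate > 0

    def test_no_terminal_drop_raises(self):
        t = np.linspace(0, 1, 100)
        with pytest.raises(RuptureDetectionError):
            extract_rupture_and_loading_rate(t, t * 10, t * 50)

    def test_loading_rate_grows_with_pulling_speed(self, study_frame):
        med = [grp["loading_rate"].median()
               for _, grp in study_frame.groupby("speed")]
        assert all(a < b for a, b in zip(med[:-1], med[1:]))


class TestHistogramAlignment:
    def test_offset_recovery_and_self_alignment(self):
        h = np.zeros(100)
        h[[20, 35, 52]] = [30, 20, 25]
        shifted = np.roll(h, 5)
        master, offsets = align_and_superimpose_histograms([h, shifted, h])
        assert offsets == [0.0, -5.0, 0.0]
        assert master[20] == 90

    def test_degenerate_histogram_excluded(self):
        h = np.zeros(50)
        h[[10, 30]] = [5, 5]
        single = np.zeros(50)
        single[25] = 7
        master, offsets = align_and_superimpose_histograms([h, single, h])
        assert np.isnan(offsets[1])
        assert master[10] == 10

    def test_master_of_p2_curves_shows_fingerprint_and_xmod_spacings(self):
        """Aligned superposition histogram of several pathway-2 curves keeps
        the 64 nm double-fingerprint span and the ~37 nm XMod spacing."""
        net = default_network()
        prot = PullingProtocol(speed=400.0)
        hists = []
        edges = np.arange(0.0, 400.0, 1.0)
        found = 0
        for i in range(400):
            c = simulate_constant_speed(net, prot, np.random.default_rng(i))
            if not (c.ruptured and c.true_pathway == "P2"):
                continue
            trace = to_contour_length_space(c.extension, c.force)
            hists.append(np.histogram(trace.contour_length, bins=edges)[0]
                         .astype(float))
            found += 1
            if found == 5:
                break
        master, _ = align_and_superimpose_histograms(hists)
        from catchkit.curves import ContourTrace
        # reuse the peak detector on the master by faking a trace
        from scipy.ndimage import gaussian_filter1d
        from scipy.signal import find_peaks
        sm = gaussian_filter1d(np.pad(master, 5), 1.0)
        idx, _ = find_peaks(sm, prominence=0.04 * sm.max(), distance=10)
        peaks = np.sort(idx.astype(float))
        spacings = np.diff(peaks)
        assert peaks[-1] - peaks[0] == pytest.approx(64 + 37, abs=4.0)
        assert spacings[-1] == pytest.approx(37.0, abs=2.5)


def test_analyze_curve_rejects_no_rupture():
    net = default_network()
    c = simulate_constant_speed(net, PullingProtocol(speed=400.0),
                                np.random.default_rng(8))
    flat = type("C", (), {})()
    flat.time = np.linspace(0, 1, 200)
    flat.extension = np.linspace(0, 100, 200)
    flat.force = np.linspace(0, 50, 200)
    rec = analyze_curve(flat)
    assert rec.pathway == "rejected"
    assert rec.rupture_force is None
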