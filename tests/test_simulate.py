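import numpy as np
import pytest

from divnoise import (
    MeasurementModel,
    PartitionSpec,
    SimConfig,
    mean_at_generation,
    simulate_dilution,
    simulate_sizer,
    synth_cytometry_timecourse,
    synth_microscopy_events,
    variance_at_generation,
)


class TestDilution:
    def test_deterministic_halving(self):
        cfg = SimConfig(
            n_lineages=8, max_generation=5, partition=PartitionSpec.delta_half(),
            seed=0, founder_marker_mean=1024.0, founder_log2_sd=0.0,
        )
        res = simulate_dilution(cfg)
        assert np.all(res.markers[5] == 32.0)

    def test_two_point_support_after_two_divisions(self):
        f = 0.3
        cfg = SimConfig(
            n_lineages=4000, max_generation=2, partition=PartitionSpec.two_point(f),
            seed=1, founder_marker_mean=1.0, founder_log2_sd=0.0,
        )
        m2 = simulate_dilution(cfg).markers[2]
        support = {0.09, 0.21, 0.49}  # f^2, f(1-f), (1-f)^2
        assert set(np.round(np.unique(m2), 10)) == support
        frac = {v: np.mean(np.isclose(m2, v)) for v in support}
        assert frac[0.09] == pytest.approx(0.25, abs=0.02)
        assert frac[0.21] == pytest.approx(0.50, abs=0.02)
        assert frac[0.49] == pytest.approx(0.25, abs=0.02)

    def test_exact_conservation_and_tree_size(self):
        cfg = SimConfig(
            n_lineages=50, max_generation=6, partition=PartitionSpec.gaussian(0.1), seed=3
        )
        res = simulate_dilution(cfg)
        for g in range(6):
            parents, children = res.markers[g], res.markers[g + 1]
            assert children.size == 2 * parents.size == 50 * 2 ** (g + 1)
            np.testing.assert_allclose(
                children[0::2] + children[1::2], parents, rtol=1e-12
            )

    def test_moments_match_closed_forms(self):
        cfg = SimConfig(
            n_lineages=10_000, max_generation=6,
            partition=PartitionSpec.gaussian(0.07), seed=1, founder_marker_mean=1.0,
        )
        res = simulate_dilution(cfg)
        mu0, s0 = res.mean(0), res.variance(0)
        rng = np.random.default_rng(0)
        for g in range(7):
            m = res.markers[g]
            assert res.mean(g) == pytest.approx(mean_at_generation(mu0, g), rel=0.005)
            # 3 bootstrap SDs over founders
            founders = m.reshape(10_000, -1)
            boot = np.array([
                founders[rng.integers(0, 10_000, 10_000)].var() for _ in range(60)
            ])
            target = variance_at_generation(mu0, s0, cfg.partition, g)
            tol = max(3 * boot.std(), 1e-12)
            assert abs(res.variance(g) - target) <= tol + 0.05 * target

    def test_determinism_and_overflow_guard(self):
        cfg = SimConfig(n_lineages=10, max_generation=4, seed=7)
        a = simulate_dilution(cfg)
        b = simulate_dilution(cfg)
        for ga, gb in zip(a.markers, b.markers):
            np.testing.assert_array_equal(ga, gb)
        with pytest.raises(ValueError, match="overflow"):
            SimConfig(n_lineages=1, max_generation=26, seed=0)


class TestSizer:
    def test_synchronous_doubling_in_degenerate_limit(self):
        cfg = SimConfig(
            n_lineages=20, max_generation=4, partition=PartitionSpec.delta_half(),
            mode="sizer", seed=2, threshold_cv=0.0, founder_log2_sd=0.0,
        )
        pop = simulate_sizer(cfg, t_end=80.0)
        tau = np.log(2.0) / cfg.growth_rate
        for g in range(4):
            sel = pop.generation == g
            np.testing.assert_allclose(pop.division_time[sel], (g + 1) * tau, rtol=1e-12)
        assert pop.alive_at(tau * 2.5).size == 20 * 4  # deterministic doubling

    def test_small_daughter_cycles_longer(self):
        f = 0.3
        cfg = SimConfig(
            n_lineages=1, max_generation=2, partition=PartitionSpec.two_point(f),
            mode="sizer", seed=4, threshold_cv=0.0, founder_log2_sd=0.0,
        )
        pop = simulate_sizer(cfg, t_end=500.0)
        kids = pop.generation == 1
        cycles = pop.division_time[kids] - pop.birth_time[kids]
        expected_gap = (np.log(1 / f) - np.log(1 / (1 - f))) / cfg.growth_rate
        assert abs(cycles.max() - cycles.min()) == pytest.approx(expected_gap, rel=1e-9)

    def test_marker_and_size_split_by_same_fraction(self):
        cfg = SimConfig(
            n_lineages=5, max_generation=3, partition=PartitionSpec.gaussian(0.1),
            mode="sizer", seed=5,
        )
        pop = simulate_sizer(cfg, t_end=200.0)
        # siblings are stored as adjacent pairs within a generation block
        gen1 = np.flatnonzero(pop.generation == 1)
        for a, b in zip(gen1[0::2], gen1[1::2]):
            assert pop.parent[a] == pop.parent[b]
            p = int(pop.parent[a])
            assert pop.marker[a] + pop.marker[b] == pytest.approx(pop.marker[p], rel=1e-12)
            f_m = pop.marker[a] / pop.marker[p]
            f_s = pop.birth_size[a] / (pop.birth_size[a] + pop.birth_size[b])
            assert f_m == pytest.approx(f_s, rel=1e-9)

    def test_rejects_bad_parameters(self):
        with pytest.raises(ValueError):
            SimConfig(mode="sizer", growth_rate=-0.1, seed=0)
        with pytest.raises(ValueError, match="mode"):
            SimConfig(mode="timer", seed=0)


class TestCytometryGenerator:
    def test_single_synchronous_division_halves_intensity(self):
        cfg = SimConfig(
            n_lineages=300, max_generation=3, partition=PartitionSpec.delta_half(),
            mode="uncoupled", cycle_time_cv=0.0, founder_log2_sd=0.0, seed=6,
        )
        meas = MeasurementModel(noise_cv=0.0, events_per_acquisition=1000)
        course = synth_cytometry_timecourse(cfg, meas, [0.0, cfg.cycle_time_mean_h + 1.0])
        snap0, snap1 = course[0][0], course[1][0]
        assert np.unique(snap1.intensities).size == 1
        assert snap1.intensities[0] == pytest.approx(snap0.intensities[0] / 2.0)
        assert np.all(course[1][1] == 1)

    def test_log2_peak_spacing_is_unity_without_noise(self):
        cfg = SimConfig(
            n_lineages=500, partition=PartitionSpec.delta_half(), mode="uncoupled",
            founder_log2_sd=0.0, seed=8,
        )
        meas = MeasurementModel(noise_cv=0.0, events_per_acquisition=4000)
        (snap, labels), = synth_cytometry_timecourse(cfg, meas, [40.0])
        x = np.log2(snap.intensities)
        peaks = sorted({round(float(v), 9) for v in x}, reverse=True)
        assert np.allclose(np.diff(peaks), -1.0)

    def test_occupancies_match_cycle_time_convolution(self, rng):
        cfg = SimConfig(n_lineages=3000, partition=PartitionSpec.gaussian(0.07),
                        mode="uncoupled", seed=9)
        meas = MeasurementModel(events_per_acquisition=100_000)  # keep everyone
        t_query = 40.0
        (snap, labels), = synth_cytometry_timecourse(cfg, meas, [t_query])
        counts = np.bincount(labels, minlength=8)[:8]
        occ = counts / counts.sum()
        # oracle: P(generation g alive at t) via Monte-Carlo convolution of
        # iid lognormal cycle times, branch-weighted by 2^g
        m = 200_000
        s = np.sqrt(np.log1p(cfg.cycle_time_cv**2))
        tau = cfg.cycle_time_mean_h * np.exp(rng.normal(-s**2 / 2, s, size=(m, 8)))
        csum = np.cumsum(tau, axis=1)
        w = np.zeros(8)
        w[0] = np.mean(csum[:, 0] > t_query)
        for g in range(1, 8):
            w[g] = 2.0**g * np.mean((csum[:, g - 1] <= t_query) & (csum[:, g] > t_query))
        w /= w.sum()
        np.testing.assert_allclose(occ, w, atol=0.02)

    def test_empty_population_time_rejected(self):
        cfg = SimConfig(n_lineages=10, seed=1)
        meas = MeasurementModel()
        with pytest.raises(ValueError, match="strictly increasing"):
            synth_cytometry_timecourse(cfg, meas, [10.0, 5.0])

    def test_coupling_raises_mean_of_newer_generations(self):
        # matched sigma_f, same seeds: sizer coupling lifts mu_g above the
        # dilution expectation for the newest generations
        deviations = []
        for seed in (31, 32, 33):
            devs = {}
            for mode in ("uncoupled", "sizer"):
                cfg = SimConfig(n_lineages=800, partition=PartitionSpec.gaussian(0.07),
                                mode=mode, seed=seed)
                meas = MeasurementModel(events_per_acquisition=5000)
                course = synth_cytometry_timecourse(cfg, meas, [0.0, 36.0, 60.0, 84.0])
                mu0 = course[0][0].intensities.mean()
                num, den = {}, {}
                for snap, lab in course:
                    for g in np.unique(lab):
                        num[g] = num.get(g, 0.0) + snap.intensities[lab == g].sum()
                        den[g] = den.get(g, 0) + int((lab == g).sum())
                top = max(g for g in den if den[g] >= 50)
                devs[mode] = (num[top] / den[top]) / (mu0 / 2**top)
            deviations.append(devs["sizer"] - devs["uncoupled"])
        assert all(d > 0 for d in deviations)


class TestMicroscopyGenerator:
    def test_symmetric_noiseless_daughters_identical(self):
        events, true_f = synth_microscopy_events(
            3, PartitionSpec.delta_half(), noise_cv=0.0, seed=11
        )
        for ev in events:
            np.testing.assert_allclose(ev.daughter1.intensity, ev.daughter2.intensity)
        assert np.all(true_f == 0.5)

    def test_two_to_one_ratio_preserved_every_frame(self):
        events, true_f = synth_microscopy_events(
            2, PartitionSpec.two_point(2.0 / 3.0), noise_cv=0.0, seed=12
        )
        for ev, f in zip(events, true_f):
            ratio = ev.daughter1.intensity / ev.daughter2.intensity
            expected = f / (1 - f)
            np.testing.assert_allclose(ratio, expected, rtol=1e-12)

    def test_sampled_fraction_spread_matches_pi(self):
        _, true_f = synth_microscopy_events(
            500, PartitionSpec.gaussian(0.1), noise_cv=0.0, seed=13
        )
        se = 0.1 / np.sqrt(2 * (500 - 1))  # SE of a sample SD
        assert abs(true_f.std() - 0.1) < 4 * se

    def test_frame_floor(self):
        with pytest.raises(ValueError, match="2 frames"):
            synth_microscopy_events(1, PartitionSpec.delta_half(), frames_per_side=1)
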