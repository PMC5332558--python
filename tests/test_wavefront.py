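import numpy as np
import pytest

from polwave.annotation import TranscriptModel
from polwave.coverage import window_from_start_counts
from polwave.synthetic import WaveKineticsConfig, make_annotation, simulate_groseq
from polwave.wavefront import (
    AnalysisConfig,
    WaveFrontCall,
    call_wavefront,
    cohort_rates,
    exon_mask_offsets,
    filter_gene_set,
    fit_rate,
    median_wavefront,
    pairwise_rate,
)

from conftest import brute_force_front, make_window


def random_window(rng, length=20_000):
    """Blocky random depth with random exon masks, built to exercise
    island/gap interactions around the thresholds."""
    depth = np.zeros(length)
    pos = 0
    while pos < length:
        run = int(rng.integers(50, 4_000))
        level = rng.choice([0.0, 1.0, 3.0, 5.0], p=[0.45, 0.15, 0.2, 0.2])
        depth[pos : pos + run] = level
        pos += run
    mask = np.zeros(length, dtype=bool)
    for _ in range(int(rng.integers(0, 5))):
        a = int(rng.integers(0, length - 500))
        mask[a : a + int(rng.integers(50, 500))] = True
    return depth, mask


class TestCallWavefront:
    def test_simple_island_front_at_last_covered_bp(self):
        depth = np.zeros(120_001)
        depth[:10_000] = 3.0
        call = call_wavefront(make_window(depth))
        assert call.status == "called"
        assert call.position == 9_999
        assert not call.reached_window_end

    def test_subthreshold_gaps_shorter_than_halt_gap_are_bridged(self):
        depth = np.zeros(120_001)
        # islands separated by 4,999 bp of zeros, then a 6,000 bp gap
        depth[0:2_000] = 5.0
        depth[6_999:9_000] = 5.0
        depth[13_999:16_000] = 5.0
        depth[22_000:30_000] = 5.0  # beyond the 6,000 bp gap: ignored
        call = call_wavefront(make_window(depth))
        assert call.position == 15_999

    def test_all_zero_window_has_no_island(self):
        call = call_wavefront(make_window(np.zeros(120_001)))
        assert call.status == "no_island"
        assert call.position is None

    def test_island_to_window_end_flagged(self):
        call = call_wavefront(make_window(np.full(120_001, 4.0)))
        assert call.position == 120_000
        assert call.reached_window_end

    def test_masked_exon_spike_neither_extends_nor_breaks(self):
        config = AnalysisConfig(halt_gap=5_000)
        depth = np.zeros(120_001)
        depth[:10_000] = 5.0
        depth[20_000:20_100] = 50.0  # contamination spike inside an exon
        mask = np.zeros(120_001, dtype=bool)
        mask[20_000:20_100] = True
        call = call_wavefront(make_window(depth), config, mask)
        assert call.position == 9_999  # spike did not seed a later island
        # and masked bases do not count toward the halt gap either:
        depth2 = np.zeros(120_001)
        depth2[:10_000] = 5.0
        depth2[14_500:16_000] = 5.0
        mask2 = np.zeros(120_001, dtype=bool)
        mask2[10_000:14_500] = True  # 4,500 masked + 0 unmasked below: no gap
        call2 = call_wavefront(make_window(depth2), config, mask2)
        assert call2.position == 15_999

    def test_fully_masked_window_rejected(self):
        with pytest.raises(ValueError, match="masked"):
            call_wavefront(
                make_window(np.ones(100)), AnalysisConfig(), np.ones(100, dtype=bool)
            )

    def test_agrees_with_bruteforce_scan_on_random_windows(self, rng):
        config = AnalysisConfig(depth_threshold=3.0, halt_gap=2_000)
        for _ in range(200):
            depth, mask = random_window(rng)
            call = call_wavefront(make_window(depth), config, mask)
            front, reached_end = brute_force_front(depth, mask, 3.0, 2_000)
            if front is None:
                assert call.status == "no_island"
            else:
                assert call.position == front
                assert call.reached_window_end == reached_end

    def test_longer_halt_gap_never_moves_front_upstream(self, rng):
        for _ in range(50):
            depth, mask = random_window(rng)
            fronts = []
            for gap in (500, 1_000, 2_000, 4_000):
                c = call_wavefront(make_window(depth), AnalysisConfig(halt_gap=gap), mask)
                fronts.append(-1 if c.position is None else c.position)
            assert fronts == sorted(fronts)

    def test_truth_recovery_on_noiseless_simulation(self):
        kin = WaveKineticsConfig(
            conditions=("UV",),
            time_points=(10.0, 25.0, 40.0),
            speeds={"UV": 0.5},
            background=0.0,
            noise="none",
            seed=1,
        )
        ann = make_annotation(5, (80_000, 110_000), seed=2)
        sim = simulate_groseq(ann, kin)
        for t_min in kin.time_points:
            for gid, counts in sim.counts[("UV", t_min)].items():
                w = window_from_start_counts(gid, counts, ("UV", t_min))
                call = call_wavefront(w)
                assert call.position == int(500 * t_min) - 1  # last wave bp


class TestRates:
    def test_median_single_and_pair(self):
        calls = [WaveFrontCall("a", "s", 10_000)]
        assert median_wavefront(calls) == 10_000
        calls.append(WaveFrontCall("b", "s", 20_000))
        assert median_wavefront(calls) == 15_000

    def test_median_matches_sort_oracle(self, rng):
        pos = rng.integers(0, 120_000, size=101)
        calls = [WaveFrontCall(f"g{i}", "s", int(p)) for i, p in enumerate(pos)]
        assert median_wavefront(calls) == sorted(pos)[50]

    def test_median_requires_called_fronts(self):
        with pytest.raises(ValueError):
            median_wavefront([WaveFrontCall("a", "s", None, "no_island")])

    @pytest.mark.parametrize(
        "p1,p2,expected",
        [
            (12_500, 39_000, 1.77),  # untreated 10-25 min
            (39_000, 64_800, 1.72),  # untreated 25-40 min
            (10_300, 17_300, 0.47),  # UV 10-25 min
            (17_300, 21_000, 0.25),  # UV 25-40 min
        ],
    )
    def test_pairwise_rate_on_median_front_positions(self, p1, p2, expected):
        assert round(pairwise_rate(p1, p2, 15.0), 2) == expected

    def test_pairwise_rate_zero_and_errors(self):
        assert pairwise_rate(5_000, 5_000, 15.0) == 0.0
        with pytest.raises(ValueError):
            pairwise_rate(0, 1, 0)

    def test_fit_rate_exact_on_collinear_points(self):
        times = [120, 300, 480, 600, 720]
        pos = [40.0 * t for t in times]  # 0.04 kb/min
        est = fit_rate(times, pos)
        assert est.rate == pytest.approx(0.04)
        assert est.r_squared == pytest.approx(1.0)

    def test_fit_rate_two_points_equals_pairwise(self):
        est = fit_rate([10, 25], [12_500, 39_000])
        assert est.rate == pytest.approx(pairwise_rate(12_500, 39_000, 15))

    def test_fit_rate_matches_normal_equations(self, rng):
        t = np.array([10.0, 25.0, 40.0, 55.0, 70.0, 85.0])
        p = 500.0 * t + rng.normal(0, 2_000, size=6)
        est = fit_rate(t, p)
        slope = ((t - t.mean()) * (p - p.mean())).sum() / ((t - t.mean()) ** 2).sum()
        assert est.rate == pytest.approx(slope / 1000.0)

    def test_fit_rate_needs_two_distinct_times(self):
        with pytest.raises(ValueError):
            fit_rate([10, 10], [1, 2])


def _gene(gid, length=80_000, start=200_000):
    return TranscriptModel(gid, f"{gid}.t", "chrF", "+", start, start + length)


def _calls(gid, fronts, samples):
    return [
        WaveFrontCall(gid, s, p, "called" if p is not None else "no_island")
        for s, p in zip(samples, fronts)
    ]


class TestFilterGeneSet:
    samples = [("UV", 10.0), ("UV", 25.0), ("UV", 40.0)]

    def test_monotone_gene_retained(self):
        calls = _calls("A", [12_000, 39_000, 65_000], self.samples)
        kept, reasons = filter_gene_set(calls, {"A": _gene("A")})
        assert kept == ["A"] and reasons == {}

    def test_non_monotonic_gene_excluded(self):
        calls = _calls("A", [12_000, 39_000, 35_000], self.samples)
        kept, reasons = filter_gene_set(calls, {"A": _gene("A")})
        assert kept == []
        assert reasons["A"] == ["non_monotonic:UV"]

    def test_front_beyond_tts_excluded(self):
        calls = _calls("A", [12_000, 39_000, 79_999], self.samples)
        kept, _ = filter_gene_set(calls, {"A": _gene("A", length=80_000)})
        assert kept == ["A"]  # exactly at the TTS is allowed
        calls = _calls("B", [12_000, 39_000, 80_000], self.samples)
        kept, reasons = filter_gene_set(calls, {"B": _gene("B", length=80_000)})
        assert reasons["B"] == ["front_beyond_tts"]

    def test_missing_sample_raises(self):
        calls = _calls("A", [1_000, 2_000, 3_000], self.samples)
        calls += _calls("B", [1_000, 2_000], self.samples[:2])
        with pytest.raises(ValueError, match="missing"):
            filter_gene_set(calls, {"A": _gene("A"), "B": _gene("B")})

    def test_overlapping_gene_excluded(self):
        calls = _calls("A", [1_000, 2_000, 3_000], self.samples)
        a = _gene("A")
        intruder = TranscriptModel("X", "X.t", "chrF", "-", 250_000, 290_000)
        kept, reasons = filter_gene_set(
            calls, {"A": a}, all_transcripts=[a, intruder]
        )
        assert kept == [] and reasons["A"] == ["overlapping_gene"]

    def test_recovery_mode_rules(self):
        samples = [("untreated", 720.0), ("UV", 720.0)]
        genes = {g: _gene(g, start=200_000 + i * 400_000) for i, g in enumerate("ABCD")}
        calls = []
        calls += _calls("A", [70_000, 30_000], samples)  # good
        calls += _calls("B", [70_000, 30_000], samples)  # not expressed
        calls += _calls("C", [70_000, 30_000], samples)  # no sustained signal
        calls += _calls("D", [30_000, 70_000], samples)  # no UV reduction
        rpkm_tss = {"A": 1.0, "B": 0.1, "C": 1.0, "D": 1.0}
        rpkm_body = {"A": 0.5, "B": 0.5, "C": 0.2, "D": 0.5}
        kept, reasons = filter_gene_set(
            calls,
            genes,
            mode="recovery",
            rpkm_tss=rpkm_tss,
            rpkm_body=rpkm_body,
            untreated_condition="untreated",
        )
        assert kept == ["A"]
        assert reasons["B"] == ["not_expressed"]
        assert reasons["C"] == ["no_sustained_signal"]
        assert reasons["D"] == ["no_uv_reduction"]

    def test_mixed_violations_match_rule_by_rule_oracle(self, rng):
        """30 random genes: the retained set equals independent
        re-application of each rule."""
        samples = self.samples
        genes, calls = {}, []
        truth = {}
        for i in range(30):
            gid = f"g{i:02d}"
            length = int(rng.integers(60_000, 110_000))
            genes[gid] = _gene(gid, length=length, start=200_000 + i * 500_000)
            fronts = sorted(int(x) for x in rng.integers(1_000, 119_000, size=3))
            kind = rng.integers(0, 4)
            if kind == 1:
                fronts[2] = fronts[0]  # non-monotonic
            elif kind == 2:
                fronts[2] = length + 5_000  # beyond TTS
            elif kind == 3 and len(set(fronts)) == 3:
                pass
            calls += _calls(gid, fronts, samples)
            mono = fronts[0] < fronts[1] < fronts[2]
            in_tts = all(f <= length - 1 for f in fronts)
            truth[gid] = mono and in_tts
        kept, _ = filter_gene_set(calls, genes)
        assert set(kept) == {g for g, ok in truth.items() if ok}


class TestCohortRecovery:
    def test_poisson_noise_cohort_rates_recover_truth(self):
        """Noisy simulation at plateau 5 reads/bp: cohort pairwise rates
        recover configured speeds within 15%."""
        kin = WaveKineticsConfig(
            conditions=("fast", "slow"),
            time_points=(10.0, 25.0, 40.0),
            speeds={"fast": 1.77, "slow": 0.25},
            plateau_height=5.0,
            background=0.0,
            noise="poisson",
            seed=7,
        )
        ann = make_annotation(20, (80_000, 110_000), seed=8)
        sim = simulate_groseq(ann, kin)
        calls = []
        for sample, per_gene in sim.counts.items():
            for gid, counts in per_gene.items():
                w = window_from_start_counts(gid, counts, sample)
                calls.append(call_wavefront(w))
        medians, rates = cohort_rates(calls)
        for r in rates:
            truth = 1.77 if "fast" in r.scope else 0.25
            assert abs(r.rate - truth) / truth < 0.15
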