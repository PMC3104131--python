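import numpy as np
import pytest

from cnvcall import (
    ControlCatalog,
    GenomicInterval,
    ProbeTrack,
    RunConfig,
    bridge_segments,
    build_hmm,
    call_sample,
    decode_states,
    filter_common,
    filter_min_probes,
    segments_from_states,
    zscore_normalize,
)
from cnvcall.calling import _viterbi_chromosome
from cnvcall.core import (
    STATE_DECREASED,
    STATE_INCREASED,
    STATE_NORMAL,
    CnvSegment,
)
from cnvcall.errors import (
    AlignmentError,
    ConfigError,
    DegenerateVarianceError,
    InsufficientDataError,
    OrderingError,
)
from cnvcall.simulate import SimSpec, simulate_track

from .conftest import make_states, make_track
from .oracles import enumerate_viterbi


class TestZScoreNormalize:
    def test_three_probe_chromosome_standardizes_with_sample_sd(self):
        z = zscore_normalize(make_track([100, 200, 300], [1.0, 2.0, 3.0]))
        np.testing.assert_allclose(z.chromosomes["chr1"][1], [-1.0, 0.0, 1.0])
        mean, sd = z.stats["chr1"]
        assert mean == pytest.approx(2.0) and sd == pytest.approx(1.0)

    def test_constant_chromosome_is_degenerate(self):
        with pytest.raises(DegenerateVarianceError):
            zscore_normalize(make_track([1, 2, 3], [0.7, 0.7, 0.7]))

    def test_single_probe_chromosome_is_insufficient(self):
        with pytest.raises(InsufficientDataError):
            zscore_normalize(make_track([1], [0.5]))

    def test_chromosomes_centered_independently(self):
        track = ProbeTrack(
            "s",
            {
                "chr1": (np.array([1, 2, 3]), np.array([5.0, 6.0, 7.0])),
                "chr2": (np.array([1, 2, 3]), np.array([-3.0, 0.0, 3.0])),
            },
        )
        z = zscore_normalize(track)
        for chrom in ("chr1", "chr2"):
            vals = z.chromosomes[chrom][1]
            assert vals.mean() == pytest.approx(0.0, abs=1e-9)
            assert vals.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_mean_zero_sd_one_on_random_data(self):
        rng = np.random.default_rng(42)
        track = make_track(np.arange(500) * 1000, rng.normal(0.3, 0.2, 500))
        z = zscore_normalize(track)
        vals = z.chromosomes["chr1"][1]
        assert abs(vals.mean()) < 1e-9
        assert abs(vals.std(ddof=1) - 1.0) < 1e-9


class TestBuildHmm:
    def test_default_parameterization(self, cfg):
        m = build_hmm(cfg)
        np.testing.assert_allclose(m.emission_means, [-2.0, 0.0, 2.0])
        np.testing.assert_allclose(m.emission_sds, [1.0, 1.0, 1.0])
        np.testing.assert_allclose(np.diag(m.transition_matrix), [0.99] * 3)
        off = m.transition_matrix[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, [0.005] * 6)
        np.testing.assert_allclose(m.initial_distribution, [1 / 3] * 3)

    def test_emission_shift_passthrough(self):
        m = build_hmm(RunConfig(emission_mean_shift=3.0))
        np.testing.assert_allclose(m.emission_means, [-3.0, 0.0, 3.0])

    def test_degenerate_self_transition_rejected(self):
        with pytest.raises(ConfigError):
            RunConfig(state_self_transition=1.0)


class TestDecodeStates:
    def test_flat_zscores_decode_all_normal(self, cfg):
        z = zscore_normalize(make_track(np.arange(6) * 1000, [0.1, -0.1, 0.05, -0.05, 0.02, -0.02]))
        states = decode_states(build_hmm(cfg), z)
        # emission evidence is weak everywhere: no transition is worth paying for
        model = build_hmm(cfg)
        path = _viterbi_chromosome(model, np.zeros(6))
        assert (path == STATE_NORMAL).all()
        assert (states.states["chr1"] == STATE_NORMAL).all()

    def test_step_signal_decodes_five_increased_five_normal(self, cfg):
        z = np.array([3.0] * 5 + [0.0] * 5)
        model = build_hmm(cfg)
        path = _viterbi_chromosome(model, z)
        expected = enumerate_viterbi(model, z)
        np.testing.assert_array_equal(path, expected)
        assert (path[:5] == STATE_INCREASED).all()
        assert (path[5:] == STATE_NORMAL).all()

    def test_strong_negative_signal_decodes_all_decreased(self, cfg):
        z = np.array([-3.0] * 8)
        model = build_hmm(cfg)
        path = _viterbi_chromosome(model, z)
        np.testing.assert_array_equal(path, enumerate_viterbi(model, z))
        assert (path == STATE_DECREASED).all()

    def test_matches_exhaustive_enumeration_on_random_tracks(self, cfg):
        model = build_hmm(cfg)
        rng = np.random.default_rng(7)
        for _ in range(60):
            n = int(rng.integers(1, 11))
            z = rng.normal(0, 2, n)
            np.testing.assert_array_equal(
                _viterbi_chromosome(model, z), enumerate_viterbi(model, z)
            )

    def test_no_underflow_on_long_tracks(self, cfg):
        rng = np.random.default_rng(0)
        z = rng.standard_normal(100_000)
        path = _viterbi_chromosome(build_hmm(cfg), z)
        assert len(path) == 100_000


class TestSegmentsFromStates:
    def test_gap_at_or_above_50kb_splits_runs(self, cfg):
        track = make_track([100_000, 120_000, 200_000], [2.5, 2.5, 2.5])
        segs = segments_from_states(make_states("III"), track, cfg)
        assert [(s.start, s.end, s.n_probes) for s in segs] == [
            (100_000, 120_001, 2),
            (200_000, 200_001, 1),
        ]

    def test_exact_50kb_gap_splits(self, cfg):
        track = make_track([0, 50_000], [2.5, 2.5])
        segs = segments_from_states(make_states("II"), track, cfg)
        assert len(segs) == 2  # merge rule is strict "< 50 kb"

    def test_gap_just_under_50kb_merges(self, cfg):
        track = make_track([0, 49_999], [2.5, 2.5])
        segs = segments_from_states(make_states("II"), track, cfg)
        assert len(segs) == 1 and segs[0].n_probes == 2

    def test_single_probe_run_is_one_probe_loss_segment(self, cfg):
        track = make_track([1000, 2000, 3000], [0.0, -3.0, 0.0])
        segs = segments_from_states(make_states("NDN"), track, cfg)
        assert len(segs) == 1
        (seg,) = segs
        assert (seg.start, seg.end, seg.state, seg.n_probes) == (2000, 2001, "loss", 1)

    def test_normal_probes_never_form_segments(self, cfg):
        track = make_track(np.arange(5) * 1000, np.zeros(5))
        assert segments_from_states(make_states("NNNNN"), track, cfg) == []

    def test_mismatched_lengths_rejected(self, cfg):
        track = make_track([1000, 2000], [0.0, 0.0])
        with pytest.raises(AlignmentError):
            segments_from_states(make_states("NNN"), track, cfg)


def _bridge_fixture(gap_probes, gap_span_bp):
    """Two 2-probe gain segments separated by gap_probes normals over a span."""
    left = [0, 1_000]
    right_start = left[-1] + 1 + gap_span_bp
    right = [right_start, right_start + 1_000]
    mids = list(np.linspace(left[-1] + 200, right_start - 200, gap_probes).astype(int))
    pos = left + mids + right
    states = "II" + "N" * gap_probes + "II"
    track = make_track(pos, [2.5, 2.5] + [0.0] * gap_probes + [2.5, 2.5])
    return track, make_states(states)


class TestBridgeSegments:
    def test_three_probes_over_8kb_bridge(self, cfg):
        track, states = _bridge_fixture(3, 8_000)
        segs = segments_from_states(states, track, cfg)
        assert len(segs) == 2
        merged = bridge_segments(segs, states, track, cfg)
        assert len(merged) == 1
        assert merged[0].n_probes == 7  # both segments plus intervening probes
        assert merged[0].start == 0 and merged[0].end == track.chromosomes["chr1"][0][-1] + 1

    def test_six_intervening_probes_block_bridging(self, cfg):
        track, states = _bridge_fixture(6, 8_000)
        segs = segments_from_states(states, track, cfg)
        assert len(bridge_segments(segs, states, track, cfg)) == 2

    def test_span_over_10kb_blocks_bridging(self, cfg):
        track, states = _bridge_fixture(4, 12_000)
        segs = segments_from_states(states, track, cfg)
        assert len(bridge_segments(segs, states, track, cfg)) == 2

    def test_different_states_never_bridge(self, cfg):
        pos = [0, 1_000, 5_000, 6_000]
        track = make_track(pos, [2.5, 2.5, -2.5, -2.5])
        states = make_states("IIDD")
        segs = segments_from_states(states, track, cfg)
        assert len(bridge_segments(segs, states, track, cfg)) == 2

    def test_chained_bridging_reaches_fixed_point(self, cfg):
        # three 2-probe gain segments, each adjacent pair individually bridgeable
        pos, vals, pattern = [], [], ""
        x = 0
        for block in range(3):
            pos += [x, x + 1_000]
            vals += [2.5, 2.5]
            pattern += "II"
            if block < 2:
                pos += [x + 4_000]
                vals += [0.0]
                pattern += "N"
                x += 8_000
        track = make_track(pos, vals)
        states = make_states(pattern)
        segs = segments_from_states(states, track, cfg)
        assert len(segs) == 3
        merged = bridge_segments(segs, states, track, cfg)
        assert len(merged) == 1 and merged[0].n_probes == 8

    def test_unsorted_input_rejected(self, cfg):
        track, states = _bridge_fixture(3, 8_000)
        segs = segments_from_states(states, track, cfg)
        with pytest.raises(OrderingError):
            bridge_segments(segs[::-1], states, track, cfg)


def _seg(start, end, n_probes, state="gain", chrom="chr1"):
    return CnvSegment(chrom, start, end, state, n_probes, 2.0, "s")


class TestFilters:
    def test_min_probe_filter_keeps_five_and_up(self, cfg):
        segs = [_seg(0, 100, 4), _seg(200, 300, 5), _seg(400, 500, 12)]
        assert [s.n_probes for s in filter_min_probes(segs, cfg)] == [5, 12]

    def test_min_probe_filter_empty_input(self, cfg):
        assert filter_min_probes([], cfg) == []

    def test_min_probes_one_is_identity(self):
        cfg1 = RunConfig(min_probes=1)
        segs = [_seg(0, 100, 1), _seg(200, 300, 7)]
        assert filter_min_probes(segs, cfg1) == segs

    def test_identical_catalog_interval_removes_call(self, cfg):
        catalog = ControlCatalog([GenomicInterval("chr1", 0, 100_000, "gain")])
        seg = _seg(0, 100_000, 10)
        assert filter_common([seg], catalog, cfg) == []
        assert seg.rare is False

    def test_no_overlap_retains_call_as_rare(self, cfg):
        catalog = ControlCatalog([GenomicInterval("chr1", 500_000, 600_000, "gain")])
        seg = _seg(0, 100_000, 10)
        assert filter_common([seg], catalog, cfg) == [seg]
        assert seg.rare is True

    def test_forty_percent_reciprocal_overlap_retained_at_half_threshold(self, cfg):
        # overlap 40,000 bp; both intervals 100,000 bp long -> reciprocal 0.4
        catalog = ControlCatalog([GenomicInterval("chr1", 60_000, 160_000, "gain")])
        seg = _seg(0, 100_000, 10)
        assert filter_common([seg], catalog, cfg) == [seg]

    def test_same_type_requirement(self, cfg):
        catalog = ControlCatalog([GenomicInterval("chr1", 0, 100_000, "loss")])
        seg = _seg(0, 100_000, 10)  # gain vs catalog loss
        assert filter_common([seg], catalog, cfg) == [seg]

    def test_survivors_satisfy_soundness(self, cfg):
        rng = np.random.default_rng(3)
        catalog = ControlCatalog(
            [
                GenomicInterval("chr1", int(s), int(s) + 80_000, rng.choice(["gain", "loss"]))
                for s in rng.integers(0, 3_000_000, 30)
            ]
        )
        segs = [
            _seg(int(s), int(s) + int(l), 8, rng.choice(["gain", "loss"]))
            for s, l in zip(rng.integers(0, 3_000_000, 40), rng.integers(20_000, 200_000, 40))
        ]
        from cnvcall import max_reciprocal_overlap

        for seg in filter_common(filter_min_probes(segs, cfg), catalog, cfg):
            assert seg.n_probes >= cfg.min_probes
            same = [iv for iv in catalog.intervals if iv.payload == seg.state]
            assert max_reciprocal_overlap(seg.interval(), same) < cfg.common_overlap_fraction


class TestCallSample:
    def _dup_track(self):
        spec = SimSpec(
            chromosome_lengths={"chr1": 10_000_000},
            noise_sd_log2=0.0,
            implants=[("chr1", 3_000_000, 3_260_000, 3)],
            seed=5,
        )
        return simulate_track(spec)

    def test_noise_free_duplication_called_exactly(self, cfg):
        track, truth = self._dup_track()
        calls = call_sample(track, ControlCatalog([]), cfg)
        assert len(calls) == 1
        (call,) = calls
        assert call.state == "gain"
        assert (call.start, call.end) == (truth[0].start, truth[0].end)

    def test_catalog_match_suppresses_the_call(self, cfg):
        track, truth = self._dup_track()
        catalog = ControlCatalog([GenomicInterval("chr1", truth[0].start, truth[0].end, "gain")])
        assert call_sample(track, catalog, cfg) == []

    def test_flat_track_with_tiny_jitter_yields_no_calls(self, cfg):
        rng = np.random.default_rng(11)
        track = make_track(np.arange(2000) * 25_000 + 25_000, 0.5 + rng.normal(0, 1e-4, 2000))
        assert call_sample(track, ControlCatalog([]), cfg) == []

    def test_calls_invariant_to_per_chromosome_constant_shift(self, cfg):
        spec = SimSpec(
            chromosome_lengths={"chr1": 20_000_000, "chr2": 20_000_000},
            implants=[("chr1", 5_000_000, 5_300_000, 1)],
            seed=9,
        )
        track, _ = simulate_track(spec)
        shifted = ProbeTrack(
            track.sample_id,
            {
                chrom: (pos, val + offset)
                for (chrom, (pos, val)), offset in zip(track, [0.37, -1.2])
            },
        )
        a = call_sample(track, ControlCatalog([]), cfg)
        b = call_sample(shifted, ControlCatalog([]), cfg)
        assert [(s.chromosome, s.start, s.end, s.state) for s in a] == [
            (s.chromosome, s.start, s.end, s.state) for s in b
        ]


class TestMergingMonotonicity:
    @pytest.mark.parametrize("param", ["merge_gap_bp", "bridge_max_bp"])
    def test_larger_thresholds_never_increase_segment_count(self, param):
        rng = np.random.default_rng(21)
        for _ in range(10):
            n = 120
            pos = np.cumsum(rng.integers(2_000, 60_000, n))
            codes = rng.choice([0, 1, 2], size=n, p=[0.15, 0.7, 0.15]).astype(np.int8)
            from cnvcall import StateTrack

            states = StateTrack({"chr1": codes})
            track = make_track(pos, rng.standard_normal(n))
            counts = []
            for value in (5_000, 20_000, 80_000):
                config = RunConfig(**{param: value})
                segs = segments_from_states(states, track, config)
                segs = bridge_segments(segs, states, track, config)
                counts.append(len(segs))
            assert counts[0] >= counts[1] >= counts[2]
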