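"""Tests of asymmetry scoring, block statistics and session success."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nfsearch.errors import (
    DomainError,
    FormatError,
    InsufficientDataError,
    UndefinedStatisticError,
)
from nfsearch.asymmetry_stats import (
    BlockStats,
    asymmetry,
    cohens_d,
    extract_windows,
    score_block,
    session_success,
)
from nfsearch.neuro_signal import BlockProtocol, NirsStream, simulate_block, VirtualSubject


def _stream_from_channels(channels, rate=10.0):
    n = len(channels)
    times = np.arange(n) / rate
    return NirsStream(
        times=times, channels=channels, annotations=np.array(["rest"] * n, dtype=object)
    )


class TestAsymmetry:
    def test_symmetric_channels_give_zero(self):
        chans = np.ones((50, 8))
        assert np.all(asymmetry(_stream_from_channels(chans)) == 0.0)

    def test_left_right_offset(self):
        chans = np.full((20, 8), 0.5)
        chans[:, :4] = 1.0
        np.testing.assert_allclose(asymmetry(_stream_from_channels(chans)), 0.5)

    def test_matches_naive_loop(self):
        rng = np.random.default_rng(0)
        chans = rng.normal(size=(100, 8))
        stream = _stream_from_channels(chans)
        naive = np.array(
            [sum(row[:4]) / 4 - sum(row[4:]) / 4 for row in chans]
        )
        np.testing.assert_allclose(asymmetry(stream), naive, atol=1e-12)

    def test_wrong_channel_count_rejected(self):
        with pytest.raises(FormatError):
            NirsStream(
                times=np.arange(3.0),
                channels=np.zeros((3, 6)),
                annotations=np.array(["rest"] * 3, dtype=object),
            )

    @given(scale=st.floats(-5, 5), offset=st.floats(-5, 5))
    def test_linear_in_channels_and_offset_invariant(self, scale, offset):
        rng = np.random.default_rng(7)
        chans = rng.normal(size=(30, 8))
        base = asymmetry(_stream_from_channels(chans))
        scaled = asymmetry(_stream_from_channels(chans * scale + offset))
        np.testing.assert_allclose(scaled, base * scale, atol=1e-9)


class TestScoreBlock:
    def test_identical_windows_not_successful(self):
        # 15 s rest + 17 s nf at 10 Hz; scored nf window = last 10 s of nf
        protocol = BlockProtocol(
            epochs=(("rest", 15.0), ("nf", 17.0)), baseline_window=10.0
        )
        rng = np.random.default_rng(3)
        window = rng.normal(size=100)
        n = 320
        chans = np.zeros((n, 8))
        t = np.arange(n) / 10.0
        base_mask = (t >= 5.0) & (t < 15.0)
        nf_mask = (t >= 22.0) & (t < 32.0)
        chans[base_mask, :4] = window[:, None]
        chans[nf_mask, :4] = window[:, None]
        stream = simulate_block(
            VirtualSubject(trait_asymmetry=0.0, state_gain=0.0, noise_sd=0.0),
            protocol,
        )
        stream.channels[:] = chans
        stats = score_block(stream, protocol, seed=1)
        assert stats.effect_size == pytest.approx(0.0, abs=1e-12)
        assert stats.t_statistic == pytest.approx(0.0, abs=1e-12)
        assert not stats.success

    def test_noise_free_responder_block_succeeds_at_any_alpha(self, protocol):
        subject = VirtualSubject(trait_asymmetry=0.2, state_gain=1.0, noise_sd=0.0)
        stream = simulate_block(subject, protocol)
        stats = score_block(stream, protocol, seed=0, alpha=1e-6)
        assert stats.success
        assert stats.p_value < 1e-6
        assert stats.effect_size > 1.5
        assert stats.bootstrap_fraction == 1.0

    def test_constant_separated_windows_capped_as_maximal_evidence(self):
        # zero onset delay makes the noise-free response a step: both windows
        # are constant with a positive mean difference
        protocol = BlockProtocol(haemodynamic_delay=0.0)
        subject = VirtualSubject(trait_asymmetry=0.2, state_gain=1.0, noise_sd=0.0)
        stream = simulate_block(subject, protocol)
        stats = score_block(stream, protocol, seed=0)
        assert stats.success
        assert stats.p_value == 0.0
        assert stats.effect_size == 1.5  # capped at the saturation point
        assert stats.bootstrap_fraction == 1.0

    def test_zero_variance_equal_means_undefined(self, protocol):
        subject = VirtualSubject(trait_asymmetry=0.4, state_gain=0.0, noise_sd=0.0)
        stream = simulate_block(subject, protocol)
        with pytest.raises(UndefinedStatisticError):
            score_block(stream, protocol)

    def test_insufficient_samples_rejected(self, responder_subject):
        protocol = BlockProtocol(sampling_rate=0.1)  # 1 baseline sample
        stream = simulate_block(responder_subject, protocol)
        with pytest.raises(InsufficientDataError):
            score_block(stream, protocol)

    def test_window_sizes(self, responder_subject, protocol):
        stream = simulate_block(responder_subject, protocol)
        stats = score_block(stream, protocol, seed=0)
        assert stats.n_baseline == 100  # 10 s at 10 Hz
        assert stats.n_nf == 230  # 23 s post-delay at 10 Hz

    def test_bootstrap_deterministic_given_seed(self, responder_subject, protocol):
        stream = simulate_block(responder_subject, protocol)
        a = score_block(stream, protocol, seed=11)
        b = score_block(stream, protocol, seed=11)
        assert a == b

    def test_disabled_bootstrap_rests_on_t_test(self, responder_subject, protocol):
        stream = simulate_block(responder_subject, protocol)
        stats = score_block(stream, protocol, boot_reps=0, seed=0)
        assert stats.bootstrap_fraction is None
        assert stats.success == (stats.p_value < 0.05)

    def test_null_block_bootstrap_fraction_interior(self, null_subject, protocol):
        stream = simulate_block(null_subject, protocol, seed=2)
        stats = score_block(stream, protocol, seed=2)
        assert 0.0 < stats.bootstrap_fraction < 1.0

    def test_baseline_is_zero_reference_regardless_of_trait(self, protocol):
        # same state gain, very different traits -> same effect size
        a = simulate_block(
            VirtualSubject(trait_asymmetry=0.0, state_gain=0.8, noise_sd=1.0, seed=4),
            protocol,
        )
        b = simulate_block(
            VirtualSubject(trait_asymmetry=5.0, state_gain=0.8, noise_sd=1.0, seed=4),
            protocol,
        )
        sa = score_block(a, protocol, seed=1)
        sb = score_block(b, protocol, seed=1)
        assert sa.effect_size == pytest.approx(sb.effect_size, abs=1e-9)


class TestCohensD:
    def test_known_value(self):
        x = np.array([2.0, 4.0, 6.0])
        y = np.array([1.0, 3.0, 5.0])
        assert cohens_d(x, y) == pytest.approx(0.5)

    def test_zero_pooled_sd_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            cohens_d(np.ones(5), np.ones(5))


class TestSessionSuccess:
    def _block(self, success):
        return BlockStats(0.0, 0.5, 0.0, None, success, 100, 230)

    @pytest.mark.parametrize(
        "successes,total,expected",
        [(3, 6, True), (2, 6, False), (1, 1, True), (2, 4, True), (1, 4, False)],
    )
    def test_at_least_half_rule(self, successes, total, expected):
        blocks = [self._block(i < successes) for i in range(total)]
        assert session_success(blocks) is expected

    def test_empty_session_rejected(self):
        with pytest.raises(DomainError):
            session_success([])


def test_extract_windows_excludes_haemodynamic_delay(responder_subject, protocol):
    stream = simulate_block(responder_subject, protocol)
    win = extract_windows(stream, protocol)
    t = stream.times
    nf_mask = (t >= 37.0) & (t < 60.0)
    assert len(win.nf_samples) == nf_mask.sum()
    assert len(win.baseline_samples) == 100
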