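import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import binom

from dnastore import (
    ChannelParams,
    ConcatenatedDesign,
    RSCode,
    correctable,
    inner_failure_prob,
    outer_decoding_error_logprob,
    outer_decoding_error_prob,
    outer_symbol_channel,
    system_error_curve,
)
from dnastore.reliability import outer_failure_logprob_all_k


def enumeration_oracle(n: int, k: int, p_erasure: float, p_error: float) -> float:
    """Exhaustive sum over all 3^n symbol-outcome vectors."""
    d = n - k + 1
    p_clean = 1.0 - p_erasure - p_error
    total = 0.0
    for states in itertools.product((0, 1, 2), repeat=n):
        e = states.count(1)
        t = states.count(2)
        if 2 * t + e > d - 1:
            total += (p_clean ** (n - e - t)) * (p_erasure**e) * (p_error**t)
    return total


class TestCorrectable:
    @pytest.mark.parametrize(
        "t,e,ok",
        [(16, 0, True), (17, 0, False), (0, 32, True), (0, 33, False), (10, 12, True), (10, 13, False)],
    )
    def test_rs_255_223(self, t, e, ok):
        assert correctable(RSCode(255, 223), t, e) is ok

    def test_brute_force_rs_7_3(self):
        # enumerate every (t, e) against the 2t + e <= d - 1 rule, d = 5
        code = RSCode(7, 3)
        for t in range(8):
            for e in range(8 - t):
                assert correctable(code, t, e) is (2 * t + e <= 4)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            correctable(RSCode(7, 3), -1, 0)
        with pytest.raises(ValueError):
            correctable(RSCode(7, 3), 4, 4)


class TestRSCode:
    def test_distance(self):
        assert RSCode(255, 223).d == 33
        assert RSCode(255, 223).t == 16

    @pytest.mark.parametrize("n,k", [(256, 100), (10, 11), (10, 0)])
    def test_invalid_parameters_rejected(self, n, k):
        with pytest.raises(ValueError):
            RSCode(n, k)


class TestInnerFailure:
    def test_zero_error_rate(self):
        assert inner_failure_prob(RSCode(15, 11), 0.0) == 0.0

    def test_rate_one_code_fails_on_any_error(self):
        # no redundancy: failure iff any of the 5 symbols is wrong
        q = 0.03
        assert inner_failure_prob(RSCode(5, 5), q) == pytest.approx(
            1 - (1 - q) ** 5
        )

    def test_binomial_tail_example(self):
        # RS[15,11] corrects 2 errors; failure = P[Binom(15, 0.01) >= 3],
        # frozen from a term-by-term sum of the binomial pmf
        assert inner_failure_prob(RSCode(15, 11), 0.01) == pytest.approx(
            4.1580e-4, rel=1e-4
        )


class TestOuterSymbolChannel:
    def test_clean_channel(self):
        design = ConcatenatedDesign(outer=RSCode(255, 223), inner=RSCode(40, 36))
        chan = ChannelParams(design.strand_length_nt, breakage_factor=0.0)
        assert outer_symbol_channel(design, chan) == (0.0, 0.0)

    def test_breakage_only(self):
        design = ConcatenatedDesign(outer=RSCode(255, 223), inner=RSCode(40, 36))
        # L = 200, b chosen so L*b = 0.5
        chan = ChannelParams(200, breakage_factor=0.0025)
        p_er, p_err = outer_symbol_channel(design, chan)
        assert p_er == pytest.approx(0.5)
        assert p_err == 0.0

    def test_composition_of_loss_and_inner_failure(self):
        # p_erasure = p_strand + (1 - p_strand) * p_inner
        design = ConcatenatedDesign(outer=RSCode(255, 223), inner=RSCode(90, 84))
        chan = ChannelParams(
            design.strand_length_nt, p_error_per_nt=1e-2, breakage_factor=5e-4
        )
        p_strand = min(1.0, 400 * 5e-4)
        p_in = inner_failure_prob(RSCode(90, 84), 1 - (1 - 1e-2) ** 4)
        p_er, _ = outer_symbol_channel(design, chan)
        assert p_er == pytest.approx(p_strand + (1 - p_strand) * p_in)

    def test_inconsistent_length_rejected(self):
        design = ConcatenatedDesign(outer=RSCode(255, 223), inner=RSCode(40, 36))
        with pytest.raises(ValueError):
            outer_symbol_channel(design, ChannelParams(123))


class TestOuterDecodingError:
    def test_clean(self):
        assert outer_decoding_error_prob(RSCode(255, 223), 0.0, 0.0) == 0.0

    def test_rs_3_1_hand_enumeration(self):
        # d = 3: decoding survives up to 2 erasures; fails only if all
        # 3 symbols are erased -> 0.5^3
        assert outer_decoding_error_prob(RSCode(3, 1), 0.5, 0.0) == pytest.approx(
            0.125
        )

    def test_erasure_only_equals_binomial_tail(self):
        p = outer_decoding_error_prob(RSCode(255, 223), 0.05, 0.0)
        assert p == pytest.approx(float(binom.sf(32, 255, 0.05)), rel=1e-12)

    @pytest.mark.parametrize(
        "n,k,pe,pt",
        [
            (6, 3, 0.1, 0.05),
            (8, 5, 0.3, 0.2),
            (7, 2, 0.0, 0.1),
            (5, 4, 0.2, 0.0),
            (8, 1, 0.4, 0.3),
            (12, 7, 0.15, 0.08),
        ],
    )
    def test_matches_exhaustive_enumeration(self, n, k, pe, pt):
        ours = outer_decoding_error_prob(RSCode(n, k), pe, pt)
        oracle = enumeration_oracle(n, k, pe, pt)
        assert ours == pytest.approx(oracle, rel=1e-10, abs=1e-15)

    def test_normalized_over_full_lattice(self):
        # P[fail] + P[success] accumulated from the same trinomial lattice
        from dnastore.reliability import _logpmf_grid
        from scipy.special import logsumexp

        tt, ee, logp = _logpmf_grid(40, 0.07, 0.03)
        assert math.exp(logsumexp(logp)) == pytest.approx(1.0, rel=1e-12)

    def test_log_domain_reaches_deep_tail(self):
        # far below double underflow on the linear scale
        lp = outer_decoding_error_logprob(RSCode(255, 223), 1e-8, 0.0)
        log10 = lp / math.log(10)
        assert -300 < log10 < -100

    @settings(derandomize=True, max_examples=40)
    @given(
        n=st.integers(3, 30),
        pe=st.floats(0.0, 0.4),
        pt=st.floats(0.0, 0.4),
    )
    def test_monotone_in_redundancy(self, n, pe, pt):
        probs = [
            outer_decoding_error_logprob(RSCode(n, k), pe, pt)
            for k in range(1, n + 1)
        ]
        assert all(b >= a - 1e-9 for a, b in zip(probs, probs[1:]))

    def test_monotone_in_channel_severity(self):
        code = RSCode(63, 47)
        grid = np.linspace(0, 0.3, 10)
        for pt in (0.0, 0.05):
            vals = [outer_decoding_error_logprob(code, pe, pt) for pe in grid]
            assert all(b >= a for a, b in zip(vals, vals[1:]))
        for pe in (0.0, 0.05):
            vals = [outer_decoding_error_logprob(code, pe, pt) for pt in grid]
            assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            outer_decoding_error_prob(RSCode(10, 5), 0.7, 0.4)
        with pytest.raises(ValueError):
            outer_decoding_error_prob(RSCode(10, 5), -0.1, 0.0)


class TestAllKHelper:
    @pytest.mark.parametrize("pe,pt", [(0.1, 0.05), (0.02, 0.0), (0.0, 0.08)])
    def test_matches_scalar_path(self, pe, pt):
        arr = outer_failure_logprob_all_k(12, pe, pt)
        for k in (1, 4, 7, 12):
            assert arr[k - 1] == pytest.approx(
                outer_decoding_error_logprob(RSCode(12, k), pe, pt),
                rel=1e-10, abs=1e-12,
            )


class TestSystemErrorCurve:
    def _template(self):
        return ConcatenatedDesign(outer=RSCode(255, 223), inner=RSCode(26, 20))

    def test_perfect_channel_never_fails(self):
        res = system_error_curve(
            self._template(), [200, 400, 800], p_error_per_nt=0.0,
            breakage_factor=0.0,
        )
        assert all(r.decoder_error_prob == 0.0 for r in res)

    def test_error_curve_monotone_in_length(self):
        res = system_error_curve(
            self._template(), range(150, 1001, 50), copies=1,
            p_error_per_nt=1e-3,
        )
        logs = [r.log10_decoder_error for r in res]
        assert all(b >= a - 1e-9 for a, b in zip(logs, logs[1:]))

    def test_more_copies_never_hurt(self):
        lengths = range(150, 1001, 100)
        one = system_error_curve(self._template(), lengths, copies=1)
        two = system_error_curve(self._template(), lengths, copies=2)
        for r1, r2 in zip(one, two):
            assert r2.log10_decoder_error <= r1.log10_decoder_error + 1e-9

    def test_too_short_strand_rejected(self):
        with pytest.raises(ValueError):
            system_error_curve(self._template(), [60])
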