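"""Analytic decoding-failure probability for interleaved inner-outer
Reed-Solomon codes.

The scheme: each strand carries one codeword of an *inner* RS code (index
bytes + payload + inner parity); one symbol from each of ``outer.n`` strands
forms a codeword of the *outer* RS code.  The inner code corrects symbol
errors within a strand; an inner decode that sees more errors than it can
correct is treated as *detected*, so the outer code sees that strand as an
erasure, exactly like a physically lost strand.

An RS code of minimum distance ``d`` decodes successfully iff
``2*errors + erasures <= d - 1``.  With each outer symbol independently
erased (prob ``p_erasure``), silently wrong (prob ``p_error``), or clean,
the outer failure probability is an exact trinomial tail
``P[2T + E > d - 1]``, evaluated here in the log domain so tails far below
double-precision underflow (the 1e-14 .. 1e-30 regime relevant to archival
reliability targets) are still computed accurately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import binom

from .channel import ChannelParams, strand_erasure_prob, symbol_error_prob

__all__ = [
    "RSCode",
    "ConcatenatedDesign",
    "ReliabilityResult",
    "HARD_DRIVE_ERROR_RATE",
    "correctable",
    "inner_failure_prob",
    "outer_symbol_channel",
    "outer_decoding_error_prob",
    "outer_decoding_error_logprob",
    "outer_failure_logprob_all_k",
    "system_error_curve",
]

#: Reference read-error rate of magnetic hard drives, per bit; the
#: conventional reliability yardstick for storage-system comparisons.
HARD_DRIVE_ERROR_RATE = 1e-14

_LN10 = math.log(10.0)


@dataclass(frozen=True)
class RSCode:
    """An ``[n, k]`` Reed-Solomon block code over GF(256).

    Minimum distance ``d = n - k + 1`` (MDS); corrects ``t`` errors and
    ``e`` erasures whenever ``2t + e <= d - 1``.
    """

    n: int
    k: int

    def __post_init__(self) -> None:
        if not 1 <= self.k <= self.n <= 255:
            raise ValueError(
                f"need 1 <= k <= n <= 255 for 8-bit symbols, got [{self.n},{self.k}]"
            )

    @property
    def d(self) -> int:
        """Minimum distance ``n - k + 1``."""
        return self.n - self.k + 1

    @property
    def t(self) -> int:
        """Errors-only correction radius ``floor((d-1)/2)``."""
        return (self.d - 1) // 2


@dataclass(frozen=True)
class ConcatenatedDesign:
    """Inner RS code (within-strand) + outer RS code (across strands).

    ``index_symbols`` of each inner payload address the strand within the
    file; ``address_nt`` nucleotides per strand are PCR primer targets.
    Physical strand length is ``address_nt + inner.n * nt_per_symbol``.
    """

    outer: RSCode
    inner: RSCode
    index_symbols: int = 4
    address_nt: int = 40
    nt_per_symbol: int = 4

    def __post_init__(self) -> None:
        if self.index_symbols < 0 or self.address_nt < 0:
            raise ValueError("overheads must be non-negative")
        if self.inner.k <= self.index_symbols:
            raise ValueError(
                f"inner k={self.inner.k} leaves no payload after "
                f"{self.index_symbols} index symbols"
            )

    @property
    def strand_length_nt(self) -> int:
        return self.address_nt + self.inner.n * self.nt_per_symbol

    @property
    def payload_symbols_per_strand(self) -> int:
        return self.inner.k - self.index_symbols


@dataclass(frozen=True)
class ReliabilityResult:
    """Outer-code failure probability under one channel condition."""

    p_symbol_erasure: float
    p_symbol_error: float
    decoder_error_prob: float
    log10_decoder_error: float
    strand_length: int | None = None


def correctable(code: RSCode, errors: int, erasures: int) -> bool:
    """Whether ``errors`` unknown-position errors plus ``erasures``
    known-position erasures are within the code's capability."""
    if errors < 0 or erasures < 0:
        raise ValueError("error/erasure counts must be non-negative")
    if errors + erasures > code.n:
        raise ValueError("more corrupted symbols than code length")
    return 2 * errors + erasures <= code.d - 1


def inner_failure_prob(inner: RSCode, p_symbol: float) -> float:
    """Probability an inner decode sees more errors than it can correct.

    ``P[X > t]`` for ``X ~ Binomial(inner.n, p_symbol)``; the survival
    function stays accurate into the deep tail.
    """
    if not 0.0 <= p_symbol <= 1.0:
        raise ValueError(f"p_symbol must be in [0,1], got {p_symbol}")
    return float(binom.sf(inner.t, inner.n, p_symbol))


def outer_symbol_channel(
    design: ConcatenatedDesign, chan: ChannelParams
) -> tuple[float, float]:
    """Map the physical channel onto outer-code symbol statistics.

    An outer symbol is erased if its strand is physically lost, or if the
    strand survives but its inner decode fails (detected, hence an
    erasure).  Silent inner miscorrections are not modeled, so the silent
    symbol-error probability is 0; the outer tail computation is fully
    general should a nonzero value be supplied directly.
    """
    if chan.strand_length != design.strand_length_nt:
        raise ValueError(
            f"channel strand_length {chan.strand_length} != design "
            f"strand length {design.strand_length_nt}"
        )
    p_strand = strand_erasure_prob(chan)
    p_in = inner_failure_prob(design.inner, symbol_error_prob(chan))
    return p_strand + (1.0 - p_strand) * p_in, 0.0


def _logpmf_grid(n: int, p_erasure: float, p_error: float):
    """Log-PMF of (errors T, erasures E) over the trinomial lattice.

    Returns flat arrays (t, e, logp) over all t+e <= n.  Zero-probability
    categories are handled by the convention 0 * log 0 = 0.
    """
    p_clean = 1.0 - p_erasure - p_error
    t = np.arange(n + 1)
    tt, ee = np.meshgrid(t, t, indexing="ij")
    mask = tt + ee <= n
    tt, ee = tt[mask], ee[mask]
    cc = n - tt - ee
    logcoef = gammaln(n + 1) - gammaln(tt + 1) - gammaln(ee + 1) - gammaln(cc + 1)

    def _xlogy(x, p):
        lp = math.log(p) if p > 0 else -math.inf
        with np.errstate(invalid="ignore"):
            return np.where(x > 0, x * lp, 0.0)

    logp = logcoef + _xlogy(tt, p_error) + _xlogy(ee, p_erasure) + _xlogy(cc, p_clean)
    return tt, ee, logp


def _log_s_pmf(n: int, p_erasure: float, p_error: float) -> np.ndarray:
    """Log-PMF of the decoding load ``S = 2T + E`` (length 2n+1)."""
    tt, ee, logp = _logpmf_grid(n, p_erasure, p_error)
    s = 2 * tt + ee
    out = np.full(2 * n + 1, -np.inf)
    order = np.argsort(s, kind="stable")
    s_sorted, logp_sorted = s[order], logp[order]
    bounds = np.searchsorted(s_sorted, np.arange(2 * n + 2))
    for v in range(2 * n + 1):
        lo, hi = bounds[v], bounds[v + 1]
        if hi > lo:
            out[v] = logsumexp(logp_sorted[lo:hi])
    return out


def outer_decoding_error_logprob(
    outer: RSCode, p_erasure: float, p_error: float
) -> float:
    """Natural log of the exact outer failure probability ``P[2T+E > d-1]``.

    Computed entirely in the log domain; returns ``-inf`` for a clean
    channel.  ``p_error`` here is a *silent* outer-symbol error rate
    (unknown position), distinct from the per-nt rate.
    """
    for p, name in ((p_erasure, "p_erasure"), (p_error, "p_error")):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0,1], got {p}")
    if p_erasure + p_error > 1.0 + 1e-12:
        raise ValueError("p_erasure + p_error exceeds 1")
    n, d = outer.n, outer.d
    if p_error == 0.0:
        # erasure-only: failure iff E >= d
        return float(binom.logsf(d - 1, n, p_erasure))
    if p_erasure == 0.0:
        # errors-only: failure iff T > floor((d-1)/2)
        return float(binom.logsf(outer.t, n, p_error))
    log_s = _log_s_pmf(n, p_erasure, p_error)
    if d > 2 * n:
        return -np.inf
    return float(logsumexp(log_s[d:]))


def outer_decoding_error_prob(
    outer: RSCode, p_erasure: float, p_error: float
) -> float:
    """Exact outer decoding-failure probability (linear scale).

    Values below ~1e-300 underflow to 0.0 here; use
    :func:`outer_decoding_error_logprob` for the deep tail.
    """
    return float(np.exp(outer_decoding_error_logprob(outer, p_erasure, p_error)))


def outer_failure_logprob_all_k(
    n: int, p_erasure: float, p_error: float
) -> np.ndarray:
    """Log failure probability of ``RS[n, k]`` for every ``k = 1..n`` at once.

    The failure event depends on ``k`` only through the threshold
    ``d - 1 = n - k``, so one PMF of ``S = 2T + E`` yields the whole family
    of tails.  Entry ``i`` corresponds to ``k = i + 1``; the array is
    non-decreasing in ``k`` (less redundancy fails more).
    """
    ks = np.arange(1, n + 1)
    if p_error == 0.0:
        return binom.logsf(n - ks, n, p_erasure)
    log_s = _log_s_pmf(n, p_erasure, p_error)
    # suffix logsumexp: logtail[v] = log P[S >= v]
    logtail = np.logaddexp.accumulate(log_s[::-1])[::-1]
    logtail = np.append(logtail, -np.inf)  # P[S >= 2n+1] = 0
    d = n - ks + 1
    return logtail[np.minimum(d, 2 * n + 1)]


def system_error_curve(
    design: ConcatenatedDesign,
    lengths: Sequence[int],
    copies: int = 1,
    p_error_per_nt: float = 1e-3,
    breakage_factor: float = 5e-3,
) -> list[ReliabilityResult]:
    """Decoder-failure probability as a function of strand length.

    For each requested length the inner code is resized to fill the strand
    (fixed address overhead and symbol width), holding the inner
    redundancy ``inner.n - inner.k`` of the template design constant, then
    the full channel -> inner -> outer chain is evaluated.  Under the
    linear-breakage channel the resulting curve is non-decreasing in
    length; extra copies or a lower per-nt error rate shift it down.
    """
    redundancy = design.inner.n - design.inner.k
    results = []
    for L in lengths:
        inner_n = (L - design.address_nt) // design.nt_per_symbol
        inner_k = inner_n - redundancy
        if inner_k <= design.index_symbols:
            raise ValueError(
                f"length {L} nt too short for index + 1 payload symbol"
            )
        if inner_n > 255:
            raise ValueError(f"length {L} nt exceeds 255 inner symbols")
        d = replace(design, inner=RSCode(inner_n, inner_k))
        eff_len = d.strand_length_nt
        chan = ChannelParams(
            strand_length=eff_len,
            copies=copies,
            p_error_per_nt=p_error_per_nt,
            breakage_factor=breakage_factor,
            nt_per_symbol=design.nt_per_symbol,
        )
        p_er, p_err = outer_symbol_channel(d, chan)
        logp = outer_decoding_error_logprob(design.outer, p_er, p_err)
        results.append(
            ReliabilityResult(
                p_symbol_erasure=p_er,
                p_symbol_error=p_err,
                decoder_error_prob=float(np.exp(logp)),
                log10_decoder_error=logp / _LN10,
                strand_length=eff_len,
            )
        )
    return results
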