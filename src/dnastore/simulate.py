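"""Seeded Monte-Carlo simulation of the strand channel and concatenated
decode, the independent oracle for the analytic failure probabilities.

Two levels of fidelity:

* :func:`simulate_decode` — samples the channel (per-copy strand loss,
  per-symbol errors, inner-decode threshold) and applies the decode-success
  predicate ``2T + E <= d - 1`` directly.  This is exactly the event the
  analytic trinomial model computes, so agreement is a correctness check
  of the analytics, not a modeling assumption.
* :func:`simulate_codec_roundtrip` — full end-to-end encode/channel/decode
  with a real GF(256) Reed-Solomon codec (:mod:`dnastore.rscodec`); slower,
  used on small problems to confirm the predicate matches what an actual
  decoder does.

Reproducibility: trials are drawn in fixed-size chunks from child streams
spawned off one ``SeedSequence``, so a fixed seed gives bit-identical
results and growing the trial count never reshuffles earlier trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import rscodec
from .channel import ChannelParams, symbol_error_prob
from .reliability import ConcatenatedDesign

__all__ = ["SimulationSpec", "SimulationResult", "simulate_decode",
           "simulate_codec_roundtrip"]

_CHUNK = 10_000


@dataclass(frozen=True)
class SimulationSpec:
    design: ConcatenatedDesign
    channel: ChannelParams
    trials: int
    seed: int

    def __post_init__(self) -> None:
        if self.trials < 1:
            raise ValueError("trials must be >= 1")
        if self.channel.strand_length != self.design.strand_length_nt:
            raise ValueError(
                f"channel strand_length {self.channel.strand_length} != "
                f"design strand length {self.design.strand_length_nt}"
            )


@dataclass(frozen=True)
class SimulationResult:
    failures: int
    trials: int

    @property
    def estimate(self) -> float:
        return self.failures / self.trials

    @property
    def std_error(self) -> float:
        p = self.estimate
        return math.sqrt(p * (1.0 - p) / self.trials)


def _chunk_rngs(seed: int, trials: int) -> list[tuple[np.random.Generator, int]]:
    n_chunks = (trials + _CHUNK - 1) // _CHUNK
    children = np.random.SeedSequence(seed).spawn(n_chunks)
    out = []
    remaining = trials
    for child in children:
        size = min(_CHUNK, remaining)
        out.append((np.random.default_rng(child), size))
        remaining -= size
    return out


def simulate_decode(spec: SimulationSpec) -> SimulationResult:
    """Estimate the outer decoding-failure probability by direct sampling.

    Per trial, for each of the ``outer.n`` strands: every molecular copy is
    lost independently with probability ``min(1, L*b)``; the strand is
    erased iff all copies are lost.  Surviving strands draw
    ``Binomial(inner.n, p_symbol)`` symbol errors; more than the inner
    correction radius is a detected inner failure, also an outer erasure.
    The outer decode fails iff erasures exceed ``d_outer - 1`` (no silent
    symbol errors in this channel).
    """
    design, chan = spec.design, spec.channel
    n_out = design.outer.n
    p_lost = min(1.0, chan.strand_length * chan.breakage_factor)
    p_sym = symbol_error_prob(chan)
    t_in = design.inner.t
    max_erasures = design.outer.d - 1

    failures = 0
    for rng, size in _chunk_rngs(spec.seed, spec.trials):
        erased = np.ones((size, n_out), dtype=bool)
        for _ in range(chan.copies):
            erased &= rng.random((size, n_out)) < p_lost
        errors = rng.binomial(design.inner.n, p_sym, size=(size, n_out))
        outer_erased = erased | (errors > t_in)
        failures += int(np.sum(outer_erased.sum(axis=1) > max_erasures))
    return SimulationResult(failures=failures, trials=spec.trials)


def _encode_file(design: ConcatenatedDesign, payload: np.ndarray) -> np.ndarray:
    """Outer-then-inner encode; returns (outer.n, inner.n) symbol matrix."""
    outer, inner = design.outer, design.inner
    per_strand = design.payload_symbols_per_strand
    data = payload.reshape(outer.k, per_strand)
    # outer code runs down each payload column, one symbol per strand
    coded_cols = np.empty((outer.n, per_strand), dtype=np.uint8)
    for j in range(per_strand):
        coded_cols[:, j] = rscodec.rs_encode(
            data[:, j].tolist(), outer.n - outer.k
        )
    strands = np.empty((outer.n, inner.n), dtype=np.uint8)
    for i in range(outer.n):
        index_bytes = list(int(i).to_bytes(design.index_symbols, "big"))
        msg = index_bytes + coded_cols[i].tolist()
        strands[i] = rscodec.rs_encode(msg, inner.n - inner.k)
    return strands


def simulate_codec_roundtrip(
    spec: SimulationSpec,
    payload_bytes: int | None = None,
    return_trials: bool = False,
) -> SimulationResult | tuple[SimulationResult, list[bool]]:
    """End-to-end round trip through a real Reed-Solomon codec.

    Random payload -> outer encode (across strands) -> inner encode (per
    strand, 4 index bytes first) -> sampled channel (strand loss, symbol
    corruption) -> inner decode with detected failures becoming outer
    erasures -> outer errors-and-erasures decode -> byte-exact comparison.
    Success frequency estimates ``1 - P[decoder failure]``.

    O(outer.n * inner.n) Python-level work per trial: intended for small
    designs and modest trial counts.
    """
    design, chan = spec.design, spec.channel
    outer, inner = design.outer, design.inner
    capacity = outer.k * design.payload_symbols_per_strand
    if payload_bytes is None:
        payload_bytes = capacity
    if not 0 < payload_bytes <= capacity:
        raise ValueError(
            f"payload of {payload_bytes} B does not fit capacity {capacity} B"
        )
    if design.index_symbols < 1 and outer.n > 1:
        raise ValueError("round-trip needs >= 1 index byte to identify strands")
    if outer.n > 256 ** design.index_symbols:
        raise ValueError("index too narrow to address all strands")

    p_lost = min(1.0, chan.strand_length * chan.breakage_factor)
    p_sym = symbol_error_prob(chan)
    nsym_in = inner.n - inner.k
    nsym_out = outer.n - outer.k
    per_strand = design.payload_symbols_per_strand

    successes: list[bool] = []
    for rng, size in _chunk_rngs(spec.seed, spec.trials):
        for _ in range(size):
            payload = rng.integers(0, 256, size=capacity, dtype=np.uint8)
            payload[payload_bytes:] = 0
            strands = _encode_file(design, payload)

            # channel: all-copies loss erases the strand entirely
            lost = np.ones(outer.n, dtype=bool)
            for _c in range(chan.copies):
                lost &= rng.random(outer.n) < p_lost
            corrupt = rng.random((outer.n, inner.n)) < p_sym
            offsets = rng.integers(1, 256, size=(outer.n, inner.n), dtype=np.uint8)
            received = np.where(corrupt, strands ^ offsets, strands)

            # inner decode; detected failure => outer erasure
            recovered = np.zeros((outer.n, per_strand), dtype=np.uint8)
            erased_rows = []
            for i in range(outer.n):
                if lost[i]:
                    erased_rows.append(i)
                    continue
                try:
                    msg = rscodec.rs_decode(received[i].tolist(), nsym_in)
                except rscodec.RSDecodeError:
                    erased_rows.append(i)
                    continue
                row = int.from_bytes(
                    bytes(msg[: design.index_symbols]), "big"
                )
                if row != i:  # miscorrected index: silently wrong strand
                    erased_rows.append(i)
                    continue
                recovered[i] = msg[design.index_symbols:]

            # outer errors-and-erasures decode per payload column
            ok = True
            decoded = np.empty((outer.k, per_strand), dtype=np.uint8)
            for j in range(per_strand):
                try:
                    decoded[:, j] = rscodec.rs_decode(
                        recovered[:, j].tolist(), nsym_out, erase_pos=erased_rows
                    )
                except rscodec.RSDecodeError:
                    ok = False
                    break
            if ok:
                ok = bool(np.array_equal(decoded.reshape(-1), payload))
            successes.append(ok)

    failures = sum(1 for s in successes if not s)
    result = SimulationResult(failures=failures, trials=spec.trials)
    if return_trials:
        return result, successes
    return result
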