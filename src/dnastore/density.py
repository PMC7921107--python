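"""Information-density optimization under a reliability constraint.

For a fixed strand length the inner block length is fixed by geometry, but
the redundancy split between inner and outer codes is free.  The optimizer
enumerates every (outer k, inner k) pair, keeps the designs whose analytic
decoder-failure probability is below the reliability target (default 1e-14,
the hard-drive regime), and returns the one of maximal information density

    density = (outer.k / outer.n) * 8 * (inner.k - index) / strand_length_nt

in bits per synthesized nucleotide — payload bits after outer parity, inner
parity, per-strand index bytes, and address nucleotides are all paid for.

Sweeping the per-nt breakage probability (1e-3 down to 1e-8) against strand
length reproduces the central tradeoff: short strands win when breakage is
frequent (fewer outer parity symbols needed), long strands win when it is
rare (fixed address/index overhead is amortized), and at intermediate rates
an interior optimum length balances the two.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .reliability import (
    ConcatenatedDesign,
    RSCode,
    inner_failure_prob,
    outer_decoding_error_logprob,
    outer_failure_logprob_all_k,
)

__all__ = [
    "DensityQuery",
    "TradeoffPoint",
    "DensitySweepResult",
    "info_density",
    "optimize_design",
    "density_sweep",
]


@dataclass(frozen=True)
class DensityQuery:
    """One design question: best code for this length and degradation rate.

    ``breakage_prob_per_nt`` replaces the channel module's default 5e-3
    factor; it is exactly the quantity swept from 1e-3 to 1e-8.  Single
    copy by default (worst case for erasures, best case for density).
    """

    strand_length: int
    breakage_prob_per_nt: float
    copies: int = 1
    p_error_per_nt: float = 1e-3
    reliability_target: float = 1e-14
    outer_n: int = 255
    index_symbols: int = 4
    address_nt: int = 40
    nt_per_symbol: int = 4

    def __post_init__(self) -> None:
        for p, name in (
            (self.breakage_prob_per_nt, "breakage_prob_per_nt"),
            (self.p_error_per_nt, "p_error_per_nt"),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {p}")
        if not self.reliability_target > 0:
            raise ValueError("reliability_target must be positive")
        if self.copies < 1:
            raise ValueError("copies must be >= 1")


@dataclass(frozen=True)
class TradeoffPoint:
    """Optimizer output: the best feasible design, or explicit infeasibility."""

    query: DensityQuery
    best_design: ConcatenatedDesign | None
    density: float
    achieved_error: float
    feasible: bool


@dataclass
class DensitySweepResult:
    """Full factorial sweep plus the per-breakage-rate optimal length."""

    table: pd.DataFrame
    #: per breakage rate, the strand length whose optimal design has the
    #: highest density (the interior-optimum view of the tradeoff)
    optima: pd.DataFrame = field(default_factory=pd.DataFrame)

    def optimal_length(self, breakage: float) -> int:
        row = self.optima[np.isclose(self.optima["breakage"], breakage)]
        if row.empty:
            raise KeyError(f"breakage rate {breakage} not in sweep")
        return int(row["length"].iloc[0])


def info_density(design: ConcatenatedDesign) -> float:
    """Payload bits per synthesized nucleotide for a concatenated design.

    8 payload bits per inner symbol beyond the index, discounted by the
    outer code rate, divided by the physical strand length (address
    included).  An uncoded, overhead-free design reaches exactly
    ``8 / nt_per_symbol`` = 2.0 bits/nt for 4-nt symbols.
    """
    payload = design.payload_symbols_per_strand
    if payload <= 0:
        raise ValueError("design has no payload symbols")
    return (
        (design.outer.k / design.outer.n)
        * (payload * 8)
        / design.strand_length_nt
    )


def _inner_geometry(query: DensityQuery) -> int:
    inner_n = (query.strand_length - query.address_nt) // query.nt_per_symbol
    if inner_n <= query.index_symbols:
        raise ValueError(
            f"strand length {query.strand_length} nt cannot hold the index "
            f"plus one payload symbol"
        )
    if inner_n > 255:
        raise ValueError(
            f"strand length {query.strand_length} nt implies {inner_n} > 255 "
            "inner symbols; not representable with 8-bit symbols"
        )
    return inner_n


def optimize_design(query: DensityQuery) -> TradeoffPoint:
    """Exhaustive search over (outer k, inner k) for maximal density.

    The inner block length is fixed by the strand geometry.  For each inner
    message length the outer-symbol erasure probability is computed (strand
    loss plus detected inner-decode failure), and the failure tail of every
    outer message length is evaluated from a single distribution of the
    decoding load.  Feasible means strictly below the reliability target.
    Ties in density break toward larger outer k, then larger inner k.
    Returns an explicit infeasible point (density 0, no design) when no
    pair satisfies the constraint.
    """
    inner_n = _inner_geometry(query)
    eff_len = query.address_nt + inner_n * query.nt_per_symbol
    p_strand = min(1.0, eff_len * query.breakage_prob_per_nt) ** query.copies
    p_sym = 1.0 - (1.0 - query.p_error_per_nt) ** query.nt_per_symbol
    log_target = math.log(query.reliability_target)

    best_key = None
    best: tuple[int, int] | None = None  # (outer_k, inner_k)
    for inner_k in range(query.index_symbols + 1, inner_n + 1):
        p_in = inner_failure_prob(RSCode(inner_n, inner_k), p_sym)
        p_erasure = p_strand + (1.0 - p_strand) * p_in
        log_fail = outer_failure_logprob_all_k(query.outer_n, p_erasure, 0.0)
        feasible = np.flatnonzero(log_fail < log_target)
        if feasible.size == 0:
            continue
        outer_k = int(feasible[-1]) + 1  # log_fail non-decreasing in k
        dens = (
            (outer_k / query.outer_n)
            * ((inner_k - query.index_symbols) * 8)
            / eff_len
        )
        key = (dens, outer_k, inner_k)
        if best_key is None or key > best_key:
            best_key, best = key, (outer_k, inner_k)

    if best is None:
        return TradeoffPoint(query, None, 0.0, 1.0, False)

    outer_k, inner_k = best
    design = ConcatenatedDesign(
        outer=RSCode(query.outer_n, outer_k),
        inner=RSCode(inner_n, inner_k),
        index_symbols=query.index_symbols,
        address_nt=query.address_nt,
        nt_per_symbol=query.nt_per_symbol,
    )
    # independent post-hoc verification of the constraint
    p_in = inner_failure_prob(design.inner, p_sym)
    p_erasure = p_strand + (1.0 - p_strand) * p_in
    logp = outer_decoding_error_logprob(design.outer, p_erasure, 0.0)
    achieved = float(np.exp(logp))
    if not logp < log_target:
        raise RuntimeError(
            "search returned a design that fails post-hoc verification"
        )
    return TradeoffPoint(query, design, info_density(design), achieved, True)


def density_sweep(
    lengths: Sequence[int],
    breakage_probs: Sequence[float],
    copies: int = 1,
    p_error_per_nt: float = 1e-3,
    reliability_target: float = 1e-14,
    index_symbols: int = 4,
    address_nt: int = 40,
    nt_per_symbol: int = 4,
) -> DensitySweepResult:
    """Full factorial sweep of lengths x breakage rates.

    Every cell is an independent :func:`optimize_design` call; the result
    table carries the winning code parameters, density, and verified
    residual error, and ``optima`` records the best length per breakage
    rate.
    """
    if len(lengths) == 0 or len(breakage_probs) == 0:
        raise ValueError("length and breakage grids must be non-empty")
    rows = []
    for b in breakage_probs:
        for L in lengths:
            q = DensityQuery(
                strand_length=int(L),
                breakage_prob_per_nt=float(b),
                copies=copies,
                p_error_per_nt=p_error_per_nt,
                reliability_target=reliability_target,
                index_symbols=index_symbols,
                address_nt=address_nt,
                nt_per_symbol=nt_per_symbol,
            )
            pt = optimize_design(q)
            rows.append(
                {
                    "length": int(L),
                    "breakage": float(b),
                    "feasible": pt.feasible,
                    "outer_k": pt.best_design.outer.k if pt.feasible else 0,
                    "inner_n": pt.best_design.inner.n if pt.feasible else 0,
                    "inner_k": pt.best_design.inner.k if pt.feasible else 0,
                    "density_bits_per_nt": pt.density,
                    "achieved_error": pt.achieved_error if pt.feasible else np.nan,
                }
            )
    table = pd.DataFrame(rows)
    optima = (
        table.loc[table.groupby("breakage")["density_bits_per_nt"].idxmax()]
        .loc[:, ["breakage", "length", "density_bits_per_nt"]]
        .reset_index(drop=True)
    )
    return DensitySweepResult(table=table, optima=optima)
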