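"""The degradation channel seen by the decoder.

A stored file is a set of DNA strands; physical degradation reaches the
decoder in two forms: a whole strand missing (an *erasure* of the outer-code
symbol it carried) and a corrupted-but-present symbol (an *error*).  The
strand-erasure probability follows the empirical linear-in-length model
``p = (L * b)^c`` — breakage probability proportional to strand length, with
``c`` molecular copies all of which must be lost.  The product ``L * b`` is
clamped at 1 before exponentiation so the result is a probability for every
length.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ChannelParams", "strand_erasure_prob", "symbol_error_prob"]


def _check_prob(p: float, name: str) -> None:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {p}")


@dataclass(frozen=True)
class ChannelParams:
    """Degradation environment for one strand design.

    Parameters
    ----------
    strand_length
        Total synthesized length in nt (addresses included).
    copies
        Molecular copies of each distinct strand; the strand is erased only
        if every copy is lost.
    p_error_per_nt
        Per-nt probability of a substitution/insertion/deletion, lumped.
    breakage_factor
        Per-nt erasure coefficient ``b`` in ``p = (L*b)^c``.  Default 5e-3.
    nt_per_symbol
        Nucleotides per 8-bit code symbol; 4 nt at 2 bits/nt.
    """

    strand_length: int
    copies: int = 1
    p_error_per_nt: float = 0.0
    breakage_factor: float = 5e-3
    nt_per_symbol: int = 4

    def __post_init__(self) -> None:
        if self.strand_length < 1:
            raise ValueError("strand_length must be >= 1 nt")
        if self.copies < 1:
            raise ValueError("copies must be >= 1")
        if self.nt_per_symbol < 1:
            raise ValueError("nt_per_symbol must be >= 1")
        _check_prob(self.p_error_per_nt, "p_error_per_nt")
        if self.breakage_factor < 0:
            raise ValueError("breakage_factor must be non-negative")


def strand_erasure_prob(params: ChannelParams) -> float:
    """Probability all ``copies`` of a strand are lost: ``min(1, L*b)^c``.

    Monotone increasing in length; for a per-copy loss probability below 1,
    geometrically decreasing in copy number.
    """
    base = min(1.0, params.strand_length * params.breakage_factor)
    return base ** params.copies


def symbol_error_prob(params: ChannelParams) -> float:
    """Probability a code symbol contains >= 1 erroneous nucleotide.

    i.i.d. per-nt errors: ``1 - (1 - p)^nt_per_symbol``, bounded above by
    the union bound ``nt_per_symbol * p``.
    """
    return 1.0 - (1.0 - params.p_error_per_nt) ** params.nt_per_symbol
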