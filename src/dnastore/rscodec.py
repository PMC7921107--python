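"""A small GF(256) Reed-Solomon codec with errors-and-erasures decoding.

Serves as the deep oracle behind the Monte-Carlo round-trip simulation:
actual algebraic encode/decode on byte sequences, against which the
threshold predicate ``2t + e <= d - 1`` (the event the analytic model
computes) can be checked trial by trial.

Standard construction: GF(2^8) with primitive polynomial 0x11d, generator
roots ``alpha^0 .. alpha^(nsym-1)``, systematic encoding by polynomial
division, decoding via syndromes, Forney syndromes for known erasures,
Berlekamp-Massey for the error locator, Chien search, and the Forney
algorithm for errata magnitudes.  Shortened codes (n < 255) work
transparently.  Patterns beyond capability are usually *detected*
(:class:`RSDecodeError`); rare miscorrections return a wrong codeword, as
with any bounded-distance decoder.

Polynomials are lists of ints, highest-degree coefficient first.
Codeword positions count from the left (index 0 = first symbol).
"""

from __future__ import annotations

__all__ = ["RSDecodeError", "rs_encode", "rs_decode"]

_PRIM = 0x11D
_EXP = [0] * 512
_LOG = [0] * 256


def _init_tables() -> None:
    x = 1
    for i in range(255):
        _EXP[i] = x
        _LOG[x] = i
        x <<= 1
        if x & 0x100:
            x ^= _PRIM
    for i in range(255, 512):
        _EXP[i] = _EXP[i - 255]


_init_tables()


class RSDecodeError(Exception):
    """Decoder detected an uncorrectable errata pattern."""


def _mul(a: int, b: int) -> int:
    if a == 0 or b == 0:
        return 0
    return _EXP[_LOG[a] + _LOG[b]]


def _div(a: int, b: int) -> int:
    if b == 0:
        raise ZeroDivisionError("division by zero in GF(256)")
    if a == 0:
        return 0
    return _EXP[(_LOG[a] - _LOG[b]) % 255]


def _inv(a: int) -> int:
    return _EXP[255 - _LOG[a]]


def _pow(a: int, n: int) -> int:
    return _EXP[(_LOG[a] * n) % 255]


def _poly_scale(p: list[int], s: int) -> list[int]:
    return [_mul(c, s) for c in p]


def _poly_add(p: list[int], q: list[int]) -> list[int]:
    out = [0] * max(len(p), len(q))
    out[len(out) - len(p):] = p
    for i, c in enumerate(q):
        out[i + len(out) - len(q)] ^= c
    return out


def _poly_mul(p: list[int], q: list[int]) -> list[int]:
    out = [0] * (len(p) + len(q) - 1)
    for i, pi in enumerate(p):
        if pi == 0:
            continue
        for j, qj in enumerate(q):
            out[i + j] ^= _mul(pi, qj)
    return out


def _poly_eval(p: list[int], x: int) -> int:
    y = p[0]
    for c in p[1:]:
        y = _mul(y, x) ^ c
    return y


def _generator_poly(nsym: int) -> list[int]:
    g = [1]
    for i in range(nsym):
        g = _poly_mul(g, [1, _EXP[i]])
    return g


def rs_encode(msg: list[int], nsym: int) -> list[int]:
    """Systematic encode: returns ``msg`` followed by ``nsym`` parity symbols."""
    if len(msg) + nsym > 255:
        raise ValueError("codeword longer than 255 symbols")
    gen = _generator_poly(nsym)
    buf = list(msg) + [0] * nsym
    for i in range(len(msg)):
        coef = buf[i]
        if coef != 0:
            for j in range(1, len(gen)):
                buf[i + j] ^= _mul(gen[j], coef)
    return list(msg) + buf[len(msg):]


def _syndromes(cw: list[int], nsym: int) -> list[int]:
    return [_poly_eval(cw, _EXP[i]) for i in range(nsym)]


def _forney_syndromes(synd: list[int], erase_pos: list[int], n: int) -> list[int]:
    """Fold known erasure locations out of the syndromes so BM sees errors only."""
    fsynd = list(synd)
    for pos in erase_pos:
        x = _EXP[n - 1 - pos]
        for j in range(len(fsynd) - 1):
            fsynd[j] = _mul(fsynd[j], x) ^ fsynd[j + 1]
    return fsynd


def _error_locator(fsynd: list[int], nsym: int, erase_count: int) -> list[int]:
    """Berlekamp-Massey on Forney syndromes (highest-degree-first result)."""
    err_loc = [1]
    old_loc = [1]
    for i in range(nsym - erase_count):
        delta = fsynd[i]
        for j in range(1, len(err_loc)):
            delta ^= _mul(err_loc[-(j + 1)], fsynd[i - j])
        old_loc = old_loc + [0]
        if delta != 0:
            if len(old_loc) > len(err_loc):
                new_loc = _poly_scale(old_loc, delta)
                old_loc = _poly_scale(err_loc, _inv(delta))
                err_loc = new_loc
            err_loc = _poly_add(err_loc, _poly_scale(old_loc, delta))
    while len(err_loc) > 1 and err_loc[0] == 0:
        err_loc = err_loc[1:]
    errs = len(err_loc) - 1
    if errs * 2 + erase_count > nsym:
        raise RSDecodeError("too many errors for the remaining capability")
    return err_loc


def _find_errors(err_loc: list[int], n: int) -> list[int]:
    """Chien search: positions (from the left) whose locators are roots.

    The reciprocal of ``Lambda(x) = prod(1 + X_j x)`` has roots at the
    locators ``X_j = alpha^(n-1-pos)`` themselves, which for a shortened
    code all lie within the first ``n`` powers of alpha.
    """
    errs = len(err_loc) - 1
    recip = list(reversed(err_loc))
    positions = []
    for i in range(n):
        if _poly_eval(recip, _EXP[i]) == 0:
            positions.append(n - 1 - i)
    if len(positions) != errs:
        raise RSDecodeError("error locator does not split over the field")
    return positions


def _correct_errata(cw: list[int], synd: list[int], errata_pos: list[int]) -> list[int]:
    """Forney algorithm at known errata positions (errors + erasures)."""
    n = len(cw)
    coef_pos = [n - 1 - p for p in errata_pos]
    # errata locator Lambda(x) = prod (1 + x * alpha^cp)
    loc = [1]
    for cp in coef_pos:
        loc = _poly_mul(loc, _poly_add([1], [_EXP[cp], 0]))
    # errata evaluator Omega(x) = Synd(x) * Lambda(x) mod x^nu, nu = #errata
    synd_poly = list(reversed(synd))  # highest-first
    prod = _poly_mul(synd_poly, loc)
    nu = len(coef_pos)
    omega = prod[len(prod) - nu:]
    X = [_EXP[cp] for cp in coef_pos]
    out = list(cw)
    for i, xi in enumerate(X):
        xi_inv = _inv(xi)
        denom = 1
        for j, xj in enumerate(X):
            if j != i:
                denom = _mul(denom, 1 ^ _mul(xi_inv, xj))
        if denom == 0:
            raise RSDecodeError("degenerate errata locator")
        # magnitude Y_i = Omega(X_i^-1) / prod_{j!=i}(1 + X_i^-1 X_j); the
        # X_i factor of the formal-derivative form cancels for fcr = 0
        out[errata_pos[i]] ^= _div(_poly_eval(omega, xi_inv), denom)
    return out


def rs_decode(
    codeword: list[int], nsym: int, erase_pos: list[int] | None = None
) -> list[int]:
    """Decode a possibly corrupted codeword; returns the message symbols.

    ``erase_pos`` are known-bad positions (from the left); their values are
    ignored.  Raises :class:`RSDecodeError` when the pattern is detected as
    uncorrectable.
    """
    n = len(codeword)
    if n > 255:
        raise ValueError("codeword longer than 255 symbols")
    erase_pos = list(erase_pos or [])
    if nsym == 0:
        if erase_pos:
            raise RSDecodeError("more erasures than parity symbols")
        return list(codeword)
    if len(erase_pos) > nsym:
        raise RSDecodeError("more erasures than parity symbols")
    cw = list(codeword)
    for p in erase_pos:
        cw[p] = 0
    synd = _syndromes(cw, nsym)
    if max(synd) == 0:
        return cw[: n - nsym]
    fsynd = _forney_syndromes(synd, erase_pos, n)
    err_loc = _error_locator(fsynd, nsym, len(erase_pos))
    err_pos = _find_errors(err_loc, n) if len(err_loc) > 1 else []
    cw = _correct_errata(cw, synd, erase_pos + err_pos)
    if max(_syndromes(cw, nsym)) != 0:
        raise RSDecodeError("residual syndromes after correction")
    return cw[: n - nsym]
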