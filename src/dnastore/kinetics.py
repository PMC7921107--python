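"""Closed-form DNA degradation kinetics for stored oligonucleotides.

Four small models cover the degradation modes that dominate archival and
working DNA storage:

* :class:`FirstOrderBreakage` — backbone scission as a homogeneous Poisson
  process along the strand and through time.  A strand survives only if it
  accumulates zero scissions, so the intact fraction is
  ``exp(-rate * length * time)``.
* :class:`FreezeThawModel` — empirical exponential decay of the intact
  fraction per freeze-thaw cycle, the dominant cost of repeatedly accessing
  solubilized working copies.
* :class:`ArrheniusModel` — temperature extrapolation of any first-order
  rate, the basis of accelerated-aging studies.
* :class:`LesionModel` — accumulation of base lesions (depurination and
  8-oxo-dG pooled into one rate); these corrupt bases without breaking the
  backbone, so they feed the symbol-error side of a channel model rather
  than the erasure side.

Rates are per nucleotide per year, temperatures are Kelvin, and all
returned fractions lie in ``[0, 1]``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple

import numpy as np

__all__ = [
    "GAS_CONSTANT",
    "FirstOrderBreakage",
    "FreezeThawModel",
    "ArrheniusModel",
    "LesionModel",
    "intact_fraction_breakage",
    "rate_from_half_life",
    "freeze_thaw_intact",
    "fit_exponential_decay",
    "simulate_freeze_thaw_series",
    "arrhenius_scale",
    "lesion_probability",
]

#: Molar gas constant, J/(mol*K).
GAS_CONSTANT = 8.314


def _check_strand(length: float, time: float) -> None:
    if length < 1:
        raise ValueError(f"strand length must be >= 1 nt, got {length}")
    if time < 0:
        raise ValueError(f"time must be non-negative, got {time} years")


@dataclass(frozen=True)
class FirstOrderBreakage:
    """Backbone scission modeled as a Poisson process.

    Parameters
    ----------
    rate_per_nt_per_year
        Probability rate of a backbone break per nucleotide per year.
        Fossil DNA in permafrost is on the order of 5.5e-6 /nt/yr.
    """

    rate_per_nt_per_year: float

    def __post_init__(self) -> None:
        if self.rate_per_nt_per_year < 0:
            raise ValueError("breakage rate must be non-negative")


@dataclass(frozen=True)
class FreezeThawModel:
    """Exponential decay of intact DNA per freeze-thaw cycle.

    ``intact(n) = amplitude * exp(-decay_per_cycle * n)``.

    The defaults are the published fit to lambda-DNA freeze-thaw data
    (amplitude 0.9484, decay 0.068 per cycle), under which one cycle
    degrades ~11% of strands and twenty cycles ~76%.

    Fitted amplitudes may exceed 1 slightly on noisy data; evaluation clips
    the intact fraction to [0, 1].
    """

    amplitude: float = 0.9484
    decay_per_cycle: float = 0.068

    def __post_init__(self) -> None:
        if not self.amplitude > 0:
            raise ValueError("amplitude must be positive")
        if self.decay_per_cycle < 0:
            raise ValueError("decay per cycle must be non-negative")


@dataclass(frozen=True)
class ArrheniusModel:
    """First-order rate with Arrhenius temperature dependence.

    Parameters
    ----------
    activation_energy
        Apparent activation energy in J/mol.  There is no universal value
        for DNA degradation; it must be supplied from the aging study being
        extrapolated (typical backbone-hydrolysis values are ~100-160
        kJ/mol).
    reference_rate
        Rate measured at ``reference_temperature`` (any per-time unit; the
        scaled rate keeps the same unit).
    reference_temperature
        Kelvin.
    """

    activation_energy: float
    reference_rate: float
    reference_temperature: float

    def __post_init__(self) -> None:
        if not self.activation_energy > 0:
            raise ValueError("activation energy must be positive (J/mol)")
        if not self.reference_temperature > 0:
            raise ValueError("reference temperature must be positive (K)")


@dataclass(frozen=True)
class LesionModel:
    """Per-nucleotide base-lesion accumulation (depurination + 8-oxo-dG).

    Lesions arise independently per nucleotide per year; the probability a
    strand carries at least one lesion after ``t`` years is
    ``1 - exp(-rate * length * t)``.
    """

    lesion_rate_per_nt_per_year: float

    def __post_init__(self) -> None:
        if self.lesion_rate_per_nt_per_year < 0:
            raise ValueError("lesion rate must be non-negative")

    @classmethod
    def from_strand_fraction(
        cls, fraction: float, length: int, time: float = 1.0
    ) -> "LesionModel":
        """Calibrate the per-nt rate from an observed per-strand fraction.

        E.g. "6% of 200-nt strands develop a lesion per year" gives
        ``-ln(0.94)/200 = 3.09e-4 /nt/yr``.
        """
        if not 0 < fraction < 1:
            raise ValueError("lesioned fraction must be in (0, 1)")
        _check_strand(length, time)
        if time == 0:
            raise ValueError("calibration time must be positive")
        return cls(-math.log1p(-fraction) / (length * time))


def intact_fraction_breakage(
    model: FirstOrderBreakage, length: int, time: float
) -> float:
    """Probability a strand of ``length`` nt has zero backbone breaks after
    ``time`` years.

    Zero scissions of a Poisson process with intensity ``rate`` per nt-year
    over a ``length x time`` window: ``exp(-rate * length * time)``.
    Multiplicative in both time and length.
    """
    _check_strand(length, time)
    return math.exp(-model.rate_per_nt_per_year * length * time)


def rate_from_half_life(length: int, half_life: float) -> FirstOrderBreakage:
    """Per-nt breakage rate implied by a strand half-life.

    Inverts the exponential survival model: ``rate = ln 2 / (length *
    half_life)``, so ``intact_fraction_breakage`` returns exactly 0.5 at
    ``t = half_life``.
    """
    if length < 1:
        raise ValueError(f"strand length must be >= 1 nt, got {length}")
    if not half_life > 0:
        raise ValueError(f"half-life must be positive, got {half_life}")
    return FirstOrderBreakage(math.log(2) / (length * half_life))


def freeze_thaw_intact(model: FreezeThawModel, cycles: int) -> float:
    """Intact fraction remaining after ``cycles`` freeze-thaw cycles."""
    if cycles < 0:
        raise ValueError(f"cycle count must be non-negative, got {cycles}")
    return min(1.0, model.amplitude * math.exp(-model.decay_per_cycle * cycles))


def fit_exponential_decay(
    points: Iterable[Tuple[float, float]]
) -> FreezeThawModel:
    """Fit ``intact = A * exp(-k * cycles)`` by linear least squares in log
    space.

    Deterministic (no initialization): a straight-line fit of
    ``log(intact)`` against cycles.  With exactly two points the fit passes
    through both.  Intact fractions must be positive; values slightly above
    1 (measurement noise on a near-1 amplitude) are accepted.  Duplicate
    cycle counts are rejected.  A fitted decay that comes out negative on
    trendless data is clamped to 0 so the model invariant holds.
    """
    pts = list(points)
    if len(pts) < 2:
        raise ValueError("need at least 2 points to fit a decay curve")
    x = np.asarray([p[0] for p in pts], dtype=float)
    y = np.asarray([p[1] for p in pts], dtype=float)
    if len(np.unique(x)) != len(x):
        raise ValueError("duplicate cycle counts in fit input")
    if np.any(y <= 0):
        raise ValueError("intact fractions must be positive")
    slope, intercept = np.polyfit(x, np.log(y), 1)
    return FreezeThawModel(
        amplitude=float(np.exp(intercept)),
        decay_per_cycle=max(0.0, float(-slope)),
    )


def simulate_freeze_thaw_series(
    model: FreezeThawModel,
    cycles: Sequence[int],
    noise_sigma: float = 0.02,
    rng: np.random.Generator | None = None,
) -> list[Tuple[float, float]]:
    """Synthetic freeze-thaw time course with multiplicative Gaussian noise.

    Emulates a qPCR/gel-quantified intact-fraction measurement: the true
    exponential decay evaluated at each cycle count, perturbed by
    ``(1 + N(0, noise_sigma))``.  Values are floored at a tiny positive
    number so the series remains fittable in log space.
    """
    if noise_sigma < 0:
        raise ValueError("noise sigma must be non-negative")
    rng = rng if rng is not None else np.random.default_rng()
    out = []
    for c in cycles:
        true = freeze_thaw_intact(model, c)
        noisy = true * (1.0 + rng.normal(0.0, noise_sigma))
        out.append((float(c), max(noisy, 1e-12)))
    return out


def arrhenius_scale(model: ArrheniusModel, new_temperature: float) -> float:
    """Rate at ``new_temperature`` (K) from the Arrhenius relation.

    ``rate(T2) = rate(T1) * exp(-(Ea/R) * (1/T2 - 1/T1))``; returns the
    reference rate unchanged at the reference temperature, and a smaller
    rate at lower temperature for positive activation energy.
    """
    if not new_temperature > 0:
        raise ValueError(f"temperature must be positive (K), got {new_temperature}")
    exponent = -(model.activation_energy / GAS_CONSTANT) * (
        1.0 / new_temperature - 1.0 / model.reference_temperature
    )
    return model.reference_rate * math.exp(exponent)


def lesion_probability(model: LesionModel, length: int, time: float) -> float:
    """Probability a strand carries >= 1 base lesion after ``time`` years."""
    _check_strand(length, time)
    return -math.expm1(-model.lesion_rate_per_nt_per_year * length * time)
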