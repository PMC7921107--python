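# Methods

## Degradation kinetics

Backbone scission is modeled as a homogeneous Poisson process along the
strand and through time: the intact fraction of an *L*-nt strand after *t*
years is `exp(-r·L·t)` for per-nt rate *r* (1/nt/yr). The widely cited
permafrost worked example (r = 5.5e-6, L = 242, t = 500) evaluates to 48.6%
fragmented under this form; the linearized product `r·L·t = 0.67` sometimes
quoted alongside it is the small-argument approximation and exceeds 1 for
modest parameter changes, so the exponential form is used throughout. The
inverse helper `rate_from_half_life` uses `r = ln2/(L·t_half)`, which
round-trips to exactly 0.5 at the half-life; it gives 5.73e-6 /nt/yr for
the permafrost case, a 4% difference from the linearized 5.50e-6 that
reflects the two conventions, not an error.

Freeze-thaw damage uses the fitted exponential
`intact = A·exp(-k·cycles)` with defaults A = 0.9484, k = 0.068 per cycle
(the published lambda-DNA fit in Tris-EDTA buffer). `fit_exponential_decay`
refits these coefficients from data by ordinary least squares on
`log(intact)` vs cycles — deterministic, no initialization, exact through
two points. Two deliberate tolerances: input intact fractions slightly
above 1 are accepted (multiplicative measurement noise on a near-1
amplitude produces them), and a fitted decay that comes out negative on
trendless data is clamped to zero so the model invariant (k ≥ 0) holds.
Evaluation clips the intact fraction to [0, 1] for the same reason on the
amplitude side.

Arrhenius scaling `rate(T2) = rate(T1)·exp(-(Ea/R)(1/T2 - 1/T1))`
extrapolates accelerated-aging measurements. The activation energy is a
required parameter with no default: published DNA-degradation values span
roughly 100–160 kJ/mol depending on matrix and mechanism, and silently
choosing one would bury the dominant sensitivity of any shelf-life claim.
R = 8.314 J/(mol·K); temperatures are Kelvin internally (the CLI converts
from Celsius).

Base lesions (depurination and 8-oxo-dG) are pooled into a single per-nt
rate, as they are usually reported jointly; the published anchor "6% of
200-nt strands lesioned per year" is interpreted as the probability of at
least one lesion per strand, giving `r = -ln(0.94)/200 = 3.09e-4 /nt/yr`
via `LesionModel.from_strand_fraction`. Lesions corrupt bases without
breaking the strand, so they belong on the symbol-error side of the
channel, not the erasure side.

Qualitative effects the literature reports without usable coefficients —
e.g. that a pH drop from 6 to 5 can raise degradation rates by an order of
magnitude, or that higher DNA concentration is self-protective — are noted
here but deliberately not modeled.

## The channel

Strand loss is modeled linear in length with copy redundancy in the
exponent: `p_strand_erasure = min(1, L·b)^c`. The clamp is a minimal
repair: the raw product exceeds 1 for L > 1/b and is not a probability;
clamping preserves monotonicity in L and the exact printed values below
the clamp. The default coefficient is b = 5e-3. Note an internal tension
in the sources for this constant: the same passage that prints `(L·5E-3)^c`
also describes calibrating so that 1000-nt strands have ≤ 50% erasure
probability, which requires 5e-4. The default follows the printed formula;
the coefficient is an ordinary parameter everywhere (`breakage_factor`),
and the density optimizer sweeps it explicitly, so nothing downstream
depends on the choice.

Per-nt errors (substitutions, insertions, deletions lumped into one
`p_error_per_nt`) are i.i.d.; a 4-nt symbol (one byte at 2 bits/nt, the
natural GF(256) mapping) is wrong with probability `1-(1-p)^4`. No
position-dependent error profile, sequence bias, or PCR amplification bias
is modeled. Copies reduce only erasure probability — there is no
consensus-calling model by which copies would reduce within-strand symbol
errors.

## Concatenated-code reliability

An RS[n, k] code over GF(256) has minimum distance d = n-k+1 and decodes
iff `2T + E ≤ d-1` for T unknown-position errors and E known-position
erasures. The outer code spans 255 strands with exactly one symbol per
strand (full interleaving). Inner-decode failures are treated as detected
— a bounded-distance decoder almost always notices an uncorrectable
pattern — and become outer erasures alongside physically lost strands:

    p_symbol_erasure = p_strand + (1 - p_strand) · P[Binom(n_in, p_sym) > t_in]

Silent inner miscorrections are not modeled (the codec tests show
detection dominates by a wide margin at realistic redundancies), but the
outer tail computation accepts a nonzero silent-error probability, so the
machinery is fully general.

The outer failure probability is the exact trinomial tail
`P[2T + E > d-1]` with each of the n symbols independently erased, wrong,
or clean. It is computed from the log-PMF of the decoding load S = 2T+E
over the O(n²) lattice (log-multinomial coefficients via `gammaln`,
aggregation via `logsumexp`), which keeps tails accurate far below linear
underflow; results are exposed both as probabilities and as log10 values,
since the interesting regime sits at 1e-14 and below. Erasure-only and
error-only channels short-circuit to `scipy.stats.binom.logsf`. Two
byproducts of the same PMF: the whole family of tails for every outer k at
once (the optimizer's inner loop), and an exact normalization check used
in tests.

`system_error_curve` resizes the inner code to fill each requested strand
length (fixed 40-nt address overhead, 4 nt/symbol) while holding the inner
redundancy of the template design constant — the natural reading of
"sweep length at fixed correction capability per strand".

## Density optimization

Information density is payload through three overheads:
`(k_out/n_out) · 8·(k_in - index)/L` bits per synthesized nt, with L the
full physical strand (40 nt of primer addresses by default, 20 per end,
consistent with sub-25-nt primer targets; 4 index bytes inside the inner
payload). An overhead-free rate-1 design reaches exactly 2 bits/nt.

`optimize_design` enumerates every (outer k, inner k) pair — inner n is
fixed by strand geometry — and returns the densest design whose analytic
failure probability is strictly below the target (default 1e-14; note the
hard-drive comparison is sometimes quoted as log-probability -15, an
order-of-magnitude ambiguity the parameter absorbs). For each inner k the
erasure probability is computed once and the failure tails of all 255
outer-k values are read off one PMF, so a query costs O(inner_n) tail
computations; ties break toward larger outer k, then larger inner k.
Infeasible queries return an explicit empty point rather than raising. The
winning design's error probability is re-verified through the scalar
reliability path before it is reported. In sweeps, the per-nt breakage
probability replaces the channel module's 5e-3 coefficient — it is
precisely the quantity being swept (1e-3 down to 1e-8) — with a single
copy per strand by default, the assumption that maximizes density and
fully exercises the code.

The density section's per-nt error rate is not pinned by the sources; the
default is 1e-3 per nt, the lower of the two rates conventionally used to
bracket synthesis-plus-sequencing error (1e-2 and 1e-3). Joint
optimization over address length or symbol width, and biochemical sequence
constraints (GC content, homopolymers), are out of scope.

## Monte-Carlo validation

`simulate_decode` samples the channel directly — per-copy Bernoulli strand
loss, binomial symbol errors per surviving strand, the inner threshold,
then the outer predicate `E > d-1` — which is exactly the event the
analytic model computes, so agreement tests the analytics with no modeling
slack. Symbol errors are drawn for all strands and OR-ed with erasures;
distributionally identical to sampling only survivors and simpler to
vectorize. Trials are drawn in fixed 10,000-trial chunks from child
streams spawned off one `SeedSequence`: a fixed seed is bit-identical, and
growing the trial count never reshuffles earlier trials.

Simulation cannot certify 1e-14 events. The cross-check grid (12 parameter
sets in the tests) is confined to failure probabilities of about 5e-3 to
0.9, where 100,000 trials put at least hundreds of expected failures behind
each estimate; agreement is asserted within 3 standard errors. Claims in
the deep tail are analytic-only, backed by the exhaustive-enumeration
agreement at small n and the structural monotonicity properties.

`simulate_codec_roundtrip` goes one level deeper: real payload bytes,
outer-then-inner encoding (4 big-endian index bytes per strand), sampled
corruption, inner decode with detected failures becoming outer erasures,
outer errors-and-erasures decode, byte-exact comparison. The codec
(`rscodec`) is a standard GF(2^8)/0x11d implementation — syndromes, Forney
syndromes for erasures, Berlekamp-Massey, Chien search, Forney magnitudes
— written for clarity over speed (pure Python; fine for the small designs
and trial counts it serves). Per-trial agreement between the real decoder
and the threshold predicate is itself a test, with the caveat that a
decoder can occasionally miscorrect beyond the bound where the predicate
simply says "fail".

## Problem sizes and test design

The test suite's exhaustive enumeration oracle covers outer codes to
n = 12 (3^n outcome vectors); the Monte-Carlo grid uses 100,000 trials per
point; density sweeps cover 10 lengths × 6 breakage rates with the full
255 × inner_n enumeration per cell (about a second for the whole sweep).
Parameter-recovery tests use 10-point decay curves with 2% multiplicative
noise over 100 seeded replicates. Hypothesis-based property tests run
derandomized. The synthetic freeze-thaw generator emulates a quantified
intact-fraction time course with multiplicative Gaussian noise; it does
not emulate cycle-to-cycle correlation, detection floors, or
length-dependent fragility, so passing recovery tests demonstrate
estimator correctness under the stated noise model, not robustness to
every laboratory artifact.

## Known limitations

- The linear-breakage erasure model is an empirical stand-in; no
  sequence- or position-dependence, and the clamp at probability 1 is a
  modeling repair, not chemistry.
- Insertions and deletions are folded into symbol errors; there is no
  synchronization-aware inner decoding.
- Inner miscorrection probability is set to zero in the default chain;
  at very low inner redundancy (1–2 parity symbols) this slightly
  understates silent corruption.
- Arrhenius extrapolation assumes a single rate-limiting mechanism across
  the temperature range; accelerated-aging practice warns this can fail
  across phase changes (e.g. through the freezing point).
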