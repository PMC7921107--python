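# dnastore

Quantitative tradeoff analysis for DNA data-storage systems.

DNA stored in a tube degrades: backbones break (losing whole strands),
freeze-thaw cycles fragment working copies, and bases accumulate lesions.
A storage system compensates with error-correcting codes and molecular
redundancy — but every parity symbol, address, and index is synthesized
nucleotide that carries no payload. This package lets a system designer put
numbers on that tension: given a degradation environment, how should strand
length, copy number, and inner/outer Reed-Solomon redundancy be chosen, and
what information density (bits per nucleotide) survives the reliability
requirement?

It is a library first (`import dnastore`), with narrative scripts under
`examples/` and a thin `dnastore` CLI for sweeps and simulations.

## The model

**Kinetics.** Backbone scission is a Poisson process: a strand of length
*L* nt survives *t* years with probability `exp(-r L t)` at per-nt rate
*r* (permafrost fossil DNA: r ≈ 5.5e-6 /nt/yr). Freeze-thaw damage follows
the fitted exponential `intact = 0.9484 · e^(-0.068 · cycles)`. Arrhenius
scaling extrapolates accelerated-aging rates across temperature; a pooled
depurination/8-oxo-dG rate models base lesions.

**Channel.** Breakage probability is modeled linear in strand length; with
*c* molecular copies, a strand is erased only when all copies are lost:

    p_strand_erasure(L, c) = min(1, L·b)^c

Per-nt errors (substitutions, indels, lesions) corrupt 4-nt code symbols
with probability `1 - (1-p)^4`.

**Codes.** Each strand carries one inner RS codeword over GF(256) (index
bytes + payload + parity); one symbol from each of *n* = 255 strands forms
an outer RS codeword. A code of minimum distance *d* decodes iff
`2·errors + erasures ≤ d - 1`. Lost strands and detected inner-decode
failures are outer erasures, so the outer failure probability is an exact
trinomial tail `P[2T + E > d - 1]`, evaluated in the log domain down to the
1e-300 regime (hard-drive reliability, 1e-14 per bit, is the usual target).

**Density.** `density = (k_out/n_out) · 8·(k_in - index) / L` bits per
synthesized nt. The optimizer enumerates every redundancy split and returns
the densest design whose failure probability beats the target.

**Validation.** A seeded Monte-Carlo channel simulation and a full
encode/corrupt/decode round trip through a real GF(256) errors-and-erasures
RS codec serve as independent oracles for the analytics.

## Worked example

```python
from dnastore import DensityQuery, optimize_design

point = optimize_design(DensityQuery(strand_length=400,
                                     breakage_prob_per_nt=1e-5))
print(point.best_design.outer, point.best_design.inner)
print(f"{point.density:.3f} bits/nt, residual error {point.achieved_error:.2e}")
```

prints

```
RSCode(n=255, k=239) RSCode(n=90, k=84)
1.500 bits/nt, residual error 5.98e-15
```

— for 400-nt strands losing 1 in 10^5 nt-equivalents to breakage, the best
design spends 16 outer symbols on strand-loss protection and 6 inner
symbols per strand on within-strand errors, delivering 1.5 bits per
synthesized nucleotide at a residual decoder-error probability below the
1e-14 target. Sweeping breakage from 1e-3 to 1e-8
(`examples/density_tradeoff.py`) shows the optimum strand length moving
from 200 nt (0.789 bits/nt) up to 1000 nt (1.750 bits/nt) as conditions
improve.

The other examples: `degradation_kinetics.py` (fossil half-life,
freeze-thaw, Arrhenius, lesions), `decoder_error_curve.py` (failure
probability vs length/copies/error rate), `monte_carlo_check.py`
(analytics vs simulation).

CLI equivalents:

```sh
dnastore kinetics freeze-thaw --cycles 20
dnastore reliability sweep --lengths 100:1000:100 --copies 1,2 --p-error 1e-3
dnastore density sweep --lengths 200,400,1000 --breakage 1e-3,1e-5,1e-8
dnastore simulate --length 400 --inner 90,84 --breakage-factor 2.5e-4 --trials 100000 --seed 7
```

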