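"""Decoder failure probability versus strand length, copies and error rate.

Longer strands break more often under the linear-breakage channel, so the
outer Reed-Solomon code sees more erasures and fails more; extra molecular
copies push the curve down exponentially.  Printed values are log10 of the
failure probability of an outer RS[255,223] decode (hard-drive reliability,
1e-14 per bit, sits at -14 on this scale).
"""

from dnastore import ConcatenatedDesign, RSCode, system_error_curve

template = ConcatenatedDesign(outer=RSCode(255, 223), inner=RSCode(26, 20))
lengths = range(100, 501, 100)

# A gentler breakage coefficient than the 5e-3 default so single-copy pools
# are not certain losses at every length shown.
FACTOR = 2.5e-4

header = "length(nt) " + "".join(f"  c={c},p={p:g}" for c in (1, 2) for p in (1e-2, 1e-3))
print(header)
curves = {
    (c, p): system_error_curve(template, lengths, copies=c,
                               p_error_per_nt=p, breakage_factor=FACTOR)
    for c in (1, 2) for p in (1e-2, 1e-3)
}
for i, L in enumerate(lengths):
    row = f"{curves[(1, 1e-2)][i].strand_length:10d} "
    for c in (1, 2):
        for p in (1e-2, 1e-3):
            row += f"  {curves[(c, p)][i].log10_decoder_error:9.2f}"
    print(row)

print("\nEach column is log10 P[outer decode fails]; more negative = more "
      "reliable.  Values fall with copies and p_error, rise with length.")
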