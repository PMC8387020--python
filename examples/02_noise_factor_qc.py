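"""Noise-factor QC: when is a load quotient trustworthy?

The noise factor N is the swing in the load m/h caused by a one-read
perturbation of the counts.  Samples with N > 0.22 should be reported only
as "highly colonized", not quantified; deeper sequencing always brings N
back down at fixed load.
"""

import hampcr as h

for m, host in [(100, 100), (24000, 1000), (2400, 100), (0, 10)]:
    n = h.noise_factor(m, host)
    print(f"m={m:>6} h={host:>5}  N={n:.4f}  -> {h.classify(m, host)}")

# Planning: how many host reads keep a heavily colonized sample (load 24)
# inside the quantitative range?
h_star = h.min_host_depth_for_load(24, threshold=0.22)
print(f"\nload 24 needs >= {h_star} host reads "
      f"(~{h_star * 25} total reads) for N <= 0.22")
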