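"""Chaining amplicon loads and qPCR loads onto a CFU scale.

qPCR gives a relative ratio 2^(refCq - targetCq); amplicon load another
relative ratio; plate counts give CFU.  Two log10-log10 least-squares fits
put everything on the CFU scale for direct comparison.
"""

import numpy as np
import pandas as pd

import hampcr as h

rng = np.random.default_rng(0)
samples = [f"leaf{i}" for i in range(12)]

# ground truth: bacterial titers spanning 4 orders of magnitude
true_cfu = pd.Series(10 ** rng.uniform(4, 8, size=12), index=samples)

# each assay sees the truth through its own affine log-log lens + noise
ham = 10 ** (0.95 * np.log10(true_cfu) - 6 + rng.normal(0, 0.05, 12))
cq = pd.DataFrame({
    "target_cq": 38 - 3.3 * np.log10(true_cfu / 1e4) + rng.normal(0, 0.1, 12),
    "reference_cq": pd.Series(24.0, index=samples)})

qload = h.qpcr_load(cq)
chain = h.chain_to_cfu(ham, qload, true_cfu)

print("fit qPCR -> amplicon-load scale:",
      f"slope={chain.qpcr_to_hampcr.slope:.3f}",
      f"intercept={chain.qpcr_to_hampcr.intercept:.3f}")
print("fit amplicon-load -> CFU scale: ",
      f"slope={chain.hampcr_to_cfu.slope:.3f}",
      f"intercept={chain.hampcr_to_cfu.intercept:.3f}")
ratio = chain.hampcr_on_cfu / true_cfu
print(f"\namplicon loads on CFU scale are within "
      f"{100 * (ratio.max() - 1):.0f}% of plate counts at worst")
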