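"""Correlation networks: relative abundance vs load.

Closure makes a blooming dominant taxon anti-correlate with everything in
relative-abundance data even when the underlying absolute abundances are
independent.  Load data keep the external (host) denominator and stay quiet.
"""

import numpy as np
import pandas as pd

import hampcr as h

rng = np.random.default_rng(5)
n = 200
taxa = [f"genus{i}" for i in range(14)]
loads = pd.DataFrame(rng.lognormal(0, 0.25, size=(14, n)), index=taxa)
loads.loc["sphingomonas"] = rng.lognormal(3, 1.2, size=n)  # dominant bloomer

ra = loads.div(loads.sum(axis=0), axis=1)  # compositional closure

net_ra = h.correlation_network(ra, threshold=0.3)
net_load = h.correlation_network(loads, threshold=0.3)

print(f"RA network:   {len(net_ra.edges)} edges; "
      f"dominant-taxon degree {net_ra.degree('sphingomonas')}")
print(f"load network: {len(net_load.edges)} edges; "
      f"dominant-taxon degree {net_load.degree('sphingomonas')}")
print("\nspurious RA edges of the dominant taxon (all negative r):")
print(net_ra.edge_frame().query(
    "taxon_a == 'sphingomonas' or taxon_b == 'sphingomonas'").head())
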