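"""A simulated titration panel: does measured load track pipetted truth?

Two stocks (high-load infected, low-load uninfected) mixed 0:7 ... 7:0 give
samples of known expected load; the estimated loads should regress on the
truth with slope ~1.
"""

import numpy as np

import hampcr as h
import pandas as pd

infected = h.Stock(microbial=pd.Series({"pathogen": 50.0, "commensal": 5.0}),
                   host=10.0)
clean = h.Stock(microbial=pd.Series({"pathogen": 0.5, "commensal": 5.0}),
                host=10.0)
ratios = [(v, 7 - v) for v in range(8)]

table, amap, truth = h.simulate_titration(infected, clean, ratios,
                                          depth=100_000, seed=4)
est = h.microbial_load(table, amap).loads.loc["pathogen"]
true = truth.true_loads.loc["pathogen"]

print(f"{'mix':>8} {'true load':>10} {'measured':>10}")
for s in table.sample_ids:
    print(f"{s:>8} {true[s]:>10.3f} {est[s]:>10.3f}")
slope = np.polyfit(true, est, 1)[0]
print(f"\nregression slope measured-vs-true: {slope:.3f} (ideal 1.0)")
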