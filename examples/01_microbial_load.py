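"""From a host+microbe count table to microbial loads.

Builds the minimal experiment — one host ASV and two microbial ASVs across
three samples — and contrasts relative abundance with host-normalized load.
"""

import hampcr as h

table = h.CountTable.from_arrays(
    [[50, 4, 400],     # host gene ASV (e.g. A. thaliana GI)
     [25, 96, 30],     # microbial ASV 1
     [25, 0, 20]],     # microbial ASV 2
    ["host_GI", "sphingomonas", "pseudomonas"],
    ["healthy", "infected", "sparse"],
)
amap = h.AmpliconMap.from_dict(
    {"host_GI": "host", "sphingomonas": "16S-V4", "pseudomonas": "16S-V4"})

ra = h.relative_abundance(table, amap, drop_host=True)
loads = h.microbial_load(table, amap)

print("Relative abundance (host removed, rescaled to 1):")
print(ra.fractions.round(3))
print("\nMicrobial load (microbe counts / host counts):")
print(loads.loads.round(3))
print("\nTotal load per sample:",
      {k: float(v) for k, v in loads.total_load.round(2).items()})

# Relative abundance makes 'healthy' and 'infected' look alike in
# composition; the load row reveals that 'infected' carries 24x more
# microbial signal per unit host (96/4 = 24) than composition alone shows.
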