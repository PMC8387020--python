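"""Noise-factor QC for host-normalized loads.

When the host amplicon count h is used as a load denominator and h is
small, a single read more or less swings the load quotient m/h wildly.
The noise factor N quantifies this as the full range of load quotients
reachable by perturbing the counts by one read in either direction:

    N(m, h) = (m + 1)/(h - 1)  -  (m - 1)/(h + 1)

(the lower endpoint clamped at 0 for m = 0, since counts cannot go
negative).  N is undefined for h <= 1.  N grows with microbial load at
fixed depth and shrinks with sequencing depth at fixed load, so a noisy
sample can always be rescued by sequencing deeper.  Samples with
N > 0.22 (a conservative default) should be reported only as "highly
colonized", not quantified.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .tables import AmpliconMap, CountTable

__all__ = [
    "DEFAULT_THRESHOLD",
    "NoiseAssessment",
    "noise_factor",
    "classify",
    "assess_samples",
    "min_host_depth_for_load",
]

DEFAULT_THRESHOLD = 0.22

QUANTITATIVE = "quantitative"
HIGHLY_COLONIZED = "highly_colonized"
UNDEFINED = "undefined"


@dataclass(frozen=True)
class NoiseAssessment:
    sample_id: str
    m: int
    h: int
    N: float | None
    classification: str


def noise_factor(m: int, h: int) -> float | None:
    """Range of load quotients under a one-read perturbation; None if h <= 1."""
    if m < 0 or h < 0:
        raise ValueError("counts must be non-negative")
    if h < 2:
        return None
    upper = (m + 1) / (h - 1)
    lower = max(m - 1, 0) / (h + 1)
    return upper - lower


def classify(m: int, h: int, threshold: float = DEFAULT_THRESHOLD) -> str:
    """``quantitative`` if N <= threshold, ``highly_colonized`` if N > threshold,
    ``undefined`` if N is undefined (h <= 1)."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    n = noise_factor(m, h)
    if n is None:
        return UNDEFINED
    return HIGHLY_COLONIZED if n > threshold else QUANTITATIVE


def assess_samples(
    table: CountTable, amap: AmpliconMap, threshold: float = DEFAULT_THRESHOLD
) -> pd.DataFrame:
    """Per-sample noise assessment (columns: m, h, N, classification).

    m and h are the summed microbial and host counts of the sample; the
    host sum here is the raw read sum (no copy-number correction), since N
    models read-sampling noise, not template stoichiometry.
    """
    amap.validate_against(table, require_host=True)
    hosts = set(amap.host_asvs()) & set(table.asv_ids)
    h = table.counts.loc[sorted(hosts)].sum(axis=0)
    m = table.counts.drop(index=sorted(hosts)).sum(axis=0)
    rows = []
    for s in table.sample_ids:
        n = noise_factor(int(m[s]), int(h[s]))
        rows.append({
            "sample_id": s, "m": int(m[s]), "h": int(h[s]),
            "N": float("nan") if n is None else n,
            "classification": classify(int(m[s]), int(h[s]), threshold),
        })
    return pd.DataFrame(rows).set_index("sample_id")


def min_host_depth_for_load(
    target_load: float, threshold: float = DEFAULT_THRESHOLD
) -> int:
    """Smallest host count h* keeping a sample of the given load quantitative.

    Scans h upward from 2 until ``noise_factor(round(load*h), h) <= threshold``;
    useful for planning sequencing depth, since N at fixed load falls as
    depth rises.  Doubles an upper bracket first, then scans — N is not
    perfectly monotone in h because of the rounding of m.
    """
    if target_load <= 0:
        raise ValueError("target_load must be > 0")
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    h = 2
    while True:
        n = noise_factor(round(target_load * h), h)
        if n is not None and n <= threshold:
            return h
        h += 1
        if h > 10**8:  # pragma: no cover - unreachable for sane inputs
            raise RuntimeError("no feasible host depth found")
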