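"""Reconstruction of original host:microbe ratios after pre-sequencing remixing.

Host amplicons often dominate a pooled library (e.g. ~22% of all reads in a
leaf-microbiome run), wasting sequencing on the denominator.  Because host
and microbial amplicons differ in length, the pooled library can be split on
a gel and remixed with far less host (e.g. ~5%).  A *reference sample* — an
aliquot of the pool rebarcoded before remixing — preserves the original
host:microbe ratio and provides the key to undo the remix in silico:

    f = (H * m) / (M * h)

where h, m are the summed host and microbial counts over the remixed
(non-reference) samples and H, M the same sums over the reference
sample(s).  Multiplying every host count by f makes the pooled corrected
host:microbe ratio equal the reference's H:M, i.e. the original ratio; it
is the unique global factor with that property.  Microbial counts are
untouched, so reconstruction commutes with taxon aggregation of microbial
rows and per-sample loads computed from corrected host counts match the
pre-remix loads.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .tables import HOST_CLASS, AmpliconMap, CountTable, SampleMetadata

__all__ = ["RemixSummary", "RemixPlan", "summarize", "reconstruct", "plan_remix"]


@dataclass(frozen=True)
class RemixSummary:
    """The four pooled sums and the derived scaling constant.

    h, m: host and microbial count sums over non-reference samples.
    H, M: host and microbial count sums over reference sample(s).
    """

    h: float
    m: float
    H: float
    M: float

    def __post_init__(self) -> None:
        if min(self.h, self.m, self.H, self.M) < 0:
            raise ValueError("count sums must be non-negative")

    @property
    def f(self) -> float:
        """Scaling constant (H*m)/(M*h); undefined (raises) when M*h == 0."""
        if self.M * self.h == 0:
            raise ZeroDivisionError(
                f"f undefined: M*h == 0 (h={self.h}, M={self.M}); the remixed pool "
                "has no host counts or the reference has no microbial counts"
            )
        return (self.H * self.m) / (self.M * self.h)


def _counts_frame(table: CountTable | pd.DataFrame) -> pd.DataFrame:
    # DataFrames are accepted so real-valued (expectation-mode) libraries can
    # flow through the same summarize/reconstruct path as integer count tables.
    return table.counts if isinstance(table, CountTable) else table


def summarize(
    table: CountTable | pd.DataFrame, amap: AmpliconMap, meta: SampleMetadata
) -> RemixSummary:
    """Sum host/microbe counts over remixed samples (h, m) and references (H, M).

    With several flagged reference samples, H and M are count-weighted sums
    across all of them.
    """
    df = _counts_frame(table)
    refs = [s for s in meta.reference_samples() if s in df.columns]
    others = [s for s in meta.non_reference_samples() if s in df.columns]
    if not refs:
        raise ValueError("no reference sample flagged in metadata")
    if not others:
        raise ValueError("no non-reference samples present")
    host_rows = [a for a in df.index if amap.amplicon_class(a) == HOST_CLASS]
    if not host_rows:
        raise ValueError("no host-class rows in table")
    microbe_rows = [a for a in df.index if a not in set(host_rows)]
    return RemixSummary(
        h=float(df.loc[host_rows, others].to_numpy().sum()),
        m=float(df.loc[microbe_rows, others].to_numpy().sum()),
        H=float(df.loc[host_rows, refs].to_numpy().sum()),
        M=float(df.loc[microbe_rows, refs].to_numpy().sum()),
    )


def reconstruct(
    table: CountTable | pd.DataFrame, amap: AmpliconMap, summary: RemixSummary
) -> pd.DataFrame:
    """Multiply host rows by f, restoring original microbe-to-host ratios.

    Output is real-valued (f times an integer is generally not an integer);
    round explicitly if an integer-only consumer needs it.
    """
    df = _counts_frame(table).astype(float).copy()
    f = summary.f  # raises if undefined
    host_rows = [a for a in df.index if amap.amplicon_class(a) == HOST_CLASS]
    df.loc[host_rows] = df.loc[host_rows] * f
    return df


@dataclass(frozen=True)
class RemixPlan:
    """Molar mixing proportions for a host-reduction remix.

    ``proportions`` maps {"host", "microbial", "reference"} to molar shares
    of the final pool (summing to 1); ``volume_shares`` gives pipetting
    shares of the purified host and microbial fractions implied by their
    molarity estimates.
    """

    target_host_fraction: float
    host_molarity: float
    microbial_molarity: float
    proportions: dict[str, float]
    volume_shares: dict[str, float]

    def __post_init__(self) -> None:
        if not 0 < self.target_host_fraction < 1:
            raise ValueError("target_host_fraction must be in (0, 1)")
        if abs(sum(self.proportions.values()) - 1) > 1e-9:
            raise ValueError("proportions must sum to 1")


def plan_remix(
    current_host_fraction: float,
    target_host_fraction: float,
    host_molarity: float | None = None,
    microbial_molarity: float | None = None,
    reference_fraction_each: float = 0.01,
    n_references: int = 0,
) -> RemixPlan:
    """Plan the remix of gel-purified host and microbial library fractions.

    The final pool devotes ``reference_fraction_each`` of total molarity to
    each of ``n_references`` reference spike-ins (1% each is typical); the
    remainder is split between the purified host and microbial fractions so
    that the molar host share of the whole pool (references excluded from
    the host/microbe ratio) hits ``target_host_fraction``.

    If molarity estimates for the purified fractions are not given, they
    default to being proportional to the fractions' shares in the original
    pool (equal-volume recovery), so e.g. going from 22% host to 5% host
    implies a host:microbial volume ratio of (0.05/0.95)*(0.78/0.22).
    """
    for name, v in (("current", current_host_fraction), ("target", target_host_fraction)):
        if not 0 < v < 1:
            raise ValueError(f"{name} host fraction must be in (0, 1)")
    if host_molarity is None or microbial_molarity is None:
        host_molarity = current_host_fraction
        microbial_molarity = 1.0 - current_host_fraction
    if host_molarity <= 0 or microbial_molarity <= 0:
        raise ValueError("molarity estimates must be positive")
    ref_share = reference_fraction_each * n_references
    if ref_share >= 1:
        raise ValueError("reference spike-ins cannot fill the whole pool")
    t = target_host_fraction
    host_share = (1 - ref_share) * t
    microbial_share = (1 - ref_share) * (1 - t)
    vol_host = host_share / host_molarity
    vol_microbial = microbial_share / microbial_molarity
    vol_total = vol_host + vol_microbial
    return RemixPlan(
        target_host_fraction=t,
        host_molarity=host_molarity,
        microbial_molarity=microbial_molarity,
        proportions={"host": host_share, "microbial": microbial_share,
                     "reference": ref_share},
        volume_shares={"host": vol_host / vol_total,
                       "microbial": vol_microbial / vol_total},
    )
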