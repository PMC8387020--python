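"""Quantification: relative abundance, host-normalized microbial load, transforms.

The central statistic is the microbial load: the ratio of microbial amplicon
counts to host amplicon counts in a sample.  Because host and microbial
templates are co-amplified from the same DNA extract, this ratio is a proxy
for microbes per unit host tissue and — unlike relative abundance — is not
constrained to sum to one across taxa, so it escapes the compositionality
artifacts of pure marker-gene data.

No pseudocounts are used anywhere: a sample whose host count is zero has an
undefined load and is flagged, never imputed.  Reliability of defined loads
is the job of :mod:`hampcr.qc`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tables import HOST_CLASS, AmpliconMap, CountTable

__all__ = [
    "RelAbundanceTable",
    "LoadTable",
    "relative_abundance",
    "microbial_load",
    "copy_number_normalize",
    "fourth_root",
    "min_abundance_filter",
    "compare_replicates",
    "titration_expectation",
    "mixture_mass_fraction",
]


@dataclass(frozen=True)
class RelAbundanceTable:
    """Per-sample fractions (columns sum to 1 where depth > 0)."""

    fractions: pd.DataFrame
    host_included: bool
    zero_depth_samples: tuple[str, ...] = ()
    #: False once rows have been filtered out, so columns no longer sum to 1.
    closed: bool = True

    def __post_init__(self) -> None:
        if not self.closed:
            return
        sums = self.fractions.sum(axis=0)
        ok = sums[~sums.index.isin(self.zero_depth_samples)]
        if len(ok) and not np.allclose(ok.to_numpy(), 1.0, atol=1e-9):
            raise ValueError("relative-abundance columns must sum to 1")


@dataclass(frozen=True)
class LoadTable:
    """Microbe-to-host count ratios (M:H) per microbial ASV/taxon and sample.

    ``loads`` holds only microbial rows; ``host_count`` is the per-sample
    denominator (summed host-class counts, copy-number corrected);
    ``total_load`` is the per-sample column sum of the microbial loads.
    Samples listed in ``undefined_samples`` have zero host signal: their
    load columns are NaN and must not be interpreted quantitatively.
    """

    loads: pd.DataFrame
    host_count: pd.Series
    undefined_samples: tuple[str, ...] = ()

    @property
    def total_load(self) -> pd.Series:
        return self.loads.sum(axis=0, skipna=False)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.loads.columns)


def relative_abundance(
    table: CountTable, amap: AmpliconMap | None = None, drop_host: bool = False
) -> RelAbundanceTable:
    """Convert counts to within-sample fractions.

    With ``drop_host=True`` the host-class ASVs are removed first and the
    remaining microbial ASVs are rescaled to sum to 1 (i.e. "rescaled to
    100%"), which is how host+microbe libraries are compared against pure
    marker-gene libraries.  Zero-depth columns come back as all-zero with
    the sample recorded in ``zero_depth_samples``.
    """
    df = table.counts.astype(float)
    if drop_host:
        if amap is None:
            raise ValueError("drop_host=True requires an amplicon map")
        amap.validate_against(table)
        df = df.drop(index=[a for a in table.asv_ids if amap.amplicon_class(a) == HOST_CLASS])
    depths = df.sum(axis=0)
    zero = tuple(depths.index[depths == 0])
    if zero:
        warnings.warn(f"zero-depth samples left as zeros: {list(zero)}", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = df.div(depths, axis=1).fillna(0.0)
    return RelAbundanceTable(frac, host_included=not drop_host, zero_depth_samples=zero)


def _host_denominator(table: CountTable, amap: AmpliconMap) -> pd.Series:
    hosts = [a for a in table.asv_ids if amap.amplicon_class(a) == HOST_CLASS]
    contrib = [table.counts.loc[a] / amap.copy_number(a) for a in hosts]
    return pd.concat(contrib, axis=1).sum(axis=1)


def microbial_load(table: CountTable, amap: AmpliconMap) -> LoadTable:
    """Divide each microbial ASV's counts by the sample's host count.

    The denominator is the sum over all host-class ASVs (sequence variants
    of the host amplicon are one biological signal), each divided by its
    copy number so that multi-copy host genes such as *PolA1* in hexaploid
    wheat do not inflate the denominator.  Samples with zero host counts
    get NaN loads and are flagged.
    """
    amap.validate_against(table, require_host=True)
    host = _host_denominator(table, amap)
    microbes = [a for a in table.asv_ids if amap.amplicon_class(a) != HOST_CLASS]
    with np.errstate(invalid="ignore", divide="ignore"):
        loads = table.counts.loc[microbes].astype(float).div(host.where(host > 0), axis=1)
    undefined = tuple(host.index[host == 0])
    return LoadTable(loads, host_count=host, undefined_samples=undefined)


def copy_number_normalize(load: LoadTable, amap: AmpliconMap) -> LoadTable:
    """Divide each microbial row by its marker-gene copy number.

    rDNA operon copy number varies several-fold among bacterial families;
    dividing by the (average) copy number converts amplicon load toward a
    genome (cell-count) load.  The host denominator was already corrected
    in :func:`microbial_load`.
    """
    missing = [a for a in load.loads.index if a not in amap.table.index]
    if missing:
        raise KeyError(f"no copy number available for: {missing}")
    cn = pd.Series({a: amap.copy_number(a) for a in load.loads.index})
    return LoadTable(load.loads.div(cn, axis=0), host_count=load.host_count,
                     undefined_samples=load.undefined_samples)


def fourth_root(values: pd.DataFrame | pd.Series | np.ndarray):
    """Element-wise x**(1/4), the variance-stabilizing transform used for
    abundance scatter comparisons (compresses dominant taxa less brutally
    than log and needs no pseudocount at zero)."""
    arr = np.asarray(values, dtype=float)
    if np.any(arr < 0):
        raise ValueError("fourth_root requires non-negative input")
    out = arr ** 0.25
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index)
    return out


def min_abundance_filter(
    ra: RelAbundanceTable, threshold: float = 0.0005, rule: str = "any-sample"
) -> RelAbundanceTable:
    """Drop rows below a minimum relative abundance (default 0.05%).

    ``rule="any-sample"`` keeps a row if it reaches the threshold in at
    least one sample; ``rule="mean"`` applies the threshold to the row's
    mean fraction across samples.
    """
    if not 0 <= threshold < 1:
        raise ValueError("threshold must be in [0, 1)")
    if rule == "any-sample":
        keep = (ra.fractions >= threshold).any(axis=1)
    elif rule == "mean":
        keep = ra.fractions.mean(axis=1) >= threshold
    else:
        raise ValueError(f"unknown rule {rule!r}")
    all_kept = bool(keep.all())
    return RelAbundanceTable(
        ra.fractions.loc[keep],
        host_included=ra.host_included,
        zero_depth_samples=ra.zero_depth_samples,
        closed=ra.closed and all_kept,
    )


def compare_replicates(a, b) -> tuple[float, float, float]:
    """Replicate-fidelity statistics on matched (typically fourth-root) values.

    Returns ``(r_squared, ks_statistic, ks_pvalue)`` where R^2 is the square
    of the Pearson correlation of the paired values and the KS test is the
    two-sample two-sided Kolmogorov–Smirnov comparison of the two value
    distributions.
    """
    x = np.asarray(a, dtype=float).ravel()
    y = np.asarray(b, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("compare_replicates needs matched value sets")
    if x.size < 3:
        raise ValueError("need at least 3 shared rows to compare replicates")
    r = np.corrcoef(x, y)[0, 1]
    ks = stats.ks_2samp(x, y, alternative="two-sided", method="asymp")
    return float(r**2), float(ks.statistic), float(ks.pvalue)


def titration_expectation(
    microbes_a: pd.Series | dict,
    host_a: float,
    microbes_b: pd.Series | dict,
    host_b: float,
    volume_a: float,
    volume_b: float,
) -> pd.Series:
    """Expected loads for a volumetric mix of two component samples.

    Mixing volumes ``vA : vB`` of components with per-taxon microbial
    template concentrations ``mA, mB`` and host template concentrations
    ``hA, hB`` yields expected load

        (vA*mA + vB*mB) / (vA*hA + vB*hB)

    per microbial taxon — the ratio of volume-weighted template sums, not
    the volume-weighted ratio.  Returns NaN-filled result if the host
    denominator is zero.
    """
    if volume_a < 0 or volume_b < 0:
        raise ValueError("volumes must be non-negative")
    if volume_a == 0 and volume_b == 0:
        raise ValueError("at least one volume must be positive")
    m_a, m_b = pd.Series(microbes_a, dtype=float), pd.Series(microbes_b, dtype=float)
    m_a, m_b = m_a.align(m_b, fill_value=0.0)
    num = volume_a * m_a + volume_b * m_b
    den = volume_a * host_a + volume_b * host_b
    if den == 0:
        return pd.Series(np.nan, index=num.index)
    return num / den


def mixture_mass_fraction(
    volume_a: float, conc_a: float, volume_b: float, conc_b: float
) -> float:
    """Mass fraction contributed by component B in a two-stock mix.

    E.g. 240 µL of bacterial DNA at 10 ng/µL into 760 µL of plant DNA at
    10 ng/µL gives a 24% bacterial mass fraction.
    """
    total = volume_a * conc_a + volume_b * conc_b
    if total <= 0:
        raise ValueError("mixture has no mass")
    return volume_b * conc_b / total
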