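"""Calibration of amplicon loads against qPCR and CFU scales.

Amplicon-derived loads are internally consistent but primer-set specific:
different marker primers amplify with different efficiencies, so the same
template yields different absolute ratios.  Three anchors make loads
comparable across methods and labs:

* qPCR ratio: 2**(-target Cq) / 2**(-reference Cq) = 2**(refCq - targetCq),
  the standard delta-Cq relative quantification.
* Log10-log10 ordinary least squares between two load scales (slope m,
  intercept b); the fit maps one scale onto the other.
* Standard curves of known mixed ratios vs measured load, correcting
  per-primer-set amplification bias.

All fits run on log10-transformed positive values; zeros are excluded with
a warning, never pseudocounted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["AffineFit", "ChainedCalibration", "qpcr_load", "align_scales",
           "chain_to_cfu", "standard_curve"]


@dataclass(frozen=True)
class AffineFit:
    """y_log10 = slope * log10(x) + intercept, fitted by least squares."""

    slope: float
    intercept: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.slope) and np.isfinite(self.intercept)):
            raise ValueError("fit parameters must be finite")

    def predict_log10(self, x) -> np.ndarray:
        return self.slope * np.log10(np.asarray(x, dtype=float)) + self.intercept

    def predict(self, x):
        """Map positive values onto the fitted scale (back from log10)."""
        out = 10.0 ** self.predict_log10(x)
        if isinstance(x, pd.Series):
            return pd.Series(out, index=x.index)
        return out


def qpcr_load(cq: pd.DataFrame, target_col: str = "target_cq",
              reference_col: str = "reference_cq") -> pd.Series:
    """Per-sample qPCR load ratio 2**(reference Cq - target Cq).

    *cq* is indexed by sample with mean technical-replicate Cq values for
    the microbial target gene and the host reference gene.  Samples with a
    missing Cq come back NaN (flagged, not dropped silently).
    """
    t = pd.to_numeric(cq[target_col], errors="coerce")
    r = pd.to_numeric(cq[reference_col], errors="coerce")
    if ((t <= 0) | (r <= 0)).any():
        bad = cq.index[(t <= 0) | (r <= 0)].tolist()
        raise ValueError(f"Cq values must be positive; offending samples: {bad}")
    return 2.0 ** (r - t)


def _paired_positive(x, y) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(x, pd.Series) and isinstance(y, pd.Series):
        x, y = x.align(y, join="inner")
        x, y = x.to_numpy(float), y.to_numpy(float)
    else:
        x, y = np.asarray(x, float), np.asarray(y, float)
        if x.shape != y.shape:
            raise ValueError("x and y must be paired")
    if x.size == 0:
        raise ValueError("no overlapping samples to fit")
    bad = ~(np.isfinite(x) & np.isfinite(y)) | (x <= 0) | (y <= 0)
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} sample(s) with nonpositive or missing values; "
            "log10 fits need positive loads (exclude them explicitly)"
        )
    return x, y


def align_scales(x, y) -> AffineFit:
    """OLS fit of log10(y) on log10(x) mapping scale x onto scale y."""
    xv, yv = _paired_positive(x, y)
    if xv.size < 2:
        raise ValueError("need at least 2 points to fit")
    lx, ly = np.log10(xv), np.log10(yv)
    if np.ptp(lx) == 0:
        raise ValueError("zero variance in x; slope is unidentifiable")
    if xv.size == 2:
        # linregress is fine at n=2 but emits degenerate stats; closed form
        slope = (ly[1] - ly[0]) / (lx[1] - lx[0])
        return AffineFit(slope=float(slope), intercept=float(ly[0] - slope * lx[0]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.linregress(lx, ly)
    return AffineFit(slope=float(res.slope), intercept=float(res.intercept))


@dataclass(frozen=True)
class ChainedCalibration:
    """Two-step alignment qPCR -> amplicon-load scale -> CFU scale."""

    qpcr_to_hampcr: AffineFit
    hampcr_to_cfu: AffineFit
    hampcr_on_cfu: pd.Series
    qpcr_on_cfu: pd.Series


def chain_to_cfu(hampcr_loads: pd.Series, qpcr_loads: pd.Series,
                 cfu_counts: pd.Series) -> ChainedCalibration:
    """Put amplicon loads and qPCR loads on the CFU scale.

    First qPCR loads are regressed onto amplicon loads (log10-log10) and
    mapped onto that scale; then amplicon loads are regressed onto CFU
    counts and both the amplicon loads and the already-rescaled qPCR loads
    are mapped onto the CFU scale.
    """
    fit1 = align_scales(qpcr_loads, hampcr_loads)
    qpcr_scaled = fit1.predict(qpcr_loads)
    fit2 = align_scales(hampcr_loads, cfu_counts)
    return ChainedCalibration(
        qpcr_to_hampcr=fit1,
        hampcr_to_cfu=fit2,
        hampcr_on_cfu=fit2.predict(hampcr_loads),
        qpcr_on_cfu=fit2.predict(qpcr_scaled),
    )


def standard_curve(measured_load, true_ratio) -> AffineFit:
    """Fit mapping measured loads to known standardized mixed ratios.

    Running standards of known host:microbe ratio alongside experimental
    samples lets per-primer-set efficiency bias be divided out: applying
    the returned fit to measured loads yields bias-corrected loads
    comparable across primer sets.
    """
    return align_scales(measured_load, true_ratio)
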