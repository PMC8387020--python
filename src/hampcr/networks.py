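"""Correlation networks on relative-abundance vs load data.

Relative abundances are compositional: because taxa shares sum to one, a
genuinely independent dominant taxon drags every other taxon down whenever
it blooms, producing spurious negative correlations.  Load data carry an
external denominator (the host) and escape this closure artifact.  This
module builds thresholded Pearson networks from either kind of table so
the two can be contrasted, and exposes an adapter seam for SparCC-style
compositionality-aware estimators (third-party; never reimplemented here).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .tables import CountTable

__all__ = ["CorrelationNetwork", "correlation_network", "sparcc_adapter",
           "set_sparcc_backend", "SparccNotConfiguredError"]

DEFAULT_EDGE_THRESHOLD = 0.3


@dataclass(frozen=True)
class CorrelationNetwork:
    """Thresholded taxon correlation network.

    ``matrix`` is the full symmetric correlation matrix (unit diagonal),
    ``edges`` the list of retained (taxon_i, taxon_j, r) with i < j and
    |r| >= threshold, and ``node_weights`` the median abundance of each
    taxon across samples (a plotting size in the field's figures).
    """

    matrix: pd.DataFrame
    node_weights: pd.Series
    threshold: float
    edges: tuple[tuple[str, str, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        m = self.matrix.to_numpy()
        if m.size:
            if not np.allclose(m, m.T, atol=1e-12, equal_nan=True):
                raise ValueError("correlation matrix must be symmetric")
            if not np.allclose(np.diag(m), 1.0):
                raise ValueError("correlation matrix must have unit diagonal")

    def degree(self, taxon: str) -> int:
        return sum(1 for a, b, _ in self.edges if taxon in (a, b))

    def edge_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=["taxon_a", "taxon_b", "r"])


def _threshold_edges(corr: pd.DataFrame, threshold: float):
    taxa = list(corr.index)
    edges = []
    for i, a in enumerate(taxa):
        for b in taxa[i + 1:]:
            r = float(corr.at[a, b])
            if np.isfinite(r) and abs(r) >= threshold:
                edges.append((a, b, r))
    return tuple(edges)


def correlation_network(
    values: pd.DataFrame,
    method: str = "pearson",
    threshold: float = DEFAULT_EDGE_THRESHOLD,
    transform: Callable[[pd.DataFrame], pd.DataFrame] | None = None,
) -> CorrelationNetwork:
    """Pairwise Pearson network over taxa (rows) across samples (columns).

    Edges with |r| >= *threshold* (default 0.3) are retained.  Zero-variance
    taxa cannot be correlated and are excluded with a warning.  *transform*
    (e.g. ``hampcr.quant.fourth_root``) is applied before correlating;
    default is untransformed values.
    """
    if method != "pearson":
        raise ValueError(f"unsupported correlation method {method!r}")
    if values.shape[1] < 3:
        raise ValueError("need at least 3 samples to estimate correlations")
    df = values.astype(float)
    weights = df.median(axis=1)  # node size: median abundance on input scale
    if transform is not None:
        df = transform(df)
    variances = df.var(axis=1)
    dead = list(variances.index[variances == 0])
    if dead:
        warnings.warn(f"excluding zero-variance taxa: {dead}", stacklevel=2)
        df = df.drop(index=dead)
        weights = weights.drop(index=dead)
    corr = df.T.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    return CorrelationNetwork(
        matrix=corr,
        node_weights=weights,
        threshold=threshold,
        edges=_threshold_edges(corr, threshold),
    )


class SparccNotConfiguredError(RuntimeError):
    pass


_SPARCC_BACKEND: Callable[[pd.DataFrame], pd.DataFrame] | None = None


def set_sparcc_backend(fn: Callable[[pd.DataFrame], pd.DataFrame] | None) -> None:
    """Register an external SparCC implementation.

    *fn* must accept a taxon x sample count DataFrame and return a taxon x
    taxon correlation DataFrame in [-1, 1].  Pass ``None`` to unregister.
    """
    global _SPARCC_BACKEND
    _SPARCC_BACKEND = fn


def sparcc_adapter(
    counts: CountTable | pd.DataFrame,
    threshold: float = DEFAULT_EDGE_THRESHOLD,
) -> CorrelationNetwork:
    """Build a network from an externally computed SparCC correlation matrix.

    SparCC is a published third-party algorithm; this package deliberately
    wraps rather than reimplements it.  Configure a backend first with
    :func:`set_sparcc_backend`; an unconfigured adapter raises — it never
    falls back silently to Pearson.
    """
    df = counts.counts if isinstance(counts, CountTable) else counts
    if _SPARCC_BACKEND is None:
        raise SparccNotConfiguredError(
            "no SparCC backend configured; register one with "
            "hampcr.networks.set_sparcc_backend(fn)"
        )
    corr = _SPARCC_BACKEND(df)
    corr = corr.loc[df.index, df.index]
    m = corr.to_numpy(float)
    if np.nanmax(np.abs(m)) > 1 + 1e-9:
        raise ValueError("SparCC backend returned correlations outside [-1, 1]")
    np.fill_diagonal(corr.values, 1.0)
    return CorrelationNetwork(
        matrix=corr,
        node_weights=df.astype(float).median(axis=1),
        threshold=threshold,
        edges=_threshold_edges(corr, threshold),
    )
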