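"""Generative model of host+microbe amplicon experiments.

Every downstream stage in this package is testable offline because this
module can fabricate the whole experiment: template mixtures, per-amplicon
amplification bias, sequencing noise, titration panels, the
pool -> rebarcode-reference -> gel-split -> remix workflow, and raw FASTQ.

Model
-----
A sample holds T_host host template copies and T_i microbial template
copies per taxon i.  Two-cycle template tagging followed by universal
exponential PCR behaves as proportional amplification with a constant
per-amplicon efficiency factor beta (cycle-by-cycle stochasticity is not
modeled; empirically extra tagging cycles do not shift the output
distribution).  The expected read share of entity i is therefore

    p_i = beta_i * T_i / sum_j beta_j * T_j

and observed counts are a multinomial draw of the sample's sequencing
depth from p (optionally Dirichlet-multinomial with concentration omega
for overdispersion).  A deterministic "expectation" mode rounds depth * p
by largest remainder instead of sampling, giving exact oracles that
separate model correctness from sampling error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .demux import IUPAC_SETS, BarcodeTable, PrimerSet
from .tables import HOST_CLASS, AmpliconMap, CountTable, SampleMetadata

__all__ = [
    "SimulationDesign",
    "GroundTruth",
    "Stock",
    "simulate_counts",
    "simulate_titration",
    "simulate_remix",
    "community_design",
    "emit_fastq",
]


@dataclass(frozen=True)
class SimulationDesign:
    """Template copy numbers, efficiencies, depth and noise settings.

    ``host_templates``: per-sample host template copies (index = samples).
    ``microbial_templates``: taxa x samples template copies.
    ``efficiencies``: per-entity amplification factor beta (default 1 for
    entities not listed; the host entity is named by ``host_id``).
    ``depth``: reads per sample (scalar or per-sample Series).
    ``overdispersion``: Dirichlet-multinomial concentration omega, or None
    for plain multinomial sampling.
    """

    host_templates: pd.Series
    microbial_templates: pd.DataFrame
    depth: int | pd.Series = 100_000
    efficiencies: Mapping[str, float] = field(default_factory=dict)
    overdispersion: float | None = None
    seed: int = 0
    host_id: str = "host_GI"
    microbial_class: str = "16S-V4"

    def __post_init__(self) -> None:
        if not self.host_templates.index.equals(self.microbial_templates.columns):
            raise ValueError("host_templates index must equal microbial_templates columns")
        if (self.host_templates < 0).any() or (self.microbial_templates < 0).to_numpy().any():
            raise ValueError("template copy numbers must be non-negative")
        for beta in self.efficiencies.values():
            if beta <= 0:
                raise ValueError("efficiency factors must be positive")
        if self.overdispersion is not None and self.overdispersion <= 0:
            raise ValueError("overdispersion concentration must be positive")
        depths = self.depths
        if (depths < 1).any():
            raise ValueError("depth must be >= 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.host_templates.index)

    @property
    def depths(self) -> pd.Series:
        if isinstance(self.depth, pd.Series):
            return self.depth
        return pd.Series(int(self.depth), index=self.host_templates.index)

    def templates(self) -> pd.DataFrame:
        """Entity x sample template matrix with the host as the last row."""
        return pd.concat(
            [self.microbial_templates, self.host_templates.rename(self.host_id).to_frame().T]
        )

    def expected_fractions(self) -> pd.DataFrame:
        """beta-weighted template shares p_i per sample."""
        t = self.templates()
        betas = pd.Series({e: self.efficiencies.get(e, 1.0) for e in t.index})
        weighted = t.mul(betas, axis=0)
        totals = weighted.sum(axis=0)
        if (totals == 0).any():
            dead = list(totals.index[totals == 0])
            raise ValueError(f"all-zero templates in sample(s): {dead}")
        return weighted.div(totals, axis=1)

    def amplicon_map(self) -> AmpliconMap:
        classes = {t: self.microbial_class for t in self.microbial_templates.index}
        classes[self.host_id] = HOST_CLASS
        return AmpliconMap.from_dict(classes)


@dataclass(frozen=True)
class GroundTruth:
    """What the generator knows: deterministically recomputable from the design."""

    true_loads: pd.DataFrame          # microbial templates / host templates
    expected_fractions: pd.DataFrame  # beta-weighted read shares
    pooled_host_fraction: float       # expected host share of the pooled library
    remix_factor: float | None = None


def _round_largest_remainder(expected: np.ndarray, total: int) -> np.ndarray:
    """Round non-negative reals summing to *total* to integers, preserving the sum."""
    floors = np.floor(expected).astype(np.int64)
    deficit = int(total - floors.sum())
    if deficit > 0:
        order = np.argsort(-(expected - floors))
        floors[order[:deficit]] += 1
    return floors


def _draw_column(rng: np.random.Generator, p: np.ndarray, depth: int,
                 omega: float | None, mode: str) -> np.ndarray:
    if mode == "expectation":
        return _round_largest_remainder(depth * p, depth)
    if omega is not None:
        alpha = omega * p
        live = alpha > 0
        q = np.zeros_like(p)
        q[live] = rng.dirichlet(alpha[live])
        p = q
    return rng.multinomial(depth, p)


def simulate_counts(
    design: SimulationDesign,
    mode: str = "sample",
    rng: np.random.Generator | None = None,
) -> tuple[CountTable, AmpliconMap, GroundTruth]:
    """Draw an ASV x sample count table from the design.

    ``mode="sample"`` draws multinomial (or Dirichlet-multinomial) counts;
    ``mode="expectation"`` deterministically rounds expected counts by
    largest remainder.  The same seed always yields the same table.
    """
    if mode not in {"sample", "expectation"}:
        raise ValueError("mode must be 'sample' or 'expectation'")
    rng = rng if rng is not None else np.random.default_rng(design.seed)
    fractions = design.expected_fractions()
    depths = design.depths
    cols = {
        s: _draw_column(rng, fractions[s].to_numpy(), int(depths[s]),
                        design.overdispersion, mode)
        for s in design.sample_ids
    }
    counts = pd.DataFrame(cols, index=fractions.index)[design.sample_ids]
    table = CountTable(counts)
    with np.errstate(divide="ignore", invalid="ignore"):
        loads = design.microbial_templates.div(
            design.host_templates.where(design.host_templates > 0), axis=1)
    host_row = fractions.loc[design.host_id]
    pooled = float((host_row * depths).sum() / depths.sum())
    truth = GroundTruth(true_loads=loads, expected_fractions=fractions,
                        pooled_host_fraction=pooled)
    return table, design.amplicon_map(), truth


@dataclass(frozen=True)
class Stock:
    """Template composition of one titration component (copies per unit volume)."""

    microbial: pd.Series
    host: float

    def __post_init__(self) -> None:
        if self.host < 0 or (self.microbial < 0).any():
            raise ValueError("template concentrations must be non-negative")


def simulate_titration(
    stock_a: Stock,
    stock_b: Stock,
    ratios: Sequence[tuple[float, float]],
    depth: int = 100_000,
    efficiencies: Mapping[str, float] | None = None,
    overdispersion: float | None = None,
    seed: int = 0,
    mode: str = "sample",
) -> tuple[CountTable, AmpliconMap, GroundTruth]:
    """Simulate a two-stock titration panel (e.g. 0:7, 1:6, ..., 7:0 mixes).

    Per-mix template counts are the volume-weighted sums of the two stocks'
    template concentrations; endpoint mixes reproduce the pure stocks.
    """
    taxa_a, taxa_b = stock_a.microbial, stock_b.microbial
    taxa_a, taxa_b = taxa_a.align(taxa_b, fill_value=0.0)
    samples, host_t, microbe_cols = [], [], {}
    for va, vb in ratios:
        if va < 0 or vb < 0:
            raise ValueError("mixing volumes must be non-negative")
        name = f"mix_{va:g}:{vb:g}"
        samples.append(name)
        host_t.append(va * stock_a.host + vb * stock_b.host)
        microbe_cols[name] = va * taxa_a + vb * taxa_b
    design = SimulationDesign(
        host_templates=pd.Series(host_t, index=samples, dtype=float),
        microbial_templates=pd.DataFrame(microbe_cols),
        depth=depth,
        efficiencies=efficiencies or {},
        overdispersion=overdispersion,
        seed=seed,
    )
    return simulate_counts(design, mode=mode)


def simulate_remix(
    panel: CountTable | pd.DataFrame,
    amap: AmpliconMap,
    target_host_fraction: float,
    reference_depth: int = 100_000,
    seed: int = 0,
    mode: str = "sample",
    reference_id: str = "reference",
) -> tuple[CountTable | pd.DataFrame, SampleMetadata, float]:
    """Emulate pool -> rebarcode reference -> gel split -> remix -> resequence.

    The pooled host share F of *panel* is reduced (or raised) to
    ``target_host_fraction`` t by scaling every host entity's pooled share
    by the single common factor

        lambda = (t / (1 - t)) / (F / (1 - F)).

    A reference sample is drawn from the *unremixed* pooled proportions at
    ``reference_depth`` and appended under ``reference_id``; metadata flags
    it.  In ``mode="sample"`` each remixed sample is redrawn multinomially
    at its original depth from its host-scaled, renormalized proportions.
    In ``mode="expectation"`` host rows are scaled by lambda exactly and
    the reference equals the pooled composition rescaled to
    ``reference_depth`` — both real-valued, so downstream reconstruction
    recovers the original ratios exactly.

    Returns (remixed table incl. reference, metadata, lambda).
    """
    df = panel.counts.astype(float) if isinstance(panel, CountTable) else panel.astype(float)
    if not 0 < target_host_fraction < 1:
        raise ValueError("target_host_fraction must be in (0, 1)")
    if reference_id in df.columns:
        raise ValueError(f"sample id {reference_id!r} already present")
    host_rows = [a for a in df.index if amap.amplicon_class(a) == HOST_CLASS]
    if not host_rows:
        raise ValueError("panel has no host-class rows")
    microbe_rows = [a for a in df.index if a not in set(host_rows)]
    if not microbe_rows:
        raise ValueError("panel has no microbial rows")
    pooled = df.sum(axis=1)
    hp, mp = pooled[host_rows].sum(), pooled[microbe_rows].sum()
    if hp == 0 or mp == 0:
        raise ValueError("pooled library must contain both host and microbial counts")
    current = hp / (hp + mp)
    t = target_host_fraction
    lam = (t / (1 - t)) / (current / (1 - current))

    rng = np.random.default_rng(seed)
    pooled_p = (pooled / pooled.sum()).to_numpy()
    scaled = df.copy()
    scaled.loc[host_rows] *= lam
    if mode == "expectation":
        reference = pooled / pooled.sum() * reference_depth
        out = scaled
        out[reference_id] = reference
    elif mode == "sample":
        depths = df.sum(axis=0)
        cols = {}
        for s in df.columns:
            p = (scaled[s] / scaled[s].sum()).to_numpy()
            cols[s] = rng.multinomial(int(depths[s]), p)
        cols[reference_id] = rng.multinomial(int(reference_depth), pooled_p)
        out = CountTable(pd.DataFrame(cols, index=df.index))
    else:
        raise ValueError("mode must be 'sample' or 'expectation'")
    flags = {s: False for s in df.columns}
    flags[reference_id] = True
    meta = SampleMetadata.from_reference_flags(flags)
    return out, meta, float(lam)


def community_design(
    n_samples: int = 90,
    n_asvs: int = 50,
    pooled_host_fraction: float = 0.22,
    depth: int = 100_000,
    seed: int = 0,
    overdispersion: float | None = None,
    host_fraction_spread: float = 2.0,
) -> SimulationDesign:
    """A realistic leaf-microbiome-like design with a set pooled host share.

    Per-sample microbial compositions are lognormal across ASVs (a few
    dominant taxa, a long tail) and per-sample host shares vary between
    samples (Beta-distributed, spread controlled by
    ``host_fraction_spread``); host templates are then scaled by one global
    factor, solved numerically, so the *expected pooled* host read share
    equals ``pooled_host_fraction`` at equal per-sample depth.
    """
    if not 0 < pooled_host_fraction < 1:
        raise ValueError("pooled_host_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    samples = [f"S{i:03d}" for i in range(1, n_samples + 1)]
    asvs = [f"ASV{i:03d}" for i in range(1, n_asvs + 1)]
    abundance = rng.lognormal(mean=0.0, sigma=1.5, size=(n_asvs, n_samples))
    microbial = pd.DataFrame(abundance, index=asvs, columns=samples)
    microbial = microbial.div(microbial.sum(axis=0), axis=1) * 1e6
    # raw per-sample host shares around the pooled target, then one global
    # rescale of host templates to hit it exactly in expectation
    a = host_fraction_spread
    raw_shares = rng.beta(a, a * (1 - pooled_host_fraction) / pooled_host_fraction,
                          size=n_samples)
    raw_shares = np.clip(raw_shares, 1e-4, 1 - 1e-4)
    m_tot = microbial.sum(axis=0).to_numpy()
    h0 = m_tot * raw_shares / (1 - raw_shares)

    def pooled_share(log_lam: float) -> float:
        lam = np.exp(log_lam)
        return float(np.mean(lam * h0 / (lam * h0 + m_tot)))

    lam = np.exp(optimize.brentq(
        lambda x: pooled_share(x) - pooled_host_fraction, -20, 20))
    host = pd.Series(h0 * lam, index=samples)
    return SimulationDesign(
        host_templates=host,
        microbial_templates=microbial,
        depth=depth,
        overdispersion=overdispersion,
        seed=seed,
    )


def emit_fastq(
    table: CountTable,
    amap: AmpliconMap,
    barcodes: BarcodeTable,
    primers: Mapping[str, PrimerSet],
    inserts: Mapping[str, str],
    seed: int = 0,
    barcode_location: str = "inline",
    primer_mutation_rate: float = 0.0,
) -> tuple[list[tuple[str, str, str]], dict[str, tuple[str, str]]]:
    """Compose one read per count: [barcode +] primer + insert.

    ``primers`` maps amplicon class -> PrimerSet (the forward primer is
    written into the read); ``inserts`` maps ASV -> insert sequence;
    ``barcodes`` must cover every sample (sample -> barcode is the inverse
    of the table).  With ``barcode_location="header"`` the barcode goes
    into the read id's final colon field instead of the sequence.
    ``primer_mutation_rate`` flips the first primer base of that fraction
    of reads (to A<->C), creating ground-truth primer-mismatch reads.

    Returns (records, truth) where truth maps read id -> (sample, asv).
    """
    rng = np.random.default_rng(seed)
    sample_to_bc = {s: b for b, s in barcodes.barcodes.items()}
    missing = [s for s in table.sample_ids if s not in sample_to_bc]
    if missing:
        raise ValueError(f"no barcode for samples: {missing}")
    records: list[tuple[str, str, str]] = []
    truth: dict[str, tuple[str, str]] = {}
    for s in table.sample_ids:
        bc = sample_to_bc[s]
        for asv in table.asv_ids:
            n = int(table.counts.at[asv, s])
            if n == 0:
                continue
            if asv not in inserts:
                raise KeyError(f"no insert sequence for ASV {asv!r}")
            cls = amap.amplicon_class(asv)
            if cls not in primers:
                raise KeyError(f"no primer set for amplicon class {cls!r}")
            fwd = primers[cls].forward
            for i in range(n):
                rid = f"{s}:{asv}:{i}"
                # sequencers see concrete bases: expand degenerate positions
                primer_obs = "".join(
                    b if b in "ACGT" else
                    rng.choice(sorted(IUPAC_SETS[b.upper()]))
                    for b in fwd.upper())
                if primer_mutation_rate and rng.random() < primer_mutation_rate:
                    first = "C" if fwd[0].upper() == "A" else "A"
                    primer_obs = first + fwd[1:]
                body = primer_obs + inserts[asv]
                if barcode_location == "inline":
                    seq = bc + body
                    rid_full = rid
                else:
                    seq = body
                    rid_full = f"{rid}:{bc}"
                records.append((rid_full, seq, "I" * len(seq)))
                truth[rid_full] = (s, asv)
    return records, truth
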