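# Methods

## Model

A sample's DNA extract contains `T_host` template copies of a single- or
low-copy host gene and `T_i` copies of each microbial marker target *i*.
Two-cycle gene-specific tagging followed by universal exponential PCR is
modeled as *proportional amplification*: each amplicon class carries a
constant multiplicative efficiency factor β (default 1), and the expected
read share of entity *i* in a library is

    p_i = β_i · T_i / Σ_j β_j · T_j .

Cycle-by-cycle stochastic amplification is deliberately not modeled:
empirically the tagging-cycle number does not shift the output
distribution, so a per-amplicon constant bias captures what matters (a 1:1
two-template construct read out as 56.5% : 43.5% corresponds to a β ratio
of 0.565/0.435 ≈ 1.30, which the simulator reproduces).  Sequencing is a
multinomial draw of the sample's depth from p, optionally
Dirichlet-multinomial with concentration ω for overdispersion (no default
overdispersion: none is quantified for this assay type; ω is a stress-test
knob).

Microbial load is the plug-in ratio `count_i / host_count` with
`host_count` the sum over all host-class ASVs, each divided by its copy
number (sequence variants of one host amplicon are a single biological
signal; multi-copy host genes are corrected the same way rDNA copy number
is corrected on the microbial side).  No pseudocounts anywhere: zero host
counts give flagged, undefined loads.

## Noise factor

    N(m, h) = (m+1)/(h−1) − (m−1)/(h+1),   h ≥ 2,

with the lower endpoint clamped at 0 when m = 0 (counts cannot be
negative, so N(0, h) = 1/(h−1)); undefined for h ≤ 1.  N is the full width
of the interval of load quotients reachable by a one-read perturbation in
either direction.  It is read as relative uncertainty on the load:
samples with N > 0.22 (default, configurable) are classified
`highly_colonized` and excluded from quantitative statements.  N rises
with load at fixed depth and falls with depth at fixed load;
`min_host_depth_for_load` inverts this by upward scan over integer h
(rounding `m = round(load·h)` makes N not perfectly monotone in h, so
bisection is not safe; the scan is cheap).

## Remix reconstruction

Pooled libraries are often host-heavy.  The workflow: pool, rebarcode an
aliquot as a *reference sample* (preserving the original host:microbe
ratio), gel-separate host from microbial amplicons, remix at a cheap host
fraction, spike the reference back in, sequence.  With h, m the host and
microbial count sums over the remixed samples and H, M over the
reference(s) (multiple references are summed, i.e. count-weighted), the
scaling constant is

    f = (H·m)/(M·h),

the unique global factor such that multiplying every host count by f makes
the pooled corrected host:microbe ratio equal the reference's H:M — the
original ratio.  f is ratio-based, hence invariant to the depth granted to
the reference.  Corrected host counts are real-valued; rounding is left to
the consumer.  One f is computed per sequencing pool (remixing acts on the
pool); per-batch grouping is achieved by calling `summarize` per batch.

The simulator's remix emulation scales every host entity's pooled share by
the single factor λ = (t/(1−t)) / (F/(1−F)) (F = current pooled host
fraction, t = target) and redraws each sample multinomially at its
original depth from the host-scaled, per-sample renormalized proportions;
the reference is drawn from the unremixed pooled proportions.  Because of
per-sample renormalization, f is not exactly 1/λ under sampling — but the
reconstructed pooled host share still equals the reference share by
construction of f, which is the quantity that matters.  A deterministic
expectation mode (largest-remainder rounding for count draws; direct
host-row scaling for the remix) exists so exact-recovery oracles separate
model correctness from sampling error; it produces real-valued frames,
which `summarize`/`reconstruct` accept alongside integer count tables.

## Quantification choices

- Relative abundance with `drop_host=True` removes host-class rows first
  and rescales microbial rows to sum to 1, matching how host+microbe
  libraries are compared against pure marker-gene libraries.
- Replicate fidelity is the squared Pearson correlation of paired
  (typically fourth-root transformed) abundances, plus a two-sample
  two-sided asymptotic Kolmogorov–Smirnov test of the two distributions.
- The minimum-abundance filter defaults to 0.05% with rule `any-sample`
  (keep a row reaching the threshold in at least one sample); a `mean`
  rule is exposed because the per-sample vs mean reading is a genuine
  ambiguity in practice.
- Titration expectations use the ratio of volume-weighted template sums,
  (vA·mA + vB·mB)/(vA·hA + vB·hB), not the weighted mean of the component
  ratios.
- Calibration fits are ordinary least squares on log10–log10 scale
  (robust fits out of scope); nonpositive values are rejected with an
  explicit error rather than pseudocounted, since calibration data
  (CFU, detected loads) are positive where meaningful.

## Demultiplexing

Exact barcode match (9 nt default), no mismatches; IUPAC-aware exact
primer match at the read 5' end, any non-degenerate mismatch discards the
read; barcode and primer are trimmed; qualities pass through.  The barcode
may arrive in the FASTQ header (index read) or as the first read cycles —
instrument-dependent, so it is configuration (`barcode_location`), never
guessed.  Shared-barcode pairs (two samples, distinct primer pairs) are
resolved by forward-primer identity; reads matching both primer sets are
counted as ambiguous and dropped.

## Networks

Pearson correlations across samples, edges kept at |r| ≥ 0.3, node weight
= median abundance.  Untransformed values by default with an optional
transform hook — the appropriate input scale for such networks is
genuinely open, so it is exposed rather than decided.  SparCC is a
published third-party algorithm and is wired in only through
`set_sparcc_backend`; the adapter raises when unconfigured instead of
silently falling back to Pearson.

## Synthetic data: what it does and does not emulate

The generator emulates template mixtures, constant per-amplicon efficiency
bias, multinomial (optionally overdispersed) sequencing noise, volumetric
titration panels, the pool→reference→remix workflow, and read-level FASTQ
structure (barcode + primer with degenerate positions concretized +
insert).  It does **not** emulate: PCR chimeras, index hopping, quality
degradation, primer-binding-site variation among taxa,
amplicon-length-dependent gel co-migration (which physically limits the
remix trick for length-variable ITS amplicons), or taxonomic
misclassification.  Passing tests therefore validate the arithmetic and
statistical machinery under the stated noise model, not robustness to
those artifacts on real libraries.

## Problem sizes and tolerances

Acceptance-style checks use 40–90 simulated samples at depth 10⁵ (the
remix recovery uses 90 samples, pooled host 22% remixed to 2.6%, reference
at depth 10⁵), which gives the pooled host-share estimate a sampling
spread well under one percentage point; replicate and round-trip R²
thresholds (≥ 0.99) follow the assay's demonstrated technical
reproducibility at that depth.  Numeric tie-breaks: largest-remainder
rounding in expectation mode; columns with zero depth yield zero fractions
plus a warning; equality at the N threshold classifies as quantitative
(the rule is strictly "N > threshold").
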