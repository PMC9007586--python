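# Methods

## Model and assumptions

The pipeline treats a proteome as a bag of residue counts. For a peptide
sequence, the composition vector holds the count `N_a` of each of the 20
canonical residues and the fractions `N_a / L_eff`, where `L_eff` is the
count of canonical residues. Non-canonical codes occasionally present in
Ensembl peptide files (X, U, B, Z, O and internal stops) are excluded from
both numerator and denominator and tallied separately; counting U as Cys
was considered and rejected as an unforced assumption. A trailing `*`
(translation stop) is always stripped.

Each gene is represented by a single isoform. The default is the longest
peptide (canonical-residue length), with ties broken by lexicographically
smallest transcript ID so the choice is deterministic; an explicit
canonical map and an all-isoforms mode exist for sensitivity analyses.

The demand model assumes protein synthesis tracks mRNA abundance: the
demand change for residue `a` contributed by gene `g` between two states is
`ΔR(g) · N_a(g)` with `ΔR` the raw abundance difference (not log). The
summary statistic is the percent change relative to the starting state,

    %ΔAA(a) = 100 · Σ_g[(R_to − R_from) N_a] / Σ_g[R_from N_a].

This is deliberately simple — no translation-efficiency, turnover or
codon-level terms — because the claim being tested is only directional:
whether a differentiation program's expression changes, weighted by residue
content, shift demand toward specific amino acids. Genes absent from one
side of the gene-ID merge are counted and reported, never silently dropped;
a residue with a zero denominator is reported as undefined (NaN) rather
than 0, since a silent zero would bias cross-residue comparisons.

## Statistics

- **Set composition**: default aggregation is the unweighted mean of member
  proteins' fraction vectors (each protein counts once regardless of
  length); residue pooling over concatenated member sequences is available
  as an option. The choice matters (a long collagen dominates a pooled
  aggregate) and the mean-of-proteins reading matches how set-level
  "average composition" is usually quoted.
- **Enrichment**: fold = set fraction / background fraction; percent
  increase = 100·(fold − 1). The background is the mean-of-proteins
  composition over all representative proteins.
- **Percentile analysis**: a member's percentile is the mid-rank
  `100·(#strictly below + ½·#ties)/N` against the background of all
  representative proteins; the threshold quantile is the linearly
  interpolated order statistic (position `(N−1)q`, 0-based), and
  "above" means strict exceedance. With distinct values this yields
  `floor(N(1−q))/N` of the background above its own q-quantile.
- **Two-group comparison**: unpaired two-tailed Student's t-test with
  pooled variance (df = n1+n2−2) by default, Welch by option; medians and
  quartiles accompany the test for violin-style summaries. Two constant,
  equal groups are an error; constant unequal groups report p = 0 with a
  warning.
- **Top-N selection**: differential-expression tooling is out of scope, so
  induced/suppressed gene lists are ranked by a deterministic, tool-free
  statistic, by default the pseudocounted log2 fold change
  `log2((R_to+1)/(R_from+1))` (monotone in fold change, defined at zero
  abundance); raw differences are available. Ties break on gene ID.
- **Panel correlation**: Pearson r of log2 fold change against proline
  fraction; p from the t transform with n−2 df; slope/intercept from the
  same least-squares fit. Fold changes are ratio-scaled, hence the log2
  default; the identity transform is kept because published panels do not
  always state their axis scale.

## Synthetic data

The generator emulates the statistical structure the analysis consumes,
not the biology that produces it:

- **Compositions**: each gene has a target composition equal to the mouse
  whole-proteome background (Pro 6.12%) unless it belongs to a designated
  set, in which case the proline entry is shifted by `pro_shift` and the
  rest rescaled to keep unit sum. The realized per-protein composition is
  Dirichlet-distributed about the target with concentration 50 (between-
  protein proline SD ≈ 0.034, comparable to a real proteome's spread).
- **Sequences**: i.i.d. residues at the drawn composition, realized as a
  multinomial count vector followed by a random permutation (identical in
  distribution, much faster). Lengths are uniform on 100–600. Only
  composition is consumed downstream, so no higher-order sequence
  structure (domains, repeats, signal peptides) is modelled — tests passing
  on synthetic data say nothing about, e.g., collagen's Gly-X-Y repeat
  structure, only about the statistics of composition and expression.
- **Expression**: log2-normal baselines (mean 5, SD 2 on the log2 scale,
  FPKM-like); the induced set is multiplied and the suppressed set divided
  by `2^log2_effect` in the second condition, which also carries
  multiplicative log-normal noise (`noise_sd` = 0.25 on the log2 scale, a
  realistic residual for bulk RNA-seq fold changes). Defaults are the study
  conditions: 500 induced genes shifted +0.03 in proline, 500 suppressed,
  `log2_effect` = 1, out of 2,000 genes.
- **Panels**: proline fractions evenly spread over 0.04–0.20 (the range
  spanned by real blot panels), expression ratio `2^(α + β·pro + ε)` with
  defaults α = 0.4, β = −10, ε ~ N(0, 0.3²) — a strong negative
  proline dependence of expression under proline limitation.
- **Ground truth**: the truth object stores memberships, per-gene targets,
  realized representative counts and the noise-free abundances, and
  recomputes the analytic expected %ΔAA through the demand formula itself,
  so recovery tests compare the noisy pipeline against an exact
  expectation.

All randomness flows from one integer seed through separate named streams
(proteome / expression / panel), so every artifact is bit-reproducible.

## Numerical choices and degenerate inputs

- Stable-ID version suffixes (`.N`) are stripped by default on every input
  so gene-ID merges cannot fail on version mismatch; stripping is
  idempotent and can be disabled.
- Matrices are written as TSV with `%.17g` floats, which round-trips
  doubles exactly; reports are JSON with NaN/Inf rejected at write time.
- Empty sequences, wholly non-canonical sequences, empty gene sets,
  negative or non-numeric abundances, duplicate protein or gene IDs, and
  empty merges all raise typed errors naming the offender.
- Problem sizes in the test suite: the brute-force composition oracle runs
  1,000 random sequences; the t-test calibration 10,000 null replicates;
  the parameter-recovery check 100 seeded replicates at the default study
  conditions (2,000 genes each).

## Known limitations

- The demand statistic inherits the proportionality assumption; it is a
  prediction about demand, not a measurement of flux or uptake.
- Mean-of-proteins set composition weights a short and a long protein
  equally; pooled aggregation is provided but the two can disagree.
- The top-N ranking is not a differential-expression test; with few genes
  or heavy noise the lists are unstable even when the planted signal is
  recovered on average.
- Checks against real mouse GRCm38 data require a one-time network fetch
  (`scripts/fetch_ensembl_fixtures.py`); which Ensembl release and GO
  annotation date produced the published values is not recorded there, so
  those fixtures carry their own provenance file and set-level comparisons
  use tolerances wide enough for annotation drift.
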