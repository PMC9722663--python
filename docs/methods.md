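# Methods

## Screen model

The package analyses pooled shRNA screens read out by FACS: a library of
hairpins (one integration per cell, low-MOI design) is sorted by surface
reporter intensity into *low*, *intermediate* and *high* gates at three
time points (t0/t1/t2 ≈ days 3/13/20 of selection), with unsorted pools
kept at t0 and t2. Sequencing the hairpin inserts of each sorted
population turns gate membership into counts; genes whose knockdown moves
cells into the low gate are reporter *enhancers*, into the high gate
*suppressors*.

### Deconvolution

Each mate is trimmed by locating the 5' adapter anywhere within the first
16 bases (stagger regions shift it; ≤1 adapter mismatch), taking the
fixed-length insert that follows. Inserts are matched against the library
by substitution-only Hamming distance with a budget of 3 mismatches — a
deliberate simplification of gapped alignment, exact and deterministic,
appropriate because substitutions dominate Illumina error and the
simulator injects only substitutions. A pigeonhole partition index
(insert split into `max_mismatch + 1` chunks; any sequence within budget
matches one chunk exactly) makes matching fast; a read is *unique* only if
exactly one library sequence lies within the budget, so a second hit
within 3 mismatches voids the read — a conservative implementation of
single-hairpin concordance. A pair increments a hairpin's count only when
read 1 and the reverse-complemented read 2 both match it uniquely. Every
pair lands in exactly one bookkeeping bucket (counted / discordant /
ambiguous / unmatched / untrimmed / barcode-mismatch), and the buckets sum
to the total — checked on every run. Base qualities are ignored;
demultiplexing is by exact barcode at the start of read 2.

### Normalization, filtering, scoring

Counts are normalized per sample as `count / total_reads × n_cells`
(divide by sequencing depth, scale to sorted-cell number). The low-count
filter — raw low+intermediate+high < 100 reads at a time point — is
applied on **raw** counts before scoring, because 100 reads is a
sequencing-depth quantity; applying it after normalization would make the
threshold depend on cell numbers. Enrichment scores are
`log2((low + ψ)/(intermediate + high + ψ))` and the high-bin analogue,
with pseudocount ψ = 0.5 on the normalized scale to keep zeros finite
(ψ = 0 is allowed when all terms are positive). Each time point is scored
independently.

### Gene ranking and significance

A gene's score is its **second-best** hairpin score (descending), so at
least two independent hairpins must agree before a gene can rank highly —
insurance against single-hairpin off-target effects. Genes with fewer than
2 unfiltered hairpins are reported unscored. Ranking ties break
lexicographically by gene symbol for determinism.

Significance: the hairpin→gene assignment is permuted (preserving each
gene's unfiltered hairpin count), second-best scores recomputed, and the
null pooled across genes of equal size:

    p = (1 + #{null ≥ observed}) / (1 + n_perm × m_k)

where `m_k` is the number of genes with the same hairpin count. Pooling
size-matched genes sharpens the null far beyond `1/(n_perm+1)` at no extra
cost; the attainable floor is `1/(1 + n_perm·m_k)`. FDR is
Benjamini–Hochberg across scored genes. Defaults: `n_perm = 1000`
(minimum 10 enforced).

### QC and hit calling

Depletion log2 fold changes (unsorted t2 vs t0, pseudocount shared with
scoring) are aggregated per gene as best (most negative) and second-best;
genes are ranked by second-best depletion and the rank distributions of
the CCE and NE gold-standard sets are each compared to all genes with a
two-sided two-sample Kolmogorov–Smirnov test (raw-LFC mode available).
Exact p-values are reported without flooring.

A gene is called a hit iff significant at t1 **and** t2 but **not** at t0,
with `FDR ≤ 0.25` (or `rank ≤ top_k`) as the significance test; the t0
threshold defaults to the t1/t2 one but is separately configurable, and
outputs always carry full evidence for re-thresholding. The 0.25 default
is a screening-stage threshold: hits are candidates for validation, not
final claims.

### Survival

Expression is averaged over multiple samples of the same patient;
follow-up and event status must be patient-constant. The optimal-cutoff
scan evaluates a two-sided log-rank test (lifelines; Mantel–Haenszel with
the simultaneous-tie convention) at every observed expression value inside
a quantile window (default 20th–80th percentile) whose split leaves at
least 8 patients per arm, returning the argmin cutoff, its p, and the full
scan curve. The minimised p is **selection-biased** — it is the minimum of
many correlated tests — and is flagged as such in every report rather than
corrected, matching the cutpoint-scan convention this mirrors; treat it as
descriptive, not confirmatory.

## Synthetic-screen generator

The generator is the package's test bed and defines its study conditions:

1. **Library** — `n_genes × shrnas_per_gene` hairpins plus nontargeting
   controls; random 21-nt sequences kept at pairwise Hamming distance
   > 2·max_mismatch + 1 by rejection sampling, which makes mismatch-
   tolerant matching provably unambiguous. Gene categories (druggable /
   cancer-driver, 86/14%) mirror the composition of focused druggable +
   driver libraries.
2. **Truth** — genes are enhancer / suppressor / essential / null;
   knockdown efficiency per hairpin ~ Beta(2,2) (no empirical distribution
   is available for such libraries; symmetric, full-support, mean 0.5).
3. **Abundance** — `a_s ∝ exp(−fitness · kd_eff · generations)` for
   essential-gene hairpins (fitness 0.3 per generation per unit
   knockdown), uniform otherwise; passages at 3/13/20 generations
   (≈1 doubling/day over the screen's 20 days).
4. **Reporter** — LogNormal per cell: log-intensity
   `Normal(Δ(s)·onset(t), σ=0.6)` with `Δ(s) = ∓effect·kd_eff(s)` for
   enhancer/suppressor targets (effect size 1.5 on the log scale). The
   **onset factor** (0 at t0, 1 at t1/t2) models the delay between
   integration and a developed knockdown phenotype; without it the day-3
   baseline would already show full phenotypes and the t0-exclusion rule
   would veto every true hit — real screens use the early time point
   precisely because phenotypes have not yet emerged.
5. **Gates** — thresholds are quantiles of the abundance-weighted mixture
   giving the configured fractions (high 1–2%, intermediate 13–15%, drawn
   uniformly per time point; low fixed at 2% since no numeric low-gate
   fraction is part of the design, which gates low against unstained
   cells); per-hairpin gate probabilities are exact Gaussian tail
   integrals, so low+intermediate+high+rest ≡ 1 to 1e-9.
6. **Counts** — Dirichlet-Multinomial per sample: Multinomial over a
   Dirichlet-perturbed bin composition with concentration
   `dispersion × composition` (default 50 000 ⇒ CV ≈ 0.3 at 5 000
   hairpins, typical screen overdispersion), total reads = coverage ×
   library size (1000×). Column sums are exact by construction — a reason
   to prefer Dirichlet-Multinomial over independent negative binomials.
7. **FASTQ** — one multiplexed lane; read 1 = stagger (length cycling
   0–7) + 5' adapter + hairpin + 3' adapter padded to 100 nt, read 2 =
   6-nt sample barcode + stagger + adapter + reverse-complement hairpin;
   substitution errors at 0.1% per base; gzip output with fixed mtime so
   identical runs are byte-identical. The adapters are fixed arbitrary
   12-mers shared by simulator and deconvolver (both configurable) — no
   specific commercial amplicon architecture is reproduced.

What the generator does **not** model: PCR-cycle amplification noise and
chimeras, indel sequencing errors, multiple integrations per cell,
hairpin-specific toxicity outside the essential class, gate spillover /
sorting impurity, and cell-cycle interactions beyond exponential dropout.
Passing tests therefore demonstrate the correctness and statistical
behaviour of the analysis procedure under a faithful but idealised screen,
not robustness to every artifact of real data.

A small survival-cohort generator plants a step hazard (ratio 3 above the
40th expression percentile, exponential event and censoring times) for
cutoff-recovery testing.

## Numerical and testing choices

- Gate thresholds are found by Brent root-finding on the mixture CDF
  (xtol 1e-12); tail probabilities via `scipy.stats.norm` survival
  functions, never `1 − cdf`.
- All randomness flows from a single integer seed through
  `numpy.random.default_rng([seed, stream])` spawns, so stages are
  independently reproducible; TSV floats are written with `%.10g` and
  every output carries a config-hash comment, making whole-pipeline reruns
  byte-identical.
- Matching, second-best aggregation and the KS statistic are each checked
  in the test suite against independent brute-force oracles; the log-rank
  test is checked against hand-worked tables (frozen from an independent
  survival implementation) and a label-permutation reference.
- Test problem sizes are scaled to what the properties need: oracle
  equivalences run on 200-construct libraries and 200-gene tables,
  calibration and recovery properties on screens of 200–1000 genes with
  10–20 seeds, reporting medians across seeds.
- Degenerate inputs: empty gates, zero total reads, missing populations or
  time points, zero events, inconsistent patient follow-up, and truncated
  FASTQ pairs all raise typed validation errors naming the offending
  record.

## Known limitations

- Hamming-only matching undercounts pairs whose errors are indels
  (rare on this platform, but a documented deviation from gapped
  alignment).
- The permutation null treats hairpin scores as exchangeable across genes;
  gene-level covariates (GC content, expression) that structure real
  off-target rates are not modelled.
- The <100-count filter, second-best rule and t0-exclusion are faithful to
  the screening procedure they implement; alternatives (maximum-likelihood
  count models, weighted multi-hairpin aggregation) are out of scope.
- The optimal-cutoff p-value is reported uncorrected (flagged); if a
  confirmatory threshold is needed, pre-register the cutoff or correct for
  the scan.
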