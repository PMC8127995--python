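# Methods

## The biological model

The package models the small-RNA economy of *Drosophila* S2 cells as a set
of species, each split between two Argonaute pools. For species *i* with
baseline abundance *b·i*, Ago1 fraction *f₁* and Ago2 fraction *f₂ = 1 − f₁*:

- Ago1-pool molecules: `b·f₁·(dora_fold if Dora absent else 1)`. The
  `dora_fold ≥ 1` parameter encodes target-directed degradation: a TDD
  substrate is held down by Dora in wild-type cells and rises by that factor
  in its Ago1-loaded pool when Dora is lost.
- Ago2-pool molecules: `b·f₂·(hen1_destab if Hen1 absent else 1)`. Losing
  Hen1 (hence 3′ 2′-O-methylation) destabilizes a subset of siRNAs
  (`hen1_destab ∈ (0,1]`). The Ago2 pool never responds to Dora — that
  asymmetry is the central biological claim the analysis recovers.

Each (pool, genotype) combination carries a multinomial over the eight 3′
isoform categories {mature, N1–N3, T1–T3, other}. Methylated Ago2 cargo has
70% of its tail/trim mass returned to mature; unmethylated Ago2 cargo (in
*hen1* backgrounds) moves an extra 0.15 of mass from mature into tails and
trims; Dora-sensitive species shift 0.08–0.12 (drawn once per species,
uniformly) from mature into T1–T3 in the Ago1 pool of Dora-null genotypes;
*nibbler* suppresses 80% of Ago1-pool trimming.

Library capture weights per pool:

| library | Ago1 weight | Ago2 weight |
|---|---|---|
| total | 1 | 1 |
| periodate | leak | meth + (1 − meth)·leak |
| Ago1 IP | 1 | c |
| Ago2 IP | c | 1 |

with `leak` the probability an unmethylated molecule survives periodate
treatment (default 0.05), `meth` the Ago2-pool methylation rate (1 with
Hen1, 0 without) and `c` the IP cross-pool contamination (default 0.02).
Expected counts are `depth × efficiency ×` the normalized capture mixture,
times a per-(clone, species) log-normal factor (σ = 0.06); observed counts
are Poisson (or a single fixed-depth multinomial when exact per-sample
conservation is wanted). Reads are 4 random nt + insert + 4 random nt +
3′ adaptor with Phred+33 qualities.

A note on monotonicity: raw capture weights are monotone in `leak`, but
normalized expected counts of fully methylated species are not (the mixture
denominator grows). The package therefore exposes the raw weights
(`expected_isoform_weights`) and states invariants on those.

## Default study conditions and why

- **30 miRNAs + 25 siRNAs, 3 clonal lines per genotype, 50k reads per
  library, 5 genotypes × up to 4 library types.** Desk-scale sizes that keep
  a full simulate→quantify→analyze run under a minute while leaving every
  species with enough reads for 3-vs-3 Welch tests.
- **Planted structure.** 8 abundant Ago1-enriched Dora-insensitive miRNAs
  (the designed normalization cohort), 6 Ago2-enriched miRNAs, 5
  Dora-sensitive miRNAs (`dora_fold` 4), 11 low-abundance background
  miRNAs; 7 Dora-sensitive siRNAs, 14 mid-abundance and 4 low-abundance
  insensitive siRNAs spread over hairpin/transposon/cis-NAT loci. Group
  abundances were designed so the planted labels are separable by the
  stated selection rules: Ago2-enriched and sensitive miRNAs get modest
  baselines so they neither dominate the periodate miRNA space (which would
  compress everyone's enrichment ratio toward 1) nor the total libraries;
  background species sit well below the 1000-RPM cohort bound; the
  low-abundance siRNAs sit clearly outside the top-21 dictionary.
- **Clone overdispersion σ = 0.06, efficiency log-uniform over [0.4, 2].**
  The 5× efficiency spread models library-yield differences and is exactly
  what cohort size factors must remove. The residual per-species clone
  effect is kept small relative to the 0.25 log₂FC insensitivity tolerance
  of cohort membership, so that an exact-recovery experiment is
  well-posed; larger clone effects are exercised separately in the
  outlier-filter and calibration tests.
- **`periodate_leak` = 0.05.** Survival of unmethylated species through
  periodate treatment is a free parameter (no measured rate exists); 5%
  reproduces the qualitative observation of slight Ago1-species
  contamination in treated libraries while keeping enrichment ratios
  informative.

## Analysis choices

- **Cohort screening fold-changes are median-centered.** RPM fold-changes
  carry a common compositional offset whenever planted sensitive species
  rise; real experiments anchored total-sRNA scales with quantitative
  spike-in standards, which are out of scope here. Median-centering across
  candidate miRNAs (most of which are unchanged) substitutes for that
  anchor. It affects only cohort screening; reported fold-changes come from
  cohort-normalized Welch tests.
- **"In aggregate unchanged"** is operationalized as per-member |log₂FC| ≤
  0.25 plus iterative trimming of the largest-|log₂FC| member until the
  cohort mean satisfies |mean| ≤ 0.1 — there is no published numeric rule.
- **Sensitivity calls** require BH-adjusted p < 0.05, a positive log₂FC and
  a raw p below the adaptive threshold (the largest cutoff under which every
  call is an increase), mirroring the increases-only rule used for Dora
  sensitivity.
- **The CV-IQR outlier filter** pools all coefficients of variation (rows ×
  the two contrasted genotypes), takes quartiles by linear interpolation
  (the common type-7 rule), and flags rows strictly outside Q1 − 1.5·IQR /
  Q3 + 1.5·IQR; undefined CVs (non-positive means) are flagged as
  degenerate. The differential pipeline does not apply it by default
  (`AnalysisConfig.apply_cv_filter`): with three clones per group the fence
  rule removes a few percent of well-behaved rows by chance, which is the
  filter's job on real outlier clones but makes planted-recovery runs
  needlessly stochastic. It remains available and fully tested.
- **Ties** are resolved deterministically everywhere the source procedure
  was silent: merged dictionary entries take the lexicographically first
  constituent's sequence; mature-isoform ties break toward the longer, then
  lexicographically smaller sequence; top-n siRNA ranking breaks ties
  lexicographically; isoforms of one siRNA are deduplicated by prefix before
  ranking.
- **Differential testing** is a documented Welch-on-logs procedure
  (pseudocount 0.5, cohort size factors, BH across rows) rather than a
  negative-binomial model — a deliberate substitution for heavyweight DE
  machinery, calibrated under the null generator in the test suite.

## Decay fitting

`log y = log(A·e^(−k·t) + B)` is fit by minimizing the sum of squared log
residuals with L-BFGS-B under bounds A ∈ [0.001, 10], k, B ≥ 1e-8 (upper
ends open). Internally the amplitude is optimized on a log scale and the
analytic gradient is supplied, making the B = 0 case an exactly quadratic
problem that agrees with the closed-form log-linear regression to ~1e-13.
The optimization is re-launched up to 100 times, warm-started from the
previous solution, stopping once the parameter vector moves < 1e-10; the
chain makes the result robust to the optimizer's local stopping rule.
Default initialization: A = first observed ratio (clipped to bounds),
B = half the last ratio, k = ln 2 / time span. A rate at its lower bound is
flagged "half-life unbounded above". Reported half-lives are ln(2)/k and
deliberately conflate decay with dilution, as the assay does.

## What the simulation does and does not show

The generator reproduces the *statistical* structure the pipeline assumes:
pool-dependent methylation and survival, planted TDD substrates, clone
overdispersion, efficiency spread, isoform multinomials. It does not model
ligation bias, tail nucleotide composition (tails are uniform ACGU),
precursor/genomic context, sequencing error beyond injected low-quality
bases, or non-Poisson overdispersion at the read-sampling step. Passing
recovery tests therefore demonstrates the pipeline's correctness and
calibration under its own assumptions — not that real S2-cell libraries
satisfy those assumptions, nor the original study's specific numeric
results, which depend on the deposited sequencing data.

## Limitations

- Exact-substring locus assignment cannot place reads with sequencing
  errors or indels; it replaces a genome aligner only for clean inserts.
- The prefix dictionary ignores 3′ variation by construction; two distinct
  species sharing 19 nt are merged and never separable downstream.
- With three clones per genotype, Welch tests have limited power and the
  Satterthwaite df is small; calls on borderline species are sensitive to
  single clones (which is why the CV outlier filter exists).
- The decay model assumes a single exponential plus floor; multi-phase
  decay would bias the reported half-life.
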