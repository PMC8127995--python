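# tddseq

Small-RNA-seq analysis of **target-directed degradation (TDD)** across
*Drosophila* Argonaute pools, built as a reusable, simulation-backed Python
library.

## The scientific problem

In *Drosophila* S2 cells, miRNAs load mostly into Ago1 and endogenous siRNAs
mostly into Ago2, where Hen1 2′-*O*-methylates their 3′ termini. A small RNA
bound to an unusually complementary target can be destroyed by TDD, a decay
pathway that requires the ZSWIM8 ubiquitin-ligase adaptor (Dora in flies).
Dissecting which pool is vulnerable requires a chain of bespoke computations
on small-RNA sequencing libraries:

- **Preprocessing** — 3′ adaptor trimming, removal of the 4 degenerate
  ligation nucleotides on each side, all-bases ≥ Q30 filtering, 18–32 nt size
  selection, 2S-rRNA subtraction.
- **Assignment** — reads string-matched to species dictionaries by their
  first 19 nt (ambiguous species merged, e.g. miR-276a/b → miR-276ab); an
  siRNA dictionary derived from the top 21 locus-mapped sequences in
  periodate-treated wild-type libraries; exact-substring assignment to
  siRNA-generating loci with multi-hit weights 1/m.
- **Isoform profiling** — every read classified relative to the mature
  isoform (most abundant variant in designated reference samples) as mature,
  tailed N1–N3, trimmed T1–T3, or other.
- **Periodate enrichment** — sodium-periodate oxidation/β-elimination
  destroys unmethylated 3′ ends, so the periodate:total abundance ratio
  E estimates Ago2 loading per miRNA.
- **Cohort normalization** — cross-genotype comparisons are scaled by the
  summed counts of a cohort of abundant (mean RPM > 1000), pool-enriched
  (E < 1 or E > 3), Dora-insensitive miRNAs; per-sample size factors are
  cohort sums divided by their geometric mean.
- **Statistics** — Welch two-sample t-tests with BH adjustment, ANOVA +
  Tukey HSD, a CV-IQR (Tukey-fence) clone-outlier filter, the Δ
  Dora-sensitivity metric (log₂FC in Ago1-IP minus log₂FC in total), and the
  trimming-change statistic Σ_T (frac_dora − frac_WT).
- **Decay fitting** — probe:loading-control time courses fit with the
  log-space model `log y = log(A·e^(−k·t) + B)` by chained, bounded
  L-BFGS-B; half-life = ln(2)/k, encapsulating decay plus dilution.

Because the original deposited libraries are not required here, a
first-class **synthetic-data generator** produces populations and libraries
with the full statistical structure the analysis assumes: Ago1/Ago2 loading
fractions, methylation conditional on pool and *hen1* genotype, planted
Dora-sensitive species (fold increase of the Ago1 pool only), genotype- and
pool-dependent tailing/trimming multinomials, periodate survival with a leak
probability, IP cross-pool contamination, three clonal lines per genotype
with log-normal overdispersion, and 4N-flanked FASTQ reads.

## Worked example

`examples/` holds one short script per capability. Fitting a decay course
(`python examples/05_decay_fit.py`):

```
time (h)   miR-7 : miR-11 ratio
     24     0.6689
     32     0.5491
     48     0.3081
     80     0.1424

fitted rate k        = 0.0387 /h
fitted amplitude A   = 1.561
fitted baseline B    = 0.0714
half-life ln(2)/k    = 17.9 h  (simulated: 20 h)
chain converged after 2 warm-started rounds
```

The fitted half-life (17.9 h against a simulated truth of 20 h at 5% noise
on four time points) folds together molecular decay and dilution by cell
division; the baseline B absorbs the endogenous steady-state signal.
`examples/04_differential_and_trimming.py` shows the central recovery: all
twelve planted Dora-sensitive species are flagged in the Ago1-IP contrast
with log₂ fold-changes near +2, and none in the Ago2-IP contrast.

A thin CLI wraps the pipeline stages:

```bash
tddseq simulate --seed 1 --outdir run/sim
tddseq quantify --simdir run/sim --outdir run/quant
tddseq analyze  --quantdir run/quant --sample-sheet run/sim/sample_sheet.tsv --outdir run/an
tddseq decay    --courses courses.tsv --out fits.tsv
```

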