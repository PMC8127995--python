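"""End-to-end orchestration: simulate -> quantify -> analyze (-> decay).

Each stage has a functional core that passes plain Python/pandas objects
(used by the test suite) and a thin file-facing wrapper used by the CLI,
with TSV/FASTA/JSON as the interchange formats.
"""

from __future__ import annotations

import json
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assign as asg
from . import quantify as qn
from . import stats as st
from .constants import DEFAULT_ADAPTER3, ISOFORM_CATEGORIES
from .decay import DecayCourse, fit_decay
from .preprocess import PreprocessConfig, process_fastq
from .simulate import (
    SimConfig,
    build_ground_truth,
    build_loci,
    default_designs,
    simulate_counts,
    simulate_fastq,
    write_truth_tables,
)
from .tables import CountTable, read_sample_sheet, write_counts_tsv, write_sample_sheet

log = logging.getLogger("tddseq")

__all__ = [
    "AnalysisConfig",
    "QuantifyResult",
    "AnalyzeResult",
    "run_simulate",
    "quantify_samples",
    "run_quantify",
    "analyze_counts",
    "run_analyze",
    "run_decay",
]


@dataclass
class AnalysisConfig:
    """Thresholds for cohort selection, filtering, and sensitivity calls."""

    sirna_top_n: int = 21
    e_bounds: tuple[float, float] = (1.0, 3.0)
    cohort_min_rpm: float = 1000.0
    cohort_member_tol: float = 0.25
    cohort_aggregate_tol: float = 0.1
    min_rpm_filter: float = 5.0
    trimming_min_reads: float = 40.0
    alpha: float = 0.05
    apply_cv_filter: bool = False
    pseudocount: float = 0.5


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------

def run_simulate(config: SimConfig, out_dir: str | Path, depth: int = 50_000,
                 low_quality_fraction: float = 0.0,
                 n_contaminant_reads: int = 0) -> dict[str, Path]:
    """Generate ground truth, libraries and FASTQ files under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth = build_ground_truth(config)
    loci = build_loci(truth, config.seed)
    designs = default_designs(config, depth=depth)
    counts = simulate_counts(truth, designs, config)
    sequences = {s.name: s.dna_sequence for s in truth}
    fastq_paths = simulate_fastq(counts, sequences, config, out_dir / "fastq",
                                 low_quality_fraction=low_quality_fraction,
                                 n_contaminant_reads=n_contaminant_reads)

    paths = write_truth_tables(truth, out_dir)
    asg.write_fasta_species([(l.locus_id, l.sequence) for l in loci],
                            out_dir / "loci.fasta")
    manifest = counts.samples.copy()
    manifest["fastq"] = [str(fastq_paths[s]) for s in manifest.index]
    write_sample_sheet(manifest, out_dir / "sample_sheet.tsv")
    write_counts_tsv(counts.counts, out_dir / "isoform_counts_true.tsv")
    paths.update({"sample_sheet": out_dir / "sample_sheet.tsv",
                  "loci": out_dir / "loci.fasta",
                  "isoform_counts_true": out_dir / "isoform_counts_true.tsv"})
    log.info("simulate: %d species, %d samples, seed %d",
             len(truth), len(designs), config.seed)
    return paths


# ---------------------------------------------------------------------------
# quantify
# ---------------------------------------------------------------------------

@dataclass
class QuantifyResult:
    species_counts: CountTable
    isoform_counts: CountTable
    locus_counts: pd.DataFrame
    qc: pd.DataFrame
    mirna_dict: asg.PrefixDictionary
    sirna_dict: list[tuple[str, str]]
    mature: dict[str, str]
    mirna_names: list[str] = field(default_factory=list)
    sirna_names: list[str] = field(default_factory=list)


def _species_seq_counts(kept: Counter, dictionary: asg.PrefixDictionary
                        ) -> dict[str, Counter]:
    """Assign unique inserts to species; returns species -> {insert: reads}."""
    out: dict[str, Counter] = defaultdict(Counter)
    for insert, n in kept.items():
        species = asg.assign_read(insert, dictionary)
        if species is not None:
            out[species][insert] += n
    return out


def quantify_samples(fastq_paths: dict[str, Path], samples: pd.DataFrame,
                     mirna_species: list[tuple[str, str]],
                     loci: list[asg.LocusAnnotation],
                     preproc: PreprocessConfig,
                     config: AnalysisConfig | None = None) -> QuantifyResult:
    """Preprocess and assign every sample; build count tables.

    The miRNA dictionary comes from the mature reference; the siRNA
    dictionary is data-derived from the periodate-treated wild-type samples
    (top-n locus-mapped sequences). Mature isoforms are annotated from the
    wild-type total (miRNA) or wild-type periodate (siRNA) samples, falling
    back to the dictionary representative when those samples are absent.
    """
    config = config or AnalysisConfig()
    kept_by_sample: dict[str, Counter] = {}
    qc_rows = {}
    for sample_id, path in fastq_paths.items():
        kept, stats_ = process_fastq(path, preproc)
        kept_by_sample[sample_id] = kept
        qc_rows[sample_id] = stats_
    qc = pd.DataFrame.from_dict(qc_rows, orient="index")
    qc.index.name = "sample_id"

    mirna_dict = asg.build_prefix_dictionary(mirna_species)

    # siRNA dictionary from periodate-treated wild-type libraries
    ref_ids = [s for s in samples.index
               if samples.at[s, "genotype"] == "WT"
               and samples.at[s, "library_type"] == "periodate"
               and s in kept_by_sample]
    pooled: Counter = Counter()
    for s in ref_ids:
        pooled.update(kept_by_sample[s])
    sirna_dict: list[tuple[str, str]] = []
    if pooled and loci:
        sirna_dict = asg.build_sirna_dictionary(pooled, loci, n=config.sirna_top_n)
    sirna_pdict = (asg.build_prefix_dictionary(sirna_dict)
                   if sirna_dict else asg.PrefixDictionary({}, {}))
    collisions = set(mirna_dict.entries) & set(sirna_pdict.entries)
    if collisions:
        import warnings
        warnings.warn(f"{len(collisions)} 19-nt prefixes shared between the "
                      "miRNA and siRNA dictionaries; reads counted in both")

    # per-sample, per-species sequence-level counts, per dictionary
    per_sample: dict[str, dict[str, Counter]] = {}
    for sample_id, kept in kept_by_sample.items():
        merged: dict[str, Counter] = _species_seq_counts(kept, mirna_dict)
        for species, seqs in _species_seq_counts(kept, sirna_pdict).items():
            merged.setdefault(species, Counter()).update(seqs)
        per_sample[sample_id] = merged

    # mature isoform per species from designated reference samples
    def _pooled_for(names: set[str], library_type: str) -> dict[str, Counter]:
        ids = [s for s in samples.index
               if samples.at[s, "genotype"] == "WT"
               and samples.at[s, "library_type"] == library_type
               and s in per_sample]
        agg: dict[str, Counter] = {n: Counter() for n in names}
        for s in ids:
            for species, seqs in per_sample[s].items():
                if species in names:
                    agg[species].update(seqs)
        return {k: v for k, v in agg.items() if v}

    mirna_names = sorted(set(mirna_dict.entries.values()))
    sirna_names = sorted(set(sirna_pdict.entries.values()))
    mature: dict[str, str] = {}
    mature.update(asg.annotate_mature_isoform(
        _pooled_for(set(mirna_names), "total")))
    mature.update(asg.annotate_mature_isoform(
        _pooled_for(set(sirna_names), "periodate")))
    for name in mirna_names:
        mature.setdefault(name, mirna_dict.representative[name])
    for name in sirna_names:
        mature.setdefault(name, sirna_pdict.representative[name])

    # isoform-resolved table over the full species x category grid
    all_names = mirna_names + sirna_names
    index = pd.MultiIndex.from_product([all_names, list(ISOFORM_CATEGORIES)],
                                       names=["species", "category"])
    sample_ids = list(fastq_paths)
    iso = pd.DataFrame(0.0, index=index, columns=sample_ids)
    for sample_id in sample_ids:
        for species, seqs in per_sample[sample_id].items():
            ref = mature[species]
            for insert, n in seqs.items():
                category = asg.classify_isoform(insert, ref)
                iso.at[(species, category), sample_id] += n

    # locus-space counts via exact substring matching (multi-hit split)
    locus_ids = [l.locus_id for l in loci]
    locus_counts = pd.DataFrame(0.0, index=locus_ids, columns=sample_ids)
    hit_cache: dict[str, list[tuple[str, float]]] = {}
    for sample_id in sample_ids:
        for insert, n in kept_by_sample[sample_id].items():
            hits = hit_cache.get(insert)
            if hits is None:
                hits = asg.assign_to_locus(insert, loci) if len(insert) >= 19 else []
                hit_cache[insert] = hits
            for locus_id, w in hits:
                locus_counts.at[locus_id, sample_id] += w * n

    meta = samples.loc[sample_ids]
    isoform_ct = CountTable(iso, meta)
    species_ct = isoform_ct.species_level()
    return QuantifyResult(species_counts=species_ct, isoform_counts=isoform_ct,
                          locus_counts=locus_counts, qc=qc,
                          mirna_dict=mirna_dict, sirna_dict=sirna_dict,
                          mature=mature, mirna_names=mirna_names,
                          sirna_names=sirna_names)


def run_quantify(sim_dir: str | Path, out_dir: str | Path,
                 preproc: PreprocessConfig | None = None,
                 config: AnalysisConfig | None = None) -> QuantifyResult:
    """File-facing quantify: reads the simulate manifest, writes TSV tables."""
    sim_dir, out_dir = Path(sim_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    preproc = preproc or PreprocessConfig(adapter3=DEFAULT_ADAPTER3)
    manifest = read_sample_sheet(sim_dir / "sample_sheet.tsv")
    fastq_paths = {s: Path(manifest.at[s, "fastq"]) for s in manifest.index}
    mirna_species = asg.read_fasta_species(sim_dir / "mirna_reference.fasta")
    loci_fa = asg.read_fasta_species(sim_dir / "loci.fasta")
    loci = [asg.LocusAnnotation(name, seq, "curated", len(seq))
            for name, seq in loci_fa]
    result = quantify_samples(fastq_paths, manifest, mirna_species, loci,
                              preproc, config)
    write_counts_tsv(result.species_counts.counts, out_dir / "species_counts.tsv")
    write_counts_tsv(result.isoform_counts.counts, out_dir / "isoform_counts.tsv")
    write_counts_tsv(result.locus_counts, out_dir / "locus_counts.tsv")
    result.qc.to_csv(out_dir / "qc_summary.tsv", sep="\t")
    asg.write_fasta_species(result.sirna_dict, out_dir / "sirna_dictionary.fasta")
    merge_rows = [{"merged_name": m, "constituents": ",".join(members),
                   "representative": rep}
                  for m, members, rep in result.mirna_dict.merge_log]
    pd.DataFrame(merge_rows, columns=["merged_name", "constituents",
                                      "representative"]
                 ).to_csv(out_dir / "merge_log.tsv", sep="\t", index=False)
    return result


# ---------------------------------------------------------------------------
# analyze
# ---------------------------------------------------------------------------

@dataclass
class AnalyzeResult:
    enrichment: pd.Series
    cohort_ago1: qn.Cohort
    cohort_ago2: qn.Cohort | None
    de: dict[str, pd.DataFrame]  # library type -> per-species results
    size_factors: dict[str, pd.Series]
    trimming: pd.DataFrame
    delta_sensitivity: pd.Series


#: which cohort normalizes which library type
_COHORT_FOR_LIBRARY = {"total": "ago1", "ago1_ip": "ago1",
                       "periodate": "ago2", "ago2_ip": "ago2"}


def analyze_counts(species: CountTable, isoform: CountTable,
                   mirna_names: list[str],
                   config: AnalysisConfig | None = None,
                   test_genotype: str = "dora",
                   ref_genotype: str = "WT") -> AnalyzeResult:
    """Cohort selection, normalization, differential tests and TDD statistics.

    Enrichment and cohorts are computed from the wild-type total and
    periodate libraries; each library type with clones of both contrast
    genotypes is then tested with the Welch-based differential test,
    normalized to the Ago1 cohort (total, Ago1-IP) or Ago2 cohort
    (periodate, Ago2-IP). Sensitivity calls require BH-adjusted p below
    alpha, a positive log2FC, and a raw p below the adaptive
    "increases-only" threshold.
    """
    config = config or AnalysisConfig()
    counts = species.counts
    samples = species.samples

    wt_total = species.sample_ids(genotype="WT", library_type="total")
    wt_peri = species.sample_ids(genotype="WT", library_type="periodate")
    if not wt_total or not wt_peri:
        raise ValueError("cohort selection needs WT total and WT periodate samples")

    mirna_present = [m for m in mirna_names if m in counts.index]
    total_ms = qn.mirna_space_abundance(counts[wt_total], mirna_present)
    peri_ms = qn.mirna_space_abundance(counts[wt_peri], mirna_present)
    enrichment = qn.ago2_enrichment(total_ms, peri_ms)

    mean_rpm_wt = qn.rpm(counts)[wt_total].mean(axis=1)

    total_ids = species.sample_ids(library_type="total")
    total_rpm = qn.rpm(counts[total_ids])
    dora_lfc = qn.log2_fold_change(
        total_rpm,
        [i for i in total_ids if samples.at[i, "genotype"] == test_genotype],
        [i for i in total_ids if samples.at[i, "genotype"] == ref_genotype],
        pseudocount=config.pseudocount)
    # RPM fold-changes carry a compositional shift when sensitive species
    # rise; median-centering across candidate miRNAs (most of which are
    # unchanged) anchors the screening scale, standing in for the spike-in
    # standards used for total-sRNA libraries. Screening only: reported
    # fold-changes come from the cohort-normalized differential tests.
    dora_lfc = dora_lfc - dora_lfc.reindex(mirna_present).median()

    cohort_ago1 = qn.select_cohort(
        enrichment, mean_rpm_wt, dora_lfc, "ago1_cohort",
        e_bounds=config.e_bounds, min_rpm=config.cohort_min_rpm,
        member_tol=config.cohort_member_tol,
        aggregate_tol=config.cohort_aggregate_tol, candidates=mirna_present)
    try:
        cohort_ago2 = qn.select_cohort(
            enrichment, mean_rpm_wt, dora_lfc, "ago2_cohort",
            e_bounds=config.e_bounds, min_rpm=config.cohort_min_rpm,
            member_tol=config.cohort_member_tol,
            aggregate_tol=config.cohort_aggregate_tol, candidates=mirna_present)
    except ValueError:
        cohort_ago2 = None

    de: dict[str, pd.DataFrame] = {}
    size_factors: dict[str, pd.Series] = {}
    for library in sorted(set(samples["library_type"])):
        sub = species.subset(library_type=library)
        test_ids = sub.sample_ids(genotype=test_genotype)
        ref_ids = sub.sample_ids(genotype=ref_genotype)
        if len(test_ids) < 2 or len(ref_ids) < 2:
            continue
        ids = ref_ids + test_ids
        sub_counts = sub.counts[ids]
        cohort = (cohort_ago2 if _COHORT_FOR_LIBRARY.get(library) == "ago2"
                  and cohort_ago2 is not None else cohort_ago1)
        _, sf = qn.normalize_to_cohort(sub_counts, cohort)
        table = sub_counts
        if config.apply_cv_filter:
            normalized = sub_counts / sf
            table, _flags = st.cv_outlier_filter(
                normalized, sub.samples.loc[ids], [ref_genotype, test_genotype])
            table = sub_counts.loc[table.index]
        res = st.simple_differential_test(table, sf, sub.samples.loc[ids],
                                          test_genotype, ref_genotype,
                                          pseudocount=config.pseudocount)
        threshold = st.sensitivity_threshold(res["p"], res["log2FC"])
        res["sensitive"] = ((res["p_adj"] < config.alpha) & (res["log2FC"] > 0)
                            & (res["p"] < threshold))
        de[library] = res
        size_factors[library] = sf

    # trimming-change statistic on Ago1-IP isoform fractions
    trimming_rows = []
    iso = isoform.counts
    ago1_wt = isoform.sample_ids(genotype=ref_genotype, library_type="ago1_ip")
    ago1_test = isoform.sample_ids(genotype=test_genotype, library_type="ago1_ip")
    if ago1_wt and ago1_test:
        species_names = iso.index.get_level_values(0).unique()
        wt_species_reads = iso[ago1_wt].groupby(level=0).sum().mean(axis=1)
        for name in species_names:
            if wt_species_reads.get(name, 0.0) <= config.trimming_min_reads:
                continue
            frac = {}
            ok = True
            for label, ids in (("wt", ago1_wt), ("test", ago1_test)):
                block = iso.loc[name, ids]
                totals = block.sum(axis=0)
                if (totals <= 0).any():
                    ok = False
                    break
                frac[label] = (block / totals).mean(axis=1).reindex(
                    list(ISOFORM_CATEGORIES)).to_numpy()
                frac[label] = frac[label] / frac[label].sum()
            if not ok:
                continue
            tc = st.trimming_change_statistic(frac["wt"], frac["test"],
                                              species=name)
            trimming_rows.append((name, tc.delta))
    trimming = pd.DataFrame(trimming_rows, columns=["species", "delta"]
                            ).set_index("species")

    # increased Dora sensitivity: Ago1-IP vs total log2 fold-changes
    if "ago1_ip" in de and "total" in de:
        common = de["ago1_ip"].index.intersection(de["total"].index)
        delta_sens = pd.Series(
            {s: st.delta_dora_sensitivity(de["ago1_ip"].at[s, "log2FC"],
                                          de["total"].at[s, "log2FC"])
             for s in common}, dtype=float)
    else:
        delta_sens = pd.Series(dtype=float)

    return AnalyzeResult(enrichment=enrichment, cohort_ago1=cohort_ago1,
                         cohort_ago2=cohort_ago2, de=de,
                         size_factors=size_factors, trimming=trimming,
                         delta_sensitivity=delta_sens)


def run_analyze(quant_dir: str | Path, out_dir: str | Path,
                config: AnalysisConfig | None = None,
                sample_sheet: str | Path | None = None) -> AnalyzeResult:
    """File-facing analyze: reads quantify TSVs, writes results + cohort JSON."""
    from .tables import read_counts_tsv

    quant_dir, out_dir = Path(quant_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = config or AnalysisConfig()
    sheet_path = Path(sample_sheet) if sample_sheet else quant_dir / "sample_sheet.tsv"
    samples = read_sample_sheet(sheet_path)
    species = CountTable(read_counts_tsv(quant_dir / "species_counts.tsv"), samples)
    isoform = CountTable(
        read_counts_tsv(quant_dir / "isoform_counts.tsv", isoform=True), samples)
    mirna_names = [n for n in species.counts.index if not _looks_like_locus(n)]
    result = analyze_counts(species, isoform, mirna_names, config)

    for library, table in result.de.items():
        table.to_csv(out_dir / f"de_{library}.tsv", sep="\t")
        result.size_factors[library].to_csv(
            out_dir / f"size_factors_{library}.tsv", sep="\t")
    result.enrichment.rename("ago2_enrichment").to_csv(
        out_dir / "ago2_enrichment.tsv", sep="\t")
    result.trimming.to_csv(out_dir / "trimming_change.tsv", sep="\t")
    cohorts = {"ago1_cohort": {"members": result.cohort_ago1.members,
                               "criteria": result.cohort_ago1.criteria}}
    if result.cohort_ago2 is not None:
        cohorts["ago2_cohort"] = {"members": result.cohort_ago2.members,
                                  "criteria": result.cohort_ago2.criteria}
    (out_dir / "cohorts.json").write_text(json.dumps(cohorts, indent=2, default=str))
    return result


def _looks_like_locus(name: str) -> bool:
    """siRNA entries are named <locus>_<rank>; miRNAs are not."""
    head = name.rsplit("_", 1)
    return len(head) == 2 and head[1].isdigit()


# ---------------------------------------------------------------------------
# decay
# ---------------------------------------------------------------------------

def run_decay(course_tsv: str | Path, out_path: str | Path | None = None,
              n_chain: int = 100) -> pd.DataFrame:
    """Fit every labelled course in a TSV (time_h, ratio, label)."""
    df = pd.read_csv(course_tsv, sep="\t")
    required = {"time_h", "ratio"}
    if not required <= set(df.columns):
        raise ValueError(f"course TSV must have columns {sorted(required)} "
                         f"(got {list(df.columns)})")
    if "label" not in df.columns:
        df["label"] = ""
    rows = []
    for label, group in df.groupby("label", sort=True):
        group = group.sort_values("time_h")
        course = DecayCourse(group["time_h"].to_numpy(),
                             group["ratio"].to_numpy(), label=str(label))
        fit = fit_decay(course, n_chain=n_chain)
        rows.append({"label": label, "rate_k": fit.rate_k,
                     "amplitude_A": fit.amplitude_A, "baseline_B": fit.baseline_B,
                     "half_life_h": fit.half_life_h, "ssr": fit.ssr,
                     "converged": fit.converged})
    out = pd.DataFrame(rows)
    if out_path is not None:
        out.to_csv(out_path, sep="\t", index=False)
    return out
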