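"""Abundance scaling, enrichment ratios, cohort selection, normalization.

Cross-genotype comparisons of individual small RNAs are normalized to the
summed reads of a *cohort* of miRNAs that are abundant (mean RPM > 1000 in
wild-type total-sRNA libraries), enriched in the relevant Argonaute pool
(periodate:total relative abundance E < 1 for the Ago1 cohort, E > 3 for
the Ago2 cohort), and in aggregate unchanged upon loss of Dora. Per-sample
size factors are the cohort sums divided by their geometric mean, so
normalized counts stay on the raw-count scale and within-sample ratios are
untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Cohort",
    "rpm",
    "mirna_space_abundance",
    "ago2_enrichment",
    "log2_fold_change",
    "select_cohort",
    "normalize_to_cohort",
    "apply_expression_filters",
]


@dataclass
class Cohort:
    """A named normalization cohort and the criteria that selected it."""

    members: list[str]
    role: str  # "ago1_cohort" | "ago2_cohort"
    criteria: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("cohort is empty")
        if self.role not in ("ago1_cohort", "ago2_cohort"):
            raise ValueError(f"unknown cohort role {self.role!r}")


def rpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample column to sum to 1e6 over the table's counting space."""
    sums = counts.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValueError(f"zero column sum for sample(s): {list(zero.index)}")
    return counts * (1e6 / sums)


def mirna_space_abundance(counts: pd.DataFrame,
                          mirna_rows: list[str] | None = None) -> pd.DataFrame:
    """Per-sample fraction of miRNA-mapped reads x 1e6.

    ``mirna_rows`` restricts the table to miRNA species first; the result is
    invariant to any non-miRNA rows present in the input.
    """
    sub = counts.loc[mirna_rows] if mirna_rows is not None else counts
    sums = sub.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValueError(f"no miRNA reads in sample(s): {list(zero.index)}")
    return sub * (1e6 / sums)


def ago2_enrichment(total_abundance: pd.DataFrame,
                    periodate_abundance: pd.DataFrame) -> pd.Series:
    """E(m) = mean periodate abundance / mean total abundance, per miRNA.

    Inputs are miRNA-space abundance tables restricted to the wild-type
    clones of each library type. Species with zero mean in the total
    libraries get NaN (undefined), never infinity. E is scale-invariant in
    the raw counts because both inputs are within-sample normalized.
    """
    if total_abundance.shape[1] == 0 or periodate_abundance.shape[1] == 0:
        raise ValueError("need at least one sample of each library type")
    common = total_abundance.index.intersection(periodate_abundance.index)
    t_mean = total_abundance.loc[common].mean(axis=1)
    p_mean = periodate_abundance.loc[common].mean(axis=1)
    enrichment = p_mean / t_mean
    enrichment[t_mean == 0] = np.nan
    return enrichment


def log2_fold_change(counts: pd.DataFrame, test_samples: list[str],
                     ref_samples: list[str], pseudocount: float = 0.5) -> pd.Series:
    """log2((mean test + pc) / (mean ref + pc)) per row on normalized counts."""
    mt = counts[test_samples].mean(axis=1)
    mr = counts[ref_samples].mean(axis=1)
    return np.log2((mt + pseudocount) / (mr + pseudocount))


def select_cohort(enrichment: pd.Series, mean_rpm_wt_total: pd.Series,
                  dora_log2fc: pd.Series, role: str,
                  e_bounds: tuple[float, float] = (1.0, 3.0),
                  min_rpm: float = 1000.0, member_tol: float = 0.25,
                  aggregate_tol: float = 0.1,
                  candidates: list[str] | None = None) -> Cohort:
    """Select the normalization cohort by enrichment/abundance/insensitivity.

    Members must satisfy E < ``e_bounds[0]`` (ago1_cohort) or E >
    ``e_bounds[1]`` (ago2_cohort), mean wild-type total RPM > ``min_rpm``,
    and |log2FC(dora/WT)| <= ``member_tol``. "In aggregate unchanged" is
    enforced by iteratively dropping the largest-|log2FC| member until
    |mean log2FC| <= ``aggregate_tol``. The result is order-invariant.
    """
    if role not in ("ago1_cohort", "ago2_cohort"):
        raise ValueError(f"unknown cohort role {role!r}")
    index = enrichment.index if candidates is None else pd.Index(candidates)
    index = index.sort_values()
    stage_counts = {"candidates": len(index)}

    e = enrichment.reindex(index)
    if role == "ago1_cohort":
        passing = index[e.notna() & (e < e_bounds[0])]
    else:
        passing = index[e.notna() & (e > e_bounds[1])]
    stage_counts["enrichment"] = len(passing)

    abundant = mean_rpm_wt_total.reindex(passing)
    passing = passing[abundant.notna() & (abundant > min_rpm)]
    stage_counts["abundance"] = len(passing)

    lfc = dora_log2fc.reindex(passing)
    passing = passing[lfc.notna() & (lfc.abs() <= member_tol)]
    stage_counts["insensitivity"] = len(passing)

    members = list(passing)
    lfc = dora_log2fc.reindex(members)
    while members and abs(lfc.loc[members].mean()) > aggregate_tol:
        worst = lfc.loc[members].abs().idxmax()
        members.remove(worst)
    stage_counts["aggregate"] = len(members)

    if not members:
        raise ValueError(f"empty cohort after filtering; survivors per stage: "
                         f"{stage_counts}")
    return Cohort(members=sorted(members), role=role,
                  criteria={"e_bounds": e_bounds, "min_rpm": min_rpm,
                            "member_tol": member_tol,
                            "aggregate_tol": aggregate_tol,
                            "stage_counts": stage_counts})


def normalize_to_cohort(counts: pd.DataFrame,
                        cohort: Cohort | list[str]
                        ) -> tuple[pd.DataFrame, pd.Series]:
    """Divide every count by its sample's cohort-derived size factor.

    Size factor = sum of cohort-member counts in the sample / geometric mean
    of those sums across samples. Works on species-level or isoform-level
    tables (isoform tables sum cohort members over their isoforms).
    """
    members = cohort.members if isinstance(cohort, Cohort) else list(cohort)
    if counts.index.nlevels > 1:
        level0 = counts.index.get_level_values(0)
        cohort_counts = counts[level0.isin(members)]
        present = set(level0)
    else:
        present = set(counts.index)
        cohort_counts = counts.loc[[m for m in members if m in present]]
    missing = [m for m in members if m not in present]
    if missing:
        raise ValueError(f"cohort members absent from table: {missing}")
    sums = cohort_counts.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValueError(f"zero cohort sum in sample(s): {list(zero.index)}")
    size_factors = sums / np.exp(np.log(sums).mean())
    size_factors.name = "size_factor"
    return counts / size_factors, size_factors


def apply_expression_filters(counts: pd.DataFrame, rule: str,
                             samples: pd.DataFrame | None = None,
                             sample_ids: list[str] | None = None,
                             threshold: float | None = None,
                             genotypes: list[str] | None = None,
                             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Row filters mirroring the documented expression cutoffs.

    Rules:

    - ``"min_rpm"``: keep rows with mean RPM > threshold (default 5) across
      ``sample_ids`` (the wild-type samples of the contrast).
    - ``"min_mean_reads"``: keep rows with mean raw reads > threshold
      (default 40) across ``sample_ids``.
    - ``"locus_presence_cv"``: keep rows with >= 1 read in every sample of
      the table and a per-genotype CV < threshold (default 1.0) of the
      RPM/RPKM values across that genotype's clones (CV is invariant to the
      per-kilobase length term). Needs ``samples`` and ``genotypes``.

    Returns (filtered table, removal log with reasons).
    """
    removed: list[tuple[str, str]] = []
    if rule == "min_rpm":
        if sample_ids is None:
            raise ValueError("min_rpm needs sample_ids")
        threshold = 5.0 if threshold is None else threshold
        values = rpm(counts)[sample_ids].mean(axis=1)
        keep = values > threshold
        removed = [(str(r), f"mean RPM {values[r]:.3g} <= {threshold}")
                   for r in counts.index[~keep]]
    elif rule == "min_mean_reads":
        if sample_ids is None:
            raise ValueError("min_mean_reads needs sample_ids")
        threshold = 40.0 if threshold is None else threshold
        values = counts[sample_ids].mean(axis=1)
        keep = values > threshold
        removed = [(str(r), f"mean reads {values[r]:.3g} <= {threshold}")
                   for r in counts.index[~keep]]
    elif rule == "locus_presence_cv":
        if samples is None or genotypes is None:
            raise ValueError("locus_presence_cv needs samples and genotypes")
        threshold = 1.0 if threshold is None else threshold
        keep = (counts >= 1).all(axis=1)
        scaled = rpm(counts)
        for genotype in genotypes:
            ids = list(samples.index[samples["genotype"] == genotype])
            ids = [i for i in ids if i in counts.columns]
            sub = scaled[ids]
            cv = sub.std(axis=1, ddof=1) / sub.mean(axis=1)
            keep &= cv.fillna(np.inf) < threshold
        removed = [(str(r), "absent in some sample or CV >= threshold")
                   for r in counts.index[~keep]]
    else:
        raise ValueError(f"unknown filter rule {rule!r}")
    log = pd.DataFrame(removed, columns=["row", "reason"])
    return counts[keep], log
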