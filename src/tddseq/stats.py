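"""The inferential layer: outlier filtering, tests, and the TDD statistics.

Standard machinery (Welch's t, one-way ANOVA, Tukey HSD, Benjamini-Hochberg)
is delegated to scipy/statsmodels. The analysis-specific statistics are
implemented here: the CV-IQR clone-outlier rule, the Dora-sensitivity
difference (Ago1 vs total log2 fold-changes), the summed trimming-change
statistic, the adaptive "increases-only" significance threshold, and a
Welch-based differential test operating on cohort-normalized log counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .constants import ISOFORM_CATEGORIES

__all__ = [
    "WelchResult",
    "TrimmingChange",
    "cv_outlier_filter",
    "welch_t",
    "anova_tukey",
    "bh_adjust",
    "delta_dora_sensitivity",
    "trimming_change_statistic",
    "sensitivity_threshold",
    "simple_differential_test",
]

_TRIM = [ISOFORM_CATEGORIES.index(c) for c in ("T1", "T2", "T3")]


class WelchResult(NamedTuple):
    t: float
    df: float
    p: float
    flag: str = ""


@dataclass
class TrimmingChange:
    """Summed change in trimmed-isoform fractional abundance (dora - WT)."""

    species: str
    delta: float
    group: str | None = None  # "dora_sensitive" | "dora_insensitive"

    def __post_init__(self) -> None:
        if not (-1.0 - 1e-9 <= self.delta <= 1.0 + 1e-9):
            raise ValueError("trimming delta outside [-1, 1]")


def welch_t(x: Sequence[float], y: Sequence[float]) -> WelchResult:
    """Welch two-sample t-test with Satterthwaite df, two-sided p.

    Degenerate zero-variance cases resolve by convention: equal means give
    p = 1, unequal means give p = 0, both flagged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 values per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return WelchResult(0.0, float(x.size + y.size - 2), 1.0,
                               "zero variance, equal means")
        sign = np.sign(x.mean() - y.mean())
        return WelchResult(float(sign * np.inf), float("nan"), 0.0,
                           "zero variance, unequal means")
    import warnings

    with warnings.catch_warnings():
        # near-identical groups trigger a harmless precision warning upstream
        warnings.simplefilter("ignore", RuntimeWarning)
        res = sps.ttest_ind(x, y, equal_var=False)
    return WelchResult(float(res.statistic), float(res.df), float(res.pvalue))


def anova_tukey(groups: Sequence[Sequence[float]]
                ) -> tuple[float, dict[tuple[int, int], float]]:
    """One-way ANOVA omnibus p plus Tukey-HSD pairwise adjusted p-values.

    Pairwise p-values use the studentized-range distribution and are keyed
    by group index pairs (i, j), i < j.
    """
    if len(groups) < 3:
        raise ValueError("need at least 3 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least 2 values")
    omnibus = float(sps.f_oneway(*arrays).pvalue)
    hsd = sps.tukey_hsd(*arrays)
    pairs = {(i, j): float(hsd.pvalue[i, j])
             for i in range(len(arrays)) for j in range(i + 1, len(arrays))}
    return omnibus, pairs


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def cv_outlier_filter(counts: pd.DataFrame, samples: pd.DataFrame,
                      genotypes: Sequence[str]
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag rows whose clone-level CV is a Tukey-fence outlier.

    Per row and genotype, CV = sd/mean of the normalized values across that
    genotype's clones. All CVs (rows x genotypes of the contrast) are pooled
    and a row is flagged if any of its CVs falls strictly below
    Q1 - 1.5 IQR or above Q3 + 1.5 IQR of the pooled distribution
    (quartiles by linear interpolation). Rows with an undefined CV
    (non-positive mean) are flagged as degenerate.

    Returns (kept table, flag log).
    """
    cv_cols = {}
    for genotype in genotypes:
        ids = list(samples.index[samples["genotype"] == genotype])
        ids = [i for i in ids if i in counts.columns]
        if len(ids) < 2:
            raise ValueError(f"genotype {genotype!r} has fewer than 2 clones")
        sub = counts[ids]
        mean = sub.mean(axis=1)
        cv = sub.std(axis=1, ddof=1) / mean
        cv[mean <= 0] = np.nan
        cv_cols[genotype] = cv
    cv_df = pd.DataFrame(cv_cols)

    pooled = cv_df.to_numpy().ravel()
    finite = pooled[np.isfinite(pooled)]
    if finite.size == 0:
        raise ValueError("no finite CVs to pool")
    q1, q3 = np.percentile(finite, [25, 75])  # linear interpolation (type 7)
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr

    flags = []
    for row in cv_df.index:
        for genotype in genotypes:
            cv = cv_df.at[row, genotype]
            if not np.isfinite(cv):
                flags.append((row, genotype, cv, "degenerate (non-positive mean)"))
            elif cv < lo or cv > hi:
                flags.append((row, genotype, cv, "CV outside Tukey fences"))
    flag_log = pd.DataFrame(flags, columns=["row", "genotype", "cv", "reason"])
    flagged_rows = set(flag_log["row"])
    kept = counts.loc[[r for r in counts.index if r not in flagged_rows]]
    return kept, flag_log


def delta_dora_sensitivity(log2fc_ago1: float, log2fc_total: float) -> float:
    """Increased Dora sensitivity in the Ago1 pool: lfc(Ago1) - lfc(total)."""
    return log2fc_ago1 - log2fc_total


def trimming_change_statistic(fractions_wt: Sequence[float],
                              fractions_dora: Sequence[float],
                              species: str = "",
                              group: str | None = None) -> TrimmingChange:
    """Sum of (dora - WT) fractional-abundance differences over T1-T3.

    Inputs are clone-mean isoform fraction vectors over the eight categories
    for each genotype; each must sum to 1 (+-1e-6).
    """
    fw = np.asarray(fractions_wt, dtype=float)
    fd = np.asarray(fractions_dora, dtype=float)
    for name, vec in (("WT", fw), ("dora", fd)):
        if vec.shape != (len(ISOFORM_CATEGORIES),):
            raise ValueError(f"{name} fractions must have {len(ISOFORM_CATEGORIES)} "
                             "entries")
        if abs(vec.sum() - 1.0) > 1e-6:
            raise ValueError(f"{name} fractions sum to {vec.sum():.8f}, not 1")
    delta = float((fd[_TRIM] - fw[_TRIM]).sum())
    return TrimmingChange(species=species, delta=delta, group=group)


def sensitivity_threshold(p: pd.Series, log2fc: pd.Series) -> float:
    """Largest p cutoff below which every row is an increase.

    Mirrors the rule used when calling Dora sensitivity: the significance
    threshold is the p-value below which only up-regulated species remain.
    Returns the smallest p among non-increasing rows (inf when every row
    increases).
    """
    down = p[log2fc.reindex(p.index) <= 0]
    return float(down.min()) if len(down) else float("inf")


def simple_differential_test(counts: pd.DataFrame, size_factors: pd.Series,
                             samples: pd.DataFrame, test_genotype: str,
                             ref_genotype: str,
                             pseudocount: float = 0.5) -> pd.DataFrame:
    """Welch-based per-row differential test on cohort-normalized log counts.

    Counts are divided by the per-sample size factors, log2-transformed with
    a pseudocount, and compared across genotypes with Welch's t; p-values
    are BH-adjusted across rows. log2FC is the difference of group means of
    the logs (test - reference). Columns: log2FC, t, df, p, p_adj, flag.
    """
    test_ids = [i for i in samples.index[samples["genotype"] == test_genotype]
                if i in counts.columns]
    ref_ids = [i for i in samples.index[samples["genotype"] == ref_genotype]
               if i in counts.columns]
    if len(test_ids) < 2 or len(ref_ids) < 2:
        raise ValueError("need at least 2 clones per genotype")
    normalized = counts / size_factors.reindex(counts.columns)
    logged = np.log2(normalized + pseudocount)

    rows = []
    for row in logged.index:
        x = logged.loc[row, test_ids].to_numpy(dtype=float)
        y = logged.loc[row, ref_ids].to_numpy(dtype=float)
        res = welch_t(x, y)
        rows.append((row, float(x.mean() - y.mean()), res.t, res.df, res.p,
                     res.flag))
    out = pd.DataFrame(rows, columns=["row", "log2FC", "t", "df", "p", "flag"])
    out = out.set_index("row")
    out.index.name = None
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out[["log2FC", "t", "df", "p", "p_adj", "flag"]]
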