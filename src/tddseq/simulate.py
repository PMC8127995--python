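"""Synthetic small-RNA populations, libraries, reads, and decay courses.

The generator emulates the statistical structure the downstream analysis
assumes for *Drosophila* S2 cells:

* a population of miRNAs (mostly Ago1-loaded) and hairpin/transposon/cis-NAT
  siRNAs (mostly Ago2-loaded), each with a baseline abundance and a loading
  split between the two Argonaute pools;
* 2'-O-methylation of Ago2-loaded molecules by Hen1, which governs survival
  of periodate oxidation / beta-elimination (unmethylated molecules survive
  only with a small leak probability);
* target-directed degradation (TDD): Dora-sensitive species carry a
  ``dora_fold`` > 1, the fold increase of their Ago1-loaded pool when Dora
  is absent; the Ago2 pool never responds to Dora;
* tailing/trimming isoform multinomials over {mature, N1-N3, T1-T3, other}
  that shift with pool and genotype (methylation suppresses tailing and
  trimming; loss of Hen1 increases both on the Ago2 pool; loss of Dora
  increases trimming of sensitive species in the Ago1 pool; loss of Nibbler
  suppresses Ago1-pool trimming);
* Argonaute immunoprecipitations with a small cross-pool contamination;
* three clonal lines per genotype with a log-normal clone x species
  overdispersion factor;
* sequencing reads carrying 4 degenerate nucleotides on each side of the
  insert plus a 3' adaptor, with optional low-quality bases and 2S-rRNA
  contaminant reads;
* exponential decay time courses with multiplicative log-normal noise.

All randomness flows from the integer seed in :class:`SimConfig` (or
:class:`DecaySimParams`); identical configuration gives bit-identical output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import (
    DEFAULT_ADAPTER3,
    GENOTYPES,
    HEN1_NULL,
    ISOFORM_CATEGORIES,
    LIBRARY_TYPES,
    POOLS,
    RRNA_2S,
    _check_genotype,
    _check_library_type,
    as_dna,
    lacks_dora,
    lacks_hen1,
)
from .decay import DecayCourse
from .tables import CountTable

__all__ = [
    "SpeciesSpec",
    "SampleDesign",
    "SimConfig",
    "DecaySimParams",
    "build_ground_truth",
    "build_loci",
    "graded_loading_truth",
    "expected_pool_abundance",
    "expected_isoform_weights",
    "simulate_counts",
    "simulate_fastq",
    "simulate_decay_course",
    "default_designs",
    "write_truth_tables",
]

_NT = np.array(list("ACGT"))


def _stream(seed: int, *keys) -> np.random.Generator:
    """Named, reproducible RNG substream derived from the global seed."""
    ints = [seed & 0x7FFFFFFF]
    for key in keys:
        if isinstance(key, str):
            ints.append(zlib.crc32(key.encode()))
        else:
            ints.append(int(key) & 0xFFFFFFFF)
    return np.random.default_rng(ints)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class SpeciesSpec:
    """Ground truth for one small-RNA species.

    ``isoform_probs`` maps (pool, genotype) to a probability vector over the
    eight isoform categories. ``tags`` records the designed role of the
    species (e.g. "ago1_cohort", "dora_sensitive") for recovery tests.
    """

    name: str
    sequence: str  # RNA alphabet, 19-30 nt
    rna_class: str  # "miRNA" | "siRNA"
    baseline_abundance: float
    ago1_fraction: float
    ago2_fraction: float
    dora_fold: float = 1.0
    hen1_destab: float = 1.0
    locus_id: str | None = None
    isoform_probs: dict = field(default_factory=dict)
    tags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not (19 <= len(seq) <= 30):
            raise ValueError(f"{self.name}: sequence length {len(seq)} outside 19-30 nt")
        if set(seq) - set("ACGU") and set(seq) - set("ACGT"):
            raise ValueError(f"{self.name}: sequence not in ACGU/ACGT alphabet")
        if abs(self.ago1_fraction + self.ago2_fraction - 1.0) > 1e-12:
            raise ValueError(f"{self.name}: pool fractions must sum to 1")
        if self.baseline_abundance <= 0:
            raise ValueError(f"{self.name}: baseline abundance must be positive")
        if self.dora_fold < 1:
            raise ValueError(f"{self.name}: dora_fold must be >= 1")
        if not (0 < self.hen1_destab <= 1):
            raise ValueError(f"{self.name}: hen1_destab must be in (0, 1]")
        for key, probs in self.isoform_probs.items():
            probs = np.asarray(probs, dtype=float)
            if probs.shape != (len(ISOFORM_CATEGORIES),):
                raise ValueError(f"{self.name}: isoform vector for {key} has wrong shape")
            if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
                raise ValueError(f"{self.name}: isoform vector for {key} is not a distribution")
            self.isoform_probs[key] = probs

    @property
    def dna_sequence(self) -> str:
        return as_dna(self.sequence)


@dataclass
class SampleDesign:
    """One sequencing library: genotype x library type x clonal line."""

    genotype: str
    library_type: str
    clone_id: str
    depth: int = 50_000
    efficiency: float = 1.0

    def __post_init__(self) -> None:
        _check_genotype(self.genotype)
        _check_library_type(self.library_type)
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.efficiency <= 0:
            raise ValueError("efficiency must be positive")

    @property
    def sample_id(self) -> str:
        return f"{self.genotype}_{self.library_type}_{self.clone_id}"


@dataclass
class SimConfig:
    """Study-level simulation parameters.

    Defaults are the desk-scale study conditions used throughout the test
    suite: 30 miRNAs, 25 siRNAs, a 5% periodate leak, 2% IP cross-pool
    contamination, full Hen1 methylation of the Ago2 pool, and a clone-level
    log-normal sigma of 0.15.
    """

    n_mirna: int = 30
    n_sirna: int = 25
    periodate_leak: float = 0.05
    ip_contamination: float = 0.02
    methylation_rate_ago2: float = 1.0
    overdispersion: float = 0.06
    seed: int = 0
    #: optional explicit (cohort, ago2_enriched, sensitive, background) and
    #: (sensitive, mid, low) group sizes; derived from the totals when None
    mirna_groups: tuple[int, int, int, int] | None = None
    sirna_groups: tuple[int, int, int] | None = None
    dora_fold_sensitive: float = 4.0
    #: trimming mass gained by sensitive species' Ago1 pool upon Dora loss
    trim_gain_range: tuple[float, float] = (0.08, 0.12)
    #: tail+trim mass gained by the Ago2 pool upon Hen1 loss
    hen1_tt_gain: float = 0.15
    force_prefix_collision: bool = False

    def __post_init__(self) -> None:
        for name in ("periodate_leak", "ip_contamination", "methylation_rate_ago2"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_mirna < 0 or self.n_sirna < 0:
            raise ValueError("species counts must be non-negative")
        if self.overdispersion < 0:
            raise ValueError("overdispersion must be non-negative")


@dataclass
class DecaySimParams:
    rate_k: float
    amplitude_A: float
    baseline_B: float = 0.0
    times_h: tuple[float, ...] = (24.0, 32.0, 48.0, 80.0)
    noise_sigma: float = 0.0
    seed: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if self.rate_k <= 0:
            raise ValueError("rate_k must be positive")
        if self.amplitude_A <= 0:
            raise ValueError("amplitude_A must be positive")
        if self.baseline_B < 0:
            raise ValueError("baseline_B must be non-negative")
        times = np.asarray(self.times_h, dtype=float)
        if times.size and (np.diff(times) <= 0).any():
            raise ValueError("times_h must be strictly increasing")


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

def _random_sequences(rng: np.random.Generator, n: int,
                      taken_prefixes: set[str]) -> list[str]:
    """Random 22-24 nt RNA sequences with unique 19-nt prefixes."""
    out: list[str] = []
    while len(out) < n:
        length = int(rng.integers(22, 25))
        seq = "".join(rng.choice(list("ACGU"), size=length))
        if seq[:19] in taken_prefixes:
            continue
        taken_prefixes.add(seq[:19])
        out.append(seq)
    return out


def _base_isoform_profile(rng: np.random.Generator) -> np.ndarray:
    """Baseline isoform multinomial: mostly mature, light 3' heterogeneity."""
    mature = rng.uniform(0.78, 0.88)
    shares = np.array([0.18, 0.08, 0.04, 0.22, 0.12, 0.06, 0.30])  # N1-3, T1-3, other
    shares = shares * rng.uniform(0.7, 1.3, size=7)
    shares /= shares.sum()
    probs = np.empty(8)
    probs[0] = mature
    probs[1:] = (1.0 - mature) * shares
    return probs / probs.sum()


def _pool_genotype_profile(base: np.ndarray, pool: str, genotype: str,
                           sensitive: bool, trim_gain: float,
                           hen1_gain: float) -> np.ndarray:
    p = base.copy()
    if pool == "ago2":
        if genotype in HEN1_NULL:
            # unmethylated Ago2 cargo: increased tailing and trimming
            add = min(hen1_gain, 0.8 * p[0])
            p[0] -= add
            p[1:7] += add * np.array([0.25, 0.10, 0.05, 0.30, 0.20, 0.10])
        else:
            # methylated 3' end protects from tailing and trimming
            moved = 0.7 * p[1:7].sum()
            p[1:7] *= 0.3
            p[0] += moved
    else:  # ago1 pool
        if sensitive and lacks_dora(genotype):
            # TDD substrates accumulate trimmed isoforms without Dora
            add = min(trim_gain, 0.8 * p[0])
            p[0] -= add
            p[4:7] += add * np.array([0.5, 0.3, 0.2])
        if genotype == "nibbler":
            moved = 0.8 * p[4:7].sum()
            p[4:7] *= 0.2
            p[0] += moved
    return p / p.sum()


def _make_species(name, seq, rna_class, rng, baseline, ago1, dora_fold,
                  hen1_destab, locus_id, tags, trim_gain, hen1_gain) -> SpeciesSpec:
    base = _base_isoform_profile(rng)
    sensitive = dora_fold > 1.0
    probs = {
        (pool, genotype): _pool_genotype_profile(base, pool, genotype, sensitive,
                                                 trim_gain, hen1_gain)
        for pool in POOLS for genotype in GENOTYPES
    }
    return SpeciesSpec(
        name=name, sequence=seq, rna_class=rna_class,
        baseline_abundance=baseline, ago1_fraction=ago1, ago2_fraction=1.0 - ago1,
        dora_fold=dora_fold, hen1_destab=hen1_destab, locus_id=locus_id,
        isoform_probs=probs, tags=tags,
    )


def _partition(n: int, fractions: list[float]) -> list[int]:
    """Split n into groups by rounded fractions; remainder to the last group."""
    counts = [int(round(n * f)) for f in fractions[:-1]]
    counts.append(n - sum(counts))
    if counts[-1] < 0:
        raise ValueError("group fractions incompatible with species count")
    return counts


def build_ground_truth(config: SimConfig) -> list[SpeciesSpec]:
    """Generate the designed small-RNA population.

    miRNAs are partitioned into four designed subsets, tagged for recovery
    tests: an abundant Ago1-enriched Dora-insensitive set ("ago1_cohort",
    which seeds cohort selection), an Ago2-enriched set ("ago2_enriched"),
    a Dora-sensitive set ("dora_sensitive") with ``dora_fold`` > 1, and
    low-abundance background. siRNAs are grouped by locus of origin, with a
    Dora-sensitive subset (sensitive only via their small Ago1-loaded pool)
    and a low-abundance tail that keeps them out of the top-ranked siRNA
    dictionary.
    """
    if config.n_mirna + config.n_sirna < 2:
        raise ValueError("need at least 2 species in total")
    rng = _stream(config.seed, "truth")
    taken: set[str] = set()
    species: list[SpeciesSpec] = []

    # --- miRNAs: cohort / ago2-enriched / dora-sensitive / background
    if config.mirna_groups is not None:
        n_cohort, n_ago2, n_sens, n_bg = config.mirna_groups
        if n_cohort + n_ago2 + n_sens + n_bg != config.n_mirna:
            raise ValueError("mirna_groups must sum to n_mirna")
    else:
        n_cohort, n_ago2, n_sens, n_bg = _partition(
            config.n_mirna, [0.27, 0.20, 0.17, 0.36])
    mirna_seqs = _random_sequences(rng, config.n_mirna, taken)
    idx = 0
    for j in range(n_cohort):
        species.append(_make_species(
            f"miR-{idx + 1:03d}", mirna_seqs[idx], "miRNA", rng,
            baseline=rng.uniform(40, 80), ago1=rng.uniform(0.85, 0.95),
            dora_fold=1.0, hen1_destab=1.0, locus_id=None,
            tags=("ago1_cohort",), trim_gain=0.0, hen1_gain=config.hen1_tt_gain))
        idx += 1
    for j in range(n_ago2):
        species.append(_make_species(
            f"miR-{idx + 1:03d}", mirna_seqs[idx], "miRNA", rng,
            baseline=rng.uniform(5, 12), ago1=rng.uniform(0.05, 0.15),
            dora_fold=1.0, hen1_destab=1.0, locus_id=None,
            tags=("ago2_enriched",), trim_gain=0.0, hen1_gain=config.hen1_tt_gain))
        idx += 1
    for j in range(n_sens):
        trim_gain = rng.uniform(*config.trim_gain_range)
        species.append(_make_species(
            f"miR-{idx + 1:03d}", mirna_seqs[idx], "miRNA", rng,
            baseline=rng.uniform(2, 8), ago1=rng.uniform(0.88, 0.95),
            dora_fold=config.dora_fold_sensitive, hen1_destab=1.0, locus_id=None,
            tags=("dora_sensitive",), trim_gain=trim_gain,
            hen1_gain=config.hen1_tt_gain))
        idx += 1
    for j in range(n_bg):
        species.append(_make_species(
            f"miR-{idx + 1:03d}", mirna_seqs[idx], "miRNA", rng,
            baseline=rng.uniform(0.1, 0.5), ago1=rng.uniform(0.3, 0.8),
            dora_fold=1.0, hen1_destab=1.0, locus_id=None,
            tags=("background",), trim_gain=0.0, hen1_gain=config.hen1_tt_gain))
        idx += 1

    # --- siRNAs across hairpin / transposon / cis-NAT loci
    if config.sirna_groups is not None:
        n_s_sens, n_s_mid, n_s_low = config.sirna_groups
        if n_s_sens + n_s_mid + n_s_low != config.n_sirna:
            raise ValueError("sirna_groups must sum to n_sirna")
    else:
        n_s_sens, n_s_mid, n_s_low = _partition(config.n_sirna, [0.28, 0.56, 0.16])
    sirna_seqs = _random_sequences(rng, config.n_sirna, taken)
    locus_plan = (["hairpin_1"] * 3 + ["hairpin_2"] * 2)  # sensitive loci first
    loci_cycle = ["hairpin_1", "hairpin_2", "transposon_1", "transposon_2", "cisnat_1"]
    locus_counter: dict[str, int] = {}

    def next_name(locus: str) -> str:
        locus_counter[locus] = locus_counter.get(locus, 0) + 1
        return f"{locus}_{locus_counter[locus]}"

    sdx = 0
    for j in range(n_s_sens):
        locus = locus_plan[j % len(locus_plan)]
        trim_gain = rng.uniform(*config.trim_gain_range)
        species.append(_make_species(
            next_name(locus), sirna_seqs[sdx], "siRNA", rng,
            baseline=rng.uniform(20, 100), ago1=rng.uniform(0.03, 0.08),
            dora_fold=config.dora_fold_sensitive,
            hen1_destab=rng.uniform(0.3, 0.8), locus_id=locus,
            tags=("dora_sensitive",), trim_gain=trim_gain,
            hen1_gain=config.hen1_tt_gain))
        sdx += 1
    for j in range(n_s_mid):
        locus = loci_cycle[j % len(loci_cycle)]
        destab = rng.uniform(0.3, 0.8) if j % 2 == 0 else 1.0
        species.append(_make_species(
            next_name(locus), sirna_seqs[sdx], "siRNA", rng,
            baseline=rng.uniform(10, 80), ago1=rng.uniform(0.02, 0.10),
            dora_fold=1.0, hen1_destab=destab, locus_id=locus,
            tags=("background",), trim_gain=0.0, hen1_gain=config.hen1_tt_gain))
        sdx += 1
    for j in range(n_s_low):
        locus = loci_cycle[(j + 2) % len(loci_cycle)]
        species.append(_make_species(
            next_name(locus), sirna_seqs[sdx], "siRNA", rng,
            baseline=rng.uniform(0.5, 2.0), ago1=rng.uniform(0.02, 0.10),
            dora_fold=1.0, hen1_destab=1.0, locus_id=locus,
            tags=("background", "low_abundance"), trim_gain=0.0,
            hen1_gain=config.hen1_tt_gain))
        sdx += 1

    if config.force_prefix_collision and len(species) >= 2:
        a, b = species[0], species[1]
        collided = a.sequence[:19] + b.sequence[19:]
        species[1] = replace(b, sequence=collided)
    return species


def graded_loading_truth(n: int, seed: int = 0, baseline: float = 10.0,
                         config: SimConfig | None = None) -> list[SpeciesSpec]:
    """A calibration population with Ago2 loading spread evenly over (0, 1).

    All species share the same baseline abundance and are Dora-insensitive;
    ``ago2_fraction`` runs from 0.02 to 0.98 across the population. Used to
    validate that the periodate:total enrichment ratio tracks true Ago2
    loading.
    """
    config = config or SimConfig(seed=seed)
    rng = _stream(seed, "graded")
    taken: set[str] = set()
    seqs = _random_sequences(rng, n, taken)
    fractions = np.linspace(0.02, 0.98, n)
    return [
        _make_species(
            f"cal-{i + 1:03d}", seqs[i], "miRNA", rng, baseline=baseline,
            ago1=1.0 - float(fractions[i]), dora_fold=1.0, hen1_destab=1.0,
            locus_id=None, tags=("calibration",), trim_gain=0.0,
            hen1_gain=config.hen1_tt_gain)
        for i in range(n)
    ]


def build_loci(truth: list[SpeciesSpec], seed: int = 0) -> list:
    """Synthesize locus sequences embedding each siRNA (see assign.LocusAnnotation)."""
    from .assign import LocusAnnotation

    rng = _stream(seed, "loci")
    groups: dict[str, list[str]] = {}
    for spec in truth:
        if spec.rna_class == "siRNA" and spec.locus_id:
            groups.setdefault(spec.locus_id, []).append(spec.dna_sequence)
    loci = []
    for locus_id in sorted(groups):
        parts = []
        for seq in groups[locus_id]:
            spacer = "".join(rng.choice(list("ACGT"), size=10))
            parts.append(seq + spacer)
        source = ("hairpin" if locus_id.startswith("hairpin")
                  else "transposon" if locus_id.startswith("transposon")
                  else "cis-NAT")
        sequence = "".join(parts)
        loci.append(LocusAnnotation(locus_id=locus_id, sequence=sequence,
                                    source_class=source, length=len(sequence)))
    return loci


# ---------------------------------------------------------------------------
# Expected abundances and count simulation
# ---------------------------------------------------------------------------

def expected_pool_abundance(spec: SpeciesSpec, genotype: str, pool: str) -> float:
    """Expected molecules of a species in one Argonaute pool.

    The Ago1 pool scales with Dora status (x ``dora_fold`` when Dora is
    absent); the Ago2 pool scales with Hen1 status (x ``hen1_destab`` when
    Hen1 is absent) and never responds to Dora.
    """
    if pool not in POOLS:
        raise ValueError(f"unknown pool {pool!r}")
    if pool == "ago1":
        fold = spec.dora_fold if lacks_dora(genotype) else 1.0
        return spec.baseline_abundance * spec.ago1_fraction * fold
    destab = spec.hen1_destab if lacks_hen1(genotype) else 1.0
    return spec.baseline_abundance * spec.ago2_fraction * destab


def _library_pool_weights(library_type: str, genotype: str,
                          config: SimConfig) -> tuple[float, float]:
    """Capture weight applied to (ago1, ago2) pool molecules for a library."""
    if library_type == "total":
        return 1.0, 1.0
    if library_type == "periodate":
        meth = 0.0 if lacks_hen1(genotype) else config.methylation_rate_ago2
        leak = config.periodate_leak
        return leak, meth + (1.0 - meth) * leak
    if library_type == "ago1_ip":
        return 1.0, config.ip_contamination
    if library_type == "ago2_ip":
        return config.ip_contamination, 1.0
    raise ValueError(f"unknown library type {library_type!r}")


def _clone_factor(config: SimConfig, clone_id: str, species: str) -> float:
    if config.overdispersion == 0:
        return 1.0
    rng = _stream(config.seed, "clone", clone_id, species)
    return float(np.exp(config.overdispersion * rng.standard_normal()))


def expected_isoform_weights(truth: list[SpeciesSpec], design: SampleDesign,
                             config: SimConfig) -> pd.Series:
    """Raw expected capture weights per (species, category) for one sample.

    These are molecule-scale expectations before depth scaling and mixture
    normalization; the clone-level log-normal factor is included. Increasing
    ``periodate_leak`` can only increase these weights.
    """
    w1, w2 = _library_pool_weights(design.library_type, design.genotype, config)
    index = pd.MultiIndex.from_product(
        [[s.name for s in truth], list(ISOFORM_CATEGORIES)],
        names=["species", "category"])
    values = np.zeros(len(index))
    for i, spec in enumerate(truth):
        vec = np.zeros(len(ISOFORM_CATEGORIES))
        for pool, w in (("ago1", w1), ("ago2", w2)):
            if w == 0.0:
                continue
            amount = expected_pool_abundance(spec, design.genotype, pool) * w
            vec += amount * spec.isoform_probs[(pool, design.genotype)]
        vec *= _clone_factor(config, design.clone_id, spec.name)
        values[i * len(ISOFORM_CATEGORIES):(i + 1) * len(ISOFORM_CATEGORIES)] = vec
    return pd.Series(values, index=index)


def simulate_counts(truth: list[SpeciesSpec], designs: list[SampleDesign],
                    config: SimConfig, mode: str = "poisson") -> CountTable:
    """Draw an isoform-resolved count table for every designed sample.

    Expected counts are depth x efficiency x the normalized capture mixture;
    counts are Poisson around expectations, or a single multinomial at fixed
    depth when ``mode="multinomial"`` (per-sample totals then equal
    round(depth x efficiency) exactly).
    """
    if not truth:
        raise ValueError("ground truth is empty")
    if not designs:
        raise ValueError("no sample designs given")
    if mode not in ("poisson", "multinomial"):
        raise ValueError(f"unknown count mode {mode!r}")

    columns = {}
    meta_rows = {}
    index = None
    for design in designs:
        weights = expected_isoform_weights(truth, design, config)
        total = weights.to_numpy().sum()
        if total <= 0:
            raise ValueError(f"all-zero expected mixture for sample {design.sample_id}")
        fractions = weights.to_numpy() / total
        n_expected = design.depth * design.efficiency
        rng = _stream(config.seed, "counts", design.sample_id)
        if mode == "poisson":
            counts = rng.poisson(n_expected * fractions)
        else:
            counts = rng.multinomial(int(round(n_expected)), fractions)
        columns[design.sample_id] = counts
        meta_rows[design.sample_id] = {
            "genotype": design.genotype, "library_type": design.library_type,
            "clone_id": design.clone_id, "depth": design.depth,
            "efficiency": design.efficiency,
        }
        index = weights.index
    counts_df = pd.DataFrame(columns, index=index)
    samples = pd.DataFrame.from_dict(meta_rows, orient="index")
    samples.index.name = "sample_id"
    return CountTable(counts_df, samples)


def default_designs(config: SimConfig, depth: int = 50_000,
                    n_clones: int = 3,
                    efficiency_range: tuple[float, float] = (0.4, 2.0)
                    ) -> list[SampleDesign]:
    """The default study design: 5 genotypes x up to 4 library types x 3 clones.

    WT and *dora* get all four library types; *hen1* and *hen1/dora* get
    total and FLAG-Ago2 IP; *nibbler* gets total only. Per-sample capture
    efficiencies are drawn log-uniformly over ``efficiency_range`` (a 5x
    span by default), emulating batch-to-batch library yield differences.
    """
    plan = {
        "WT": ("total", "periodate", "ago1_ip", "ago2_ip"),
        "dora": ("total", "periodate", "ago1_ip", "ago2_ip"),
        "hen1": ("total", "ago2_ip"),
        "hen1_dora": ("total", "ago2_ip"),
        "nibbler": ("total",),
    }
    rng = _stream(config.seed, "designs")
    designs = []
    for genotype, libs in plan.items():
        for clone in range(1, n_clones + 1):
            clone_id = f"{genotype}_c{clone}"
            for lib in libs:
                eff = float(np.exp(rng.uniform(np.log(efficiency_range[0]),
                                               np.log(efficiency_range[1]))))
                designs.append(SampleDesign(genotype=genotype, library_type=lib,
                                            clone_id=clone_id, depth=depth,
                                            efficiency=eff))
    return designs


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

def _realized_isoform(rng: np.random.Generator, mature_dna: str,
                      category: str, n: int) -> list[str]:
    """Concrete insert sequences for ``n`` reads of one isoform category."""
    if category == "mature":
        return [mature_dna] * n
    if category.startswith("T"):
        j = int(category[1])
        return [mature_dna[:-j]] * n
    if category.startswith("N"):
        j = int(category[1])
        tails = _NT[rng.integers(0, 4, size=(n, j))]
        return [mature_dna + "".join(row) for row in tails]
    # "other": same length as mature but a non-matching final nucleotide
    # (a trimmed-then-tailed molecule), keeping the 19-nt prefix intact
    choices = [nt for nt in "ACGT" if nt != mature_dna[-1]]
    picks = rng.integers(0, len(choices), size=n)
    return [mature_dna[:-1] + choices[k] for k in picks]


def simulate_fastq(counts: CountTable, sequences: dict[str, str],
                   config: SimConfig, out_dir: str | Path,
                   adapter3: str = DEFAULT_ADAPTER3,
                   low_quality_fraction: float = 0.0,
                   n_contaminant_reads: int = 0,
                   contaminant_seq: str = RRNA_2S) -> dict[str, Path]:
    """Write one FASTQ (Phred+33) per sample from an isoform count table.

    Each read is 4 random nt + insert (DNA alphabet) + 4 random nt +
    ``adapter3``, with uniformly high qualities. A ``low_quality_fraction``
    of reads get one insert base dropped below Q30, and
    ``n_contaminant_reads`` extra 2S-rRNA reads are appended per sample.
    """
    if not adapter3:
        raise ValueError("adapter3 must be non-empty")
    if counts.counts.index.nlevels != 2:
        raise ValueError("simulate_fastq needs an isoform-resolved count table")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for sample_id in counts.counts.columns:
        rng = _stream(config.seed, "fastq", sample_id)
        col = counts.counts[sample_id]
        inserts: list[str] = []
        for (species, category), n in col.items():
            n = int(n)
            if n == 0:
                continue
            mature = as_dna(sequences[species])
            inserts.extend(_realized_isoform(rng, mature, category, n))
        inserts.extend([as_dna(contaminant_seq)] * int(n_contaminant_reads))

        n_reads = len(inserts)
        flanks = _NT[rng.integers(0, 4, size=(n_reads, 8))]
        low = (rng.random(n_reads) < low_quality_fraction
               if low_quality_fraction > 0 else np.zeros(n_reads, dtype=bool))
        lines: list[str] = []
        for i, insert in enumerate(inserts):
            f = flanks[i]
            seq = ("".join(f[:4]) + insert + "".join(f[4:]) + adapter3)
            qual = "I" * len(seq)  # Q40
            if low[i]:
                pos = 4 + int(rng.integers(0, len(insert)))  # within the insert
                qual = qual[:pos] + "5" + qual[pos + 1:]  # Q20
            lines.append(f"@{sample_id}_{i}\n{seq}\n+\n{qual}")
        path = out_dir / f"{sample_id}.fastq"
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
        paths[sample_id] = path
    return paths


# ---------------------------------------------------------------------------
# Decay courses and truth export
# ---------------------------------------------------------------------------

def simulate_decay_course(params: DecaySimParams) -> DecayCourse:
    """y(t) = (A exp(-k t) + B) * exp(eps), eps ~ N(0, noise_sigma^2)."""
    t = np.asarray(params.times_h, dtype=float)
    clean = params.amplitude_A * np.exp(-params.rate_k * t) + params.baseline_B
    if params.noise_sigma > 0:
        rng = _stream(params.seed, "decay", params.label)
        clean = clean * np.exp(rng.normal(0.0, params.noise_sigma, size=t.size))
    return DecayCourse(times_h=t, ratios=clean, label=params.label)


def write_truth_tables(truth: list[SpeciesSpec], out_dir: str | Path) -> dict[str, Path]:
    """Export ground truth as TSV + reference FASTA files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = [{
        "name": s.name, "sequence": s.sequence, "rna_class": s.rna_class,
        "locus_id": s.locus_id or "", "baseline_abundance": s.baseline_abundance,
        "ago1_fraction": s.ago1_fraction, "ago2_fraction": s.ago2_fraction,
        "dora_fold": s.dora_fold, "hen1_destab": s.hen1_destab,
        "tags": ",".join(s.tags),
    } for s in truth]
    truth_path = out_dir / "ground_truth.tsv"
    pd.DataFrame(rows).to_csv(truth_path, sep="\t", index=False)

    mirna_path = out_dir / "mirna_reference.fasta"
    with open(mirna_path, "w") as fh:
        for s in truth:
            if s.rna_class == "miRNA":
                fh.write(f">{s.name}\n{s.sequence}\n")
    return {"truth": truth_path, "mirna_reference": mirna_path}
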