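"""Raw FASTQ -> clean insert sequences.

The pipeline order is fixed: 3' adaptor removal, degenerate-nucleotide
stripping (4 nt on each side by default), per-base quality filtering (every
base >= Q30, i.e. >99.9% per-base accuracy), then size selection (18-32 nt,
mirroring the gel markers) and contaminant subtraction (2S rRNA). Every read
ends up either kept or rejected with a recorded reason, so kept + rejected
always equals the input read count.

Quality filtering applies to the post-trim insert only; the adaptor's and
degenerate bases' qualities are irrelevant to the insert call.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .constants import RRNA_2S, as_dna

__all__ = [
    "ReadRecord",
    "PreprocessConfig",
    "trim_adapter3",
    "strip_random_nt",
    "quality_filter",
    "length_and_contaminant_filter",
    "preprocess_read",
    "process_fastq",
    "REJECTION_REASONS",
]

REJECTION_REASONS = ("no_adapter", "too_short_to_strip", "low_quality",
                     "length", "contaminant")


@dataclass
class ReadRecord:
    id: str
    sequence: str
    qualities: str  # Phred+33 string, same length as sequence

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(f"{self.id}: sequence/quality length mismatch")


@dataclass
class PreprocessConfig:
    adapter3: str
    n_random_5p: int = 4
    n_random_3p: int = 4
    min_q: int = 30
    min_len: int = 18
    max_len: int = 32
    contaminant_seqs: tuple[str, ...] = (RRNA_2S,)
    min_overlap: int = 6
    max_mismatches: int = 0  # mismatch tolerance for adaptor matching, off by default

    def __post_init__(self) -> None:
        if len(self.adapter3) < self.min_overlap:
            raise ValueError("adapter3 shorter than the minimum overlap")
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")
        if self.min_q < 0:
            raise ValueError("min_q must be >= 0")
        self.contaminant_seqs = tuple(as_dna(s) for s in self.contaminant_seqs)
        self.adapter3 = as_dna(self.adapter3)


def _find_adapter(sequence: str, adapter: str, min_overlap: int,
                  max_mismatches: int) -> int:
    """Start of the leftmost adaptor occurrence, or -1.

    The full adaptor is preferred; failing that, progressively shorter
    prefixes down to ``min_overlap`` handle reads that end inside the
    adaptor (read-through truncation). With ``max_mismatches`` = 1, a
    Hamming-distance-1 scan is tried at each overlap length.
    """
    for k in range(len(adapter), min_overlap - 1, -1):
        probe = adapter[:k]
        # prefixes shorter than the full adaptor can only sit flush at the end
        if k < len(adapter) and len(sequence) - k >= 0:
            if sequence.endswith(probe):
                return len(sequence) - k
            if max_mismatches >= 1:
                tail = sequence[len(sequence) - k:]
                if sum(a != b for a, b in zip(tail, probe)) <= max_mismatches:
                    return len(sequence) - k
            continue
        pos = sequence.find(probe)
        if pos != -1:
            return pos
        if max_mismatches >= 1:
            for start in range(len(sequence) - k + 1):
                window = sequence[start:start + k]
                if sum(a != b for a, b in zip(window, probe)) <= max_mismatches:
                    return start
    return -1


def trim_adapter3(read: ReadRecord, adapter3: str, min_overlap: int = 6,
                  max_mismatches: int = 0) -> ReadRecord | None:
    """Truncate at the 3' adaptor; None when no adaptor is found."""
    pos = _find_adapter(read.sequence, as_dna(adapter3), min_overlap, max_mismatches)
    if pos < 0:
        return None
    return ReadRecord(read.id, read.sequence[:pos], read.qualities[:pos])


def strip_random_nt(read: ReadRecord, n5: int, n3: int) -> ReadRecord | None:
    """Remove the degenerate ligation nucleotides; None if too short."""
    if len(read.sequence) <= n5 + n3:
        return None
    end = len(read.sequence) - n3 if n3 else len(read.sequence)
    return ReadRecord(read.id, read.sequence[n5:end], read.qualities[n5:end])


def quality_filter(read: ReadRecord, min_q: int) -> bool:
    """True iff the read is non-empty and every base has Phred >= min_q."""
    if not read.sequence:
        return False
    return min(read.qualities) >= chr(33 + min_q)


def length_and_contaminant_filter(read: ReadRecord,
                                  config: PreprocessConfig) -> str | None:
    """Rejection reason ("length" / "contaminant"), or None if kept.

    An insert is a contaminant if it is a substring of any contaminant
    sequence: subtractive hybridization removes rRNA fragments regardless of
    which register ligated.
    """
    if not (config.min_len <= len(read.sequence) <= config.max_len):
        return "length"
    for contaminant in config.contaminant_seqs:
        if read.sequence in contaminant:
            return "contaminant"
    return None


def preprocess_read(read: ReadRecord,
                    config: PreprocessConfig) -> tuple[ReadRecord | None, str]:
    """Run one read through the full pipeline; returns (insert, outcome)."""
    trimmed = trim_adapter3(read, config.adapter3, config.min_overlap,
                            config.max_mismatches)
    if trimmed is None:
        return None, "no_adapter"
    stripped = strip_random_nt(trimmed, config.n_random_5p, config.n_random_3p)
    if stripped is None:
        return None, "too_short_to_strip"
    if not quality_filter(stripped, config.min_q):
        return None, "low_quality"
    reason = length_and_contaminant_filter(stripped, config)
    if reason is not None:
        return None, reason
    return stripped, "kept"


def process_fastq(path: str | Path,
                  config: PreprocessConfig) -> tuple[Counter, dict[str, int]]:
    """Preprocess a FASTQ file (optionally gzipped).

    Returns (Counter of kept insert sequences, outcome tally). The tally
    always satisfies sum(outcomes) == input reads. The hot loop inlines the
    per-operation logic for throughput; :func:`preprocess_read` is the
    reference semantics and the two are tested for agreement.
    """
    path = Path(path)
    stats: dict[str, int] = {"kept": 0, **{r: 0 for r in REJECTION_REASONS}}
    kept: Counter = Counter()

    adapter = config.adapter3
    n5, n3 = config.n_random_5p, config.n_random_3p
    min_char = chr(33 + config.min_q)
    min_len, max_len = config.min_len, config.max_len
    contaminants = config.contaminant_seqs
    simple = config.max_mismatches == 0

    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        for _id, seq, qual in FastqGeneralIterator(handle):
            pos = seq.find(adapter) if simple else -1
            if pos == -1:
                pos = _find_adapter(seq, adapter, config.min_overlap,
                                    config.max_mismatches)
            if pos < 0:
                stats["no_adapter"] += 1
                continue
            if pos <= n5 + n3:
                stats["too_short_to_strip"] += 1
                continue
            insert = seq[n5:pos - n3]
            q = qual[n5:pos - n3]
            if not insert or min(q) < min_char:
                stats["low_quality"] += 1
                continue
            if not (min_len <= len(insert) <= max_len):
                stats["length"] += 1
                continue
            if any(insert in c for c in contaminants):
                stats["contaminant"] += 1
                continue
            stats["kept"] += 1
            kept[insert] += 1
    return kept, stats
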