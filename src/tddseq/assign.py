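"""Species dictionaries, 19-nt prefix read assignment, and isoform calls.

Reads are assigned by exact string-matching of their first 19 nt against a
dictionary of mature small-RNA sequences; species whose mature sequences
cannot be distinguished by 19 nt collapse into one merged entry (e.g.
miR-276a-5p + miR-276b-5p -> miR-276ab-5p). Inserts shorter than 19 nt are
never assigned. Tailing/trimming isoforms are called relative to the mature
isoform: N1-N3 for 1-3 extra 3' nucleotides, T1-T3 for 1-3 fewer, anything
else (including trim-then-tail combinations) is "other".

Locus assignment replaces a genome aligner with an exact substring search of
the insert (and its reverse complement) against curated locus sequences,
splitting multi-mapping reads evenly across matching loci.
"""

from __future__ import annotations

import os
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

from .constants import as_dna, reverse_complement

__all__ = [
    "PrefixDictionary",
    "LocusAnnotation",
    "build_prefix_dictionary",
    "assign_read",
    "build_sirna_dictionary",
    "classify_isoform",
    "annotate_mature_isoform",
    "assign_to_locus",
    "read_fasta_species",
    "write_fasta_species",
    "PREFIX_LENGTH",
]

PREFIX_LENGTH = 19


@dataclass
class PrefixDictionary:
    """19-nt prefix -> species name, with a log of any merged entries."""

    entries: dict[str, str]
    representative: dict[str, str]  # entry name -> representative mature sequence
    merge_log: list[tuple[str, tuple[str, ...], str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for prefix in self.entries:
            if len(prefix) != PREFIX_LENGTH:
                raise ValueError(f"prefix {prefix!r} is not {PREFIX_LENGTH} nt")


@dataclass
class LocusAnnotation:
    """A curated siRNA-generating genomic region (hairpin/transposon/cis-NAT)."""

    locus_id: str
    sequence: str
    source_class: str
    length: int

    def __post_init__(self) -> None:
        self.sequence = as_dna(self.sequence)
        if len(self.sequence) < PREFIX_LENGTH:
            raise ValueError(f"locus {self.locus_id}: sequence shorter than "
                             f"{PREFIX_LENGTH} nt")


def _merged_name(names: Iterable[str]) -> str:
    """Deterministic merged name for prefix-colliding species.

    Names differing only by a single letter on a shared stem concatenate
    those letters (276a-5p + 276b-5p -> 276ab-5p); otherwise the sorted
    names are joined with "/".
    """
    names = sorted(names)
    prefix = os.path.commonprefix(names)
    suffix = os.path.commonprefix([n[::-1] for n in names])[::-1]
    mids = []
    for n in names:
        mid_end = len(n) - len(suffix)
        if mid_end < len(prefix):
            return "/".join(names)
        mids.append(n[len(prefix):mid_end])
    if all(len(m) == 1 and m.isalpha() for m in mids):
        return prefix + "".join(mids) + suffix
    return "/".join(names)


def build_prefix_dictionary(species: list[tuple[str, str]]) -> PrefixDictionary:
    """Build the 19-nt prefix dictionary, collapsing ambiguous species.

    The representative sequence of a merged entry is that of the
    lexicographically first constituent name (a deterministic stand-in for
    an arbitrary choice).
    """
    groups: dict[str, list[tuple[str, str]]] = defaultdict(list)
    seen_names = set()
    for name, seq in species:
        if name in seen_names:
            raise ValueError(f"duplicate species name {name!r}")
        seen_names.add(name)
        seq = as_dna(seq)
        if len(seq) < PREFIX_LENGTH:
            raise ValueError(f"species {name!r}: sequence shorter than "
                             f"{PREFIX_LENGTH} nt")
        groups[seq[:PREFIX_LENGTH]].append((name, seq))

    entries: dict[str, str] = {}
    representative: dict[str, str] = {}
    merge_log: list[tuple[str, tuple[str, ...], str]] = []
    for prefix, members in groups.items():
        if len(members) == 1:
            name, seq = members[0]
            entries[prefix] = name
            representative[name] = seq
        else:
            members = sorted(members)
            merged = _merged_name([m[0] for m in members])
            rep_seq = members[0][1]
            entries[prefix] = merged
            representative[merged] = rep_seq
            merge_log.append((merged, tuple(m[0] for m in members), rep_seq))
    return PrefixDictionary(entries=entries, representative=representative,
                            merge_log=merge_log)


def assign_read(insert: str, dictionary: PrefixDictionary) -> str | None:
    """Species entry whose 19-nt prefix equals insert[:19]; None if unassigned."""
    if len(insert) < PREFIX_LENGTH:
        return None
    return dictionary.entries.get(insert[:PREFIX_LENGTH])


def assign_to_locus(insert: str,
                    loci: list[LocusAnnotation]) -> list[tuple[str, float]]:
    """Exact-substring locus hits (either strand), multi-hit weight 1/m."""
    insert = as_dna(insert)
    rc = reverse_complement(insert)
    hits = [loc.locus_id for loc in loci
            if insert in loc.sequence or rc in loc.sequence]
    if not hits:
        return []
    w = 1.0 / len(hits)
    return [(locus_id, w) for locus_id in hits]


def build_sirna_dictionary(counts: Mapping[str, float],
                           loci: list[LocusAnnotation],
                           n: int = 21) -> list[tuple[str, str]]:
    """Top-``n`` locus-mapped sequences from reference (periodate WT) samples.

    ``counts`` maps insert sequence -> summed reads across the reference
    samples. Sequences are first deduplicated by 19-nt prefix (keeping the
    most-read sequence per prefix, so isoforms of one siRNA occupy one
    slot), then ranked by read count with lexicographic tie-breaking.
    Entries are named ``<locus_id>_<rank>`` with ranks assigned per locus in
    descending abundance.
    """
    import warnings

    mapped: list[tuple[str, float, str]] = []
    for seq, count in counts.items():
        seq = as_dna(seq)
        if len(seq) < PREFIX_LENGTH:
            continue
        hits = assign_to_locus(seq, loci)
        if not hits:
            continue
        locus = sorted(hits, key=lambda h: (-h[1], h[0]))[0][0]
        mapped.append((seq, float(count), locus))

    by_prefix: dict[str, tuple[str, float, str]] = {}
    for seq, count, locus in mapped:
        prev = by_prefix.get(seq[:PREFIX_LENGTH])
        if prev is None or (count, seq) > (prev[1], prev[0]):
            by_prefix[seq[:PREFIX_LENGTH]] = (seq, count, locus)

    ranked = sorted(by_prefix.values(), key=lambda x: (-x[1], x[0]))
    if len(ranked) < n:
        warnings.warn(f"only {len(ranked)} distinct locus-mapped sequences "
                      f"available (requested {n})")
    chosen = ranked[:n]
    per_locus: dict[str, int] = defaultdict(int)
    out = []
    for seq, _count, locus in chosen:
        per_locus[locus] += 1
        out.append((f"{locus}_{per_locus[locus]}", seq))
    return out


def classify_isoform(insert: str, mature: str) -> str:
    """Isoform category of an insert relative to the mature sequence.

    Pure function of (insert, mature): "mature" for an exact match, "Nj"
    for mature plus j extra 3' nucleotides (j <= 3), "Tj" for mature minus
    j nucleotides (j <= 3, insert still >= 19 nt), otherwise "other".
    Raises if the two do not share a 19-nt prefix (a caller bug).
    """
    insert, mature = as_dna(insert), as_dna(mature)
    if len(insert) < PREFIX_LENGTH:
        raise ValueError("insert shorter than the 19-nt prefix")
    if insert[:PREFIX_LENGTH] != mature[:PREFIX_LENGTH]:
        raise ValueError("insert does not share the species' 19-nt prefix")
    if insert == mature:
        return "mature"
    d = len(insert) - len(mature)
    if 1 <= d <= 3 and insert.startswith(mature):
        return f"N{d}"
    if 1 <= -d <= 3 and mature.startswith(insert):
        return f"T{-d}"
    return "other"


def annotate_mature_isoform(seq_counts: Mapping[str, Mapping[str, float]],
                            ) -> dict[str, str]:
    """Most abundant isoform per species across designated reference samples.

    ``seq_counts`` maps species -> {insert sequence: summed reads over the
    reference samples}. Ties break toward the longer sequence, then
    lexicographically smaller.
    """
    mature: dict[str, str] = {}
    missing = []
    for species, per_seq in seq_counts.items():
        if not per_seq:
            missing.append(species)
            continue
        best = min(per_seq.items(), key=lambda kv: (-kv[1], -len(kv[0]), kv[0]))
        mature[species] = best[0]
    if missing:
        raise ValueError(f"species absent from reference samples: {missing}")
    return mature


def read_fasta_species(path: str | Path) -> list[tuple[str, str]]:
    """(name, sequence) pairs from a miRBase-style FASTA."""
    records = SeqIO.parse(str(path), "fasta")
    return [(rec.id, str(rec.seq)) for rec in records]


def write_fasta_species(species: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in species:
            fh.write(f">{name}\n{seq}\n")
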