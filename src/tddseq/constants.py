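"""Shared vocabulary for the small-RNA analysis.

Genotypes follow the *Drosophila* S2-cell crosses analysed throughout the
package: wild type, *dora* (the fly ZSWIM8 homolog required for
target-directed degradation), *hen1* (the 2'-O-methyltransferase acting on
Ago2-loaded small RNAs), the double knockout, and *nibbler* (the 3'-5'
exonuclease that trims Ago1-loaded miRNAs).
"""

from __future__ import annotations

GENOTYPES = ("WT", "dora", "hen1", "hen1_dora", "nibbler")
LIBRARY_TYPES = ("total", "periodate", "ago1_ip", "ago2_ip")
POOLS = ("ago1", "ago2")

#: 3' isoform categories relative to the mature sequence: exact, tailed by
#: 1-3 untemplated nucleotides, trimmed by 1-3 nucleotides, anything else.
ISOFORM_CATEGORIES = ("mature", "N1", "N2", "N3", "T1", "T2", "T3", "other")

#: Genotypes lacking functional Dora (TDD-deficient).
DORA_NULL = frozenset({"dora", "hen1_dora"})
#: Genotypes lacking functional Hen1 (no 2'-O-methylation of Ago2 cargo).
HEN1_NULL = frozenset({"hen1", "hen1_dora"})

#: Drosophila melanogaster 2S rRNA (30 nt), the dominant small-RNA-sized
#: contaminant removed by subtractive hybridization during library prep.
RRNA_2S = "TGCTTGGACTACATATGGTTGAGGGTTGTA"

#: Default 3' sequencing adaptor used by the simulator and preprocessor.
DEFAULT_ADAPTER3 = "TGGAATTCTCGGGTGCCAAGG"

_RNA_TO_DNA = str.maketrans("Uu", "Tt")
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def as_dna(sequence: str) -> str:
    """Uppercase and map U->T so RNA and DNA spellings compare equal."""
    return sequence.translate(_RNA_TO_DNA).upper()


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def lacks_dora(genotype: str) -> bool:
    _check_genotype(genotype)
    return genotype in DORA_NULL


def lacks_hen1(genotype: str) -> bool:
    _check_genotype(genotype)
    return genotype in HEN1_NULL


def _check_genotype(genotype: str) -> None:
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}; expected one of {GENOTYPES}")


def _check_library_type(library_type: str) -> None:
    if library_type not in LIBRARY_TYPES:
        raise ValueError(
            f"unknown library type {library_type!r}; expected one of {LIBRARY_TYPES}"
        )
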