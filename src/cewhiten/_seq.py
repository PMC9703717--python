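"""Small sequence helpers shared across modules.

DNA and RNA are compared with T and U equivalent; sequences are stored as
given (the genome side is DNA, mature miRNAs are RNA).
"""

from __future__ import annotations

_DNA_ALPHABET = frozenset("ACGTN")
_RNA_ALPHABET = frozenset("ACGUN")

_COMPLEMENT = str.maketrans("ACGTUN", "TGCAAN")


def revcomp(seq: str) -> str:
    """Reverse complement; U complements to A, output is DNA-alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def to_dna(seq: str) -> str:
    """Map RNA to DNA alphabet (U -> T) for T/U-equivalent comparison."""
    return seq.replace("U", "T").replace("u", "t")


def to_rna(seq: str) -> str:
    return seq.replace("T", "U").replace("t", "u")


def is_dna(seq: str) -> bool:
    return set(seq) <= _DNA_ALPHABET


def is_rna(seq: str) -> bool:
    return set(seq) <= _RNA_ALPHABET


def validate_alphabet(seq: str, record_id: str) -> None:
    """Accept DNA or RNA (not mixed T+U); raise naming the record otherwise."""
    s = set(seq)
    if not (s <= _DNA_ALPHABET or s <= _RNA_ALPHABET):
        bad = sorted(s - (_DNA_ALPHABET | _RNA_ALPHABET)) or ["mixed T/U"]
        raise ValueError(
            f"record {record_id!r}: invalid characters {bad} "
            "(allowed: ACGTN for DNA, ACGUN for RNA)"
        )
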