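"""Shared helpers: sequence alphabet handling, half-up rounding, FASTA/FASTQ I/O."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA/RNA string (result is DNA-spelled)."""
    return seq.translate(_COMPLEMENT)[::-1]


def to_dna(seq: str) -> str:
    """Uppercase and spell with T (U -> T)."""
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    """Uppercase and spell with U (T -> U)."""
    return seq.upper().replace("T", "U")


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, as tables are conventionally printed.

    Python's built-in round() is banker's rounding; table percentages such as
    94.645 -> 94.65 require half-up.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: int, denominator: int, ndigits: int = 2) -> float:
    """Exact half-up percentage of two integer counts."""
    if denominator == 0:
        raise ZeroDivisionError("percentage denominator is zero")
    f = Fraction(numerator, denominator) * 100
    return _round_fraction_half_up(f, ndigits)


def ratio(numerator: int, denominator: int, ndigits: int = 2) -> float:
    """Exact half-up ratio of two integer counts."""
    if denominator == 0:
        raise ZeroDivisionError("ratio denominator is zero")
    return _round_fraction_half_up(Fraction(numerator, denominator), ndigits)


def _round_fraction_half_up(f: Fraction, ndigits: int) -> float:
    scale = 10**ndigits
    sign = 1 if f >= 0 else -1
    shifted = abs(f) * scale + Fraction(1, 2)
    return sign * (shifted.numerator // shifted.denominator) / scale


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: uppercase sequence} mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    # SeqIO wraps at 60 by default; width kept for signature stability.


def iter_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (title, sequence, quality) tuples from a Phred+33 FASTQ file."""
    with open(path) as fh:
        yield from FastqGeneralIterator(fh)


def write_fastq(records: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for title, seq, qual in records:
            fh.write(f"@{title}\n{seq}\n+\n{qual}\n")


def mean_phred(qual: str) -> float:
    if not qual:
        return 0.0
    return sum(ord(c) - 33 for c in qual) / len(qual)
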