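"""Raw-read cleaning, tag collapsing and two-library composition summaries.

Small-RNA reads are sequenced through the insert into the 3' adapter.  Cleaning
recovers the insert and discards technical artifacts in a fixed rule order so
that every high-quality read lands in exactly one removal category or in the
clean set, mirroring how sRNA-library cleaning tables are conventionally
reported (total reads, high quality, 3'-adapter nulls, empty inserts,
5'-adapter contaminants, length failures, poly-A, clean reads).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from ._util import iter_fastq, mean_phred, percent

#: TruSeq small-RNA 3' adapter.
DEFAULT_ADAPTER3 = "TGGAATTCTCGGGTGCCAAGG"
#: TruSeq small-RNA 5' adapter (its 3'-most bases flag 5' contaminants).
DEFAULT_ADAPTER5 = "GTTCAGAGTTCTACAGTCCGACGATC"


class FastqParseError(ValueError):
    """Malformed FASTQ input; carries the index of the offending record."""

    def __init__(self, record_index: int, message: str):
        self.record_index = record_index
        super().__init__(f"malformed FASTQ at record {record_index}: {message}")


@dataclass
class CleaningReport:
    """Counts of reads removed per rule, in rule order.

    ``high_quality`` is the denominator for the percentage column;
    ``clean_reads`` equals ``high_quality`` minus all removal categories.
    """

    total_reads: int = 0
    high_quality: int = 0
    adapter3_null: int = 0
    insert_null: int = 0
    adapter5_contaminant: int = 0
    too_short: int = 0
    too_long: int = 0
    polyA: int = 0
    clean_reads: int = 0

    _PCT_FIELDS = (
        "high_quality",
        "adapter3_null",
        "insert_null",
        "adapter5_contaminant",
        "too_short",
        "too_long",
        "polyA",
        "clean_reads",
    )

    @classmethod
    def from_counts(cls, **counts: int) -> "CleaningReport":
        """Build a report directly from category counts (e.g. a printed table).

        ``clean_reads`` is recomputed from the categories when not supplied.
        """
        rep = cls(**counts)
        if "clean_reads" not in counts:
            rep.clean_reads = rep.high_quality - (
                rep.adapter3_null
                + rep.insert_null
                + rep.adapter5_contaminant
                + rep.too_short
                + rep.too_long
                + rep.polyA
            )
        return rep

    @property
    def percentages(self) -> dict[str, float]:
        """Each category as a half-up 2-decimal percent of high-quality reads."""
        if self.high_quality == 0:
            return {f: 0.0 for f in self._PCT_FIELDS}
        return {f: percent(getattr(self, f), self.high_quality) for f in self._PCT_FIELDS}

    def validate(self) -> None:
        removed = (
            self.adapter3_null
            + self.insert_null
            + self.adapter5_contaminant
            + self.too_short
            + self.too_long
            + self.polyA
        )
        if self.clean_reads != self.high_quality - removed:
            raise ValueError("cleaning categories do not partition high-quality reads")


@dataclass
class SequenceTag:
    """A unique cleaned insert with per-library read counts (DNA spelling)."""

    sequence: str
    count_ck: int = 0
    count_na: int = 0

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def total(self) -> int:
        return self.count_ck + self.count_na


@dataclass
class LibraryComparison:
    """Common/specific partition of unique tags and their read totals."""

    unique_common: int
    unique_ck_only: int
    unique_na_only: int
    total_common: int
    total_ck_only: int
    total_na_only: int
    pct: dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_counts(
        cls,
        unique_common: int,
        unique_ck_only: int,
        unique_na_only: int,
        total_common: int,
        total_ck_only: int,
        total_na_only: int,
    ) -> "LibraryComparison":
        """Percentage arithmetic from partition counts.

        Unique percentages are of all unique tags; total percentages are of all
        clean reads of both libraries combined (a common tag contributes its
        reads from both libraries to ``total_common``).
        """
        cmp_ = cls(
            unique_common,
            unique_ck_only,
            unique_na_only,
            total_common,
            total_ck_only,
            total_na_only,
        )
        uni_all = unique_common + unique_ck_only + unique_na_only
        tot_all = total_common + total_ck_only + total_na_only
        cmp_.pct = {
            "unique_common": percent(unique_common, uni_all) if uni_all else 0.0,
            "unique_ck_only": percent(unique_ck_only, uni_all) if uni_all else 0.0,
            "unique_na_only": percent(unique_na_only, uni_all) if uni_all else 0.0,
            "total_common": percent(total_common, tot_all) if tot_all else 0.0,
            "total_ck_only": percent(total_ck_only, tot_all) if tot_all else 0.0,
            "total_na_only": percent(total_na_only, tot_all) if tot_all else 0.0,
        }
        return cmp_

    def to_frame(self) -> pd.DataFrame:
        uni_all = self.unique_common + self.unique_ck_only + self.unique_na_only
        tot_all = self.total_common + self.total_ck_only + self.total_na_only
        rows = [
            ("Total_sRNAs", uni_all, 100.0, tot_all, 100.0),
            ("Na200&CK", self.unique_common, self.pct["unique_common"], self.total_common, self.pct["total_common"]),
            ("Na200_specific", self.unique_na_only, self.pct["unique_na_only"], self.total_na_only, self.pct["total_na_only"]),
            ("CK_specific", self.unique_ck_only, self.pct["unique_ck_only"], self.total_ck_only, self.pct["total_ck_only"]),
        ]
        return pd.DataFrame(rows, columns=["class", "unique", "unique_pct", "total", "total_pct"])


def _is_polya(insert: str, min_frac: float = 0.8, min_run: int = 10) -> bool:
    if insert.count("A") >= min_frac * len(insert):
        return True
    return "A" * min_run in insert


def clean_reads(
    fastq: str | Path | Iterable[tuple[str, str, str]],
    min_len: int = 18,
    max_len: int = 30,
    min_qual: float = 20.0,
    adapter3: str = DEFAULT_ADAPTER3,
    adapter5: str = DEFAULT_ADAPTER5,
    seed_len: int = 8,
) -> tuple[list[str], CleaningReport]:
    """Clean one FASTQ library down to trimmed inserts.

    Rules are applied in order, first match claims the read:
    mean Phred < ``min_qual`` (not high quality) -> 3' adapter absent ->
    empty insert -> 5'-adapter contaminant -> length outside
    [``min_len``, ``max_len``] -> poly-A.  Survivors are emitted as inserts.

    Adapter detection is an exact match of the first ``seed_len`` nt of the 3'
    adapter anywhere in the read (trim at the match); a 5' contaminant is an
    insert beginning with the last ``seed_len`` nt of the 5' adapter.
    """
    if not adapter3:
        raise ValueError("adapter3 must be non-empty")
    seed3 = adapter3[:seed_len]
    tail5 = adapter5[-seed_len:] if adapter5 else None
    report = CleaningReport()
    inserts: list[str] = []

    if isinstance(fastq, (str, Path)):
        records: Iterable[tuple[str, str, str]] = _checked_fastq(fastq)
    else:
        records = fastq

    for _title, seq, qual in records:
        report.total_reads += 1
        seq = seq.upper()
        if mean_phred(qual) < min_qual:
            continue
        report.high_quality += 1
        pos = seq.find(seed3)
        if pos < 0:
            report.adapter3_null += 1
            continue
        if pos == 0:
            report.insert_null += 1
            continue
        insert = seq[:pos]
        if tail5 and insert.startswith(tail5):
            report.adapter5_contaminant += 1
            continue
        if len(insert) < min_len:
            report.too_short += 1
            continue
        if len(insert) > max_len:
            report.too_long += 1
            continue
        if _is_polya(insert):
            report.polyA += 1
            continue
        report.clean_reads += 1
        inserts.append(insert)

    report.validate()
    return inserts, report


def _checked_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    it = iter_fastq(path)
    index = 0
    while True:
        try:
            rec = next(it)
        except StopIteration:
            return
        except ValueError as exc:
            raise FastqParseError(index, str(exc)) from exc
        index += 1
        yield rec


def collapse(clean_ck: Iterable[str], clean_na: Iterable[str]) -> dict[str, SequenceTag]:
    """Collapse cleaned inserts of both libraries into unique tags with counts."""
    ck = Counter(clean_ck)
    na = Counter(clean_na)
    tags: dict[str, SequenceTag] = {}
    for seq in ck.keys() | na.keys():
        tags[seq] = SequenceTag(seq, count_ck=ck.get(seq, 0), count_na=na.get(seq, 0))
    return tags


def length_distribution(tags: Iterable[SequenceTag]) -> dict[str, dict[int, float]]:
    """Per-library read-weighted length spectrum, percent of clean reads."""
    tags = list(tags)
    if not tags:
        raise ValueError("length_distribution requires at least one tag")
    out: dict[str, dict[int, float]] = {}
    for lib, attr in (("ck", "count_ck"), ("na", "count_na")):
        total = sum(getattr(t, attr) for t in tags)
        dist: dict[int, float] = {}
        if total:
            by_len = Counter()
            for t in tags:
                by_len[t.length] += getattr(t, attr)
            dist = {ln: 100.0 * c / total for ln, c in sorted(by_len.items())}
        out[lib] = dist
    return out


def compare_libraries(tags: Iterable[SequenceTag]) -> LibraryComparison:
    """Partition tags into common / CK-specific / Na200-specific classes."""
    uc = uck = una = tc = tck = tna = 0
    for t in tags:
        if t.count_ck > 0 and t.count_na > 0:
            uc += 1
            tc += t.count_ck + t.count_na
        elif t.count_ck > 0:
            uck += 1
            tck += t.count_ck
        else:
            una += 1
            tna += t.count_na
    return LibraryComparison.from_counts(uc, uck, una, tc, tck, tna)


def write_collapsed_fasta(tags: dict[str, SequenceTag], path: str | Path) -> None:
    """Write tags as ``>tag{i}_ck{count}_na{count}`` FASTA (stable order)."""
    with open(path, "w") as fh:
        for i, seq in enumerate(sorted(tags), start=1):
            t = tags[seq]
            fh.write(f">tag{i}_ck{t.count_ck}_na{t.count_na}\n{seq}\n")


def read_collapsed_fasta(path: str | Path) -> dict[str, SequenceTag]:
    tags: dict[str, SequenceTag] = {}
    with open(path) as fh:
        header = None
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                header = line[1:]
            elif line and header:
                parts = header.split("_")
                ck = int(parts[-2][2:])
                na = int(parts[-1][2:])
                tags[line] = SequenceTag(line, ck, na)
                header = None
    return tags


def cleaning_table(reports: dict[str, CleaningReport]) -> pd.DataFrame:
    """Cleaning summary for any number of libraries, in printed-table layout."""
    rows = []
    order = (
        ("Total_reads", "total_reads"),
        ("High_quality", "high_quality"),
        ("3'adapter_null", "adapter3_null"),
        ("Insert_null", "insert_null"),
        ("5'adapter_contaminants", "adapter5_contaminant"),
        ("Smaller_than_min", "too_short"),
        ("Larger_than_max", "too_long"),
        ("Poly(A)", "polyA"),
        ("Clean_reads", "clean_reads"),
    )
    for label, attr in order:
        row: dict[str, object] = {"type": label}
        for lib, rep in reports.items():
            row[f"{lib}_count"] = getattr(rep, attr)
            row[f"{lib}_pct"] = rep.percentages.get(attr, "")
        rows.append(row)
    return pd.DataFrame(rows)
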