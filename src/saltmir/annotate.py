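"""Genome mapping (perfect match) and category classification of sRNA tags.

Tags are mapped as exact substrings of the reference contigs on both strands.
Classification applies the non-coding-RNA exclusion first (rRNA > tRNA >
snRNA > snoRNA, exact substring of a reference entry), then assigns surviving
tags to the miRNA category via the known-miRNA mismatch rules; everything else
is unannotated.  The exclusion-before-miRNA precedence is configurable.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd

from ._util import percent, revcomp
from .known import KnownMatcher
from .preprocess import SequenceTag

CATEGORIES = ("miRNA", "rRNA", "snRNA", "snoRNA", "tRNA", "unannotated")
DEFAULT_PRECEDENCE = ("rRNA", "tRNA", "snRNA", "snoRNA")


@dataclass
class AnnotatedTag:
    tag: SequenceTag
    genome_hits: list[tuple[str, int, str]] = field(default_factory=list)
    category: str = "unannotated"
    mirna_name: Optional[str] = None
    mirna_mismatches: float = 0.0


class GenomeIndex:
    """Concatenated-contig substring index for exact mapping on both strands.

    Contigs are joined with a run of 'N' longer than any tag so matches cannot
    straddle a boundary; hit coordinates are translated back to 1-based
    per-contig positions.  Reverse-strand hits are found by searching the
    tag's reverse complement on the forward text and are reported with the
    forward-strand start of the matched region and strand '-'.
    """

    def __init__(self, genome: Mapping[str, str], spacer: int = 35):
        if not genome or all(len(s) == 0 for s in genome.values()):
            raise ValueError("empty genome reference")
        self.names = list(genome)
        self.starts: list[int] = []
        parts = []
        pos = 0
        for name in self.names:
            self.starts.append(pos)
            seq = genome[name].upper()
            parts.append(seq)
            pos += len(seq) + spacer
        self.lengths = [len(genome[n]) for n in self.names]
        self.text = ("N" * spacer).join(parts)

    def _locate(self, abs_pos: int) -> tuple[str, int]:
        i = bisect_right(self.starts, abs_pos) - 1
        return self.names[i], abs_pos - self.starts[i] + 1

    def hits(self, tag_seq: str) -> list[tuple[str, int, str]]:
        """All perfect hits as (contig, start 1-based on forward strand, strand)."""
        out = []
        for query, strand in ((tag_seq, "+"), (revcomp(tag_seq), "-")):
            start = self.text.find(query)
            while start >= 0:
                contig, pos = self._locate(start)
                out.append((contig, pos, strand))
                start = self.text.find(query, start + 1)
        return out

    def fetch(self, contig: str, start: int, end: int) -> str:
        """1-based inclusive slice of a contig, clipped at bounds."""
        i = self.names.index(contig)
        lo = max(1, start)
        hi = min(self.lengths[i], end)
        off = self.starts[i]
        return self.text[off + lo - 1 : off + hi]

    def contig_length(self, contig: str) -> int:
        return self.lengths[self.names.index(contig)]


def map_perfect(
    tags: Iterable[SequenceTag], genome: Mapping[str, str] | GenomeIndex
) -> dict[str, list[tuple[str, int, str]]]:
    """Perfect-match genome hits per tag sequence (both strands)."""
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)
    return {t.sequence: index.hits(t.sequence) for t in tags}


class _SubstringRef:
    """Membership test: is a tag an exact substring of any reference entry?"""

    def __init__(self, entries: Mapping[str, str], spacer: int = 35):
        self.text = ("N" * spacer).join(s.upper() for s in entries.values()) if entries else ""

    def __contains__(self, seq: str) -> bool:
        return bool(self.text) and seq in self.text


def classify(
    tags: Iterable[SequenceTag],
    ncrna_refs: Mapping[str, Mapping[str, str]],
    mature_ref: Mapping[str, str],
    genome: Mapping[str, str] | GenomeIndex | None = None,
    max_mm: int = 2,
    precedence: tuple[str, ...] = DEFAULT_PRECEDENCE,
    mirna_first: bool = False,
) -> list[AnnotatedTag]:
    """Assign each tag to exactly one category.

    ``mirna_first=True`` flips the precedence so that the miRNA assignment is
    attempted before the ncRNA exclusion (the alternative reading of summary
    tables that list miRNA as a sibling category).
    """
    subrefs = {cat: _SubstringRef(ncrna_refs.get(cat, {})) for cat in precedence}
    matcher = KnownMatcher(mature_ref, max_mm=max_mm)
    index: Optional[GenomeIndex] = None
    if genome is not None:
        index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)

    out: list[AnnotatedTag] = []
    for t in tags:
        at = AnnotatedTag(tag=t)
        if index is not None:
            at.genome_hits = index.hits(t.sequence)

        def _ncrna_cat() -> Optional[str]:
            for cat in precedence:
                if t.sequence in subrefs[cat]:
                    return cat
            return None

        def _mirna() -> Optional[tuple[str, float]]:
            return matcher.match(t.sequence)

        if mirna_first:
            res = _mirna()
            if res:
                at.category, (at.mirna_name, at.mirna_mismatches) = "miRNA", res
            else:
                cat = _ncrna_cat()
                if cat:
                    at.category = cat
        else:
            cat = _ncrna_cat()
            if cat:
                at.category = cat
            else:
                res = _mirna()
                if res:
                    at.category, (at.mirna_name, at.mirna_mismatches) = "miRNA", res
        out.append(at)
    return out


def category_percentages(
    unique_counts: Mapping[str, int], total_counts: Mapping[str, int]
) -> pd.DataFrame:
    """Percentage arithmetic for a category summary from raw counts.

    ``unique_counts``/``total_counts`` map category -> unique tags / reads.
    Percentages (half-up, 2 decimals) are of the column sums.
    """
    uni_all = sum(unique_counts.values())
    tot_all = sum(total_counts.values())
    rows = []
    for cat in unique_counts:
        rows.append(
            {
                "category": cat,
                "unique": unique_counts[cat],
                "unique_pct": percent(unique_counts[cat], uni_all) if uni_all else 0.0,
                "total": total_counts.get(cat, 0),
                "total_pct": percent(total_counts.get(cat, 0), tot_all) if tot_all else 0.0,
            }
        )
    return pd.DataFrame(rows, columns=["category", "unique", "unique_pct", "total", "total_pct"])


def category_summary(annotated: Iterable[AnnotatedTag]) -> pd.DataFrame:
    """Per-library unique/total category breakdown with percentages."""
    frames = {}
    annotated = list(annotated)
    for lib, attr in (("ck", "count_ck"), ("na", "count_na")):
        uniq = {cat: 0 for cat in CATEGORIES}
        tot = {cat: 0 for cat in CATEGORIES}
        for at in annotated:
            n = getattr(at.tag, attr)
            if n > 0:
                uniq[at.category] += 1
                tot[at.category] += n
        df = category_percentages(uniq, tot)
        df.columns = ["category"] + [f"{lib}_{c}" for c in df.columns[1:]]
        frames[lib] = df
    merged = frames["ck"].merge(frames["na"], on="category")
    return merged
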