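"""Known-miRNA identification: mismatch-tolerant matching against a mature
reference set and family-level abundance/ratio tables.

A sequenced tag is called a known miRNA when it aligns, without gaps, to a
mature reference sequence with at most ``max_mm`` mismatches.  Length variants
(isomiRs) are handled by sliding the shorter sequence over the longer one when
lengths differ by at most ``length_slack`` nucleotides; every unaligned
overhang base of the longer sequence costs one mismatch, so the total mismatch
budget is shared between substitutions and end shifts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import pandas as pd

from ._util import ratio, to_dna
from .preprocess import SequenceTag

#: Families conventionally reported merged in plant miRNA tables.
DEFAULT_FAMILY_MERGES = {
    "miR156": "miR156/157",
    "miR157": "miR156/157",
    "miR165": "miR165/166",
    "miR166": "miR165/166",
}

_NAME_RE = re.compile(
    r"""
    ^(?:[a-z]{3,4}-)?          # species prefix, e.g. rsa- / ath-
    (mir|miR|MIR)(\d+)         # family stem
    [a-z]*                     # member letter(s)
    (?:[-._]\d+)?              # paralog index, e.g. miR169-2
    (?:-[35]p)?$               # arm suffix
    """,
    re.VERBOSE,
)


@dataclass
class MirnaMatch:
    """A tag assigned to a mature reference miRNA."""

    tag: SequenceTag
    reference_name: str
    family: str
    mismatches: float


def family_of(name: str, merges: Mapping[str, str] | None = None) -> str:
    """Normalize a mature-miRNA name to its family.

    Strips species prefix, member letters, paralog indices and arm suffixes
    (miR156h -> miR156, rsa-miR169b-3p -> miR169), then applies the configured
    merge list for families reported jointly (miR156/157, miR165/166).
    """
    if merges is None:
        merges = DEFAULT_FAMILY_MERGES
    m = _NAME_RE.match(name.strip())
    if not m:
        fam = name.strip()
    else:
        fam = "miR" + m.group(2)
    return merges.get(fam, fam)


def _aligned_mismatches(short: str, long_: str, max_mm: float) -> float:
    """Fewest mismatches over all ungapped offsets of ``short`` on ``long_``.

    Each overhang base of the longer sequence counts one mismatch.  Returns a
    value > max_mm as soon as no offset can do better (early exit).
    """
    d = len(long_) - len(short)
    best = float("inf")
    for off in range(d + 1):
        mm = d  # overhangs
        if mm >= best:
            break
        window = long_[off : off + len(short)]
        for a, b in zip(short, window):
            if a != b or a == "N":
                mm += 1
                if mm >= best:
                    break
        else:
            best = mm
    return best


class KnownMatcher:
    """Reusable matcher over one mature reference set.

    A k-mer prefilter (k=6) restricts the full sliding comparison to
    references sharing at least one exact 6-mer with the tag; with a total
    mismatch budget of 2 over >=18 aligned nt, any true match is guaranteed to
    share an exact run of >= 6 nt (pigeonhole), so the prefilter loses nothing.
    """

    K = 6

    def __init__(
        self,
        mature_ref: Mapping[str, str],
        max_mm: int = 2,
        length_slack: int = 2,
    ):
        self.max_mm = max_mm
        self.length_slack = length_slack
        self.ref: dict[str, str] = {name: to_dna(seq) for name, seq in mature_ref.items()}
        self._exact: dict[str, list[str]] = {}
        self._kmer_index: dict[str, set[str]] = {}
        for name, seq in self.ref.items():
            self._exact.setdefault(seq, []).append(name)
            for i in range(len(seq) - self.K + 1):
                self._kmer_index.setdefault(seq[i : i + self.K], set()).add(name)
        for names in self._exact.values():
            names.sort()

    def _candidates(self, tag: str) -> set[str]:
        cands: set[str] = set()
        for i in range(len(tag) - self.K + 1):
            hit = self._kmer_index.get(tag[i : i + self.K])
            if hit:
                cands |= hit
        return cands

    def match(self, tag_seq: str) -> Optional[tuple[str, float]]:
        """Best reference for a tag, or None if every reference exceeds the
        mismatch budget.  Ties are broken lexicographically by reference name."""
        tag = to_dna(tag_seq)
        exact = self._exact.get(tag)
        if exact:
            return exact[0], 0.0
        best_name: Optional[str] = None
        best_mm = float("inf")
        for name in sorted(self._candidates(tag)):
            ref = self.ref[name]
            if abs(len(ref) - len(tag)) > self.length_slack:
                continue
            short, long_ = (tag, ref) if len(tag) <= len(ref) else (ref, tag)
            mm = _aligned_mismatches(short, long_, self.max_mm)
            if mm < best_mm:
                best_mm, best_name = mm, name
        if best_name is None or best_mm > self.max_mm:
            return None
        return best_name, best_mm


def match(
    tag: SequenceTag | str,
    mature_ref: Mapping[str, str],
    max_mm: int = 2,
    length_slack: int = 2,
    merges: Mapping[str, str] | None = None,
) -> Optional[MirnaMatch]:
    """Match a single tag against a mature reference FASTA mapping."""
    seq = tag.sequence if isinstance(tag, SequenceTag) else tag
    res = KnownMatcher(mature_ref, max_mm=max_mm, length_slack=length_slack).match(seq)
    if res is None:
        return None
    name, mm = res
    st = tag if isinstance(tag, SequenceTag) else SequenceTag(to_dna(seq), 0, 0)
    return MirnaMatch(st, name, family_of(name, merges), mm)


@dataclass
class FamilyAbundance:
    family: str
    n_members: int
    reads_ck: int
    reads_na: int

    @property
    def total(self) -> int:
        return self.reads_ck + self.reads_na

    @property
    def ratio_na_over_ck(self) -> Optional[float]:
        """Na200/CK read ratio on raw counts, half-up 2 decimals; None
        (printed as "_") when the family has no CK reads."""
        if self.reads_ck == 0:
            return None
        return ratio(self.reads_na, self.reads_ck)


def family_table(matches: Iterable[MirnaMatch]) -> pd.DataFrame:
    """Aggregate matches into a family abundance/ratio table.

    Members are distinct matched reference names; reads are summed over all
    member tags per library; the ratio is computed on raw read counts.
    """
    fams: dict[str, dict] = {}
    for m in matches:
        rec = fams.setdefault(
            m.family, {"members": set(), "reads_ck": 0, "reads_na": 0}
        )
        rec["members"].add(m.reference_name)
        rec["reads_ck"] += m.tag.count_ck
        rec["reads_na"] += m.tag.count_na
    rows = []
    for fam in sorted(fams):
        rec = fams[fam]
        fa = FamilyAbundance(fam, len(rec["members"]), rec["reads_ck"], rec["reads_na"])
        r = fa.ratio_na_over_ck
        rows.append(
            {
                "family": fam,
                "n_members": fa.n_members,
                "reads_ck": fa.reads_ck,
                "reads_na": fa.reads_na,
                "total": fa.total,
                "ratio_na_over_ck": "_" if r is None else r,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["family", "n_members", "reads_ck", "reads_na", "total", "ratio_na_over_ck"],
    )


def member_table(matches: Iterable[MirnaMatch]) -> pd.DataFrame:
    """Per-reference (per-member) counts, one row per matched reference name."""
    members: dict[str, dict] = {}
    for m in matches:
        rec = members.setdefault(
            m.reference_name, {"family": m.family, "reads_ck": 0, "reads_na": 0, "tags": 0}
        )
        rec["reads_ck"] += m.tag.count_ck
        rec["reads_na"] += m.tag.count_na
        rec["tags"] += 1
    rows = [
        {"reference": name, **members[name]} for name in sorted(members)
    ]
    return pd.DataFrame(rows, columns=["reference", "family", "reads_ck", "reads_na", "tags"])
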