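"""Plant miRNA target prediction by positional complementarity scoring.

The miRNA is aligned antiparallel and ungapped against every window of the
transcript sense strand.  Each position (counted from the miRNA 5' end)
scores 0 for a Watson-Crick pair, 0.5 for a G:U wobble and 1 otherwise.  A
site passes when all five rules hold: total score <= 4; longest run of
adjacent positions scoring >= 1 is <= 2; score over positions 1-9 <= 1;
zero score at positions 10-11; score over positions 1-12 <= 2.5.  The
half-point budgets are reachable only through wobble scoring; with
``no_wobble`` every non-Watson-Crick pair costs a full mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from ._util import to_rna

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}

MAX_TOTAL = 4.0
MAX_ADJACENT = 2
MAX_SEED_1_9 = 1.0
MAX_CENTER_10_11 = 0.0
MAX_5PRIME_1_12 = 2.5


@dataclass
class TargetHit:
    mirna: str
    transcript: str
    site_start: int  # 1-based inclusive, transcript coordinates
    site_end: int
    mirna_seq: str  # 5'->3'
    target_rev: str  # target site 3'->5', aligned position-wise to mirna_seq
    scores: list[float] = field(default_factory=list)
    mm_total: float = 0.0
    mm_adjacent_max: int = 0
    mm_1to9: float = 0.0
    mm_10to11: float = 0.0
    mm_1to12: float = 0.0
    passes: bool = False

    @property
    def alignment(self) -> str:
        """Three-line alignment; '|' Watson-Crick, 'o' wobble, ' ' mismatch."""
        mid = "".join(
            "|" if s == 0 else ("o" if s == 0.5 else " ") for s in self.scores
        )
        return (
            f"miRNA  5' {self.mirna_seq} 3'\n"
            f"          {mid}\n"
            f"target 3' {self.target_rev} 5'"
        )


def position_score(mirna_base: str, target_base: str, no_wobble: bool = False) -> float:
    """Mismatch cost of one duplex position (miRNA base vs target base)."""
    pair = (mirna_base, target_base)
    if pair in _WC:
        return 0.0
    if pair in _WOBBLE:
        return 1.0 if no_wobble else 0.5
    return 1.0


def score_site(
    mirna_seq: str,
    target_window: str,
    mirna_name: str = "miRNA",
    transcript: str = "transcript",
    site_start: int = 1,
    no_wobble: bool = False,
) -> TargetHit:
    """Score one candidate site.

    ``target_window`` is the transcript site 5'->3' (sense strand, same length
    as the miRNA); internally it is reversed so position i of the miRNA faces
    its antiparallel partner.
    """
    mi = to_rna(mirna_seq)
    tw = to_rna(target_window)
    if len(mi) != len(tw):
        raise ValueError("miRNA and target window lengths differ")
    rev = tw[::-1]
    scores = [position_score(a, b, no_wobble) for a, b in zip(mi, rev)]

    hit = TargetHit(
        mirna=mirna_name,
        transcript=transcript,
        site_start=site_start,
        site_end=site_start + len(tw) - 1,
        mirna_seq=mi,
        target_rev=rev,
        scores=scores,
    )
    hit.mm_total = sum(scores)
    hit.mm_1to9 = sum(scores[:9])
    hit.mm_10to11 = sum(scores[9:11])
    hit.mm_1to12 = sum(scores[:12])
    run = best = 0
    for s in scores:
        if s >= 1.0:
            run += 1
            best = max(best, run)
        else:
            run = 0
    hit.mm_adjacent_max = best
    hit.passes = (
        hit.mm_total <= MAX_TOTAL
        and hit.mm_adjacent_max <= MAX_ADJACENT
        and hit.mm_1to9 <= MAX_SEED_1_9
        and hit.mm_10to11 <= MAX_CENTER_10_11
        and hit.mm_1to12 <= MAX_5PRIME_1_12
    )
    return hit


def scan(
    mirna_seq: str,
    transcripts: Mapping[str, str],
    mirna_name: str = "miRNA",
    no_wobble: bool = False,
) -> list[TargetHit]:
    """All passing sites of one miRNA over a transcript set.

    Every ungapped window on the transcript sense strand is evaluated;
    overlapping passing sites are all reported.  Output order is
    (transcript id, site start), independent of mapping insertion order.
    """
    mi = to_rna(mirna_seq)
    L = len(mi)
    hits: list[TargetHit] = []
    for tid in sorted(transcripts):
        seq = to_rna(transcripts[tid])
        for start in range(0, len(seq) - L + 1):
            hit = score_site(
                mi,
                seq[start : start + L],
                mirna_name=mirna_name,
                transcript=tid,
                site_start=start + 1,
                no_wobble=no_wobble,
            )
            if hit.passes:
                hits.append(hit)
    return hits


def hits_table(hits: Iterable[TargetHit]) -> pd.DataFrame:
    rows = [
        {
            "mirna": h.mirna,
            "transcript": h.transcript,
            "start": h.site_start,
            "end": h.site_end,
            "mm_total": h.mm_total,
            "mm_adjacent_max": h.mm_adjacent_max,
            "mm_1to9": h.mm_1to9,
            "mm_10to11": h.mm_10to11,
            "mm_1to12": h.mm_1to12,
            "mirna_5to3": h.mirna_seq,
            "target_3to5": h.target_rev,
        }
        for h in hits
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "mirna",
            "transcript",
            "start",
            "end",
            "mm_total",
            "mm_adjacent_max",
            "mm_1to9",
            "mm_10to11",
            "mm_1to12",
            "mirna_5to3",
            "target_3to5",
        ],
    )
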