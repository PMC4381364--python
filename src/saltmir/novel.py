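"""Novel-miRNA discovery: fold genomic windows around unannotated tags and
test the stem-loop against plant miRNA annotation criteria.

A candidate precursor is the tag plus flanking genomic sequence (the tag tried
as the 5p arm and as the 3p arm).  The window is folded — by the ViennaRNA
thermodynamic backend when its Python bindings are importable, otherwise by a
bundled Nussinov-style maximum-weight algorithm with fixed per-pair
pseudo-energies (GC -3, AU -2, GU -1 kcal/mol, hairpin loops >= 3 nt) — and
the mature:star duplex is read off the structure with the canonical 2-nt 3'
overhangs.  Pass criteria: (a) the mature sits on one arm and never pairs
with itself, (b) at most 4 mismatched mature bases in the duplex and at most
a 2-nt asymmetric bulge, (c) a star partner is derivable from the structure,
(d) folding energy at or below the configured ceiling, (e) precursor length
within [60, 400] nt.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from ._util import revcomp, to_dna, to_rna
from .annotate import AnnotatedTag, GenomeIndex
from .preprocess import SequenceTag

_PAIR_WEIGHT = {
    ("G", "C"): 3.0,
    ("C", "G"): 3.0,
    ("A", "U"): 2.0,
    ("U", "A"): 2.0,
    ("G", "U"): 1.0,
    ("U", "G"): 1.0,
}
MIN_HAIRPIN_LOOP = 3

try:  # thermodynamic backend (optional)
    import RNA as _vienna
except ImportError:  # pragma: no cover - depends on environment
    _vienna = None


def _validate_rna(seq: str) -> str:
    rna = to_rna(seq)
    if not rna or set(rna) - set("ACGU"):
        raise ValueError(f"sequence contains non-ACGU characters: {seq!r}")
    return rna


def fold(seq: str, backend: str = "auto") -> tuple[str, float]:
    """Fold a precursor; returns (dot-bracket structure, MFE in kcal/mol).

    ``backend`` is 'vienna', 'maxpair' (the bundled fallback) or 'auto'
    (vienna when importable).  Results are deterministic per backend and
    invariant to T/U spelling of the input.
    """
    rna = _validate_rna(seq)
    if backend == "auto":
        backend = "vienna" if _vienna is not None else "maxpair"
    if backend == "vienna":
        if _vienna is None:
            raise RuntimeError("ViennaRNA python bindings are not available")
        structure, mfe = _vienna.fold(rna)
        return structure, float(mfe)
    if backend == "maxpair":
        return _fold_maxpair(rna)
    raise ValueError(f"unknown folding backend {backend!r}")


def _fold_maxpair(rna: str) -> tuple[str, float]:
    """Maximum-weight base pairing (Nussinov recursion) with pseudo-energies.

    Deterministic traceback: leaving the 3' base unpaired is preferred at
    equal score, then the smallest pairing partner index.
    """
    n = len(rna)
    W = [[0.0] * n for _ in range(n)]
    for span in range(MIN_HAIRPIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = W[i][j - 1]
            for k in range(i, j - MIN_HAIRPIN_LOOP):
                w = _PAIR_WEIGHT.get((rna[k], rna[j]))
                if w is None:
                    continue
                left = W[i][k - 1] if k > i else 0.0
                inner = W[k + 1][j - 1] if k + 1 <= j - 1 else 0.0
                cand = left + inner + w
                if cand > best:
                    best = cand
            W[i][j] = best
    structure = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j:
            continue
        if W[i][j] == W[i][j - 1]:
            stack.append((i, j - 1))
            continue
        for k in range(i, j - MIN_HAIRPIN_LOOP):
            w = _PAIR_WEIGHT.get((rna[k], rna[j]))
            if w is None:
                continue
            left = W[i][k - 1] if k > i else 0.0
            inner = W[k + 1][j - 1] if k + 1 <= j - 1 else 0.0
            if left + inner + w == W[i][j]:
                structure[k] = "("
                structure[j] = ")"
                if k > i:
                    stack.append((i, k - 1))
                stack.append((k + 1, j - 1))
                break
    return "".join(structure), -W[0][n - 1] if n else 0.0


def pair_table(structure: str) -> list[int]:
    """1-based pairing partners; index 0 unused, 0 means unpaired."""
    pt = [0] * (len(structure) + 1)
    stack: list[int] = []
    for i, c in enumerate(structure, start=1):
        if c == "(":
            stack.append(i)
        elif c == ")":
            j = stack.pop()
            pt[i], pt[j] = j, i
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return pt


@dataclass
class CandidateWindow:
    """A genomic window oriented 5'->3' as the putative precursor strand."""

    contig: str
    start: int  # 1-based inclusive, forward-strand coordinates
    end: int
    strand: str
    seq: str  # oriented precursor sequence (DNA spelling)
    mature_offset: int  # 1-based start of the tag within ``seq``
    arm_hint: str  # which arm the window layout puts the tag on


@dataclass
class HairpinCandidate:
    name: str
    contig: str
    window: tuple[int, int]
    strand: str
    precursor_seq: str  # RNA spelling
    structure: str = ""
    mfe: float = 0.0
    mature_arm: str = ""
    mature_seq: str = ""
    star_seq: Optional[str] = None
    star_count_ck: int = 0
    star_count_na: int = 0
    count_ck: int = 0
    count_na: int = 0
    flags: dict[str, bool] = field(default_factory=dict)
    passes: bool = False
    backend: str = ""


def extract_windows(
    tag_seq: str,
    hit: tuple[str, int, str],
    genome: Mapping[str, str] | GenomeIndex,
    flank: int = 150,
) -> list[CandidateWindow]:
    """Two candidate windows per genome hit: tag as 5p arm and as 3p arm.

    Windows are clipped at contig bounds; minus-strand windows are reverse
    complemented so the returned sequence is the precursor strand 5'->3'.
    """
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)
    contig, start, strand = hit
    L = len(tag_seq)
    end = start + L - 1
    out = []
    for arm in ("5p", "3p"):
        downstream = (arm == "5p") == (strand == "+")
        if downstream:
            lo, hi = start, end + flank
        else:
            lo, hi = start - flank, end
        seq = index.fetch(contig, lo, hi)
        lo_c = max(1, lo)
        hi_c = min(index.contig_length(contig), hi)
        if strand == "+":
            oriented = seq
            offset = start - lo_c + 1
        else:
            oriented = revcomp(seq)
            offset = hi_c - end + 1
        out.append(
            CandidateWindow(contig, lo_c, hi_c, strand, oriented, offset, arm)
        )
    return out


def evaluate_hairpin(
    window: CandidateWindow | str,
    mature_len: int | None = None,
    mature_offset: int = 1,
    tags: Mapping[str, SequenceTag] | None = None,
    mfe_max: float = -18.0,
    min_precursor: int = 60,
    max_precursor: int = 400,
    max_duplex_mismatch: int = 4,
    max_bulge: int = 2,
    backend: str = "auto",
    name: str = "candidate",
) -> HairpinCandidate:
    """Fold a candidate window and score the annotation criteria.

    ``window`` may be a :class:`CandidateWindow` or a bare precursor sequence
    (then ``mature_offset``/``mature_len`` locate the mature within it).
    """
    if isinstance(window, CandidateWindow):
        seq, ms = window.seq, window.mature_offset
        cand = HairpinCandidate(
            name, window.contig, (window.start, window.end), window.strand, to_rna(window.seq)
        )
        if mature_len is None:
            raise ValueError("mature_len is required with a CandidateWindow")
    else:
        seq, ms = window, mature_offset
        if mature_len is None:
            raise ValueError("mature_len is required")
        cand = HairpinCandidate(name, "", (1, len(seq)), "+", to_rna(seq))

    rna = to_rna(seq)
    n = len(rna)
    me = ms + mature_len - 1
    if not (1 <= ms <= me <= n):
        raise ValueError("mature coordinates outside the precursor")
    cand.mature_seq = rna[ms - 1 : me]

    used_backend = backend
    if backend == "auto":
        used_backend = "vienna" if _vienna is not None else "maxpair"
    structure, mfe = fold(rna, backend=used_backend)
    cand.structure, cand.mfe, cand.backend = structure, mfe, used_backend
    pt = pair_table(structure)

    partners = [pt[i] for i in range(ms, me + 1) if pt[i]]
    self_paired = any(ms <= pt[i] <= me for i in range(ms, me + 1) if pt[i])
    one_sided = bool(partners) and (all(p > me for p in partners) or all(p < ms for p in partners))
    cand.flags["a_one_arm"] = (not self_paired) and one_sided
    cand.mature_arm = "5p" if partners and partners[0] > me else "3p"

    # Duplex region: mature minus its 2-nt 3' overhang.
    dm_end = me - 2
    star_beg = star_end = None
    if cand.flags["a_one_arm"]:
        anchors = [i for i in range(ms, dm_end + 1) if pt[i]]
        if anchors:
            i0, j0 = anchors[0], anchors[-1]
            star_end = pt[i0] + 2 + (i0 - ms)
            star_beg = pt[j0] - (dm_end - j0)
            star_beg = max(1, star_beg)
            star_end = min(n, star_end)
    if star_beg is not None and star_end is not None and star_beg <= star_end:
        overlaps = not (star_end < ms or star_beg > me)
        cand.flags["c_star_defined"] = not overlaps
        if not overlaps:
            cand.star_seq = rna[star_beg - 1 : star_end]
    else:
        cand.flags["c_star_defined"] = False

    if cand.flags["c_star_defined"]:
        mm = 0
        dm_partners = []
        for i in range(ms, dm_end + 1):
            p = pt[i]
            if p == 0 or not (star_beg <= p <= star_end):
                mm += 1
            else:
                dm_partners.append((i, p))
        if dm_partners:
            mspan = dm_partners[-1][0] - dm_partners[0][0] + 1
            sspan = max(p for _, p in dm_partners) - min(p for _, p in dm_partners) + 1
            bulge = abs(mspan - sspan)
        else:
            bulge = max_bulge + 1
        cand.flags["b_duplex"] = mm <= max_duplex_mismatch and bulge <= max_bulge
    else:
        cand.flags["b_duplex"] = False

    cand.flags["d_mfe"] = mfe <= mfe_max
    cand.flags["e_length"] = min_precursor <= n <= max_precursor
    cand.passes = all(cand.flags.values())

    if tags is not None and cand.star_seq:
        st = tags.get(to_dna(cand.star_seq))
        if st is not None:
            cand.star_count_ck, cand.star_count_na = st.count_ck, st.count_na
    return cand


def find_novel(
    annotated: Iterable[AnnotatedTag],
    genome: Mapping[str, str] | GenomeIndex,
    tags: Mapping[str, SequenceTag] | None = None,
    flank: int = 150,
    min_count: int = 10,
    mfe_max: float = -18.0,
    backend: str = "auto",
    max_hits_per_tag: int = 5,
) -> list[HairpinCandidate]:
    """Scan unannotated, genome-mapped tags for passing hairpin candidates.

    Tags below ``min_count`` total reads are skipped (singleton noise cannot
    support an annotation).  Overlapping passing candidates on the same locus
    are reduced to the lowest-MFE one.  Survivors are named ``rsa-mirN-<arm>``
    in locus order.
    """
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)
    passing: list[HairpinCandidate] = []
    for at in annotated:
        if at.category != "unannotated" or not at.genome_hits:
            continue
        if at.tag.total < min_count:
            continue
        for hit in at.genome_hits[:max_hits_per_tag]:
            for win in extract_windows(at.tag.sequence, hit, index, flank=flank):
                cand = evaluate_hairpin(
                    win,
                    mature_len=at.tag.length,
                    tags=tags,
                    mfe_max=mfe_max,
                    backend=backend,
                )
                cand.count_ck, cand.count_na = at.tag.count_ck, at.tag.count_na
                if cand.passes:
                    passing.append(cand)

    passing.sort(key=lambda c: (c.contig, c.window[0], c.window[1], c.mfe))
    kept: list[HairpinCandidate] = []
    for cand in passing:
        if kept:
            prev = kept[-1]
            if (
                prev.contig == cand.contig
                and prev.strand == cand.strand
                and cand.window[0] <= prev.window[1]
            ):
                if cand.mfe < prev.mfe:
                    kept[-1] = cand
                continue
        kept.append(cand)
    for i, cand in enumerate(kept, start=1):
        cand.name = f"rsa-mir{i}-{cand.mature_arm}"
    return kept
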