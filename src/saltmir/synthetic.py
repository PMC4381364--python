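"""Synthetic two-condition small-RNA study generator.

Builds every input the pipeline needs — a contig "genome", a mature-miRNA
reference, non-coding-RNA references, transcripts with planted target sites,
and two FASTQ libraries (control CK and salt-treated Na200) — together with a
ground-truth manifest, so recovery of planted signal can be measured without
any external download.

The count model is a negative binomial per planted miRNA (dispersion
configurable, default 0.05; dispersion 0 degenerates to Poisson).  Library
means obey the planted log2(Na200/CK) effects after library-size scaling, so
the true effects are defined on the TPM scale.  Reads carry a 3' adapter and
the configured mixture of technical artifacts (adapter-only reads, 5'-adapter
contaminants, too-short inserts, poly-A, ncRNA fragments, unannotatable
random tags).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import yaml

from ._util import revcomp, to_dna, write_fasta
from .preprocess import DEFAULT_ADAPTER3, DEFAULT_ADAPTER5

_BASES = np.array(list("ACGT"))

#: Conditional composition of non-miRNA reads (normalized among noise
#: categories); dominated by unannotatable tags with an rRNA shoulder, the
#: technical categories at the per-mille level seen in cleaning tables.
NOISE_COMPOSITION = {
    "random": 0.500,
    "rRNA": 0.120,
    "tRNA": 0.015,
    "snRNA": 0.002,
    "snoRNA": 0.001,
    "adapter_only": 0.002,
    "adapter5": 0.005,
    "short": 0.008,
    "polyA": 0.002,
}

_FAMILY_STEMS = [
    "miR156", "miR157", "miR158", "miR159", "miR160", "miR164", "miR165",
    "miR166", "miR167", "miR168", "miR169", "miR171", "miR172", "miR319",
    "miR390", "miR393", "miR395", "miR396", "miR397", "miR398", "miR399",
    "miR403", "miR408", "miR482", "miR535",
]


class ManifestError(ValueError):
    """The ground-truth manifest is internally inconsistent."""


@dataclass
class PlantedMirna:
    name: str
    family: str
    sequence: str  # DNA spelling
    contig: str
    start: int  # 1-based locus of the mature sequence in the genome
    mean_ck: float  # expected read count at the manifest's nominal depth
    mean_na: float


@dataclass
class PlantedHairpin:
    name: str
    contig: str
    start: int  # 1-based inclusive precursor locus
    end: int
    arm: str  # arm carrying the mature: '5p' or '3p'
    mature_seq: str  # DNA spelling
    star_seq: str
    precursor_seq: str
    mean_mature_ck: float = 0.0
    mean_mature_na: float = 0.0
    mean_star_ck: float = 0.0
    mean_star_na: float = 0.0


@dataclass
class PlantedTargetSite:
    mirna: str
    transcript: str
    start: int  # 1-based site start on the transcript
    n_wobble: int = 0
    n_mismatch: int = 0


@dataclass
class GroundTruthManifest:
    planted_known: list[PlantedMirna] = field(default_factory=list)
    planted_novel: list[PlantedHairpin] = field(default_factory=list)
    planted_de_effects: dict[str, float] = field(default_factory=dict)
    planted_target_sites: list[PlantedTargetSite] = field(default_factory=list)
    noise_fractions: dict[str, float] = field(default_factory=dict)
    mirna_fraction: float = 0.0
    nominal_depth: int = 200_000
    seed: int = 0

    def validate(self, genome: Mapping[str, str] | None = None) -> None:
        total = sum(self.noise_fractions.values()) + self.mirna_fraction
        if abs(total - 1.0) > 1e-9:
            raise ManifestError(
                f"noise fractions plus miRNA fraction sum to {total!r}, not 1"
            )
        names = {m.name for m in self.planted_known}
        names |= {h.name for h in self.planted_novel}
        unknown = set(self.planted_de_effects) - names
        if unknown:
            raise ManifestError(f"DE effects reference unplanted miRNAs: {sorted(unknown)}")
        for h in self.planted_novel:
            if to_dna(h.mature_seq) not in to_dna(h.precursor_seq):
                raise ManifestError(f"{h.name}: mature is not a substring of its precursor")
        if genome is not None:
            for m in self.planted_known:
                if m.start < 1 or m.start + len(m.sequence) - 1 > len(genome[m.contig]):
                    raise ManifestError(f"{m.name}: locus outside contig bounds")
            for h in self.planted_novel:
                if h.start < 1 or h.end > len(genome[h.contig]):
                    raise ManifestError(f"{h.name}: locus outside contig bounds")


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=length, p=p)])


def generate_genome(
    length: int, gc: float = 0.5, seed: int = 0, n_contigs: int = 10
) -> dict[str, str]:
    """Random multi-contig reference; contigs named contig_1..contig_k."""
    if length <= 0:
        raise ValueError("genome length must be positive")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must lie in [0, 1]")
    n_contigs = max(1, min(n_contigs, length))
    rng = np.random.default_rng(seed)
    per = length // n_contigs
    genome = {}
    for i in range(n_contigs):
        ln = per if i < n_contigs - 1 else length - per * (n_contigs - 1)
        genome[f"contig_{i + 1}"] = _random_seq(rng, ln, gc)
    return genome


def build_hairpin(
    mature: str, arm: str = "5p", loop_len: int = 18, seed: int = 0
) -> tuple[str, str]:
    """Construct a precursor in which the mature and its star form a perfect
    duplex with canonical 2-nt 3' overhangs; returns (precursor, star), DNA.

    The star strand is the reverse complement of the mature minus its 2-nt 3'
    overhang, plus a free 2-nt 3' end of its own.  The loop is drawn from
    {A, C} so it cannot pair with itself.
    """
    mature_d = to_dna(mature)
    if set(mature_d) - set("ACGT"):
        raise ValueError(f"mature sequence contains non-ACGU bases: {mature!r}")
    if not 18 <= len(mature_d) <= 30:
        raise ValueError("mature length must be 18-30 nt")
    if loop_len < 3:
        raise ValueError("loop must be at least 3 nt")
    if arm not in ("5p", "3p"):
        raise ValueError("arm must be '5p' or '3p'")
    rng = np.random.default_rng(seed)
    ac = np.array(["A", "C"])
    loop = "".join(ac[rng.integers(0, 2, size=loop_len)])
    overhang = "".join(ac[rng.integers(0, 2, size=2)])
    core = revcomp(mature_d[:-2])
    star = core + overhang
    if arm == "5p":
        precursor = mature_d + loop + star
    else:
        precursor = star + loop + mature_d
    return precursor, star


def plant_hairpin(
    genome: Mapping[str, str],
    mature: str,
    arm: str = "5p",
    loop_len: int = 18,
    seed: int = 0,
    name: str = "novel_1",
) -> tuple[dict[str, str], PlantedHairpin]:
    """Insert a constructed hairpin precursor into a copy of the genome."""
    precursor, star = build_hairpin(mature, arm=arm, loop_len=loop_len, seed=seed)
    rng = np.random.default_rng(seed)
    new_genome = dict(genome)
    contig = list(genome)[int(rng.integers(0, len(genome)))]
    seq = new_genome[contig]
    pos = int(rng.integers(0, len(seq) + 1))  # insertion point, 0-based
    new_genome[contig] = seq[:pos] + precursor + seq[pos:]
    truth = PlantedHairpin(
        name=name,
        contig=contig,
        start=pos + 1,
        end=pos + len(precursor),
        arm=arm,
        mature_seq=to_dna(mature),
        star_seq=star,
        precursor_seq=precursor,
    )
    return new_genome, truth


@dataclass
class SyntheticDataset:
    genome: dict[str, str]
    mature_ref: dict[str, str]  # reference name -> mature sequence (DNA)
    ncrna: dict[str, dict[str, str]]  # category -> {entry id: sequence}
    transcripts: dict[str, str]
    manifest: GroundTruthManifest

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {"genome": outdir / "genome.fa", "mature": outdir / "mature.fa",
                 "transcripts": outdir / "transcripts.fa"}
        write_fasta(self.genome, paths["genome"])
        write_fasta(self.mature_ref, paths["mature"])
        write_fasta(self.transcripts, paths["transcripts"])
        for cat, entries in self.ncrna.items():
            paths[cat] = outdir / f"{cat}.fa"
            write_fasta(entries, paths[cat])
        paths["manifest"] = outdir / "manifest.tsv"
        write_manifest(self.manifest, paths["manifest"])
        paths["config"] = outdir / "dataset.yaml"
        with open(paths["config"], "w") as fh:
            yaml.safe_dump(
                {
                    "seed": self.manifest.seed,
                    "nominal_depth": self.manifest.nominal_depth,
                    "mirna_fraction": self.manifest.mirna_fraction,
                    "noise_fractions": self.manifest.noise_fractions,
                },
                fh,
                sort_keys=True,
            )
        return paths


def build_dataset(
    n_known: int = 50,
    n_novel: int = 5,
    n_de: int = 20,
    genome_length: int = 100_000,
    n_contigs: int = 10,
    gc: float = 0.42,
    n_transcripts: int = 20,
    transcript_length: int = 1500,
    n_targets: int = 10,
    nominal_depth: int = 200_000,
    de_mean_range: tuple[float, float] = (600.0, 2500.0),
    de_log2_range: tuple[float, float] = (1.0, 3.0),
    background_mean_range: tuple[float, float] = (20.0, 2000.0),
    noise_composition: Mapping[str, float] | None = None,
    seed: int = 0,
) -> SyntheticDataset:
    """Assemble a full two-condition study with known ground truth.

    ``n_de`` of the ``n_known`` mature miRNAs carry true log2(Na200/CK)
    effects with magnitude drawn from ``de_log2_range`` (random sign) and a
    lower-side expected count drawn from ``de_mean_range`` at
    ``nominal_depth`` reads per library; the rest have equal means drawn
    log-uniformly from ``background_mean_range``.
    """
    if n_de > n_known:
        raise ValueError("cannot plant more DE effects than known miRNAs")
    rng = np.random.default_rng(seed)
    genome = generate_genome(genome_length, gc=gc, seed=seed + 1, n_contigs=n_contigs)

    # Planted features must stay intact and addressable: insertions avoid the
    # interior of earlier features, and downstream coordinates are shifted.
    intervals: dict[str, list[list]] = {c: [] for c in genome}  # [start, end, record]
    contig_names = list(genome)

    def _insert(ins_seq: str, record) -> None:
        contig = contig_names[int(rng.integers(0, len(contig_names)))]
        cseq = genome[contig]
        while True:
            pos = int(rng.integers(0, len(cseq) + 1))  # 0-based insertion point
            if all(not (iv[0] - 1 < pos < iv[1]) for iv in intervals[contig]):
                break
        genome[contig] = cseq[:pos] + ins_seq + cseq[pos:]
        shift = len(ins_seq)
        for iv in intervals[contig]:
            if iv[0] - 1 >= pos:
                iv[0] += shift
                iv[1] += shift
                iv[2].start += shift
                if hasattr(iv[2], "end"):
                    iv[2].end += shift
        record.contig = contig
        record.start = pos + 1
        if hasattr(record, "end"):
            record.end = pos + shift
        intervals[contig].append([pos + 1, pos + shift, record])

    # --- known miRNAs, planted into the genome ---------------------------
    planted_known: list[PlantedMirna] = []
    de_effects: dict[str, float] = {}
    member = {}
    de_idx = set(rng.choice(n_known, size=n_de, replace=False).tolist())
    for i in range(n_known):
        fam = _FAMILY_STEMS[i % len(_FAMILY_STEMS)]
        member[fam] = member.get(fam, 0) + 1
        name = f"rsa-{fam}{chr(ord('a') + member[fam] - 1)}"
        length = int(rng.choice([20, 21, 21, 21, 22]))
        seq = _random_seq(rng, length, gc=0.5)
        if i in de_idx:
            base = float(rng.uniform(*de_mean_range))
            lfc = float(rng.uniform(*de_log2_range)) * (1 if rng.random() < 0.5 else -1)
            if lfc >= 0:
                mean_ck, mean_na = base, base * 2**lfc
            else:
                mean_ck, mean_na = base * 2 ** (-lfc), base
            de_effects[name] = lfc
        else:
            lo, hi = background_mean_range
            mean_ck = mean_na = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        rec = PlantedMirna(name, fam, seq, "", 0, mean_ck, mean_na)
        _insert(seq, rec)
        planted_known.append(rec)

    # --- novel hairpins ---------------------------------------------------
    planted_novel: list[PlantedHairpin] = []
    for i in range(n_novel):
        mature = _random_seq(rng, 21, gc=0.5)
        arm = "5p" if i % 2 == 0 else "3p"
        precursor, star = build_hairpin(
            mature,
            arm=arm,
            loop_len=int(rng.integers(18, 29)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        mean = float(rng.uniform(200, 1000))
        truth = PlantedHairpin(
            name=f"novel_{i + 1}",
            contig="",
            start=0,
            end=0,
            arm=arm,
            mature_seq=mature,
            star_seq=star,
            precursor_seq=precursor,
            mean_mature_ck=mean,
            mean_mature_na=mean,
            mean_star_ck=1.5,
            mean_star_na=1.5,
        )
        _insert(precursor, truth)
        planted_novel.append(truth)

    # --- references -------------------------------------------------------
    mature_ref = {m.name: m.sequence for m in planted_known}
    ncrna = {
        "rRNA": {f"rRNA_{i + 1}": _random_seq(rng, 1500, gc=0.55) for i in range(3)},
        "tRNA": {f"tRNA_{i + 1}": _random_seq(rng, 75, gc=0.55) for i in range(10)},
        "snRNA": {f"snRNA_{i + 1}": _random_seq(rng, 150, gc=0.5) for i in range(5)},
        "snoRNA": {f"snoRNA_{i + 1}": _random_seq(rng, 120, gc=0.5) for i in range(5)},
    }

    # --- transcripts with planted target sites ---------------------------
    transcripts = {
        f"transcript_{i + 1}": _random_seq(rng, transcript_length, gc=0.45)
        for i in range(n_transcripts)
    }
    planted_sites: list[PlantedTargetSite] = []
    tids = list(transcripts)
    chosen = rng.choice(n_known, size=min(n_targets, n_known), replace=False)
    for k, mi in enumerate(sorted(chosen.tolist())):
        m = planted_known[mi]
        window = list(revcomp(m.sequence))  # perfect-complement site, 5'->3'
        n_wob = k % 3
        placed = 0
        L = len(m.sequence)
        for i in range(12, L):  # outside the 5'-end rule windows
            if placed >= n_wob:
                break
            b = m.sequence[i]  # DNA spelling; U is T
            if b == "G":
                window[L - 1 - i] = "T"
                placed += 1
            elif b == "T":
                window[L - 1 - i] = "G"
                placed += 1
        tid = tids[int(rng.integers(0, len(tids)))]
        seq = transcripts[tid]
        pos = int(rng.integers(0, len(seq) - L + 1))
        transcripts[tid] = seq[:pos] + "".join(window) + seq[pos + L :]
        planted_sites.append(PlantedTargetSite(m.name, tid, pos + 1, n_wobble=placed))

    # --- composition ------------------------------------------------------
    mean_total = sum(m.mean_ck for m in planted_known) + sum(
        h.mean_mature_ck + h.mean_star_ck for h in planted_novel
    )
    mirna_fraction = mean_total / nominal_depth
    if mirna_fraction >= 1:
        raise ValueError("planted means exceed the nominal depth")
    comp = dict(noise_composition or NOISE_COMPOSITION)
    s = sum(comp.values())
    noise_fractions = {k: v / s * (1 - mirna_fraction) for k, v in comp.items()}

    manifest = GroundTruthManifest(
        planted_known=planted_known,
        planted_novel=planted_novel,
        planted_de_effects=de_effects,
        planted_target_sites=planted_sites,
        noise_fractions=noise_fractions,
        mirna_fraction=mirna_fraction,
        nominal_depth=nominal_depth,
        seed=seed,
    )
    manifest.validate(genome)
    return SyntheticDataset(genome, mature_ref, ncrna, transcripts, manifest)


def draw_nb_counts(
    rng: np.random.Generator, mean: float, dispersion: float, size: int = 1
) -> np.ndarray:
    """Negative-binomial counts with the given mean and dispersion.

    Parameterized so Var = mean + dispersion * mean^2; dispersion 0 is Poisson.
    """
    if mean < 0:
        raise ValueError("mean must be non-negative")
    if mean == 0:
        return np.zeros(size, dtype=int)
    if dispersion <= 0:
        return rng.poisson(mean, size=size)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def _make_read(insert: str, adapter3: str, read_len: int) -> str:
    read = insert + adapter3
    while len(read) < read_len:
        read += adapter3
    return read[:read_len]


def simulate_libraries(
    dataset: SyntheticDataset,
    out_ck: str | Path,
    out_na: str | Path,
    depth_ck: int = 200_000,
    depth_na: int = 200_000,
    dispersion: float = 0.05,
    read_len: int = 50,
    adapter3: str = DEFAULT_ADAPTER3,
    adapter5: str = DEFAULT_ADAPTER5,
    degrade: float = 0.0,
    seed: Optional[int] = None,
) -> tuple[Path, Path]:
    """Write the two FASTQ libraries (Phred+33) for a synthetic dataset.

    Planted counts are negative-binomial around the manifest means scaled by
    depth/nominal_depth; noise categories fill their configured read
    fractions.  ``degrade`` > 0 additionally converts that fraction of reads
    to low-quality (mean Phred 8) to exercise the quality filter.
    Deterministic for a fixed seed (default: the manifest seed).
    """
    if depth_ck < 1 or depth_na < 1:
        raise ValueError("library depths must be at least 1")
    man = dataset.manifest
    man.validate(dataset.genome)
    rng = np.random.default_rng(man.seed if seed is None else seed)

    paths = (Path(out_ck), Path(out_na))
    for lib, path, depth in (("ck", paths[0], depth_ck), ("na", paths[1], depth_na)):
        scale = depth / man.nominal_depth
        entries: list[tuple[str, int]] = []  # (insert, copies)
        for m in man.planted_known:
            mean = (m.mean_ck if lib == "ck" else m.mean_na) * scale
            entries.append((m.sequence, int(draw_nb_counts(rng, mean, dispersion)[0])))
        for h in man.planted_novel:
            mean = (h.mean_mature_ck if lib == "ck" else h.mean_mature_na) * scale
            entries.append((h.mature_seq, int(draw_nb_counts(rng, mean, dispersion)[0])))
            smean = (h.mean_star_ck if lib == "ck" else h.mean_star_na) * scale
            entries.append((h.star_seq, int(draw_nb_counts(rng, smean, dispersion)[0])))

        frac = man.noise_fractions
        n_cat = {k: int(round(depth * frac.get(k, 0.0))) for k in frac}
        tail5 = adapter5[-8:] if adapter5 else ""

        # category inserts
        noise: list[str] = []
        for _ in range(n_cat.get("adapter_only", 0)):
            noise.append("")
        for _ in range(n_cat.get("adapter5", 0)):
            noise.append(tail5 + _random_seq(rng, 21))
        for _ in range(n_cat.get("short", 0)):
            noise.append(_random_seq(rng, int(rng.integers(10, 18))))
        for _ in range(n_cat.get("polyA", 0)):
            noise.append("A" * int(rng.integers(18, 26)))
        for cat in ("rRNA", "tRNA", "snRNA", "snoRNA"):
            pool = list(dataset.ncrna.get(cat, {}).values())
            for _ in range(n_cat.get(cat, 0)):
                src = pool[int(rng.integers(0, len(pool)))]
                ln = int(rng.integers(18, 29))
                start = int(rng.integers(0, max(1, len(src) - ln + 1)))
                noise.append(src[start : start + ln])
        n_random = n_cat.get("random", 0)
        if n_random:
            lens = rng.choice(
                [18, 19, 20, 21, 22, 23, 24],
                size=n_random,
                p=[0.025, 0.025, 0.15, 0.40, 0.15, 0.10, 0.15],
            )
            mat = rng.integers(0, 4, size=(n_random, 24))
            for ln, row in zip(lens, mat):
                noise.append("".join(_BASES[row[:ln]]))

        def records():
            i = 0
            for insert, copies in entries:
                read = _make_read(insert, adapter3, read_len)
                for _ in range(copies):
                    i += 1
                    yield f"{lib}_{i}", read, "I" * len(read)
            degraded = 0
            n_degrade = int(round(degrade * depth))
            for insert in noise:
                read = _make_read(insert, adapter3, read_len)
                i += 1
                if degraded < n_degrade:
                    degraded += 1
                    yield f"{lib}_{i}", read, ")" * len(read)
                else:
                    yield f"{lib}_{i}", read, "I" * len(read)

        with open(path, "w") as fh:
            for title, seq, qual in records():
                fh.write(f"@{title}\n{seq}\n+\n{qual}\n")
    return paths


def write_manifest(manifest: GroundTruthManifest, path: str | Path) -> None:
    """Ground truth as a sectioned tab-separated file."""
    with open(path, "w") as fh:
        fh.write("#section\tname\tfields...\n")
        for m in manifest.planted_known:
            lfc = manifest.planted_de_effects.get(m.name, 0.0)
            fh.write(
                f"known\t{m.name}\t{m.family}\t{m.sequence}\t{m.contig}\t{m.start}"
                f"\t{m.mean_ck:.3f}\t{m.mean_na:.3f}\t{lfc:.4f}\n"
            )
        for h in manifest.planted_novel:
            fh.write(
                f"novel\t{h.name}\t{h.contig}\t{h.start}\t{h.end}\t{h.arm}"
                f"\t{h.mature_seq}\t{h.star_seq}\n"
            )
        for s in manifest.planted_target_sites:
            fh.write(
                f"target\t{s.mirna}\t{s.transcript}\t{s.start}\t{s.n_wobble}\t{s.n_mismatch}\n"
            )
        for cat, fr in sorted(manifest.noise_fractions.items()):
            fh.write(f"noise\t{cat}\t{fr:.6f}\n")
        fh.write(f"noise\tmiRNA\t{manifest.mirna_fraction:.6f}\n")
        fh.write(f"meta\tseed\t{manifest.seed}\n")
        fh.write(f"meta\tnominal_depth\t{manifest.nominal_depth}\n")
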