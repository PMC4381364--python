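"""End-to-end orchestration: clean -> collapse -> annotate -> known -> novel
-> differential expression -> targets, with table outputs mirroring the
conventional sRNA-study summaries."""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from ._util import read_fasta
from .annotate import GenomeIndex, category_summary, classify
from .diffexpr import build_records, call_regulation, expression_table
from .known import MirnaMatch, family_of, family_table, member_table
from .novel import find_novel
from .preprocess import (
    DEFAULT_ADAPTER3,
    DEFAULT_ADAPTER5,
    CleaningReport,
    clean_reads,
    cleaning_table,
    collapse,
    compare_libraries,
    length_distribution,
    read_collapsed_fasta,
    write_collapsed_fasta,
)
from .targets import hits_table, scan

logger = logging.getLogger("saltmir")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for context."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineConfig:
    """All inputs and thresholds of one pipeline run.

    Thresholds default to the study conventions: 18-30 nt length window
    (15-30 reachable via ``min_len``), <=2 mismatches for known miRNAs,
    log2 fold-change cut 0.5 with p < 0.05, hairpin MFE ceiling -18.0
    kcal/mol, 150 nt precursor flank.
    """

    fastq_ck: str = ""
    fastq_na: str = ""
    genome: str = ""
    mature_ref: str = ""
    rrna: str = ""
    trna: str = ""
    snrna: str = ""
    snorna: str = ""
    transcripts: str = ""
    outdir: str = "saltmir_out"
    min_len: int = 18
    max_len: int = 30
    min_qual: float = 20.0
    adapter3: str = DEFAULT_ADAPTER3
    adapter5: str = DEFAULT_ADAPTER5
    max_mm: int = 2
    fc_cut: float = 0.5
    p_cut: float = 0.05
    pvalue_method: str = "binomial"
    mfe_max: float = -18.0
    flank: int = 150
    novel_min_count: int = 10
    fold_backend: str = "auto"
    no_wobble: bool = False
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def validate(self) -> None:
        for name in ("fastq_ck", "fastq_na", "genome", "mature_ref"):
            p = getattr(self, name)
            if not p or not Path(p).exists():
                raise PipelineError("config", f"required input {name!r} missing: {p!r}")
        if not 0 < self.min_len <= self.max_len:
            raise PipelineError("config", "invalid length window")
        if self.mfe_max > 0:
            raise PipelineError("config", "mfe_max must be <= 0")


@dataclass
class PipelineResult:
    outdir: Path
    reports: dict[str, CleaningReport]
    tags: dict
    annotated: list
    known_matches: list
    families: pd.DataFrame
    novel: list
    expression: pd.DataFrame
    targets: pd.DataFrame
    tables: dict[str, Path] = field(default_factory=dict)


def _write_tsv(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def run_all(config: PipelineConfig, resume: bool = False) -> PipelineResult:
    """Run every stage in order and write the table analogues.

    ``resume`` reuses the cached clean/collapse output in ``outdir`` when
    present (the most expensive stage); all downstream stages recompute.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    logger.info("saltmir %s | python %s", __version__, sys.version.split()[0])
    logger.info("config: %s", json.dumps(asdict(config), sort_keys=True))
    tables: dict[str, Path] = {}

    try:
        # --- clean + collapse (cached for resume) ------------------------
        stage = "clean"
        cache_fa = outdir / "collapsed.fa"
        cache_meta = outdir / "cleaning.json"
        if resume and cache_fa.exists() and cache_meta.exists():
            logger.info("resuming from cached collapse output")
            tags = read_collapsed_fasta(cache_fa)
            meta = json.loads(cache_meta.read_text())
            reports = {lib: CleaningReport(**meta[lib]) for lib in ("ck", "na")}
        else:
            clean_ck, rep_ck = clean_reads(
                config.fastq_ck, config.min_len, config.max_len,
                config.min_qual, config.adapter3, config.adapter5,
            )
            clean_na, rep_na = clean_reads(
                config.fastq_na, config.min_len, config.max_len,
                config.min_qual, config.adapter3, config.adapter5,
            )
            reports = {"ck": rep_ck, "na": rep_na}
            stage = "collapse"
            tags = collapse(clean_ck, clean_na)
            write_collapsed_fasta(tags, cache_fa)
            cache_meta.write_text(json.dumps({k: asdict(v) for k, v in reports.items()}))
        logger.info(
            "clean reads ck=%d na=%d, unique tags=%d",
            reports["ck"].clean_reads, reports["na"].clean_reads, len(tags),
        )
        tables["table1_cleaning"] = _write_tsv(cleaning_table(reports), outdir / "table1_cleaning.tsv")

        stage = "compare"
        comparison = compare_libraries(tags.values())
        tables["table3_common_specific"] = _write_tsv(
            comparison.to_frame(), outdir / "table3_common_specific.tsv"
        )
        lengths = length_distribution(tags.values())
        ldf = pd.DataFrame(
            [
                {"length": ln, "ck_pct": lengths["ck"].get(ln, 0.0), "na_pct": lengths["na"].get(ln, 0.0)}
                for ln in sorted(set(lengths["ck"]) | set(lengths["na"]))
            ]
        )
        tables["fig1_length_distribution"] = _write_tsv(ldf, outdir / "fig1_length_distribution.tsv")

        # --- annotation ---------------------------------------------------
        stage = "annotate"
        genome = read_fasta(config.genome)
        index = GenomeIndex(genome)
        mature_ref = read_fasta(config.mature_ref)
        ncrna = {}
        for cat, attr in (("rRNA", "rrna"), ("tRNA", "trna"), ("snRNA", "snrna"), ("snoRNA", "snorna")):
            path = getattr(config, attr)
            ncrna[cat] = read_fasta(path) if path and Path(path).exists() else {}
        annotated = classify(
            tags.values(), ncrna, mature_ref, genome=index, max_mm=config.max_mm
        )
        tables["table2_categories"] = _write_tsv(
            category_summary(annotated), outdir / "table2_categories.tsv"
        )

        # --- known miRNAs -------------------------------------------------
        stage = "known"
        known_matches = [
            MirnaMatch(at.tag, at.mirna_name, family_of(at.mirna_name), at.mirna_mismatches)
            for at in annotated
            if at.category == "miRNA" and at.mirna_name
        ]
        families = family_table(known_matches)
        tables["table4_families"] = _write_tsv(families, outdir / "table4_families.tsv")
        members = member_table(known_matches)
        tables["table4b_members"] = _write_tsv(members, outdir / "table4b_members.tsv")

        # --- novel miRNAs -------------------------------------------------
        stage = "novel"
        novel = find_novel(
            annotated,
            index,
            tags=tags,
            flank=config.flank,
            min_count=config.novel_min_count,
            mfe_max=config.mfe_max,
            backend=config.fold_backend,
        )
        novel_df = pd.DataFrame(
            [
                {
                    "name": c.name,
                    "mature": c.mature_seq,
                    "length": len(c.mature_seq),
                    "precursor_length": len(c.precursor_seq),
                    "count_ck": c.count_ck,
                    "count_na": c.count_na,
                    "star": c.star_seq or "",
                    "star_count_ck": c.star_count_ck,
                    "star_count_na": c.star_count_na,
                    "mfe": c.mfe,
                    "arm": c.mature_arm,
                    "location": f"{c.contig}:{c.window[0]}-{c.window[1]}({c.strand})",
                    "backend": c.backend,
                }
                for c in novel
            ],
            columns=[
                "name", "mature", "length", "precursor_length", "count_ck", "count_na",
                "star", "star_count_ck", "star_count_na", "mfe", "arm", "location", "backend",
            ],
        )
        tables["table5_novel"] = _write_tsv(novel_df, outdir / "table5_novel.tsv")
        with open(outdir / "novel_precursors.fa", "w") as fh:
            for c in novel:
                fh.write(f">{c.name}\n{c.precursor_seq}\n")
        with open(outdir / "novel_structures.txt", "w") as fh:
            for c in novel:
                fh.write(f">{c.name}\n{c.precursor_seq}\n{c.structure} ({c.mfe:.1f})\n")

        # --- differential expression --------------------------------------
        stage = "diffexpr"
        counts: dict[str, tuple[int, int]] = {}
        for _, row in members.iterrows():
            counts[row["reference"]] = (int(row["reads_ck"]), int(row["reads_na"]))
        for c in novel:
            counts[c.name] = (c.count_ck, c.count_na)
        n1 = max(1, reports["ck"].clean_reads)
        n2 = max(1, reports["na"].clean_reads)
        records = build_records(counts, n1, n2, method=config.pvalue_method)
        records, summary = call_regulation(records, fc_cut=config.fc_cut, p_cut=config.p_cut)
        expression = expression_table(records)
        tables["table6_diffexpr"] = _write_tsv(expression, outdir / "table6_diffexpr.tsv")
        logger.info("differential expression: %d up, %d down", summary["up"], summary["down"])

        # --- target prediction --------------------------------------------
        stage = "targets"
        hits = []
        if config.transcripts and Path(config.transcripts).exists():
            transcripts = read_fasta(config.transcripts)
            novel_by_name = {c.name: c.mature_seq for c in novel}
            for rec in records:
                if rec.call == "unchanged":
                    continue
                seq = mature_ref.get(rec.mirna) or novel_by_name.get(rec.mirna)
                if seq:
                    hits.extend(
                        scan(seq, transcripts, mirna_name=rec.mirna, no_wobble=config.no_wobble)
                    )
        targets_df = hits_table(hits)
        tables["targets"] = _write_tsv(targets_df, outdir / "targets.tsv")
    except PipelineError:
        raise
    except Exception as exc:
        logger.exception("stage %s failed", stage)
        raise PipelineError(stage, str(exc)) from exc
    finally:
        logger.removeHandler(handler)
        handler.close()

    return PipelineResult(
        outdir=outdir,
        reports=reports,
        tags=tags,
        annotated=annotated,
        known_matches=known_matches,
        families=families,
        novel=novel,
        expression=expression,
        targets=targets_df,
        tables=tables,
    )
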