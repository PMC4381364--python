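"""Generate a small two-condition sRNA study and run the whole pipeline.

Builds a synthetic genome with planted known miRNAs, novel hairpins and
differential-expression effects, simulates two FASTQ libraries (control CK
vs salt-treated Na200), runs clean -> collapse -> annotate -> known -> novel
-> diffexpr -> targets, and reports how much of the planted signal the
pipeline recovered.
"""

import tempfile
from pathlib import Path

import saltmir as sm

tmp = Path(tempfile.mkdtemp(prefix="saltmir_example_"))
ds = sm.build_dataset(
    n_known=20, n_novel=3, n_de=8,
    genome_length=50_000, nominal_depth=60_000,
    de_mean_range=(400.0, 1500.0), seed=7,
)
paths = ds.write(tmp / "refs")
sm.simulate_libraries(ds, tmp / "ck.fastq", tmp / "na.fastq",
                      depth_ck=60_000, depth_na=60_000, seed=7)

config = sm.PipelineConfig(
    fastq_ck=str(tmp / "ck.fastq"), fastq_na=str(tmp / "na.fastq"),
    genome=str(paths["genome"]), mature_ref=str(paths["mature"]),
    rrna=str(paths["rRNA"]), trna=str(paths["tRNA"]),
    snrna=str(paths["snRNA"]), snorna=str(paths["snoRNA"]),
    transcripts=str(paths["transcripts"]), outdir=str(tmp / "out"), seed=7,
)
result = sm.run_all(config)

man = ds.manifest
matched = {m.reference_name for m in result.known_matches}
known_rec = sum(1 for m in man.planted_known if m.name in matched)
novel_mature = {c.mature_seq.replace("U", "T") for c in result.novel}
novel_rec = sum(1 for h in man.planted_novel if h.mature_seq in novel_mature)
expr = result.expression.set_index("mirna")
de_ok = sum(
    1 for name, lfc in man.planted_de_effects.items()
    if name in expr.index and expr.loc[name, "call"] == ("up" if lfc > 0 else "down")
)

print(f"clean reads: CK={result.reports['ck'].clean_reads} Na200={result.reports['na'].clean_reads}")
print(f"unique tags: {len(result.tags)}")
print(f"known miRNAs recovered: {known_rec}/{len(man.planted_known)}")
print(f"novel hairpins passing: {novel_rec}/{len(man.planted_novel)}")
print(f"DE effects called with correct direction: {de_ok}/{len(man.planted_de_effects)}")
print(f"tables written under {result.outdir}")
# Recovery fractions near 1 mean the pipeline finds what was planted;
# the tables mirror the conventional sRNA-study summaries.
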