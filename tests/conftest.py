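import numpy as np
import pytest

import saltmir as sm


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_study(tmp_path_factory):
    """A scaled-down synthetic study run end to end once per session."""
    tmp = tmp_path_factory.mktemp("study")
    ds = sm.build_dataset(
        n_known=12,
        n_novel=2,
        n_de=5,
        genome_length=30_000,
        n_contigs=5,
        n_transcripts=8,
        transcript_length=800,
        n_targets=4,
        nominal_depth=30_000,
        de_mean_range=(200.0, 800.0),
        background_mean_range=(10.0, 300.0),
        seed=11,
    )
    paths = ds.write(tmp / "refs")
    sm.simulate_libraries(
        ds, tmp / "ck.fastq", tmp / "na.fastq", depth_ck=30_000, depth_na=30_000, seed=11
    )
    config = sm.PipelineConfig(
        fastq_ck=str(tmp / "ck.fastq"),
        fastq_na=str(tmp / "na.fastq"),
        genome=str(paths["genome"]),
        mature_ref=str(paths["mature"]),
        rrna=str(paths["rRNA"]),
        trna=str(paths["tRNA"]),
        snrna=str(paths["snRNA"]),
        snorna=str(paths["snoRNA"]),
        transcripts=str(paths["transcripts"]),
        outdir=str(tmp / "out"),
        seed=11,
    )
    result = sm.run_all(config)
    return {"dataset": ds, "config": config, "result": result, "tmp": tmp}
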