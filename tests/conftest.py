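import pytest

from lncorth.pipeline import PipelineConfig, run_pipeline
from lncorth.synthetic_data import WorldSpec, generate_world


@pytest.fixture(scope="session")
def default_world(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("world")
    return generate_world(WorldSpec(seed=0), outdir)


def world_config(world, seed=0, **overrides) -> PipelineConfig:
    kwargs = dict(
        src_genome=str(world.paths["src_genome.fa"]),
        src_coding_gtf=str(world.paths["src_coding.gtf"]),
        tgt_coding_gtf=str(world.paths["tgt_coding.gtf"]),
        sample_gtfs=[
            str(world.paths[f"sample_{k}.gtf"]) for k in range(world.spec.n_samples)
        ],
        maf=str(world.paths["alignment.maf"]),
        counts_tsv=str(world.paths["counts.tsv"]),
        conditions_tsv=str(world.paths["conditions.tsv"]),
        lengths_tsv=str(world.paths["gene_lengths.tsv"]),
        seed=seed,
    )
    kwargs.update(overrides)
    return PipelineConfig(**kwargs)


@pytest.fixture(scope="session")
def pipeline_run(default_world, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("run")
    manifest = run_pipeline(world_config(default_world), outdir)
    return {"world": default_world, "outdir": outdir, "manifest": manifest}
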