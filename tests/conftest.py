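import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cpehmr.pipeline import build_group_matrices, load_study, PipelineConfig
from cpehmr.synthetic_data import SyntheticConfig, generate_study

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_study(tmp_path_factory):
    """Full-size synthetic study (24/33/25/14 promoters x 11 stages) on disk."""
    outdir = tmp_path_factory.mktemp("study")
    truth = generate_study(SyntheticConfig(seed=0), outdir)
    return truth


@pytest.fixture(scope="session")
def study_config(default_study, tmp_path_factory):
    d = default_study.paths
    return PipelineConfig(
        annotation=str(d["annotation"]),
        transcripts_bed=str(d["transcripts_bed"]),
        peaks_dir=str(d["peaks_dir"]),
        expression_tsv=str(d["expression"]),
        promoters_fasta=str(d["promoters_fasta"]),
        output_dir=str(tmp_path_factory.mktemp("out")),
        cluster_n_iter=2000,
        kmeans_restarts=20,
        ntree=100,
        seed=0,
    )


@pytest.fixture(scope="session")
def study_matrices(study_config):
    """Per-group HMR matrices with expression, from the default study files."""
    promoters, transcripts, tracks, expression = load_study(study_config)
    return build_group_matrices(promoters, transcripts, tracks, expression)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
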