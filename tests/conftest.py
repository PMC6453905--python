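import numpy as np
import pandas as pd
import pytest

from surfdbm.catalogue import filter_to_surfaceome, load_surfaceome
from surfdbm.cli import RunConfig, run_pipeline
from surfdbm.expression import (
    STAGES,
    ExpressionMatrix,
    SampleMeta,
    aggregate_to_genes,
    assemble_matrix,
    read_abundance,
    read_sample_sheet,
    read_t2g,
)
from surfdbm.synthetic import SyntheticConfig, generate_dataset

DEFAULT_SEED = 1


def make_metas(n_replicates: int = 1) -> list[SampleMeta]:
    """2 genotypes x 4 stages x n replicates, transgenic first."""
    metas = []
    for genotype, tag in (("transgenic", "tg"), ("wildtype", "wt")):
        for stage in STAGES:
            for rep in range(1, n_replicates + 1):
                metas.append(SampleMeta(f"{tag}_{stage}_r{rep}", genotype, stage, rep))
    return metas


def make_matrix(values: dict[str, list[float]], metas: list[SampleMeta]) -> ExpressionMatrix:
    df = pd.DataFrame.from_dict(values, orient="index", columns=[m.sample_id for m in metas])
    return ExpressionMatrix(values=df.astype(float), samples=metas, unit="TPM")


@pytest.fixture
def metas8() -> list[SampleMeta]:
    return make_metas(1)


@pytest.fixture
def toy_matrix(metas8) -> ExpressionMatrix:
    """5 genes, 1 replicate per (genotype, stage); G1 is up everywhere, G5 down everywhere."""
    values = {
        # columns: tg DN1..DN4, wt DN1..DN4
        "G1": [25, 30, 40, 25, 2, 2, 3, 2],
        "G2": [2, 2, 2, 2, 2, 2, 2, 2],
        "G3": [0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5],
        "G4": [0.05, 15, 0.05, 15, 0.05, 0.05, 0.05, 0.05],
        "G5": [0.2, 0.2, 0.2, 0.2, 15, 15, 15, 15],
    }
    return make_matrix(values, metas8)


@pytest.fixture(scope="session")
def default_dataset(tmp_path_factory):
    """The default synthetic dataset at a fixed seed, shared across tests."""
    d = tmp_path_factory.mktemp("dataset")
    cfg = SyntheticConfig(seed=DEFAULT_SEED)
    truth = generate_dataset(cfg, d)
    return d, cfg, truth


@pytest.fixture(scope="session")
def default_surf_matrix(default_dataset) -> ExpressionMatrix:
    """Surfaceome-filtered TPM matrix assembled from the default dataset's files."""
    d, _, _ = default_dataset
    sheet = read_sample_sheet(d / "samples.tsv")
    t2g = read_t2g(d / "t2g.tsv")
    per = {m.sample_id: aggregate_to_genes(read_abundance(p), t2g) for m, p in sheet}
    matrix = assemble_matrix(per, [m for m, _ in sheet], unit="TPM", species="mouse")
    db = load_surfaceome(d / "surfaceome.tsv", "mouse")
    return filter_to_surfaceome(matrix, db)


@pytest.fixture(scope="session")
def default_run(default_dataset, tmp_path_factory):
    """A complete pipeline run over the default dataset."""
    d, _, truth = default_dataset
    out = tmp_path_factory.mktemp("run")
    cfg = RunConfig(
        sample_sheet=d / "samples.tsv", t2g=d / "t2g.tsv", surfaceome=d / "surfaceome.tsv"
    )
    report = run_pipeline(cfg, out)
    return out, report, truth
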