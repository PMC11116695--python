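import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from cmifuse import (
    EmbedderConfig,
    FusionConfig,
    PipelineConfig,
    SyntheticSpec,
    generate_benchmark,
)
from cmifuse.data_io import SequenceRecord


def random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGU"))[rng.integers(0, 4, size=length)])


@pytest.fixture(scope="session")
def mirna_corpus() -> list[SequenceRecord]:
    rng = np.random.default_rng(11)
    return [
        SequenceRecord(f"m{i:03d}", "miRNA", random_rna(rng, int(rng.integers(20, 23))))
        for i in range(50)
    ]


@pytest.fixture(scope="session")
def small_benchmark():
    """Reduced planted-block benchmark for pipeline-level unit tests.

    Two blocks with strong contrast and motif-rich short circRNAs, so
    both the sequence pathway and the graph pathway carry clearly
    recoverable signal at unit-test scale.
    """
    return generate_benchmark(
        SyntheticSpec(
            n_circ=60,
            n_mirna=40,
            n_blocks=2,
            p_in=0.35,
            p_out=0.02,
            circ_len_range=(100, 200),
            motif_copies_circ=8,
            seed=7,
        )
    )


def fast_pipeline_config(seed: int = 0, **overrides) -> PipelineConfig:
    """Pipeline settings scaled down for unit-test runtime."""
    defaults = dict(
        embedder=EmbedderConfig(n_layers=2, hidden=64, n_heads=4, epochs=50, seed=0),
        line_dim=32,
        line_samples_per_edge=200,
        fusion=FusionConfig(k=32, epochs=150, infer_steps=300, seed=0),
        classifier_params={"n_estimators": 200, "max_depth": 4},
        n_folds=3,
        seed=seed,
    )
    defaults.update(overrides)
    return PipelineConfig(**defaults)
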