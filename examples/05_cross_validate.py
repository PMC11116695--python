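"""Cross-validate the full pipeline on a small planted benchmark.

Fold-safe mode refits the graph embedding and fusion network inside each
training fold, so no test edge or test sample can leak into features.
"""

from cmifuse import (
    EmbedderConfig,
    FusionConfig,
    PipelineConfig,
    SyntheticSpec,
    cross_validate,
    generate_benchmark,
)

bench = generate_benchmark(
    SyntheticSpec(
        n_circ=60, n_mirna=40, n_blocks=2, p_in=0.35, p_out=0.02,
        circ_len_range=(100, 200), motif_copies_circ=8, seed=7,
    )
)
config = PipelineConfig(
    embedder=EmbedderConfig(epochs=50, seed=0),
    line_dim=32,
    fusion=FusionConfig(k=32, epochs=150, infer_steps=300, seed=0),
    classifier_params={"n_estimators": 200, "max_depth": 4},
    n_folds=3,
    seed=0,
)

report = cross_validate(
    bench.circ_records, bench.mirna_records, bench.interactions, config
)
print(report.summary())

# AUC well above 0.5 = the pipeline recovered planted structure through
# leakage-safe features; each +/- value is the SD across folds.
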