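"""Run the full comparison pipeline: raw vs random vs model augmentation.

The pipeline fixes one D2 train/validation/test split, trains M1 on D1,
checks it against a top-3 accuracy gate, builds the requested training
cohorts, trains one cost model per mode, and evaluates all of them on the
same test patients.  Two runs with the same configuration produce
byte-identical report JSON.  Runs in a few minutes on one CPU.
"""

from osacost import PipelineConfig, SyntheticConfig, run_pipeline
from osacost.pipeline import render_report_markdown

model = dict(
    d_model=32, n_heads=4, n_encoder_layers=1, n_decoder_layers=1,
    feedforward_width=64, dropout=0.1, max_input_len=64,
)
config = PipelineConfig(
    synthetic=SyntheticConfig(n_patients=600, n_cost_types=8, seed=21),
    modes=("none", "random", "transformer"),
    sample_ratio=0.55,
    iterations=3,
    # the held-out top-3 accuracy M1 must reach before its augmentations
    # are trusted; on stochastic synthetic dynamics the Bayes-optimal
    # accuracy is well below the 0.91 default, so relax the gate here
    gate_threshold=0.5,
    seed=21,
    m1_model=dict(model, max_target_len=4),
    m2_model=dict(model, max_target_len=24),
    m1_train=dict(epochs=15, batch_size=32, learning_rate=1e-3),
    m2_train=dict(epochs=15, batch_size=32, learning_rate=1e-3),
    out_dir="pipeline_out",
)

report = run_pipeline(config)
print(f"|D1| = {report['n_d1']}  |D2| = {report['n_d2']}  "
      f"test patients = {report['n_test_patients']}")
print(f"M1 held-out top-k: {report['m1_top_k']}")
print()
print(render_report_markdown(report))
print("full report written to pipeline_out/report.json")
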