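"""Recursive forest elimination on data with five planted effects."""

from ewasrf import ForestParams, SimulationConfig, generate_dataset, recursive_rf

cfg = SimulationConfig(n_samples_stage1=200, n_samples_stage2=0, n_probes=500,
                       n_informative=5, effect_size=2.0, seed=0)
dataset, _, phenotype, _, truth = generate_dataset(cfg)

trace = recursive_rf(dataset.beta.T, phenotype["atopy"],
                     ForestParams(ntree=500, mtry="0.1p", sampsize=(50, 50),
                                  seed=0),
                     focal_class=1, stop_policy="global_min",
                     max_iterations=8)
print(trace.to_frame().round(2).to_string(index=False))
print(f"selected iteration {trace.selected_iteration} "
      f"({len(trace.selected_variables)} probes)")
hits = truth.informative_probes & set(trace.selected_variables)
print(f"planted probes recovered: {len(hits)} of "
      f"{len(truth.informative_probes)}")
# Halving the variable set sharpens the atopic-class (error_1) trajectory
# until noise probes are gone; the selected iteration minimizes that error,
# and the surviving set contains the planted signal.
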